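"""Site identification, filtering, polarization and matched-control
construction.

A "site table" is a pandas DataFrame with one row per candidate site
(columns as in :data:`cubdfe.io.SITE_TABLE_COLUMNS`, plus optional flag /
truth columns). Matching pairs every fourfold-degenerate (4D) site with a
short-intron (SI) site on the same chromosome within a distance cutoff
whose ancestral allele and 3-bp context agree under the four strand-blind
transforms, cancelling mutation-rate and linked-selection differences; 200
independent random assignments form the replicate control sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

from .codons import is_fourfold
from .errors import DataError, DomainError
from .io import read_bed
from .seq import canonical_context, comp, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedReplicate",
    "annotate_4d_sites",
    "extract_si_sites",
    "attach_alleles",
    "apply_filters",
    "downsample_haplotypes",
    "polarize",
    "match_controls",
    "match_by_state",
    "bootstrap_resample",
    "annotate_strata",
]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _load_db(annotation):
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def _transcript_layout(db, mrna, genome):
    """CDS bases of a transcript in translation order.

    Returns (positions0, bases, segment_id, segment_offsets) or None when
    the model is unusable; positions are 0-based reference coordinates,
    bases are coding-strand nucleotides.
    """
    cds = sorted(
        db.children(mrna, featuretype="CDS"), key=lambda f: f.start
    )
    if not cds:
        return None
    chrom = cds[0].seqid
    if chrom not in genome:
        raise DataError(f"sequence {chrom!r} missing from genome")
    seq = genome[chrom]
    strand = mrna.strand
    segs = cds if strand == "+" else cds[::-1]
    pos_chunks, base_chunks, seg_ids = [], [], []
    for si, f in enumerate(segs):
        p = np.arange(f.start - 1, f.end)  # 0-based
        b = seq[f.start - 1 : f.end]
        if strand == "-":
            p = p[::-1]
            b = revcomp(b)
        pos_chunks.append(p)
        base_chunks.append(b)
        seg_ids.append(np.full(len(p), si))
    positions = np.concatenate(pos_chunks)
    bases = "".join(base_chunks)
    seg = np.concatenate(seg_ids)
    phase = segs[0].frame
    offset = int(phase) if phase in ("0", "1", "2") else 0
    if offset:
        positions, bases, seg = positions[offset:], bases[offset:], seg[offset:]
    if len(bases) % 3 != 0:
        logger.warning(
            "CDS length of %s not divisible by 3; skipping model", mrna.id
        )
        return None
    return chrom, positions, bases, seg, len(segs)


def annotate_4d_sites(genome: dict, annotation) -> pd.DataFrame:
    """Third positions of fourfold-degenerate codons from a genome + GFF3.

    ``genome`` maps chrom -> sequence (see :func:`cubdfe.io.read_genome`);
    ``annotation`` is a GFF3 path or an open :class:`gffutils.FeatureDB`.
    Positions claimed by overlapping CDS with conflicting frames (different
    codon or strand at the same coordinate) are excluded.
    """
    db = _load_db(annotation)
    claims: dict = {}
    for mrna in db.features_of_type("mRNA"):
        layout = _transcript_layout(db, mrna, genome)
        if layout is None:
            continue
        chrom, positions, bases, seg, n_segs = layout
        parents = mrna.attributes.get("Parent", [mrna.id])
        gene_id = parents[0]
        seq = genome[chrom]
        # per-segment codon counts for relative exon position
        seg_start = {}
        for i, s in enumerate(seg):
            if s not in seg_start:
                seg_start[s] = i
        seg_len = {s: int(np.sum(seg == s)) for s in seg_start}
        for t in range(0, len(bases) - 2, 3):
            codon = bases[t : t + 3]
            if not is_fourfold(codon):
                continue
            pos0 = int(positions[t + 2])
            if pos0 < 1 or pos0 >= len(seq) - 1:
                continue
            s = int(seg[t + 2])
            if n_segs == 1:
                rank = "single"
            elif s == 0:
                rank = "first"
            elif s == n_segs - 1:
                rank = "last"
            else:
                rank = "internal"
            ci = (t + 2 - seg_start[s]) // 3
            ncod = max(1, int(np.ceil(seg_len[s] / 3)))
            record = (
                chrom,
                pos0 + 1,
                seq[pos0],
                seq[pos0 - 1 : pos0 + 2],
                gene_id,
                codon,
                mrna.strand,
                rank,
                (ci + 0.5) / ncod,
            )
            key = (chrom, pos0)
            if key in claims:
                prev = claims[key]
                if prev is not None and (prev[5], prev[6]) != (codon, mrna.strand):
                    claims[key] = None  # conflicting frames -> exclude
            else:
                claims[key] = record
    rows = [r for r in claims.values() if r is not None]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ancestral",
            "context3",
            "gene_id",
            "codon",
            "strand",
            "exon_rank",
            "exon_rel_pos",
        ],
    )
    df.insert(2, "site_class", "4D")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def extract_si_sites(
    genome: dict,
    annotation,
    length_threshold: int = 86,
    trim: int = 8,
    comparison: str = ">",
) -> pd.DataFrame:
    """Short-intron positions derived from the gaps between exons.

    Introns passing the length rule (``length > length_threshold`` by
    default; pass ``comparison="<="`` for the opposite convention)
    contribute all positions except the first and last ``trim`` bases.
    Introns shorter than ``2 * trim`` are silently excluded.
    """
    if comparison not in (">", "<="):
        raise DomainError("comparison must be '>' or '<='")
    db = _load_db(annotation)
    seen = set()
    rows = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
        if len(exons) < 2:
            continue
        chrom = exons[0].seqid
        if chrom not in genome:
            raise DataError(f"sequence {chrom!r} missing from genome")
        seq = genome[chrom]
        parents = mrna.attributes.get("Parent", [mrna.id])
        gene_id = parents[0]
        for a, b in zip(exons[:-1], exons[1:]):
            istart0, iend0 = a.end, b.start - 1  # half-open 0-based intron span
            length = iend0 - istart0
            if length <= 0:
                continue
            passes = length > length_threshold if comparison == ">" else (
                length <= length_threshold
            )
            if not passes or length <= 2 * trim:
                continue
            for pos0 in range(istart0 + trim, iend0 - trim):
                key = (chrom, pos0)
                if key in seen:
                    continue
                seen.add(key)
                rows.append(
                    (
                        chrom,
                        pos0 + 1,
                        seq[pos0],
                        seq[pos0 - 1 : pos0 + 2],
                        gene_id,
                        ".",
                        mrna.strand,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ancestral", "context3", "gene_id", "codon", "strand"],
    )
    df.insert(2, "site_class", "SI")
    df["exon_rank"] = "."
    df["exon_rel_pos"] = np.nan
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def attach_alleles(annotated: pd.DataFrame, alleles: pd.DataFrame) -> pd.DataFrame:
    """Join annotation rows with the per-site allele table on (chrom, pos).

    Brings over derived allele, derived count, haplotype number and any
    flag columns; sites absent from the allele table are dropped.
    """
    cols = ["chrom", "pos", "derived", "derived_count", "n_haplotypes"]
    extra = [
        c
        for c in alleles.columns
        if c not in cols + ["site_class", "ancestral", "context3", "gene_id",
                           "codon", "strand", "exon_rank", "exon_rel_pos",
                           "preferred", "theta_site"]
    ]
    merged = annotated.merge(
        alleles[cols + [c for c in extra if c not in ("chrom", "pos")]],
        on=["chrom", "pos"],
        how="inner",
    )
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _interval_membership(
    pos0: np.ndarray, chroms: np.ndarray, intervals: pd.DataFrame, pad: int = 0
) -> np.ndarray:
    """Boolean mask of 0-based positions falling inside (padded) 0-based
    half-open intervals."""
    out = np.zeros(len(pos0), dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        starts = np.maximum(sub["start"].to_numpy() - pad, 0)
        ends = sub["end"].to_numpy() + pad
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # merge overlaps
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        mask = chroms == chrom
        p = pos0[mask]
        idx = np.searchsorted(ms, p, side="right") - 1
        hit = (idx >= 0) & (p < me[np.clip(idx, 0, None)])
        out[mask] = hit
    return out


def apply_filters(
    sites: pd.DataFrame,
    mapq_min: float = 20,
    indel_window: int = 10,
    indels: pd.DataFrame | str | None = None,
) -> pd.DataFrame:
    """Remove low-quality sites, sites within ``indel_window`` bp of an
    indel (boundary inclusive) and sites with more than two alleles.

    Each filter runs only when its supporting column/track is present
    (``mapq`` or ``low_quality``; an indel BED; ``n_alleles``); missing
    tracks disable the filter with a logged warning. Removal counts are
    logged and stored in ``result.attrs["filter_counts"]``.
    """
    keep = np.ones(len(sites), dtype=bool)
    counts = {}
    if "mapq" in sites.columns:
        bad = sites["mapq"].to_numpy() < mapq_min
        counts["low_mapq"] = int((bad & keep).sum())
        keep &= ~bad
    elif "low_quality" in sites.columns:
        bad = sites["low_quality"].to_numpy().astype(bool)
        counts["low_quality"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        logger.warning("no mapping-quality column; quality filter disabled")
    if indels is not None:
        if not isinstance(indels, pd.DataFrame):
            indels = read_bed(indels)
        if len(indels):
            near = _interval_membership(
                sites["pos"].to_numpy() - 1,
                sites["chrom"].to_numpy(),
                indels,
                pad=indel_window,
            )
        else:
            near = np.zeros(len(sites), dtype=bool)
        counts["near_indel"] = int((near & keep).sum())
        keep &= ~near
    else:
        logger.warning("no indel track supplied; indel-proximity filter disabled")
    if "n_alleles" in sites.columns:
        multi = sites["n_alleles"].to_numpy() > 2
        counts["multiallelic"] = int((multi & keep).sum())
        keep &= ~multi
    out = sites[keep].reset_index(drop=True)
    logger.info("filters removed %s of %d sites", counts, len(sites))
    out.attrs["filter_counts"] = counts
    return out


def downsample_haplotypes(
    sites: pd.DataFrame, target_ns: int = 160, seed: int = 0
) -> pd.DataFrame:
    """Hypergeometric downsampling to a uniform haplotype count.

    Sites covered by at least ``target_ns`` haplotypes have their derived
    counts redrawn to exactly ``target_ns``; sites with fewer are dropped.
    """
    if target_ns < 2:
        raise DomainError("target_ns must be at least 2")
    n = sites["n_haplotypes"].to_numpy()
    k = sites["derived_count"].to_numpy()
    keep = n >= target_ns
    out = sites[keep].reset_index(drop=True)
    n, k = n[keep], k[keep]
    rng = np.random.default_rng(seed)
    new_k = rng.hypergeometric(k, n - k, target_ns)
    out = out.copy()
    out["derived_count"] = new_k
    out["n_haplotypes"] = target_ns
    out.loc[out["derived_count"] == 0, "derived"] = "."
    # derived copies that vanished (or fixed) stay recorded as monomorphic
    out.loc[out["derived_count"] == target_ns, ["derived_count"]] = 0
    out.loc[out["derived_count"] == 0, "derived"] = "."
    return out


def polarize(
    sites: pd.DataFrame,
    outgroup_col: str = "outgroup",
    reference_col: str = "reference",
) -> pd.DataFrame:
    """Parsimony polarization against an outgroup allele.

    The ancestral allele is the observed allele matching the outgroup when
    exactly one does; otherwise the reference allele is used and the site
    flagged ambiguous. Derived counts are re-expressed relative to the
    assigned ancestral allele and the context centre is kept consistent.
    """
    for col in (outgroup_col, reference_col):
        if col not in sites.columns:
            raise DataError(f"polarize requires column {col!r}")
    out = sites.copy()
    a1 = out["ancestral"].to_numpy(dtype=object)
    a2 = out["derived"].to_numpy(dtype=object)
    og = out[outgroup_col].to_numpy(dtype=object)
    ref = out[reference_col].to_numpy(dtype=object)
    counts = out["derived_count"].to_numpy().copy()
    ns = out["n_haplotypes"].to_numpy()
    ctx = out["context3"].to_numpy(dtype=object)
    source = np.empty(len(out), dtype=object)
    valid = set("ACGT")
    for i in range(len(out)):
        if a1[i] not in valid and a2[i] not in valid:
            raise DataError(f"site {i}: no nucleotide allele ({a1[i]!r}/{a2[i]!r})")
        if a2[i] not in valid:  # monomorphic
            source[i] = "monomorphic"
            continue
        if og[i] == a1[i] and og[i] != a2[i]:
            source[i] = "outgroup"
        elif og[i] == a2[i] and og[i] != a1[i]:
            a1[i], a2[i] = a2[i], a1[i]
            counts[i] = ns[i] - counts[i]
            ctx[i] = ctx[i][0] + a1[i] + ctx[i][2]
            source[i] = "outgroup"
        else:
            source[i] = "ambiguous"
            if ref[i] == a2[i] and ref[i] != a1[i]:
                a1[i], a2[i] = a2[i], a1[i]
                counts[i] = ns[i] - counts[i]
                ctx[i] = ctx[i][0] + a1[i] + ctx[i][2]
    out["ancestral"] = a1
    out["derived"] = a2
    out["derived_count"] = counts
    out["context3"] = ctx
    out["polarization"] = source
    return out


# ---------------------------------------------------------------------------
# matched controls
# ---------------------------------------------------------------------------


@dataclass
class MatchedReplicate:
    """One random 4D -> SI control assignment.

    ``fourd`` and ``si`` are parallel positional row indices into
    ``sites``; pair i matches ``sites.iloc[fourd[i]]`` with
    ``sites.iloc[si[i]]``. SI reuse across pairs is permitted.
    """

    replicate_id: int
    sites: pd.DataFrame
    fourd: np.ndarray
    si: np.ndarray

    def __len__(self) -> int:
        return len(self.fourd)

    def pairs(self) -> pd.DataFrame:
        left = self.sites.iloc[self.fourd].reset_index(drop=True)
        right = self.sites.iloc[self.si].reset_index(drop=True)
        return left.join(right, lsuffix="_4d", rsuffix="_si")

    def polymorphic_counts(self, stratum_mask: np.ndarray | None = None):
        """(P_4D, P_SI): polymorphic pair counts, optionally restricted to
        pairs whose 4D member lies in a stratum (boolean mask over sites rows)."""
        poly = (self.sites["derived_count"].to_numpy() > 0) & (
            self.sites["derived_count"].to_numpy()
            < self.sites["n_haplotypes"].to_numpy()
        )
        f, s = self.fourd, self.si
        if stratum_mask is not None:
            inside = stratum_mask[f]
            f, s = f[inside], s[inside]
        return int(poly[f].sum()), int(poly[s].sum())


def _candidate_pools(sites, fourd_mask, si_mask, max_dist, si_key, fourd_key):
    """Per-4D-site candidate SI pools under canonical-context matching.

    Returns (kept 4D row indices sorted by row order, pool start offsets,
    pool counts, flat candidate row-index array).
    """
    si_rows = np.flatnonzero(si_mask)
    si_df = pd.DataFrame(
        {
            "row": si_rows,
            "chrom": sites["chrom"].to_numpy()[si_rows],
            "pos": sites["pos"].to_numpy()[si_rows],
            "key": si_key,
        }
    ).sort_values(["chrom", "key", "pos"], kind="stable")
    groups = {
        name: (g["pos"].to_numpy(), g["row"].to_numpy())
        for name, g in si_df.groupby(["chrom", "key"], sort=False)
    }
    fourd_rows = np.flatnonzero(fourd_mask)
    fpos = sites["pos"].to_numpy()[fourd_rows]
    fchrom = sites["chrom"].to_numpy()[fourd_rows]
    kept, cand_chunks, counts, starts = [], [], [], []
    offset = 0
    for i in range(len(fourd_rows)):
        grp = groups.get((fchrom[i], fourd_key[i]))
        if grp is None:
            continue
        p, rows = grp
        lo = np.searchsorted(p, fpos[i] - max_dist, side="left")
        hi = np.searchsorted(p, fpos[i] + max_dist, side="right")
        if hi <= lo:
            continue
        kept.append(fourd_rows[i])
        cand_chunks.append(rows[lo:hi])
        counts.append(hi - lo)
        starts.append(offset)
        offset += hi - lo
    if not kept:
        raise DataError("no 4D site has an eligible SI control")
    return (
        np.asarray(kept),
        np.asarray(starts),
        np.asarray(counts),
        np.concatenate(cand_chunks),
    )


def match_controls(
    sites: pd.DataFrame,
    n_replicates: int = 200,
    max_dist: int = 1000,
    seed: int = 0,
) -> list:
    """Build replicate matched 4D/SI control sets.

    For every 4D site the candidate pool is all SI sites on the same
    chromosome within ``max_dist`` bp whose (ancestral, 3-bp context) agree
    under a strand-blind transform; each replicate draws one candidate
    uniformly at random per 4D site. 4D sites with an empty pool are
    dropped before any replicate is built, so all replicates share an
    identical 4D site set.
    """
    fourd_mask = (sites["site_class"] == "4D").to_numpy()
    si_mask = (sites["site_class"] == "SI").to_numpy()
    if not fourd_mask.any() or not si_mask.any():
        raise DataError("need both 4D and SI sites to build matched controls")
    ctx = sites["context3"].to_numpy()
    si_key = np.array([canonical_context(c) for c in ctx[si_mask]])
    fourd_key = np.array([canonical_context(c) for c in ctx[fourd_mask]])
    kept, starts, counts, cand = _candidate_pools(
        sites, fourd_mask, si_mask, max_dist, si_key, fourd_key
    )
    replicates = []
    for r in range(1, n_replicates + 1):
        rng = np.random.default_rng([seed, r])
        pick = starts + (rng.random(len(kept)) * counts).astype(np.int64)
        replicates.append(
            MatchedReplicate(
                replicate_id=r,
                sites=sites,
                fourd=kept.astype(np.int32),
                si=cand[pick].astype(np.int32),
            )
        )
    return replicates


def match_by_state(
    sites: pd.DataFrame,
    ancestral_codon: str,
    derived_codon: str,
    max_dist: int = 1000,
    seed: int = 0,
    replicate_id: int = 1,
) -> MatchedReplicate:
    """State-matched control set for one synonymous codon change.

    Takes 4D sites whose ancestral codon is ``ancestral_codon`` and that
    are either monomorphic or polymorphic for exactly the specified
    third-position change, and matches each to an SI site that is
    monomorphic for the same ancestral base or polymorphic for the same
    base change (up to the strand-blind transforms), under the usual
    distance and context rules.
    """
    ancestral_codon = ancestral_codon.upper()
    derived_codon = derived_codon.upper()
    if (
        len(ancestral_codon) != 3
        or len(derived_codon) != 3
        or ancestral_codon[:2] != derived_codon[:2]
        or ancestral_codon[2] == derived_codon[2]
    ):
        raise DomainError(
            "codon pair must differ at the third position only "
            f"({ancestral_codon} -> {derived_codon})"
        )
    ctx = sites["context3"].to_numpy(dtype=object)
    derived = sites["derived"].to_numpy(dtype=object)
    strand = sites["strand"].to_numpy(dtype=object)
    codon = sites["codon"].to_numpy(dtype=object)
    si_mask = (sites["site_class"] == "SI").to_numpy()
    fourd_all = (sites["site_class"] == "4D").to_numpy()

    # per-site expected derived base on the reference strand
    d_ref = np.where(
        strand == "+", derived_codon[2], comp(derived_codon[2])
    )
    in_class = fourd_all & (codon == ancestral_codon) & (
        (derived == ".") | (derived == d_ref)
    )
    if not in_class.any():
        raise DataError("no 4D sites in the requested codon-change class")

    # SI state keys: canonical(context) for monomorphic sites,
    # canonical(context, derived) for polymorphic ones
    si_rows = np.flatnonzero(si_mask)
    si_key = np.array(
        [
            canonical_context(ctx[i])
            if derived[i] == "."
            else canonical_context(ctx[i], derived[i])
            for i in si_rows
        ]
    )
    fourd_rows = np.flatnonzero(in_class)
    # pool accepts either the monomorphic or the matching polymorphic key;
    # encode by matching twice and merging pools
    key_mono = np.array([canonical_context(ctx[i]) for i in fourd_rows])
    key_poly = np.array(
        [canonical_context(ctx[i], d_ref[i]) for i in fourd_rows]
    )

    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    si_by_key: dict = {}
    order = np.argsort(pos[si_rows], kind="stable")
    for j in order:
        i = si_rows[j]
        si_by_key.setdefault((chroms[i], si_key[j]), []).append(i)
    si_by_key = {
        k: (pos[np.asarray(v)], np.asarray(v)) for k, v in si_by_key.items()
    }

    rng = np.random.default_rng(seed)
    kept, chosen = [], []
    for idx, i in enumerate(fourd_rows):
        pools = []
        for key in {(chroms[i], key_mono[idx]), (chroms[i], key_poly[idx])}:
            grp = si_by_key.get(key)
            if grp is None:
                continue
            p, rows = grp
            lo = np.searchsorted(p, pos[i] - max_dist, side="left")
            hi = np.searchsorted(p, pos[i] + max_dist, side="right")
            if hi > lo:
                pools.append(rows[lo:hi])
        if not pools:
            continue
        pool = pools[0] if len(pools) == 1 else np.concatenate(pools)
        kept.append(i)
        chosen.append(int(pool[int(rng.random() * len(pool))]))
    if not kept:
        raise DataError("no matched SI control for the requested codon change")
    return MatchedReplicate(
        replicate_id=replicate_id,
        sites=sites,
        fourd=np.asarray(kept, dtype=np.int32),
        si=np.asarray(chosen, dtype=np.int32),
    )


def bootstrap_resample(replicate: MatchedReplicate, seed: int = 0) -> MatchedReplicate:
    """Resample the replicate's pairs with replacement (same pair count)."""
    n = len(replicate)
    if n == 0:
        raise DataError("cannot resample an empty replicate")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n)
    return MatchedReplicate(
        replicate_id=replicate.replicate_id,
        sites=replicate.sites,
        fourd=replicate.fourd[idx],
        si=replicate.si[idx],
    )


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------


def annotate_strata(sites: pd.DataFrame, strata: dict) -> pd.DataFrame:
    """Add stratum membership columns.

    ``strata`` maps a name to a definition dict:

    * ``{"kind": "bed", "path": ... | "intervals": DataFrame}`` ->
      boolean column ``stratum_<name>`` (BED is 0-based half-open);
    * ``{"kind": "recombination", "windows": DataFrame(chrom,start,end,rate)}``
      -> ``recomb_rate`` and tertile column ``recomb_group``;
    * ``{"kind": "fop", "per_gene": mapping gene_id -> FOP}`` ->
      quartile column ``fop_group`` (low/medium/high);
    * ``{"kind": "exon_position"}`` -> ``exon_position_group`` from the
      relative codon position (start / middle / end quartiles).
    """
    out = sites.copy()
    pos0 = out["pos"].to_numpy() - 1
    chroms = out["chrom"].to_numpy()
    for name, spec in strata.items():
        kind = spec.get("kind", "bed")
        if kind == "bed":
            intervals = spec.get("intervals")
            if intervals is None:
                intervals = read_bed(spec["path"])
            out[f"stratum_{name}"] = _interval_membership(pos0, chroms, intervals)
        elif kind == "recombination":
            win = spec["windows"]
            rate = np.full(len(out), np.nan)
            for chrom, sub in win.groupby("chrom"):
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                rates = sub["rate"].to_numpy()
                order = np.argsort(starts, kind="stable")
                starts, ends, rates = starts[order], ends[order], rates[order]
                mask = chroms == chrom
                idx = np.searchsorted(starts, pos0[mask], side="right") - 1
                ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
                vals = np.full(mask.sum(), np.nan)
                vals[ok] = rates[idx[ok]]
                rate[mask] = vals
            out["recomb_rate"] = rate
            finite = np.isfinite(rate)
            groups = np.full(len(out), ".", dtype=object)
            if finite.sum() >= 3:
                q1, q2 = np.quantile(rate[finite], [1 / 3, 2 / 3])
                groups[finite & (rate <= q1)] = "low"
                groups[finite & (rate > q1) & (rate <= q2)] = "medium"
                groups[finite & (rate > q2)] = "high"
            out["recomb_group"] = groups
        elif kind == "fop":
            per_gene = spec["per_gene"]
            fop = out["gene_id"].map(per_gene)
            vals = fop.dropna()
            groups = np.full(len(out), ".", dtype=object)
            if len(vals):
                q1, q3 = np.quantile(vals.to_numpy(dtype=float), [0.25, 0.75])
                f = fop.to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    groups[f <= q1] = "low"
                    groups[(f > q1) & (f <= q3)] = "medium"
                    groups[f > q3] = "high"
            out["fop_group"] = groups
        elif kind == "exon_position":
            rel = out["exon_rel_pos"].to_numpy(dtype=float)
            groups = np.full(len(out), ".", dtype=object)
            with np.errstate(invalid="ignore"):
                groups[rel < 0.25] = "start"
                groups[(rel >= 0.25) & (rel <= 0.75)] = "middle"
                groups[rel > 0.75] = "end"
            out["exon_position_group"] = groups
        else:
            raise DomainError(f"unknown stratum kind {kind!r} for {name!r}")
    return out
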