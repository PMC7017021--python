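"""Synthetic data generation.

Two levels of synthesis are provided:

* spectrum level — expected folded spectra under a categorical DFE and
  multinomial draws from them (:func:`simulate_sfs_counts`);
* site level — a full synthetic site table with genes, fourfold-degenerate
  codon sites carrying preference-dependent DFEs, short-intron neutral
  sites, 3-bp-context-dependent mutation rates, a smooth regional theta
  gradient standing in for linked selection, and optional indel /
  low-quality artifacts (:func:`simulate_site_table`). Companion FASTA /
  GFF3 / BED fixtures and a ground-truth manifest are emitted so the
  annotation and matching stages can be tested end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import FOURFOLD_FAMILIES, is_fourfold
from .errors import ConfigError, DomainError, ModelInvalidError
from .io import write_bed, write_genome, write_gff3, write_json, write_site_table
from .seq import NUCLEOTIDES, canonical_context, comp, revcomp
from .spectra import (
    LETHAL,
    AlphaCorrection,
    DFEClass,
    DFEModel,
    FoldedSFS,
    PopulationModel,
    expected_folded_sfs,
    fold,
    sample_frequency_probs,
    sojourn_density,
    _unit_sample_probs,
)

__all__ = [
    "DFEModel",
    "DFEClass",
    "LETHAL",
    "PopulationModel",
    "SyntheticConfig",
    "SyntheticDataset",
    "sojourn_density",
    "sample_frequency_probs",
    "expected_folded_sfs",
    "simulate_sfs_counts",
    "simulate_site_table",
    "gc_biased_multipliers",
    "random_context_multipliers",
]

#: codon used for the preferred member of each fourfold family
PREFERRED_CODONS = {
    "GC": "GCC",  # Ala
    "GG": "GGC",  # Gly
    "CT": "CTG",  # Leu
    "CC": "CCC",  # Pro
    "AC": "ACC",  # Thr
    "GT": "GTG",  # Val
    "TC": "TCC",  # Ser
    "CG": "CGC",  # Arg
}

_NONDEGENERATE_CODONS = ("ATG", "TGG", "GAT", "AAT")

_FAMILIES = tuple(sorted(FOURFOLD_FAMILIES))

# safety margin: per-site polymorphism probability may not exceed this
_MAX_POLY_PROB = 0.95


def simulate_sfs_counts(expected, L: int, seed, ns: int | None = None) -> FoldedSFS:
    """One multinomial draw of ``L`` sites across folded frequency classes.

    ``expected`` is a probability vector over {monomorphic, folded classes
    1..Ns//2} (e.g. from :func:`expected_folded_sfs`). ``ns`` defaults to
    ``2 * (len(expected) - 1)``.
    """
    expected = np.asarray(expected, dtype=float)
    if L < 1:
        raise DomainError("L must be at least 1")
    if np.any(expected < 0) or abs(expected.sum() - 1.0) > 1e-9:
        raise DomainError("expected must be a probability vector summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(L, expected / expected.sum())
    if ns is None:
        ns = 2 * (len(expected) - 1)
    return FoldedSFS(counts[1:], int(counts[0]), ns)


# ---------------------------------------------------------------------------
# context mutation-rate multipliers
# ---------------------------------------------------------------------------


def _all_canonical_contexts() -> list:
    out = sorted(
        {
            canonical_context(a + b + c)
            for a in NUCLEOTIDES
            for b in NUCLEOTIDES
            for c in NUCLEOTIDES
        }
    )
    return out


def gc_biased_multipliers(strength: float = 1.5) -> dict:
    """Multiplier = strength^(GC count - 1.5), keyed by canonical context.

    GC content is invariant under the strand-blind transforms, so matched
    4D/SI pairs always share a multiplier.
    """
    if strength <= 0:
        raise ConfigError("strength must be positive")
    out = {}
    for ctx in _all_canonical_contexts():
        gc = sum(1 for b in ctx if b in "GC")
        out[ctx] = strength ** (gc - 1.5)
    return out


def random_context_multipliers(sigma: float = 0.3, seed: int = 0) -> dict:
    """Independent lognormal multiplier per canonical context."""
    rng = np.random.default_rng(seed)
    contexts = _all_canonical_contexts()
    mult = np.exp(rng.normal(0.0, sigma, size=len(contexts)))
    return dict(zip(contexts, mult.tolist()))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Layout and model parameters for :func:`simulate_site_table`."""

    n_genes: int = 20
    exons_per_gene: int = 3
    codons_per_exon: int = 30
    intron_length: int = 120
    intergenic_length: int = 200
    n_chroms: int = 1
    chrom_prefix: str = "chrS"

    ne: int = 2000
    ns: int = 160
    theta: float = 0.035

    #: canonical-context -> mutation-rate multiplier (None = uniform)
    context_multipliers: dict | None = None
    #: amplitude/period of the regional log-theta sinusoid (linked-selection proxy)
    gradient_amplitude: float = 0.0
    gradient_period: float = 20000.0

    dfe_preferred: DFEModel = field(default_factory=DFEModel.neutral)
    dfe_unpreferred: DFEModel = field(default_factory=DFEModel.neutral)

    #: extra probability mass on the preferred codon within each family
    preferred_codon_bias: float = 0.5
    #: fraction of codons drawn from non-fourfold codons
    nondegenerate_rate: float = 0.05

    si_trim: int = 8
    si_length_threshold: int = 86

    indel_rate: float = 0.0
    low_quality_rate: float = 0.0

    #: stratum name -> fraction of genes covered by its BED track
    strata_fractions: dict = field(default_factory=dict)

    seed: int = 0

    def validate(self) -> None:
        if self.intron_length <= 2 * self.si_trim:
            raise ConfigError(
                f"intron_length {self.intron_length} must exceed twice the "
                f"trim ({self.si_trim})"
            )
        if not (0 <= self.preferred_codon_bias < 1):
            raise ConfigError("preferred_codon_bias must be in [0, 1)")
        if not (0 <= self.nondegenerate_rate < 1):
            raise ConfigError("nondegenerate_rate must be in [0, 1)")
        if self.context_multipliers is not None:
            if any(m <= 0 for m in self.context_multipliers.values()):
                raise ConfigError("context multipliers must be positive")
        if self.n_genes < 1 or self.exons_per_gene < 1 or self.codons_per_exon < 1:
            raise ConfigError("genome layout counts must be positive")
        if self.intergenic_length < 2:
            raise ConfigError("intergenic_length must be at least 2")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("dfe_preferred", "dfe_unpreferred"):
            d[key] = [[c["gamma"], c["f"]] for c in d[key]["classes"]]
        return d


@dataclass
class SyntheticDataset:
    """Synthetic site table plus its companion fixtures and ground truth."""

    sites: pd.DataFrame
    genome: dict
    features: list
    indels: pd.DataFrame
    strata: dict
    manifest: dict

    def write(self, outdir) -> dict:
        """Write FASTA/GFF3/TSV/BED/JSON fixtures; returns the path map."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "genes.gff3",
            "sites": outdir / "sites.tsv",
            "indels": outdir / "indels.bed",
            "manifest": outdir / "manifest.json",
        }
        write_genome(self.genome, paths["genome"])
        write_gff3(self.features, paths["annotation"])
        write_site_table(self.sites, paths["sites"])
        write_bed(self.indels, paths["indels"])
        for name, df in self.strata.items():
            paths[f"strata:{name}"] = outdir / f"stratum_{name}.bed"
            write_bed(df, paths[f"strata:{name}"])
        write_json(self.manifest, paths["manifest"])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# site-table simulation
# ---------------------------------------------------------------------------


def _dfe_class_table(dfe: DFEModel):
    """(probabilities, gamma per class, labels) with the implicit neutral
    class first."""
    probs = [dfe.f0]
    gammas = [0.0]
    labels = ["neutral"]
    for c in dfe.classes:
        probs.append(c.f)
        if c.is_lethal:
            gammas.append(-np.inf)
            labels.append("lethal")
        else:
            gammas.append(float(c.gamma))
            labels.append(f"s{c.gamma:g}")
    return np.array(probs), np.array(gammas), labels


def _draw_codons(rng, n: int, bias: float, nd_rate: float) -> list:
    """Random codons: mostly fourfold families with preference bias."""
    fam_idx = rng.integers(0, len(_FAMILIES), size=n)
    p_pref = bias + (1.0 - bias) / 4.0
    take_pref = rng.random(n) < p_pref
    alt_idx = rng.integers(0, 3, size=n)
    is_nd = rng.random(n) < nd_rate
    nd_idx = rng.integers(0, len(_NONDEGENERATE_CODONS), size=n)
    codons = []
    for i in range(n):
        if is_nd[i]:
            codons.append(_NONDEGENERATE_CODONS[nd_idx[i]])
            continue
        fam = _FAMILIES[fam_idx[i]]
        pref = PREFERRED_CODONS[fam]
        if take_pref[i]:
            codons.append(pref)
        else:
            others = [fam + b for b in NUCLEOTIDES if fam + b != pref]
            codons.append(others[alt_idx[i]])
    return codons


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(NUCLEOTIDES)[rng.integers(0, 4, size=n)])


def simulate_site_table(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset at Wright-Fisher equilibrium.

    Fourfold sites carry the preference-dependent DFE of their codon class,
    short-intron sites the neutral model; per-site theta combines the base
    rate, a canonical 3-bp-context multiplier and a smooth positional
    gradient shared by co-located 4D and SI sites. Derived counts are drawn
    from the class-conditional unfolded sample distribution. Deterministic
    given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genome: dict = {}
    features: list = []
    site_rows = {
        "chrom": [],
        "pos": [],  # 1-based
        "site_class": [],
        "ancestral": [],
        "context3": [],
        "gene_id": [],
        "codon": [],
        "strand": [],
        "preferred": [],
        "exon_rank": [],
        "exon_rel_pos": [],
    }
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gene_counter = 0
    gene_spans = []  # (chrom, start0, end0, gene_id) for strata BEDs

    for ci in range(config.n_chroms):
        chrom = f"{config.chrom_prefix}{ci + 1}"
        pieces = []
        cursor = 0  # 0-based position of next base

        def emit(seqpiece: str):
            nonlocal cursor
            pieces.append(seqpiece)
            cursor += len(seqpiece)

        emit(_random_seq(rng, config.intergenic_length))
        n_here = min(genes_per_chrom, config.n_genes - gene_counter)
        for gi in range(n_here):
            gene_counter += 1
            gene_id = f"g{gene_counter:05d}"
            strand = "+" if gene_counter % 2 == 1 else "-"
            n_codons = config.exons_per_gene * config.codons_per_exon
            codons = _draw_codons(
                rng, n_codons, config.preferred_codon_bias, config.nondegenerate_rate
            )
            # transcript-order exon chunks
            chunks = [
                codons[e * config.codons_per_exon : (e + 1) * config.codons_per_exon]
                for e in range(config.exons_per_gene)
            ]
            # genomic order: transcript order for '+', reversed for '-'
            genomic_chunks = chunks if strand == "+" else chunks[::-1]
            gene_start0 = cursor
            exon_spans = []
            for ei, chunk in enumerate(genomic_chunks):
                exon_seq_t = "".join(chunk)
                exon_start0 = cursor
                emit(exon_seq_t if strand == "+" else revcomp(exon_seq_t))
                exon_spans.append((exon_start0, cursor))  # half-open, 0-based
                if ei < len(genomic_chunks) - 1:
                    emit(_random_seq(rng, config.intron_length))
            gene_end0 = cursor
            gene_spans.append((chrom, gene_start0, gene_end0, gene_id))
            emit(_random_seq(rng, config.intergenic_length))

            # --- features (coordinates 1-based inclusive) ---
            mrna_id = f"{gene_id}.t1"
            features.append(
                dict(
                    chrom=chrom,
                    source="cubdfe",
                    type="gene",
                    start=gene_start0 + 1,
                    end=gene_end0,
                    strand=strand,
                    attributes=f"ID={gene_id}",
                )
            )
            features.append(
                dict(
                    chrom=chrom,
                    source="cubdfe",
                    type="mRNA",
                    start=gene_start0 + 1,
                    end=gene_end0,
                    strand=strand,
                    attributes=f"ID={mrna_id};Parent={gene_id}",
                )
            )
            for ei, (s0, e0) in enumerate(exon_spans):
                features.append(
                    dict(
                        chrom=chrom,
                        source="cubdfe",
                        type="exon",
                        start=s0 + 1,
                        end=e0,
                        strand=strand,
                        attributes=f"ID={mrna_id}.exon{ei + 1};Parent={mrna_id}",
                    )
                )
                features.append(
                    dict(
                        chrom=chrom,
                        source="cubdfe",
                        type="CDS",
                        start=s0 + 1,
                        end=e0,
                        strand=strand,
                        phase=0,
                        attributes=f"ID={mrna_id}.cds{ei + 1};Parent={mrna_id}",
                    )
                )

            # --- 4D sites ---
            n_exons = config.exons_per_gene
            for ti, chunk in enumerate(chunks):  # transcript order
                if n_exons == 1:
                    rank = "single"
                elif ti == 0:
                    rank = "first"
                elif ti == n_exons - 1:
                    rank = "last"
                else:
                    rank = "internal"
                # genomic span of this transcript exon
                gidx = ti if strand == "+" else n_exons - 1 - ti
                s0, e0 = exon_spans[gidx]
                for i, codon in enumerate(chunk):
                    if not is_fourfold(codon):
                        continue
                    if strand == "+":
                        pos0 = s0 + 3 * i + 2
                        anc = codon[2]
                    else:
                        pos0 = (e0 - 1) - (3 * i + 2)
                        anc = comp(codon[2])
                    site_rows["chrom"].append(chrom)
                    site_rows["pos"].append(pos0 + 1)
                    site_rows["site_class"].append("4D")
                    site_rows["ancestral"].append(anc)
                    site_rows["context3"].append(None)  # filled from sequence
                    site_rows["gene_id"].append(gene_id)
                    site_rows["codon"].append(codon)
                    site_rows["strand"].append(strand)
                    site_rows["preferred"].append(
                        codon == PREFERRED_CODONS.get(codon[:2], "")
                    )
                    site_rows["exon_rank"].append(rank)
                    site_rows["exon_rel_pos"].append(
                        (i + 0.5) / config.codons_per_exon
                    )

            # --- SI sites ---
            intron_len = config.intron_length
            keep_intron = intron_len > config.si_length_threshold
            if keep_intron and n_exons > 1:
                for k in range(n_exons - 1):
                    intron_start0 = exon_spans[k][1]
                    for off in range(config.si_trim, intron_len - config.si_trim):
                        pos0 = intron_start0 + off
                        site_rows["chrom"].append(chrom)
                        site_rows["pos"].append(pos0 + 1)
                        site_rows["site_class"].append("SI")
                        site_rows["ancestral"].append(None)
                        site_rows["context3"].append(None)
                        site_rows["gene_id"].append(gene_id)
                        site_rows["codon"].append(".")
                        site_rows["strand"].append(strand)
                        site_rows["preferred"].append(False)
                        site_rows["exon_rank"].append(".")
                        site_rows["exon_rel_pos"].append(np.nan)

        genome[chrom] = "".join(pieces)

    sites = pd.DataFrame(site_rows)
    # fill ancestral (SI) and contexts from the assembled sequence
    anc, ctx = [], []
    for chrom, pos, a in zip(sites["chrom"], sites["pos"], sites["ancestral"]):
        seq = genome[chrom]
        base = seq[pos - 1]
        if a is not None and a != base:
            raise AssertionError("internal inconsistency: codon vs genome")
        anc.append(base)
        ctx.append(seq[pos - 2 : pos + 1])
    sites["ancestral"] = anc
    sites["context3"] = ctx

    # --- per-site theta ---
    canon = sites["context3"].map(canonical_context)
    if config.context_multipliers is not None:
        mult = canon.map(lambda c: config.context_multipliers.get(c, 1.0)).to_numpy()
    else:
        mult = np.ones(len(sites))
    if config.gradient_amplitude != 0.0:
        grad = np.exp(
            config.gradient_amplitude
            * np.sin(2.0 * np.pi * sites["pos"].to_numpy() / config.gradient_period)
        )
    else:
        grad = np.ones(len(sites))
    theta_site = config.theta * mult * grad
    sites["theta_site"] = theta_site

    # --- truth selection classes ---
    is4d = (sites["site_class"] == "4D").to_numpy()
    pref = sites["preferred"].to_numpy().astype(bool)
    truth_gamma = np.zeros(len(sites))
    truth_class = np.full(len(sites), "neutral", dtype=object)
    for group_mask, dfe in (
        (is4d & pref, config.dfe_preferred),
        (is4d & ~pref, config.dfe_unpreferred),
    ):
        idx = np.flatnonzero(group_mask)
        if len(idx) == 0:
            continue
        probs, gammas, labels = _dfe_class_table(dfe)
        draw = rng.choice(len(probs), size=len(idx), p=probs / probs.sum())
        truth_gamma[idx] = gammas[draw]
        truth_class[idx] = np.array(labels, dtype=object)[draw]
    sites["truth_gamma"] = truth_gamma
    sites["truth_class"] = truth_class

    # --- derived counts ---
    ns = config.ns
    derived_count = np.zeros(len(sites), dtype=np.int64)
    u_poly = rng.random(len(sites))
    for gamma in np.unique(truth_gamma):
        idx = np.flatnonzero(truth_gamma == gamma)
        if np.isneginf(gamma):
            continue  # lethal: always monomorphic
        w = _unit_sample_probs(config.ne, ns, float(gamma))
        W = w.sum()
        p_poly = theta_site[idx] * W
        if np.any(p_poly > _MAX_POLY_PROB):
            raise ModelInvalidError(
                "per-site polymorphism probability exceeds "
                f"{_MAX_POLY_PROB}; reduce theta / multipliers"
            )
        poly = np.flatnonzero(u_poly[idx] < p_poly)
        if len(poly):
            cum = np.cumsum(w) / W
            ks = np.searchsorted(cum, rng.random(len(poly))) + 1
            derived_count[idx[poly]] = ks
    sites["derived_count"] = derived_count
    sites["n_haplotypes"] = ns

    # derived alleles
    derived = np.full(len(sites), ".", dtype=object)
    poly_idx = np.flatnonzero(derived_count > 0)
    alt_choice = rng.integers(0, 3, size=len(poly_idx))
    anc_arr = sites["ancestral"].to_numpy()
    for j, i in enumerate(poly_idx):
        alts = [b for b in NUCLEOTIDES if b != anc_arr[i]]
        derived[i] = alts[alt_choice[j]]
    sites["derived"] = derived

    # --- artifacts ---
    sites["low_quality"] = (
        rng.random(len(sites)) < config.low_quality_rate
        if config.low_quality_rate > 0
        else False
    )
    indel_rows = []
    if config.indel_rate > 0:
        for chrom, seq in genome.items():
            hits = np.flatnonzero(rng.random(len(seq)) < config.indel_rate)
            for p0 in hits:
                indel_rows.append((chrom, int(p0), int(p0) + 1, "indel"))
    indels = pd.DataFrame(indel_rows, columns=["chrom", "start", "end", "name"])

    # --- strata BEDs ---
    strata = {}
    for name, frac in config.strata_fractions.items():
        n_pick = int(round(frac * len(gene_spans)))
        pick = rng.choice(len(gene_spans), size=n_pick, replace=False)
        rows = [
            (gene_spans[i][0], gene_spans[i][1], gene_spans[i][2], gene_spans[i][3])
            for i in sorted(pick)
        ]
        strata[name] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    sites = sites[
        [
            "chrom",
            "pos",
            "site_class",
            "ancestral",
            "derived",
            "derived_count",
            "n_haplotypes",
            "context3",
            "gene_id",
            "codon",
            "strand",
            "preferred",
            "exon_rank",
            "exon_rel_pos",
            "theta_site",
            "truth_gamma",
            "truth_class",
            "low_quality",
        ]
    ].reset_index(drop=True)

    n4d = int(is4d.sum())
    manifest = {
        "config": config.to_jsonable(),
        "preferred_codons": PREFERRED_CODONS,
        "n_sites": len(sites),
        "n_4d": n4d,
        "n_si": len(sites) - n4d,
        "truth_class_counts": sites["truth_class"].value_counts().to_dict(),
        "strata_genes": {name: sorted(df["name"]) for name, df in strata.items()},
    }
    return SyntheticDataset(sites, genome, features, indels, strata, manifest)
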