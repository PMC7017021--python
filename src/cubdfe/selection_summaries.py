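"""Codon-usage metrics and polymorphism-ratio statistics.

The polymorphism ratio log(P_SI / P_4D) over matched control sets is the
small-sample proxy for the fraction of test sites under strong purifying
selection; RSCU / FOP quantify codon usage bias; the remaining helpers
stratify and correlate these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .codons import FOURFOLD_FAMILIES
from .errors import DataError, DomainError
from .seq import NUCLEOTIDES
from .site_matching import MatchedReplicate, bootstrap_resample, match_by_state

__all__ = [
    "RSCUTable",
    "PolymorphismRatioEstimate",
    "codon_counts",
    "rscu",
    "polymorphism_ratio",
    "strong_selection_count",
    "fop",
    "rscu_change_analysis",
    "ribosomal_occupancy",
    "windowed_score_correlation",
]


@dataclass
class RSCUTable:
    """Relative synonymous codon usage for the fourfold families.

    ``table`` has one row per codon (family, count, family frequency,
    RSCU); ``preferred`` maps family prefix -> preferred codon (highest
    RSCU; ties broken lexicographically and flagged).
    """

    table: pd.DataFrame
    preferred: dict
    ties: list = field(default_factory=list)
    undefined_families: list = field(default_factory=list)

    def value(self, codon: str) -> float:
        row = self.table.loc[self.table["codon"] == codon.upper()]
        if row.empty:
            raise DomainError(f"{codon!r} is not a fourfold-degenerate codon")
        return float(row["rscu"].iloc[0])

    def is_preferred(self, codon: str) -> bool:
        return self.preferred.get(codon[:2].upper()) == codon.upper()


def codon_counts(sites: pd.DataFrame) -> pd.Series:
    """Codon usage counts from the ancestral codons of 4D sites."""
    fourd = sites[sites["site_class"] == "4D"]
    return fourd["codon"].value_counts()


def rscu(counts) -> RSCUTable:
    """RSCU per fourfold codon: within-family frequency / 0.25.

    ``counts`` is a mapping or Series codon -> count; missing codons count
    zero. A family with zero total usage has undefined RSCU and no
    preference labels.
    """
    counts = dict(pd.Series(counts))
    rows = []
    preferred = {}
    ties = []
    undefined = []
    for fam in sorted(FOURFOLD_FAMILIES):
        codons = [fam + b for b in NUCLEOTIDES]
        vals = np.array([float(counts.get(c, 0)) for c in codons])
        total = vals.sum()
        if total == 0:
            undefined.append(fam)
            for c in codons:
                rows.append((c, fam, 0.0, np.nan, np.nan, False))
            continue
        freqs = vals / total
        rscus = freqs / 0.25
        best = rscus.max()
        winners = [codons[i] for i in range(4) if rscus[i] == best]
        if len(winners) > 1:
            ties.append(fam)
        pref = min(winners)  # lexicographic tie-break
        preferred[fam] = pref
        for c, v, fr, rs in zip(codons, vals, freqs, rscus):
            rows.append((c, fam, v, fr, rs, c == pref))
    table = pd.DataFrame(
        rows,
        columns=["codon", "family", "count", "family_freq", "rscu", "preferred"],
    )
    return RSCUTable(table, preferred, ties, undefined)


# ---------------------------------------------------------------------------
# polymorphism ratio
# ---------------------------------------------------------------------------


@dataclass
class PolymorphismRatioEstimate:
    """log(P_SI / P_4D) summarized over matched replicates.

    ``ratio`` is the median per-replicate log-ratio, ``se`` the standard
    deviation of the per-replicate values (figures quote 2*SE error bars);
    for a single replicate the SE comes from pair bootstrap.
    """

    p_si: float
    p_4d: float
    ratio: float
    se: float
    per_replicate: np.ndarray
    defined: bool = True
    diagnostics: dict = field(default_factory=dict)


def polymorphism_ratio(
    replicates,
    stratum_mask: np.ndarray | None = None,
    n_boot: int = 200,
    boot_seed: int = 0,
) -> PolymorphismRatioEstimate:
    """Polymorphism ratio for a stratum across matched replicates.

    Counts polymorphic 4D pairs and their matched polymorphic SI pairs in
    each replicate (restricted to pairs whose 4D member lies in the
    stratum) and reports the median log(P_SI / P_4D). A replicate with a
    zero count on either side renders the stratum undefined; the
    diagnostics record which.
    """
    if isinstance(replicates, MatchedReplicate):
        replicates = [replicates]
    if not replicates:
        raise DataError("at least one matched replicate is required")
    p4, psi = [], []
    for rep in replicates:
        a, b = rep.polymorphic_counts(stratum_mask)
        p4.append(a)
        psi.append(b)
    p4 = np.asarray(p4, dtype=float)
    psi = np.asarray(psi, dtype=float)
    bad = (p4 == 0) | (psi == 0)
    if bad.any():
        return PolymorphismRatioEstimate(
            p_si=float(np.median(psi)),
            p_4d=float(np.median(p4)),
            ratio=np.nan,
            se=np.nan,
            per_replicate=np.full(len(p4), np.nan),
            defined=False,
            diagnostics={
                "zero_replicates": np.flatnonzero(bad).tolist(),
                "p_4d": p4.tolist(),
                "p_si": psi.tolist(),
            },
        )
    ratios = np.log(psi / p4)
    if len(replicates) > 1:
        se = float(np.std(ratios, ddof=1))
    else:
        boots = []
        for b in range(n_boot):
            rep = bootstrap_resample(replicates[0], seed=[boot_seed, b])
            a, c = rep.polymorphic_counts(stratum_mask)
            if a > 0 and c > 0:
                boots.append(np.log(c / a))
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    return PolymorphismRatioEstimate(
        p_si=float(np.median(psi)),
        p_4d=float(np.median(p4)),
        ratio=float(np.median(ratios)),
        se=se,
        per_replicate=ratios,
    )


def strong_selection_count(
    class_pr: PolymorphismRatioEstimate,
    background_pr: PolymorphismRatioEstimate,
    n_class_sites: int,
):
    """Estimated number of class sites under strong purifying selection:
    (class ratio - background ratio) * class size, with propagated SE.

    Valid only in the roughly one-to-one regime between polymorphism ratio
    and strongly selected fraction.
    """
    if not (class_pr.defined and background_pr.defined):
        raise DataError("both polymorphism-ratio estimates must be defined")
    delta = class_pr.ratio - background_pr.ratio
    est = delta * n_class_sites
    se = float(np.hypot(class_pr.se, background_pr.se) * n_class_sites)
    return est, se


# ---------------------------------------------------------------------------
# FOP
# ---------------------------------------------------------------------------


def fop(sites: pd.DataFrame, rscu_table: RSCUTable) -> pd.DataFrame:
    """Frequency of preferred codons per gene, with quartile groups.

    Only codons present in the 4D dataset contribute. Returns a DataFrame
    indexed by gene with ``fop``, ``n_codons`` and ``fop_group`` in
    {low, medium, high} (bottom quartile / middle two / top quartile); a
    degenerate split (all genes identical) is flagged in ``attrs``.
    """
    fourd = sites[sites["site_class"] == "4D"]
    if fourd.empty:
        raise DataError("no 4D sites to compute FOP from")
    pref = fourd["codon"].map(rscu_table.is_preferred)
    per_gene = pd.DataFrame(
        {
            "n_codons": fourd.groupby("gene_id")["codon"].size(),
            "n_preferred": pref.groupby(fourd["gene_id"]).sum(),
        }
    )
    per_gene = per_gene[per_gene["n_codons"] > 0]
    per_gene["fop"] = per_gene["n_preferred"] / per_gene["n_codons"]
    q1, q3 = np.quantile(per_gene["fop"], [0.25, 0.75])
    degenerate = q1 == q3
    group = np.full(len(per_gene), "medium", dtype=object)
    group[per_gene["fop"].to_numpy() <= q1] = "low"
    group[per_gene["fop"].to_numpy() > q3] = "high"
    if degenerate:
        group[:] = "medium"
    per_gene["fop_group"] = group
    per_gene.attrs["degenerate_quartiles"] = bool(degenerate)
    return per_gene


# ---------------------------------------------------------------------------
# per-codon-change analysis
# ---------------------------------------------------------------------------


def rscu_change_analysis(
    sites: pd.DataFrame,
    rscu_table: RSCUTable,
    max_dist: int = 1000,
    n_replicates: int = 20,
    seed: int = 0,
    min_poly_pairs: int = 1,
) -> dict:
    """Polymorphism ratio vs RSCU change for every synonymous codon pair.

    For each ancestral -> derived third-position change observed among 4D
    sites, builds state-matched control sets (:func:`match_by_state`),
    estimates the polymorphism ratio (median over ``n_replicates`` random
    assignments) and the RSCU change, oriented so that mutations toward a
    less preferred codon have positive delta. Returns the per-pair table,
    the OLS fit (slope, R^2, p) and the list of excluded pairs.
    """
    fourd = sites[sites["site_class"] == "4D"]
    pairs = set()
    for codon, derived, strand in zip(
        fourd["codon"], fourd["derived"], fourd["strand"]
    ):
        if derived == ".":
            continue
        d_coding = derived if strand == "+" else {
            "A": "T", "C": "G", "G": "C", "T": "A"
        }[derived]
        if d_coding != codon[2]:
            pairs.add((codon, codon[:2] + d_coding))
    rows, excluded = [], []
    for anc, der in sorted(pairs):
        try:
            ratios = []
            for r in range(n_replicates):
                rep = match_by_state(
                    sites, anc, der, max_dist=max_dist, seed=[seed, r],
                    replicate_id=r + 1,
                )
                p4, psi = rep.polymorphic_counts()
                if p4 < min_poly_pairs or psi < min_poly_pairs:
                    raise DataError("zero polymorphic pairs")
                ratios.append(np.log(psi / p4))
        except DataError as exc:
            excluded.append({"pair": f"{anc}>{der}", "reason": str(exc)})
            continue
        delta = rscu_table.value(anc) - rscu_table.value(der)
        rows.append(
            {
                "ancestral_codon": anc,
                "derived_codon": der,
                "delta_rscu": delta,
                "ratio": float(np.median(ratios)),
            }
        )
    table = pd.DataFrame(rows)
    result = {"table": table, "excluded": excluded, "slope": np.nan,
              "r2": np.nan, "p": np.nan}
    if len(table) >= 3 and table["delta_rscu"].nunique() > 1:
        fit = linregress(table["delta_rscu"], table["ratio"])
        result.update(slope=fit.slope, r2=fit.rvalue**2, p=fit.pvalue)
    return result


# ---------------------------------------------------------------------------
# ribosomal occupancy
# ---------------------------------------------------------------------------


def ribosomal_occupancy(
    footprint: pd.Series,
    expression: pd.Series,
    strand: pd.Series | None = None,
    top_fraction: float = 0.25,
    trim_percentile: float = 1.0,
) -> pd.DataFrame:
    """Occupancy = normalized footprint / normalized expression per region.

    Each input is normalized to its own total (per strand when ``strand``
    is given); regions with a zero count in either input are excluded,
    scores outside the (1st, 99th) percentile removed, and the top 25% of
    the remainder labeled high occupancy.
    """
    if footprint.sum() <= 0 or expression.sum() <= 0:
        raise DataError("footprint and expression totals must be positive")
    df = pd.DataFrame({"footprint": footprint, "expression": expression})
    df["strand"] = strand if strand is not None else "+"
    df = df[(df["footprint"] > 0) & (df["expression"] > 0)]
    scores = []
    for _, sub in df.groupby("strand"):
        fp = sub["footprint"] / sub["footprint"].sum()
        ex = sub["expression"] / sub["expression"].sum()
        scores.append(fp / ex)
    df["occupancy"] = pd.concat(scores)
    lo, hi = np.percentile(
        df["occupancy"], [trim_percentile, 100 - trim_percentile]
    )
    df = df[(df["occupancy"] >= lo) & (df["occupancy"] <= hi)].copy()
    cutoff = df["occupancy"].quantile(1 - top_fraction)
    df["high_occupancy"] = df["occupancy"] > cutoff
    return df


# ---------------------------------------------------------------------------
# windowed correlation with an external per-site score
# ---------------------------------------------------------------------------


def windowed_score_correlation(
    sites: pd.DataFrame,
    score_col: str,
    replicates,
    window_snps: int = 100_000,
    step_snps: int | None = None,
) -> dict:
    """Sliding-window polymorphism ratio along a per-site score.

    4D sites are sorted by score; windows containing ``window_snps``
    polymorphic 4D sites (step = half a window by default) each get a
    matched polymorphism ratio, which is regressed on the median window
    score. Returns windows, slope, R^2 and p; a single window reports the
    correlation as undefined.
    """
    if score_col not in sites.columns:
        raise DataError(f"missing score column {score_col!r}")
    step_snps = step_snps or max(1, window_snps // 2)
    fourd_rows = np.flatnonzero((sites["site_class"] == "4D").to_numpy())
    scores = sites[score_col].to_numpy()[fourd_rows]
    poly = (
        (sites["derived_count"].to_numpy() > 0)
        & (sites["derived_count"].to_numpy() < sites["n_haplotypes"].to_numpy())
    )[fourd_rows]
    order = np.argsort(scores, kind="stable")
    fourd_rows, scores, poly = fourd_rows[order], scores[order], poly[order]
    n_snps = int(poly.sum())
    if n_snps < window_snps:
        raise DataError(
            f"only {n_snps} polymorphic 4D sites; need at least {window_snps}"
        )
    snp_cum = np.cumsum(poly)
    windows = []
    start_snp = 0
    while start_snp + window_snps <= n_snps:
        lo = int(np.searchsorted(snp_cum, start_snp + 1))
        hi = int(np.searchsorted(snp_cum, start_snp + window_snps, side="left")) + 1
        mask = np.zeros(len(sites), dtype=bool)
        mask[fourd_rows[lo:hi]] = True
        pr = polymorphism_ratio(replicates, stratum_mask=mask)
        windows.append(
            {
                "median_score": float(np.median(scores[lo:hi])),
                "ratio": pr.ratio,
                "n_snps": int(poly[lo:hi].sum()),
                "defined": pr.defined,
            }
        )
        start_snp += step_snps
    table = pd.DataFrame(windows)
    result = {"windows": table, "slope": np.nan, "r2": np.nan, "p": np.nan}
    usable = table[table["defined"] & np.isfinite(table["ratio"])]
    if len(usable) >= 3 and usable["median_score"].nunique() > 1:
        fit = linregress(usable["median_score"], usable["ratio"])
        result.update(slope=fit.slope, r2=fit.rvalue**2, p=fit.pvalue)
    return result
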