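"""End-to-end orchestration: simulate -> annotate -> match -> fit -> summarize.

A run is driven by a single YAML/dict configuration; every stage writes a
manifest (parameters, input hashes, seeds) into the output directory and
all randomness derives from the top-level seed, so a rerun with the same
configuration reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dfe_likelihood import (
    MODEL_NAMES,
    FitResult,
    FoldedSFS,
    ModelSpec,
    fit_alpha,
    fit_model,
    fit_model_profile,
    rank_bootstrap_ci,
    select_best_model,
)
from .errors import ConfigError, CubdfeError, DataError
from .io import read_genome, read_site_table, write_json, write_site_table
from .selection_summaries import codon_counts, fop, polymorphism_ratio, rscu
from .site_matching import (
    annotate_4d_sites,
    apply_filters,
    attach_alleles,
    downsample_haplotypes,
    extract_si_sites,
    match_controls,
    polarize,
)
from .spectra import DFEClass, DFEModel, PopulationModel
from .synthetic_data import LETHAL, SyntheticConfig, simulate_site_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures", "folded_sfs_from_sites"]

DEFAULTS = {
    "seed": 0,
    "population": {"ne": 2000, "ns": 160},
    "matching": {"n_replicates": 200, "max_dist": 1000},
    "filters": {"enabled": True, "mapq_min": 20, "indel_window": 10},
    "downsample": {"target_ns": None},  # default: population ns
    "si": {"length_threshold": 86, "trim": 8, "comparison": ">"},
    "fit": {
        "models": list(MODEL_NAMES),
        "boundary": 10.0,
        "replicates": 1,
        "threshold": 0.05,
    },
    "summaries": {"enabled": True},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _parse_dfe(spec) -> DFEModel:
    """[[gamma-or-'lethal', fraction], ...] -> DFEModel."""
    classes = []
    for gamma, f in spec or []:
        classes.append(DFEClass(LETHAL if gamma == LETHAL else float(gamma), float(f)))
    return DFEModel(tuple(classes))


class RunConfig:
    """Validated pipeline configuration (YAML file, path, or dict)."""

    def __init__(self, data: dict):
        self.data = _deep_merge(DEFAULTS, data)
        if "synthetic" not in self.data and "inputs" not in self.data:
            raise ConfigError("config needs either a 'synthetic' or an 'inputs' block")
        if "inputs" in self.data:
            for key in ("genome", "annotation", "sites"):
                path = self.data["inputs"].get(key)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"input file for {key!r} missing: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def __getitem__(self, key):
        return self.data[key]

    def get(self, key, default=None):
        return self.data.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def synthetic_config(self) -> SyntheticConfig:
        raw = dict(self.data["synthetic"])
        raw.setdefault("seed", self.seed)
        raw.setdefault("ne", self.data["population"]["ne"])
        raw.setdefault("ns", self.data["population"]["ns"])
        for key in ("dfe_preferred", "dfe_unpreferred"):
            if key in raw and not isinstance(raw[key], DFEModel):
                raw[key] = _parse_dfe(raw[key])
        known = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
        return SyntheticConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_manifest(outdir: Path, stage: str, params: dict, inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "params": params,
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
    }
    write_json(manifest, outdir / f"manifest_{stage}.json")


def folded_sfs_from_sites(derived_counts, ns: int) -> FoldedSFS:
    """Fold per-site derived counts (0..ns) into a spectrum."""
    k = np.asarray(derived_counts)
    folded = np.minimum(k, ns - k)
    nf = ns // 2
    counts = np.bincount(folded[folded > 0], minlength=nf + 1)[1:]
    return FoldedSFS(counts, int((folded == 0).sum()), ns)


def _fit_replicate(rep, ns, ne, fit_cfg):
    """Fit all requested models on one matched replicate."""
    k = rep.sites["derived_count"].to_numpy()
    sfs4 = folded_sfs_from_sites(k[rep.fourd], ns)
    sfssi = folded_sfs_from_sites(k[rep.si], ns)
    alpha, theta0 = fit_alpha(sfssi, ne=ne)
    pop = PopulationModel(ne=ne, ns=ns, theta=max(theta0, 1e-8), L=sfs4.L)
    fitter = fit_model_profile if fit_cfg.get("method") == "profile" else fit_model
    fits = {}
    for name in fit_cfg["models"]:
        spec = ModelSpec.from_name(name, boundary=float(fit_cfg["boundary"]))
        fits[name] = fitter(spec, sfs4, sfssi, alpha, model=pop)
    return fits, alpha, theta0


def _median_fit(per_replicate: list, name: str) -> FitResult:
    """Synthetic FitResult carrying the per-replicate medians (table style)."""
    fits = [fits[name] for fits in per_replicate]
    base = fits[0]
    med_ll = float(np.median([f.loglik for f in fits]))
    med_theta = float(np.median([f.theta for f in fits]))
    classes = []
    for ci, c in enumerate(base.dfe.classes):
        f_med = float(np.median([f.dfe.classes[ci].f for f in fits]))
        if c.is_lethal:
            classes.append(DFEClass(LETHAL, f_med))
        else:
            g_med = float(np.median([f.dfe.classes[ci].gamma for f in fits]))
            classes.append(DFEClass(g_med, f_med))
    return FitResult(
        model=base.model,
        dfe=DFEModel(tuple(classes)),
        theta=med_theta,
        alpha=base.alpha,
        loglik=med_ll,
        converged=all(f.converged for f in fits),
    )


def run_pipeline(config: RunConfig | dict | str, outdir) -> dict:
    """Execute all stages; returns a dict of result paths and headline values."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.data, sort_keys=True)
    )
    pop = config["population"]
    ne, ns = int(pop["ne"]), int(pop["ns"])
    results: dict = {"outdir": str(outdir)}

    try:
        # ---- stage: simulate or load ----
        if "synthetic" in config.data:
            stage = "simulate"
            dataset = simulate_site_table(config.synthetic_config())
            fixdir = outdir / "fixtures"
            paths = dataset.write(fixdir)
            _stage_manifest(
                outdir, "simulate", config.data["synthetic"], {}
            )
        else:
            stage = "load"
            paths = {k: str(v) for k, v in config.data["inputs"].items()}

        # ---- stage: annotate ----
        stage = "annotate"
        genome = read_genome(paths["genome"])
        alleles = read_site_table(paths["sites"])
        si_cfg = config["si"]
        fourd = annotate_4d_sites(genome, paths["annotation"])
        si = extract_si_sites(
            genome,
            paths["annotation"],
            length_threshold=int(si_cfg["length_threshold"]),
            trim=int(si_cfg["trim"]),
            comparison=si_cfg["comparison"],
        )
        annotated = pd.concat(
            [attach_alleles(fourd, alleles), attach_alleles(si, alleles)],
            ignore_index=True,
        )
        _stage_manifest(
            outdir,
            "annotate",
            {"n_4d": int((annotated["site_class"] == "4D").sum()),
             "n_si": int((annotated["site_class"] == "SI").sum())},
            {k: paths[k] for k in ("genome", "annotation", "sites")},
        )

        # ---- stage: filter / polarize / downsample ----
        stage = "filter"
        sites = annotated
        if config["filters"].get("enabled", True):
            indels = paths.get("indels")
            sites = apply_filters(
                sites,
                mapq_min=float(config["filters"]["mapq_min"]),
                indel_window=int(config["filters"]["indel_window"]),
                indels=indels if indels and Path(indels).exists() else None,
            )
        if "outgroup" in sites.columns:
            sites = polarize(sites)
        target_ns = config["downsample"]["target_ns"] or ns
        sites = downsample_haplotypes(sites, target_ns=int(target_ns),
                                      seed=config.seed)
        sites = sites.reset_index(drop=True)
        write_site_table(sites, outdir / "sites_filtered.tsv")
        _stage_manifest(
            outdir,
            "filter",
            {"filter_counts": sites.attrs.get("filter_counts", {}),
             "n_sites": len(sites)},
            {},
        )

        # ---- stage: match ----
        stage = "match"
        mcfg = config["matching"]
        replicates = match_controls(
            sites,
            n_replicates=int(mcfg["n_replicates"]),
            max_dist=int(mcfg["max_dist"]),
            seed=config.seed,
        )
        pool_report = {
            "n_replicates": len(replicates),
            "n_4d_matched": len(replicates[0]),
            "si_reuse_mean": float(
                len(replicates[0]) / max(1, len(np.unique(replicates[0].si)))
            ),
        }
        write_json(pool_report, outdir / "matching_report.json")
        _stage_manifest(outdir, "match", dict(mcfg), {})

        # ---- stage: fit ----
        stage = "fit"
        fit_cfg = config["fit"]
        n_fit = min(int(fit_cfg["replicates"]), len(replicates))
        per_replicate = []
        for rep in replicates[:n_fit]:
            fits, alpha, theta0 = _fit_replicate(rep, target_ns, ne, fit_cfg)
            per_replicate.append(fits)
        agg = {
            name: _median_fit(per_replicate, name) for name in fit_cfg["models"]
        }
        if set(MODEL_NAMES) <= set(agg):
            best_spec, report = select_best_model(
                agg, threshold=float(fit_cfg["threshold"])
            )
            results["best_model"] = best_spec.name
        else:
            report = [agg[m].params_dict() for m in fit_cfg["models"]]
            results["best_model"] = None
        if n_fit >= 200:
            cis = {}
            for name in fit_cfg["models"]:
                lls = [fits[name].loglik for fits in per_replicate]
                cis[name] = rank_bootstrap_ci(lls)
            write_json(cis, outdir / "fit_rank_ci.json")
        fit_table = pd.DataFrame(report)
        fit_table.to_csv(outdir / "fit_summary.tsv", sep="\t", index=False,
                         float_format="%.6g")
        write_json(
            {name: agg[name].params_dict() for name in fit_cfg["models"]},
            outdir / "fit_params.json",
        )
        _stage_manifest(outdir, "fit", {"models": list(fit_cfg["models"]),
                                        "replicates": n_fit}, {})

        # ---- stage: summarize ----
        stage = "summarize"
        if config["summaries"].get("enabled", True):
            counts = codon_counts(sites)
            rtab = rscu(counts)
            rtab.table.to_csv(outdir / "rscu.tsv", sep="\t", index=False)
            fop_table = fop(sites, rtab)
            fop_table.to_csv(outdir / "fop.tsv", sep="\t")
            pref_mask = sites["codon"].map(rtab.is_preferred).to_numpy()
            fourd_mask = (sites["site_class"] == "4D").to_numpy()
            pr_rows = []
            for label, mask in (
                ("full", None),
                ("preferred", fourd_mask & pref_mask),
                ("unpreferred", fourd_mask & ~pref_mask),
            ):
                pr = polymorphism_ratio(replicates, stratum_mask=mask)
                pr_rows.append(
                    {
                        "stratum": label,
                        "ratio": pr.ratio,
                        "se": pr.se,
                        "two_se": 2 * pr.se,
                        "p_4d": pr.p_4d,
                        "p_si": pr.p_si,
                        "defined": pr.defined,
                    }
                )
            pd.DataFrame(pr_rows).to_csv(
                outdir / "polymorphism_ratio.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            results["polymorphism_ratio"] = {
                r["stratum"]: r["ratio"] for r in pr_rows
            }
        _stage_manifest(outdir, "summarize", {}, {})
    except CubdfeError as exc:
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        write_json(record, outdir / "error.json")
        raise
    results["fit_summary"] = str(outdir / "fit_summary.tsv")
    return results


def generate_fixtures(scale: str = "tiny", outdir=None, seed: int = 0):
    """Bundled synthetic test datasets.

    ``tiny``: ~5K sites for unit tests. ``desk``: ~750K 4D sites emulating
    the high-diversity population design (theta 0.035, 160 haplotypes).
    """
    if scale == "tiny":
        cfg = SyntheticConfig(
            n_genes=25,
            exons_per_gene=3,
            codons_per_exon=30,
            theta=0.035,
            dfe_preferred=DFEModel(((-30.0, 0.15), (LETHAL, 0.05))),
            seed=seed,
        )
    elif scale == "desk":
        cfg = SyntheticConfig(
            n_genes=9300,
            exons_per_gene=3,
            codons_per_exon=32,
            theta=0.035,
            dfe_preferred=DFEModel(((-1.0, 0.2), (-30.0, 0.1))),
            gradient_amplitude=0.2,
            seed=seed,
        )
    else:
        raise ConfigError("scale must be 'tiny' or 'desk'")
    dataset = simulate_site_table(cfg)
    if outdir is not None:
        dataset.write(outdir)
    return dataset
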