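"""Orchestration: compose the stages into the two headline analyses
(geography-only GDM; GDM with environmental selection, cross-validation and
significance testing) plus diversity and LD reports.

Every run takes a :class:`RunConfig` (loadable from YAML), writes its
artifacts under an output directory, echoes the config verbatim and records
a ``manifest.json`` with SHA-256 hashes of every artifact so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import genio, popgen, synthdata
from .gdmcore import GEO, build_pair_table, fit_gdm, spline_table
from .gdmselect import (backward_select, cross_validate, forward_select,
                        jackknife_splines, model_significance)
from .lddecay import ld_decay_table, summarize_ld

log = logging.getLogger("landgen")

__all__ = ["RunConfig", "run_ibd_analysis", "run_ibe_analysis",
           "run_diversity_report", "run_ld_report", "load_inputs"]


@dataclass
class RunConfig:
    """Single configuration object for a pipeline run.

    Either real input paths (``vcf``, ``locality_csv``, ``env_csv``) or
    simulation parameters (``simulate``) must be given. All stochastic stages
    draw from ``seed``.
    """

    out_dir: str = "run"
    vcf: str | None = None
    locality_csv: str | None = None
    env_csv: str | None = None
    simulate: dict | None = None
    min_maf: float = 0.0
    max_missing: float = 1.0
    min_geo_km: float = 10.0
    n_knots: int = 3
    spline_order: int = 2
    threshold_pct: float = 1.0
    n_perm: int = 100
    n_jackknife: int = 100
    n_cv: int = 100
    drop_fraction: float = 0.1
    test_fraction: float = 0.1
    ld_window: int = 30_000
    ld_overlap: int = 10_000
    ld_min_pairs: int = 50
    total_sites: int | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _finish(out: Path, cfg: RunConfig, stage: str) -> dict:
    cfg.to_yaml(out / "config.yaml")
    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_inputs(cfg: RunConfig) -> genio.Bundle:
    """Load or simulate the genotype/locality/environment bundle."""
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        gm, loc, env, truth = synthdata.simulate_landscape(
            n_localities=sim.get("n_localities", 39),
            n_per_locality=tuple(sim["n_per_locality"]) if isinstance(
                sim.get("n_per_locality"), (list, tuple)) else sim.get("n_per_locality", 6),
            n_loci=sim.get("n_loci", 1000),
            ibd=sim.get("ibd", {"sigma2": 1.0, "phi": 300.0}),
            ibe=sim.get("ibe", {"sigma2": 0.0, "phi": 1.0, "causal_ids": []}),
            seed=cfg.seed,
        )
        return genio.validate_join(gm, loc, env)
    if cfg.vcf is None or cfg.locality_csv is None:
        raise ValueError("config needs either input paths or a simulate block")
    gm = genio.read_vcf(cfg.vcf, min_maf=cfg.min_maf, max_missing=cfg.max_missing)
    loc = genio.read_locality(cfg.locality_csv)
    env = genio.read_env(cfg.env_csv) if cfg.env_csv else None
    return genio.validate_join(gm, loc, env)


def _pairs_from_bundle(bundle: genio.Bundle, cfg: RunConfig):
    cov = popgen.genotype_covariance(bundle.genotypes)
    dist = popgen.gower_distance(cov)
    env = bundle.environment if len(bundle.environment) else None
    return build_pair_table(dist, bundle.localities, env,
                            min_geo_km=cfg.min_geo_km)


def run_ibd_analysis(cfg: RunConfig) -> dict:
    """Geography-only GDM with a locality jackknife envelope."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(cfg)
    pairs = _pairs_from_bundle(bundle, cfg)
    log.info("IBD analysis: %d pairs after %g km filter", pairs.n_pairs, cfg.min_geo_km)
    model = fit_gdm(pairs, [GEO], n_knots=cfg.n_knots, order=cfg.spline_order)
    model.to_json(out / "gdm_ibd.json")
    spline_table(model).to_csv(out / "splines_ibd.tsv", sep="\t", index=False)
    env_rep = jackknife_splines(
        pairs, [GEO], drop_fraction=cfg.drop_fraction, n_reps=cfg.n_jackknife,
        seed=cfg.seed, n_knots=cfg.n_knots, order=cfg.spline_order)
    np.savetxt(out / "jackknife_geo.tsv", env_rep.replicates[GEO], delimiter="\t")
    report = {
        "deviance_explained": model.deviance_explained,
        "n_pairs": pairs.n_pairs,
        "jackknife_skipped": env_rep.n_skipped,
    }
    (out / "report_ibd.json").write_text(json.dumps(report, indent=2))
    _finish(out, cfg, "ibd")
    return report


def run_ibe_analysis(cfg: RunConfig) -> dict:
    """Full analysis: selection, final model, CV, significance, envelopes."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(cfg)
    if not len(bundle.environment):
        raise ValueError("IBE analysis requires an environment table")
    pairs = _pairs_from_bundle(bundle, cfg)
    env = bundle.environment
    fit_kw = dict(n_knots=cfg.n_knots, order=cfg.spline_order)

    geo_model = fit_gdm(pairs, [GEO], **fit_kw)
    trace, candidates = forward_select(
        pairs, env, threshold_pct=cfg.threshold_pct, **fit_kw)
    trace.to_frame().to_csv(out / "forward_trace.tsv", sep="\t", index=False)
    log.info("forward selection kept %d candidate variable(s)", len(candidates))

    suggested = None
    if candidates:
        btrace, model, suggested = backward_select(
            pairs, env, candidates, n_perm=cfg.n_perm, seed=cfg.seed, **fit_kw)
        btrace.to_frame().to_csv(out / "backward_trace.tsv", sep="\t", index=False)
    else:
        model = geo_model
    model.to_json(out / "gdm_ibe.json")
    spline_table(model).to_csv(out / "splines_ibe.tsv", sep="\t", index=False)

    predictors = [GEO] + [p for p in model.predictors if p != GEO]
    cv = cross_validate(pairs, predictors, test_fraction=cfg.test_fraction,
                        n_reps=cfg.n_cv, seed=cfg.seed, **fit_kw)
    cv.to_csv(out / "cv.tsv", sep="\t", index=False)
    p_value = None
    if len(predictors) > 1:
        p_value = model_significance(pairs, env, predictors,
                                     n_perm=cfg.n_perm, seed=cfg.seed, **fit_kw)
    report = {
        "deviance_explained": model.deviance_explained,
        "geo_only_deviance_explained": geo_model.deviance_explained,
        "de_gain_over_geography": model.deviance_explained - geo_model.deviance_explained,
        "candidates": list(candidates),
        "final_variables": [p for p in model.predictors if p != GEO],
        "suggested_size": suggested,
        "cv_r2_mean": float(np.nanmean(cv["r2"])) if len(cv) else None,
        "significance_p": p_value,
        "n_pairs": pairs.n_pairs,
    }
    (out / "report_ibe.json").write_text(json.dumps(report, indent=2))
    _finish(out, cfg, "ibe")
    return report


def run_diversity_report(cfg: RunConfig) -> dict:
    """Per-locality H_e (and pi), with optional global F_ST between
    localities."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(cfg)
    gm, loc = bundle.genotypes, bundle.localities
    table = popgen.diversity_report(gm, loc, total_sites=cfg.total_sites)
    table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    labels = loc.set_index("sample").loc[gm.samples, "locality"].to_numpy()
    fst = None
    counts = table["n_samples"]
    if (counts >= 2).sum() >= 2:
        try:
            fst = popgen.wc_fst(gm, labels)
        except ValueError as exc:
            log.warning("F_ST unavailable: %s", exc)
    report = {
        "n_localities": int(len(table)),
        "n_flagged": int((table["flag"] != "").sum()),
        "global_fst": fst,
        "he_mean": float(np.nanmean(table["he"])),
    }
    (out / "report_diversity.json").write_text(json.dumps(report, indent=2))
    _finish(out, cfg, "diversity")
    return report


def run_ld_report(cfg: RunConfig) -> dict:
    """Windowed LD decay fits and half-decay summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(cfg)
    table, fits = ld_decay_table(
        bundle.genotypes, window_bp=cfg.ld_window, overlap_bp=cfg.ld_overlap,
        min_pairs=cfg.ld_min_pairs)
    table.to_csv(out / "ld_windows.tsv", sep="\t", index=False)
    summary = summarize_ld(fits)
    (out / "report_ld.json").write_text(json.dumps(summary, indent=2))
    _finish(out, cfg, "ld")
    return summary
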