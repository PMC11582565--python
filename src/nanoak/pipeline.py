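"""End-to-end pipeline: simulate -> select segments -> fit/compare -> rates.

Thin orchestration over the library modules; every stage logs its seed and a
summary, and all artifacts carry the master seed and a config hash so reruns
are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .event_analysis import pick_fit_segments, select_segments
from .hmm_core import CurrentTrace
from .inference import FitConfig, compare_variants, fit_model, predict_aggregate_rates
from .io import RunConfig, config_hash, write_trace
from .kinetic_model import LigandConcentrations, ModelVariant
from .reference import REFERENCE_RATES
from .trace_simulator import (
    ArtifactSpec,
    ExperimentDesign,
    default_adp_design,
    default_atp_amp_design,
    simulate_experiment,
)

log = logging.getLogger("nanoak")

__all__ = ["run_pipeline", "design_from_config", "fit_config_from_dict"]


def design_from_config(d: dict) -> ExperimentDesign:
    kind = d.get("kind", "atp_amp")
    kw = {}
    if "n_replicates" in d:
        kw["n_replicates"] = int(d["n_replicates"])
    if "duration_ms" in d:
        kw["duration_ms"] = float(d["duration_ms"])
    if kind == "atp_amp":
        design = default_atp_amp_design(**kw)
    elif kind == "adp":
        design = default_adp_design(**kw)
    elif kind == "custom":
        conds = [
            (LigandConcentrations(**c["conc"]), int(c.get("n_replicates", 2)),
             float(c.get("duration_ms", 1000.0)))
            for c in d["conditions"]
        ]
        design = ExperimentDesign(conds)
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    if "dt_ms" in d:
        design.dt_ms = float(d["dt_ms"])
    return design


def fit_config_from_dict(d: dict, seed: int) -> FitConfig:
    kw = dict(d)
    if "bounds" in kw:
        kw["bounds"] = tuple(kw["bounds"])
    if "sigma_bounds" in kw:
        kw["sigma_bounds"] = tuple(kw["sigma_bounds"])
    if "bound_overrides" in kw:
        kw["bound_overrides"] = {k: tuple(v) for k, v in kw["bound_overrides"].items()}
    return FitConfig(seed=seed, **kw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict also written to disk."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log.info("pipeline start seed=%d config=%s", cfg.seed, chash)

    variant = ModelVariant(cfg.variant)
    design = design_from_config(cfg.design)
    if cfg.artifacts:
        design.artifacts = ArtifactSpec(**cfg.artifacts)

    traces = simulate_experiment(REFERENCE_RATES, variant, design, seed=cfg.seed)
    tdir = out / "traces"
    tdir.mkdir(exist_ok=True)
    for i, tr in enumerate(traces):
        write_trace(tr, tdir / f"trace_{i:03d}.tsv")
    log.info("simulated %d traces", len(traces))

    # segment selection, then one random fit segment per condition
    by_cond: dict[str, list] = {}
    conc_of: dict[str, LigandConcentrations] = {}
    for tr in traces:
        key = tr.label.split("_rep")[0]
        by_cond.setdefault(key, []).extend(select_segments(tr))
        conc_of[key] = tr.conc
    picked = pick_fit_segments(by_cond, seed=cfg.seed)
    fit_traces = [
        CurrentTrace(seg.samples, seg.dt_ms, conc_of[cond], label=cond)
        for cond, seg in picked.items()
    ]
    log.info("selected %d fit segments", len(fit_traces))

    fit_cfg = fit_config_from_dict(cfg.fit, seed=cfg.seed)
    summary: dict = {"seed": cfg.seed, "config_hash": chash, "variant": cfg.variant}
    if cfg.mode == "compare":
        comp = compare_variants(fit_traces, ("V1", "V2", "V3"), fit_cfg)
        (out / "comparison.json").write_text(json.dumps(comp.to_dict(), indent=1, sort_keys=True))
        summary["best_variant"] = comp.best_variant
        summary["delta_loglik"] = comp.delta_loglik
        best = comp.results[comp.best_variant]
    else:
        best = fit_model(fit_traces, variant, fit_cfg)
        (out / "fit.json").write_text(json.dumps(best.to_dict(), indent=1, sort_keys=True))
        summary["loglik"] = best.loglik

    rates_out = {}
    for cond, conc in conc_of.items():
        ar = predict_aggregate_rates(best.rates, best.variant, conc, seed=cfg.seed)
        rates_out[cond] = {
            "lid_closing_per_s": ar.lid_closing,
            "lid_opening_per_s": ar.lid_opening,
            "nmp_closing_per_s": ar.nmp_closing,
        }
    summary["aggregate_rates"] = rates_out
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline done: %s", out / "summary.json")
    return summary
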