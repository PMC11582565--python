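"""On-disk formats and pipeline configuration.

A trace is stored as two-column tab-separated text (time_ms, current_pA) with
a JSON sidecar ``<path>.meta.json`` holding the sampling interval, ligand
concentrations (mM) and provenance.  Output is deterministic byte-for-byte
for identical inputs (full double precision, fixed ordering).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hmm_core import CurrentTrace
from .kinetic_model import LigandConcentrations

__all__ = [
    "read_trace",
    "write_trace",
    "sidecar_path",
    "RunConfig",
    "load_run_config",
    "config_hash",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Write samples + sidecar metadata; rejects empty traces."""
    path = Path(path)
    if trace.n_samples < 1:
        raise ValueError("refusing to write an empty trace")
    t = np.arange(trace.n_samples) * trace.dt_ms
    lines = ["time_ms\tcurrent_pA"]
    lines += [f"{ti:.17g}\t{si:.17g}" for ti, si in zip(t, trace.samples)]
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "dt_ms": trace.dt_ms,
        "concentrations_mM": trace.conc.to_dict(),
        "label": trace.label,
        "n_samples": trace.n_samples,
        "units": {"current": "pA", "time": "ms", "concentration": "mM"},
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_trace(path: str | Path) -> CurrentTrace:
    """Load a trace; validates metadata presence and sampling-interval consistency."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar metadata {side}")
    meta = json.loads(side.read_text())
    for key in ("dt_ms", "concentrations_mM"):
        if key not in meta:
            raise ValueError(f"sidecar metadata missing required field {key!r}")
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if raw.shape[1] != 2:
        raise ValueError("trace file must have two columns (time_ms, current_pA)")
    t, samples = raw[:, 0], raw[:, 1]
    dt = float(meta["dt_ms"])
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("inconsistent sampling interval in trace file")
    conc = LigandConcentrations.from_dict(meta["concentrations_mM"])
    return CurrentTrace(samples, dt, conc, meta.get("label", ""))


_RUN_KEYS = {
    "variant",
    "seed",
    "out_dir",
    "design",
    "fit",
    "mode",
    "artifacts",
    "schema_version",
}
_DESIGN_KEYS = {"conditions", "n_replicates", "duration_ms", "dt_ms", "kind"}
_FIT_KEYS = {
    "bounds",
    "step_tol",
    "max_iter",
    "n_starts",
    "fit_emissions",
    "sigma_bounds",
    "mean_offset_halfwidth",
    "bound_overrides",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    variant: str = "V3"
    seed: int = 0
    out_dir: str = "results/run"
    mode: str = "compare"  # "fit" | "compare"
    design: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    artifacts: dict | None = None
    schema_version: int = 1


def load_run_config(path_or_dict) -> RunConfig:
    if isinstance(path_or_dict, (str, Path)):
        doc = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        doc = dict(path_or_dict)
    if not isinstance(doc, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(doc) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for sub, allowed in (("design", _DESIGN_KEYS), ("fit", _FIT_KEYS)):
        bad = set(doc.get(sub, {}) or {}) - allowed
        if bad:
            raise ValueError(f"unknown {sub} keys: {sorted(bad)}")
    cfg = RunConfig(**doc)
    from .kinetic_model import ModelVariant

    ModelVariant(cfg.variant)  # validates before any computation
    if cfg.mode not in ("fit", "compare"):
        raise ValueError("mode must be 'fit' or 'compare'")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
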