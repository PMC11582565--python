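"""Synthetic nanopore-trace generator for the ligand-gated kinetic model.

Simulates exact CTMC sample paths (Gillespie), samples them at the recording
interval, and adds grouped Gaussian current noise, reproducing the
statistical structure the HMM likelihood assumes: conditionally independent
normal emissions around conformation-specific levels near -180 to -245 pA.
Artifact injection (open-pore and shallow excursions) exercises the
segment-selection filters.  Everything is reproducible from a single master
seed via numpy SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._forward import gillespie
from .hmm_core import CurrentTrace, EmissionModel, discretize, stationary_distribution
from .kinetic_model import (
    GeneratorMatrix,
    LigandConcentrations,
    ModelVariant,
    RateVector,
    build_generator,
    build_state_space,
)
from .reference import (
    ADP_CONDITIONS_MM,
    ATP_AMP_CONDITIONS,
    OPEN_PORE_PA,
    default_emission_model,
)

__all__ = [
    "JumpPath",
    "ExperimentDesign",
    "ArtifactSpec",
    "sample_ctmc_path",
    "discretize_path",
    "emit_trace",
    "simulate_experiment",
    "inject_artifacts",
    "simulate_dose_response",
    "default_atp_amp_design",
    "default_adp_design",
]

_SEED_MOD = 2**31 - 1


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % _SEED_MOD) for s in ss.spawn(n)]


@dataclass
class JumpPath:
    """CTMC sample path: visited states with sojourn durations (ms)."""

    states: np.ndarray  # state indices
    sojourns_ms: np.ndarray
    total_ms: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.sojourns_ms <= 0):
            raise ValueError("sojourns must be positive")
        if abs(self.sojourns_ms.sum() - self.total_ms) > 1e-9 * max(1.0, self.total_ms):
            raise ValueError("sojourns must sum to the total duration")


def sample_ctmc_path(
    Q: GeneratorMatrix | np.ndarray,
    duration_ms: float,
    initial: np.ndarray | int | None = None,
    seed: int = 0,
) -> JumpPath:
    """Exact stochastic simulation of the CTMC for duration_ms.

    ``initial`` may be a state index, a probability vector, or None (stationary
    distribution of the generator).  The last sojourn is truncated at the end
    of the path.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    mat = Q.Q if isinstance(Q, GeneratorMatrix) else np.asarray(Q, dtype=float)
    n = mat.shape[0]
    off = mat.copy()
    np.fill_diagonal(off, 0.0)
    exit_rates = off.sum(axis=1)
    q_cum = np.cumsum(off, axis=1)
    rng = np.random.default_rng(seed)
    if initial is None:
        dist = stationary_distribution(discretize(mat, 1.0))
        init_state = int(rng.choice(n, p=dist))
    elif np.ndim(initial) == 0:
        init_state = int(initial)
        if not 0 <= init_state < n:
            raise ValueError("initial state out of range")
    else:
        dist = np.asarray(initial, dtype=float)
        if dist.shape != (n,) or np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("invalid initial distribution")
        init_state = int(rng.choice(n, p=dist))
    kernel_seed = int(rng.integers(_SEED_MOD))
    states, sojourns = gillespie(q_cum, exit_rates, init_state, float(duration_ms), kernel_seed)
    return JumpPath(states, sojourns, float(duration_ms), seed)


def discretize_path(path: JumpPath, dt_ms: float) -> np.ndarray:
    """State occupied at each sampling instant t = i*dt, i = 0..floor(T/dt)-1.

    Sojourns shorter than dt that straddle no sampling instant leave no sample
    (aliasing inherent to discrete sampling).
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    n_samples = int(np.floor(path.total_ms / dt_ms + 1e-12))
    instants = np.arange(n_samples) * dt_ms
    ends = np.cumsum(path.sojourns_ms)
    idx = np.searchsorted(ends, instants, side="right")
    idx = np.minimum(idx, len(path.states) - 1)
    return path.states[idx]


def emit_trace(
    states: np.ndarray,
    em: EmissionModel,
    dt_ms: float,
    conc: LigandConcentrations,
    seed: int = 0,
    label: str = "",
    variant: ModelVariant | str = "V3",
) -> CurrentTrace:
    """Gaussian current sample per time point, conditioned on the hidden state."""
    space = build_state_space(variant if isinstance(variant, ModelVariant) else ModelVariant(variant))
    mus, sigmas = em.per_state(space)
    rng = np.random.default_rng(seed)
    samples = mus[states] + sigmas[states] * rng.standard_normal(len(states))
    return CurrentTrace(samples, dt_ms, conc, label)


@dataclass
class ArtifactSpec:
    """Sporadic excursions the segment filters must remove."""

    n_open_pore: int = 0
    n_shallow: int = 0
    open_pore_mean_pA: float = OPEN_PORE_PA
    shallow_mean_pA: float = -140.0
    duration_ms: float = 100.0
    sigma_pA: float = 8.0
    positions_ms: Sequence[float] | None = None  # explicit starts; else random


@dataclass
class ExperimentDesign:
    """Concentration series with replicates: the synthetic campaign layout.

    Defaults mirror the recording campaign: 2-4 replicates per condition
    (default 3) and per-trace durations within the 500-10000 ms range of the
    deposited series (default 2000 ms).
    """

    conditions: list[tuple[LigandConcentrations, int, float]]  # (conc, n_rep, duration_ms)
    dt_ms: float = 0.2
    emissions: EmissionModel = field(default_factory=default_emission_model)
    artifacts: ArtifactSpec | None = None

    def __post_init__(self) -> None:
        for conc, n_rep, dur in self.conditions:
            if dur < self.dt_ms:
                raise ValueError("each condition needs at least one sample")
            if n_rep < 1:
                raise ValueError("need at least one replicate")


def default_atp_amp_design(
    n_replicates: int = 3, duration_ms: float = 2000.0, **kw
) -> ExperimentDesign:
    conds = [
        (LigandConcentrations(atp_mM=a, amp_mM=b), n_replicates, duration_ms)
        for a, b in ATP_AMP_CONDITIONS
    ]
    return ExperimentDesign(conds, **kw)


def default_adp_design(
    n_replicates: int = 3, duration_ms: float = 2000.0, **kw
) -> ExperimentDesign:
    conds = [
        (LigandConcentrations(adp_mM=c), n_replicates, duration_ms)
        for c in ADP_CONDITIONS_MM
    ]
    return ExperimentDesign(conds, **kw)


def simulate_experiment(
    rates: RateVector,
    variant: ModelVariant | str,
    design: ExperimentDesign,
    seed: int = 0,
) -> list[CurrentTrace]:
    """One trace per replicate per condition; initial states drawn from the
    condition's stationary distribution; bit-reproducible given the seed."""
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    n_total = sum(n for _, n, _ in design.conditions)
    seeds = iter(_child_seeds(seed, 2 * n_total))
    traces: list[CurrentTrace] = []
    for ci, (conc, n_rep, dur) in enumerate(design.conditions):
        gen = build_generator(rates, conc, variant)
        for rep in range(n_rep):
            s_path, s_emit = next(seeds), next(seeds)
            path = sample_ctmc_path(gen, dur, initial=None, seed=s_path)
            states = discretize_path(path, design.dt_ms)
            tr = emit_trace(
                states, design.emissions, design.dt_ms, conc,
                seed=s_emit, label=f"cond{ci}_rep{rep}", variant=variant,
            )
            if design.artifacts is not None:
                tr = inject_artifacts(tr, design.artifacts, seed=s_emit + 1)
            traces.append(tr)
    return traces


def inject_artifacts(trace: CurrentTrace, spec: ArtifactSpec, seed: int = 0) -> CurrentTrace:
    """Overwrite stretches with open-pore (~ -433 pA) or shallow (>= -160 pA)
    current; positions random unless given explicitly."""
    n_art = spec.n_open_pore + spec.n_shallow
    if n_art == 0:
        return CurrentTrace(trace.samples.copy(), trace.dt_ms, trace.conc, trace.label)
    rng = np.random.default_rng(seed)
    samples = trace.samples.copy()
    n_len = max(1, int(round(spec.duration_ms / trace.dt_ms)))
    means = [spec.open_pore_mean_pA] * spec.n_open_pore + [spec.shallow_mean_pA] * spec.n_shallow
    if spec.positions_ms is not None:
        if len(spec.positions_ms) != n_art:
            raise ValueError("positions_ms must match the number of artifacts")
        starts = [int(round(p / trace.dt_ms)) for p in spec.positions_ms]
    else:
        hi = max(1, trace.n_samples - n_len)
        starts = sorted(int(x) for x in rng.integers(0, hi, size=n_art))
    for start, mean in zip(starts, means):
        stop = min(trace.n_samples, start + n_len)
        samples[start:stop] = mean + spec.sigma_pA * rng.standard_normal(stop - start)
    return CurrentTrace(samples, trace.dt_ms, trace.conc, trace.label)


def simulate_dose_response(
    kd: float,
    n_hill: float,
    y_max: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-curve percent-closed data: y = y_max c^n / (K_D^n + c^n) + noise,
    clipped to [0, 100].  Returns columns (concentration, replicate, response)."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        y = y_max * conc**n_hill / (kd**n_hill + conc**n_hill)
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(conc.size)
        y = np.clip(y, 0.0, 100.0)
        rows.append(pd.DataFrame({"concentration": conc, "replicate": rep, "response": y}))
    return pd.concat(rows, ignore_index=True)
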