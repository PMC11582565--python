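"""Discrete-time HMM over the conformational CTMC and its scaled forward likelihood.

The continuous-time chain with generator Q (s^-1) is discretized at the data
sampling interval dt (ms) into Gamma = exp(dt.Q).  Emissions are Gaussian per
*emission group*: hidden states sharing the same LID/NMP arrangement emit from
the same distribution, so ligand binding is invisible in the current.  The
likelihood of a trace y_1..y_T is

    L = delta' ( prod_t Gamma diag(phi(y_t)) ) 1

with delta' the stationary distribution of Gamma.  Note the convention: the
transition matrix is applied before *every* emission, including the first —
the stationary prior is propagated one step before the first sample is scored.
Per-step normalization of the forward vector guards against underflow; the
log-likelihood is recovered from the accumulated log scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from ._forward import forward_scan
from .kinetic_model import (
    EMISSION_GROUPS,
    GeneratorMatrix,
    LigandConcentrations,
    ModelVariant,
    RateVector,
    StateSpace,
    build_generator,
    build_state_space,
)

__all__ = [
    "TransitionMatrix",
    "EmissionModel",
    "CurrentTrace",
    "ForwardResult",
    "discretize",
    "stationary_distribution",
    "emission_density_vector",
    "forward_loglik",
    "forward_loglik_unscaled",
    "joint_loglik",
    "DEFAULT_DT_MS",
]

DEFAULT_DT_MS = 0.2  # equal to the 5 kHz effective sampling of the recordings


@dataclass
class TransitionMatrix:
    """One-step transition probabilities Gamma = exp(dt.Q), dt in ms."""

    gamma: np.ndarray
    dt_ms: float
    state_space: StateSpace | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("transition matrix must be square")
        self.gamma = g

    @property
    def n(self) -> int:
        return self.gamma.shape[0]


def discretize(Q: GeneratorMatrix | np.ndarray, dt_ms: float = DEFAULT_DT_MS) -> TransitionMatrix:
    """Matrix exponential of (dt.Q); Q in s^-1, dt in ms (converted internally)."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if isinstance(Q, GeneratorMatrix):
        mat, space = Q.Q, Q.state_space
    else:
        mat, space = np.asarray(Q, dtype=float), None
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("generator must be square")
    gamma = expm(mat * (dt_ms / 1000.0))
    # exp of a generator is stochastic up to roundoff; clip tiny negatives
    gamma = np.clip(gamma, 0.0, None)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return TransitionMatrix(gamma, dt_ms, space)


def stationary_distribution(G: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Unique stationary row vector of an irreducible stochastic matrix."""
    gamma = G.gamma if isinstance(G, TransitionMatrix) else np.asarray(G, dtype=float)
    n = gamma.shape[0]
    if n == 1:
        return np.array([1.0])
    from scipy.sparse.csgraph import connected_components

    # Uniqueness needs exactly one closed communicating class (e.g. at zero
    # second-ligand concentration the two-ligand states are unreachable but
    # the stationary distribution is still unique).
    ncomp, labels = connected_components(gamma > 0, directed=True, connection="strong")
    closed = 0
    for c in range(ncomp):
        members = labels == c
        if not gamma[np.ix_(members, ~members)].any():
            closed += 1
    if closed != 1:
        raise ValueError("stationary distribution is not unique (reducible chain)")
    # solve delta (Gamma - I) = 0 with sum(delta) = 1
    A = np.vstack([gamma.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


@dataclass
class EmissionModel:
    """Grouped Gaussian emissions: one (mu, sigma) per emission group, in pA.

    ``offsets`` shift group means (e.g. per-molecule baseline wander) without
    touching the canonical levels.
    """

    group_means: dict[str, float]
    group_sigmas: dict[str, float]
    offsets: dict[str, float] = field(default_factory=dict)
    groups: tuple[str, ...] = EMISSION_GROUPS

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in self.group_means or g not in self.group_sigmas:
                raise ValueError(f"missing emission parameters for group {g}")
            if self.group_sigmas[g] <= 0:
                raise ValueError(f"sigma for group {g} must be positive")

    def mean(self, group: str) -> float:
        return self.group_means[group] + self.offsets.get(group, 0.0)

    def per_state(self, space: StateSpace) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) arrays aligned with the state roster."""
        mus = np.array([self.mean(s.emission_group) for s in space.states])
        sigmas = np.array([self.group_sigmas[s.emission_group] for s in space.states])
        return mus, sigmas

    def with_offsets(self, offsets: dict[str, float]) -> "EmissionModel":
        return EmissionModel(dict(self.group_means), dict(self.group_sigmas), dict(offsets), self.groups)


@dataclass
class CurrentTrace:
    """Sampled nanopore current (pA, signed; blockades negative) with metadata."""

    samples: np.ndarray
    dt_ms: float
    conc: LigandConcentrations
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("trace needs at least one sample")
        if self.dt_ms <= 0:
            raise ValueError("sampling interval must be positive")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms


@dataclass
class ForwardResult:
    loglik: float
    log_scale: np.ndarray
    stationary: np.ndarray
    filtered: np.ndarray | None = None


def _state_logdens(samples: np.ndarray, em: EmissionModel, space: StateSpace) -> np.ndarray:
    """(T, n_states) log emission densities, computed per group then broadcast."""
    gidx = space.group_index(em.groups)
    mus = np.array([em.mean(g) for g in em.groups])
    sigmas = np.array([em.group_sigmas[g] for g in em.groups])
    z = (samples[:, None] - mus[None, :]) / sigmas[None, :]
    logphi = -0.5 * z**2 - np.log(sigmas[None, :] * np.sqrt(2.0 * np.pi))
    return logphi[:, gidx]


def emission_density_vector(y: float, em: EmissionModel, space: StateSpace | None = None) -> np.ndarray:
    """Per-state Gaussian density phi(y; mu(m), sigma(m)); grouped states match."""
    space = space or build_state_space("V3")
    return np.exp(_state_logdens(np.atleast_1d(float(y)), em, space)[0])


def forward_loglik(
    G: TransitionMatrix,
    em: EmissionModel,
    trace: CurrentTrace,
    space: StateSpace | None = None,
    stationary: np.ndarray | None = None,
    keep_filtered: bool = False,
) -> ForwardResult:
    """Scaled forward log-likelihood of one trace."""
    samples = trace.samples
    if not np.all(np.isfinite(samples)):
        raise ValueError("trace contains non-finite samples")
    space = space or G.state_space or build_state_space("V3")
    if G.n != space.n:
        raise ValueError("transition matrix and state space sizes differ")
    delta = stationary if stationary is not None else stationary_distribution(G)
    logdens = _state_logdens(samples, em, space)
    ll, log_scale, filtered = forward_scan(
        np.ascontiguousarray(G.gamma), np.ascontiguousarray(logdens), np.ascontiguousarray(delta)
    )
    return ForwardResult(
        loglik=float(ll),
        log_scale=log_scale,
        stationary=delta,
        filtered=filtered if keep_filtered else None,
    )


def forward_loglik_unscaled(
    G: TransitionMatrix, em: EmissionModel, trace: CurrentTrace, space: StateSpace | None = None
) -> float:
    """Direct (unnormalized) evaluation of log L; for short traces / testing."""
    space = space or G.state_space or build_state_space("V3")
    delta = stationary_distribution(G)
    dens = np.exp(_state_logdens(trace.samples, em, space))
    alpha = delta.copy()
    for t in range(trace.n_samples):
        alpha = (alpha @ G.gamma) * dens[t]
    return float(np.log(alpha.sum()))


def joint_loglik(
    rates: RateVector,
    em: EmissionModel,
    traces: Sequence[CurrentTrace],
    variant: ModelVariant,
    dt_ms: float | None = None,
    per_trace_offsets: Sequence[dict[str, float]] | None = None,
) -> float:
    """Sum of per-trace log-likelihoods; Gamma rebuilt per concentration condition.

    Independent recordings multiply in likelihood, so their logs add.  The
    stationary prior is computed from each trace's own transition matrix.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    space = build_state_space(variant)
    cache: dict[tuple, tuple[TransitionMatrix, np.ndarray]] = {}
    total = 0.0
    for i, tr in enumerate(traces):
        dt = dt_ms if dt_ms is not None else tr.dt_ms
        key = (tr.conc.ligands_for(variant), dt)
        if key not in cache:
            G = discretize(build_generator(rates, tr.conc, variant), dt)
            cache[key] = (G, stationary_distribution(G))
        G, delta = cache[key]
        em_i = em if per_trace_offsets is None else em.with_offsets(per_trace_offsets[i])
        total += forward_loglik(G, em_i, tr, space, stationary=delta).loglik
    return total
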