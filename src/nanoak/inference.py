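"""Maximum-likelihood estimation of kinetic rates and model-variant comparison.

The joint likelihood over all concentration conditions is maximized directly
(no Baum-Welch): bounded local optimization over log10-transformed rates,
multi-started from log-uniform random points within the bounds.  Optionally
the grouped emission means (as bounded offsets around their canonical levels)
and standard deviations are co-estimated.  Variant comparison refits each
topology on the same traces and tabulates maximal log-likelihoods; aggregate
LID opening/closing rates are predicted by simulating a long sample path and
inverting mean group dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .hmm_core import CurrentTrace, EmissionModel, joint_loglik
from .kinetic_model import (
    LigandConcentrations,
    ModelVariant,
    RateVector,
    build_generator,
    build_state_space,
    free_parameters,
)
from .reference import default_emission_model
from .trace_simulator import sample_ctmc_path

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "AggregateRates",
    "fit_model",
    "compare_variants",
    "predict_aggregate_rates",
    "bootstrap_confidence",
    "derive_bound_overrides",
    "multistart_minimize",
    "aggregate_rates_for_generator",
]

_SEED_MOD = 2**31 - 1


@dataclass
class FitConfig:
    """Optimizer settings (defaults follow the estimation protocol).

    Rates are optimized as log10 values inside ``bounds`` (default 1e-1..1e6
    s^-1, i.e. [-1, 6] in log10); ``bound_overrides`` narrows individual
    parameters, e.g. from dwell-time pre-analysis.  Emission co-estimation
    adds one mean offset per group (within +/- ``mean_offset_halfwidth`` pA)
    and one sigma per group (within ``sigma_bounds`` pA).
    """

    bounds: tuple[float, float] = (1e-1, 1e6)
    step_tol: float = 1e-3
    max_iter: int = 200
    n_starts: int = 6
    seed: int = 0
    mean_offset_halfwidth: float = 3.0
    sigma_bounds: tuple[float, float] = (7.0, 10.0)
    fit_emissions: bool = True
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    dt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy low < high")
        if self.n_starts < 1:
            raise ValueError("need at least one multistart")


@dataclass
class StartRecord:
    x0: np.ndarray
    loglik0: float
    loglik: float
    converged: bool


@dataclass
class FitResult:
    rates: RateVector
    emissions: EmissionModel
    loglik: float
    variant: ModelVariant
    starts: list[StartRecord]
    seed: int
    param_names: list[str]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.variant_id,
            "loglik": self.loglik,
            "rates": self.rates.to_dict(),
            "group_means": {g: self.emissions.mean(g) for g in self.emissions.groups},
            "group_sigmas": dict(self.emissions.group_sigmas),
            "seed": self.seed,
            "starts": [
                {"loglik0": s.loglik0, "loglik": s.loglik, "converged": s.converged}
                for s in self.starts
            ],
        }


@dataclass
class ModelComparison:
    results: dict[str, FitResult]

    @property
    def best_variant(self) -> str:
        return max(self.results, key=lambda v: self.results[v].loglik)

    @property
    def delta_loglik(self) -> dict[str, float]:
        """Log-likelihood difference of each variant vs the best (<= 0)."""
        best = self.results[self.best_variant].loglik
        return {v: r.loglik - best for v, r in self.results.items()}

    def to_dict(self) -> dict:
        return {
            "best_variant": self.best_variant,
            "delta_loglik": self.delta_loglik,
            "results": {v: r.to_dict() for v, r in self.results.items()},
        }


@dataclass
class AggregateRates:
    """Group-level rates from a simulated sample path (completed dwells only)."""

    lid_closing: float | None
    lid_opening: float | None
    nmp_closing: float | None
    n_open_dwells: int
    n_closed_dwells: int
    duration_ms: float
    seed: int


def _pack(config: FitConfig, names: list[str], groups: tuple[str, ...]):
    """Bounds and start-sampler for the optimizer vector.

    Layout: log10 rates (len(names)), then [offsets per group, sigmas per
    group] when emissions are co-estimated.
    """
    lo, hi = np.log10(config.bounds[0]), np.log10(config.bounds[1])
    lob = [lo] * len(names)
    hib = [hi] * len(names)
    for i, nm in enumerate(names):
        if nm in config.bound_overrides:
            l, h = config.bound_overrides[nm]
            lob[i], hib[i] = np.log10(l), np.log10(h)
    if config.fit_emissions:
        w = config.mean_offset_halfwidth
        lob += [-w] * len(groups) + [config.sigma_bounds[0]] * len(groups)
        hib += [w] * len(groups) + [config.sigma_bounds[1]] * len(groups)
    return np.array(lob), np.array(hib)


def _unpack(
    x: np.ndarray,
    names: list[str],
    base_em: EmissionModel,
    fit_emissions: bool,
) -> tuple[RateVector, EmissionModel]:
    rates = RateVector.from_dict({nm: 10.0 ** x[i] for i, nm in enumerate(names)})
    if not fit_emissions:
        return rates, base_em
    groups = base_em.groups
    k = len(names)
    offsets = {g: float(x[k + i]) for i, g in enumerate(groups)}
    sigmas = {g: float(x[k + len(groups) + i]) for i, g in enumerate(groups)}
    em = EmissionModel(dict(base_em.group_means), sigmas, offsets, groups)
    return rates, em


def multistart_minimize(
    negll,
    lob: np.ndarray,
    hib: np.ndarray,
    config: FitConfig,
    fixed_tail: np.ndarray | None = None,
):
    """Best-of-N bounded local minimization from log-uniform random starts.

    ``fixed_tail`` pins the last len(fixed_tail) coordinates of every start
    (used for emission offsets/sigmas, which have natural neutral starts).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    starts: list[StartRecord] = []
    best = None
    for _ in range(config.n_starts):
        x0 = lob + (hib - lob) * rng.random(lob.size)
        if fixed_tail is not None and fixed_tail.size:
            x0[-fixed_tail.size:] = fixed_tail
        f0 = negll(x0)
        res = minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lob, hib)),
            options={
                "maxiter": config.max_iter,
                "ftol": config.step_tol * 1e-6,
                "gtol": 1e-6,
                "eps": 1e-4,
            },
        )
        starts.append(StartRecord(x0, -f0, -res.fun, bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("no multistart produced a finite likelihood")
    return best, starts


def fit_model(
    traces: Sequence[CurrentTrace],
    variant: ModelVariant | str,
    config: FitConfig | None = None,
    emissions: EmissionModel | None = None,
    extra_starts: Sequence[dict[str, float]] | None = None,
) -> FitResult:
    """Best-of-N-multistart bounded ML fit of a model variant.

    Deterministic given ``config.seed``: start points are log-uniform within
    the bounds, drawn from seeds spawned off the master seed.  ``extra_starts``
    adds warm starts given as rate dicts in natural units (e.g. another
    variant's solution when comparing nested topologies); values are clipped
    into the bounds.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    config = config or FitConfig()
    base_em = emissions or default_emission_model()
    names = free_parameters(variant)
    lob, hib = _pack(config, names, base_em.groups)

    def negll(x: np.ndarray) -> float:
        rates, em = _unpack(x, names, base_em, config.fit_emissions)
        try:
            ll = joint_loglik(rates, em, traces, variant, dt_ms=config.dt_ms)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    n_rates = len(names)
    fixed_tail = None
    if config.fit_emissions:
        # start offsets at 0 and sigmas mid-interval rather than random
        fixed_tail = np.r_[
            np.zeros(len(base_em.groups)),
            np.full(len(base_em.groups), 0.5 * sum(config.sigma_bounds)),
        ]
    best, starts = multistart_minimize(negll, lob, hib, config, fixed_tail=fixed_tail)
    for warm in extra_starts or ():
        x0 = lob.copy()
        if fixed_tail is not None and fixed_tail.size:
            x0[-fixed_tail.size:] = fixed_tail
        for i, nm in enumerate(names):
            if nm in warm and warm[nm] > 0:
                x0[i] = np.clip(np.log10(warm[nm]), lob[i], hib[i])
        f0 = negll(x0)
        res = minimize(
            negll, x0, method="L-BFGS-B", bounds=list(zip(lob, hib)),
            options={"maxiter": config.max_iter, "ftol": config.step_tol * 1e-6,
                     "gtol": 1e-6, "eps": 1e-4},
        )
        starts.append(StartRecord(x0, -f0, -res.fun, bool(res.success)))
        if res.fun < best.fun:
            best = res
    rates, em = _unpack(best.x, names, base_em, config.fit_emissions)
    rates = replace(rates)  # ties applied at generator build; stored as fitted
    return FitResult(
        rates=rates,
        emissions=em,
        loglik=-float(best.fun),
        variant=variant,
        starts=starts,
        seed=config.seed,
        param_names=names,
    )


def compare_variants(
    traces: Sequence[CurrentTrace],
    variants: Sequence[ModelVariant | str] = ("V1", "V2", "V3"),
    config: FitConfig | None = None,
    emissions: EmissionModel | None = None,
    cross_seed: bool = True,
) -> ModelComparison:
    """Fit each variant on the same traces and rank by maximal log-likelihood.

    With ``cross_seed`` each variant is polished once more from the other
    variants' solutions (the topologies share their parameterization, and V1
    is nested in V3), which stops a lucky basin found under one variant from
    distorting the comparison.  Deterministic given the config seed.
    """
    ids = [v if isinstance(v, str) else v.variant_id for v in variants]
    config = config or FitConfig()
    results: dict[str, FitResult] = {}
    for vid in ids:
        results[vid] = fit_model(traces, vid, config, emissions)
    if cross_seed and len(ids) > 1:
        solutions = {
            vid: {nm: getattr(r.rates, nm) for nm in r.param_names}
            for vid, r in results.items()
        }
        polish_cfg = replace(config, n_starts=1)
        for vid in ids:
            warm = [sol for other, sol in solutions.items() if other != vid]
            polished = fit_model(traces, vid, polish_cfg, emissions, extra_starts=warm)
            if polished.loglik > results[vid].loglik:
                results[vid] = polished
    return ModelComparison(results)


def _group_dwells(path_states, sojourns, member_mask):
    """Completed dwell times per group from a jump path.

    A dwell is completed when it ends with a switch to the other group; the
    trailing (truncated) dwell is discarded.
    """
    grp = member_mask[path_states].astype(np.int8)
    change = np.empty(grp.size, dtype=bool)
    change[0] = True
    change[1:] = grp[1:] != grp[:-1]
    run_id = np.cumsum(change) - 1
    dwell = np.bincount(run_id, weights=sojourns)
    labels = grp[change]
    return dwell[:-1], labels[:-1]


def aggregate_rates_for_generator(
    Q: np.ndarray,
    lid_closed_mask: np.ndarray,
    duration_ms: float = 20000.0,
    seed: int = 0,
    nmp_closed_mask: np.ndarray | None = None,
    initial=None,
) -> AggregateRates:
    """Aggregate group rates for an arbitrary generator matrix.

    One sample path is simulated; the inverse mean completed dwell time in the
    group-open (group-closed) states is the closing (opening) rate.  A group
    with no completed dwell yields None.  If the default stationary initial
    state is undefined (degenerate generators with unreachable absorbing
    states), the initial state is drawn uniformly instead.
    """
    try:
        path = sample_ctmc_path(Q, duration_ms, initial=initial, seed=seed)
    except ValueError as err:
        if initial is not None or "not unique" not in str(err):
            raise
        n = np.asarray(Q).shape[0]
        path = sample_ctmc_path(Q, duration_ms, initial=np.full(n, 1.0 / n), seed=seed)
    dwell, labels = _group_dwells(path.states, path.sojourns_ms, np.asarray(lid_closed_mask))
    open_dw = dwell[labels == 0]
    closed_dw = dwell[labels == 1]
    nmp_closing = None
    if nmp_closed_mask is not None:
        ndw, nlab = _group_dwells(path.states, path.sojourns_ms, np.asarray(nmp_closed_mask))
        nmp_open = ndw[nlab == 0]
        nmp_closing = 1000.0 / nmp_open.mean() if nmp_open.size else None
    return AggregateRates(
        lid_closing=1000.0 / open_dw.mean() if open_dw.size else None,
        lid_opening=1000.0 / closed_dw.mean() if closed_dw.size else None,
        nmp_closing=nmp_closing,
        n_open_dwells=int(open_dw.size),
        n_closed_dwells=int(closed_dw.size),
        duration_ms=duration_ms,
        seed=seed,
    )


def predict_aggregate_rates(
    rates: RateVector,
    variant: ModelVariant | str,
    conc: LigandConcentrations,
    duration_ms: float = 20000.0,
    seed: int = 0,
) -> AggregateRates:
    """Aggregate LID (and NMP) closing/opening rates at one condition.

    One sample path is simulated from the CTMC; the inverse mean dwell time in
    the LID-open (LID-closed) group is the LID closing (opening) rate.  A
    group with no completed dwell yields None.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    gen = build_generator(rates, conc, variant)
    space = gen.state_space
    return aggregate_rates_for_generator(
        gen.Q,
        space.lid_closed,
        duration_ms,
        seed,
        nmp_closed_mask=space.nmp_closed,
    )


def _clip_bounds(lo: float, hi: float, global_bounds: tuple[float, float]) -> tuple[float, float]:
    lo = max(lo, global_bounds[0])
    hi = min(hi, global_bounds[1])
    if lo >= hi:  # degenerate estimate; fall back to the global range
        return global_bounds
    return lo, hi


def derive_bound_overrides(
    traces: Sequence[CurrentTrace],
    emissions: EmissionModel | None = None,
    global_bounds: tuple[float, float] = (1e-1, 1e6),
    smooth_ms: float = 0.6,
    min_dwell_ms: float = 0.6,
) -> dict[str, tuple[float, float]]:
    """Rough per-parameter rate bounds inferred from event-level dwell statistics.

    The observable aggregate kinetics pin several elementary rates to within
    one or two orders of magnitude before any likelihood evaluation: the LID
    opening rate from mean dwell in LID-closed levels, the first-ligand
    association rate from the closing frequency per unit concentration, the
    NMP rates from M1/M3 dwells and M2->M3 transition frequencies, and the
    anomalous-level exchange rates from M0 dwells and visit frequencies.
    Rates with no direct event-level signature (ligand unbinding, hidden
    second-ligand exchange) keep the global bounds.  Multistart sampling
    within these narrowed boxes keeps random starts out of hopeless basins,
    in the same spirit as constraining rates that can be read off the data.
    """
    from .event_analysis import idealize

    em = emissions or default_emission_model()
    levels = {g: em.mean(g) for g in em.groups}
    lid_closed_levels = {"M2", "M3"}

    # pooled statistics across traces
    open_dwells: list[float] = []        # LID-open dwells at the highest first-ligand conc
    closed_dwells_nolig2: list[float] = []   # LID-closed dwells without second ligand
    closed_dwells_lig2: list[float] = []     # with second ligand present
    m1_dwells: list[float] = []
    m3_dwells: list[float] = []
    m0_dwells: list[float] = []
    m2_time_ms = 0.0
    m2_to_m3 = 0
    m_time_low = 0.0
    m_to_m1 = 0
    non_m0_time = 0.0
    m0_entries = 0

    c1_all = []
    for tr in traces:
        c1 = max(tr.conc.atp_mM, tr.conc.adp_mM)
        c1_all.append(c1)
    c1_max = max(c1_all) if c1_all else 0.0

    for tr in traces:
        c1 = max(tr.conc.atp_mM, tr.conc.adp_mM)
        c2 = max(tr.conc.amp_mM, tr.conc.adp_mM)
        events = idealize(tr.samples, levels, dt_ms=tr.dt_ms,
                          min_dwell_ms=min_dwell_ms, smooth_ms=smooth_ms)
        # collapse into LID-open / LID-closed runs
        run_label = [e.level in lid_closed_levels for e in events]
        run_dwell: list[float] = []
        runs: list[bool] = []
        for lab, e in zip(run_label, events):
            if runs and runs[-1] == lab:
                run_dwell[-1] += e.dwell_ms
            else:
                runs.append(lab)
                run_dwell.append(e.dwell_ms)
        for lab, dw in zip(runs[:-1], run_dwell[:-1]):  # completed runs only
            if lab:
                (closed_dwells_lig2 if c2 > 0 else closed_dwells_nolig2).append(dw)
            elif c1 == c1_max and c1 > 0:
                open_dwells.append(dw)
        for prev, nxt in zip(events[:-1], events[1:]):
            if prev.level == "M2" and nxt.level == "M3":
                m2_to_m3 += 1
            if prev.level == "M" and nxt.level == "M1":
                m_to_m1 += 1
            if nxt.level == "M0":
                m0_entries += 1
        for e in events[:-1]:
            if e.level == "M1":
                m1_dwells.append(e.dwell_ms)
            elif e.level == "M3":
                m3_dwells.append(e.dwell_ms)
            elif e.level == "M0":
                m0_dwells.append(e.dwell_ms)
        m2_time_ms += sum(e.dwell_ms for e in events if e.level == "M2")
        m_time_low += sum(e.dwell_ms for e in events if e.level == "M")
        non_m0_time += sum(e.dwell_ms for e in events if e.level != "M0")

    out: dict[str, tuple[float, float]] = {}

    def band(est: float | None, down: float, up: float, params: Sequence[str]) -> None:
        if est is None or not np.isfinite(est) or est <= 0:
            return
        b = _clip_bounds(est / down, est * up, global_bounds)
        for p in params:
            out[p] = b

    f_close = 1000.0 / np.mean(open_dwells) if open_dwells else None
    if f_close is not None and c1_max > 0:
        band(f_close / c1_max, 30.0, 30.0, ["k1"])
        # an individual closing channel can sit well below the pooled
        # aggregate when a faster parallel channel dominates entries
        band(f_close, 30.0, 300.0, ["r1", "r3", "r4"])
    f_open_bin = 1000.0 / np.mean(closed_dwells_nolig2) if closed_dwells_nolig2 else None
    band(f_open_bin, 10.0, 10.0, ["r_m1"])
    f_open_ter = 1000.0 / np.mean(closed_dwells_lig2) if closed_dwells_lig2 else None
    band(f_open_ter, 30.0, 30.0, ["r_m3", "r_m4"])
    band(1000.0 * m2_to_m3 / m2_time_ms if m2_time_ms > 0 else None, 30.0, 30.0, ["b2"])
    band(1000.0 / np.mean(m3_dwells) if m3_dwells else None, 10.0, 30.0, ["b_m2"])
    # false M<->M1 events from noise chatter bias both estimates upward,
    # so the downward band is wider
    band(1000.0 * m_to_m1 / m_time_low if m_time_low > 0 else None, 100.0, 30.0, ["b1"])
    band(1000.0 / np.mean(m1_dwells) if m1_dwells else None, 30.0, 10.0, ["b_m1"])
    band(1000.0 * m0_entries / non_m0_time if non_m0_time > 0 else None, 30.0, 30.0,
         ["c_m1", "c_m2", "c_m3", "c_m4"])
    if m0_dwells:
        # mean M0 dwell estimates the total exit rate, shared by four channels
        band(250.0 / np.mean(m0_dwells), 30.0, 30.0, ["c1", "c2", "c3", "c4"])
    return out


def bootstrap_confidence(
    traces: Sequence[CurrentTrace],
    variant: ModelVariant | str,
    config: FitConfig | None = None,
    n_boot: int = 20,
    seed: int = 0,
    level: float = 0.9,
    fit_fn=None,
) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap percentile intervals for the fitted rates.

    Plumbing: the interval method behind the reported confidence bounds is
    not documented, so this makes no claim to reproduce it.
    The observed-data fit is included among the replicates, so intervals
    always contain the point estimate.  ``fit_fn(traces) -> dict[name, value]``
    substitutes a custom estimator; by default the full variant ML fit is
    rerun per replicate (with the same optimizer seed, so variability comes
    from the resampling alone and identical data reproduce identical fits).
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    config = config or FitConfig()
    if fit_fn is None:
        def fit_fn(ts):
            fr = fit_model(ts, variant, config)
            return {nm: getattr(fr.rates, nm) for nm in fr.param_names}
    point = fit_fn(list(traces))
    names = list(point)
    rng = np.random.default_rng(seed)
    draws = [np.array([point[nm] for nm in names])]
    for _ in range(n_boot):
        idx = rng.integers(0, len(traces), size=len(traces))
        est = fit_fn([traces[i] for i in idx])
        draws.append(np.array([est[nm] for nm in names]))
    arr = np.vstack(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(arr, alpha, axis=0)
    hi = np.quantile(arr, 1.0 - alpha, axis=0)
    return {nm: (float(lo[i]), float(hi[i])) for i, nm in enumerate(names)}
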