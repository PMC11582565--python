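"""Event-level analysis of nanopore current traces.

Covers the classical single-channel workflow: selection of usable segments
(dropping open-pore and shallow stretches), all-point amplitude histograms
with multi-Gaussian peak fits, level idealization by nearest-level (half-
amplitude) thresholding with minimum-duration merging, exponential dwell-time
fits, and counting of ordered level-to-level transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .hmm_core import CurrentTrace

__all__ = [
    "TraceSegment",
    "Histogram",
    "Event",
    "DwellStats",
    "GaussianPeak",
    "select_segments",
    "pick_fit_segments",
    "all_point_histogram",
    "fit_gaussian_peaks",
    "occurrence_percent",
    "residual_current",
    "idealize",
    "dwell_exponential_fit",
    "count_transitions",
]

OPEN_PORE_CUTOFF_PA = -350.0  # exclude windows deeper than this ("around -400 pA")
SHALLOW_CUTOFF_PA = -160.0  # exclude windows at or above this
DEFAULT_WINDOW_MS = 50.0


@dataclass
class TraceSegment:
    """Contiguous usable slice [start, stop) of a parent trace."""

    parent: CurrentTrace
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop <= self.parent.n_samples):
            raise ValueError("segment bounds outside parent trace")

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start : self.stop]

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def dt_ms(self) -> float:
        return self.parent.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def truncated(self, max_samples: int) -> "TraceSegment":
        return TraceSegment(self.parent, self.start, min(self.stop, self.start + max_samples))


def select_segments(
    trace: CurrentTrace,
    open_pore_cutoff: float = OPEN_PORE_CUTOFF_PA,
    shallow_cutoff: float = SHALLOW_CUTOFF_PA,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> list[TraceSegment]:
    """Contiguous runs whose sliding-window mean stays between the cutoffs.

    Windows with mean current below ``open_pore_cutoff`` (open pore) or at /
    above ``shallow_cutoff`` (shallow excursion) are excluded; what remains is
    split into maximal contiguous segments.
    """
    w = max(1, int(round(window_ms / trace.dt_ms)))
    if w > trace.n_samples:
        w = trace.n_samples
    means = (
        pd.Series(trace.samples)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    good = (means > open_pore_cutoff) & (means < shallow_cutoff)
    segments: list[TraceSegment] = []
    idx = np.flatnonzero(np.diff(np.r_[0, good.astype(int), 0]))
    for start, stop in zip(idx[0::2], idx[1::2]):
        segments.append(TraceSegment(trace, int(start), int(stop)))
    return segments


def pick_fit_segments(
    segments_by_condition: dict[str, Sequence[TraceSegment]],
    max_len_ms: float = 1000.0,
    seed: int = 0,
) -> dict[str, TraceSegment]:
    """One uniformly-random segment per condition, all right-truncated to the
    lesser of the shortest selected segment and ``max_len_ms``."""
    rng = np.random.default_rng(seed)
    chosen: dict[str, TraceSegment] = {}
    for cond in segments_by_condition:
        segs = list(segments_by_condition[cond])
        if not segs:
            raise ValueError(f"condition {cond!r} has no usable segments")
        chosen[cond] = segs[int(rng.integers(len(segs)))]
    cap_ms = min(min(s.duration_ms for s in chosen.values()), max_len_ms)
    out = {}
    for cond, seg in chosen.items():
        n = max(1, int(round(cap_ms / seg.dt_ms)))
        out[cond] = seg.truncated(n)
    return out


@dataclass
class Histogram:
    """All-point amplitude histogram with uniform bins anchored at 0 pA."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center_pA": self.centers, "count": self.counts})


def all_point_histogram(
    samples: np.ndarray | TraceSegment, bin_width: float = 0.1
) -> Histogram:
    """Every sample counted once; bin edges are multiples of the bin width so
    histograms from different runs align exactly."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = samples.samples if isinstance(samples, TraceSegment) else np.asarray(samples, float)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # guard the top edge so the maximum falls inside the last bin
    if edges[-1] <= x.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram(edges, counts)


@dataclass
class GaussianPeak:
    mean: float
    sd: float
    height: float
    flagged: bool = False


def fit_gaussian_peaks(
    hist: Histogram,
    n_peaks: int,
    initial_means: Sequence[float] | None = None,
    min_sd: float = 0.5,
) -> list[GaussianPeak]:
    """Least-squares multi-Gaussian fit to a histogram; peaks sorted by mean.

    Non-convergence or a sd stuck at its lower bound flags the peak.
    """
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    x, y = hist.centers, hist.counts.astype(float)
    if initial_means is None:
        # spread starts across the occupied amplitude range
        occ = x[y > 0]
        initial_means = np.linspace(occ.min(), occ.max(), n_peaks + 2)[1:-1]
    if len(initial_means) != n_peaks:
        raise ValueError("initial_means length must equal n_peaks")

    if x.size < 3 * n_peaks + 1:
        # degenerate histogram (e.g. constant data): moment estimates, flagged
        mu = float(np.average(x, weights=np.maximum(y, 1e-12)))
        return [
            GaussianPeak(mean=mu, sd=min_sd, height=float(y.max()), flagged=True)
            for _ in range(n_peaks)
        ]
    model = None
    params = lmfit.Parameters()
    span = max(x.max() - x.min(), 1.0)
    for i, mu0 in enumerate(initial_means):
        g = lmfit.models.GaussianModel(prefix=f"g{i}_")
        model = g if model is None else model + g
        params.update(g.make_params())
        params[f"g{i}_center"].set(value=mu0, min=x.min() - span, max=x.max() + span)
        params[f"g{i}_sigma"].set(value=max(2.0, min_sd), min=min_sd, max=span)
        params[f"g{i}_amplitude"].set(value=max(y.sum() * hist.bin_width / n_peaks, 1e-6), min=0)
    out = model.fit(y, params, x=x)
    peaks = []
    for i in range(n_peaks):
        sd = float(out.params[f"g{i}_sigma"].value)
        peaks.append(
            GaussianPeak(
                mean=float(out.params[f"g{i}_center"].value),
                sd=sd,
                height=float(out.params[f"g{i}_height"].value),
                flagged=(not out.success) or sd <= min_sd * 1.0001,
            )
        )
    return sorted(peaks, key=lambda p: p.mean)


def occurrence_percent(peaks: Sequence[GaussianPeak]) -> list[float]:
    """Level occurrence from peak *maxima* (heights, not areas), summing to 100."""
    if len(peaks) == 0:
        raise ValueError("need at least one peak")
    h = np.array([p.height for p in peaks], dtype=float)
    return list(100.0 * h / h.sum())


def residual_current(i_b: float, i_o: float) -> float:
    """I_RES percent = (I_B / I_O) * 100; sign-insensitive for same-sign input."""
    if i_o == 0:
        raise ValueError("open-pore current must be nonzero")
    return 100.0 * i_b / i_o


@dataclass
class Event:
    level: str
    start_ms: float
    dwell_ms: float
    mean_pA: float


def idealize(
    samples: np.ndarray | TraceSegment,
    levels: dict[str, float],
    dt_ms: float | None = None,
    min_dwell_ms: float = 0.1,
    smooth_ms: float = 0.0,
) -> list[Event]:
    """Threshold-crossing idealization into a time-ordered event list.

    Samples (optionally boxcar-smoothed over ``smooth_ms``) are assigned to
    the configured level with the nearest mean — equivalent to half-amplitude
    thresholds midway between adjacent levels — runs are compressed to events,
    and events shorter than ``min_dwell_ms`` are merged into their flanking
    events (shortest first), mirroring the ignore-short-events rule of
    single-channel search.
    """
    if isinstance(samples, TraceSegment):
        dt_ms = samples.dt_ms
        x = samples.samples
    else:
        if dt_ms is None:
            raise ValueError("dt_ms required when passing a bare sample array")
        x = np.asarray(samples, dtype=float)
    if min_dwell_ms < 0:
        raise ValueError("min_dwell_ms must be >= 0")
    names = sorted(levels, key=lambda k: levels[k])
    means = np.array([levels[k] for k in names])
    if np.any(np.diff(means) == 0):
        raise ValueError("level definitions overlap")

    xs = x
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / dt_ms)))
        if w > 1:
            xs = pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()

    assign = np.argmin(np.abs(xs[:, None] - means[None, :]), axis=1)

    # run-length encode
    change = np.r_[True, assign[1:] != assign[:-1]]
    starts = np.flatnonzero(change)
    lengths = np.diff(np.r_[starts, assign.size])
    labels = assign[starts].tolist()
    lengths = lengths.tolist()

    # merge sub-threshold events into flanking events, shortest first
    min_len = int(np.ceil(min_dwell_ms / dt_ms - 1e-9))
    while len(lengths) > 1:
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        if i == 0:
            labels[1], lengths[1] = labels[1], lengths[1] + lengths[0]
            del labels[0], lengths[0]
        elif i == len(lengths) - 1:
            lengths[i - 1] += lengths[i]
            del labels[i], lengths[i]
        else:
            # absorb into the longer neighbour
            if lengths[i - 1] >= lengths[i + 1]:
                lengths[i - 1] += lengths[i]
                del labels[i], lengths[i]
            else:
                lengths[i + 1] += lengths[i]
                del labels[i], lengths[i]
        # coalesce equal neighbours created by the merge
        j = 1
        while j < len(labels):
            if labels[j] == labels[j - 1]:
                lengths[j - 1] += lengths[j]
                del labels[j], lengths[j]
            else:
                j += 1

    events: list[Event] = []
    pos = 0
    for lab, ln in zip(labels, lengths):
        events.append(
            Event(
                level=names[lab],
                start_ms=pos * dt_ms,
                dwell_ms=ln * dt_ms,
                mean_pA=float(x[pos : pos + ln].mean()),
            )
        )
        pos += ln
    return events


def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level": [e.level for e in events],
            "start_ms": [e.start_ms for e in events],
            "dwell_ms": [e.dwell_ms for e in events],
            "mean_pA": [e.mean_pA for e in events],
        }
    )


@dataclass
class DwellStats:
    level: str
    n_dwells: int
    tau_ms: float
    rate_per_s: float
    fit_mode: str

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")


def dwell_exponential_fit(
    dwells_ms: Sequence[float],
    mode: str = "histogram",
    bin_width_ms: float | None = None,
    level: str = "",
) -> DwellStats:
    """Mean dwell time tau by exponential fit; rate = 1000/tau (s^-1).

    ``histogram`` mode bins the dwells (default bin width: the sample mean,
    i.e. close to the expected dwell time) and least-squares fits
    A*exp(-t/tau); ``direct`` mode uses the ML estimator for exponential
    data, the sample mean.
    """
    d = np.asarray(dwells_ms, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("dwells must be positive and non-empty")
    if mode == "direct":
        tau = float(d.mean())
    elif mode == "histogram":
        if d.size < 10:
            raise ValueError("histogram mode needs at least 10 dwells")
        bw = bin_width_ms if bin_width_ms is not None else float(d.mean())
        edges = np.arange(0.0, d.max() + 2 * bw, bw)
        counts, _ = np.histogram(d, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        model = lmfit.Model(lambda t, amp, tau: amp * np.exp(-t / tau))
        params = model.make_params(amp=float(counts.max()), tau=float(d.mean()))
        params["tau"].set(min=1e-9)
        params["amp"].set(min=0)
        out = model.fit(counts.astype(float), params, t=centers)
        tau = float(out.params["tau"].value)
    else:
        raise ValueError("mode must be 'histogram' or 'direct'")
    return DwellStats(level=level, n_dwells=int(d.size), tau_ms=tau, rate_per_s=1000.0 / tau, fit_mode=mode)


def count_transitions(
    events: Sequence[Event], levels: Sequence[str] = ("M", "M2", "M3")
) -> pd.DataFrame:
    """Ordered transition counts among the given levels with per-origin percents.

    Events outside ``levels`` are ignored.  Returns a tidy frame with columns
    (from, to, count, percent); per-origin percents sum to 100 for every
    origin with at least one outgoing transition.
    """
    seq = [e.level for e in events if e.level in levels]
    counts: dict[tuple[str, str], int] = {
        (a, b): 0 for a in levels for b in levels if a != b
    }
    for a, b in zip(seq[:-1], seq[1:]):
        if a != b:
            counts[(a, b)] += 1
    rows = []
    for (a, b), c in counts.items():
        total = sum(v for (x, _), v in counts.items() if x == a)
        pct = 100.0 * c / total if total else np.nan
        rows.append({"from": a, "to": b, "count": c, "percent": pct})
    return pd.DataFrame(rows)
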