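"""Concentration-response fitting: Hill, linear, and one-site binding curves.

Interfaces take concentrations in µM (dissociation constants are reported in
µM) whereas the kinetic model works in mM; converters are provided.  The
increasing Hill form y = y_max c^n / (K_D^n + c^n) describes percent-closed
dose responses; the decreasing form, with a floor y_min for the nonzero
plateau of opening frequencies, is y = y_max - (y_max - y_min) c^n /
(K_D^n + c^n).  A two-state binding-closure steady state provides the
consistency check 100 k_on C / (k_on C + k_off) for the percent of time the
LID domain is closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "HillFitResult",
    "LinearFitResult",
    "BindingFitResult",
    "hill_fit",
    "linear_fit",
    "one_site_binding_fit",
    "two_state_closed_fraction",
    "um_to_mm",
    "mm_to_um",
]


def um_to_mm(x):
    return np.asarray(x, dtype=float) / 1000.0


def mm_to_um(x):
    return np.asarray(x, dtype=float) * 1000.0


@dataclass
class HillFitResult:
    kd: float  # µM
    n: float
    y_max: float
    y_min: float
    kd_stderr: float | None
    n_stderr: float | None
    residual_norm: float
    increasing: bool
    success: bool


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def hill_fit(conc_um, response, increasing: bool = True) -> HillFitResult:
    """Least-squares Hill fit with deterministic starts.

    Starts: K_D at the geometric mean concentration, n = 1, plateaus at the
    empirical extremes — reproducible without global search.
    """
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")

    if increasing:
        def f(x, kd, n, y_max):
            return y_max * x**n / (kd**n + x**n)

        model = lmfit.Model(f)
        params = model.make_params(kd=_geomean(c), n=1.0, y_max=float(np.max(y)))
    else:
        def f(x, kd, n, y_max, y_min):
            return y_max - (y_max - y_min) * x**n / (kd**n + x**n)

        model = lmfit.Model(f)
        params = model.make_params(
            kd=_geomean(c), n=1.0, y_max=float(np.max(y)), y_min=float(np.min(y))
        )
        params["y_min"].set(min=0.0)
    params["kd"].set(min=1e-12)
    params["n"].set(min=1e-3, max=20.0)
    out = model.fit(y, params, x=c)
    p = out.params
    return HillFitResult(
        kd=float(p["kd"].value),
        n=float(p["n"].value),
        y_max=float(p["y_max"].value),
        y_min=float(p["y_min"].value) if "y_min" in p else 0.0,
        kd_stderr=float(p["kd"].stderr) if p["kd"].stderr is not None else None,
        n_stderr=float(p["n"].stderr) if p["n"].stderr is not None else None,
        residual_norm=float(np.linalg.norm(out.residual)),
        increasing=increasing,
        success=bool(out.success),
    )


@dataclass
class LinearFitResult:
    slope: float  # s^-1 µM^-1 when x in µM, y in s^-1
    intercept: float
    slope_stderr: float
    intercept_stderr: float


def linear_fit(conc_um, closing_frequency) -> LinearFitResult:
    """Ordinary least squares; the slope is the apparent association rate k_on."""
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(closing_frequency, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    res = stats.linregress(c, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        intercept_stderr=float(res.intercept_stderr)
        if np.isfinite(res.intercept_stderr)
        else 0.0,
    )


@dataclass
class BindingFitResult:
    b_max: float
    kd: float  # same units as x
    b_max_stderr: float | None
    kd_stderr: float | None
    success: bool


def one_site_binding_fit(x, y) -> BindingFitResult:
    """Least-squares fit of the one-site specific binding curve
    y = B_max x / (K_d + x)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 points")

    def f(x, b_max, kd):
        return b_max * x / (kd + x)

    model = lmfit.Model(f)
    params = model.make_params(b_max=float(np.max(yv)), kd=float(np.median(xv[xv > 0])) if np.any(xv > 0) else 1.0)
    params["kd"].set(min=1e-12)
    out = model.fit(yv, params, x=xv)
    p = out.params
    return BindingFitResult(
        b_max=float(p["b_max"].value),
        kd=float(p["kd"].value),
        b_max_stderr=float(p["b_max"].stderr) if p["b_max"].stderr is not None else None,
        kd_stderr=float(p["kd"].stderr) if p["kd"].stderr is not None else None,
        success=bool(out.success),
    )


def two_state_closed_fraction(k_on: float, conc_um: float, k_off: float) -> float:
    """Steady-state percent closed of a two-state binding-closure scheme:
    100 k_on C / (k_on C + k_off); k_on in µM^-1 s^-1, C in µM, k_off in s^-1."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("k_on and k_off must be positive")
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    return 100.0 * k_on * conc_um / (k_on * conc_um + k_off)
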