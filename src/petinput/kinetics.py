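"""Reversible two-tissue compartment modelling and Patlak graphical analysis.

The two-tissue compartment model (2TCM) describes tracer exchange between
plasma and two tissue compartments:

    dC1/dt = K1*cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    PET(t) = (1 - vB)*(C1 + C2) + vB*cb(t)

with rates K1 [ml/min/ml] and k2, k3, k4 [1/min], fractional blood volume
vB, plasma input cp and whole-blood input cb. The net influx macro-parameter
is Ki = K1*k3/(k2+k3). Internally all rate computations use minutes, the
unit the rate constants are conventionally reported in; public time axes
are seconds.

The forward solution uses the analytic bi-exponential impulse response of
the system convolved with a piecewise-linear input via an exact exponential
update, which is fast and smooth enough for gradient-based fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .core_model import FrameSchedule, TimeActivityCurve

__all__ = [
    "TwoTissueParams",
    "PatlakResult",
    "FitDiagnostics",
    "forward_2tcm_values",
    "frame_average_values",
    "macro_ki",
    "fit_2tcm",
    "fit_patlak",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when no optimisation start converges; carries the best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class TwoTissueParams:
    """2TCM micro-parameters. K1 in ml/min/ml, k2..k4 in 1/min, vB a fraction."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0 <= self.vB <= 1:
            raise ValueError("vB must lie in [0, 1]")

    @property
    def Ki(self) -> float:
        return macro_ki(self)


@dataclass
class FitDiagnostics:
    sse: float
    rms: float
    n_starts_converged: int


@dataclass
class PatlakResult:
    """Patlak plot fit: slope Ki_patlak [ml/min/ml], intercept [ml/ml], r^2."""

    Ki_patlak: float
    intercept: float
    t_star: float
    r_squared: float
    n_frames: int


def macro_ki(params: TwoTissueParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3); 0 (with warning) when k2=k3=0."""
    if params.k2 + params.k3 == 0:
        warnings.warn("k2 = k3 = 0: net influx rate undefined, returning 0", stacklevel=2)
        return 0.0
    return params.K1 * params.k3 / (params.k2 + params.k3)


def _exp_conv(x: np.ndarray, t_min: np.ndarray, alpha: float) -> np.ndarray:
    """Convolution y(t) = int_0^t e^{-alpha(t-s)} x(s) ds for piecewise-linear x.

    Exact per-interval exponential update; t_min in minutes, alpha in 1/min.
    """
    y = np.zeros_like(x)
    dt = np.diff(t_min)
    if alpha * max(dt.max(initial=0.0), 0.0) < 1e-8:
        # effectively alpha == 0: plain cumulative integral
        return np.concatenate([[0.0], np.cumsum(0.5 * (x[1:] + x[:-1]) * dt)])
    e = np.exp(-alpha * dt)
    # exact interval update for linear x on [t_i, t_{i+1}]:
    #   int_0^dt e^{-alpha(dt-s)} x(s) ds, x(s) = x_i + (x_{i+1}-x_i) s/dt
    #   = x_i*(1-e)/alpha + (x_{i+1}-x_i)*(dt - (1-e)/alpha)/(alpha*dt)
    a = alpha * dt
    base = (1.0 - e) / alpha
    slope_term = (dt - base) / a
    drive = x[:-1] * base + (x[1:] - x[:-1]) * slope_term
    if np.ptp(dt) < 1e-12 * dt[0]:
        # uniform grid: the recurrence y_{i+1} = e*y_i + drive_i is an IIR filter
        y[1:] = signal.lfilter([1.0], [1.0, -e[0]], drive)
    else:
        for i in range(x.size - 1):
            y[i + 1] = y[i] * e[i] + drive[i]
    return y


def _impulse_terms(params: TwoTissueParams) -> list[tuple[float, float]]:
    """(coefficient, rate) pairs of the 2TCM impulse response K1*sum B_j e^{-a_j t}."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    if s == 0:
        return [(K1, 0.0)]
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-10:
        # repeated root; nudge apart (error O(eps) on smooth inputs)
        a1 -= 5e-11
        a2 += 5e-11
    b1 = K1 * (k3 + k4 - a1) / (a2 - a1)
    b2 = K1 * (a2 - k3 - k4) / (a2 - a1)
    return [(b1, a1), (b2, a2)]


def forward_2tcm_values(
    params: TwoTissueParams,
    cp: np.ndarray,
    cb: np.ndarray,
    times_s: np.ndarray,
) -> np.ndarray:
    """Tissue concentration on a dense grid: (1-vB)(C1+C2) + vB*cb.

    ``cp``/``cb`` are the plasma and whole-blood inputs sampled on
    ``times_s`` (seconds, sorted).
    """
    cp = np.asarray(cp, dtype=float)
    cb = np.asarray(cb, dtype=float)
    t_min = np.asarray(times_s, dtype=float) / 60.0
    tissue = np.zeros_like(cp)
    for coeff, rate in _impulse_terms(params):
        if coeff != 0.0:
            tissue += coeff * _exp_conv(cp, t_min, rate)
    return (1.0 - params.vB) * tissue + params.vB * cb


def frame_average_values(
    dense_times_s: np.ndarray, dense_values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Mean of a dense curve over each frame ``[start, end)`` (trapezoid/duration)."""
    t = np.asarray(dense_times_s, dtype=float)
    v = np.asarray(dense_values, dtype=float)
    if schedule.start[0] < t[0] - 1e-9 or schedule.end[-1] > t[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the dense grid")
    # integrate on a grid refined with the exact frame boundaries
    bounds = np.unique(np.concatenate([schedule.start, schedule.end]))
    grid = np.unique(np.concatenate([t, bounds]))
    vals = np.interp(grid, t, v)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    cum_at = np.interp(np.concatenate([schedule.start, schedule.end]), grid, cum)
    n = len(schedule)
    integral = cum_at[n:] - cum_at[:n]
    return integral / schedule.duration


# ---------------------------------------------------------------------------
# 2TCM fitting
# ---------------------------------------------------------------------------

_DEFAULT_STARTS = (
    (0.2, 0.3, 0.05, 0.01, 0.05),
    (1.0, 2.0, 0.15, 0.04, 0.20),
    (0.5, 0.5, 0.30, 0.02, 0.10),
    (0.1, 0.8, 0.01, 0.001, 0.02),
    (2.0, 1.0, 0.50, 0.10, 0.30),
)


def fit_2tcm(
    tissue: TimeActivityCurve,
    plasma_times_s: np.ndarray,
    plasma_values: np.ndarray,
    blood_values: np.ndarray | None = None,
    init: TwoTissueParams | None = None,
    bounds_upper: float = 5.0,
) -> tuple[TwoTissueParams, FitDiagnostics]:
    """Weighted nonlinear least-squares fit of the reversible 2TCM.

    The model prediction is the frame average of the dense forward solution;
    residuals are weighted by sqrt(frame duration). Five deterministic
    starting points (plus ``init`` if given) are tried and the best
    sum-of-squares wins. Bounds: K1, k2, k3, k4 in [0, ``bounds_upper``],
    vB in [0, 1].
    """
    if tissue.schedule is None:
        raise ValueError("tissue curve must carry a frame schedule")
    plasma_values = np.asarray(plasma_values, dtype=float)
    if np.any(plasma_values < -1e-9):
        raise ValueError("negative values in plasma input curve")
    if blood_values is None:
        blood_values = plasma_values
    blood_values = np.asarray(blood_values, dtype=float)
    schedule = tissue.schedule
    w = np.sqrt(schedule.duration / schedule.duration.mean())
    y = tissue.values

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = TwoTissueParams(*theta)
        dense = forward_2tcm_values(p, plasma_values, blood_values, plasma_times_s)
        model = frame_average_values(plasma_times_s, dense, schedule)
        return w * (model - y)

    starts = list(_DEFAULT_STARTS)
    if init is not None:
        starts.insert(0, (init.K1, init.k2, init.k3, init.k4, init.vB))
    lb = np.zeros(5)
    ub = np.array([bounds_upper] * 4 + [1.0])
    best = None
    n_ok = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lb + 1e-9, ub - 1e-9)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or n_ok == 0:
        raise FitError("2TCM fit failed to converge from any starting point", best)
    params = TwoTissueParams(*best.x)
    sse = float(2.0 * best.cost)
    diag = FitDiagnostics(sse=sse, rms=float(np.sqrt(sse / y.size)), n_starts_converged=n_ok)
    return params, diag


def fit_patlak(
    tissue: TimeActivityCurve,
    plasma_times_s: np.ndarray,
    plasma_values: np.ndarray,
    t_star_s: float = 600.0,
) -> PatlakResult:
    """Patlak graphical analysis past ``t_star``.

    Ordinary least squares of y = C_T(t)/cp(t) against the "stretched time"
    x = int_0^t cp ds / cp(t) over frames with mid-time >= t_star; the slope
    estimates the net influx rate Ki (per minute once x is in minutes).
    """
    if tissue.schedule is None:
        raise ValueError("tissue curve must carry a frame schedule")
    t = np.asarray(plasma_times_s, dtype=float)
    cp = np.asarray(plasma_values, dtype=float)
    mids = tissue.schedule.mid
    mask = mids >= t_star_s
    if mask.sum() < 3:
        raise ValueError("fewer than 3 frames past t_star")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
    cp_at = np.interp(mids[mask], t, cp)
    if np.any(cp_at <= 0):
        raise ValueError("plasma input is non-positive past t_star")
    cum_at = np.interp(mids[mask], t, cum)
    x = (cum_at / cp_at) / 60.0  # minutes
    y = tissue.values[mask] / cp_at
    res = stats.linregress(x, y)
    return PatlakResult(
        Ki_patlak=float(res.slope),
        intercept=float(res.intercept),
        t_star=float(t_star_s),
        r_squared=float(res.rvalue**2),
        n_frames=int(mask.sum()),
    )
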