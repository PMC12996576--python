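"""Objective input-function curve features.

Six features summarise an input-function curve: the peak value (SUVmax),
time to peak (TTP), full width at half maximum (FWHM), the areas under the
peak and tail regions and their ratio. The peak/tail split uses an
objective break point derived from derivative landmarks: the minimum of the
first derivative after the peak (steepest descent) and the inflection point
where the curve changes concavity back (a positive peak of the second
derivative); the break point lies beyond the inflection by half the
distance between the two landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import TimeActivityCurve
from .input_function import FengModel

__all__ = ["CurveFeatures", "BreakPoint", "find_break_point", "compute_features"]


@dataclass
class BreakPoint:
    break_time: float
    t_minslope: float
    t_inflection: float


@dataclass
class CurveFeatures:
    """The six curve features plus the break point (all times in seconds)."""

    suv_max: float
    ttp: float
    fwhm: float
    auc_peak: float
    auc_tail: float
    auc_ratio: float
    break_point: float


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([values[:1].repeat(pad), values, values[-1:].repeat(pad)])
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima (first index of a plateau)."""
    idx = []
    n = x.size
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] >= x[i + 1]:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def find_break_point(
    times: np.ndarray,
    values: np.ndarray,
    smooth_window: int = 1,
) -> BreakPoint:
    """Locate the peak/tail break point of an input-function curve.

    On a dense, smooth curve (a parametric fit, or raw data with
    ``smooth_window`` > 1):

    1. ``t_minslope``: argmin of the first derivative after the global peak.
    2. ``t_inflection``: the second positive local maximum of the second
       derivative; when fewer than two positive maxima exist, the only
       positive maximum after the peak is used.
    3. ``break = t_inflection + (t_inflection - t_minslope)/2``.
    """
    t = np.asarray(times, dtype=float)
    v = _smooth(np.asarray(values, dtype=float), smooth_window)
    peak_i = int(np.argmax(v))
    if peak_i == 0:
        raise ValueError("curve has no interior peak (monotone decay?)")
    if peak_i >= t.size - 3:
        raise ValueError("curve peak too close to the end; no tail to analyse")
    d1 = np.gradient(v, t)
    d2 = np.gradient(d1, t)
    post = np.arange(peak_i + 1, t.size)
    t_minslope = float(t[post[np.argmin(d1[post])]])

    maxima = _local_maxima(d2)
    # "positive" requires non-negligible curvature: guards against counting
    # floating-point ripple on flat or exactly-cancelled regions
    floor = 1e-6 * np.abs(d2).max()
    pos_maxima = maxima[d2[maxima] > floor]
    after = pos_maxima[pos_maxima > peak_i]
    if after.size == 0:
        raise ValueError("no positive second-derivative peak after the curve peak")
    if pos_maxima.size >= 2:
        t_inflection = float(t[pos_maxima[1]])
    else:
        t_inflection = float(t[after[0]])
    break_time = t_inflection + 0.5 * (t_inflection - t_minslope)
    return BreakPoint(break_time=break_time, t_minslope=t_minslope, t_inflection=t_inflection)


def _half_max_crossings(t: np.ndarray, v: np.ndarray, peak_i: int, half: float) -> tuple[float, float]:
    """Half-max crossing times bracketing the peak, by linear interpolation."""
    left = None
    for i in range(peak_i, 0, -1):
        if v[i - 1] <= half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    if left is None:
        if v[0] <= half:
            left = t[0]
        else:
            raise ValueError("half maximum never crossed before the peak")
    right = None
    for i in range(peak_i, t.size - 1):
        if v[i] >= half >= v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    if right is None:
        raise ValueError("half maximum never re-crossed after the peak")
    return float(left), float(right)


def _trapz_between(t: np.ndarray, v: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of the piecewise-linear curve over [a, b]."""
    if b <= a:
        return 0.0
    grid = np.concatenate([[a], t[(t > a) & (t < b)], [b]])
    vals = np.interp(grid, t, v)
    return float(np.trapezoid(vals, grid))


def compute_features(
    curve: TimeActivityCurve | None = None,
    injection_time: float = 0.0,
    *,
    times: np.ndarray | None = None,
    values: np.ndarray | None = None,
    fit: FengModel | None = None,
    smooth_window: int = 1,
) -> CurveFeatures:
    """Compute the six curve features and the break point.

    The curve may be given as a :class:`TimeActivityCurve`, as raw
    ``times``/``values`` arrays, or as a Feng ``fit`` (evaluated on a dense
    1 s grid to the curve end, or 2730 s when no curve is given). Times are
    referenced to ``injection_time``; ties in the argmax break to the
    earliest time.
    """
    if fit is not None and curve is None and times is None:
        times = np.arange(0.0, 2730.0 + 0.5, 1.0)
        values = fit(times)
    elif curve is not None:
        times, values = curve.times, curve.values
        if fit is not None:
            times = np.arange(float(times[0]), float(times[-1]) + 0.5, 1.0)
            values = fit(times)
    if times is None or values is None:
        raise ValueError("provide a curve, times/values arrays, or a fit")
    t = np.asarray(times, dtype=float)
    v = _smooth(np.asarray(values, dtype=float), smooth_window)
    if t[0] > injection_time + 1e-9:
        raise ValueError("curve must cover the injection time")

    peak_i = int(np.argmax(v))  # np.argmax returns the first/earliest maximum
    suv_max = float(v[peak_i])
    ttp = float(t[peak_i] - injection_time)
    left, right = _half_max_crossings(t, v, peak_i, 0.5 * suv_max)
    fwhm = right - left

    bp = find_break_point(t, v)
    auc_peak = _trapz_between(t, v, injection_time, bp.break_time)
    auc_tail = _trapz_between(t, v, bp.break_time, float(t[-1]))
    if auc_tail <= 0:
        raise ValueError("tail area is zero; AUC ratio undefined")
    return CurveFeatures(
        suv_max=suv_max,
        ttp=ttp,
        fwhm=fwhm,
        auc_peak=auc_peak,
        auc_tail=auc_tail,
        auc_ratio=auc_peak / auc_tail,
        break_point=bp.break_time,
    )
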