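"""Arterial and image-derived input function processing.

Covers every step between the raw continuous detector trace and a plasma
input function ready for kinetic modelling:

* calibration of the detector trace against manual blood samples,
* parametric (Feng) fitting with onset-delay estimation,
* dispersion correction (inverse of the mono-exponential tubing kernel),
* whole-blood to plasma conversion,
* IDIF construction from partial-volume-corrected left ventricle and
  blood-sample-scaled liver curves,
* overlap correction for triple-injection experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .core_model import BloodSample, TimeActivityCurve

__all__ = [
    "FengModel",
    "CalibratedAif",
    "FitError",
    "feng_values",
    "calibrate_trace",
    "fit_feng",
    "correct_dispersion",
    "to_plasma",
    "pvc_left_ventricle",
    "find_lv_liver_intersection",
    "scale_liver",
    "build_idif",
    "correct_triple_injection",
]


class FitError(RuntimeError):
    """Raised when a parametric input-function fit fails; carries best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FengModel:
    """Parametric bolus input-function model with onset delay.

    For t >= t0 (tau = t - t0):

        cp(tau) = (A1*tau - A2 - A3) e^{-l1 tau} + A2 e^{-l2 tau} + A3 e^{-l3 tau}

    and 0 before onset. The construction makes cp(t0) = 0 exactly. A1 is a
    rise slope in (g/ml)/s, A2 and A3 are washout amplitudes in g/ml and the
    eigenvalues obey l1 > l2 > l3 > 0 (fast peak, intermediate and slow
    washout).
    """

    A1: float
    A2: float
    A3: float
    l1: float
    l2: float
    l3: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 > l2 > l3 > 0")
        if self.A1 <= 0:
            raise ValueError("A1 must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    def __call__(self, times: np.ndarray | float) -> np.ndarray:
        return feng_values(self, times)

    def with_onset(self, t0: float) -> "FengModel":
        """Same shape with the onset moved to ``t0`` (delay correction)."""
        return replace(self, t0=t0)


def feng_values(model: FengModel, times: np.ndarray | float) -> np.ndarray:
    """Evaluate a :class:`FengModel` on ``times`` (seconds); 0 before onset."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    tau = t - model.t0
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    out[pos] = (
        (model.A1 * tp - model.A2 - model.A3) * np.exp(-model.l1 * tp)
        + model.A2 * np.exp(-model.l2 * tp)
        + model.A3 * np.exp(-model.l3 * tp)
    )
    return out if np.ndim(times) else float(out[0])


@dataclass
class CalibratedAif:
    """A calibrated whole-blood curve with (optionally) its parametric fit."""

    curve: TimeActivityCurve
    calibration_factor: float
    fit: FengModel | None = None
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        if self.calibration_factor <= 0:
            raise ValueError("calibration factor must be positive")


# ---------------------------------------------------------------------------
# Calibration and parametric fitting
# ---------------------------------------------------------------------------


def calibrate_trace(
    trace: TimeActivityCurve, samples: Sequence[BloodSample]
) -> CalibratedAif:
    """Calibrate a continuous detector trace against manual blood samples.

    A single multiplicative factor is estimated as the through-origin
    least-squares slope of sample concentration on the trace value at the
    sample times. The calibrated curve is factor * trace.
    """
    if not samples:
        raise ValueError("at least one blood sample is required")
    t = np.array([s.time for s in samples], dtype=float)
    c = np.array([s.concentration for s in samples], dtype=float)
    if t.min() < trace.times[0] - 1e-9 or t.max() > trace.times[-1] + 1e-9:
        raise ValueError("sample times fall outside the detector trace")
    v = np.interp(t, trace.times, trace.values)
    denom = float(np.dot(v, v))
    if denom <= 0:
        raise ValueError("trace is zero at all sample times; cannot calibrate")
    factor = float(np.dot(v, c) / denom)
    curve = trace.replace(values=trace.values * factor, region="whole_blood")
    return CalibratedAif(curve=curve, calibration_factor=factor)


def _feng_inits(t: np.ndarray, v: np.ndarray) -> list[np.ndarray]:
    """Deterministic starting points (A1, A2, A3, l3, d2, d1, t0)."""
    peak_i = int(np.argmax(v))
    peak = float(v[peak_i])
    tpk = float(t[peak_i])
    # onset guesses: first crossing of 1% / 5% / 10% of peak
    t0s = []
    for frac in (0.01, 0.05, 0.10):
        above = np.nonzero(v > frac * peak)[0]
        t0s.append(float(t[above[0]]) if above.size else float(t[0]))
    # tail decay guess from the last third (log-linear)
    tail = slice(int(0.67 * t.size), None)
    vt = np.clip(v[tail], peak * 1e-6, None)
    slope = np.polyfit(t[tail], np.log(vt), 1)[0]
    l3 = float(np.clip(-slope, 1e-5, 5e-3))
    tail_amp = float(max(np.median(v[tail]), 1e-6 * peak))
    inits = []
    for t0, l1_scale in ((t0s[1], 1.0), (t0s[0], 0.5), (t0s[2], 2.0), (t0s[1], 4.0), (t0s[0], 1.0)):
        rise = max(tpk - t0, 1.0)
        l1 = l1_scale / rise
        l2 = max(np.sqrt(l1 * l3), 2 * l3)
        A1 = peak * l1 * np.e
        inits.append(
            np.array([A1, tail_amp, tail_amp, l3, max(l2 - l3, 1e-5), max(l1 - l2, 1e-4), t0])
        )
    return inits


def _theta_to_model(theta: np.ndarray) -> FengModel:
    A1, A2, A3, l3, d2, d1, t0 = theta
    return FengModel(A1=A1, A2=A2, A3=A3, l1=l3 + d2 + d1, l2=l3 + d2, l3=l3, t0=t0)


def disperse(times: np.ndarray, values: np.ndarray, tau: float, delay: float = 0.0) -> np.ndarray:
    """Forward dispersion: convolve with (1/tau)e^{-t/tau}, then delay-shift.

    The convolution uses an exact exponential update for piecewise-linear
    input; ``tau = 0`` is the identity kernel.
    """
    from .kinetics import _exp_conv

    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if tau > 0:
        y = _exp_conv(y, t / 60.0, 60.0 / tau) * (60.0 / tau)
    else:
        y = y.copy()
    if delay > 0:
        y = np.interp(t - delay, t, y, left=0.0)
    return y


def _boxcar_shape(times: np.ndarray, values: np.ndarray, duration: float) -> np.ndarray:
    """Convolve with a unit-area boxcar of width ``duration`` (injection shaping)."""
    dt = float(times[1] - times[0])
    n = int(round(duration / dt))
    if n < 1:
        return np.asarray(values, dtype=float).copy()
    kernel = np.full(n, 1.0 / n)
    return np.convolve(np.asarray(values, dtype=float), kernel)[: times.size]


def measurement_operator(
    times: np.ndarray,
    injection_duration: float | None = None,
    dispersion=None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build the bolus-to-detector measurement map on a dense grid.

    Chains injection-duration boxcar shaping and tubing dispersion/delay
    (``dispersion`` is anything with ``tau``/``delay`` attributes or a
    ``(tau, delay)`` pair). Fitting the parametric bolus model through this
    operator lets the fit extrapolate correctly beyond its window.
    """
    tau, delay = 0.0, 0.0
    if dispersion is not None:
        tau = getattr(dispersion, "tau", None)
        delay = getattr(dispersion, "delay", None)
        if tau is None:
            tau, delay = float(dispersion[0]), float(dispersion[1])

    def forward(values: np.ndarray) -> np.ndarray:
        out = values
        if injection_duration:
            out = _boxcar_shape(times, out, injection_duration)
        if tau > 0 or delay > 0:
            out = disperse(times, out, tau, delay)
        return out

    return forward


def fit_feng(
    curve: TimeActivityCurve,
    init: FengModel | None = None,
    forward: Callable[[np.ndarray], np.ndarray] | None = None,
    weights: np.ndarray | str | None = None,
) -> tuple[FengModel, float]:
    """Nonlinear least-squares Feng fit with multi-start initialisation.

    Parameters are constrained so that l1 > l2 > l3 > 0 and t0 >= 0 by
    fitting positive eigenvalue gaps. Five deterministic heuristic starts
    (plus ``init`` if given) are tried; the best sum of squared residuals
    wins. Returns the model and the residual RMS.

    ``forward``, when given, maps the model curve to the measured domain
    (see :func:`measurement_operator`); residuals are then formed against
    the measured data and the returned model describes the underlying bolus.

    ``weights`` are per-sample residual weights; the string ``"counts"``
    selects inverse-standard-deviation weights 1/sqrt(max(v, 2% of peak))
    matching value-proportional count-noise variance.
    """
    t = curve.times
    v = curve.values
    if isinstance(weights, str):
        if weights != "counts":
            raise ValueError(f"unknown weighting scheme {weights!r}")
        w = 1.0 / np.sqrt(np.maximum(v, 0.02 * v.max()))
        w /= w.mean()
    elif weights is not None:
        w = np.asarray(weights, dtype=float)
    else:
        w = None
    peak = float(v.max())
    tail_mean = float(v[int(0.67 * v.size):].mean())
    if peak <= 0 or peak <= tail_mean:
        raise FitError("curve has no discernible peak above its tail")

    def residuals(theta: np.ndarray) -> np.ndarray:
        model_v = _theta_to_model(theta)(t)
        if forward is not None:
            model_v = forward(model_v)
        r = model_v - v
        return r if w is None else w * r

    lb = np.array([1e-9, 0.0, 0.0, 1e-7, 1e-7, 1e-6, 0.0])
    ub = np.array([np.inf, np.inf, np.inf, 1.0, 2.0, 10.0, float(t[-1])])
    starts = _feng_inits(t, v)
    if init is not None:
        starts.insert(
            0,
            np.array(
                [
                    init.A1,
                    init.A2,
                    init.A3,
                    init.l3,
                    init.l2 - init.l3,
                    init.l1 - init.l2,
                    init.t0,
                ]
            ),
        )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, None)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:  # noqa: BLE001
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("Feng fit failed from all starting points")
    model = _theta_to_model(best.x)
    rms = float(np.sqrt(2.0 * best.cost / v.size))
    return model, rms


# ---------------------------------------------------------------------------
# Dispersion and plasma conversion
# ---------------------------------------------------------------------------


def correct_dispersion(
    times: np.ndarray, values: np.ndarray, tau: float
) -> np.ndarray:
    """Invert mono-exponential dispersion: c_true(t) = c(t) + tau * dc/dt.

    The derivative is taken by central differences on the dense grid, so the
    input should be smooth (a parametric fit or smoothed trace). Negative
    excursions are clipped to zero; if they exceed 10% of samples a warning
    is emitted.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    values = np.asarray(values, dtype=float)
    if tau == 0:
        return values.copy()
    out = values + tau * np.gradient(values, np.asarray(times, dtype=float))
    neg = out < 0
    if neg.mean() > 0.10:
        warnings.warn(
            f"dispersion correction produced {neg.mean():.0%} negative samples; "
            "tau may be too large for this curve",
            stacklevel=2,
        )
    return np.where(neg, 0.0, out)


def to_plasma(
    curve: TimeActivityCurve,
    ratio: float | Callable[[np.ndarray], np.ndarray] = 1.0,
) -> TimeActivityCurve:
    """Convert a whole-blood curve to plasma by a constant or time-varying ratio."""
    if callable(ratio):
        r = np.asarray(ratio(curve.times), dtype=float)
    else:
        r = np.full_like(curve.values, float(ratio))
    if np.any(r <= 0):
        raise ValueError("plasma-to-whole-blood ratio must be positive")
    return curve.replace(values=curve.values * r, region="plasma")


# ---------------------------------------------------------------------------
# IDIF construction
# ---------------------------------------------------------------------------


def pvc_left_ventricle(
    lv: TimeActivityCurve, myocardium: TimeActivityCurve, rc: float
) -> TimeActivityCurve:
    """Partial-volume correction of the left-ventricle curve.

    Inverts the two-compartment spill model measured = RC*true +
    (1-RC)*background, with the surrounding myocardium as background:
    corrected = (lv - (1-RC)*myocardium) / RC.
    """
    if not 0 < rc <= 1:
        raise ValueError("recovery coefficient must be in (0, 1]")
    if lv.times.shape != myocardium.times.shape or not np.allclose(lv.times, myocardium.times):
        raise ValueError("LV and myocardium curves must share a schedule")
    corrected = (lv.values - (1.0 - rc) * myocardium.values) / rc
    if (corrected < 0).mean() > 0.20:
        warnings.warn("partial-volume corrected LV is negative on >20% of frames", stacklevel=2)
    return lv.replace(values=corrected, region="whole_blood")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([values[:1].repeat(pad), values, values[-1:].repeat(pad)])
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def find_lv_liver_intersection(
    lv_corrected: TimeActivityCurve, smooth_window: int = 3
) -> float:
    """Objective LV/liver junction time for IDIF construction.

    Returns the frame mid-time (s) maximising the smoothed second derivative
    of the LV curve after its peak — where the fast ventricular washout
    flattens into the tail. Ties break to the earlier time.
    """
    t = lv_corrected.times
    v = _smooth(lv_corrected.values, smooth_window)
    peak_i = int(np.argmax(v))
    if t.size - peak_i < 5:
        raise ValueError("need at least 5 frames past the LV peak")
    if peak_i == 0 and np.all(np.diff(v) >= 0):
        raise ValueError("LV curve is monotone; no peak found")
    d1 = np.gradient(v, t)
    d2 = np.gradient(d1, t)
    post = slice(peak_i + 1, None)
    idx = int(np.argmax(d2[post])) + peak_i + 1  # argmax returns first max: earlier tie wins
    return float(t[idx])


def scale_liver(liver: TimeActivityCurve, sample: BloodSample) -> TimeActivityCurve:
    """Scale the liver curve to a late manual blood sample.

    factor = sample concentration / liver value at the sample time (linear
    interpolation).
    """
    if liver.schedule is not None:
        lo, hi = liver.schedule.span
    else:
        lo, hi = float(liver.times[0]), float(liver.times[-1])
    if not lo - 1e-9 <= sample.time <= hi + 1e-9:
        raise ValueError("sample time outside the liver curve support")
    ref = float(liver.interp(sample.time))  # np.interp holds edge values
    if ref <= 0:
        raise ValueError("liver curve is non-positive at the sample time")
    factor = sample.concentration / ref
    return liver.replace(values=liver.values * factor, region="whole_blood")


def build_idif(
    lv: TimeActivityCurve,
    myocardium: TimeActivityCurve,
    liver: TimeActivityCurve,
    sample: BloodSample,
    rc: float,
    junction_qc_threshold: float = 0.15,
    smooth_window: int = 3,
) -> TimeActivityCurve:
    """Compose an image-derived input function.

    Partial-volume-corrected left ventricle supplies the early frames (up to
    the LV/liver junction found from the LV second derivative); the
    blood-sample-scaled liver supplies the later frames. No interpolation is
    applied across the junction; a relative jump above
    ``junction_qc_threshold`` raises a QC warning.
    """
    lv_corr = pvc_left_ventricle(lv, myocardium, rc)
    t_junction = find_lv_liver_intersection(lv_corr, smooth_window=smooth_window)
    liver_scaled = scale_liver(liver, sample)
    early = lv.times <= t_junction
    values = np.where(early, lv_corr.values, liver_scaled.values)
    j = int(np.nonzero(early)[0][-1])
    if j + 1 < values.size:
        # discontinuity between the two sources at the hand-over frame
        ref = max(abs(lv_corr.values[j + 1]), abs(liver_scaled.values[j + 1]), 1e-12)
        jump = abs(liver_scaled.values[j + 1] - lv_corr.values[j + 1]) / ref
        if jump > junction_qc_threshold:
            warnings.warn(
                f"IDIF junction discontinuity {jump:.1%} exceeds QC threshold", stacklevel=2
            )
    return lv.replace(values=values, region="whole_blood")


# ---------------------------------------------------------------------------
# Triple-injection overlap correction
# ---------------------------------------------------------------------------


def correct_triple_injection(
    trace: TimeActivityCurve,
    injection_times: Sequence[float],
    samples: Sequence[BloodSample] | None = None,
    injection_duration: float | None = None,
    dispersion=None,
) -> tuple[list[TimeActivityCurve], list[FengModel]]:
    """Overlap-correct a calibrated trace containing three bolus injections.

    Each injection's segment runs from its injection time to the next
    injection (the last one to the end of the trace). The first segment is
    fitted with the Feng model; its extrapolated tail is subtracted from
    segment two before fitting, and the extrapolations of fits one and two
    are subtracted from segment three. The corrected curves for injections
    two and three are realigned to the first injection time. If ``samples``
    (one per injection) are given, the trace is calibrated first.

    ``injection_duration`` and ``dispersion`` (tau/delay), when known from
    the acquisition, are folded into the fit via
    :func:`measurement_operator` so that tail extrapolation into later
    segments matches what the detector actually records.

    Returns the three aligned corrected curves (on the trace clock of
    injection one) and their Feng fits (underlying bolus models).
    """
    inj = np.asarray(injection_times, dtype=float)
    if inj.size != 3 or np.any(np.diff(inj) <= 0):
        raise ValueError("three strictly increasing injection times are required")
    t = trace.times
    if inj[0] < t[0] - 1e-9 or inj[-1] > t[-1]:
        raise ValueError("injection times outside the trace span")
    values = trace.values.astype(float).copy()
    if samples is not None:
        if len(samples) != 3:
            raise ValueError("expected one calibration sample per injection")
        cal = calibrate_trace(trace, samples)
        values = cal.curve.values.copy()

    bounds = list(inj) + [float(t[-1]) + 1e-9]
    segments = [(t >= bounds[i]) & (t < bounds[i + 1]) for i in range(3)]
    fits: list[FengModel] = []
    dt = float(t[1] - t[0])
    # local grid from injection onset, long enough for any extrapolation
    extrap_grid = np.arange(0.0, float(t[-1]) - inj[0] + dt / 2, dt)
    fwd_full = measurement_operator(extrap_grid, injection_duration, dispersion)
    corrected: list[TimeActivityCurve] = []
    for i, seg in enumerate(segments):
        seg_t = t[seg] - inj[i]  # local clock from this injection
        seg_v = values[seg].copy()
        for prev_i, prev_fit in enumerate(fits):
            # extrapolate earlier fits, in the measured domain, on the
            # global clock of their own injection
            local = t[seg] - inj[prev_i]
            measured = fwd_full(prev_fit(extrap_grid))
            seg_v -= np.interp(local, extrap_grid, measured)
        seg_curve = TimeActivityCurve(seg_t, seg_v, units=trace.units, region="whole_blood")
        fwd_seg = measurement_operator(seg_t, injection_duration, dispersion)
        try:
            fit, _rms = fit_feng(seg_curve, forward=fwd_seg)
        except FitError as err:
            raise FitError(f"Feng fit failed for injection {i + 1}") from err
        fits.append(fit)
        corrected.append(
            TimeActivityCurve(
                seg_t + inj[0], seg_v, units=trace.units, region="whole_blood"
            )
        )
    return corrected, fits
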