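"""Synthetic small-animal dynamic PET data with realistic acquisition physics.

Generates subject- and cohort-level datasets with the statistical structure
the analysis pipeline assumes: a Feng-shaped arterial bolus, widening by the
injection duration, withdrawal-rate-dependent tubing dispersion and catheter
delay, reversible 2TCM tissue responses with fractional blood volume,
left-ventricle partial-volume spill from the myocardium, PET frame
averaging, duration-weighted count noise and late-scan calibration samples.

Every stochastic operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import (
    BloodSample,
    ExperimentConfig,
    FrameSchedule,
    TimeActivityCurve,
    UNITS_SUV,
    default_mouse_schedule,
)
from .input_function import FengModel, feng_values
from .kinetics import TwoTissueParams, forward_2tcm_values, frame_average_values

__all__ = [
    "DispersionSpec",
    "NoiseSpec",
    "CohortSpec",
    "SubjectDataset",
    "TripleInjectionDataset",
    "DEFAULT_FENG",
    "DEFAULT_KINETICS",
    "feng_curve",
    "shape_injection",
    "forward_2tcm",
    "frame_average",
    "apply_dispersion",
    "add_noise",
    "draw_blood_samples",
    "dispersion_for_config",
    "simulate_subject",
    "simulate_cohort",
    "simulate_triple_injection",
]

#: Dispersion-link coefficient: tau = KAPPA / withdrawal_rate, calibrated so
#: that the reference 120 ul/min withdrawal gives tau = 5 s.
KAPPA_UL_S_PER_MIN = 600.0
#: Extra dispersion and transit delay of the long PET/MR tubing.
PET_MR_EXTRA_TAU_S = 10.0
PET_MR_EXTRA_DELAY_S = 30.0

#: Reference arterial bolus shape (SUV units, seconds). With the reference
#: 30 s injection and 5 s dispersion this yields a measured peak near
#: 8.8 g/ml, matching a healthy reference mouse.
DEFAULT_FENG = FengModel(A1=3.65, A2=0.7, A3=1.3, l1=0.115, l2=0.014, l3=0.00019, t0=4.0)

#: Reference tissue kinetic parameters (per-minute rates, FDG-like).
DEFAULT_KINETICS: dict[str, TwoTissueParams] = {
    "brain": TwoTissueParams(K1=0.24, k2=0.42, k3=0.06, k4=0.012, vB=0.05),
    "myocardium": TwoTissueParams(K1=1.10, k2=2.60, k3=0.45, k4=0.04, vB=0.25),
}

#: Liver modelled as a blood-pool-dominated region: a constant fraction of
#: whole blood, which makes the sample-scaled liver tail an exact surrogate
#: for blood in the noise-free limit.
LIVER_BLOOD_FRACTION = 0.6

DENSE_DT_S = 1.0


@dataclass(frozen=True)
class DispersionSpec:
    """Mono-exponential dispersion kernel (tau) plus catheter transit delay."""

    tau: float = 5.0
    delay: float = 30.4

    def __post_init__(self) -> None:
        if self.tau < 0 or self.delay < 0:
            raise ValueError("tau and delay must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Duration-weighted gaussian count noise: SD = scale*sqrt(value/duration)."""

    scale: float = 0.1
    model: str = "gaussian_duration_weighted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.model != "gaussian_duration_weighted":
            raise ValueError(f"unknown noise model {self.model!r}")


@dataclass
class ParamDist:
    """Lognormal distribution summarised by its mean and coefficient of variation."""

    mean: float
    cv: float = 0.15

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("CV must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.mean == 0 or self.cv == 0:
            return self.mean
        sigma2 = np.log1p(self.cv**2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _default_kinetic_dists() -> dict[str, dict[str, ParamDist]]:
    out: dict[str, dict[str, ParamDist]] = {}
    for region, p in DEFAULT_KINETICS.items():
        out[region] = {
            "K1": ParamDist(p.K1),
            "k2": ParamDist(p.k2),
            "k3": ParamDist(p.k3),
            "k4": ParamDist(p.k4),
            "vB": ParamDist(p.vB),
        }
    return out


def _default_feng_dists() -> dict[str, ParamDist]:
    return {
        name: ParamDist(getattr(DEFAULT_FENG, name))
        for name in ("A1", "A2", "A3", "l1", "l2", "l3")
    } | {"t0": ParamDist(DEFAULT_FENG.t0, 0.0)}


@dataclass
class CohortSpec:
    """A group of subjects sharing an acquisition config.

    Per-subject kinetic and bolus-shape parameters are drawn from lognormal
    distributions (mean, CV); within-cohort biological CV defaults to 15%.
    """

    n_subjects: int = 9
    config: ExperimentConfig = field(default_factory=ExperimentConfig)
    kinetic_dists: dict[str, dict[str, ParamDist]] = field(default_factory=_default_kinetic_dists)
    feng_dists: dict[str, ParamDist] = field(default_factory=_default_feng_dists)
    noise_scale: float = 0.1
    sample_cv: float = 0.03
    label: str = "reference"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class SubjectDataset:
    """One simulated subject: measurements plus retained ground truth."""

    config: ExperimentConfig
    schedule: FrameSchedule
    dense_times: np.ndarray
    true_aif: TimeActivityCurve        # undispersed whole-blood truth (dense, SUV)
    detector_trace: TimeActivityCurve  # dispersed, delayed, uncalibrated, noisy
    blood_samples: list[BloodSample]
    tacs: dict[str, TimeActivityCurve]
    truth_feng: FengModel
    truth_kinetics: dict[str, TwoTissueParams]
    truth_calibration_factor: float
    truth_dispersion: DispersionSpec
    seed: int


@dataclass
class TripleInjectionDataset:
    """A triple-injection trace plus its noiseless per-injection components."""

    dense_times: np.ndarray
    trace: TimeActivityCurve
    components: list[TimeActivityCurve]  # dispersed+delayed truth per injection
    injection_times: list[float]
    models: list[FengModel]
    samples: list[BloodSample]
    truth_dispersion: DispersionSpec


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def feng_curve(model: FengModel, times: np.ndarray) -> np.ndarray:
    """Evaluate the parametric bolus model on ``times`` (delegates to the model)."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    return feng_values(model, times)


def shape_injection(times: np.ndarray, bolus: np.ndarray, duration: float) -> np.ndarray:
    """Widen an instantaneous bolus by a finite injection duration.

    Convolution with a unit-area boxcar of width ``duration`` (seconds);
    total AUC is preserved. Durations below the grid step return the input
    unchanged with a warning.
    """
    if duration <= 0:
        raise ValueError("injection duration must be positive")
    t = np.asarray(times, dtype=float)
    dt = float(t[1] - t[0])
    n = int(round(duration / dt))
    if n < 1:
        warnings.warn("injection duration below grid step; returning input", stacklevel=2)
        return np.asarray(bolus, dtype=float).copy()
    kernel = np.full(n, 1.0 / n)
    out = np.convolve(np.asarray(bolus, dtype=float), kernel)[: t.size]
    return out


def forward_2tcm(
    params: TwoTissueParams,
    cp: np.ndarray,
    cb: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Tissue response of the reversible 2TCM (see :mod:`petinput.kinetics`)."""
    return forward_2tcm_values(params, cp, cb, times)


def frame_average(
    dense_times: np.ndarray,
    dense_values: np.ndarray,
    schedule: FrameSchedule,
    units: str = UNITS_SUV,
    region: str = "whole_blood",
) -> TimeActivityCurve:
    """Average a dense curve over PET frames, returning a framed TAC."""
    vals = frame_average_values(dense_times, dense_values, schedule)
    return TimeActivityCurve(schedule.mid, vals, units=units, region=region, schedule=schedule)


def apply_dispersion(
    times: np.ndarray, values: np.ndarray, spec: DispersionSpec
) -> np.ndarray:
    """Disperse and delay a dense curve.

    Convolution with the unit-area kernel (1/tau) e^{-t/tau} — computed with
    an exact exponential update assuming a piecewise-linear input — followed
    by a shift of ``delay`` seconds (zero-padded at the front).
    """
    from .input_function import disperse

    return disperse(times, values, spec.tau, spec.delay)


def add_noise(
    curve: TimeActivityCurve, spec: NoiseSpec, frame_duration: np.ndarray | float | None = None
) -> TimeActivityCurve:
    """Add zero-mean gaussian noise with SD = scale*sqrt(max(v,0)/duration).

    For framed curves the frame durations come from the schedule; for dense
    traces the grid step is used. Reproducible for a fixed seed.
    """
    if spec.scale == 0:
        return curve.replace(values=curve.values.copy())
    if frame_duration is None:
        if curve.schedule is not None:
            frame_duration = curve.schedule.duration
        else:
            frame_duration = float(np.median(np.diff(curve.times)))
    rng = np.random.default_rng(spec.seed)
    sd = spec.scale * np.sqrt(np.maximum(curve.values, 0.0) / frame_duration)
    return curve.replace(values=curve.values + rng.normal(0.0, 1.0, curve.values.size) * sd)


def draw_blood_samples(
    true_curve: TimeActivityCurve,
    times: Sequence[float],
    cv: float = 0.03,
    seed: int = 0,
) -> list[BloodSample]:
    """Manual blood samples: truth at ``times`` with multiplicative gaussian error."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.min() < true_curve.times[0] - 1e-9 or t.max() > true_curve.times[-1] + 1e-9:
        raise ValueError("sample times outside the curve support")
    rng = np.random.default_rng(seed)
    vals = np.interp(t, true_curve.times, true_curve.values)
    noisy = vals * (1.0 + rng.normal(0.0, cv, t.size))
    return [BloodSample(float(ti), float(max(c, 0.0))) for ti, c in zip(t, noisy)]


def dispersion_for_config(config: ExperimentConfig) -> DispersionSpec:
    """Dispersion/delay implied by the acquisition: tau = kappa/withdrawal_rate.

    The PET/MR system's longer tubing adds extra dispersion and delay.
    """
    tau = KAPPA_UL_S_PER_MIN / config.withdrawal_rate_ul_min
    delay = config.catheter_delay_s
    if config.scanner == "PET/MR":
        tau += PET_MR_EXTRA_TAU_S
        delay += PET_MR_EXTRA_DELAY_S
    return DispersionSpec(tau=tau, delay=delay)


# ---------------------------------------------------------------------------
# Subject- and cohort-level simulation
# ---------------------------------------------------------------------------

DEFAULT_SAMPLE_TIMES_S = (1800.0, 2250.0, 2700.0)
#: Detector counts per SUV: the uncalibrated trace is this factor times the
#: dispersed blood curve, so trace calibration has something to estimate.
DEFAULT_DETECTOR_GAIN = 250.0


def simulate_subject(
    config: ExperimentConfig,
    feng: FengModel | None = None,
    kinetics: dict[str, TwoTissueParams] | None = None,
    noise_scale: float = 0.1,
    sample_cv: float = 0.03,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES_S,
    schedule: FrameSchedule | None = None,
    detector_gain: float = DEFAULT_DETECTOR_GAIN,
    seed: int = 0,
) -> SubjectDataset:
    """Simulate one complete subject.

    Produces the ground-truth arterial curve, the dispersed/delayed/noisy
    uncalibrated detector trace, three late-scan calibration samples, and
    framed tissue TACs (brain, myocardium, left ventricle, liver) with
    partial-volume spill in the left ventricle:
    LV = RC*blood + (1-RC)*myocardium.
    """
    feng = feng if feng is not None else DEFAULT_FENG
    kin = kinetics if kinetics is not None else DEFAULT_KINETICS
    schedule = schedule if schedule is not None else default_mouse_schedule()
    t = np.arange(0.0, config.scan_length_s + DENSE_DT_S / 2, DENSE_DT_S)

    bolus = feng_curve(feng, t)
    aif = shape_injection(t, bolus, config.injection_duration_s)
    true_aif = TimeActivityCurve(t, aif, units=UNITS_SUV, region="whole_blood")

    disp = dispersion_for_config(config)
    dispersed = apply_dispersion(t, aif, disp)
    gain = detector_gain
    ss = np.random.SeedSequence([seed, 0x7E7])
    trace_seed, sample_seed, *tac_seeds = [int(s) for s in ss.generate_state(6)]
    trace = TimeActivityCurve(t, gain * dispersed, units=UNITS_SUV, region="whole_blood")
    trace = add_noise(trace, NoiseSpec(scale=noise_scale * np.sqrt(gain), seed=trace_seed))

    samples = draw_blood_samples(true_aif, sample_times, cv=sample_cv, seed=sample_seed)

    plasma = aif  # plasma-to-whole-blood ratio 1.0 in the forward model
    rc = config.recovery_coefficient
    dense = {}
    for region in ("brain", "myocardium"):
        dense[region] = forward_2tcm(kin[region], plasma, aif, t)
    dense["left_ventricle"] = rc * aif + (1.0 - rc) * dense["myocardium"]
    dense["liver"] = LIVER_BLOOD_FRACTION * aif

    tacs: dict[str, TimeActivityCurve] = {}
    for (region, dvals), tseed in zip(dense.items(), tac_seeds):
        tac = frame_average(t, dvals, schedule, units=UNITS_SUV, region=region)
        tacs[region] = add_noise(tac, NoiseSpec(scale=noise_scale, seed=int(tseed)))

    return SubjectDataset(
        config=config,
        schedule=schedule,
        dense_times=t,
        true_aif=true_aif,
        detector_trace=trace,
        blood_samples=samples,
        tacs=tacs,
        truth_feng=feng,
        truth_kinetics=dict(kin),
        truth_calibration_factor=1.0 / gain,
        truth_dispersion=disp,
        seed=seed,
    )


def _draw_subject_params(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[FengModel, dict[str, TwoTissueParams]]:
    f = {name: dist.draw(rng) for name, dist in spec.feng_dists.items()}
    # enforce the eigenvalue ordering after independent draws
    l1, l2, l3 = sorted((f["l1"], f["l2"], f["l3"]), reverse=True)
    feng = FengModel(A1=f["A1"], A2=f["A2"], A3=f["A3"], l1=l1, l2=l2, l3=l3, t0=f["t0"])
    kin = {}
    for region, dists in spec.kinetic_dists.items():
        kin[region] = TwoTissueParams(**{k: d.draw(rng) for k, d in dists.items()})
    return feng, kin


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> list[SubjectDataset]:
    """Simulate ``spec.n_subjects`` subjects with per-subject parameter draws.

    Subject seeds derive deterministically from ``seed``; with all CVs zero
    and one subject, the output equals :func:`simulate_subject`.
    """
    ss = np.random.SeedSequence([seed, 0xC0407])
    subject_seeds = [int(s) for s in ss.generate_state(spec.n_subjects)]
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = []
    for sub_seed in subject_seeds:
        feng, kin = _draw_subject_params(spec, param_rng)
        subjects.append(
            simulate_subject(
                spec.config,
                feng=feng,
                kinetics=kin,
                noise_scale=spec.noise_scale,
                sample_cv=spec.sample_cv,
                seed=sub_seed,
            )
        )
    return subjects


def simulate_triple_injection(
    models: Sequence[FengModel],
    injection_times: Sequence[float],
    config: ExperimentConfig | None = None,
    noise_scale: float = 0.1,
    sample_delay_s: float = 600.0,
    sample_cv: float = 0.0,
    seed: int = 0,
) -> TripleInjectionDataset:
    """Simulate a triple-injection experiment on one arterial line.

    The trace is the superposition of three dispersed and delayed bolus
    curves (one per injection) plus count noise; the noiseless individual
    components are retained as ground truth. One calibration blood sample is
    drawn ``sample_delay_s`` after each injection (10 min by default).
    """
    if len(models) != 3:
        raise ValueError("three bolus models are required")
    inj = np.asarray(injection_times, dtype=float)
    if inj.size != 3 or np.any(np.diff(inj) <= 0):
        raise ValueError("three strictly increasing injection times are required")
    config = config if config is not None else dataclasses.replace(
        ExperimentConfig(), injection_volume_ul=30.0, injection_duration_s=10.0
    )
    t = np.arange(0.0, config.scan_length_s + DENSE_DT_S / 2, DENSE_DT_S)
    disp = dispersion_for_config(config)
    components = []
    total = np.zeros_like(t)
    for model, t_inj in zip(models, inj):
        bolus = feng_curve(model, np.maximum(t - t_inj, 0.0)) * (t >= t_inj)
        shaped = shape_injection(t, bolus, config.injection_duration_s)
        dispersed = apply_dispersion(t, shaped, disp)
        components.append(
            TimeActivityCurve(t, dispersed, units=UNITS_SUV, region="whole_blood")
        )
        total += dispersed
    trace = TimeActivityCurve(t, total, units=UNITS_SUV, region="whole_blood")
    ss = np.random.SeedSequence([seed, 0x731])
    noise_seed, samp_seed = [int(s) for s in ss.generate_state(2)]
    trace = add_noise(trace, NoiseSpec(scale=noise_scale, seed=noise_seed))
    sample_times = inj + sample_delay_s
    truth_total = TimeActivityCurve(t, total, units=UNITS_SUV, region="whole_blood")
    samples = draw_blood_samples(truth_total, sample_times, cv=sample_cv, seed=samp_seed)
    return TripleInjectionDataset(
        dense_times=t,
        trace=trace,
        components=components,
        injection_times=[float(x) for x in inj],
        models=list(models),
        samples=samples,
        truth_dispersion=disp,
    )
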