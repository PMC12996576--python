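"""Shared data model, units, file I/O and guideline checks.

Time is measured in seconds from injection start throughout the package.
PET frames are half-open intervals ``[start, end)``; continuous detector
traces are stored on a fixed 1 s grid. Activity concentrations are either
``kBq/ml`` (raw) or ``SUV`` (g/ml, dose- and weight-normalised).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "BloodSample",
    "ExperimentConfig",
    "FormatError",
    "UNITS_KBQ_ML",
    "UNITS_SUV",
    "REGIONS",
    "read_tac_table",
    "write_tac_table",
    "read_blood_samples",
    "write_blood_samples",
    "write_results_table",
    "read_config",
    "write_config",
    "to_suv",
    "from_suv",
    "max_bolus_volume",
    "check_injection_volumes",
    "default_mouse_schedule",
]

UNITS_KBQ_ML = "kBq/ml"
UNITS_SUV = "SUV"

REGIONS = ("brain", "myocardium", "left_ventricle", "liver", "whole_blood", "plasma")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass(frozen=True)
class FrameSchedule:
    """PET frame schedule: half-open frames ``[start[i], end[i])`` in seconds."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise FormatError("frame start/end must be 1-D arrays of equal length")
        if start.size == 0:
            raise FormatError("empty frame schedule")
        if not np.all(end > start):
            bad = int(np.argmin(end - start))
            raise FormatError(f"frame {bad}: end must exceed start")
        if start.size > 1 and not np.all(start[1:] >= end[:-1] - 1e-9):
            bad = int(np.argmax(start[1:] < end[:-1] - 1e-9)) + 1
            raise FormatError(f"frame {bad} starts before frame {bad - 1} ends")

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.end - self.start

    @property
    def span(self) -> tuple[float, float]:
        return float(self.start[0]), float(self.end[-1])


def default_mouse_schedule() -> FrameSchedule:
    """Default 45.5 min small-animal framing: 30x2, 14x5, 10x10, 10x30, 22x100 s."""
    durations = np.concatenate(
        [
            np.full(30, 2.0),
            np.full(14, 5.0),
            np.full(10, 10.0),
            np.full(10, 30.0),
            np.full(22, 100.0),
        ]
    )
    end = np.cumsum(durations)
    start = end - durations
    return FrameSchedule(start, end)


@dataclass
class TimeActivityCurve:
    """A regional time-activity curve on frame mid-times or a dense grid."""

    times: np.ndarray
    values: np.ndarray
    units: str = UNITS_KBQ_ML
    region: str = "whole_blood"
    schedule: FrameSchedule | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise FormatError("times and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite values in curve '{self.region}'")
        if self.units not in (UNITS_KBQ_ML, UNITS_SUV):
            raise FormatError(f"unknown units {self.units!r}")
        if self.schedule is not None and len(self.schedule) != self.times.size:
            raise FormatError("schedule length does not match curve length")

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of the curve at time(s) ``t`` (seconds)."""
        return np.interp(t, self.times, self.values)

    def replace(self, **kwargs) -> "TimeActivityCurve":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class BloodSample:
    """A manual blood sample: time on the scan clock (s), concentration >= 0."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("blood sample concentration must be >= 0")


@dataclass
class ExperimentConfig:
    """Acquisition parameters for one experiment.

    Defaults follow the reference mouse protocol: 15 MBq FDG in 100 ul over
    30 s, 120 ul/min arterial withdrawal, PET/CT, 45.5 min scan.
    """

    dose_mbq: float = 15.0
    body_weight_g: float = 20.0
    injection_volume_ul: float = 100.0
    injection_duration_s: float = 30.0
    withdrawal_rate_ul_min: float = 120.0
    recovery_coefficient: float = 0.42
    tracer: str = "FDG"
    scanner: str = "PET/CT"
    scan_length_s: float = 2730.0
    isotope_half_life_s: float = 6586.2  # F-18
    catheter_delay_s: float = 30.4
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        for name in (
            "dose_mbq",
            "body_weight_g",
            "injection_volume_ul",
            "injection_duration_s",
            "withdrawal_rate_ul_min",
            "recovery_coefficient",
            "scan_length_s",
            "isotope_half_life_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recovery_coefficient > 1:
            raise ValueError("recovery coefficient must be in (0, 1]")
        if self.scanner not in ("PET/CT", "PET/MR"):
            raise ValueError("scanner must be 'PET/CT' or 'PET/MR'")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "#"


def _format_meta(meta: dict) -> str:
    pairs = ",".join(f"{k}={v}" for k, v in meta.items())
    return f"{_META_PREFIX} {pairs}"


def _parse_meta(line: str) -> dict:
    meta = {}
    body = line.lstrip(_META_PREFIX).strip()
    if body:
        for pair in body.split(","):
            if "=" in pair:
                k, v = pair.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_tac_table(
    path: str | Path,
    schedule: FrameSchedule,
    curves: Sequence[TimeActivityCurve],
    meta: dict | None = None,
) -> None:
    """Write frame schedule plus one column per region to a CSV file.

    The first line is a ``#``-prefixed metadata header carrying at least the
    units tag; data columns are frame_start, frame_end, then one per region.
    """
    if not curves:
        raise ValueError("no curves to write")
    units = curves[0].units
    if any(c.units != units for c in curves):
        raise ValueError("all curves in one table must share units")
    header = dict(meta or {})
    header["units"] = units
    df = pd.DataFrame({"frame_start": schedule.start, "frame_end": schedule.end})
    for c in curves:
        if len(c) != len(schedule):
            raise FormatError(f"curve '{c.region}' length does not match schedule")
        df[c.region] = c.values
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_format_meta(header) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_tac_table(path: str | Path) -> tuple[FrameSchedule, list[TimeActivityCurve], dict]:
    """Read a TAC table written by :func:`write_tac_table`.

    Returns the schedule, one curve per region column, and the metadata dict.
    Raises :class:`FormatError` on overlapping frames, missing columns or
    non-numeric cells, naming the offending row where possible.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_META_PREFIX):
            meta = _parse_meta(first)
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            meta = {}
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("frame_start", "frame_end"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {path.name}")
    region_cols = [c for c in df.columns if c not in ("frame_start", "frame_end")]
    if not region_cols:
        raise FormatError(f"no region columns in {path.name}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise FormatError(f"non-numeric cell in column '{col}', row {row}")
        df[col] = numeric
    if df.isna().any().any():
        raise FormatError(f"missing cells in {path.name}")
    schedule = FrameSchedule(df["frame_start"].to_numpy(), df["frame_end"].to_numpy())
    units = meta.get("units", UNITS_KBQ_ML)
    curves = [
        TimeActivityCurve(schedule.mid, df[c].to_numpy(), units=units, region=c, schedule=schedule)
        for c in region_cols
    ]
    return schedule, curves, meta


def write_blood_samples(path: str | Path, samples: Sequence[BloodSample]) -> None:
    df = pd.DataFrame(
        {"time_s": [s.time for s in samples], "concentration": [s.concentration for s in samples]}
    )
    df.to_csv(path, index=False)


def read_blood_samples(path: str | Path) -> list[BloodSample]:
    df = pd.read_csv(path)
    for col in ("time_s", "concentration"):
        if col not in df.columns:
            raise FormatError(f"missing column '{col}' in blood sample file")
    return [BloodSample(float(r.time_s), float(r.concentration)) for r in df.itertuples()]


def write_results_table(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of result dataclasses to CSV with stable columns.

    Accepts e.g. ``CurveFeatures`` or ``GroupComparison`` records. An empty
    list produces a header-only file and a warning (the record type is then
    unknown, so only a bare file is written).
    """
    path = Path(path)
    if not records:
        warnings.warn("writing empty results table (no records)", stacklevel=2)
        path.write_text("", encoding="utf-8")
        return
    first_type = type(records[0])
    if not dataclasses.is_dataclass(records[0]):
        raise TypeError("records must be dataclass instances")
    if any(type(r) is not first_type for r in records):
        raise TypeError("mixed record types in results table")
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=[f.name for f in dataclasses.fields(first_type)]).to_csv(
        path, index=False
    )


def read_results_table(path: str | Path, record_type) -> list:
    """Read back a results table into a list of ``record_type`` instances."""
    df = pd.read_csv(path, float_precision="round_trip")
    fields = [f.name for f in dataclasses.fields(record_type)]
    missing = set(fields) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns {sorted(missing)} for {record_type.__name__}")
    out = []
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in fields}
        out.append(record_type(**kwargs))
    return out


def write_config(path: str | Path, config: ExperimentConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)), encoding="utf-8")


def read_config(path: str | Path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ExperimentConfig(**data)


# ---------------------------------------------------------------------------
# Unit conversions and guideline checks
# ---------------------------------------------------------------------------


def to_suv(curve: TimeActivityCurve, dose_mbq: float, weight_g: float) -> TimeActivityCurve:
    """Convert a kBq/ml curve to SUV (g/ml): values * weight / dose_in_kBq.

    A curve already in SUV is returned unchanged with a warning.
    """
    if dose_mbq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    if curve.units == UNITS_SUV:
        warnings.warn("curve already in SUV; no conversion applied", stacklevel=2)
        return curve
    dose_kbq = dose_mbq * 1000.0
    return curve.replace(values=curve.values * weight_g / dose_kbq, units=UNITS_SUV)


def from_suv(curve: TimeActivityCurve, dose_mbq: float, weight_g: float) -> TimeActivityCurve:
    """Inverse of :func:`to_suv`: SUV back to kBq/ml."""
    if dose_mbq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    if curve.units == UNITS_KBQ_ML:
        warnings.warn("curve already in kBq/ml; no conversion applied", stacklevel=2)
        return curve
    dose_kbq = dose_mbq * 1000.0
    return curve.replace(values=curve.values * dose_kbq / weight_g, units=UNITS_KBQ_ML)


def max_bolus_volume(weight_g: float, limit_ml_per_kg: float = 5.0) -> float:
    """Maximum recommended intravenous bolus volume in microlitres.

    Rodent welfare guidelines cap single intravenous boluses at 5 ml/kg,
    i.e. 100 ul for a 20 g mouse.
    """
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    return limit_ml_per_kg * weight_g  # (ml/kg)*(g) == ul


def check_injection_volumes(
    volumes_ul: Iterable[float], weight_g: float, limit_ml_per_kg: float = 5.0
) -> bool:
    """True when each planned bolus stays within the per-injection limit."""
    limit = max_bolus_volume(weight_g, limit_ml_per_kg)
    return all(v <= limit for v in volumes_ul)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
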