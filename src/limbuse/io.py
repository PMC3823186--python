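"""Reading, validating and writing accelerometer recordings and cohort tables.

All downstream stages consume only the containers defined here.  Raw
recordings are plain delimited text with one header row and columns
``time_s, ax_ms2, ay_ms2, az_ms2``; one file per limb.  Accelerations are
stored in m/s² *including* the gravity component: the detector's range
statistic is offset-invariant within a window, so no gravity removal is
performed.  The time column is informative only — sample spacing is assumed
uniform at the declared rate.

The cohort table is delimited text with one row per participant (see
:data:`COHORT_COLUMNS`).  Missing values are empty cells, never sentinel
numbers, so that a missing covariate can never silently enter a model as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "CohortRecord",
    "InputFormatError",
    "ValidationError",
    "read_accel",
    "write_accel",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "COHORT_COLUMNS",
    "GROUPS",
    "ACCEL_COLUMNS",
]

ACCEL_COLUMNS = ("time_s", "ax_ms2", "ay_ms2", "az_ms2")
GROUPS = ("congenital", "acquired", "control")
LIMB_LABELS = ("intact", "residual")


class InputFormatError(ValueError):
    """Malformed raw input file (bad columns, non-numeric cells, ...)."""


class ValidationError(ValueError):
    """A record violates a coded range or an internal invariant."""


@dataclass(frozen=True)
class AccelTrace:
    """One limb's tri-axial acceleration time series.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, 3)`` holding the x, y, z acceleration
        axes in m/s² (gravity included).
    sample_rate:
        Samples per second (Hz).  The wrist/arm monitors emulated here
        record at 100 Hz.
    limb_label:
        ``"intact"`` (wrist sensor) or ``"residual"`` (upper-arm sensor).
    """

    data: np.ndarray
    sample_rate: float
    limb_label: str = "intact"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(
                f"acceleration data must have shape (n, 3), got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValidationError("acceleration trace must contain at least 1 sample")
        if not np.isfinite(arr).all():
            bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
            raise ValidationError(f"non-finite acceleration sample at row {bad}")
        if not (self.sample_rate > 0 and math.isfinite(self.sample_rate)):
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.limb_label not in LIMB_LABELS:
            raise ValidationError(
                f"limb_label must be one of {LIMB_LABELS}, got {self.limb_label!r}"
            )
        object.__setattr__(self, "data", arr)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def wear_duration(self) -> float:
        """Seconds of recording (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    def axis(self, i: int) -> np.ndarray:
        return self.data[:, i]

    def replace_data(self, data: np.ndarray) -> "AccelTrace":
        return AccelTrace(data=data, sample_rate=self.sample_rate, limb_label=self.limb_label)


def read_accel(path: str | Path, limb_label: str, sample_rate: float = 100.0) -> AccelTrace:
    """Read a raw tri-axial recording from delimited text.

    The file must have a single header row with the columns
    ``time_s, ax_ms2, ay_ms2, az_ms2``.  Non-numeric cells raise
    :class:`InputFormatError` naming the offending data row (1-based,
    excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise InputFormatError(f"{path}: unequal column lengths ({exc})") from exc
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing columns {missing}; header must be {list(ACCEL_COLUMNS)}")
    numeric = df[list(ACCEL_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[list(ACCEL_COLUMNS)].notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0]) + 1
        raise InputFormatError(f"{path}: non-numeric cell in data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0]) + 1
        raise InputFormatError(f"{path}: missing cell in data row {row}")
    data = numeric[["ax_ms2", "ay_ms2", "az_ms2"]].to_numpy(dtype=float)
    return AccelTrace(data=data, sample_rate=sample_rate, limb_label=limb_label)


def write_accel(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as delimited text readable by :func:`read_accel`.

    Floats are written with ``repr`` precision so that a read/write
    round-trip reproduces samples bit-identically.
    """
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.sample_rate
    df = pd.DataFrame(
        {
            "time_s": t,
            "ax_ms2": trace.data[:, 0],
            "ay_ms2": trace.data[:, 1],
            "az_ms2": trace.data[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "participant_id",
    "group",
    "amputation_level",
    "side",
    "deprivation_age",
    "cosmetic_prosthesis_usage",
    "functional_prosthesis_usage",
    "mal_score",
    "pain_intensity",
    "pain_frequency",
    "laterality_index",
    "beta_intact_hand",
    "beta_residual_arm",
)

# Fields that code amputation-specific facts; missing is allowed only for
# controls (who have no residual arm).
_AMPUTEE_ONLY = (
    "amputation_level",
    "deprivation_age",
    "side",
    "cosmetic_prosthesis_usage",
    "functional_prosthesis_usage",
    "mal_score",
    "pain_intensity",
    "pain_frequency",
)


@dataclass(frozen=True)
class CohortRecord:
    """One participant's covariates, scores and ROI activation estimates.

    Coded ranges follow the cohort schema: ``amputation_level`` 1–5
    (1 = through shoulder … 5 = through wrist), prosthesis-usage
    frequencies 0–5 (0 = never … 5 = more than 8 h a day), pain intensity
    0–10, pain frequency 1–5 (1 = all the time … 5 = once or less per
    month).  ``beta_intact_hand`` / ``beta_residual_arm`` are externally
    supplied region-of-interest activation estimates (arbitrary units);
    this package never computes them.
    """

    participant_id: str
    group: str
    amputation_level: int | None = None
    side: str | None = None
    deprivation_age: float | None = None
    cosmetic_prosthesis_usage: int | None = None
    functional_prosthesis_usage: int | None = None
    mal_score: float | None = None
    pain_intensity: float | None = None
    pain_frequency: int | None = None
    laterality_index: float | None = None
    beta_intact_hand: float | None = None
    beta_residual_arm: float | None = None

    def __post_init__(self) -> None:
        pid = str(self.participant_id)
        if self.group not in GROUPS:
            raise ValidationError(f"{pid}: group must be one of {GROUPS}, got {self.group!r}")
        if self.group != "control":
            for name in ("amputation_level", "deprivation_age"):
                if getattr(self, name) is None:
                    raise ValidationError(f"{pid}: {name} is required for group {self.group!r}")
        self._check_coded(pid, "amputation_level", 1, 5, integer=True)
        self._check_coded(pid, "cosmetic_prosthesis_usage", 0, 5, integer=True)
        self._check_coded(pid, "functional_prosthesis_usage", 0, 5, integer=True)
        self._check_coded(pid, "pain_frequency", 1, 5, integer=True)
        self._check_coded(pid, "pain_intensity", 0, 10)
        self._check_coded(pid, "mal_score", 0.0, 1.0)
        self._check_coded(pid, "laterality_index", -1.0, 1.0)
        self._check_coded(pid, "deprivation_age", 0.0, math.inf)
        if self.side is not None and self.side not in ("L", "R"):
            raise ValidationError(f"{pid}: side must be 'L' or 'R', got {self.side!r}")

    def _check_coded(self, pid: str, name: str, lo: float, hi: float, integer: bool = False) -> None:
        value = getattr(self, name)
        if value is None:
            return
        if integer and float(value) != int(value):
            raise ValidationError(f"{pid}: {name} must be an integer code, got {value!r}")
        if not (lo <= float(value) <= hi):
            raise ValidationError(f"{pid}: {name}={value!r} outside coded range [{lo}, {hi}]")


def _cell(value):
    """Convert a pandas cell to None (missing) or a plain Python scalar."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if pd.isna(value):
        return None
    return value


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read and validate a cohort table; missing cells stay missing."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing cohort columns {missing}")
    records = []
    int_fields = {
        "amputation_level",
        "cosmetic_prosthesis_usage",
        "functional_prosthesis_usage",
        "pain_frequency",
    }
    for _, row in df.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            value = _cell(row[col])
            if value is not None and col in int_fields:
                if float(value) != int(float(value)):
                    raise ValidationError(
                        f"{row['participant_id']}: {col} must be an integer code, got {value!r}"
                    )
                value = int(float(value))
            kwargs[col] = value
        kwargs["participant_id"] = str(kwargs["participant_id"])
        records.append(CohortRecord(**kwargs))
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Tabulate records for the statistics layer (missing → NaN)."""
    rows = []
    for r in records:
        rows.append({f.name: getattr(r, f.name) for f in dc_fields(r)})
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    for col in COHORT_COLUMNS:
        if col not in ("participant_id", "group", "side"):
            df[col] = pd.to_numeric(df[col])  # None -> NaN
    return df


def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    df = cohort_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")
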