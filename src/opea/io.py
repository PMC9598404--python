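"""Readers and writers for analyzer trace dumps, cohort tables and calibrations.

The analyzer streams one data line every 2 s for 180 s per measurement; each
line carries the measurement id, the elapsed time from t0 (s) and the
normalized absorption index of the colorimetric reaction.  The on-disk
dialect used here is tab-separated ``id<TAB>t_s<TAB>abs_index`` with
``#``-prefixed comment lines.  Decimal separators must be ``.``; lines with
``,`` separators are rejected as malformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "KineticTrace",
    "Calibration",
    "TraceValidationError",
    "CohortValidationError",
    "read_traces",
    "write_traces",
    "read_cohort",
    "write_cohort",
    "read_calibration",
    "write_calibration",
    "read_lms_table",
]


class TraceValidationError(ValueError):
    """A kinetic trace violates the acquisition contract."""


class CohortValidationError(ValueError):
    """A cohort table is missing mandatory structure."""


TRACE_ROLES = ("exhaled", "ambient")

#: total acquisition time per measurement, seconds
ACQUISITION_SPAN_S = 180.0
#: nominal sampling period, seconds
SAMPLING_PERIOD_S = 2.0


@dataclass
class KineticTrace:
    """One measurement's (time, absorption index) series.

    ``times`` are seconds elapsed from t0, strictly increasing, on the nominal
    0..180 s grid sampled every 2 s.  ``absorption`` is the dimensionless
    normalized absorption index tracking the Fe(III)-orange xylenol reaction.
    """

    measurement_id: int
    times: np.ndarray
    absorption: np.ndarray
    role: str = "exhaled"
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if self.times.size != self.absorption.size:
            raise TraceValidationError(
                f"trace {self.measurement_id}: times and absorption lengths differ "
                f"({self.times.size} vs {self.absorption.size})"
            )
        if self.times.size < 2:
            raise TraceValidationError(
                f"trace {self.measurement_id}: fewer than 2 points ({self.times.size})"
            )
        if np.any(np.diff(self.times) <= 0):
            raise TraceValidationError(
                f"trace {self.measurement_id}: times are not strictly increasing"
            )
        if self.times[0] < 0 or self.times[-1] > ACQUISITION_SPAN_S:
            raise TraceValidationError(
                f"trace {self.measurement_id}: times outside [0, {ACQUISITION_SPAN_S:g}] s"
            )
        if self.role not in TRACE_ROLES:
            raise TraceValidationError(
                f"trace {self.measurement_id}: unknown role {self.role!r}"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class Calibration:
    """Linear calibration from fitted slope (s^-1) to pmol/L of air.

    ``lod`` is the instrument's limit of detection in pmol; it is carried as
    metadata and does not gate any computation here.
    """

    gain: float
    intercept: float = 0.0
    lod: float = 0.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"calibration gain must be > 0, got {self.gain}")
        if self.lod < 0:
            raise ValueError(f"calibration lod must be >= 0, got {self.lod}")


def _parse_trace_line(line: str) -> tuple[int, float, float]:
    parts = line.split("\t")
    if len(parts) != 3:
        raise ValueError(f"expected 3 tab-separated fields, got {len(parts)}")
    if "," in line:
        raise ValueError("comma decimal separator not allowed; use '.'")
    mid = int(parts[0])
    t = float(parts[1])
    a = float(parts[2])
    return mid, t, a


def read_traces(path: str | Path) -> list[KineticTrace]:
    """Read a trace dump file into one :class:`KineticTrace` per distinct id.

    Points are ordered by time regardless of file order, so parsing is
    insensitive to line shuffling.  Malformed lines are skipped and reported
    with their line numbers via the module logger.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    TraceValidationError
        If any id ends up with fewer than 2 points.
    """
    path = Path(path)
    points: dict[int, list[tuple[float, float]]] = {}
    bad_lines: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                mid, t, a = _parse_trace_line(line)
            except ValueError as exc:
                bad_lines.append((lineno, str(exc)))
                continue
            points.setdefault(mid, []).append((t, a))
    for lineno, reason in bad_lines:
        logger.warning("%s:%d malformed trace line: %s", path, lineno, reason)
    if not points:
        logger.warning("%s: no trace records found", path)
        return []
    traces = []
    for mid in sorted(points):
        pts = sorted(points[mid])
        if len(pts) < 2:
            raise TraceValidationError(
                f"trace {mid}: fewer than 2 points in {path}"
            )
        t, a = zip(*pts)
        traces.append(KineticTrace(measurement_id=mid, times=np.array(t), absorption=np.array(a)))
    return traces


def write_traces(traces: Iterable[KineticTrace], path: str | Path) -> None:
    """Write traces in the tab-separated dialect read by :func:`read_traces`.

    Values are written with 10 significant digits, so a write→read round trip
    preserves traces to that precision.  Role and participant assignment are
    not part of the dump format; they travel in the pairing map.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id\tt_s\tabs_index\n")
        for trace in traces:
            for t, a in zip(trace.times, trace.absorption):
                fh.write(f"{trace.measurement_id}\t{t:.10g}\t{a:.10g}\n")


# Cohort table -------------------------------------------------------------

#: canonical category vocabulary per categorical column (Unknown added where
#: the study reported missing data as its own category)
COHORT_VOCAB: dict[str, tuple[str, ...]] = {
    "sex": ("Female", "Male"),
    "diet": ("Omnivore", "Vegetarian", "Vegan"),
    "smoking": ("Non-smoker", "Smoker", "Ex-smoker"),
    "self_health": ("Healthy", "Unhealthy"),
    "serology": ("Positive", "Negative"),
}

_ALIASES = {"Omnivor": "Omnivore"}

_NUMERIC_COLUMNS = ("age", "bmi", "height", "fev1", "fvc", "fef2575", "opea")
_BOOL_COLUMNS = ("respiratory_disease", "general_health_bad", "other_disease")


def _clean_category(value: object, vocab: tuple[str, ...]) -> str:
    if pd.isna(value) or str(value).strip() == "":
        return "Unknown"
    label = _ALIASES.get(str(value).strip(), str(value).strip())
    return label if label in vocab else "Unknown"


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Categorical columns are normalized against the study vocabulary; labels
    outside it (and empty cells) map to ``"Unknown"``.  Numeric columns keep
    missing values as NaN.  ``participant_id`` is mandatory.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise CohortValidationError(f"{path}: missing mandatory column 'participant_id'")
    for col, vocab in COHORT_VOCAB.items():
        if col in df.columns:
            df[col] = df[col].map(lambda v: _clean_category(v, vocab))
    for col in _NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in ("true", "1", "yes")
            )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (floats at 10 significant digits)."""
    df.to_csv(path, index=False, float_format="%.10g")


def read_calibration(path: str | Path) -> Calibration:
    """Read a YAML/JSON calibration file with keys gain, intercept, lod."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "gain" not in data:
        raise ValueError(f"{path}: calibration file must define at least 'gain'")
    return Calibration(
        gain=float(data["gain"]),
        intercept=float(data.get("intercept", 0.0)),
        lod=float(data.get("lod", 0.0)),
    )


def write_calibration(cal: Calibration, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"gain": cal.gain, "intercept": cal.intercept, "lod": cal.lod},
            fh,
            sort_keys=True,
        )


def read_lms_table(path: str | Path) -> pd.DataFrame:
    """Read an LMS coefficient CSV with columns parameter, sex, L, M, S."""
    df = pd.read_csv(path)
    required = {"parameter", "sex", "L", "M", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: LMS table missing columns {sorted(missing)}")
    return df
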