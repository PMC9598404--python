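"""Kinetic-trace reduction: windowed slope fit, calibration, replicate pooling.

The reaction advancement is linear in time over the stable part of the run, so
each measurement reduces to the ordinary least-squares slope of the absorption
index on time over a fixed window (default 60-150 s inclusive, 46 points on
the 2 s grid).  The coefficient of determination of that fit gates quality
control, and the slope converts to pmol H2O2-equivalents per litre of air
through a linear calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Calibration, KineticTrace, TraceValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_R2_THRESHOLD",
    "SlopeFit",
    "OxidativePotential",
    "ReplicateError",
    "fit_slope",
    "calibrate",
    "aggregate_replicates",
]

#: default slope-fit window in seconds, endpoints inclusive
DEFAULT_WINDOW: tuple[float, float] = (60.0, 150.0)
#: default R^2 below which a replicate fails quality control
DEFAULT_R2_THRESHOLD = 0.95


class ReplicateError(ValueError):
    """No quality-passing replicate is available for aggregation."""


@dataclass
class SlopeFit:
    """OLS slope of absorption on time inside a window.

    ``r2`` is 1 - SS_res/SS_tot; a fit with zero residuals on constant data is
    reported as r2 = 1 (the line reproduces the data exactly).
    """

    slope: float
    r2: float
    n_points: int
    window: tuple[float, float]
    intercept: float = 0.0
    measurement_id: int | None = None


@dataclass
class OxidativePotential:
    """Calibrated oxidative potential of one replicate, pmol/L of air."""

    value: float
    fit: SlopeFit
    qc_pass: bool
    replicate_index: int = 0


def fit_slope(trace: KineticTrace, window: tuple[float, float] = DEFAULT_WINDOW) -> SlopeFit:
    """Fit the OLS slope of the absorption index over the closed time window.

    Parameters
    ----------
    trace
        Kinetic trace; points outside the window are ignored.
    window
        ``(start, end)`` seconds, endpoints inclusive; start < end.

    Raises
    ------
    TraceValidationError
        If fewer than 2 points fall inside the window.
    """
    start, end = window
    if not start < end:
        raise ValueError(f"window start must be < end, got {window}")
    mask = (trace.times >= start) & (trace.times <= end)
    n = int(mask.sum())
    if n < 2:
        raise TraceValidationError(
            f"trace {trace.measurement_id}: {n} point(s) inside window [{start}, {end}] s"
        )
    t = trace.times[mask]
    y = trace.absorption[mask]
    tbar = t.mean()
    ybar = y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_res = float(np.sum((y - (intercept + slope * t)) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        # constant data: the zero-slope line is an exact fit
        r2 = 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return SlopeFit(
        slope=slope,
        r2=r2,
        n_points=n,
        window=(float(start), float(end)),
        intercept=intercept,
        measurement_id=trace.measurement_id,
    )


def calibrate(
    fit: SlopeFit,
    cal: Calibration,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    replicate_index: int = 0,
) -> OxidativePotential:
    """Convert a fitted slope (s^-1) to pmol/L_air: value = gain·slope + intercept.

    QC fails whenever the fit's R^2 is below ``r2_threshold``.  Negative
    calibrated values are possible with noisy near-zero slopes; they are kept
    but logged, since the ratio normalization downstream decides their fate.
    """
    value = cal.gain * fit.slope + cal.intercept
    qc_pass = fit.r2 >= r2_threshold
    if value < 0:
        logger.info(
            "negative oxidative potential %.4g pmol/L (id=%s, slope=%.4g)",
            value,
            fit.measurement_id,
            fit.slope,
        )
    return OxidativePotential(value=value, fit=fit, qc_pass=qc_pass, replicate_index=replicate_index)


def aggregate_replicates(
    values: Sequence[OxidativePotential],
    how: str = "mean",
) -> float:
    """Pool replicate measurements (assays run in triplicate) into one value.

    Only QC-passing replicates contribute; the default pool is the arithmetic
    mean (``how="median"`` selects the median).

    Raises
    ------
    ReplicateError
        If no replicate passes QC; the error lists the failing ids.
    """
    passing = [op.value for op in values if op.qc_pass]
    if not passing:
        failed = [op.fit.measurement_id for op in values]
        raise ReplicateError(f"no QC-passing replicate among ids {failed}")
    n_failed = len(values) - len(passing)
    if n_failed:
        logger.info("aggregating %d replicate(s); %d failed QC", len(passing), n_failed)
    if how == "mean":
        return float(np.mean(passing))
    if how == "median":
        return float(np.median(passing))
    raise ValueError(f"unknown aggregation {how!r}; use 'mean' or 'median'")
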