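"""LMS-based spirometry reference values and lower-limit-of-normal flagging.

Lung-function reference equations express the distribution of a parameter
(FEV1, FVC, FEV1/FVC, FEF25-75) in the healthy population through three
quantities: L (Box-Cox skewness), M (median) and S (coefficient of
variation).  The value at standard-normal quantile z is

    M * (1 + L*S*z)**(1/L)   if L != 0
    M * exp(S*z)             if L == 0

The lower limit of normal (LLN) is the 5th percentile, z = -1.6449; an
observed value strictly below the LLN is flagged abnormal.  Coefficients are
supplied per parameter and sex stratum; this module does not re-derive the
published age-spline coefficient tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LLN_Z",
    "PARAMETERS",
    "LmsCoefficients",
    "SpiroAssessment",
    "lms_percentile",
    "assess",
    "flag_cohort",
]

#: standard-normal quantile defining the LLN (5th percentile)
LLN_Z = -1.6449

PARAMETERS = ("FEV1", "FVC", "FEV1_FVC", "FEF2575")

#: cohort column holding the observed value for each spirometry parameter;
#: the FEV1/FVC ratio is derived from its two components
PARAMETER_COLUMNS = {"FEV1": "fev1", "FVC": "fvc", "FEF2575": "fef2575"}


@dataclass
class LmsCoefficients:
    """One stratum's LMS triple for a spirometry parameter."""

    parameter: str
    sex: str
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"LMS median M must be > 0, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"LMS coefficient of variation S must be > 0, got {self.S}")


@dataclass
class SpiroAssessment:
    """Observed value versus its LMS-derived LLN and predicted (median) value."""

    parameter: str
    observed: float
    lln: float
    predicted: float
    below_lln: bool


def lms_percentile(coef: LmsCoefficients, z: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the LMS distribution at standard-normal quantile(s) z.

    Accepts a scalar or an array of z values.  Raises a domain error when
    ``1 + L*S*z <= 0`` with L != 0 (the Box-Cox transform leaves its domain).
    """
    z = np.asarray(z, dtype=float)
    if coef.L != 0.0:
        base = 1.0 + coef.L * coef.S * z
        if np.any(base <= 0):
            raise ValueError(
                f"{coef.parameter}/{coef.sex}: 1 + L*S*z <= 0 at z extreme "
                f"(L={coef.L}, S={coef.S})"
            )
        out = coef.M * base ** (1.0 / coef.L)
    else:
        out = coef.M * np.exp(coef.S * z)
    return float(out) if out.ndim == 0 else out


def assess(observed: float, coef: LmsCoefficients) -> SpiroAssessment:
    """Dichotomize an observed value against its LLN (strictly below = abnormal).

    A value exactly at the LLN counts as normal: the dichotomy is
    <LLN versus >=LLN.
    """
    if not observed > 0:
        raise ValueError(f"observed {coef.parameter} must be > 0, got {observed}")
    lln = lms_percentile(coef, LLN_Z)
    predicted = lms_percentile(coef, 0.0)
    return SpiroAssessment(
        parameter=coef.parameter,
        observed=observed,
        lln=lln,
        predicted=predicted,
        below_lln=observed < lln,
    )


def _coef_lookup(lms_table: pd.DataFrame) -> dict[tuple[str, str], LmsCoefficients]:
    lookup: dict[tuple[str, str], LmsCoefficients] = {}
    for row in lms_table.itertuples(index=False):
        lookup[(row.parameter, row.sex)] = LmsCoefficients(
            parameter=row.parameter, sex=row.sex, L=float(row.L), M=float(row.M), S=float(row.S)
        )
    return lookup


def flag_cohort(cohort: pd.DataFrame, lms_table: pd.DataFrame) -> pd.DataFrame:
    """Append ``{param}_lln`` and ``{param}_below_lln`` columns to a cohort.

    Observed FEV1/FVC is computed from the fev1 and fvc columns.  Rows with a
    missing observed value, or with a sex stratum absent from the coefficient
    table, keep missing flags (the study's "Unknown" rows).
    """
    lookup = _coef_lookup(lms_table)
    out = cohort.copy()
    observed: dict[str, pd.Series] = {
        param: pd.to_numeric(out.get(col), errors="coerce")
        for param, col in PARAMETER_COLUMNS.items()
        if col in out.columns
    }
    if "fev1" in out.columns and "fvc" in out.columns:
        observed["FEV1_FVC"] = observed["FEV1"] / observed["FVC"]
    for param, obs in observed.items():
        lln = np.full(len(out), np.nan)
        for sex in out["sex"].unique():
            coef = lookup.get((param, sex))
            if coef is None:
                continue
            lln[(out["sex"] == sex).to_numpy()] = lms_percentile(coef, LLN_Z)
        lln_s = pd.Series(lln, index=out.index)
        out[f"{param.lower()}_lln"] = lln_s
        flag = (obs < lln_s).astype("boolean")
        flag[obs.isna() | lln_s.isna()] = pd.NA
        out[f"{param.lower()}_below_lln"] = flag
    return out
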