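"""Health-status classification and cohort summary statistics.

A participant is unhealthy when they declare a respiratory disease (asthma,
chronic bronchitis, COPD, emphysema), rate their general health as bad, or —
optionally — report another disease; otherwise healthy.  Group comparisons of
the log-scale OPEA use a one-sided two-sample t-test for dichotomous
variables (the working hypothesis being that OPEA is higher under abnormal
respiratory conditions) and one-way ANOVA for variables with more than two
categories.  No multiple-testing correction is applied across variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "HealthStatus",
    "GroupSummary",
    "classify_health",
    "add_health_status",
    "one_sided_t_test",
    "anova",
    "mean_ci",
    "percent",
    "table1_proportions",
    "summarize_table2",
    "age_category",
    "bmi_category",
]


@dataclass
class HealthStatus:
    status: str  # "healthy" | "unhealthy"
    reasons: list[str] = field(default_factory=list)


@dataclass
class GroupSummary:
    """One category's OPEA summary within a variable, plus the variable-level p."""

    variable: str
    category: str
    n: int
    mean: float
    ci95: tuple[float, float]
    p_value: float | None


def classify_health(
    declared_respiratory_disease: bool = False,
    general_health_bad: bool = False,
    other_disease: bool = False,
    include_other: bool = True,
) -> HealthStatus:
    """Binary health status from self-declared questionnaire triggers.

    ``include_other=False`` restricts the rule to the two core triggers
    (respiratory disease declared, general health rated bad).
    """
    reasons = []
    if declared_respiratory_disease:
        reasons.append("respiratory_disease_declared")
    if general_health_bad:
        reasons.append("general_health_bad")
    if include_other and other_disease:
        reasons.append("other_disease")
    return HealthStatus(status="unhealthy" if reasons else "healthy", reasons=reasons)


def add_health_status(cohort: pd.DataFrame, include_other: bool = True) -> pd.DataFrame:
    """Append a ``health_status`` column.

    Uses the boolean trigger columns when present; falls back to the
    ``self_health`` label otherwise.
    """
    out = cohort.copy()
    if "respiratory_disease" in out.columns:
        out["health_status"] = [
            classify_health(
                bool(r), bool(g), bool(o), include_other=include_other
            ).status
            for r, g, o in zip(
                out["respiratory_disease"],
                out.get("general_health_bad", pd.Series(False, index=out.index)),
                out.get("other_disease", pd.Series(False, index=out.index)),
            )
        ]
    elif "self_health" in out.columns:
        out["health_status"] = np.where(out["self_health"] == "Unhealthy", "unhealthy", "healthy")
    else:
        raise ValueError("cohort has neither trigger columns nor self_health")
    return out


def one_sided_t_test(
    reference: Sequence[float],
    exposed: Sequence[float],
    equal_var: bool = True,
) -> float:
    """One-sided p-value for H1: mean(exposed) > mean(reference).

    Pooled-variance Student t by default; ``equal_var=False`` gives Welch.
    """
    ref = np.asarray(reference, dtype=float)
    exp = np.asarray(exposed, dtype=float)
    for name, grp in (("reference", ref), ("exposed", exp)):
        if grp.size < 2:
            raise ValueError(f"{name} group has fewer than 2 values")
    if ref.var(ddof=1) + exp.var(ddof=1) == 0:
        raise ValueError("both groups are constant; t statistic undefined")
    res = sps.ttest_ind(exp, ref, equal_var=equal_var, alternative="greater")
    return float(res.pvalue)


def anova(groups: Mapping[str, Sequence[float]]) -> float:
    """One-way fixed-effects ANOVA p-value across labelled groups."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for label, arr in zip(groups, arrays):
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    if sum(a.var(ddof=1) * (a.size - 1) for a in arrays) == 0:
        raise ValueError("zero within-group variance; F statistic undefined")
    res = sps.f_oneway(*arrays)
    return float(res.pvalue)


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample mean with its normal-theory (Student t) confidence interval."""
    arr = np.asarray(values, dtype=float)
    m = float(arr.mean())
    if arr.size < 2:
        return m, (float("nan"), float("nan"))
    se = arr.std(ddof=1) / np.sqrt(arr.size)
    tcrit = sps.t.ppf(0.5 + level / 2, df=arr.size - 1)
    return m, (m - tcrit * se, m + tcrit * se)


def percent(count: int, total: int) -> float:
    """Percentage of total, rounded to 2 decimals."""
    return round(100.0 * count / total, 2)


def age_category(age: float) -> str:
    if pd.isna(age):
        return "Unknown"
    for lo, hi, label in ((20, 30, "20-29"), (30, 40, "30-39"), (40, 50, "40-49"), (50, 60, "50-59"), (60, 72, "60-71")):
        if lo <= age < hi:
            return label
    return "Unknown"


def bmi_category(bmi: float) -> str:
    if pd.isna(bmi):
        return "Unknown"
    if bmi <= 25:
        return "<=25"
    if bmi < 30:
        return "25-30"
    return ">=30"


#: variable name -> (category extractor, exposed category for one-sided tests).
#: ``exposed`` is the category hypothesized to have the higher OPEA; None means
#: the variable has >2 categories and is tested by ANOVA.
def _spiro_flag(col: str):
    def extract(df: pd.DataFrame) -> pd.Series:
        if col not in df.columns:
            raise KeyError(col)
        flags = df[col]
        return pd.Series(
            np.where(flags.isna(), "Unknown", np.where(flags.astype("boolean").fillna(False), "<LLN(GLI)", "Normal")),
            index=df.index,
        )

    return extract


def _column(col: str):
    def extract(df: pd.DataFrame) -> pd.Series:
        if col not in df.columns:
            raise KeyError(col)
        return df[col].fillna("Unknown").astype(str)

    return extract


TABLE_VARIABLES: dict[str, tuple] = {
    "sex": (_column("sex"), "Male"),
    "age_category": (lambda df: df["age"].map(age_category), None),
    "diet": (_column("diet"), None),
    "bmi_category": (lambda df: df["bmi"].map(bmi_category), None),
    "smoking": (_column("smoking"), None),
    "self_health": (_column("self_health"), "Unhealthy"),
    "serology": (_column("serology"), "Positive"),
    "fev1": (_spiro_flag("fev1_below_lln"), "<LLN(GLI)"),
    "fvc": (_spiro_flag("fvc_below_lln"), "<LLN(GLI)"),
    "fev1_fvc": (_spiro_flag("fev1_fvc_below_lln"), "<LLN(GLI)"),
    "fef2575": (_spiro_flag("fef2575_below_lln"), "<LLN(GLI)"),
}


def table1_proportions(
    cohort: pd.DataFrame,
    variables: Mapping[str, tuple] | None = None,
) -> pd.DataFrame:
    """Per-variable category counts and percentages of the total sample.

    Percentages use the full cohort as denominator and are rounded to two
    decimals; "Unknown" counts as its own category, so percentages within a
    variable sum to 100 up to rounding.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    variables = variables if variables is not None else TABLE_VARIABLES
    total = len(cohort)
    rows = []
    for var, (extract, _) in variables.items():
        try:
            cats = extract(cohort)
        except KeyError:
            logger.warning("table1: variable %s absent from cohort, skipped", var)
            continue
        counts = cats.value_counts()
        for category, n in counts.items():
            rows.append(
                {"variable": var, "category": category, "n": int(n), "percent": percent(int(n), total)}
            )
    return pd.DataFrame(rows)


def summarize_table2(
    cohort: pd.DataFrame,
    opea_col: str = "opea",
    variables: Mapping[str, tuple] | None = None,
    equal_var: bool = True,
) -> list[GroupSummary]:
    """OPEA mean, 95% CI and test p-value per participant characteristic.

    Per category: n (participants with OPEA), mean, Student-t 95% CI of the
    mean.  Per variable: one p-value — a one-sided pooled t-test for
    dichotomous variables (exposed category per :data:`TABLE_VARIABLES`),
    one-way ANOVA otherwise.  "Unknown" categories are excluded from both the
    tests and the summary rows, mirroring how the study tabulated results;
    variables absent from the cohort are skipped with a warning.
    """
    variables = variables if variables is not None else TABLE_VARIABLES
    opea = pd.to_numeric(cohort[opea_col], errors="coerce")
    summaries: list[GroupSummary] = []
    for var, (extract, exposed_cat) in variables.items():
        try:
            cats = extract(cohort)
        except KeyError:
            logger.warning("table2: variable %s absent from cohort, skipped", var)
            continue
        mask = cats.ne("Unknown") & opea.notna()
        groups = {
            str(c): opea[mask & (cats == c)].to_numpy()
            for c in cats[mask].unique()
        }
        groups = {c: v for c, v in groups.items() if v.size > 0}
        p: float | None = None
        testable = {c: v for c, v in groups.items() if v.size >= 2}
        if len(testable) >= 2:
            try:
                if len(testable) == 2 and exposed_cat in testable:
                    ref_cat = next(c for c in testable if c != exposed_cat)
                    p = one_sided_t_test(testable[ref_cat], testable[exposed_cat], equal_var=equal_var)
                else:
                    p = anova(testable)
            except ValueError as exc:
                logger.warning("table2: test for %s failed: %s", var, exc)
        for category in sorted(groups):
            vals = groups[category]
            m, ci = mean_ci(vals)
            summaries.append(
                GroupSummary(variable=var, category=category, n=int(vals.size), mean=m, ci95=ci, p_value=p)
            )
    return summaries


def table2_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [s.variable for s in summaries],
            "category": [s.category for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "ci95_low": [s.ci95[0] for s in summaries],
            "ci95_high": [s.ci95[1] for s in summaries],
            "p_value": [s.p_value for s in summaries],
        }
    )
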