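"""Synthetic instrument traces and cohort tables for pipeline validation.

The study's participant-level data are not public, so this module generates
data with the statistical structure the analysis assumes: kinetic traces with
linear-in-time absorption growth plus Gaussian point noise, and cohort tables
whose covariate frequencies, log-scale OPEA distribution, and group effect
sizes default to the study's published marginals.

Two spread regimes for the healthy log-OPEA are supported (see the methods
note): the narrow regime (SD 0.012) matching the published reference-interval
arithmetic, and the wide regime (SD 0.21) implied by the published group-mean
confidence intervals.  The published group effects (seropositive +0.0657,
obstructive +0.1071) are large relative to the narrow spread, so
reference-interval scenarios in the narrow regime should be generated with
zero effects; group-comparison scenarios belong in the wide regime.

Healthy OPEA values are drawn from a normal truncated at ±2.5 SD, and any
non-planted healthy value that would still fall outside the sample's own
Tukey fences is redrawn: the study's healthy bulk contained a single extreme
value in 221 participants, i.e. tails lighter than Gaussian relative to Tukey
fences (which sit near ±2.70 SD in the population but fluctuate with the
sample quartiles), so by construction the outlier screen flags exactly the
planted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import Calibration, KineticTrace, write_calibration, write_cohort, write_traces
from .spirometry import LLN_Z, LmsCoefficients, lms_percentile

__all__ = [
    "TABLE1_PROBS",
    "DEFAULT_CALIBRATION",
    "TraceSpec",
    "CohortSpec",
    "gen_trace",
    "gen_cohort",
    "default_lms_table",
    "write_fixtures",
]

#: marginal category frequencies of the study sample (N = 247)
TABLE1_PROBS: dict[str, dict[str, float]] = {
    "sex": {"Female": 150 / 247, "Male": 97 / 247},
    "age_category": {
        "20-29": 53 / 247,
        "30-39": 48 / 247,
        "40-49": 43 / 247,
        "50-59": 56 / 247,
        "60-71": 47 / 247,
    },
    "diet": {"Omnivore": 182 / 247, "Vegetarian": 33 / 247, "Vegan": 29 / 247, "Unknown": 3 / 247},
    "smoking": {"Non-smoker": 134 / 247, "Smoker": 28 / 247, "Ex-smoker": 85 / 247},
    "bmi_category": {"<=25": 139 / 247, "25-30": 73 / 247, ">=30": 24 / 247, "Unknown": 11 / 247},
    "serology": {"Positive": 51 / 247, "Negative": 173 / 247, "Unknown": 23 / 247},
}

#: fraction of the study sample flagged unhealthy (26 of 247)
UNHEALTHY_PROB = 26 / 247
#: fraction of unhealthy participants declaring a respiratory disease (15 of 26)
RESPIRATORY_FRACTION = 15 / 26
#: fraction with missing spirometry (9 of 247)
SPIRO_MISSING_PROB = 9 / 247
#: obstructive-pattern prevalence among measured spirometries (13 of 238)
OBSTRUCTION_PROB = 13 / 238

DEFAULT_CALIBRATION = Calibration(gain=1000.0, intercept=0.0, lod=3.0)

_AGE_RANGES = {"20-29": (20, 30), "30-39": (30, 40), "40-49": (40, 50), "50-59": (50, 60), "60-71": (60, 72)}
_BMI_RANGES = {"<=25": (19.0, 25.0), "25-30": (25.0, 30.0), ">=30": (30.0, 40.0)}


@dataclass
class TraceSpec:
    """Parameters of a simulated triplicate measurement.

    ``noise_sd`` is the per-point Gaussian noise on the absorption index
    (default 0.002, about 1% replicate CV on the calibrated value, in line
    with a triplicated colorimetric assay).
    """

    true_op: float
    cal: Calibration = field(default_factory=lambda: DEFAULT_CALIBRATION)
    noise_sd: float = 0.002
    n_replicates: int = 3
    baseline: float = 0.1
    t_start: float = 0.0
    t_end: float = 180.0
    dt: float = 2.0


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    Category frequencies default to the study marginals; ``n_unhealthy``
    defaults to round(n × 26/247).  Effects are additive on the log10 scale.
    Planted outliers sit at mean ± 6 SD among healthy participants.
    """

    n: int = 247
    seed: int = 42
    category_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in TABLE1_PROBS.items()})
    healthy_opea_mean: float = -0.028
    healthy_opea_sd: float = 0.012
    serology_effect: float = 0.0657
    obstruction_effect: float = 0.1071
    outlier_count: int = 1
    n_unhealthy: int | None = None
    truncation_z: float = 2.5
    spiro_missing_prob: float = SPIRO_MISSING_PROB
    obstruction_prob: float = OBSTRUCTION_PROB

    def __post_init__(self) -> None:
        if self.healthy_opea_sd <= 0:
            raise ValueError("healthy_opea_sd must be > 0")
        for var, probs in self.category_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{var}: category probabilities sum to {total}, not 1")


def gen_trace(
    spec: TraceSpec,
    seed: int,
    start_id: int = 1,
    role: str = "exhaled",
    participant_id: str | None = None,
) -> list[KineticTrace]:
    """Simulate replicate kinetic traces with a given true oxidative potential.

    Each trace is ``absorption(t) = baseline + slope·t + N(0, noise_sd)`` per
    point on the nominal 2 s grid, with ``slope = (true_op − intercept)/gain``
    — the exact inverse of the fit→calibrate reduction, so noiseless traces
    recover ``true_op`` to machine precision.
    """
    rng = np.random.default_rng(seed)
    slope = (spec.true_op - spec.cal.intercept) / spec.cal.gain
    times = np.arange(spec.t_start, spec.t_end + spec.dt / 2, spec.dt)
    traces = []
    for i in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=times.size) if spec.noise_sd > 0 else 0.0
        traces.append(
            KineticTrace(
                measurement_id=start_id + i,
                times=times,
                absorption=spec.baseline + slope * times + noise,
                role=role,
                participant_id=participant_id,
            )
        )
    return traces


def _truncated_normal(rng: np.random.Generator, size: int, low_z: float, high_z: float) -> np.ndarray:
    """Standard-normal draws restricted to (low_z, high_z) via inverse CDF."""
    u = rng.uniform(norm.cdf(low_z), norm.cdf(high_z), size=size)
    return norm.ppf(u)


def _draw_categories(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    return rng.choice(labels, size=n, p=[probs[c] for c in labels])


def gen_cohort(spec: CohortSpec, lms_table: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort table together with its ground truth.

    Returns ``(cohort, truth)``.  ``cohort`` has the columns the readers and
    statistics expect (including an ``opea`` column); ``truth`` carries the
    latent labels (healthy, seropositive, obstructed, planted outlier) used to
    generate it.

    OPEA is drawn directly on the log10 scale: truncated normal base plus the
    configured effect shifts for seropositive and obstructed participants.
    Spirometry values follow the LMS reference distributions, with obstructed
    participants' FEV1/FVC forced below its LLN and FEV1 derived as
    ratio × FVC.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    lms = lms_table if lms_table is not None else default_lms_table()
    coefs = {
        (row.parameter, row.sex): LmsCoefficients(row.parameter, row.sex, row.L, row.M, row.S)
        for row in lms.itertuples(index=False)
    }

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    sex = _draw_categories(rng, spec.category_probs["sex"], n)
    age_cat = _draw_categories(rng, spec.category_probs["age_category"], n)
    age = np.array([rng.uniform(*_AGE_RANGES[c]) for c in age_cat])
    diet = _draw_categories(rng, spec.category_probs["diet"], n)
    smoking = _draw_categories(rng, spec.category_probs["smoking"], n)
    bmi_cat = _draw_categories(rng, spec.category_probs["bmi_category"], n)
    bmi = np.array([rng.uniform(*_BMI_RANGES[c]) if c != "Unknown" else np.nan for c in bmi_cat])
    serology = _draw_categories(rng, spec.category_probs["serology"], n)
    height = np.where(sex == "Female", rng.normal(165.0, 7.0, n), rng.normal(178.0, 7.0, n))

    # health status: exact unhealthy count, split into reason triggers
    n_unhealthy = spec.n_unhealthy if spec.n_unhealthy is not None else round(n * UNHEALTHY_PROB)
    unhealthy_idx = rng.choice(n, size=n_unhealthy, replace=False)
    healthy = np.ones(n, dtype=bool)
    healthy[unhealthy_idx] = False
    respiratory = np.zeros(n, dtype=bool)
    general_bad = np.zeros(n, dtype=bool)
    other = np.zeros(n, dtype=bool)
    n_resp = round(n_unhealthy * RESPIRATORY_FRACTION)
    respiratory[unhealthy_idx[:n_resp]] = True
    rest = unhealthy_idx[n_resp:]
    general_bad[rest[: len(rest) // 2 + len(rest) % 2]] = True
    other[rest[len(rest) // 2 + len(rest) % 2 :]] = True

    # spirometry: LMS draws, obstructed participants forced below the ratio LLN
    spiro_missing = rng.uniform(size=n) < spec.spiro_missing_prob
    obstructed = (~spiro_missing) & (rng.uniform(size=n) < spec.obstruction_prob)
    z_ratio = np.where(
        obstructed,
        _truncated_normal(rng, n, -4.0, LLN_Z),
        _truncated_normal(rng, n, LLN_Z, 4.0),
    )
    z_fvc = _truncated_normal(rng, n, -4.0, 4.0)
    z_fef = _truncated_normal(rng, n, -4.0, 4.0)
    fvc = np.empty(n)
    ratio = np.empty(n)
    fef = np.empty(n)
    for s in np.unique(sex):
        m = sex == s
        fvc[m] = lms_percentile(coefs[("FVC", s)], z_fvc[m])
        ratio[m] = lms_percentile(coefs[("FEV1_FVC", s)], z_ratio[m])
        fef[m] = lms_percentile(coefs[("FEF2575", s)], z_fef[m])
    fev1 = ratio * fvc
    for arr in (fvc, fev1, fef):
        arr[spiro_missing] = np.nan
    obstructed[spiro_missing] = False

    # log-scale OPEA: truncated-normal base + planted outliers + additive effects
    base_z = _truncated_normal(rng, n, -spec.truncation_z, spec.truncation_z)
    opea = spec.healthy_opea_mean + spec.healthy_opea_sd * base_z
    is_outlier = np.zeros(n, dtype=bool)
    if spec.outlier_count > 0:
        healthy_idx = np.flatnonzero(healthy)
        chosen = rng.choice(healthy_idx, size=min(spec.outlier_count, healthy_idx.size), replace=False)
        signs = np.where(np.arange(chosen.size) % 2 == 0, 1.0, -1.0)
        opea[chosen] = spec.healthy_opea_mean + signs * 6.0 * spec.healthy_opea_sd
        is_outlier[chosen] = True
    # The healthy bulk emulates a reference sample whose only extreme values
    # are the planted ones: any non-planted healthy value falling outside the
    # sample's own Tukey fences (k = 1.5, computed as the outlier screen will
    # compute them) is redrawn.  Sample quartiles fluctuate enough at a few
    # hundred participants that a fixed truncation alone cannot guarantee this.
    h = healthy.copy()
    for _ in range(50 if h.sum() >= 4 else 0):
        q1, q3 = np.quantile(opea[h], [0.25, 0.75])
        iqr = q3 - q1
        stray = h & ~is_outlier & ((opea < q1 - 1.5 * iqr) | (opea > q3 + 1.5 * iqr))
        if not stray.any():
            break
        opea[stray] = spec.healthy_opea_mean + spec.healthy_opea_sd * _truncated_normal(
            rng, int(stray.sum()), -spec.truncation_z, spec.truncation_z
        )
    opea = opea + np.where(serology == "Positive", spec.serology_effect, 0.0)
    opea = opea + np.where(obstructed, spec.obstruction_effect, 0.0)

    cohort = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "diet": diet,
            "smoking": smoking,
            "respiratory_disease": respiratory,
            "general_health_bad": general_bad,
            "other_disease": other,
            "self_health": np.where(healthy, "Healthy", "Unhealthy"),
            "serology": serology,
            "height": height,
            "fev1": fev1,
            "fvc": fvc,
            "fef2575": fef,
            "opea": opea,
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "healthy": healthy,
            "seropositive": serology == "Positive",
            "obstructed": obstructed,
            "spiro_missing": spiro_missing,
            "is_outlier": is_outlier,
            "opea": opea,
        }
    )
    return cohort, truth


def default_lms_table() -> pd.DataFrame:
    """Synthetic placeholder LMS coefficients per parameter and sex.

    These are plausible adult magnitudes for exercising the LLN machinery;
    they are NOT clinical reference coefficients and must not be used to
    interpret real spirometry.
    """
    rows = [
        ("FEV1", "Female", 1.0, 3.2, 0.13),
        ("FEV1", "Male", 1.0, 4.2, 0.13),
        ("FVC", "Female", 0.9, 3.9, 0.13),
        ("FVC", "Male", 0.9, 5.2, 0.13),
        ("FEV1_FVC", "Female", 2.0, 0.82, 0.05),
        ("FEV1_FVC", "Male", 2.0, 0.80, 0.05),
        ("FEF2575", "Female", 0.7, 3.0, 0.25),
        ("FEF2575", "Male", 0.7, 3.9, 0.25),
    ]
    return pd.DataFrame(rows, columns=["parameter", "sex", "L", "M", "S"])


def write_fixtures(
    outdir: str | Path,
    spec: CohortSpec | None = None,
    trace_noise_sd: float = 0.002,
    ambient_op_mean: float = 2.0,
    ambient_op_sd: float = 0.3,
    cal: Calibration = DEFAULT_CALIBRATION,
) -> dict[str, Path]:
    """Write a deterministic, self-consistent fixture set for the pipeline.

    Produces ``cohort.csv`` (without the opea column — in the study the
    questionnaire table and the instrument data are separate sources),
    ``traces.txt`` with triplicate exhaled and ambient traces per participant
    whose slopes encode each participant's latent OPEA, ``pairing.json``,
    ``calibration.yaml``, ``lms.csv`` and ``truth.csv``.  Repeated runs with
    the same spec are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else CohortSpec()
    cohort, truth = gen_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    traces: list[KineticTrace] = []
    pairing: dict[str, dict[str, list[int]]] = {}
    next_id = 1
    for pid, opea in zip(cohort["participant_id"], truth["opea"]):
        ambient_op = max(float(rng.normal(ambient_op_mean, ambient_op_sd)), 0.5)
        exhaled_op = ambient_op * 10.0**opea
        seed_e, seed_a = rng.integers(0, 2**31, size=2)
        exh = gen_trace(
            TraceSpec(true_op=exhaled_op, cal=cal, noise_sd=trace_noise_sd),
            seed=int(seed_e),
            start_id=next_id,
            role="exhaled",
            participant_id=pid,
        )
        next_id += len(exh)
        amb = gen_trace(
            TraceSpec(true_op=ambient_op, cal=cal, noise_sd=trace_noise_sd),
            seed=int(seed_a),
            start_id=next_id,
            role="ambient",
            participant_id=pid,
        )
        next_id += len(amb)
        traces.extend(exh)
        traces.extend(amb)
        pairing[pid] = {
            "exhaled": [t.measurement_id for t in exh],
            "ambient": [t.measurement_id for t in amb],
        }

    paths = {
        "cohort": outdir / "cohort.csv",
        "traces": outdir / "traces.txt",
        "pairing": outdir / "pairing.json",
        "calibration": outdir / "calibration.yaml",
        "lms": outdir / "lms.csv",
        "truth": outdir / "truth.csv",
    }
    write_cohort(cohort.drop(columns=["opea"]), paths["cohort"])
    write_traces(traces, paths["traces"])
    with open(paths["pairing"], "w", encoding="utf-8") as fh:
        json.dump(pairing, fh, indent=1, sort_keys=True)
    write_calibration(cal, paths["calibration"])
    default_lms_table().to_csv(paths["lms"], index=False)
    write_cohort(truth, paths["truth"])
    return paths
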