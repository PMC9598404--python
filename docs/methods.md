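# Methods

This document specifies the statistical model behind each stage, the default
parameters with units and rationale, the design of the synthetic-data
generator, and the limitations of both.

## 1. From kinetic trace to oxidative potential

A measurement is a series of (time, absorption index) points on a 2 s grid
over 0–180 s. The oxidation rate is estimated by ordinary least squares of the
absorption index on time restricted to the **closed window [60, 150] s**
(46 points on the standard grid). The window endpoints are inclusive; the
early segment is excluded because the probe response has not stabilized, the
late segment because the reaction saturates.

- **Fit quality**: the coefficient of determination R² of the windowed fit
  must reach `r2_threshold` (default **0.95**) for the replicate to pass QC.
  A trace that is exactly constant in the window has zero residual and zero
  total variance; we define its R² as 1.0 (a perfect fit to a zero slope)
  rather than NaN, so that such traces are judged on their value, not dropped
  by a 0/0 artifact.
- **Calibration**: `value = gain · slope + intercept`, with `gain` in
  pmol · L⁻¹_air per s⁻¹ (must be positive) and `intercept` in pmol/L_air.
  Values below the limit of detection, or negative, are kept but logged; the
  downstream normalization raises on non-positive inputs, so they cannot
  silently propagate into a log.
- **Replicates**: per participant and air type, QC-passing replicates are
  pooled by the mean (median available as an option). If no replicate passes,
  a `ReplicateError` names the failing measurement ids.

## 2. Normalization

For each participant,

```
OPEA = log10(OP_exhaled / OP_ambient)
```

with both OP values in pmol H₂O₂-equivalents per litre of air; the ratio makes
OPEA dimensionless and cancels session-level instrument drift. With multiple
pooled values per side the default is the **ratio of means**; the mean of
per-replicate ratios is available as an option (the two differ under
replicate-level noise; the ratio of means weights replicates equally on the
linear scale). Non-positive OP on either side is a domain error naming the
failing side; participants whose normalization fails are retained in the
output table with a reason, so attrition is visible.

## 3. Spirometry lower limit of normal

Reference curves follow the LMS form: the p-th percentile of a parameter for
given covariates is

```
M · (1 + L·S·z_p)^(1/L)    (L ≠ 0)        M · exp(S·z_p)    (L = 0)
```

The **LLN** is the 5th percentile, `z = −1.6449`. A value is flagged if it is
**strictly below** the LLN; a value exactly at the limit is normal, so the
dichotomy is `<LLN` versus `≥LLN` with no middle case. The ratio FEV1/FVC is
derived from its components before lookup. Missing inputs yield missing flags
(`pandas` nullable boolean), never a silent False. A z-value with
`1 + L·S·z ≤ 0` is outside the LMS domain and raises.

## 4. Health classification and group comparisons

A participant is *unhealthy* if they declare a respiratory disease, or rate
their general health as bad; declaring any other disease can optionally also
exclude. Everyone else is *healthy*. Group comparisons of OPEA use:

- a **one-sided two-sample t-test** (pooled variance by default, Welch as an
  option) with the alternative "the abnormal group has higher mean OPEA" —
  one-sided because the biological hypothesis is directional (inflammation
  raises oxidant load);
- **one-way ANOVA** for variables with three or more levels;
- per-category mean with Student-t 95 % CI.

"Unknown" categories are shown in descriptive counts but excluded from tests.

## 5. Reference interval

Following the CLSI C28-A3 parametric approach:

1. restrict to the healthy subsample;
2. remove outliers **once** by Tukey fences: values strictly outside
   `[Q1 − k·IQR, Q3 + k·IQR]` with `k = 1.5` and **type-7** sample quantiles
   (the numpy/R default; the choice of quantile type moves the fences by a
   fraction of one observation spacing and is fixed for reproducibility);
   an iterative variant is available but off by default;
3. interval = `mean ± 1.96 · SD` (SD with ddof = 1);
4. **bootstrap smoothing**: draw `n_bootstrap` resamples (default **50**) with
   replacement, compute the limits on each; the reported limits are the means
   of the resample limits, and the 90 % CIs of the limits are the 5th/95th
   percentiles of the resample limits. 50 resamples keeps the smoothed limits
   within a fraction of the limit's own standard error of the plug-in value
   while staying cheap; for publication-grade CIs of the limits themselves,
   1000–2000 resamples are recommended (`n_bootstrap` is a parameter).

A reference sample below **120** (the usual nonparametric minimum) triggers a
warning, not an error.

Defaults at a glance:

| parameter | default | units | rationale |
|---|---|---|---|
| fit window | [60, 150] | s | stabilized, pre-saturation segment |
| `r2_threshold` | 0.95 | — | rejects non-linear / noisy traces |
| calibration gain | instrument-specific | pmol·L⁻¹ per s⁻¹ | from calibration file |
| LLN z | −1.6449 | — | 5th percentile of N(0,1) |
| Tukey `k` | 1.5 | IQR units | conventional fence multiplier |
| interval z | 1.96 | — | central 95 % under normality |
| `n_bootstrap` | 50 | resamples | smoothing; raise to ≥1000 for CI precision |
| minimum reference n | 120 | participants | CLSI guidance (warning only) |

## 6. Synthetic-data generator

`opea.simulate` produces cohorts and raw traces with known ground truth, for
testing and demonstration. It emulates:

- categorical covariates (sex, age class, BMI class, smoking, diet, serology,
  self-rated health, diseases) drawn from fixed marginal probabilities typical
  of an adult population survey, with the unhealthy count set **exactly**
  (`n_unhealthy`, default the expected proportion rounded) rather than
  binomially, so exclusion flows are reproducible;
- spirometry via the same LMS model used for flagging, with an "obstructed"
  subgroup forced below the FEV1/FVC LLN;
- healthy-participant OPEA as a truncated normal (±`truncation_z` = 2.5 SD)
  around `healthy_opea_mean` (default −0.028) with `healthy_opea_sd`
  (default 0.012);
- optional planted gross outliers at ±6 SD among the healthy;
- optional additive group effects: `serology_effect` (default +0.0657) for
  seropositive and `obstruction_effect` (default +0.1071) for obstructed
  participants;
- raw traces consistent with each participant's OP through the inverse of the
  calibration line, with i.i.d. Gaussian noise on the absorption index.

### Two spread regimes

The defaults expose two *mutually inconsistent* parameterizations on purpose,
because the two kinds of published summary they mimic are themselves
inconsistent:

- the **narrow regime** (`healthy_opea_sd = 0.012`) matches a reference
  interval whose width is ±1.96 × 0.012 ≈ ±0.024 around the mean;
- the **wide regime** (`healthy_opea_sd ≈ 0.21`) is what per-group means with
  CIs of several hundredths at n in the tens to hundreds imply for the
  *individual-level* SD.

Group effects of +0.0657 and +0.1071 are ≈ 5.5 and 9 narrow-regime SDs: under
the narrow regime every affected participant would be a Tukey outlier, which
is not a meaningful population. Consequently:

- reference-interval scenarios use the narrow regime with
  `serology_effect = obstruction_effect = 0`;
- group-comparison / power scenarios use the wide regime with the effects on.

Mixing effects into the narrow regime is allowed (the generator does not
police it) but produces the degenerate exclusion behaviour described above;
`examples/05_full_workflow.py` notes this.

### Exact outlier counts by rejection redraw

Tests and demonstrations need "exactly `outlier_count` values flagged by the
sample Tukey fences". Truncating the bulk at ±2.5 SD is not sufficient: at
n ≈ 220 the *sample* fences fluctuate by a substantial fraction of an SD, so a
bulk value occasionally strays outside them. After planting the outliers, the
generator therefore recomputes the sample fences on the healthy values and
**redraws** any non-planted value that falls outside, repeating (bounded at 50
iterations) until only planted values trip the fences. This guarantees the
flagged count by construction without narrowing the bulk distribution enough
to bias its SD. Group effects are added *after* this step, which is exactly
why the zero-effect configuration is the one with a guaranteed outlier count.

### What the generator does **not** emulate

- correlations between covariates (smoking × age, BMI × diet, …): all
  categoricals are drawn independently except health status;
- measurement-session structure (day, operator, device drift beyond what the
  ambient normalization models);
- realistic LMS coefficient tables — the built-in table
  (`default_lms_table()`) is a synthetic placeholder with plausible
  magnitudes, not a published reference equation, and must not be used for
  clinical interpretation;
- non-normal OPEA distributions (skew, heavy tails) or age trends in OPEA.

## 7. Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded explicitly;
independent streams are derived with `SeedSequence.spawn`, and derived seeds
stay below 2³¹. File writers emit fixed-precision text (`%.10g` for traces)
and the pipeline manifest records counts and parameters but no timestamps, so
identical inputs and seed give byte-identical outputs.

The test suite exercises cohorts up to n = 247 and Monte-Carlo checks up to
10⁵ simulated values / 10⁴ replicate simulations; `scripts/acceptance.py` uses
a 247-participant pipeline run plus two 10⁵-value empirical-coverage checks.

## 8. Limitations

- The parametric interval assumes normal OPEA in the reference sample; no
  normality test is run, and the nonparametric (percentile) interval is not
  implemented.
- One-pass Tukey removal (the default) depends on the initial quartiles;
  masked multiple outliers can survive it. The iterative option mitigates but
  does not solve masking.
- Pooled-variance t-tests assume equal group variances; use the Welch option
  when group sizes and spreads differ materially.
- The LLN dichotomy discards information near the limit; no probabilistic
  (z-score) analysis of spirometry is provided beyond the flag.
- The generator's independence assumptions (Section 6) make it unsuitable for
  studying confounding or adjustment strategies.
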