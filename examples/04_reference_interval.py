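"""Estimating the OPEA reference interval on the healthy subsample.

Reproduces the study flow on synthetic data: 247 participants, 26 excluded as
unhealthy, one Tukey-fence outlier removed, then mean ± 1.96 SD with
bootstrap-smoothed limits and 90% CIs from 50 resamples.
"""

from opea import run_reference_pipeline
from opea.simulate import CohortSpec, gen_cohort

spec = CohortSpec(
    n=247, n_unhealthy=26, outlier_count=1,
    serology_effect=0.0, obstruction_effect=0.0,  # exclusion-flow demo: no group shifts
    seed=42,
)
cohort, _ = gen_cohort(spec)
interval, outliers = run_reference_pipeline(cohort, k=1.5, n_bootstrap=50, seed=42)

print(f"participants            : {len(cohort)}")
print(f"healthy                 : {len(cohort)} - 26 unhealthy = 221")
print(f"outliers removed (Tukey): {interval.n_outliers_removed} {outliers.flagged_ids}")
print(f"reference sample        : {interval.n_reference}")
print(f"mean                    : {interval.mean:+.7f}")
print(f"standard deviation      : {interval.sd:.7f}")
print(f"lower limit             : {interval.lower:+.7f}  90% CI {tuple(round(x, 7) for x in interval.lower_ci90)}")
print(f"upper limit             : {interval.upper:+.7f}  90% CI {tuple(round(x, 7) for x in interval.upper_ci90)}")
print("\nThe interval brackets the central 95% of healthy log10 exhaled/ambient ratios;")
print("an individual's OPEA outside it is atypical for a healthy adult under these conditions.")
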