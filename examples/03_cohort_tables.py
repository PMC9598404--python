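"""Cohort description and OPEA group comparisons.

Generates a synthetic cohort with the published covariate frequencies and
group effects (seropositive +0.0657 and obstructive +0.1071 on the log10
scale), then tabulates category counts and per-characteristic OPEA means with
one-sided t / ANOVA p-values.
"""

from opea import add_health_status, flag_cohort, summarize_table2, table1_proportions
from opea.simulate import CohortSpec, default_lms_table, gen_cohort

cohort, _ = gen_cohort(CohortSpec(n=247, seed=42))
cohort = flag_cohort(cohort, default_lms_table())
cohort = add_health_status(cohort)

table1 = table1_proportions(cohort)
print("sample description (counts and % of 247):")
print(table1[table1["variable"].isin(["sex", "serology", "self_health"])].to_string(index=False))

print("\nOPEA by characteristic (mean, 95% CI, variable-level p):")
for s in summarize_table2(cohort):
    if s.variable in ("serology", "fev1_fvc", "self_health"):
        print(
            f"{s.variable:10s} {s.category:10s} n={s.n:3d} mean={s.mean:+.4f} "
            f"CI=({s.ci95[0]:+.4f}, {s.ci95[1]:+.4f}) p={s.p_value:.3g}"
        )

print(
    "\nSmall p-values for serology and FEV1/FVC reflect the generated effect shifts;"
    "\nthe one-sided alternative is a higher OPEA mean in the abnormal category."
)
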