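"""Health classification, group tests and the cohort summary tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from opea.simulate import CohortSpec, gen_cohort
from opea.stats import (
    add_health_status,
    anova,
    classify_health,
    mean_ci,
    one_sided_t_test,
    percent,
    summarize_table2,
    table1_proportions,
)


def pooled_t_oracle(reference, exposed):
    """One-sided pooled-t p-value straight from the Student-t CDF special function."""
    a, b = np.asarray(exposed, float), np.asarray(reference, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 1.0 - special.stdtr(n1 + n2 - 2, t)


class TestClassifyHealth:
    def test_respiratory_disease_triggers_unhealthy(self):
        hs = classify_health(declared_respiratory_disease=True)
        assert hs.status == "unhealthy"
        assert hs.reasons == ["respiratory_disease_declared"]

    def test_all_false_is_healthy(self):
        hs = classify_health()
        assert hs.status == "healthy"
        assert hs.reasons == []

    def test_bad_general_health_alone_is_unhealthy(self):
        hs = classify_health(general_health_bad=True)
        assert hs.status == "unhealthy"
        assert hs.reasons == ["general_health_bad"]

    def test_other_disease_trigger_is_configurable(self):
        assert classify_health(other_disease=True).status == "unhealthy"
        assert classify_health(other_disease=True, include_other=False).status == "healthy"

    def test_add_health_status_falls_back_to_label(self):
        df = pd.DataFrame({"participant_id": ["A", "B"], "self_health": ["Healthy", "Unhealthy"]})
        out = add_health_status(df)
        assert list(out["health_status"]) == ["healthy", "unhealthy"]


class TestOneSidedT:
    def test_identical_groups_give_half(self, rng):
        x = rng.normal(size=20)
        assert one_sided_t_test(x, x.copy()) == pytest.approx(0.5, abs=1e-12)

    def test_large_shift_is_highly_significant(self, rng):
        ref = rng.normal(0, 1, 50)
        exp = rng.normal(5, 1, 50)
        assert one_sided_t_test(ref, exp) < 1e-6

    def test_direction_is_exposed_greater(self, rng):
        ref = rng.normal(5, 1, 50)
        exp = rng.normal(0, 1, 50)
        assert one_sided_t_test(ref, exp) > 0.999

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_t_cdf_oracle_on_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        ref, exp = rng.normal(0, 1, 8), rng.normal(0.3, 1.2, 8)
        assert one_sided_t_test(ref, exp) == pytest.approx(pooled_t_oracle(ref, exp), abs=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        ref, exp = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        _, p_sm, _ = sm_ttest(exp, ref, alternative="larger", usevar="pooled")
        assert one_sided_t_test(ref, exp) == pytest.approx(p_sm, abs=1e-10)

    def test_complement_identity(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.2, 1, 11)
        assert one_sided_t_test(a, b) + one_sided_t_test(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_type_one_error_calibration(self):
        """Under the null the one-sided test at alpha=0.05 rejects about 5% of the time."""
        rng = np.random.default_rng(99)
        n, reps = 15, 2000
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        rejections = sum(one_sided_t_test(a[i], b[i]) < 0.05 for i in range(reps))
        assert rejections / reps == pytest.approx(0.05, abs=0.015)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError, match="exposed"):
            one_sided_t_test([1.0, 2.0], [1.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        p_anova = anova({"a": a, "b": b})
        # two-sided pooled t p-value equals the two-group ANOVA p-value
        p_two_sided = 2 * min(one_sided_t_test(a, b), one_sided_t_test(b, a))
        assert p_anova == pytest.approx(p_two_sided, abs=1e-10)

    def test_toy_table_against_sums_of_squares_oracle(self):
        groups = {
            "g1": np.array([1.0, 2.0, 3.0, 4.0]),
            "g2": np.array([2.0, 3.0, 4.0, 5.0]),
            "g3": np.array([5.0, 6.0, 7.0, 8.0]),
        }
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        df_b, df_w = len(groups) - 1, all_vals.size - len(groups)
        f = (ss_between / df_b) / (ss_within / df_w)
        p_oracle = special.fdtrc(df_b, df_w, f)
        assert anova(groups) == pytest.approx(p_oracle, abs=1e-10)

    def test_null_type_one_error(self):
        """Three equal-mean groups with jitter: ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(4)
        reps, n = 2000, 10
        from scipy.stats import f_oneway

        a, b, c = (rng.normal(size=(n, reps)) for _ in range(3))
        pvals = f_oneway(a, b, c, axis=0).pvalue
        assert np.mean(pvals < 0.05) == pytest.approx(0.05, abs=0.015)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            anova({"only": [1.0, 2.0]})


class TestTables:
    def test_percent_rounding(self):
        assert percent(51, 247) == 20.65
        assert percent(238, 247) == 96.36

    def test_table1_percentages_sum_to_100(self):
        cohort, _ = gen_cohort(CohortSpec(n=500, seed=8))
        table = table1_proportions(cohort)
        for var, grp in table.groupby("variable"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.02)
            assert grp["n"].sum() == 500

    def test_table1_all_one_category(self):
        df = pd.DataFrame({"participant_id": ["A", "B"], "sex": ["Female", "Female"]})
        table = table1_proportions(df, variables={"sex": (lambda d: d["sex"], "Male")})
        assert table.loc[0, "percent"] == 100.00

    def test_serology_effect_direction_in_summary(self):
        cohort, _ = gen_cohort(CohortSpec(n=247, seed=12))
        summaries = summarize_table2(add_health_status(cohort))
        by_cat = {s.category: s for s in summaries if s.variable == "serology"}
        assert by_cat["Positive"].mean > by_cat["Negative"].mean
        assert by_cat["Positive"].p_value < 0.05

    def test_single_category_variable_has_no_p(self):
        df = pd.DataFrame(
            {"participant_id": ["A", "B", "C"], "sex": ["Female"] * 3, "opea": [0.1, 0.2, 0.3]}
        )
        (s,) = summarize_table2(df, variables={"sex": (lambda d: d["sex"], "Male")})
        assert s.p_value is None
        assert s.n == 3

    def test_unknown_categories_excluded(self):
        df = pd.DataFrame(
            {
                "participant_id": list("ABCDEF"),
                "serology": ["Positive", "Positive", "Negative", "Negative", "Unknown", "Unknown"],
                "opea": [0.2, 0.3, 0.0, 0.1, 9.0, 9.0],
            }
        )
        summaries = summarize_table2(df, variables={"serology": (lambda d: d["serology"], "Positive")})
        cats = {s.category for s in summaries}
        assert cats == {"Positive", "Negative"}

    def test_ci_brackets_mean(self, rng):
        vals = rng.normal(size=40)
        m, (lo, hi) = mean_ci(vals)
        assert lo <= m <= hi

    def test_power_at_published_group_structure(self):
        """With the published group means and individual-level spread, the
        seropositive-vs-seronegative test rejects in a majority of replicates."""
        rng = np.random.default_rng(21)
        reps, rejections = 1000, 0
        for _ in range(reps):
            neg = rng.normal(-0.0561, 0.21, 173)
            pos = rng.normal(0.0096, 0.21, 51)
            rejections += one_sided_t_test(neg, pos) < 0.05
        assert rejections / reps > 0.5
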