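"""Reference-sample selection, Tukey screening, plug-in and bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest

from opea.reference import (
    bootstrap_interval,
    estimate_interval,
    run_reference_pipeline,
    select_reference_sample,
    tukey_outliers,
)
from opea.simulate import CohortSpec, gen_cohort

# published summary statistics of the healthy-adult OPEA distribution
PUB_MEAN, PUB_SD = -0.0280414, 0.0120425
PUB_LOWER, PUB_UPPER = -0.0516443, -0.0044385


def effect_free_spec(**kw):
    return CohortSpec(serology_effect=0.0, obstruction_effect=0.0, **kw)


class TestSelectReferenceSample:
    def test_study_flow_counts(self):
        cohort, _ = gen_cohort(effect_free_spec(n=247, n_unhealthy=26, seed=1))
        values, ids = select_reference_sample(cohort)
        assert values.size == 221
        assert len(ids) == 221

    def test_all_healthy_is_identity(self):
        cohort, _ = gen_cohort(effect_free_spec(n=50, n_unhealthy=0, outlier_count=0, seed=2))
        values, ids = select_reference_sample(cohort)
        assert values.size == 50

    def test_retained_ids_equal_healthy_set(self):
        cohort, truth = gen_cohort(effect_free_spec(n=100, seed=3))
        _, ids = select_reference_sample(cohort)
        expected = set(truth.loc[truth["healthy"], "participant_id"])
        assert set(ids) == expected

    def test_empty_reference_raises(self):
        df = pd.DataFrame(
            {"participant_id": ["A"], "self_health": ["Unhealthy"], "opea": [0.1]}
        )
        with pytest.raises(ValueError, match="healthy"):
            select_reference_sample(df)


class TestTukeyOutliers:
    def test_hand_computed_example(self):
        # sorted [1,2,3,4,100]: type-7 quartiles Q1=2, Q3=4, IQR=2, fences (-1, 7)
        report = tukey_outliers([1, 2, 3, 4, 100], k=1.5)
        assert report.fences == (-1.0, 7.0)
        assert report.flagged_ids == [4]
        assert report.n_flagged == 1

    def test_constant_vector_has_no_outliers(self):
        report = tukey_outliers([2.0] * 10)
        assert report.n_flagged == 0
        assert report.fences == (2.0, 2.0)

    def test_fences_symmetric_for_symmetric_data(self):
        data = np.concatenate([-np.arange(1, 50), np.arange(1, 50)])
        report = tukey_outliers(data)
        median = np.median(data)
        assert report.fences[1] - median == pytest.approx(median - report.fences[0], abs=1e-12)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            tukey_outliers([1.0, 2.0, 3.0])

    def test_ids_are_reported(self):
        report = tukey_outliers([1, 2, 3, 4, 100], ids=["a", "b", "c", "d", "e"])
        assert report.flagged_ids == ["e"]


class TestEstimateInterval:
    def test_published_two_moment_summary(self):
        # two points reproducing the published mean and SD exactly
        values = [PUB_MEAN - PUB_SD / np.sqrt(2), PUB_MEAN + PUB_SD / np.sqrt(2)]
        ri = estimate_interval(values)
        assert ri.mean == pytest.approx(PUB_MEAN, abs=1e-12)
        assert ri.sd == pytest.approx(PUB_SD, abs=1e-12)
        assert ri.lower == pytest.approx(PUB_LOWER, abs=1e-4)
        assert ri.upper == pytest.approx(PUB_UPPER, abs=1e-4)

    def test_plug_in_identity(self, rng):
        ri = estimate_interval(rng.normal(size=100))
        assert ri.lower == pytest.approx(ri.mean - 1.96 * ri.sd, abs=1e-12)
        assert ri.upper == pytest.approx(ri.mean + 1.96 * ri.sd, abs=1e-12)

    def test_constant_data_collapses(self):
        ri = estimate_interval([3.0, 3.0, 3.0])
        assert ri.lower == ri.upper == ri.mean == 3.0

    def test_toy_vector_against_hand_moments(self):
        vals = [1.0, 2.0, 3.0, 4.0, 10.0]
        ri = estimate_interval(vals)
        assert ri.mean == pytest.approx(4.0, abs=1e-12)
        # sum of squared deviations = 9+4+1+0+36 = 50; sd = sqrt(50/4)
        assert ri.sd == pytest.approx(np.sqrt(12.5), abs=1e-12)


class TestBootstrapInterval:
    def test_constant_data_zero_width(self):
        ri = bootstrap_interval([5.0] * 30, n_bootstrap=20, seed=1)
        assert ri.lower == ri.upper == 5.0
        assert ri.lower_ci90 == (5.0, 5.0)

    def test_fixed_seed_is_bit_identical(self, rng):
        data = rng.normal(size=80)
        a = bootstrap_interval(data, n_bootstrap=50, seed=42)
        b = bootstrap_interval(data, n_bootstrap=50, seed=42)
        assert (a.lower, a.upper, a.lower_ci90, a.upper_ci90) == (
            b.lower,
            b.upper,
            b.lower_ci90,
            b.upper_ci90,
        )

    def test_ci_brackets_smoothed_limit(self, rng):
        data = rng.normal(size=150)
        ri = bootstrap_interval(data, n_bootstrap=200, seed=0)
        assert ri.lower_ci90[0] <= ri.lower <= ri.lower_ci90[1]
        assert ri.upper_ci90[0] <= ri.upper <= ri.upper_ci90[1]

    def test_large_sample_consistency(self):
        """Smoothed lower limit converges to the analytic mean − 1.96·sd."""
        rng = np.random.default_rng(31)
        data = rng.normal(PUB_MEAN, 0.012, 5000)
        ri = bootstrap_interval(data, n_bootstrap=500, seed=9)
        assert ri.lower == pytest.approx(PUB_MEAN - 1.96 * 0.012, abs=0.001)

    def test_smoothing_stabilizes_with_more_resamples(self, rng):
        data = rng.normal(size=200)
        spread = {}
        for n_boot in (25, 400):
            lowers = [bootstrap_interval(data, n_bootstrap=n_boot, seed=s).lower for s in range(12)]
            spread[n_boot] = np.std(lowers)
        assert spread[400] < spread[25]


class TestPipeline:
    def test_study_flow_247_to_220(self):
        cohort, truth = gen_cohort(effect_free_spec(n=247, n_unhealthy=26, outlier_count=1, seed=5))
        interval, report = run_reference_pipeline(cohort, seed=5)
        assert interval.n_reference == 220
        assert interval.n_outliers_removed == 1
        assert report.flagged_ids == list(truth.loc[truth["is_outlier"], "participant_id"])

    def test_no_planted_outliers_none_removed(self):
        cohort, _ = gen_cohort(effect_free_spec(n=247, outlier_count=0, seed=6))
        interval, _ = run_reference_pipeline(cohort, seed=6)
        assert interval.n_outliers_removed == 0

    def test_equals_manual_composition(self):
        cohort, _ = gen_cohort(effect_free_spec(n=200, seed=7))
        interval, _ = run_reference_pipeline(cohort, seed=7, n_bootstrap=50)
        values, ids = select_reference_sample(cohort)
        report = tukey_outliers(values, k=1.5, ids=ids)
        keep = np.array([i not in set(report.flagged_ids) for i in ids])
        manual = bootstrap_interval(values[keep], n_bootstrap=50, seed=7)
        assert interval.lower == manual.lower
        assert interval.upper == manual.upper
        assert interval.mean == manual.mean

    def test_outlier_screen_nearly_idempotent(self):
        """A second Tukey pass on the retained values flags at most one point."""
        cohort, _ = gen_cohort(effect_free_spec(n=247, seed=8))
        values, ids = select_reference_sample(cohort)
        first = tukey_outliers(values, ids=ids)
        keep = np.array([i not in set(first.flagged_ids) for i in ids])
        second = tukey_outliers(values[keep])
        assert second.n_flagged <= 1
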