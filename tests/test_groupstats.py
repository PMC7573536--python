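"""Group-level statistics: profile correlations, Fisher z, outliers, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcnf.groupstats import (
    DEFAULT_OUTLIER_THRESHOLD,
    correlate_measures,
    fisher_compare,
    group_profile,
    mahalanobis_bootstrap_outliers,
    one_sample_t,
    paired_t,
    profile_vs_count,
)


def toy_profile(mean_fc, counts):
    return pd.DataFrame(
        {
            "condition": ["fcnf"] * len(mean_fc),
            "position": range(1, len(mean_fc) + 1),
            "mean_fc": mean_fc,
            "n_negative": [0] * len(mean_fc),
            "mean_n_fcnf": counts,
        }
    )


class TestProfileVsCount:
    def test_textbook_pearson_on_toy_profile(self):
        # six points with a hand-computable Pearson r
        prof = toy_profile([0.4, 0.3, 0.25, 0.15, 0.1, 0.0], [1, 2, 3, 4, 5, 6])
        res = profile_vs_count(prof)
        expected, p = stats.pearsonr([1, 2, 3, 4, 5, 6], [0.4, 0.3, 0.25, 0.15, 0.1, 0.0])
        assert res.r == pytest.approx(float(expected), abs=1e-12)
        assert res.p == pytest.approx(float(p), abs=1e-12)
        assert res.n == 6

    def test_constant_profile_flagged_zero_variance(self):
        res = profile_vs_count(toy_profile([0.2] * 6, [1, 2, 3, 4, 5, 6]))
        assert res.zero_variance and np.isnan(res.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="three profile points"):
            profile_vs_count(toy_profile([0.1, 0.2], [1, 2]))

    def test_responsive_cohort_sign_pattern(self, exp12_schedule, weighted_config):
        # delta_response < 0: mean fc falls (negative r) and negative-fc
        # frequency rises (positive r) with the feedback-volume count
        from fcnf.pipeline import compute_cohort_metrics, compute_cohort_streams
        from fcnf.simulate import CohortParams, simulate_cohort

        signs = []
        for seed in range(10):
            cohort = simulate_cohort(
                CohortParams(n_subjects=6, seed=seed), exp12_schedule, n_runs=2
            )
            streams = compute_cohort_streams(cohort, weighted_config)
            _, profiles = compute_cohort_metrics(streams)
            gp = group_profile(profiles)
            signs.append(
                (
                    profile_vs_count(gp, "mean_fc").r < 0,
                    profile_vs_count(gp, "n_negative").r > 0,
                )
            )
        ok = [a and b for a, b in signs]
        assert sum(ok) >= 9


class TestFisherCompare:
    def test_equal_correlations_give_zero_statistic(self):
        stat, p = fisher_compare(0.4, 50, 0.4, 80)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_opposite_implementations_differ_strongly(self):
        # the weighted-negative vs negative profile correlations at n = 40
        stat, p = fisher_compare(-0.72, 40, 0.37, 40)
        assert p < 0.001

    def test_closed_form_statistic(self):
        stat, p = fisher_compare(0.5, 103, 0.3, 103)
        assert stat == pytest.approx(1.6955468856385014, abs=1e-12)
        assert p == pytest.approx(0.08997172386784993, abs=1e-12)

    def test_antisymmetric_in_arguments(self):
        a, pa = fisher_compare(0.6, 30, -0.2, 45)
        b, pb = fisher_compare(-0.2, 45, 0.6, 30)
        assert a == pytest.approx(-b)
        assert pa == pytest.approx(pb)

    def test_t_variant_close_to_z_at_moderate_n(self):
        z_stat, z_p = fisher_compare(0.5, 40, 0.3, 40, variant="z")
        t_stat, t_p = fisher_compare(0.5, 40, 0.3, 40, variant="t")
        assert t_stat == pytest.approx(z_stat)
        assert t_p == pytest.approx(z_p, rel=0.05)
        # the paper-scale decision is insensitive to the variant
        assert fisher_compare(-0.72, 40, 0.37, 40, variant="t")[1] < 0.001

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="transform undefined"):
            fisher_compare(1.0, 40, 0.3, 40)


class TestMahalanobisBootstrap:
    def test_gross_outlier_flagged_alone(self):
        # a tight cluster (no point near the chi-square cutoff) plus one
        # point ~10 SDs away: only the far point exceeds the threshold
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, size=(30, 2)), [[10.0, 10.0]]])
        flags = mahalanobis_bootstrap_outliers(pts, B=300, seed=1)
        assert flags[-1]
        assert flags[:-1].sum() == 0

    def test_identical_points_rejected(self):
        pts = np.ones((10, 2))
        with pytest.raises(ValueError, match="singular covariance"):
            mahalanobis_bootstrap_outliers(pts, B=200, seed=1)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(40, 2))
        a = mahalanobis_bootstrap_outliers(pts, B=200, seed=9)
        b = mahalanobis_bootstrap_outliers(pts, B=200, seed=9)
        assert (a == b).all()

    def test_affine_invariance_of_flags(self, rng):
        pts = rng.normal(size=(50, 2))
        A = np.array([[2.0, 0.5], [-0.3, 1.5]])
        transformed = pts @ A.T + np.array([10.0, -4.0])
        a = mahalanobis_bootstrap_outliers(pts, B=300, seed=5)
        b = mahalanobis_bootstrap_outliers(transformed, B=300, seed=5)
        assert (a == b).all()

    def test_null_flag_rate_near_nominal(self, rng):
        # chi-square(2) 0.975 cutoff: ~2.5% of clean Gaussian points flagged
        flagged = total = 0
        for rep in range(10):
            pts = rng.normal(size=(200, 2))
            flags = mahalanobis_bootstrap_outliers(pts, B=300, seed=rep)
            flagged += flags.sum()
            total += len(flags)
        rate = flagged / total
        se = np.sqrt(0.025 * 0.975 / total)
        assert abs(rate - 0.025) < 3 * se


class TestCorrelateMeasures:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = correlate_measures(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_hand_computed_toy_pairs(self):
        x = [1.0, 2.0, 4.0, 5.0, 7.0]
        y = [2.0, 1.0, 5.0, 4.0, 8.0]
        expected, p = stats.pearsonr(x, y)
        res = correlate_measures(x, y)
        assert res.r == pytest.approx(float(expected), abs=1e-12)

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        res = correlate_measures(x, y)
        assert res.n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete pairs"):
            correlate_measures([1.0, np.nan], [1.0, 2.0])

    def test_no_flagged_points_equals_plain_result(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30) * 0.5
        plain = correlate_measures(x, y)
        robust = correlate_measures(x, y, remove_outliers=True, B=200, seed=2)
        if robust.outliers.size == 0:
            assert robust.r_after_removal == pytest.approx(plain.r)

    def test_outlier_removal_restores_relation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30) * 0.2
        x = np.append(x, 4.0)
        y = np.append(y, -6.0)  # one point against the trend
        res = correlate_measures(x, y, remove_outliers=True, B=300, seed=3)
        assert res.outliers.size >= 1
        assert res.r_after_removal > res.r

    def test_null_p_values_uniform(self):
        # rejection rate at alpha = 0.05 within 3 MC SEs of 5%
        rng = np.random.default_rng(808)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            res = correlate_measures(rng.normal(size=25), rng.normal(size=25))
            rejections += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se

    def test_cohort_trait_link_recovered(self, exp12_schedule, weighted_config):
        # positive trait-anxiety -> baseline-coupling link shows up as a
        # positive initial-fc correlation at n = 200
        from fcnf.pipeline import compute_cohort_metrics, compute_cohort_streams
        from fcnf.simulate import CohortParams, simulate_cohort

        cohort = simulate_cohort(
            CohortParams(n_subjects=200, seed=31), exp12_schedule, n_runs=2
        )
        streams = compute_cohort_streams(cohort, weighted_config)
        metrics, _ = compute_cohort_metrics(streams)
        merged = metrics.merge(cohort.covariates, on="subject")
        res = correlate_measures(merged["initial_fc"], merged["stai_t"])
        assert res.r > 0
        assert res.p < 0.05


class TestTTests:
    def test_identical_samples(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_closed_form_paired_t(self):
        # differences (1, 2, 3): t = mean/ (sd/sqrt(3)) = 2*sqrt(3)
        t, df, p = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_one_sample_centered_data(self):
        t, df, p = one_sample_t([4.0, 5.0, 6.0], mu0=5.0)
        assert t == pytest.approx(0.0)
        assert df == 2


def test_group_profile_weights_subjects_equally():
    profiles = pd.DataFrame(
        {
            "subject": ["a", "a", "b", "b"],
            "condition": ["fcnf", "fcnf", "fcnf", "fcnf"],
            "position": [1, 2, 1, 2],
            "mean_fc": [0.2, 0.4, 0.6, 0.0],
            "n_negative": [0, 1, 2, 3],
            "n_contributing": [7, 7, 14, 14],
            "mean_n_fcnf": [1.0, 2.0, 1.0, 2.0],
        }
    )
    gp = group_profile(profiles)
    assert gp["mean_fc"].tolist() == pytest.approx([0.4, 0.2])
    assert gp["n_subjects"].tolist() == [2, 2]
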