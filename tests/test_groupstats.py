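"""Sample-side estimators: group stats, decomposition, combination, bias."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolcorr import (
    InvalidParameterError,
    PairedSampleGroup,
    argmax_pearson_bias,
    compute_group_stats,
    correlation_bias_metric,
    estimate_pooled_decomposition,
    hunter_schmidt_average,
    pearson_expected_bias,
    pooled_pearson,
    residual_error_profile,
)
from poolcorr.groupstats import between_group_covariance, stats_from_groups


def _group(xs, ys, label=""):
    return PairedSampleGroup(np.asarray(xs, float), np.asarray(ys, float), label)


WORKED_A = _group([0, 1, 2], [0, 1, 2], "A")
WORKED_B = _group([4, 5, 6], [6, 5, 4], "B")


def _random_grouped_data(rng, min_n=3):
    n_groups = rng.integers(1, 6)
    groups = []
    for _ in range(n_groups):
        n = int(rng.integers(min_n, 30))
        groups.append(_group(rng.normal(0, 2, n) + rng.normal(0, 3), rng.normal(1, 1.5, n)))
    return groups


class TestComputeGroupStats:
    def test_ml_convention_hand_values(self):
        s = compute_group_stats(_group([0, 1, 2], [0, 1, 2]), "ml")
        assert (s.mean_x, s.mean_y) == (1.0, 1.0)
        assert s.var_x == pytest.approx(2 / 3)
        assert s.cov_xy == pytest.approx(2 / 3)

    def test_unbiased_convention_hand_values(self):
        s = compute_group_stats(_group([0, 1, 2], [0, 1, 2]), "unbiased")
        assert s.var_x == pytest.approx(1.0)
        assert s.cov_xy == pytest.approx(1.0)

    def test_constant_axis(self):
        s = compute_group_stats(_group([3, 3, 3], [0, 1, 2]))
        assert s.var_x == 0.0 and s.cov_xy == 0.0

    def test_too_few_observations(self):
        with pytest.raises(InvalidParameterError):
            _group([1.0], [2.0])


class TestPooledPearson:
    def test_worked_example(self):
        assert pooled_pearson([WORKED_A, WORKED_B]) == pytest.approx(24 / 28, rel=1e-12)

    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert pooled_pearson([_group(x, 2 * x + 1)]) == pytest.approx(1.0)

    def test_symmetry(self):
        r1 = pooled_pearson([WORKED_A, WORKED_B])
        r2 = pooled_pearson(
            [_group(g.values_y, g.values_x) for g in (WORKED_A, WORKED_B)]
        )
        assert r1 == pytest.approx(r2, rel=1e-14)


class TestPooledDecomposition:
    def test_single_group_reduces_to_within_correlation(self):
        g = _group([0, 1, 2, 4], [1, 0, 3, 5])
        est = estimate_pooled_decomposition([compute_group_stats(g, "ml")])
        assert est.mean_diff_term == 0.0
        assert est.tau_hat == pytest.approx(pooled_pearson([g]), rel=1e-12)

    def test_worked_example_ml_identity(self):
        stats = stats_from_groups([WORKED_A, WORKED_B], "ml")
        est = estimate_pooled_decomposition(stats)
        assert est.cov_term == pytest.approx(0.0, abs=1e-14)
        assert est.mean_diff_term == pytest.approx(4.0, rel=1e-12)
        assert est.d_x**2 == pytest.approx(14 / 3, rel=1e-12)
        assert est.tau_hat == pytest.approx(6 / 7, rel=1e-12)
        assert est.tau_hat == pytest.approx(pooled_pearson([WORKED_A, WORKED_B]), rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_ml_identity_on_random_grouped_data(self, seed):
        """Law of total covariance: tau_hat (ml) == pooled Pearson exactly."""
        rng = np.random.default_rng(seed)
        groups = _random_grouped_data(rng)
        est = estimate_pooled_decomposition(stats_from_groups(groups, "ml"))
        assert est.tau_hat == pytest.approx(pooled_pearson(groups), rel=1e-12, abs=1e-12)
        assert abs(est.tau_hat) <= 1 + 1e-12

    def test_unbiased_gap_small_for_large_groups(self):
        rng = np.random.default_rng(5)
        groups = [
            _group(rng.normal(i, 1, 150), rng.normal(-i, 2, 150)) for i in range(4)
        ]
        est = estimate_pooled_decomposition(stats_from_groups(groups, "unbiased"))
        assert abs(est.tau_hat - pooled_pearson(groups)) < 0.01

    def test_dxy_equals_between_group_covariance(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            groups = _random_grouped_data(rng)
            stats = stats_from_groups(groups, "ml")
            est = estimate_pooled_decomposition(stats)
            bg = between_group_covariance(
                [s.mean_x for s in stats], [s.mean_y for s in stats], [s.n for s in stats]
            )
            assert est.mean_diff_term == pytest.approx(bg, rel=1e-12, abs=1e-12)

    def test_percent_contributions(self):
        stats = stats_from_groups([WORKED_A, WORKED_B], "ml")
        est = estimate_pooled_decomposition(stats)
        assert est.cov_pct + est.mean_pct == pytest.approx(1.0, rel=1e-12)
        ref = estimate_pooled_decomposition(stats, reference_r=0.5)
        assert ref.mean_pct == pytest.approx(est.mean_diff_term / (0.5 * est.d_x * est.d_y))

    def test_mixed_conventions_rejected(self):
        stats = [
            compute_group_stats(WORKED_A, "ml"),
            compute_group_stats(WORKED_B, "unbiased"),
        ]
        with pytest.raises(InvalidParameterError):
            estimate_pooled_decomposition(stats)


class TestHunterSchmidt:
    def test_equal_correlations(self):
        assert hunter_schmidt_average([0.4, 0.4, 0.4], [5, 9, 2]) == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "r, n, expected", [(((1, -1)), (3, 3), 0.0), ((0.8, 0.4), (30, 10), 0.7)]
    )
    def test_hand_values(self, r, n, expected):
        assert hunter_schmidt_average(r, n) == pytest.approx(expected, rel=1e-12)

    def test_size_rescaling_invariance(self):
        r = [0.2, -0.5, 0.9]
        assert hunter_schmidt_average(r, [2, 4, 6]) == pytest.approx(
            hunter_schmidt_average(r, [20, 40, 60]), rel=1e-14
        )

    def test_nan_groups_excluded_with_renormalization(self):
        assert hunter_schmidt_average([0.5, math.nan], [10, 10]) == pytest.approx(0.5)


class TestBiasMetric:
    def test_zero_when_pooled_matches_all(self):
        assert correlation_bias_metric(0.3, [0.3, 0.3], [4, 6]).value == 0.0

    def test_hand_value_weighted_msd(self):
        b = correlation_bias_metric(6 / 7, [1.0, -1.0], [5, 5])
        expected = 0.5 * (6 / 7 - 1) ** 2 + 0.5 * (6 / 7 + 1) ** 2
        assert b.value == pytest.approx(expected, rel=1e-12)

    def test_as_printed_divides_by_group_count(self):
        w = correlation_bias_metric(6 / 7, [1.0, -1.0], [5, 5], "weighted_msd")
        p = correlation_bias_metric(6 / 7, [1.0, -1.0], [5, 5], "as_printed")
        assert p.value == pytest.approx(w.value / 2, rel=1e-12)

    def test_minimized_at_hunter_schmidt_average(self):
        # rbar minimizes the weighted MSD: B(rbar) <= B(anything else)
        rng = np.random.default_rng(11)
        r = rng.uniform(-1, 1, 7)
        n = rng.integers(2, 30, 7)
        rbar = hunter_schmidt_average(r, n)
        b_rbar = correlation_bias_metric(rbar, r, n).value
        for other in rng.uniform(-1, 1, 10):
            assert b_rbar <= correlation_bias_metric(float(other), r, n).value + 1e-15


class TestPearsonBias:
    def test_hand_values(self):
        assert pearson_expected_bias(0.0, 10) == 0.0
        assert pearson_expected_bias(0.5, 10) == pytest.approx(0.01875)
        assert pearson_expected_bias(-0.5, 10) == pytest.approx(-0.01875)

    def test_argmax_closed_form_and_grid_oracle(self):
        assert argmax_pearson_bias() == pytest.approx(1 / math.sqrt(3), rel=1e-12)
        assert round(argmax_pearson_bias(), 2) == 0.58
        grid = np.arange(0, 1, 1e-5)
        best = grid[np.argmax(grid * (1 - grid**2))]
        assert abs(best - argmax_pearson_bias()) < 1e-4


class TestResidualErrorProfile:
    def test_zero_residuals(self):
        p = residual_error_profile([0.1, -0.4, 0.9], [0.1, -0.4, 0.9])
        assert np.all(p.residuals == 0) and not p.bimodal

    def test_bias_shaped_residuals_are_bimodal(self):
        # r = tau + rho(1-rho^2)/(2n): the small-sample bias signature
        tau = np.linspace(-0.95, 0.95, 101)
        r = tau + np.array([pearson_expected_bias(t, 10) for t in tau])
        p = residual_error_profile(r, tau)
        assert p.bimodal
        assert p.mean_negative < 0 < p.mean_positive
        # squared residuals shrink toward the extremes of |r|
        extreme = np.abs(r) > 0.9
        mid = (np.abs(r) > 0.4) & (np.abs(r) < 0.7)
        assert p.squared_residuals[extreme].mean() < p.squared_residuals[mid].mean()
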