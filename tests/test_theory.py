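"""Population-level pooled-correlation limit and its closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolcorr import (
    GroupParams,
    GroupParamsSet,
    InvalidParameterError,
    UndefinedCorrelationError,
    asymptotic_pooled_correlation,
    asymptotic_pooled_correlation_common_means,
    closed_form_heteroskedastic,
    closed_form_mean_shift,
    closed_form_simpson,
    pair_distance_sum,
)
from poolcorr.simulate import build_group_params


def _random_params_set(rng, n_groups=None):
    """Random valid parameter sets for property tests."""
    N = n_groups or rng.integers(1, 8)
    groups = []
    for _ in range(N):
        sx, sy = rng.uniform(0.2, 3.0, size=2)
        rho = rng.uniform(-0.95, 0.95)
        groups.append(
            GroupParams(
                mean_x=rng.normal(0, 3),
                mean_y=rng.normal(0, 3),
                var_x=sx**2,
                var_y=sy**2,
                cov_xy=rho * sx * sy,
                size=int(rng.integers(1, 50)),
            )
        )
    return GroupParamsSet(groups)


class TestAsymptoticPooledCorrelation:
    def test_homogeneous_pool_recovers_common_correlation(self):
        groups = [GroupParams(1.0, -2.0, 1.0, 1.0, 0.5, 10) for _ in range(5)]
        dec = asymptotic_pooled_correlation(GroupParamsSet(groups))
        assert dec.tau == pytest.approx(0.5, abs=1e-12)
        assert dec.mean_diff_term == pytest.approx(0.0, abs=1e-12)

    def test_two_shifted_groups_hand_value(self):
        # means (0,0) and (2,2), unit variances, zero covariance, equal weights:
        # cov term 0, mean-diff term 0.25*2*2 = 1, delta_x = delta_y = sqrt(2)
        groups = GroupParamsSet(
            [GroupParams(0, 0, 1, 1, 0, 5), GroupParams(2, 2, 1, 1, 0, 5)]
        )
        dec = asymptotic_pooled_correlation(groups)
        assert dec.cov_term == pytest.approx(0.0, abs=1e-15)
        assert dec.mean_diff_term == pytest.approx(1.0, rel=1e-12)
        assert dec.delta_x == pytest.approx(math.sqrt(2), rel=1e-12)
        assert dec.tau == pytest.approx(0.5, rel=1e-12)

    def test_two_shifted_groups_monte_carlo_oracle(self):
        # pooled Pearson r on 1e6 draws per group approximates the limit
        rng = np.random.default_rng(42)
        n = 10**6
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5, abs=5e-3)

    def test_mean_shift_alpha_two_is_near_zero(self):
        dec = asymptotic_pooled_correlation(build_group_params("mean_shift", alpha=2.0, N=10))
        assert abs(dec.tau) < 0.03

    def test_identity_tau_times_deltas_equals_terms(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            groups = _random_params_set(rng)
            dec = asymptotic_pooled_correlation(groups)
            lhs = dec.tau * dec.delta_x * dec.delta_y
            assert lhs == pytest.approx(dec.cov_term + dec.mean_diff_term, rel=1e-10, abs=1e-12)
            assert abs(dec.tau) <= 1 + 1e-12

    def test_symmetric_under_axis_swap(self):
        rng = np.random.default_rng(8)
        groups = _random_params_set(rng, n_groups=5)
        a = asymptotic_pooled_correlation(groups)
        b = asymptotic_pooled_correlation(groups.swapped())
        assert a.tau == pytest.approx(b.tau, rel=1e-12)

    def test_degenerate_deltas_raise(self):
        groups = GroupParamsSet([GroupParams(1, 1, 0, 0, 0, 5), GroupParams(1, 1, 0, 0, 0, 5)])
        with pytest.raises(UndefinedCorrelationError):
            asymptotic_pooled_correlation(groups)

    def test_cauchy_schwarz_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            GroupParams(0, 0, 1.0, 1.0, 1.5, 5)

    @given(st.floats(-5, 5), st.integers(1, 6), st.data())
    @settings(max_examples=60, deadline=None)
    def test_location_invariance(self, shift, n_groups, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        groups = _random_params_set(np.random.default_rng(seed), n_groups)
        shifted = GroupParamsSet(
            [
                GroupParams(g.mean_x + shift, g.mean_y, g.var_x, g.var_y, g.cov_xy, g.size)
                for g in groups
            ]
        )
        assert asymptotic_pooled_correlation(shifted).tau == pytest.approx(
            asymptotic_pooled_correlation(groups).tau, rel=1e-9, abs=1e-9
        )

    @given(st.floats(0.1, 4).filter(lambda c: abs(c) > 1e-3), st.booleans(), st.data())
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, c, negate, data):
        c = -c if negate else c
        seed = data.draw(st.integers(0, 2**31 - 1))
        groups = _random_params_set(np.random.default_rng(seed), 4)
        scaled = GroupParamsSet(
            [
                GroupParams(c * g.mean_x, g.mean_y, c * c * g.var_x, g.var_y, c * g.cov_xy, g.size)
                for g in groups
            ]
        )
        expected = math.copysign(1, c) * asymptotic_pooled_correlation(groups).tau
        assert asymptotic_pooled_correlation(scaled).tau == pytest.approx(
            expected, rel=1e-9, abs=1e-9
        )


class TestCommonMeansSpecialCase:
    def test_zero_covariances_give_zero(self):
        groups = GroupParamsSet(
            [GroupParams(2, 2, float(i * i), float((5 - i) ** 2), 0.0, 10) for i in range(1, 5)]
        )
        assert asymptotic_pooled_correlation_common_means(groups) == pytest.approx(0.0, abs=1e-15)

    def test_single_group_recovers_within_correlation(self):
        g = GroupParams(3, 3, 4.0, 9.0, 3.0, 10)
        assert asymptotic_pooled_correlation_common_means(
            GroupParamsSet([g])
        ) == pytest.approx(g.correlation, rel=1e-12)

    def test_heteroskedastic_scenario_value(self):
        # sigma_x,i = i, sigma_y = 1, cov = 0.9 i -> 0.9 * 5.5 / sqrt(38.5)
        groups = GroupParamsSet(
            [GroupParams(0, 0, float(i * i), 1.0, 0.9 * i, 10) for i in range(1, 11)]
        )
        expected = 0.9 * 5.5 / math.sqrt(38.5)
        assert asymptotic_pooled_correlation_common_means(groups) == pytest.approx(
            expected, rel=1e-12
        )
        # agrees with the general limit
        assert asymptotic_pooled_correlation(groups).tau == pytest.approx(expected, rel=1e-12)

    def test_unequal_means_rejected(self):
        groups = GroupParamsSet([GroupParams(0, 0, 1, 1, 0, 5), GroupParams(1, 0, 1, 1, 0, 5)])
        with pytest.raises(InvalidParameterError):
            asymptotic_pooled_correlation_common_means(groups)


class TestClosedForms:
    @pytest.mark.parametrize(
        "alpha, lam, expected",
        [
            (2.0, 0.1, -4 * 0.01 / (4 * 0.01 + 4 * 0.1 * 0.8 + 1)),
            (10.0, 0.1, -3.56 / 7.44),
            (0.0, 0.1, 0.64 / 1.64),
        ],
    )
    def test_mean_shift_values(self, alpha, lam, expected):
        assert closed_form_mean_shift(alpha, lam) == pytest.approx(expected, rel=1e-10)

    def test_mean_shift_sign_structure(self):
        for lam in (0.01, 0.05, 0.1):
            assert closed_form_mean_shift(1.0, lam) > 0
            assert closed_form_mean_shift(5.0, lam) < 0
            assert abs(closed_form_mean_shift(2.0, lam)) < 0.03

    def test_mean_shift_invalid_weight(self):
        with pytest.raises(InvalidParameterError):
            closed_form_mean_shift(1.0, 0.7)

    @pytest.mark.parametrize("N, expected", [(1, 0), (10, 825), (100, 8_332_500)])
    def test_pair_distance_sum(self, N, expected):
        assert pair_distance_sum(N) == expected

    def test_pair_distance_sum_brute_force(self):
        for N in (2, 5, 13):
            brute = sum((i - j) ** 2 for i in range(1, N + 1) for j in range(i + 1, N + 1))
            assert pair_distance_sum(N) == brute

    def test_simpson_values(self):
        assert closed_form_simpson(0.3, 1) == pytest.approx(0.3)
        assert closed_form_simpson(0.9, 10) == pytest.approx((0.9 - 8.25) / 9.25, rel=1e-12)
        assert closed_form_simpson(0.9, 100) < -0.99  # nearly -1 at large N

    def test_simpson_monotone_in_rho(self):
        taus = [closed_form_simpson(r, 10) for r in np.linspace(-1, 1, 21)]
        assert np.all(np.diff(taus) > 0)

    def test_heteroskedastic_values(self):
        assert closed_form_heteroskedastic(0.7, [2.0, 2.0, 2.0]) == pytest.approx(0.7)
        assert closed_form_heteroskedastic(0.9, np.arange(1, 11)) == pytest.approx(
            0.9 * 5.5 / math.sqrt(38.5), rel=1e-12
        )
        with pytest.raises(InvalidParameterError):
            closed_form_heteroskedastic(0.5, [1.0, 0.0])

    def test_heteroskedastic_attenuation(self):
        # |tau| <= |rho|, equality only for equal sigmas (Jensen)
        assert abs(closed_form_heteroskedastic(0.8, [1, 5])) < 0.8

    def test_mean_slope_over_N_grid_matches_printed(self):
        slopes = [
            closed_form_heteroskedastic(1.0, np.arange(1, N + 1)) for N in range(10, 101, 10)
        ]
        assert np.mean(slopes) == pytest.approx(0.872, abs=5e-4)


class TestClosedFormEquivalence:
    """Closed forms agree with the general limit on the matching parameters."""

    @given(st.floats(-10, 10), st.integers(3, 60))
    @settings(max_examples=80, deadline=None)
    def test_mean_shift(self, alpha, N):
        tau = asymptotic_pooled_correlation(
            build_group_params("mean_shift", alpha=alpha, N=N)
        ).tau
        assert closed_form_mean_shift(alpha, 1.0 / N) == pytest.approx(tau, rel=1e-10, abs=1e-10)

    @given(st.floats(-0.95, 0.95), st.integers(2, 60))
    @settings(max_examples=80, deadline=None)
    def test_simpson(self, rho, N):
        tau = asymptotic_pooled_correlation(build_group_params("simpson", rho=rho, N=N)).tau
        assert closed_form_simpson(rho, N) == pytest.approx(tau, rel=1e-10, abs=1e-10)

    @given(st.floats(-0.95, 0.95).filter(lambda r: abs(r) > 1e-6), st.integers(2, 60))
    @settings(max_examples=80, deadline=None)
    def test_heteroskedastic(self, rho, N):
        tau = asymptotic_pooled_correlation(
            build_group_params("heteroskedastic", rho=rho, N=N)
        ).tau
        expected = closed_form_heteroskedastic(rho, np.arange(1, N + 1, dtype=float))
        assert expected == pytest.approx(tau, rel=1e-10, abs=1e-10)


def test_monte_carlo_convergence_to_tau():
    """Pooled sample r at total n = 1e5 is within 0.01 of the limit."""
    groups = build_group_params("simpson", rho=0.9, N=10, n_per_group=10_000)
    tau = asymptotic_pooled_correlation(groups).tau
    rng = np.random.default_rng(123)
    xs, ys = [], []
    for g in groups:
        L11 = math.sqrt(g.var_x)
        L21 = g.cov_xy / L11
        L22 = math.sqrt(g.var_y - L21**2)
        z = rng.standard_normal((2, g.size))
        xs.append(g.mean_x + L11 * z[0])
        ys.append(g.mean_y + L21 * z[0] + L22 * z[1])
    r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
    assert abs(r - tau) < 0.01


def test_explicit_weights_renormalized():
    groups = [GroupParams(0, 0, 1, 1, 0.5, 1), GroupParams(0, 0, 1, 1, 0.1, 1)]
    gs = GroupParamsSet.from_weights(groups, [3.0, 1.0])
    assert np.allclose(gs.weights, [0.75, 0.25])
    assert gs.weights.sum() == pytest.approx(1.0, abs=1e-12)
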