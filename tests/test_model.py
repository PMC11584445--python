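"""Closed forms, simulation, and invariants of the explosive process."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coxplosive import (
    ModelParams,
    count_curve,
    deterioration_rate,
    expected_increment,
    mu_infinity,
    mu_segment,
    rate,
    simulate,
)

alphas = st.floats(min_value=0.01, max_value=0.99)
lams = st.floats(min_value=0.1, max_value=1e4)


class TestClosedForms:
    def test_rate_grows_geometrically(self, params):
        assert rate(1, params) == 2.0
        assert rate(2, params) == 4.0
        assert rate(3, params) == 8.0

    def test_expected_increment_is_inverse_rate(self, params):
        assert expected_increment(1, params) == pytest.approx(0.5)
        assert expected_increment(2, params) == pytest.approx(0.25)

    def test_index_below_one_rejected(self, params):
        with pytest.raises(ValueError):
            rate(0, params)
        with pytest.raises(ValueError):
            expected_increment(-1, params)

    def test_mu_infinity_value(self):
        assert mu_infinity(ModelParams(0.9, 50.0)) == pytest.approx(0.2)

    def test_mu_infinity_single_event_limit(self):
        # alpha -> 0+: only the first increment matters, mean 1/lam
        assert mu_infinity(ModelParams(1e-12, 4.0)) == pytest.approx(0.25)

    def test_mu_segment_examples(self, params):
        assert mu_segment(1, 2, params) == pytest.approx(0.25)
        assert mu_segment(0, 2, params) == pytest.approx(0.75)
        assert mu_segment(0, np.inf, ModelParams(0.9, 50.0)) == pytest.approx(0.2)

    def test_mu_segment_equals_expected_increment(self, params):
        # one-event segment (i, i+1) is exactly E(d_eps_{i+1})
        for i in range(5):
            assert mu_segment(i, i + 1, params) == pytest.approx(
                expected_increment(i + 1, params)
            )

    def test_mu_segment_rejects_bad_indices(self, params):
        with pytest.raises(ValueError):
            mu_segment(2, 2, params)
        with pytest.raises(ValueError):
            mu_segment(-1, 2, params)

    def test_shifted_convention_matches_alternate_formula(self, params):
        a, lam = params.alpha, params.lam
        got = mu_segment(1, 3, params, convention="shifted")
        assert got == pytest.approx((a**1 - a**4) / ((1 - a) * lam))

    def test_deterioration_rate(self):
        assert deterioration_rate(ModelParams(1 / np.e, 1.0)) == pytest.approx(1.0)
        assert deterioration_rate(ModelParams(0.5, 1.0)) == pytest.approx(np.log(2))
        assert deterioration_rate(ModelParams(1 - 1e-9, 1.0)) == pytest.approx(0.0, abs=1e-8)

    def test_invalid_params_rejected(self):
        for alpha, lam in [(0.0, 1.0), (1.0, 1.0), (1.3, 1.0), (0.5, 0.0), (0.5, -2.0)]:
            with pytest.raises(ValueError):
                ModelParams(alpha, lam)


class TestAnalyticInvariants:
    @given(alpha=alphas, lam=lams)
    @settings(derandomize=True, max_examples=80)
    def test_nbue_strictly_decreasing_increments(self, alpha, lam):
        p = ModelParams(alpha, lam)
        inc = expected_increment(np.arange(1, 30), p)
        assert np.all(np.diff(inc) < 0)

    @given(alpha=alphas, lam=lams)
    @settings(derandomize=True, max_examples=80)
    def test_beta_is_minus_log_alpha(self, alpha, lam):
        p = ModelParams(alpha, lam)
        assert deterioration_rate(p) == pytest.approx(-np.log(alpha))
        # and equals the log ratio of consecutive rates
        assert deterioration_rate(p) == pytest.approx(
            -np.log(rate(3, p) / rate(4, p))
        )

    @given(alpha=alphas, lam=lams,
           i=st.integers(0, 10), dj=st.integers(1, 10), dl=st.integers(1, 10))
    @settings(derandomize=True, max_examples=100)
    def test_mu_segment_additive_and_telescoping(self, alpha, lam, i, dj, dl):
        p = ModelParams(alpha, lam)
        j, l = i + dj, i + dj + dl
        assert mu_segment(i, j, p) + mu_segment(j, l, p) == pytest.approx(
            mu_segment(i, l, p), rel=1e-12
        )
        assert mu_segment(0, np.inf, p) == pytest.approx(mu_infinity(p), rel=1e-12)

    @given(alpha=alphas, lam=lams, n=st.integers(1, 200))
    @settings(derandomize=True, max_examples=80)
    def test_partial_sums_bounded_by_mu_infinity(self, alpha, lam, n):
        p = ModelParams(alpha, lam)
        partial = float(np.sum(expected_increment(np.arange(1, n + 1), p)))
        # strict bound analytically; allow float rounding at large n
        assert partial <= mu_infinity(p) * (1 + 1e-12)


class TestSimulation:
    def test_reproducible_given_seed(self):
        p = ModelParams(0.85, 100.0)
        a = simulate(p, seed=42, max_events=200)
        b = simulate(p, seed=42, max_events=200)
        np.testing.assert_array_equal(a.increments, b.increments)
        assert a.stop_reason == b.stop_reason

    def test_strains_strictly_increasing(self):
        s = simulate(ModelParams(0.9, 50.0), seed=0, max_events=300, min_increment=0)
        assert np.all(np.diff(s.cum_strains) > 0)
        assert len(s) == 300 and s.stop_reason == "max_events"

    def test_underflow_stop(self):
        s = simulate(ModelParams(0.5, 10.0), seed=1, max_events=2000, min_increment=1e-9)
        assert s.stop_reason == "increment_underflow"
        assert len(s) >= 1
        # every increment before the terminal one is above the resolution
        assert np.all(s.increments[:-1] >= 1e-9)

    def test_first_increment_mean_matches_exponential(self, rng):
        # mean of d_eps_1 over many runs ~ 1/lam within 3 SE
        draws = np.array([
            simulate(ModelParams(0.5, 2.0), seed=rng, max_events=1).increments[0]
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_total_strain_mean_matches_mu_infinity(self, rng):
        # Monte-Carlo mean of realized totals vs closed form, 3 SE
        p = ModelParams(0.9, 50.0)
        totals = np.array([
            simulate(p, seed=rng, max_events=500, min_increment=0).total_strain
            for _ in range(4_000)
        ])
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - mu_infinity(p)) < 3 * se

    def test_total_strain_variance_matches_closed_form(self, rng):
        # Var(eps_inf) = sum 1/lambda_k^2 = 1/(lam^2 (1 - alpha^2))
        p = ModelParams(0.9, 50.0)
        totals = np.array([
            simulate(p, seed=rng, max_events=500, min_increment=0).total_strain
            for _ in range(4_000)
        ])
        expected_var = 1.0 / (p.lam**2 * (1 - p.alpha**2))
        assert totals.var(ddof=1) == pytest.approx(expected_var, rel=0.15)

    def test_memoryless_increment_distribution(self, rng):
        # the law of d_eps_3 must not depend on the accumulated history:
        # condition on small vs large eps_2 and compare the two samples
        p = ModelParams(0.8, 20.0)
        eps2, inc3 = [], []
        for _ in range(4_000):
            s = simulate(p, seed=rng, max_events=3, min_increment=0)
            eps2.append(s.cum_strains[1])
            inc3.append(s.increments[2])
        eps2, inc3 = np.array(eps2), np.array(inc3)
        low = inc3[eps2 <= np.median(eps2)]
        high = inc3[eps2 > np.median(eps2)]
        assert stats.ks_2samp(low, high).pvalue > 0.01


class TestCountCurve:
    def test_counts_on_grid(self):
        got = count_curve(np.array([0.1, 0.2]), np.array([0.05, 0.15, 0.25]))
        np.testing.assert_array_equal(got, [0, 1, 2])

    def test_empty_sequence_counts_zero(self):
        got = count_curve(np.array([]), np.array([0.0, 1.0]))
        np.testing.assert_array_equal(got, [0, 0])

    def test_grid_point_on_event_is_counted(self):
        # N(eps) is closed at eps: an event exactly at a grid point counts
        got = count_curve(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
        np.testing.assert_array_equal(got, [1, 2])

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            count_curve(np.array([0.1]), np.array([0.3, 0.1]))

    def test_accepts_simulated_sequence(self):
        s = simulate(ModelParams(0.7, 10.0), seed=5, max_events=50, min_increment=0)
        grid = np.linspace(0, s.total_strain, 20)
        counts = count_curve(s, grid)
        assert counts[-1] == len(s)
        assert np.all(np.diff(counts) >= 0)
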