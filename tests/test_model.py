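"""Closed-form model components against quadrature oracles and known limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from avloc import (
    ModelParams,
    StructureEstimates,
    apply_strategy,
    estimate_c1,
    estimate_c2,
    likelihood_c1,
    likelihood_c2,
    matching_expected_accuracy,
    maximizing_expected_accuracy,
    posterior_c1,
    structure_estimates,
)

UNIT = ModelParams(sigma_A=1.0, sigma_V=1.0, sigma_P=1.0, p_common=0.5)


def quadrature_c1(x_A, x_V, p):
    """Oracle: marginalize the common source numerically, p(x_A,x_V|C=1)."""
    f = lambda s: norm.pdf(x_A, s, p.sigma_A) * norm.pdf(x_V, s, p.sigma_V) * norm.pdf(s, 0, p.sigma_P)
    val, _ = quad(f, -np.inf, np.inf, epsabs=0, epsrel=1e-12)
    return val


def quadrature_c2(x_A, x_V, p):
    """Oracle: two independent sources, each integrated against the prior."""
    fa = lambda s: norm.pdf(x_A, s, p.sigma_A) * norm.pdf(s, 0, p.sigma_P)
    fv = lambda s: norm.pdf(x_V, s, p.sigma_V) * norm.pdf(s, 0, p.sigma_P)
    va, _ = quad(fa, -np.inf, np.inf, epsabs=0, epsrel=1e-12)
    vv, _ = quad(fv, -np.inf, np.inf, epsabs=0, epsrel=1e-12)
    return va * vv


class TestLikelihoods:
    def test_c1_at_origin_unit_params(self):
        # exponent vanishes, leaving the normalizer 1/(2*pi*sqrt(3))
        assert likelihood_c1(0.0, 0.0, UNIT) == pytest.approx(1.0 / (2 * np.pi * np.sqrt(3)), rel=1e-12)

    def test_c2_at_origin_unit_params(self):
        assert likelihood_c2(0.0, 0.0, UNIT) == pytest.approx((1.0 / np.sqrt(4 * np.pi)) ** 2, rel=1e-12)

    def test_c1_matches_quadrature_at_typical_sensations(self, mean_params):
        got = likelihood_c1(10.1, 2.5, mean_params)
        assert got == pytest.approx(quadrature_c1(10.1, 2.5, mean_params), rel=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_closed_forms_match_quadrature(self, seed):
        r = np.random.default_rng(seed)
        p = ModelParams(r.uniform(1, 20), r.uniform(1, 20), r.uniform(5, 100), 0.5)
        x_A, x_V = r.uniform(-40, 40, size=2)
        assert likelihood_c1(x_A, x_V, p) == pytest.approx(quadrature_c1(x_A, x_V, p), rel=1e-8)
        assert likelihood_c2(x_A, x_V, p) == pytest.approx(quadrature_c2(x_A, x_V, p), rel=1e-8)

    def test_c1_symmetric_under_cue_swap_with_equal_sigmas(self):
        p = ModelParams(3.0, 3.0, 20.0, 0.5)
        assert likelihood_c1(7.0, -2.0, p) == pytest.approx(likelihood_c1(-2.0, 7.0, p), rel=1e-12)

    def test_c2_factorizes(self, mean_params, rng):
        # cross-ratio identity L(a,b) L(c,d) == L(a,d) L(c,b) holds iff the
        # joint factorizes into an auditory and a visual marginal
        for _ in range(10):
            a, b, c, d = rng.uniform(-40, 40, size=4)
            lhs = likelihood_c2(a, b, mean_params) * likelihood_c2(c, d, mean_params)
            rhs = likelihood_c2(a, d, mean_params) * likelihood_c2(c, b, mean_params)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(sigma_A=-1.0, sigma_V=1.0, sigma_P=1.0, p_common=0.5)
        with pytest.raises(ValueError):
            ModelParams(sigma_A=1.0, sigma_V=1.0, sigma_P=1.0, p_common=1.2)


class TestPosterior:
    def test_degenerate_priors(self, mean_params):
        sure = ModelParams(10.1, 2.5, 33.0, 1.0)
        never = ModelParams(10.1, 2.5, 33.0, 0.0)
        assert posterior_c1(25.0, -25.0, sure) == 1.0
        assert posterior_c1(0.0, 0.0, never) == 0.0

    def test_equals_prior_when_likelihoods_tie(self, mean_params):
        # locate a sensation pair where the two structure likelihoods cross;
        # there the posterior must reduce to the prior p_common
        from dataclasses import replace

        from scipy.optimize import brentq

        from avloc import log_likelihood_c1, log_likelihood_c2

        p = replace(mean_params, p_common=0.37)
        gap = lambda x_V: log_likelihood_c1(5.0, x_V, p) - log_likelihood_c2(5.0, x_V, p)
        x_V = brentq(gap, 5.0, 60.0)
        assert posterior_c1(5.0, x_V, p) == pytest.approx(0.37, rel=1e-9)

    def test_monotone_decreasing_in_discrepancy(self, mean_params):
        for midpoint in (0.0, 5.0):
            d = np.linspace(0, 60, 121)
            post = posterior_c1(midpoint + d / 2, midpoint - d / 2, mean_params)
            assert np.all(np.diff(post) <= 1e-12)

    def test_finite_at_huge_discrepancy(self, mean_params):
        post = posterior_c1(1e4, -1e4, mean_params)
        assert 0.0 <= post <= 1.0

    @given(
        x_A=st.floats(-60, 60),
        x_V=st.floats(-60, 60),
        pc=st.floats(0.01, 0.99),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_everywhere(self, x_A, x_V, pc):
        p = ModelParams(10.1, 2.5, 33.0, pc)
        assert 0.0 <= posterior_c1(x_A, x_V, p) <= 1.0


class TestEstimates:
    def test_fused_estimate_at_origin(self, mean_params):
        assert estimate_c1(0.0, 0.0, mean_params) == 0.0

    def test_fused_estimate_flat_prior_equal_sigmas_is_midpoint(self):
        p = ModelParams(3.0, 3.0, 1e8, 0.5)
        assert estimate_c1(10.0, 4.0, p) == pytest.approx(7.0, rel=1e-6)

    def test_fused_estimate_matches_posterior_mean_quadrature(self, mean_params):
        x_A, x_V = 21.0, 1.0
        f = lambda s: norm.pdf(x_A, s, mean_params.sigma_A) * norm.pdf(x_V, s, mean_params.sigma_V) * norm.pdf(s, 0, mean_params.sigma_P)
        z, _ = quad(f, -np.inf, np.inf, epsabs=0, epsrel=1e-12)
        mean, _ = quad(lambda s: s * f(s), -np.inf, np.inf, epsabs=0, epsrel=1e-12)
        assert estimate_c1(x_A, x_V, mean_params) == pytest.approx(mean / z, rel=1e-8)

    def test_single_cue_shrinkage_formula(self, mean_params):
        vp, va = 33.0**2, 10.1**2
        assert estimate_c2(13.0, 10.1, mean_params) == pytest.approx(13.0 * vp / (vp + va), rel=1e-12)
        assert estimate_c2(0.0, 10.1, mean_params) == 0.0

    def test_single_cue_flat_prior_returns_sensation(self):
        p = ModelParams(5.0, 2.0, 1e9, 0.5)
        assert estimate_c2(13.0, 5.0, p) == pytest.approx(13.0, rel=1e-6)

    def test_missing_sensation_rejected(self, mean_params):
        with pytest.raises(ValueError):
            estimate_c1(None, 3.0, mean_params)
        with pytest.raises(ValueError):
            estimate_c2(None, 10.1, mean_params)

    @given(x_A=st.floats(-60, 60), x_V=st.floats(-60, 60))
    @settings(max_examples=60, deadline=None)
    def test_fused_estimate_between_cues_and_prior(self, x_A, x_V):
        p = ModelParams(10.1, 2.5, 33.0, 0.5)
        s = estimate_c1(x_A, x_V, p)
        assert min(x_A, x_V, 0.0) - 1e-9 <= s <= max(x_A, x_V, 0.0) + 1e-9

    @given(x=st.floats(-60, 60))
    @settings(max_examples=60, deadline=None)
    def test_shrinkage_keeps_sign_and_shrinks(self, x):
        p = ModelParams(10.1, 2.5, 33.0, 0.5)
        s = float(estimate_c2(x, 10.1, p))
        assert abs(s) <= abs(x) + 1e-12
        assert s * x >= 0.0


def _estimates(post, c1=5.0, c2_A=-3.0, c2_V=1.0):
    return StructureEstimates(s_hat_A_c1=c1, s_hat_V_c1=c1, s_hat_A_c2=c2_A, s_hat_V_c2=c2_V, post_c1=post)


class TestStrategies:
    def test_certain_common_cause_all_strategies_fuse(self, mean_params):
        est = _estimates(post=1.0)
        for strategy in ("averaging", "selection", "matching"):
            r_A, r_V = apply_strategy(strategy, est, mean_params, xi=0.99)
            assert float(r_A) == 5.0 and float(r_V) == 5.0

    def test_averaging_midpoint_at_half_posterior(self, mean_params):
        r_A, r_V = apply_strategy("averaging", _estimates(post=0.5), mean_params)
        assert float(r_A) == pytest.approx(1.0)  # (5 + -3)/2
        assert float(r_V) == pytest.approx(3.0)  # (5 + 1)/2

    def test_selection_commits_to_likelier_structure(self, mean_params):
        # the worked scenario: posterior of a common cause 0.30 -> independent estimates
        r_A, r_V = apply_strategy("selection", _estimates(post=0.30), mean_params)
        assert (float(r_A), float(r_V)) == (-3.0, 1.0)
        r_A, _ = apply_strategy("selection", _estimates(post=0.70), mean_params)
        assert float(r_A) == 5.0

    def test_tie_at_threshold_resolves_to_independent(self, mean_params):
        r_A, _ = apply_strategy("selection", _estimates(post=0.5), mean_params)
        assert float(r_A) == -3.0
        r_A, _ = apply_strategy("matching", _estimates(post=0.5), mean_params, xi=0.5)
        assert float(r_A) == -3.0

    def test_matching_with_point_mass_xi_reduces_to_selection(self, mean_params):
        for post in np.linspace(0, 1, 21):
            est = _estimates(post=float(post))
            sel = apply_strategy("selection", est, mean_params)
            mat = apply_strategy("matching", est, mean_params, xi=0.5)
            assert float(sel[0]) == float(mat[0]) and float(sel[1]) == float(mat[1])

    def test_matching_choice_frequency_tracks_posterior(self, mean_params, rng):
        n = 10_000
        for post in (0.2, 0.57, 0.9):
            est = _estimates(post=post)
            r_A, _ = apply_strategy("matching", est, mean_params, xi=rng.uniform(size=n))
            freq = float(np.mean(np.asarray(r_A) == 5.0))
            assert abs(freq - post) < 3 * np.sqrt(post * (1 - post) / n)

    def test_single_structure_choice_covers_both_modalities(self, mean_params, rng):
        est = _estimates(post=0.5)
        r_A, r_V = apply_strategy("matching", est, mean_params, xi=rng.uniform(size=1000))
        fused = np.asarray(r_A) == 5.0
        assert np.array_equal(fused, np.asarray(r_V) == 5.0)

    @given(post=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_averaging_is_convex_combination(self, post):
        p = ModelParams(10.1, 2.5, 33.0, 0.5)
        r_A, r_V = apply_strategy("averaging", _estimates(post=post), p)
        assert min(-3.0, 5.0) - 1e-9 <= float(r_A) <= max(-3.0, 5.0) + 1e-9
        assert min(1.0, 5.0) - 1e-9 <= float(r_V) <= max(1.0, 5.0) + 1e-9

    def test_unknown_strategy_and_missing_xi_rejected(self, mean_params):
        with pytest.raises(ValueError):
            apply_strategy("oracle", _estimates(0.5), mean_params)
        with pytest.raises(ValueError):
            apply_strategy("matching", _estimates(0.5), mean_params)


class TestStructureEstimates:
    def test_bundle_consistency(self, mean_params, rng):
        x_A, x_V = rng.normal(size=50), rng.normal(size=50)
        est = structure_estimates(x_A, x_V, mean_params)
        np.testing.assert_allclose(est.s_hat_A_c1, est.s_hat_V_c1)
        np.testing.assert_allclose(est.s_hat_A_c1, estimate_c1(x_A, x_V, mean_params))
        np.testing.assert_allclose(est.post_c1, posterior_c1(x_A, x_V, mean_params))


def test_binary_guessing_accuracies():
    assert matching_expected_accuracy(0.7) == pytest.approx(0.58)
    assert maximizing_expected_accuracy(0.7) == pytest.approx(0.70)
    assert matching_expected_accuracy(0.5) == pytest.approx(0.5)
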