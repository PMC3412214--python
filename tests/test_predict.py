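"""Cut-posterior sampling and the derived predictive quantities."""

import copy
import math

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.optimize import brentq

from aaagrowth.model import ModelSpec, PosteriorDraws, PriorSpec
from aaagrowth.predict import (
    cut_posterior,
    exceedance_prob,
    exceedance_profile,
    growth_rate,
    predict_measurement,
    stored_individual,
    time_to_threshold,
)
from aaagrowth.simulate import build_covariance

from conftest import make_subject


def fixed_draws(beta, Sigma=None, sigma_w=3.12, K=400, spec=None, seed=0):
    """Population draws with all-identical parameter values (point mass)."""
    spec = spec or ModelSpec()
    q = spec.q
    Sigma = np.eye(q) if Sigma is None else np.asarray(Sigma, dtype=float)
    return PosteriorDraws(
        spec=spec,
        prior=PriorSpec(),
        subject_ids=(),
        beta=np.tile(np.asarray(beta, dtype=float), (K, 1)),
        Sigma=np.tile(Sigma, (K, 1, 1)),
        sigma_w=np.full(K, float(sigma_w)),
        b=np.zeros((K, 0, q), dtype=np.float32),
        chain=np.zeros(K, dtype=int),
        n_chains=1,
    )


def table2_draws(K=2000):
    """Point-mass draws at the linear-model population point estimates."""
    return fixed_draws(
        (37.5, 2.19), Sigma=build_covariance((7.12, 1.74), (0.51,)),
        sigma_w=3.12, K=K,
    )


class TestCutPosterior:
    def test_noiseless_two_points_identify_the_line(self):
        pop = fixed_draws((40.0, 2.0), Sigma=4 * np.eye(2), sigma_w=1e-6, K=100)
        subj = make_subject([0.0, 1.0], [43.0, 47.0])  # intercept 43, slope 4
        ind = cut_posterior(subj, pop, rng=np.random.default_rng(0))
        np.testing.assert_allclose(ind.b[:, 0], 3.0, atol=1e-3)
        np.testing.assert_allclose(ind.b[:, 1], 2.0, atol=1e-3)

    def test_single_high_scan_is_shrunk_toward_population_mean(self):
        pop = table2_draws()
        subj = make_subject([0.0], [50.0])
        ind = cut_posterior(subj, pop, rng=np.random.default_rng(1))
        level0 = ind.level(0.0)
        assert level0.mean() < 50.0
        # closed form: E[level | y=50] = beta0 + (sigma0^2/(sigma0^2+sw^2)) * 12.5
        expected = 37.5 + (7.12**2 / (7.12**2 + 3.12**2)) * 12.5
        assert level0.mean() == pytest.approx(expected, abs=0.15)

    def test_population_draws_untouched(self):
        pop = table2_draws(K=200)
        snapshot = copy.deepcopy(pop)
        cut_posterior(make_subject([0.0], [45.0]), pop, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(pop.beta, snapshot.beta)
        np.testing.assert_array_equal(pop.Sigma, snapshot.Sigma)
        np.testing.assert_array_equal(pop.sigma_w, snapshot.sigma_w)

    def test_missing_covariate_rejected(self):
        spec = ModelSpec(covariate_names=("smoker",))
        pop = fixed_draws((37.5, 2.19), spec=spec)
        pop.gamma = np.zeros((pop.n_draws, 2))
        with pytest.raises(ValueError, match="covariate"):
            cut_posterior(make_subject([0.0], [40.0]), pop,
                          rng=np.random.default_rng(0))

    def test_more_data_tightens_growth_rate(self, small_fit):
        draws, _ = small_fit
        rng = np.random.default_rng(3)
        times = [0.0, 1.0, 2.0, 3.0, 4.0]
        values = [40.0, 42.0, 44.0, 46.0, 48.0]
        sds = []
        for k in (1, 2, 3, 5):
            subj = make_subject(times[:k], values[:k])
            ind = cut_posterior(subj, draws, rng=rng)
            sds.append(growth_rate(ind).draws.std())
        assert sds[0] >= sds[1] >= sds[2] >= sds[3]

    def test_in_sample_reuse_matches_subject(self, small_cohort, small_fit):
        draws, _ = small_fit
        subj = small_cohort.dataset.subjects[0]
        ind = stored_individual(draws, subj)
        assert ind.n_draws == draws.n_draws
        # stored effects should track the subject's own trajectory direction
        obs_slope = np.polyfit(subj.times, subj.values, 1)[0]
        post_slope = growth_rate(ind).median
        assert abs(post_slope - obs_slope) < 3.0


class TestGrowthRate:
    def test_linear_point_mass(self):
        pop = fixed_draws((37.5, 2.19), Sigma=np.zeros((2, 2)), sigma_w=1.0, K=50)
        ind = cut_posterior(make_subject([0.0], [37.5]), pop,
                            rng=np.random.default_rng(0))
        g = growth_rate(ind)
        np.testing.assert_allclose(g.draws, 2.19, atol=1e-9)

    def test_quadratic_needs_time(self):
        spec = ModelSpec(trend="quadratic")
        pop = fixed_draws((38.0, 1.5, 0.1), Sigma=np.zeros((3, 3)),
                          sigma_w=1.0, spec=spec, K=20)
        ind = cut_posterior(make_subject([0.0], [38.0]), pop,
                            rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            growth_rate(ind)
        g = growth_rate(ind, t=2.0)
        np.testing.assert_allclose(g.draws, 1.5 + 2 * 0.1 * 2.0, atol=1e-9)


class TestTimeToThreshold:
    def test_linear_closed_form(self):
        pop = fixed_draws((40.0, 3.0), Sigma=np.zeros((2, 2)), sigma_w=1e-9, K=10)
        ind = cut_posterior(make_subject([0.0], [40.0]), pop,
                            rng=np.random.default_rng(0))
        w = time_to_threshold(ind, t=0.0, alpha=55.0)
        np.testing.assert_allclose(w.draws, 5.0, atol=1e-6)

    def test_negative_growth_never_crosses(self):
        pop = fixed_draws((40.0, -1.0), Sigma=np.zeros((2, 2)), sigma_w=1e-9, K=10)
        ind = cut_posterior(make_subject([0.0], [40.0]), pop,
                            rng=np.random.default_rng(0))
        w = time_to_threshold(ind, t=0.0, alpha=55.0)
        assert np.all(np.isinf(w.draws))
        assert w.p_inf == 1.0

    def test_already_over_threshold_is_zero(self):
        pop = fixed_draws((60.0, 1.0), Sigma=np.zeros((2, 2)), sigma_w=1e-9, K=10)
        ind = cut_posterior(make_subject([0.0], [60.0]), pop,
                            rng=np.random.default_rng(0))
        w = time_to_threshold(ind, t=0.0, alpha=55.0)
        assert np.all(w.draws == 0.0)
        assert w.p_zero == 1.0

    def test_quadratic_root_against_bisection(self):
        spec = ModelSpec(trend="quadratic")
        pop = fixed_draws((40.0, 2.0, 0.1), Sigma=np.zeros((3, 3)),
                          sigma_w=1e-9, spec=spec, K=5)
        ind = cut_posterior(make_subject([0.0], [40.0]), pop,
                            rng=np.random.default_rng(0))
        w = time_to_threshold(ind, t=0.0, alpha=55.0)
        # oracle: sign change of the curve 40 + 2s + 0.1 s^2 - 55
        root = brentq(lambda s: 40 + 2 * s + 0.1 * s * s - 55, 0, 100, xtol=1e-10)
        np.testing.assert_allclose(w.draws, root, atol=1e-6)

    def test_random_draw_consistency_with_oracle(self, small_fit):
        """Per-draw: W = 0 iff level(t) >= alpha; finite iff the curve attains
        alpha after t (checked against bracketing bisection)."""
        draws, _ = small_fit
        ind = cut_posterior(make_subject([0.0], [44.0]), draws,
                            rng=np.random.default_rng(9))
        t0, alpha = 0.5, 55.0
        w = time_to_threshold(ind, t=t0, alpha=alpha)
        a = ind.curve_coefficients()
        level_t = ind.level(t0)
        for k in range(0, ind.n_draws, 7):
            a0, a1 = a[k, 0], a[k, 1]
            f = lambda s: a0 + a1 * (t0 + s) - alpha
            if level_t[k] >= alpha:
                assert w.draws[k] == 0.0
            elif f(1e7) < 0:
                assert np.isinf(w.draws[k])
            else:
                root = brentq(f, 0, 1e7, xtol=1e-9)
                assert w.draws[k] == pytest.approx(root, abs=1e-3)


class TestPredictMeasurement:
    def test_zero_horizon_zero_noise_returns_level(self):
        pop = fixed_draws((42.0, 2.0), Sigma=np.zeros((2, 2)), sigma_w=1e-12, K=30)
        ind = cut_posterior(make_subject([0.0], [42.0]), pop,
                            rng=np.random.default_rng(0))
        p = predict_measurement(ind, t=0.0, s=0.0, rng=np.random.default_rng(1))
        np.testing.assert_allclose(p.draws, 42.0, atol=1e-6)

    def test_predictive_spread_matches_error_scale(self):
        pop = fixed_draws((50.0, 0.0), Sigma=np.zeros((2, 2)), sigma_w=3.12,
                          K=20000)
        ind = cut_posterior(make_subject([0.0], [50.0]), pop,
                            rng=np.random.default_rng(0))
        underlying = predict_measurement(ind, s=1.0, observed=False,
                                         rng=np.random.default_rng(1))
        observed = predict_measurement(ind, s=1.0, observed=True,
                                       rng=np.random.default_rng(2))
        extra_sd = math.sqrt(max(observed.draws.var() - underlying.draws.var(), 0))
        assert extra_sd == pytest.approx(3.12, rel=0.05)

    def test_negative_horizon_rejected(self):
        pop = table2_draws(K=10)
        ind = cut_posterior(make_subject([0.0], [40.0]), pop,
                            rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            predict_measurement(ind, s=-0.5)


class TestExceedance:
    def test_closed_form_tail(self):
        pop = fixed_draws((50.0, 0.0), Sigma=np.zeros((2, 2)), sigma_w=3.2, K=10)
        # cut with a 50 mm scan and zero Sigma keeps the level at exactly 50
        ind = cut_posterior(make_subject([0.0], [50.0]), pop,
                            rng=np.random.default_rng(0))
        p = exceedance_prob(ind, t=0.0, s=0.0, alpha=55.0)
        assert p == pytest.approx(1.0 - ndtr((55.0 - 50.0) / 3.2), abs=1e-12)

    def test_threshold_below_all_mass_gives_one(self):
        pop = table2_draws(K=100)
        ind = cut_posterior(make_subject([0.0], [40.0]), pop,
                            rng=np.random.default_rng(0))
        assert exceedance_prob(ind, s=0.0, alpha=1e-6) == pytest.approx(1.0)

    def test_rao_blackwell_matches_indicator_monte_carlo(self, small_fit):
        draws, _ = small_fit
        rng = np.random.default_rng(11)
        ind = cut_posterior(make_subject([0.0], [48.0]), draws, rng=rng)
        p_rb, tails = exceedance_prob(ind, s=0.5, alpha=55.0, return_draws=True)
        sim = predict_measurement(ind, s=0.5, rng=rng).draws
        p_mc = float(np.mean(sim >= 55.0))
        se = math.sqrt(np.sum(tails * (1 - tails))) / len(tails)
        assert abs(p_rb - p_mc) <= 3 * se + 1e-12

    def test_monotone_in_horizon_for_positive_growth(self):
        pop = fixed_draws((45.0, 2.0), Sigma=np.zeros((2, 2)), sigma_w=3.0, K=20)
        ind = cut_posterior(make_subject([0.0], [45.0]), pop,
                            rng=np.random.default_rng(0))
        profile = exceedance_profile(ind, np.linspace(0, 5, 21), alpha=55.0)
        assert np.all(np.diff(profile) >= -1e-12)
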