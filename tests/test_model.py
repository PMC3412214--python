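"""Gibbs sampler correctness: conjugate updates, likelihood, diagnostics,
parameter recovery, and cross-checks against an independent REML fit."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

from aaagrowth.data import LongitudinalDataset
from aaagrowth.model import (
    FitDiagnostics,
    GrowthModel,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    _sample_mvn,
    dic,
    fit_growth_model,
    log_likelihood,
    rhat,
)
from aaagrowth.simulate import (
    GeneratorConfig,
    TruthParams,
    build_covariance,
    simulate_cohort,
)

from conftest import make_subject


def _point_mass_draws(beta, sigma_w, n_subjects=1, K=2, spec=None, b=None):
    spec = spec or ModelSpec()
    q = spec.q
    beta = np.tile(np.asarray(beta, dtype=float), (K, 1))
    b = np.zeros((K, n_subjects, q), dtype=np.float32) if b is None else b
    return PosteriorDraws(
        spec=spec,
        prior=PriorSpec(),
        subject_ids=tuple(f"s{i}" for i in range(n_subjects)),
        beta=beta,
        Sigma=np.tile(np.eye(q), (K, 1, 1)),
        sigma_w=np.full(K, sigma_w),
        b=b,
        chain=np.zeros(K, dtype=int),
        n_chains=1,
    )


class TestModelSpec:
    def test_independent_intercepts_require_linear_trend(self):
        with pytest.raises(ValueError):
            ModelSpec(trend="quadratic", intercept_model="independent")

    def test_censoring_requires_gaussian_errors(self):
        with pytest.raises(ValueError):
            ModelSpec(error_family="student_t", censor_bound=30.0)


class TestConjugateUpdate:
    def test_fixed_effect_update_matches_closed_form_posterior(self):
        """The normal-normal update reproduces the exact conjugate posterior
        of a linear regression with known error variance."""
        rng = np.random.default_rng(0)
        n, sigma2, tau2 = 60, 2.0, 1000.0**2
        X = np.column_stack([np.ones(n), rng.uniform(0, 5, n)])
        y = 3.0 + 1.5 * X[:, 1] + rng.normal(0, math.sqrt(sigma2), n)
        A = X.T @ X / sigma2 + np.eye(2) / tau2
        rhs = X.T @ y / sigma2
        exact_mean = np.linalg.solve(A, rhs)
        exact_cov = np.linalg.inv(A)
        draws = np.array([_sample_mvn(A, rhs, rng) for _ in range(4000)])
        se = np.sqrt(np.diag(exact_cov) / 4000)
        np.testing.assert_allclose(draws.mean(axis=0), exact_mean, atol=4 * se.max())
        np.testing.assert_allclose(np.cov(draws.T), exact_cov, rtol=0.15)


class TestLogLikelihood:
    def test_single_observation_closed_form(self):
        ds = LongitudinalDataset(subjects=(make_subject([0.0], [37.5]),))
        draws = _point_mass_draws([37.5, 0.0], sigma_w=1.0)
        ll = log_likelihood(draws, ds)
        np.testing.assert_allclose(ll, -0.5 * math.log(2 * math.pi), rtol=1e-12)

    def test_censored_record_matches_normal_cdf_oracle(self):
        from aaagrowth.data import Measurement, Subject

        cens = Subject(subject_id="s0",
                       measurements=(Measurement(time=0.0, censored_below=30.0),))
        obs = make_subject([0.0], [35.0], subject_id="s1")
        ds = LongitudinalDataset(subjects=(cens, obs))
        spec = ModelSpec(censor_bound=30.0)
        draws = _point_mass_draws([20.0, 0.0], sigma_w=8.0, n_subjects=2, spec=spec)
        ll = log_likelihood(draws, ds)
        expected = math.log(ndtr((30.0 - 20.0) / 8.0)) + stats.norm.logpdf(
            35.0, 20.0, 8.0
        )
        np.testing.assert_allclose(ll, expected, rtol=1e-10)

    def test_student_t_converges_to_gaussian(self):
        ds = LongitudinalDataset(
            subjects=(make_subject([0, 1, 2], [35.0, 37.0, 40.0]),)
        )
        g = _point_mass_draws([36.0, 2.0], sigma_w=3.0)
        t_spec = ModelSpec(error_family="student_t")
        t = _point_mass_draws([36.0, 2.0], sigma_w=3.0, spec=t_spec)
        t.nu = np.full(2, 1000.0)
        ll_g = log_likelihood(g, ds)[0]
        ll_t = log_likelihood(t, ds)[0]
        assert abs(ll_g - ll_t) < 1e-3

    def test_censoring_off_equals_censored_model_when_no_censored_records(
        self, small_cohort, small_fit
    ):
        """With zero censored records the censored likelihood reduces exactly
        to the standard one on every draw."""
        draws, _ = small_fit
        idx = np.arange(0, draws.n_draws, 50)
        ll_plain = log_likelihood(draws, small_cohort.dataset, indices=idx)
        cens_spec = dataclasses.replace(draws.spec, censor_bound=30.0)
        cens_draws = dataclasses.replace(draws, spec=cens_spec)
        ll_cens = log_likelihood(cens_draws, small_cohort.dataset, indices=idx)
        np.testing.assert_array_equal(ll_plain, ll_cens)


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        x = np.random.default_rng(0).normal(size=200)
        assert rhat(np.vstack([x, x])) == 1.0

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 500), rng.normal(10, 1, 500)
        assert rhat(np.vstack([a, b])) > 3.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self):
        ds = LongitudinalDataset(
            subjects=(make_subject([0, 1], [35.0, 37.0]),)
        )
        draws = _point_mass_draws([35.0, 2.0], sigma_w=2.0, K=4)
        diag = dic(draws, ds)
        assert diag.p_d == pytest.approx(0.0, abs=1e-9)
        assert diag.dic == pytest.approx(diag.dbar, abs=1e-9)


class TestRecovery:
    def test_degenerate_noise_concentrates_on_generating_line(self):
        truth = TruthParams(beta=(40.0, 2.0), Sigma=np.zeros((2, 2)), sigma_w=0.05)
        cfg = GeneratorConfig(n_subjects=40, seed=8, entry="all", truth=truth)
        ds = simulate_cohort(cfg).dataset
        draws, _ = fit_growth_model(ds, n_chains=2, n_iter=500, n_burnin=200,
                                    seed=2, compute_dic=False)
        s = draws.summary()
        for name, target in (("beta0", 40.0), ("beta1", 2.0)):
            assert abs(s.loc[name, "median"] - target) < 2 * s.loc[name, "sd"] + 0.01

    def test_linear_truth_recovery_and_mixing(self, small_cohort, small_fit):
        draws, diag = small_fit
        s = draws.summary()
        truth = {"beta0": 37.5, "beta1": 2.19, "sigma0": 7.12,
                 "sigma1": 1.74, "rho01": 0.51, "sigma_w": 3.12}
        for name, v in truth.items():
            z = abs(s.loc[name, "median"] - v) / s.loc[name, "sd"]
            assert z < 3.0, f"{name}: z={z:.2f}"
        assert diag.max_rhat < 1.2

    def test_well_mixed_fit_has_low_rhat(self, small_cohort):
        draws, diag = fit_growth_model(
            small_cohort.dataset, n_chains=2, n_iter=3000, n_burnin=1000,
            seed=5, compute_dic=False,
        )
        assert diag.max_rhat <= 1.05

    def test_matches_reml_oracle(self, small_cohort):
        """Posterior medians agree with an independent REML mixed-model fit."""
        import statsmodels.formula.api as smf

        rows = []
        for s in small_cohort.dataset:
            for t, v in zip(s.times, s.values):
                rows.append({"sid": s.subject_id, "t": t, "y": v})
        import pandas as pd

        df = pd.DataFrame(rows)
        md = smf.mixedlm("y ~ t", df, groups=df["sid"], re_formula="~t")
        reml = md.fit(reml=True)
        draws, _ = fit_growth_model(small_cohort.dataset, n_chains=2,
                                    n_iter=1200, n_burnin=400, seed=11,
                                    compute_dic=False)
        s = draws.summary()
        assert s.loc["beta0", "median"] == pytest.approx(
            reml.params["Intercept"], abs=3 * reml.bse["Intercept"] + 0.05
        )
        assert s.loc["beta1", "median"] == pytest.approx(
            reml.params["t"], abs=3 * reml.bse["t"] + 0.05
        )
        assert s.loc["sigma_w", "median"] == pytest.approx(
            math.sqrt(reml.scale), rel=0.05
        )

    def test_covariate_effects_recovered(self):
        truth = TruthParams(gamma={"smoker": (2.5, 0.8)})
        cfg = GeneratorConfig(
            n_subjects=250, seed=33, entry="all", truth=truth,
            covariate_specs={"smoker": ("bernoulli", 0.5)},
        )
        ds = simulate_cohort(cfg).dataset
        draws, _ = fit_growth_model(
            ds, ModelSpec(covariate_names=("smoker",)),
            n_chains=2, n_iter=900, n_burnin=300, seed=44, compute_dic=False,
        )
        s = draws.summary()
        for name, v in (("gamma_smoker_intercept", 2.5), ("gamma_smoker_slope", 0.8)):
            z = abs(s.loc[name, "median"] - v) / s.loc[name, "sd"]
            assert z < 3.0, f"{name}: z={z:.2f}"

    def test_single_subject_two_points_runs_with_shrinkage(self):
        ds = LongitudinalDataset(subjects=(make_subject([0.0, 1.0], [40.0, 49.0]),))
        draws, _ = fit_growth_model(ds, n_chains=2, n_iter=400, n_burnin=100,
                                    seed=3, compute_dic=False)
        # the population slope absorbs the trend; the subject's random effect
        # is shrunk hard toward the population prior mean of zero
        assert abs(np.median(draws.b[:, 0, 1])) < 1.0
        assert abs(np.median(draws.b[:, 0, 0])) < 2.0

    def test_sigma_draws_positive_definite(self, small_fit):
        draws, _ = small_fit
        eigvals = np.linalg.eigvalsh(draws.Sigma)
        assert np.all(eigvals > 0)


class TestIndependentIntercepts:
    def test_no_shrinkage_widens_intercept_spread(self, small_cohort):
        d2, _ = fit_growth_model(
            small_cohort.dataset, ModelSpec(intercept_model="independent"),
            n_chains=2, n_iter=1200, n_burnin=400, seed=21, compute_dic=False,
        )
        d1, _ = fit_growth_model(
            small_cohort.dataset, ModelSpec(),
            n_chains=2, n_iter=1200, n_burnin=400, seed=21, compute_dic=False,
        )
        emp_sd_l2 = float(np.median(np.sqrt(d2.Sigma[:, 0, 0])))
        sd_l1 = float(np.median(np.sqrt(d1.Sigma[:, 0, 0])))
        assert emp_sd_l2 >= sd_l1

    def test_lambda_within_prior_bounds(self, small_cohort):
        d2, _ = fit_growth_model(
            small_cohort.dataset, ModelSpec(intercept_model="independent"),
            n_chains=2, n_iter=600, n_burnin=200, seed=22, compute_dic=False,
        )
        assert np.all((d2.lam >= -5.0) & (d2.lam <= 5.0))


class TestCalibration:
    def test_nominal_interval_coverage(self):
        """Reduced simulation-based calibration: 90% posterior intervals for
        the mean slope cover the generating value at near-nominal rate."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = GeneratorConfig(n_subjects=100, seed=80_000 + rep, entry="all",
                                  truth=TruthParams())
            ds = simulate_cohort(cfg).dataset
            draws, _ = fit_growth_model(ds, n_chains=1, n_iter=2000, n_burnin=500,
                                        seed=rep, compute_dic=False)
            lo, hi = np.quantile(draws.beta[:, 1], [0.05, 0.95])
            hits += lo <= 2.19 <= hi
        assert 0.85 <= hits / n_rep <= 0.95


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        m = GrowthModel(trend="quadratic", n_iter=500)
        params = m.get_params()
        assert params["trend"] == "quadratic"
        m.set_params(n_iter=800)
        assert m.n_iter == 800

    def test_fit_from_dataframe(self, small_cohort):
        df = small_cohort.dataset.to_frame()
        m = GrowthModel(n_iter=300, n_burnin=100, random_state=1,
                        compute_dic=False).fit(df)
        assert hasattr(m, "draws_")
        assert m.summary_.loc["beta1", "median"] == pytest.approx(2.19, abs=0.6)

    def test_invalid_input_type(self):
        with pytest.raises(TypeError):
            GrowthModel().fit([1, 2, 3])
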