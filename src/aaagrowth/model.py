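"""Bayesian hierarchical growth models fit by blocked Gibbs sampling.

The observation model for subject i at time t_ij is

    y_ij = x_ij'(beta + b_i) + w_ij' gamma + eps_ij,

with x_ij = (1, t_ij) for a linear trend or (1, t_ij, t_ij^2) for a quadratic
one, subject random effects b_i ~ MVN(0, Sigma), covariate design
w_ij = (z_i, t_ij z_i[, t_ij^2 z_i]) for baseline covariates z_i, and
measurement errors eps_ij that are either Gaussian with SD sigma_w or scaled
Student-t with estimated degrees of freedom.  Variants:

* independent-intercept model: each subject's intercept is a free parameter
  with a flat prior (no shrinkage); the slope effect is Gaussian conditional
  on the intercept with regression coefficient lambda,
* left-censored model: screens known only to lie below a bound contribute a
  normal-CDF term to the likelihood, handled in the sampler by imputing the
  latent diameter from its truncated-normal conditional.

Priors follow common vague choices for these models: N(0, tau^2) with
tau = 1000 on fixed effects, IG(0.001, 0.001) on the error variance, an
inverse Wishart with dim(Sigma) + 1 degrees of freedom (uniform marginal
correlations) on Sigma, U(-5, 5) on lambda, U(0, 1000) on free intercepts and
U(2, 1000) on the t degrees of freedom.

All conditional updates are conjugate (normal / inverse-gamma / inverse-
Wishart) except the t degrees of freedom, sampled on a log-spaced grid, which
keeps every update unit-testable against its closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr, ndtri
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .data import LongitudinalDataset, dataset_from_frame

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "PosteriorDraws",
    "FitDiagnostics",
    "GrowthModel",
    "fit_growth_model",
    "log_likelihood",
    "rhat",
    "dic",
]

_EFFECT_NAMES = ("intercept", "slope", "curvature")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit.

    ``censor_bound`` switches on the left-censored likelihood for records
    known only to lie below that bound (mm).  The independent-intercept
    variant is defined for the linear trend without covariates; the t-error
    variant estimates its degrees of freedom.
    """

    trend: str = "linear"
    covariate_names: tuple[str, ...] = ()
    intercept_model: str = "shared_normal"
    error_family: str = "gaussian"
    censor_bound: float | None = None

    def __post_init__(self) -> None:
        if self.trend not in ("linear", "quadratic"):
            raise ValueError("trend must be 'linear' or 'quadratic'")
        if self.intercept_model not in ("shared_normal", "independent"):
            raise ValueError("intercept_model must be 'shared_normal' or 'independent'")
        if self.error_family not in ("gaussian", "student_t"):
            raise ValueError("error_family must be 'gaussian' or 'student_t'")
        if self.intercept_model == "independent":
            if self.trend != "linear":
                raise ValueError("independent intercepts are defined for the linear trend")
            if self.covariate_names:
                raise ValueError("independent-intercept model does not support covariates")
        if self.censor_bound is not None and self.error_family != "gaussian":
            raise ValueError("the censored likelihood is implemented for gaussian errors")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @property
    def q(self) -> int:
        return 3 if self.trend == "quadratic" else 2


@dataclass(frozen=True)
class PriorSpec:
    tau_fixed: float = 1000.0
    sigma_w_shape: float = 0.001
    sigma_w_rate: float = 0.001
    wishart_df_offset: float = 1.0
    wishart_scale: np.ndarray | None = None  # None -> 0.01 * identity
    lambda_bounds: tuple[float, float] = (-5.0, 5.0)
    intercept_bounds: tuple[float, float] = (0.0, 1000.0)
    df_bounds: tuple[float, float] = (2.0, 1000.0)

    def __post_init__(self) -> None:
        if min(self.tau_fixed, self.sigma_w_shape, self.sigma_w_rate) <= 0:
            raise ValueError("tau_fixed and IG hyperparameters must be positive")
        if self.df_bounds[0] < 2 or self.df_bounds[1] <= self.df_bounds[0]:
            raise ValueError("df_bounds must satisfy 2 <= lo < hi")


@dataclass
class FitDiagnostics:
    """Convergence and model-comparison summaries.

    ``dic = dbar + p_d`` with ``p_d = dbar - d_at_mean``; the deviance
    conditions on the subject random effects (the 'conditional focus'), which
    is why ``p_d`` is of the order of the number of subjects.
    """

    rhat: dict[str, float]
    dbar: float = math.nan
    p_d: float = math.nan
    dic: float = math.nan

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else math.nan


@dataclass
class PosteriorDraws:
    """MCMC draws of population parameters and subject random effects.

    ``beta`` has shape (K, q); ``b`` has shape (K, n_subjects, q) and holds
    deviations from the population curve, so a subject's curve coefficients in
    draw k are ``beta[k] + b[k, i] + (covariate terms)``.  For the
    independent-intercept model ``beta[:, 0]`` is the per-draw empirical mean
    intercept and ``Sigma`` the per-draw empirical covariance of (intercept,
    slope effect); ``lam``/``mu_alpha``/``sigma_cond`` carry the conditional-
    slope parameters.
    """

    spec: ModelSpec
    prior: PriorSpec
    subject_ids: tuple[str, ...]
    beta: np.ndarray
    Sigma: np.ndarray
    sigma_w: np.ndarray
    b: np.ndarray
    chain: np.ndarray
    gamma: np.ndarray | None = None
    nu: np.ndarray | None = None
    lam: np.ndarray | None = None
    mu_alpha: np.ndarray | None = None
    sigma_cond: np.ndarray | None = None
    n_chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def gamma_names(self) -> tuple[str, ...]:
        q = self.spec.q
        return tuple(
            f"gamma_{name}_{_EFFECT_NAMES[k]}"
            for name in self.spec.covariate_names
            for k in range(q)
        )

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Named scalar parameter traces (pooled over chains, in chain order)."""
        out: dict[str, np.ndarray] = {}
        q = self.spec.q
        for k in range(q):
            out[f"beta{k}"] = self.beta[:, k]
        if self.gamma is not None:
            for j, name in enumerate(self.gamma_names):
                out[name] = self.gamma[:, j]
        for k in range(q):
            out[f"sigma{k}"] = np.sqrt(self.Sigma[:, k, k])
        for k in range(q):
            for l in range(k + 1, q):
                denom = np.sqrt(self.Sigma[:, k, k] * self.Sigma[:, l, l])
                out[f"rho{k}{l}"] = np.where(denom > 0, self.Sigma[:, k, l] / denom, 0.0)
        out["sigma_w"] = self.sigma_w
        if self.nu is not None:
            out["nu"] = self.nu
        if self.lam is not None:
            out["lambda"] = self.lam
        return out

    def per_chain(self, series: np.ndarray) -> np.ndarray:
        return series.reshape(self.n_chains, -1)

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"subject {subject_id!r} not in fitted cohort") from None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in self.scalar_series().items():
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "q2.5": float(np.quantile(x, 0.025)),
                    "q97.5": float(np.quantile(x, 0.975)),
                    "rhat": rhat(self.per_chain(x)) if self.n_chains > 1 else math.nan,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self, include_random_effects: bool = False) -> pd.DataFrame:
        """Long-format table (parameter, chain, iteration, value)."""
        per_chain_n = self.n_draws // self.n_chains
        it = np.tile(np.arange(per_chain_n), self.n_chains)
        frames = []
        for name, x in self.scalar_series().items():
            frames.append(
                pd.DataFrame(
                    {"parameter": name, "chain": self.chain, "iteration": it, "value": x}
                )
            )
        if include_random_effects:
            for i, sid in enumerate(self.subject_ids):
                for k in range(self.spec.q):
                    frames.append(
                        pd.DataFrame(
                            {
                                "parameter": f"b_{_EFFECT_NAMES[k]}[{sid}]",
                                "chain": self.chain,
                                "iteration": it,
                                "value": self.b[:, i, k],
                            }
                        )
                    )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _FitData:
    subject_ids: tuple[str, ...]
    subj: np.ndarray  # (N,) subject index per observation
    t: np.ndarray
    y: np.ndarray  # observed value; NaN for censored records
    cens: np.ndarray  # bool mask
    bound: np.ndarray  # censoring bound where cens
    X: np.ndarray  # (N, q) trend design
    F: np.ndarray  # (N, q + p*q) fixed-effect design [X, W]
    n: int
    N: int


def _prepare(dataset: LongitudinalDataset, spec: ModelSpec) -> _FitData:
    subject_ids = tuple(s.subject_id for s in dataset)
    subj, t, y, cens, bound = [], [], [], [], []
    for i, s in enumerate(dataset):
        for m in s.measurements:
            if m.is_censored and spec.censor_bound is None:
                raise ValueError(
                    f"dataset contains censored records (subject {s.subject_id!r}) "
                    "but the model has censoring off"
                )
            subj.append(i)
            t.append(m.time)
            y.append(np.nan if m.is_censored else m.value)
            cens.append(m.is_censored)
            bound.append(m.censored_below if m.is_censored else np.nan)
    subj = np.asarray(subj, dtype=np.intp)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    cens = np.asarray(cens, dtype=bool)
    bound = np.asarray(bound, dtype=float)

    q = spec.q
    X = np.column_stack([np.ones_like(t), t, t**2][:q])
    cols = [X]
    if spec.covariate_names:
        n = len(subject_ids)
        Z = np.empty((n, len(spec.covariate_names)))
        for i, s in enumerate(dataset):
            for j, name in enumerate(spec.covariate_names):
                if name not in s.covariates:
                    raise ValueError(
                        f"subject {s.subject_id!r} is missing covariate {name!r}"
                    )
                Z[i, j] = s.covariates[name]
        for j in range(Z.shape[1]):
            cols.append(X * Z[subj, j][:, None])
    F = np.concatenate(cols, axis=1)
    return _FitData(
        subject_ids=subject_ids, subj=subj, t=t, y=y, cens=cens, bound=bound,
        X=X, F=F, n=len(subject_ids), N=len(t),
    )


def _subject_crossprods(data: _FitData, weights: np.ndarray | None) -> np.ndarray:
    """Per-subject (weighted) X'X, shape (n, q, q)."""
    q = data.X.shape[1]
    out = np.empty((data.n, q, q))
    w = weights if weights is not None else np.ones(data.N)
    for k in range(q):
        for l in range(k, q):
            s = np.bincount(data.subj, weights=w * data.X[:, k] * data.X[:, l],
                            minlength=data.n)
            out[:, k, l] = s
            out[:, l, k] = s
    return out


def _segment_outer(data: _FitData, A: np.ndarray, B: np.ndarray,
                   weights: np.ndarray | None) -> np.ndarray:
    """Per-subject weighted cross-products sum_j w_j a_j b_j', shape (n, dA, dB)."""
    dA, dB = A.shape[1], B.shape[1]
    out = np.empty((data.n, dA, dB))
    w = weights if weights is not None else None
    for k in range(dA):
        col = A[:, k] if w is None else A[:, k] * w
        for l in range(dB):
            out[:, k, l] = np.bincount(data.subj, weights=col * B[:, l],
                                       minlength=data.n)
    return out


def _segment_vec(data: _FitData, A: np.ndarray, y: np.ndarray,
                 weights: np.ndarray | None) -> np.ndarray:
    """Per-subject weighted sums sum_j w_j a_j y_j, shape (n, dA)."""
    out = np.empty((data.n, A.shape[1]))
    w = y if weights is None else y * weights
    for k in range(A.shape[1]):
        out[:, k] = np.bincount(data.subj, weights=A[:, k] * w, minlength=data.n)
    return out


def _truncated_normal_below(mean, sd, upper, rng):
    """Draws from N(mean, sd^2) truncated to (-inf, upper), vectorised."""
    p = np.clip(ndtr((upper - mean) / sd), 1e-300, 1.0)
    u = rng.uniform(low=1e-12, high=1.0, size=np.shape(mean))
    return mean + sd * ndtri(u * p)


def _sample_mvn_batch(prec, rhs, rng):
    """For each i, draw from MVN with precision prec[i] and mean prec[i]^-1 rhs[i]."""
    try:
        cov = np.linalg.inv(prec)
    except np.linalg.LinAlgError:
        prec = prec + 1e-8 * np.eye(prec.shape[-1])
        cov = np.linalg.inv(prec)
    mean = np.einsum("nkl,nl->nk", cov, rhs)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e-10 * np.eye(cov.shape[-1])
        L = np.linalg.cholesky(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("nkl,nl->nk", L, z)


def _sample_mvn(prec, rhs, rng):
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(len(rhs))
    from scipy.linalg import solve_triangular

    return mean + solve_triangular(L.T, z, lower=False)


# ---------------------------------------------------------------------------
# Gibbs samplers
# ---------------------------------------------------------------------------

_NU_GRID = np.geomspace(2.01, 1000.0, 600)
_NU_LOG_WIDTH = np.log(np.gradient(_NU_GRID))


def _sample_nu(omega: np.ndarray, rng: np.random.Generator,
               bounds: tuple[float, float]) -> float:
    """Grid update of the t degrees of freedom given latent scale weights.

    The conditional density is prod_j Gamma(omega_j; nu/2, nu/2) times a flat
    prior on nu in ``bounds``; sampled on a fixed log-spaced grid with cell
    widths folded in.
    """
    N = omega.size
    slog = float(np.sum(np.log(omega)))
    ssum = float(np.sum(omega))
    half = _NU_GRID / 2.0
    logp = N * (half * np.log(half) - gammaln(half)) + (half - 1.0) * slog - half * ssum
    logp = logp + _NU_LOG_WIDTH
    mask = (_NU_GRID >= bounds[0]) & (_NU_GRID <= bounds[1])
    logp[~mask] = -np.inf
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(rng.choice(_NU_GRID, p=p))


def _gibbs_shared(data: _FitData, spec: ModelSpec, prior: PriorSpec,
                  n_iter: int, n_burnin: int, rng: np.random.Generator):
    """One chain of the shared-normal-intercept sampler (L1/Q1, covariates,
    t errors, censoring)."""
    q = spec.q
    d = data.F.shape[1]
    n, N = data.n, data.N
    student = spec.error_family == "student_t"
    censored = data.cens.any()

    # working response: censored records imputed each sweep
    y = data.y.copy()
    if censored:
        y[data.cens] = data.bound[data.cens] - 1.0

    # initial values from pooled least squares + per-subject intercept residuals
    theta, *_ = np.linalg.lstsq(data.F, y, rcond=None)
    r = y - data.F @ theta
    b = np.zeros((n, q))
    counts = np.maximum(np.bincount(data.subj, minlength=n), 1)
    b[:, 0] = np.bincount(data.subj, weights=r, minlength=n) / counts
    Sigma = np.eye(q) * [25.0, 1.0, 0.05][:q]
    Sigma[0, 0] = max(np.var(b[:, 0]), 1.0)
    sigw2 = max(float(np.var(r - b[data.subj, 0])), 0.25)
    omega = np.ones(N)
    nu = 10.0

    # default scale 0.01 I: with df = dim + 1 a small scale keeps the prior
    # genuinely vague for variance components far below 1 (curvature SDs are
    # ~0.1 mm/yr^2, where an identity scale would be strongly informative)
    S0 = prior.wishart_scale if prior.wishart_scale is not None else 0.01 * np.eye(q)
    df0 = prior.wishart_df_offset + q
    tau2 = prior.tau_fixed**2

    keep = n_iter - n_burnin
    out = {
        "beta": np.empty((keep, q)),
        "gamma": np.empty((keep, d - q)) if d > q else None,
        "Sigma": np.empty((keep, q, q)),
        "sigma_w": np.empty(keep),
        "nu": np.empty(keep) if student else None,
        "b": np.empty((keep, n, q), dtype=np.float32),
    }

    # per-subject cross-products; constant unless reweighted (t errors) or the
    # working response changes (censoring imputation)
    XtX_const = _subject_crossprods(data, None)
    FtX_const = _segment_outer(data, data.F, data.X, None)
    FtF_const = (data.F.T @ data.F)
    Fty_const = _segment_vec(data, data.F, y, None)
    Xty_const = _segment_vec(data, data.X, y, None)

    for it in range(n_iter):
        mu_pop = data.F @ theta

        if censored:
            mean_c = mu_pop[data.cens] + np.einsum(
                "nk,nk->n", data.X[data.cens], b[data.subj[data.cens]]
            )
            y[data.cens] = _truncated_normal_below(
                mean_c, math.sqrt(sigw2), data.bound[data.cens], rng
            )

        # latent t scale weights
        if student:
            Xb = np.einsum("nk,nk->n", data.X, b[data.subj])
            r = y - mu_pop - Xb
            omega = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + r * r / sigw2))

        refresh = student or censored
        w = omega if student else None
        XtX = _subject_crossprods(data, w) if student else XtX_const
        FtX = _segment_outer(data, data.F, data.X, w) if student else FtX_const
        Fty = _segment_vec(data, data.F, y, w) if refresh else Fty_const
        Xty = _segment_vec(data, data.X, y, w) if refresh else Xty_const
        Sigma_inv = np.linalg.inv(Sigma)

        # fixed effects, with the random effects integrated out:
        # per subject, V_i^-1 = (sigw2 I + X_i Sigma X_i')^-1 via Woodbury
        M = np.linalg.inv(sigw2 * Sigma_inv[None, :, :] + XtX)  # (n, q, q)
        FtXM = np.einsum("ndq,nqr->ndr", FtX, M)
        if student:
            FtWF = (data.F * omega[:, None]).T @ data.F
        else:
            FtWF = FtF_const
        A = (FtWF - np.einsum("ndq,neq->de", FtXM, FtX)) / sigw2
        A = A + np.eye(d) / tau2
        rhs_f = (Fty.sum(axis=0) - np.einsum("ndq,nq->d", FtXM, Xty)) / sigw2
        theta = _sample_mvn(A, rhs_f, rng)

        # subject random effects given the fixed effects
        rhs_b = (Xty - np.einsum("ndq,d->nq", FtX, theta)) / sigw2
        prec = Sigma_inv[None, :, :] + XtX / sigw2
        b = _sample_mvn_batch(prec, rhs_b, rng)

        # error variance
        Xb = np.einsum("nk,nk->n", data.X, b[data.subj])
        r = y - Xb - data.F @ theta
        ssq = float(np.sum(omega * r * r)) if student else float(np.sum(r * r))
        sigw2 = 1.0 / rng.gamma(prior.sigma_w_shape + 0.5 * N,
                                1.0 / (prior.sigma_w_rate + 0.5 * ssq))

        # random-effect covariance
        S = S0 + b.T @ b
        Sigma = invwishart.rvs(df=df0 + n, scale=S, random_state=rng)
        Sigma = np.atleast_2d(Sigma)

        # t degrees of freedom
        if student:
            nu = _sample_nu(omega, rng, prior.df_bounds)

        if it >= n_burnin:
            j = it - n_burnin
            out["beta"][j] = theta[:q]
            if out["gamma"] is not None:
                out["gamma"][j] = theta[q:]
            out["Sigma"][j] = Sigma
            out["sigma_w"][j] = math.sqrt(sigw2)
            if student:
                out["nu"][j] = nu
            out["b"][j] = b
    return out


def _gibbs_independent(data: _FitData, spec: ModelSpec, prior: PriorSpec,
                       n_iter: int, n_burnin: int, rng: np.random.Generator):
    """One chain of the independent-intercept sampler (linear trend).

    Intercepts alpha_i carry flat priors; slope effects u_i are Gaussian
    conditional on the intercept: u_i ~ N(lambda (alpha_i - mu_alpha),
    sigma_cond^2), with lambda ~ U(lambda_bounds) and a vague normal prior on
    the centring level mu_alpha.
    """
    n, N = data.n, data.N
    y = data.y.copy()
    t = data.t
    tau2 = prior.tau_fixed**2
    lam_lo, lam_hi = prior.lambda_bounds

    counts = np.maximum(np.bincount(data.subj, minlength=n), 1)
    alpha = np.bincount(data.subj, weights=y, minlength=n) / counts
    u = np.zeros(n)
    beta1 = 2.0
    lam = 0.0
    mu_a = float(np.mean(alpha))
    sig2c = 1.0
    sigw2 = max(float(np.var(y - alpha[data.subj])), 0.25)

    keep = n_iter - n_burnin
    out = {
        "beta": np.empty((keep, 2)),
        "Sigma": np.empty((keep, 2, 2)),
        "sigma_w": np.empty(keep),
        "lam": np.empty(keep),
        "mu_alpha": np.empty(keep),
        "sigma_cond": np.empty(keep),
        "b": np.empty((keep, n, 2), dtype=np.float32),
        "alpha_mean": np.empty(keep),
    }

    s1 = np.bincount(data.subj, minlength=n).astype(float)
    st = np.bincount(data.subj, weights=t, minlength=n)
    stt = np.bincount(data.subj, weights=t * t, minlength=n)
    sy = np.bincount(data.subj, weights=y, minlength=n)

    for it in range(n_iter):
        # joint (alpha_i, u_i) update
        r = y - beta1 * t
        sr = np.bincount(data.subj, weights=r, minlength=n)
        str_ = np.bincount(data.subj, weights=t * r, minlength=n)
        prec = np.empty((n, 2, 2))
        prec[:, 0, 0] = s1 / sigw2 + lam * lam / sig2c
        prec[:, 0, 1] = prec[:, 1, 0] = st / sigw2 - lam / sig2c
        prec[:, 1, 1] = stt / sigw2 + 1.0 / sig2c
        c = lam * mu_a
        rhs = np.empty((n, 2))
        rhs[:, 0] = sr / sigw2 + lam * c / sig2c
        rhs[:, 1] = str_ / sigw2 - c / sig2c
        au = _sample_mvn_batch(prec, rhs, rng)
        alpha, u = au[:, 0], au[:, 1]

        # population slope
        r = y - alpha[data.subj] - u[data.subj] * t
        A = float(np.sum(t * t)) / sigw2 + 1.0 / tau2
        m = float(np.sum(t * r)) / sigw2 / A
        beta1 = m + rng.standard_normal() / math.sqrt(A)

        # conditional-slope regression coefficient, truncated to its bounds
        x = alpha - mu_a
        sxx = float(np.sum(x * x))
        if sxx > 0:
            mlam = float(np.sum(x * u)) / sxx
            slam = math.sqrt(sig2c / sxx)
            plo, phi = ndtr((lam_lo - mlam) / slam), ndtr((lam_hi - mlam) / slam)
            uu = rng.uniform(plo + 1e-12, max(phi, plo + 2e-12))
            lam = mlam + slam * ndtri(min(max(uu, 1e-12), 1 - 1e-12))
            lam = min(max(lam, lam_lo), lam_hi)

        # centring level
        A_mu = n * lam * lam / sig2c + 1.0 / tau2
        B_mu = (lam / sig2c) * float(np.sum(lam * alpha - u))
        mu_a = B_mu / A_mu + rng.standard_normal() / math.sqrt(A_mu)

        # conditional slope variance
        dev = u - lam * (alpha - mu_a)
        sig2c = 1.0 / rng.gamma(0.001 + 0.5 * n, 1.0 / (0.001 + 0.5 * float(dev @ dev)))

        # error variance
        r = y - alpha[data.subj] - (beta1 + u[data.subj]) * t
        sigw2 = 1.0 / rng.gamma(prior.sigma_w_shape + 0.5 * N,
                                1.0 / (prior.sigma_w_rate + 0.5 * float(r @ r)))

        if it >= n_burnin:
            j = it - n_burnin
            am = float(np.mean(alpha))
            out["alpha_mean"][j] = am
            out["beta"][j] = (am, beta1)
            dev0 = alpha - am
            dev1 = u - float(np.mean(u))
            C = np.cov(np.vstack([dev0, dev1]), ddof=1)
            out["Sigma"][j] = C
            out["sigma_w"][j] = math.sqrt(sigw2)
            out["lam"][j] = lam
            out["mu_alpha"][j] = mu_a
            out["sigma_cond"][j] = math.sqrt(sig2c)
            out["b"][j, :, 0] = dev0
            out["b"][j, :, 1] = u
    return out


def fit_growth_model(
    dataset: LongitudinalDataset,
    spec: ModelSpec | None = None,
    prior: PriorSpec | None = None,
    n_chains: int = 2,
    n_iter: int = 10000,
    n_burnin: int = 500,
    seed: int | None = None,
    compute_dic: bool = True,
) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit a hierarchical growth model by Gibbs sampling.

    Runs ``n_chains`` independent chains of ``n_iter`` sweeps each, discarding
    ``n_burnin`` as burn-in, and returns pooled draws with convergence
    (potential scale reduction) and deviance (DIC) diagnostics.
    """
    spec = spec or ModelSpec()
    prior = prior or PriorSpec()
    if n_burnin >= n_iter:
        raise ValueError("n_burnin must be smaller than n_iter")
    data = _prepare(dataset, spec)
    if data.cens.any() and spec.censor_bound is None:  # pragma: no cover
        raise ValueError("censored records present but censoring off")

    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(seed or 0, spawn_key=(c,)))
        if spec.intercept_model == "independent":
            chains.append(_gibbs_independent(data, spec, prior, n_iter, n_burnin, rng))
        else:
            chains.append(_gibbs_shared(data, spec, prior, n_iter, n_burnin, rng))

    keep = n_iter - n_burnin

    def stack(key):
        if chains[0].get(key) is None:
            return None
        return np.concatenate([ch[key] for ch in chains], axis=0)

    draws = PosteriorDraws(
        spec=spec,
        prior=prior,
        subject_ids=data.subject_ids,
        beta=stack("beta"),
        gamma=stack("gamma") if spec.intercept_model == "shared_normal" else None,
        Sigma=stack("Sigma"),
        sigma_w=stack("sigma_w"),
        b=stack("b"),
        nu=stack("nu") if spec.error_family == "student_t" else None,
        lam=stack("lam") if spec.intercept_model == "independent" else None,
        mu_alpha=stack("mu_alpha") if spec.intercept_model == "independent" else None,
        sigma_cond=stack("sigma_cond") if spec.intercept_model == "independent" else None,
        chain=np.repeat(np.arange(n_chains), keep),
        n_chains=n_chains,
    )

    rhats: dict[str, float] = {}
    if n_chains >= 2 and keep >= 10:
        for name, x in draws.scalar_series().items():
            rhats[name] = rhat(draws.per_chain(x))
    diag = FitDiagnostics(rhat=rhats)
    if compute_dic:
        diag = dic(draws, dataset, diagnostics=diag)
    return draws, diag


# ---------------------------------------------------------------------------
# likelihood, DIC, convergence
# ---------------------------------------------------------------------------


def _loglik_terms(y, mean, sigma_w, cens, bound, error_family, nu):
    """Per-observation conditional log density; censored records contribute
    the lower-tail mass below their bound."""
    out = np.empty(len(mean))
    obs = ~cens
    r = y[obs] - mean[obs]
    if error_family == "student_t":
        half = (nu + 1.0) / 2.0
        out[obs] = (
            gammaln(half)
            - gammaln(nu / 2.0)
            - 0.5 * math.log(nu * math.pi * sigma_w**2)
            - half * np.log1p(r * r / (nu * sigma_w**2))
        )
    else:
        out[obs] = -0.5 * math.log(2 * math.pi * sigma_w**2) - r * r / (2 * sigma_w**2)
    if cens.any():
        z = (bound[cens] - mean[cens]) / sigma_w
        out[cens] = np.log(np.clip(ndtr(z), 1e-300, 1.0))
    return out


def log_likelihood(
    draws: PosteriorDraws,
    dataset: LongitudinalDataset,
    indices: np.ndarray | None = None,
    chunk: int = 200,
) -> np.ndarray:
    """Conditional log likelihood log p(y | beta, gamma, b, sigma_w[, nu])
    for each requested draw (all draws by default).

    This is the deviance scale used for DIC: the density of the observations
    given the subject random effects, with censored records contributing
    log Phi((bound - mean) / sigma_w).
    """
    data = _prepare(dataset, draws.spec)
    if tuple(data.subject_ids) != tuple(draws.subject_ids):
        raise ValueError("dataset subjects do not match the fitted draws")
    idx = np.arange(draws.n_draws) if indices is None else np.asarray(indices)
    out = np.empty(len(idx))
    for start in range(0, len(idx), chunk):
        sl = idx[start : start + chunk]
        theta = draws.beta[sl]
        if draws.gamma is not None and draws.gamma.size:
            theta = np.concatenate([theta, draws.gamma[sl]], axis=1)
        mu = theta @ data.F.T  # (C, N) — F columns are [X, W]
        bsub = draws.b[sl][:, data.subj, :].astype(float)  # (C, N, q)
        mu = mu + np.einsum("nk,cnk->cn", data.X, bsub)
        for j, k in enumerate(sl):
            nu_k = float(draws.nu[k]) if draws.nu is not None else None
            terms = _loglik_terms(
                data.y, mu[j], float(draws.sigma_w[k]), data.cens, data.bound,
                draws.spec.error_family, nu_k,
            )
            out[start + j] = float(np.sum(terms))
    return out


def dic(
    draws: PosteriorDraws,
    dataset: LongitudinalDataset,
    diagnostics: FitDiagnostics | None = None,
) -> FitDiagnostics:
    """Deviance information criterion with the conditional (subject-level)
    focus: Dbar is the posterior mean of -2 log p(y | theta, b) and the
    plug-in deviance is evaluated at the posterior means of theta and b."""
    ll = log_likelihood(draws, dataset)
    dbar = float(np.mean(-2.0 * ll))

    mean_draws = PosteriorDraws(
        spec=draws.spec,
        prior=draws.prior,
        subject_ids=draws.subject_ids,
        beta=draws.beta.mean(axis=0, keepdims=True),
        gamma=None if draws.gamma is None else draws.gamma.mean(axis=0, keepdims=True),
        Sigma=draws.Sigma.mean(axis=0, keepdims=True),
        sigma_w=np.array([draws.sigma_w.mean()]),
        b=draws.b.mean(axis=0, keepdims=True),
        nu=None if draws.nu is None else np.array([draws.nu.mean()]),
        chain=np.zeros(1, dtype=int),
        n_chains=1,
    )
    d_hat = float(-2.0 * log_likelihood(mean_draws, dataset)[0])
    p_d = dbar - d_hat
    diag = diagnostics or FitDiagnostics(rhat={})
    diag.dbar = dbar
    diag.p_d = p_d
    diag.dic = dbar + p_d
    return diag


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  This is the classic
    (non-rank-normalised) statistic, floored at 1 so that identical chains
    give exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("rhat requires at least 2 draws per chain")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    var_hat = (n - 1) / n * W + B_over_n
    return math.sqrt(max(var_hat / W, 1.0))


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


class GrowthModel(BaseEstimator):
    """Hierarchical growth-curve model with a scikit-learn estimator surface.

    Parameters
    ----------
    trend : 'linear' or 'quadratic'
        Shape of the population and subject-level mean curve.
    covariates : sequence of str
        Baseline covariate columns entering the intercept and slope (and
        curvature for a quadratic trend).
    intercept_model : 'shared_normal' or 'independent'
        'independent' frees each subject's intercept (no shrinkage).
    error_family : 'gaussian' or 'student_t'
        Measurement-error law; t degrees of freedom are estimated.
    censor_bound : float or None
        Bound (mm) below which left-censored screens are known only to lie.
    priors : PriorSpec or None
        Hyperparameters; defaults are vague.
    n_chains, n_iter, n_burnin : int
        MCMC protocol (defaults: 2 chains of 10000 sweeps, 500 burn-in).
    random_state : int or None
        Seed for all sampler randomness; fixed seed gives bit-identical draws.

    Attributes
    ----------
    draws_ : PosteriorDraws
    diagnostics_ : FitDiagnostics
    summary_ : pandas.DataFrame

    Examples
    --------
    >>> cohort = simulate_cohort(GeneratorConfig(n_subjects=50, seed=1)).dataset
    >>> model = GrowthModel(n_iter=1000, n_burnin=200, random_state=0).fit(cohort)
    >>> model.summary_.loc["beta1", "median"]  # population growth rate, mm/yr
    """

    def __init__(
        self,
        trend: str = "linear",
        covariates: tuple[str, ...] = (),
        intercept_model: str = "shared_normal",
        error_family: str = "gaussian",
        censor_bound: float | None = None,
        priors: PriorSpec | None = None,
        n_chains: int = 2,
        n_iter: int = 10000,
        n_burnin: int = 500,
        compute_dic: bool = True,
        random_state: int | None = None,
    ):
        self.trend = trend
        self.covariates = covariates
        self.intercept_model = intercept_model
        self.error_family = error_family
        self.censor_bound = censor_bound
        self.priors = priors
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.compute_dic = compute_dic
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            trend=self.trend,
            covariate_names=tuple(self.covariates),
            intercept_model=self.intercept_model,
            error_family=self.error_family,
            censor_bound=self.censor_bound,
        )

    def fit(self, X, y=None) -> "GrowthModel":
        """Fit to a cohort.

        ``X`` is a :class:`LongitudinalDataset` or a long-format DataFrame
        with columns ``subject_id``, ``time``, ``value`` (see
        :func:`aaagrowth.data.read_cohort`); ``y`` is ignored (the response is
        part of the longitudinal records).
        """
        if isinstance(X, pd.DataFrame):
            X = dataset_from_frame(X)
        if not isinstance(X, LongitudinalDataset):
            raise TypeError("X must be a LongitudinalDataset or a long-format DataFrame")
        self.draws_, self.diagnostics_ = fit_growth_model(
            X,
            spec=self._spec(),
            prior=self.priors,
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_burnin=self.n_burnin,
            seed=self.random_state,
            compute_dic=self.compute_dic,
        )
        self.summary_ = self.draws_.summary()
        self.n_subjects_ = len(self.draws_.subject_ids)
        return self

    def individual_posterior(self, subject, rng=None, reuse_stored: bool = False):
        """Random-effect draws for one subject under cut semantics.

        See :func:`aaagrowth.predict.cut_posterior`; with ``reuse_stored``
        the subject must be in the fitted cohort and its stored draws are
        returned instead.
        """
        from .predict import cut_posterior, stored_individual

        if reuse_stored:
            return stored_individual(self.draws_, subject)
        return cut_posterior(subject, self.draws_, rng=rng)
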