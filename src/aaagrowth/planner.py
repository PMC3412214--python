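"""Rescan-interval planning and predictive validation.

A monitoring policy limits the probability that the *next observed* diameter
is at or above the surgery-referral threshold (55 mm by default).  For a
given baseline diameter the planner finds the longest rescan interval whose
exceedance probability stays within a chosen risk limit (1%, 5% or 10% are
the conventional curves), and can tabulate the policy across a baseline grid.

Predictive calibration is checked the way screening programmes must: the
model's predicted proportion of diameters >= threshold at years 1..5 after
screening (from each individual's first k scans, treated as a new patient) is
compared against a multiply-imputed empirical proportion, where scans missing
near an anniversary — often *because* the subject was referred to surgery —
are filled in from the individual's all-data posterior predictive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, Measurement, Subject
from .model import PosteriorDraws
from .predict import (
    IndividualPosterior,
    cut_posterior,
    exceedance_profile,
    stored_individual,
)

__all__ = [
    "PolicyQuery",
    "IntervalRecommendation",
    "ValidationReport",
    "recommend_interval",
    "policy_curve",
    "validate_predictions",
]


@dataclass(frozen=True)
class PolicyQuery:
    """A planning question: how long until the next scan?

    ``baseline_value`` is a single screening diameter (mm) at t = 0; a full
    ``subject`` (with its measurement history and covariates) may be given
    instead.  ``risk_limit`` is the acceptable probability that the next
    observed diameter is >= ``threshold``.
    """

    baseline_value: float | None = None
    subject: Subject | None = None
    threshold: float = 55.0
    risk_limit: float = 0.01
    max_horizon: float = 10.0
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if (self.baseline_value is None) == (self.subject is None):
            raise ValueError("give exactly one of baseline_value / subject")
        if not (0.0 < self.risk_limit < 1.0):
            raise ValueError("risk_limit must be in (0, 1)")
        if self.grid_step <= 0 or self.max_horizon <= 0:
            raise ValueError("grid_step and max_horizon must be positive")

    def as_subject(self) -> Subject:
        if self.subject is not None:
            return self.subject
        return Subject(
            subject_id="query",
            measurements=(Measurement(time=0.0, value=self.baseline_value),),
        )


@dataclass(frozen=True)
class IntervalRecommendation:
    interval: float
    already_exceeded: bool
    prob_at_interval: float
    prob_immediate: float


def recommend_interval(
    query: PolicyQuery,
    population: PosteriorDraws,
    rng: np.random.Generator | None = None,
    individual: IndividualPosterior | None = None,
) -> IntervalRecommendation:
    """Longest horizon s in [0, max_horizon] with exceedance probability
    within the risk limit, refined by bisection to grid_step / 10.

    Returns interval 0 with ``already_exceeded`` set when even an immediate
    remeasurement would breach the limit.  The prediction time origin is the
    subject's last scan.
    """
    rng = rng if rng is not None else np.random.default_rng()
    subject = query.as_subject()
    if individual is None:
        individual = cut_posterior(subject, population, rng=rng)
    t0 = float(subject.times[-1])
    grid = np.arange(0.0, query.max_horizon + query.grid_step / 2, query.grid_step)
    probs = exceedance_profile(individual, grid, t=t0, alpha=query.threshold)

    if probs[0] > query.risk_limit:
        return IntervalRecommendation(
            interval=0.0, already_exceeded=True,
            prob_at_interval=float(probs[0]), prob_immediate=float(probs[0]),
        )
    over = np.nonzero(probs > query.risk_limit)[0]
    if len(over) == 0:
        return IntervalRecommendation(
            interval=float(query.max_horizon), already_exceeded=False,
            prob_at_interval=float(probs[-1]), prob_immediate=float(probs[0]),
        )
    j = over[0]
    lo, hi = grid[j - 1], grid[j]
    tol = query.grid_step / 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        p_mid = exceedance_profile(individual, np.array([mid]), t=t0,
                                   alpha=query.threshold)[0]
        if p_mid <= query.risk_limit:
            lo = mid
        else:
            hi = mid
    p_lo = exceedance_profile(individual, np.array([lo]), t=t0,
                              alpha=query.threshold)[0]
    return IntervalRecommendation(
        interval=float(lo), already_exceeded=False,
        prob_at_interval=float(p_lo), prob_immediate=float(probs[0]),
    )


def policy_curve(
    population: PosteriorDraws,
    baselines,
    risk_limits=(0.01, 0.05, 0.10),
    threshold: float = 55.0,
    max_horizon: float = 10.0,
    grid_step: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Recommended interval over a baseline-diameter grid and risk limits.

    One cut posterior is drawn per baseline and shared across risk limits, so
    within a limit the table is monotone non-increasing in baseline up to
    Monte-Carlo noise (a ``monotone_violation`` column flags residual noise).
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for baseline in baselines:
        query0 = PolicyQuery(
            baseline_value=float(baseline), threshold=threshold,
            risk_limit=min(risk_limits), max_horizon=max_horizon,
            grid_step=grid_step,
        )
        ind = cut_posterior(query0.as_subject(), population, rng=rng)
        for limit in risk_limits:
            q = PolicyQuery(
                baseline_value=float(baseline), threshold=threshold,
                risk_limit=float(limit), max_horizon=max_horizon,
                grid_step=grid_step,
            )
            rec = recommend_interval(q, population, rng=rng, individual=ind)
            rows.append(
                {
                    "baseline": float(baseline),
                    "risk_limit": float(limit),
                    "interval": rec.interval,
                    "already_exceeded": rec.already_exceeded,
                    "prob_at_interval": rec.prob_at_interval,
                }
            )
    df = pd.DataFrame(rows)
    df["monotone_violation"] = False
    for limit, grp in df.groupby("risk_limit"):
        grp = grp.sort_values("baseline")
        viol = grp["interval"].diff() > grid_step
        df.loc[grp.index, "monotone_violation"] = viol.fillna(False).to_numpy()
    return df


@dataclass
class ValidationReport:
    """Predicted vs multiply-imputed observed exceedance proportions.

    ``table`` has one row per (year, k): the model-predicted proportion of
    diameters >= threshold at that year using each subject's first k scans,
    the imputation-completed comparator proportion (identical across k), and
    the fraction of comparator cells that had to be imputed.
    """

    table: pd.DataFrame
    threshold: float
    n_subjects: int
    n_imputations: int
    notes: dict = field(default_factory=dict)

    def max_abs_gap(self) -> float:
        return float(
            (self.table["predicted_prop"] - self.table["comparator_prop"]).abs().max()
        )


def validate_predictions(
    analysis_population: PosteriorDraws,
    prediction_set: LongitudinalDataset,
    k_scans=(1, 2, 3),
    years=(1, 2, 3, 4, 5),
    window: float = 0.5,
    n_imputations: int = 100,
    threshold: float = 55.0,
    max_draws: int = 500,
    rng: np.random.Generator | None = None,
) -> ValidationReport:
    """Multiple-imputation check of predictive calibration.

    Predicted side: for each subject with at least k scans, a cut posterior
    is built from the first k scans only and the per-subject probability of
    an observed diameter >= ``threshold`` at each year is averaged over
    subjects.  Comparator side: per imputation, each subject contributes at
    year x their observed scan nearest x when one lies within ``window``
    years (ties to the earlier scan), otherwise a draw from their all-data
    posterior predictive; the >=threshold proportion is averaged over
    ``n_imputations`` imputed data sets.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pop = analysis_population
    years = list(years)
    subjects = list(prediction_set.subjects)
    if not subjects:
        raise ValueError("prediction set is empty")

    sub_idx = rng.choice(pop.n_draws, size=min(max_draws, pop.n_draws), replace=False)
    sub_idx.sort()
    pop_sub = _subset_draws(pop, sub_idx)

    # --- predicted proportions from first-k-scan cut posteriors; subjects
    # with fewer than k scans (e.g. early surgical exits) contribute all the
    # scans they have, keeping the prediction set identical to the comparator
    predicted: dict[tuple[int, int], float] = {}
    n_used: dict[int, int] = {}
    for k in k_scans:
        n_used[k] = len(subjects)
        per_year = np.zeros(len(years))
        for s in subjects:
            ind = cut_posterior(s.first_k(min(k, s.n_scans)), pop_sub, rng=rng)
            probs = exceedance_profile(ind, np.asarray(years, dtype=float),
                                       t=0.0, alpha=threshold)
            # profile takes horizons from t=0, i.e. absolute years since screening
            per_year += probs
        for j, x in enumerate(years):
            predicted[(x, k)] = per_year[j] / len(subjects)

    # --- multiply-imputed comparator (independent of k)
    imp_draw_idx = rng.integers(0, pop_sub.n_draws, size=n_imputations)
    comparator = np.zeros(len(years))
    imputed_frac = np.zeros(len(years))
    all_inds: list[IndividualPosterior] = []
    in_sample = set(pop.subject_ids) >= {s.subject_id for s in subjects}
    for s in subjects:
        if in_sample:
            all_inds.append(stored_individual(pop_sub, s))
        else:
            all_inds.append(cut_posterior(s, pop_sub, rng=rng))

    # precompute each subject's per-draw underlying level at every year
    levels = np.empty((len(subjects), len(years), pop_sub.n_draws))
    for i, ind in enumerate(all_inds):
        for j, x in enumerate(years):
            levels[i, j] = ind.level(float(x))

    for j, x in enumerate(years):
        observed_vals = np.full(len(subjects), np.nan)
        for i, s in enumerate(subjects):
            times = s.times
            d = np.abs(times - x)
            order = np.lexsort((times, d))  # ties to the earlier scan
            best = order[0]
            if d[best] <= window:
                observed_vals[i] = s.values[best]
        missing = np.isnan(observed_vals)
        imputed_frac[j] = float(np.mean(missing))
        prop_obs = float(np.sum(observed_vals[~missing] >= threshold))
        miss_idx = np.nonzero(missing)[0]
        prop_sum = 0.0
        for m in range(n_imputations):
            kdraw = int(imp_draw_idx[m])
            n_ge = prop_obs
            if len(miss_idx):
                lev = levels[miss_idx, j, kdraw]
                if pop_sub.spec.error_family == "student_t":
                    err = pop_sub.sigma_w[kdraw] * rng.standard_t(
                        float(pop_sub.nu[kdraw]), size=len(miss_idx)
                    )
                else:
                    err = pop_sub.sigma_w[kdraw] * rng.standard_normal(len(miss_idx))
                n_ge += float(np.sum(lev + err >= threshold))
            prop_sum += n_ge / len(subjects)
        comparator[j] = prop_sum / n_imputations

    rows = []
    for x in years:
        for k in k_scans:
            rows.append(
                {
                    "year": x,
                    "k_scans": k,
                    "predicted_prop": predicted[(x, k)],
                    "comparator_prop": comparator[years.index(x)],
                    "imputed_frac": imputed_frac[years.index(x)],
                    "n_subjects_predicted": n_used[k],
                }
            )
    return ValidationReport(
        table=pd.DataFrame(rows),
        threshold=threshold,
        n_subjects=len(subjects),
        n_imputations=n_imputations,
    )


def _subset_draws(pop: PosteriorDraws, idx: np.ndarray) -> PosteriorDraws:
    def take(x):
        return None if x is None else x[idx]

    return PosteriorDraws(
        spec=pop.spec,
        prior=pop.prior,
        subject_ids=pop.subject_ids,
        beta=pop.beta[idx],
        gamma=take(pop.gamma),
        Sigma=pop.Sigma[idx],
        sigma_w=pop.sigma_w[idx],
        b=pop.b[idx],
        nu=take(pop.nu),
        lam=take(pop.lam),
        mu_alpha=take(pop.mu_alpha),
        sigma_cond=take(pop.sigma_cond),
        chain=pop.chain[idx],
        n_chains=pop.n_chains,
    )
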