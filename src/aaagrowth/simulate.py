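"""Synthetic surveillance cohorts with known ground truth.

Emulates the structure of a national aneurysm-screening cohort: subjects enter
when their first ultrasound measures 30-54 mm, are rescanned at an interval
set by the last observed diameter (yearly under 45 mm, three-monthly at
45-54 mm), and their series terminate at the first of surgery referral
(observed diameter >= 55 mm or rapid expansion), death, loss to follow-up, or
the administrative end of the study.  Underlying growth follows a linear or
quadratic mixed-effects curve with subject-specific random effects; the
generating parameters are returned alongside the cohort so that estimators can
be tested for parameter recovery.

Entry selection on the observed first diameter is a property of the screening
programme, not of the growth model, so it is switchable: ``entry="observed_band"``
reproduces the programme's inclusion rule (rejection-sampling subjects until
the first scan falls in band), while ``entry="all"`` keeps every simulated
subject, which makes the generating model and the fitted model coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import LongitudinalDataset, Measurement, Subject

__all__ = [
    "TruthParams",
    "ScheduleRule",
    "DropoutRule",
    "GeneratorConfig",
    "SimulatedCohort",
    "draw_subject_effects",
    "simulate_subject",
    "simulate_cohort",
]

_MAX_SCANS = 200


def _sqrt_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix; rejects indefinite input."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-10 * max(1.0, vals.max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    return vecs @ (np.sqrt(vals)[:, None] * vecs.T)


def build_covariance(sigmas, correlations=None) -> np.ndarray:
    """Assemble a covariance matrix from SDs and pairwise correlations.

    ``correlations`` lists the upper-triangular entries row by row, e.g.
    ``(rho01,)`` for 2x2 or ``(rho01, rho02, rho12)`` for 3x3.
    """
    s = np.asarray(sigmas, dtype=float)
    q = len(s)
    R = np.eye(q)
    if correlations is not None:
        idx = [(k, l) for k in range(q) for l in range(k + 1, q)]
        if len(correlations) != len(idx):
            raise ValueError(f"expected {len(idx)} correlations, got {len(correlations)}")
        for (k, l), r in zip(idx, correlations):
            R[k, l] = R[l, k] = r
    return R * np.outer(s, s)


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of the hierarchical growth model.

    ``beta`` is the population mean curve: (intercept, slope) for a linear
    trend or (intercept, slope, curvature) for a quadratic one, in mm, mm/yr
    and mm/yr^2.  ``Sigma`` is the random-effect covariance.  ``gamma`` maps a
    covariate name to its effects on intercept, slope (and curvature), matching
    the covariate design used at fit time.  ``sigma_w`` is the within-subject
    measurement-error scale in mm; errors are Gaussian or scaled Student-t.
    ``baseline_law`` chooses the marginal law of the baseline random intercept:
    ``"normal"`` (the model's own assumption) or ``"skew_gamma"`` (a shifted
    gamma producing the right-skewed baseline histogram seen in screening
    cohorts, with the slope effect drawn from the usual Gaussian conditional).
    """

    beta: tuple[float, ...] = (37.5, 2.19)
    Sigma: np.ndarray = field(
        default_factory=lambda: build_covariance((7.12, 1.74), (0.51,))
    )
    sigma_w: float = 3.12
    gamma: dict[str, tuple[float, ...]] = field(default_factory=dict)
    error_family: str = "gaussian"
    error_df: float | None = None
    baseline_law: str = "normal"

    def __post_init__(self) -> None:
        q = len(self.beta)
        if q not in (2, 3):
            raise ValueError("beta must have 2 (linear) or 3 (quadratic) entries")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (q, q):
            raise ValueError(f"Sigma must be {q}x{q}, got {S.shape}")
        if not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric")
        object.__setattr__(self, "Sigma", S)
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be non-negative")
        if self.error_family not in ("gaussian", "student_t"):
            raise ValueError("error_family must be 'gaussian' or 'student_t'")
        if self.error_family == "student_t" and not (self.error_df and self.error_df > 2):
            raise ValueError("student_t errors require error_df > 2")
        if self.baseline_law not in ("normal", "skew_gamma"):
            raise ValueError("baseline_law must be 'normal' or 'skew_gamma'")
        if self.baseline_law == "skew_gamma" and q != 2:
            raise ValueError("skew_gamma baseline law is defined for the linear trend only")
        for name, g in self.gamma.items():
            if len(g) != q:
                raise ValueError(f"gamma[{name!r}] must have {q} entries")

    @property
    def n_effects(self) -> int:
        return len(self.beta)

    @classmethod
    def mass_linear(cls, **overrides) -> "TruthParams":
        """Linear-trend truth at the surveillance-cohort point estimates."""
        defaults = dict(
            beta=(37.5, 2.19),
            Sigma=build_covariance((7.12, 1.74), (0.51,)),
            sigma_w=3.12,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def mass_quadratic(cls, **overrides) -> "TruthParams":
        """Quadratic-trend truth at the surveillance-cohort point estimates."""
        defaults = dict(
            beta=(38.3, 1.49, 0.108),
            Sigma=build_covariance((6.69, 2.26, 0.15), (0.58, -0.36, -0.71)),
            sigma_w=2.97,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class ScheduleRule:
    """Next-scan interval as a function of the last observed diameter.

    ``interval_by_band`` maps half-open diameter bands [lo, hi) in mm to the
    interval (years) until the next scheduled scan; observations below the
    lowest band use the lowest band's interval and above the highest band the
    highest band's.  Scheduled scans are attended with probability
    ``attendance_prob``; a missed scan is skipped (not rescheduled) and the
    next one falls a further interval later.  Attended scan times receive
    Gaussian jitter with SD ``jitter_sd`` years, floored so consecutive scans
    are never closer than ``min_gap`` years.
    """

    interval_by_band: dict[tuple[float, float], float] = field(
        default_factory=lambda: {(30.0, 45.0): 1.0, (45.0, 55.0): 0.25}
    )
    attendance_prob: float = 0.95
    jitter_sd: float = 0.08
    min_gap: float = 0.05

    def __post_init__(self) -> None:
        if not self.interval_by_band:
            raise ValueError("interval_by_band must be non-empty")
        if any(iv <= 0 for iv in self.interval_by_band.values()):
            raise ValueError("intervals must be positive")
        if not (0 < self.attendance_prob <= 1):
            raise ValueError("attendance_prob must be in (0, 1]")
        if self.jitter_sd < 0 or self.min_gap <= 0:
            raise ValueError("jitter_sd must be >= 0 and min_gap > 0")

    def interval_for(self, value: float) -> float:
        bands = sorted(self.interval_by_band.items())
        for (lo, hi), iv in bands:
            if lo <= value < hi:
                return iv
        if value < bands[0][0][0]:
            return bands[0][1]
        return bands[-1][1]


@dataclass(frozen=True)
class DropoutRule:
    """Series-termination mechanics.

    Surgery referral ends a series when an observed diameter reaches
    ``surgery_threshold`` mm or when observed growth of at least
    ``rapid_growth_trigger`` mm occurs within one year.  Death and loss to
    follow-up are independent exponential hazards (per year); administrative
    censoring ends follow-up at a per-subject horizon drawn uniformly from
    ``admin_horizon`` (a staggered-entry stand-in).
    """

    surgery_threshold: float = 55.0
    rapid_growth_trigger: float = 10.0
    death_rate: float = 0.03
    loss_rate: float = 0.05
    admin_horizon: tuple[float, float] = (9.0, 12.0)

    def __post_init__(self) -> None:
        if min(self.death_rate, self.loss_rate) < 0:
            raise ValueError("hazard rates must be non-negative")
        lo, hi = self.admin_horizon
        if not (0 < lo <= hi):
            raise ValueError("admin_horizon must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for a synthetic cohort.

    ``entry`` is ``"observed_band"`` (keep only subjects whose first observed
    diameter falls in ``entry_band``, redrawing until ``n_subjects`` are
    included) or ``"all"`` (no entry selection).  With ``censor_population``
    on, ``population_size`` subjects are screened instead: first scans below
    ``censor_bound`` become single left-censored records, scans in band enter
    surveillance, and scans at/above the band's top are excluded.
    """

    n_subjects: int = 1000
    truth: TruthParams = field(default_factory=lambda: TruthParams(baseline_law="skew_gamma"))
    schedule: ScheduleRule = field(default_factory=ScheduleRule)
    dropout: DropoutRule = field(default_factory=DropoutRule)
    covariate_specs: dict[str, tuple] = field(default_factory=dict)
    entry: str = "observed_band"
    entry_band: tuple[float, float] = (30.0, 55.0)
    censor_population: bool = False
    population_size: int = 0
    censor_bound: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 and not self.censor_population:
            raise ValueError("n_subjects must be >= 1")
        if self.entry not in ("observed_band", "all"):
            raise ValueError("entry must be 'observed_band' or 'all'")
        if self.censor_population and self.population_size < 1:
            raise ValueError("censor_population requires population_size >= 1")


@dataclass(frozen=True)
class SimulatedCohort:
    dataset: LongitudinalDataset
    truth: TruthParams
    counts: dict[str, int]


def draw_subject_effects(truth: TruthParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one subject's random-effect vector b_i.

    Under the normal law, b_i ~ MVN(0, Sigma).  Under the skew-gamma baseline
    law the intercept effect is drawn so that the baseline level
    beta_0 + b_0i follows 30 + Gamma(k, theta) truncated to [30, 55) mm
    (shape/scale chosen for mean ~37.5 mm, SD ~7 mm before truncation), and the
    slope effect from the Gaussian conditional N(lambda * b_0i,
    sigma_1^2 (1 - rho^2)) with lambda = rho * sigma_1 / sigma_0.
    """
    S = truth.Sigma
    if truth.baseline_law == "normal":
        if not S.any():
            return np.zeros(truth.n_effects)
        L = _sqrt_psd(S)
        return L @ rng.standard_normal(truth.n_effects)
    # skew_gamma: shifted gamma on the baseline level, truncated to the band
    sigma0 = math.sqrt(S[0, 0])
    sigma1 = math.sqrt(S[1, 1])
    rho = S[0, 1] / (sigma0 * sigma1) if sigma0 > 0 and sigma1 > 0 else 0.0
    mean_excess, sd_excess = 7.5, 7.0
    shape = (mean_excess / sd_excess) ** 2
    scale = sd_excess**2 / mean_excess
    for _ in range(10000):
        level = 30.0 + rng.gamma(shape, scale)
        if level < 55.0:
            break
    b0 = level - truth.beta[0]
    lam = rho * sigma1 / sigma0 if sigma0 > 0 else 0.0
    sd_cond = sigma1 * math.sqrt(max(0.0, 1 - rho**2))
    b1 = lam * b0 + sd_cond * rng.standard_normal()
    return np.array([b0, b1])


def _measurement_error(truth: TruthParams, rng: np.random.Generator) -> float:
    if truth.sigma_w == 0:
        return 0.0
    if truth.error_family == "student_t":
        return truth.sigma_w * rng.standard_t(truth.error_df)
    return truth.sigma_w * rng.standard_normal()


def _curve_coefficients(truth: TruthParams, b: np.ndarray, covariates: dict[str, float]):
    a = np.asarray(truth.beta, dtype=float) + b
    for name, g in truth.gamma.items():
        z = covariates.get(name, 0.0)
        a = a + np.asarray(g, dtype=float) * z
    return a


def simulate_subject(
    truth: TruthParams,
    schedule: ScheduleRule,
    dropout: DropoutRule,
    covariates: dict[str, float],
    rng: np.random.Generator,
    subject_id: str = "s0",
) -> Subject:
    """Simulate one subject's full scan series with its termination mode.

    The underlying level at time t is the subject's curve evaluated at t;
    each attended scan observes it plus measurement error.  The series ends at
    the first of: surgery trigger (observed >= threshold, or rapid observed
    growth), death, loss to follow-up, or the administrative horizon.
    """
    b = draw_subject_effects(truth, rng)
    a = _curve_coefficients(truth, b, covariates)

    death_t = rng.exponential(1 / dropout.death_rate) if dropout.death_rate > 0 else math.inf
    loss_t = rng.exponential(1 / dropout.loss_rate) if dropout.loss_rate > 0 else math.inf
    admin_t = rng.uniform(*dropout.admin_horizon)

    def level(t: float) -> float:
        return a[0] + a[1] * t + (a[2] * t * t if len(a) == 3 else 0.0)

    times: list[float] = []
    obs: list[float] = []
    termination = "administrative"
    t = 0.0
    while len(times) < _MAX_SCANS:
        y = level(t) + _measurement_error(truth, rng)
        times.append(t)
        obs.append(y)
        if y >= dropout.surgery_threshold:
            termination = "surgery"
            break
        rapid = any(
            t - tj <= 1.0 and y - yj >= dropout.rapid_growth_trigger
            for tj, yj in zip(times[:-1], obs[:-1])
        )
        if rapid:
            termination = "surgery"
            break
        interval = schedule.interval_for(y)
        next_t = t + interval
        while rng.uniform() > schedule.attendance_prob:
            next_t += interval
        if schedule.jitter_sd > 0:
            next_t += schedule.jitter_sd * rng.standard_normal()
        next_t = max(next_t, t + schedule.min_gap)
        event_t = min(death_t, loss_t, admin_t)
        if event_t < next_t:
            termination = (
                "death" if event_t == death_t else "lost" if event_t == loss_t else "administrative"
            )
            break
        t = next_t

    measurements = tuple(
        Measurement(time=round(ti, 6), value=max(yi, 1e-3)) for ti, yi in zip(times, obs)
    )
    return Subject(
        subject_id=subject_id,
        measurements=measurements,
        covariates=dict(covariates),
        termination=termination,
    )


def _draw_covariates(specs: dict[str, tuple], rng: np.random.Generator) -> dict[str, float]:
    cov = {}
    for name, spec in specs.items():
        kind = spec[0]
        if kind == "bernoulli":
            cov[name] = float(rng.uniform() < spec[1])
        elif kind == "normal":
            cov[name] = float(spec[1] + spec[2] * rng.standard_normal())
        else:
            raise ValueError(f"unknown covariate spec {spec!r} for {name!r}")
    return cov


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Simulate a full cohort; bit-reproducible given ``config.seed``.

    Each subject slot uses an independent random substream spawned from the
    global seed, so the first k subjects of an n-subject cohort coincide with
    the first k of any larger cohort at the same seed.
    """
    subjects: list[Subject] = []
    counts = {"included": 0, "censored": 0, "excluded_high": 0, "excluded_low": 0}
    lo, hi = config.entry_band

    def substream(i: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))

    if config.censor_population:
        for i in range(config.population_size):
            rng = substream(i)
            cov = _draw_covariates(config.covariate_specs, rng)
            subj = simulate_subject(
                config.truth, config.schedule, config.dropout, cov, rng, subject_id=f"s{i:06d}"
            )
            first = subj.measurements[0].value
            if first < config.censor_bound:
                counts["censored"] += 1
                subjects.append(
                    Subject(
                        subject_id=subj.subject_id,
                        measurements=(
                            Measurement(time=0.0, censored_below=config.censor_bound),
                        ),
                        covariates=subj.covariates,
                        termination=None,
                    )
                )
            elif first >= hi:
                counts["excluded_high"] += 1
            else:
                counts["included"] += 1
                subjects.append(subj)
        if counts["included"] == 0:
            raise ValueError(f"no subjects entered surveillance; counts={counts}")
    else:
        for i in range(config.n_subjects):
            rng = substream(i)
            cov = _draw_covariates(config.covariate_specs, rng)
            if config.entry == "all":
                subj = simulate_subject(
                    config.truth, config.schedule, config.dropout, cov, rng,
                    subject_id=f"s{i:06d}",
                )
                subjects.append(subj)
                counts["included"] += 1
                continue
            accepted = None
            for _ in range(10000):
                subj = simulate_subject(
                    config.truth, config.schedule, config.dropout, cov, rng,
                    subject_id=f"s{i:06d}",
                )
                first = subj.measurements[0].value
                if lo <= first < hi:
                    accepted = subj
                    break
                if first < lo:
                    counts["excluded_low"] += 1
                else:
                    counts["excluded_high"] += 1
            if accepted is None:
                raise ValueError(
                    f"entry rejection failed for subject slot {i}; counts={counts}"
                )
            subjects.append(accepted)
            counts["included"] += 1

    dataset = LongitudinalDataset(subjects=tuple(subjects))
    return SimulatedCohort(dataset=dataset, truth=config.truth, counts=counts)
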