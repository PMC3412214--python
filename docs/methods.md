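# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `aaagrowth`, in the order a user meets them: data model,
synthetic cohorts, samplers and priors, predictions, planning/validation,
and limitations.

## Data model

A cohort is a set of subjects, each with a strictly time-ordered series of
diameter measurements (mm) on a per-subject time axis whose origin t = 0 is
the subject's first scan ("time since screening"). Using age as the
timescale instead is a caller-side re-expression of the time column, not a
package mode. Covariates are baseline-only (time-constant). A measurement is
either an observed value or a left-censored record carrying only an upper
bound (screens under 30 mm that were never followed up). Units are fixed:
years and mm; there is no unit-conversion layer. Subjects with a single scan
are admitted — predicting from one baseline measurement is a core use case.
CSV round-trips are bit-exact (`%.17g` on write, `round_trip` float parsing
on read).

## Synthetic cohort generator

The generator emulates a national screening cohort so that every downstream
stage can be tested against known truth:

* **Growth curves.** Subject curves follow exactly the hierarchical model
  (linear or quadratic, optional covariate effects, Gaussian or scaled-t
  errors), with generating parameters defaulting to the fitted values
  reported for such cohorts (linear: β₀ 37.5, β₁ 2.19, σ₀ 7.12, σ₁ 1.74,
  ρ 0.51, σ_w 3.12; quadratic analogues available via
  `TruthParams.mass_quadratic()`).
* **Baseline law.** The default baseline distribution is a shifted Gamma
  (30 + Gamma with mean 7.5 mm, SD 7 mm, truncated at 55 mm), reproducing
  the right-skewed baseline histogram of screened cohorts; the slope effect
  is drawn from the usual Gaussian conditional given the intercept effect. A
  `"normal"` option makes the generator exactly model-faithful. The skewed
  default matters: with a truncated-*normal* baseline the 45–54 mm band is
  overweighted and the surgery fraction rises to ~0.5.
* **Schedule.** Next-scan interval is banded on the last observed value:
  1 year below 45 mm, 3 months at 45–54 mm (values outside the bands use the
  nearest band). Each scheduled scan is attended with probability 0.95; a
  missed scan is skipped, not rescheduled. Scan times get Gaussian jitter
  (SD 0.08 y) with a 0.05 y minimum gap. The attendance parameter is a
  per-scan mechanism, distinct from (and calibrated jointly with the
  hazards against) the published "repeat within window" compliance figures.
* **Termination.** A series ends at the first of: surgery referral (observed
  ≥ 55 mm, or ≥ 10 mm observed growth within a year), death or loss to
  follow-up (independent exponential hazards, 0.03/y and 0.05/y), or an
  administrative horizon drawn U(9, 12) y per subject (a stand-in for
  staggered entry). The hazards are calibrated defaults chosen once so that
  default cohorts show ~7–8 scans/subject, ~4.5–5 y mean follow-up and a
  surgery fraction near 0.45; the source cohort reports proportions, not
  mechanisms.
* **Entry.** `entry="observed_band"` (default) rejection-samples subjects
  until the *observed* first scan lies in 30–54 mm — the programme's
  inclusion rule, which truncates and tilts the random-effect distribution
  exactly as real screening does. `entry="all"` disables selection; this is
  the right setting for parameter-recovery studies, because fitting a model
  to data re-truncated at its own fitted values cannot recover the
  generating spread. `censor_population` mode instead screens a whole
  population and emits sub-30 mm first scans as single left-censored
  records.
* **Reproducibility.** One global seed; each subject slot uses an
  independent spawned substream, so the first k subjects of a cohort are
  identical across cohort sizes.

What the generator does **not** emulate: calendar-time effects, scanner or
sonographer variation, non-exponential dropout, rupture as an outcome, and
measurement-error autocorrelation. Passing tests on these cohorts therefore
demonstrates internal correctness of the estimators and planners under the
model's own assumptions (plus realistic scheduling/selection mechanics), not
robustness to every feature of real screening data.

## Samplers and priors

All variants are fitted by a bespoke blocked Gibbs sampler rather than a
generic PPL, so each conditional update is unit-testable against its closed
form. Default protocol: 2 chains × 10000 sweeps, 500 burn-in (tests and the
acceptance script use 2 × 2000/500, which suffices at n = 1000 given the
collapsed update below).

* **Fixed effects (β, γ).** Sampled jointly from their conditional with the
  random effects *integrated out* (per-subject Woodbury identities on
  precomputed cross-products). This collapsed update removes the strong
  β–mean(b) autocorrelation of the naive scheme; R-hat for β drops from
  ~1.07 to ~1.005 at 2 × 2000 sweeps on 1000-subject cohorts at no runtime
  cost. Random effects are then redrawn given θ — a valid partially
  collapsed Gibbs scheme.
* **Random effects b_i.** Batched conjugate MVN updates (vectorised 2×2 or
  3×3 solves across subjects).
* **Variances.** σ_w² is inverse-gamma; Σ is inverse-Wishart with
  df = dim(Σ) + 1 + n.
* **t errors.** Per-observation scale-mixture augmentation
  ω_ij ∼ Gamma; the degrees of freedom ν are sampled on a fixed log-spaced
  grid of 600 points spanning (2, 1000) with cell widths folded into the
  weights, under the uniform prior.
* **Independent intercepts.** Subject intercepts α_i carry flat priors
  (bounds (0, 1000) are never active in practice); the slope effect is
  conditionally Gaussian, b₁ᵢ | αᵢ ∼ N(λ(αᵢ − μ_α), σ²_c), with
  λ ∼ U(−5, 5) sampled as a truncated normal, a vague normal prior on the
  centring level μ_α, and IG(0.001, 0.001) on σ²_c. Population summaries
  for this model are per-draw *empirical* moments of the intercepts (no
  population law is assumed for them).
* **Left-censoring.** Censored records are data-augmented from the
  truncated-normal conditional below the bound each sweep; their likelihood
  contribution is the normal CDF term, and with zero censored records the
  censored model's likelihood equals the standard one identically.

Priors: N(0, τ²), τ = 1000 on all fixed effects; IG(0.001, 0.001) on σ_w²
(the variance, WinBUGS convention); inverse Wishart with df = dim(Σ) + 1
(uniform marginal correlations) and scale **0.01·I** on Σ. The scale matrix
is the one genuinely open choice: an identity scale is far from vague for
variance components well below 1 — on quadratic cohorts it biases the
curvature SD (truth ≈ 0.15 mm/yr²) up by ~45% and drags the mean curvature
with it — while 0.01·I recovers all components cleanly and is
indistinguishable from 0.001·I. It is configurable via
`PriorSpec.wishart_scale`.

Convergence is summarised by the classic (non-rank-normalised) Gelman–Rubin
potential scale reduction, floored at 1 so identical chains report exactly
1.0; we treat ≤ 1.05 as converged. DIC uses the *conditional* focus: the
deviance conditions on the subject random effects, p_D = D̄ − D(posterior
means of θ and b), hence p_D is of the order of the number of subjects.
A small-scale frequentist calibration check (100 replicate fits at n = 100)
shows 90% posterior intervals for β₁ covering the generating value ~91% of
the time; at much smaller n (≤ 40) intervals undercover somewhat — a
genuine small-sample prior-sensitivity effect, not a sampler defect (the
collapsed sampler matches REML point estimates and closed-form conjugate
posteriors to Monte-Carlo error).

## Individual prediction (cut semantics)

For a target individual, one random-effect vector is sampled per stored
population draw from p(b_i | y_i, θ) with the population draws held fixed —
an exact realisation of prediction-without-feedback for Gaussian errors. The
conditional is computed in marginal ("Kalman") form, which remains exact
when Σ is singular; under t errors a 5-sweep inner Gibbs over the latent
scale weights is run per draw and the final state kept. In-sample subjects
can instead reuse their stored draws.

Derived quantities per draw: growth rate G; time-to-threshold W, with W = 0
when the current underlying level already meets the threshold and W = ∞ when
the curve never reaches it (for the quadratic model, the smallest root
beyond t of the threshold equation via the numerically stable quadratic
formula, falling back to the linear rule when |curvature| < 1e-12);
the posterior predictive of an observed measurement (fresh error draw); and
exceedance probabilities computed by Rao–Blackwellisation (averaging the
closed-form per-draw tail area), which is lower-variance than indicator
counting. Summaries of W are medians/quantiles on the extended line with ∞
ordered above all reals, using order statistics (no interpolation across
∞); a mean is not reported since it is undefined whenever P(W = ∞) > 0.

## Planning and validation

`recommend_interval` finds the longest horizon whose exceedance probability
stays within a risk limit: a coarse grid scan over [0, max_horizon] followed
by bisection to grid_step/10, returning 0 with an `already_exceeded` flag
when even immediate remeasurement breaches the limit. "Exceedance" refers to
the *observed* (error-inclusive) next measurement by default, matching how a
programme would experience it; an underlying-level variant is available via
`predict_measurement(..., observed=False)`.

`validate_predictions` implements the multiple-imputation calibration check:
predicted exceedance proportions at years 1–5, from cut posteriors built on
each subject's first k scans, against a comparator whose year-x cell is the
observed scan nearest x within ±0.5 y (ties to the earlier scan) or, when
missing, a draw from that subject's all-data posterior predictive; the
comparator averages over imputed data sets (default 100, drawn from a
posterior subsample). Prediction sets use the first min(k, available) scans
so the prediction and comparator sets contain identical subjects; requiring
k scans would selectively drop early surgical exits (the fastest growers)
and bias the comparison. One caveat discovered in self-consistency testing:
when series terminate on an observed ≥ 55 mm scan, that scan is selected on
positive measurement error and then serves as the comparator's "observed"
year-x value, inflating the comparator by ~1–2 percentage points relative to
any correct model prediction. The calibration check is therefore exact only
for cohorts without observed-value selection; with surgery-style termination
a small predicted-below-comparator gap is expected rather than a model
defect.

## Known limitations

* The censored-population model assumes Gaussian errors and is highly
  sensitive to the assumed intercept distribution when the censored fraction
  is large — population-level conclusions from mostly-censored screens
  should be treated as distributional extrapolation.
* The quadratic model's curvature variance is weakly identified at ~5-year
  follow-up; it is the component most sensitive to the Wishart scale (hence
  the vague default).
* No joint longitudinal–survival model: the threshold of interest is a
  feature of the underlying growth process, not an observed event time.
* Time-to-threshold posteriors are honest but extremely wide; interval
  planning should use exceedance probabilities, which is what the planner
  does.
* The independent-intercept model supports the linear trend without
  covariates, mirroring its role as a robustness check on the intercept
  distribution.
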