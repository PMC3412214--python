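# aaagrowth

Bayesian hierarchical growth models for abdominal aortic aneurysm (AAA)
surveillance.

Screening programmes detect aneurysms (aortic diameter ≥ 30 mm), follow them
with repeat ultrasound, and refer for surgery near 55 mm. The planning
question is how long the interval until the next scan can be while keeping
the probability of the diameter exceeding 55 mm acceptably small. This
package is for biostatisticians and screening-programme analysts who want to
fit growth models to longitudinal diameter series, make individual-level
predictions, and turn them into monitoring policies — and to test the whole
pipeline on synthetic cohorts with known ground truth, since individual-level
screening data are rarely shareable.

## The model

Measurement *j* of subject *i* at time *t<sub>ij</sub>* (years since the
subject's first screen) is modelled as

y<sub>ij</sub> = **x**<sub>ij</sub>ᵀ(**β** + **b**<sub>i</sub>) +
**w**<sub>ij</sub>ᵀ**γ** + ε<sub>ij</sub>,  ε<sub>ij</sub> ∼ N(0, σ<sub>w</sub>²),
  **b**<sub>i</sub> ∼ MVN(**0**, Σ),

with **x**<sub>ij</sub> = (1, t<sub>ij</sub>) for a linear trend or
(1, t<sub>ij</sub>, t<sub>ij</sub>²) for a quadratic one, subject-specific
random intercepts/slopes(/curvatures) **b**<sub>i</sub>, and optional baseline
covariates entering intercept and slope through **w**<sub>ij</sub>. Variants:
Student-t measurement errors with estimated degrees of freedom,
independent (unshrunk) subject intercepts with the slope modelled
conditionally on the intercept, and a left-censored likelihood
(Φ((30 − μ<sub>ij</sub>)/σ<sub>w</sub>) terms) for screens known only to be
below 30 mm. Fitting is by blocked Gibbs sampling with vague priors
(N(0, 1000²) fixed effects, IG(0.001, 0.001) error variance, inverse-Wishart
covariance with dim(Σ)+1 degrees of freedom); convergence is monitored by the
Gelman–Rubin statistic and models are compared by DIC.

From a fitted population posterior, a (new) individual's random effects are
sampled conditionally on their scans *per posterior draw* without feeding
back into the population ("cut" semantics). That yields posteriors for the
growth rate *G*, the time *W* to reach a threshold α (a quantity on the
extended half-line: 0 if already reached, ∞ if never), the posterior
predictive of a future observed measurement *Y*(t+s), and the exceedance
probability P{Y(t+s) ≥ α} — the quantity monitoring policies constrain.

## Worked example

```python
import numpy as np
from aaagrowth import *

# a MASS-like synthetic cohort: skewed 30-54 mm baselines, banded rescan
# schedule (yearly under 45 mm, 3-monthly at 45-54 mm), dropout by
# surgery referral / death / loss to follow-up
cohort = simulate_cohort(GeneratorConfig(n_subjects=300, seed=42)).dataset

model = GrowthModel(n_iter=2000, n_burnin=500, random_state=7).fit(cohort)
print(model.summary_.round(3))
```

```
           median     sd    q2.5   q97.5  rhat
parameter
beta0      37.662  0.309  37.084  38.277   1.0
beta1       1.929  0.119   1.706   2.172   1.0
sigma0      4.923  0.230   4.495   5.397   1.0
sigma1      1.661  0.109   1.452   1.884   1.0
rho01       0.445  0.070   0.297   0.571   1.0
sigma_w     3.006  0.052   2.910   3.113   1.0
```

The cohort's mean diameter at first screen is ~37.7 mm growing ~1.9 mm/yr,
with large between-subject spread (σ₀ ≈ 4.9 mm, σ₁ ≈ 1.7 mm/yr, positively
correlated) and ~3 mm measurement error — the familiar pattern for screened
AAA cohorts. Predictions for a new patient whose single screen reads 48 mm:

```python
rng = np.random.default_rng(0)
patient = Subject(subject_id="new",
                  measurements=(Measurement(time=0.0, value=48.0),))
ind = cut_posterior(patient, model.draws_, rng=rng)

growth_rate(ind).median                      # 3.07 mm/yr (95% CI 0.12, 6.08)
time_to_threshold(ind, alpha=55.0).median    # 3.2 years (95% CI 1.1, 90.8)
exceedance_prob(ind, s=1.0, alpha=55.0)      # 0.062
recommend_interval(PolicyQuery(baseline_value=48.0, risk_limit=0.01),
                   model.draws_, individual=ind).interval   # 0.19 years
```

The growth rate is higher than the population mean (intercept and slope are
positively correlated, and a 48 mm baseline is far above average), but the
threshold-crossing time is so imprecise (1 to 90+ years) that it is useless
for planning. The exceedance probability is the useful currency: a 6.2%
chance of an observed diameter ≥ 55 mm within a year means that holding the
risk below 1% requires rescanning within ~10 weeks (0.19 years).

A command-line interface mirrors the library
(`aaagrowth simulate | fit | predict | plan | validate | run`); `run` executes
a YAML-configured pipeline and writes a reproducibility manifest.

## Layout

| module | contents |
| --- | --- |
| `aaagrowth.data` | `Measurement` / `Subject` / `LongitudinalDataset`, CSV I/O, cohort summaries |
| `aaagrowth.simulate` | synthetic MASS-like cohort generator with known truth |
| `aaagrowth.model` | `GrowthModel` estimator, Gibbs samplers, R-hat, DIC |
| `aaagrowth.predict` | cut posteriors, G / W / Y(t+s), exceedance probabilities |
| `aaagrowth.planner` | rescan-interval recommendation, policy curves, predictive validation |
| `aaagrowth.cli` | `aaagrowth` command-line entry point |

See `docs/methods.md` for the modelling choices, priors, generator
calibration and known limitations.
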