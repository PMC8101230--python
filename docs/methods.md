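# Methods

## The estimand and the analysis model

Each participant contributes a stay of 1–30 ICU days. On day *j*
participant *i* has a binary delirium status `delirium_ij` and an integer
SOFA severity score `SOFA_ij` in [0, 24]. The summary exposure is the
delirium duration `d_i = Σ_j delirium_ij`, and the scientific target is the
slope `β_del` of the unadjusted linear model

```
outcome_i = α + β_del · d_i + ε_i,   ε_i ~ N(0, σ²).
```

The model is deliberately unadjusted and identical across strategies, so
every difference in performance is attributable to the missing-data
handling, not to model choice. Confidence intervals use t critical values:
`n − 2` degrees of freedom for the non-MI strategies, the Rubin degrees of
freedom for the MI strategies (infinite, hence normal quantiles, when the
between-imputation variance is exactly zero). A Barnard–Rubin small-sample
correction was considered and not adopted as the default: at the design's
n = 200 it changes intervals negligibly.

## Synthetic base cohort

The simulation design resamples whole participants from a base sample of
real ICU data; no such sample is distributable, so `synthbase` generates a
synthetic one with the same structure. It is a stand-in constructed from
three mechanisms, each chosen to reproduce a qualitative feature that the
strategies' behaviour depends on:

* **Length of stay** — truncated geometric on [2, 30] (Poisson by flag),
  calibrated by root finding so the pmf mean equals `los_mean` (default 7
  days). Right-skew matters: complete-case retention decays geometrically
  in stay length, so a skewed LOS produces the characteristic collapse of
  the complete-case sample at high missingness.
* **Daily delirium** — a two-state Markov chain: initial probability
  `p_init = 0.4`, persistence `p_stay_del = 0.7`, incidence
  `p_new_del = 0.2`. The stationary prevalence
  `p_new/(p_new + 1 − p_stay) = 0.4` of participant-days and the implied
  mean duration of ≈ 2.8 days are ICU-plausible. Serial correlation is
  what cluster resampling is meant to preserve, hence it must exist.
* **SOFA** — participant-level anchor N(6, 3²) plus `sofa_del_shift = 3`
  on delirious days plus day-level N(0, 2²) noise, rounded and clipped to
  the integer range [0, 24]. The induced positive SOFA–delirium
  association is what makes SOFA a useful MAR driver and imputation
  auxiliary; the rounding/clipping attenuates the realised shift slightly
  (≈ 2.8 at the defaults).

The outcome is generated *after* resampling with intercept 80, slope −1.0
and residual SD 12 — scaled like a standardised cognitive score (population
mean 100, SD 15). The intercept does not affect bias, SE or coverage of
the slope; the residual SD sets the signal-to-noise ratio and hence the
absolute coverage levels.

What the generator does **not** emulate: death and discharge as informative
truncation, time-varying severity trajectories, confounding between
severity and the outcome, and the exact (unpublished) distributions of any
real base sample. Passing tests therefore demonstrate the *relative*
behaviour of the strategies under a realistic data geometry, not the
absolute bias or coverage figures any particular real cohort would show.

## Missingness

Only the delirium assessment is ever masked; SOFA and the outcome stay
complete (the imputation models require them daily / per participant).
Mechanisms:

* MCAR: constant probability `p`;
* MAR: `P(missing_ij) = expit(α_m + β_SOFA · SOFA_ij)`, slopes 0.01 / 0.1 /
  0.2 (weak / moderate / strong);
* MNAR: `P(missing_ij) = expit(α_m + β_del_miss · delirium_ij)`, slopes
  0.1 / 0.5 / 1.0.

For MAR/MNAR the intercept `α_m` is calibrated per replicate by Brent root
finding so that the *expected* missing fraction over the realised cohort's
covariate distribution equals the target `p` (residual < 1e−8; the mean of
`expit(α + βx)` is strictly increasing in `α`, and
`logit(p) − β·max(x) ≤ α ≤ logit(p) − β·min(x)` brackets the root exactly).
Bernoulli draws then produce ordinary sampling variation around `p`.
Calibrating to the expected rather than realised fraction keeps the
intercept deterministic given the cohort. MNAR probabilities condition on
the true pre-masking status, which exists because masking is applied to a
fully observed cohort.

## The two MI engines

Both engines are "proper" in Rubin's sense: imputation-model parameters
are drawn from an approximate posterior before values are drawn, so the
between-imputation variance reflects parameter uncertainty.

**Passive (daily-level).** A single logistic regression of the observed
daily statuses on daily SOFA and the participant's outcome is fitted per
dataset; each of the B completions draws coefficients from
N(MLE, inverse observed information) and then independent Bernoulli values
for the missing days. Including the outcome in the imputation model is
standard practice (the imputation model should contain the analysis
model's variables); a SOFA-only model is available via `predictors`.
Fallbacks: complete separation or non-convergence switches to a
ridge-penalised Newton fit (penalty 1e−4); a single observed class imputes
that class, with a warning in both cases. The model treats days as
exchangeable given (SOFA, outcome) — it ignores the serial correlation the
generator builds in. That misspecification is intentional: it is exactly
what a standard daily-level imputation does, and it produces the mild
slope-magnitude amplification visible at 35% missingness.

**Active (summary-level).** The participant-level table (duration, mean
SOFA over the stay, outcome) is imputed by Bayesian normal linear
regression: `σ²` from the scaled inverse-χ² posterior `RSS/χ²_{n_obs−3}`,
coefficients from `N(β̂, σ²(X'X)⁻¹)`, predictive draws rounded and clipped
to [0, length of stay]. Predictive mean matching (k = 5 donors, nearest by
predicted mean, ties broken at random) is available via `method="pmm"`;
the Bayesian default was preferred because it is fully specified with no
donor-pool tie-breaking. Observed daily assessments of participants with
an undefined duration are deliberately ignored — that information loss is
the defining property of the approach and the source of its large
standard errors.

Rubin pooling follows the textbook formulas: `T = W + (1 + 1/B)·B_var`,
`df = (B − 1)(1 + W/((1 + 1/B)·B_var))²`, with `B_var = 0 → df = ∞`.
B defaults to 10.

## Simulation harness

Each replicate: cluster-resample n = 200 participants (without
replacement, from a base of 1000 by default) → generate the outcome →
calibrate and impose missingness → apply the strategies. Metrics per
scenario × strategy: bias `mean(β̂) − β_del`, mean SE, coverage of the
nominal 95% CI, Monte-Carlo error of the bias, and the number of estimable
replicates. Non-estimable replicates (fewer than 3 complete participants,
constant retained durations, too few observed durations) are tallied and
excluded from metric denominators — at 35–50% missingness their occurrence
is itself a finding about the strategy.

Seeding: every random stream derives from
`SeedSequence(master_seed, (cell_code, replicate_index))` where
`cell_code` is a CRC-32 of the scenario label. Any replicate is
reproducible in isolation, and all strategies within a replicate see the
identical masked dataset, so comparisons are paired.

Problem sizes: the full design is 28 cells × 5 strategies; the package's
default grid runs 200 replicates per cell with Monte-Carlo error reported
next to every metric, and the bundled analyses use 200–1000 replicates per
cell depending on how close the quantity under test sits to its threshold
(a minimum over many cells needs the per-cell Monte-Carlo error to be well
below the margin being asserted).

## Numerical and edge-case choices

* Undefined duration is a typed sentinel (`None` at the participant level,
  `NaN` in the vectorised frames); arithmetic on the object-level sentinel
  raises rather than propagating.
* An exactly collinear outcome reports SE 0 with a warning (detected as
  `SSR ≤ 1e−24 · TSS` to absorb floating-point residue).
* Calibration tolerance 1e−8 on the expected missing fraction; LOS-mean
  calibration solved to 1e−13.
* SOFA integerisation: round then clip to [0, 24], because SOFA is an
  integer clinical score.
* Posterior covariance factorisation retries Cholesky with escalating
  jitter (1e−12 …) before failing.

## Known limitations

* Bias *levels* (as opposed to SE and coverage orderings) are sensitive to
  the synthetic generator's parameters; in this world active imputation is
  noisy but nearly unbiased, while passive imputation trades a small
  outcome-amplification bias for a large efficiency gain. Real cohorts
  with different exposure–auxiliary geometry can reorder bias magnitudes.
* No death/discharge truncation, no confounders, no missingness in SOFA or
  the outcome, no monotone (dropout) missingness patterns.
* The daily imputation model is single-level by design; generalized
  linear mixed-effects imputation is out of scope.
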