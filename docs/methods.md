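# Methods

`rhythmarm` scores the regularity of a person's daily rest–activity
routine from passively sensed smartphone data and relates that score to
sleep, mood and demographic covariates. This note documents the models,
the estimation choices, and what the synthetic-data experiments do and
do not demonstrate.

## Hourly features

Raw streams are reduced to an hourly grid in participant-local time
(half-open bins `[h, h+1)`, labeled by the clock hour at the *end* of
the bin):

* `X(t)` — mean accelerometer magnitude `sqrt(ax² + ay² + az²)` (m/s²)
  over the hour; missing when the hour holds no samples (phone off, no
  signal, airplane mode). Device differences in acceleration scale
  (g-normalized vs. raw) are deliberately left unscaled: `X` enters the
  transition model log-linearly, so a constant scale factor is absorbed
  by the slope coefficient and per-participant fits are unaffected.
* `Y(t)` — screen-on (or unlock) event count over the hour. An event
  log encodes absence as *zero*, not as a gap, so `Y` is never missing.

Self-reported bed and wake clock times are cleaned before summarizing:
a time is shifted by 12 h only when it falls outside its plausible
window (bedtime 5 PM–4 AM, wake 4 AM–3 PM), the implied sleep duration
is unrealistic, and the shift repairs both. The duration window is
1–16 h: durations outside it essentially never occur as honest reports
but arise immediately from AM/PM slips. Requiring the flip to repair
the record makes the correction idempotent and total. Bedtime SDs are
computed after mapping post-midnight times (< 12:00) forward by 24 h;
corrected bedtimes never straddle more than one midnight, so this
single wrap suffices. Wake times use the raw axis. SDs use n−1.

## Dormancy model and imputation

The hourly missingness indicator of `X` is modeled with a 2-state
hidden semi-Markov model with Bernoulli state-dependent distributions
and geometric dwell times. A geometric dwell-time chain is exactly a
first-order Markov chain whose self-transition probability is the dwell
parameter, so the model is fitted as a plain 2-state Bernoulli-emission
HMM by EM (deterministic start at miss probabilities 0.9/0.1 and 0.9
self-transitions, plus two seeded random restarts; best likelihood
kept) and decoded with the Viterbi algorithm. States are ordered so
"dormant" is the one with the higher missingness probability. Constant
indicators (all observed / all missing) carry no signal and raise a
degenerate-input error; callers fall back to single-branch imputation.

Missing `X` is then filled by a two-branch rule:

* dormant hours ← a floor value: the 2.5th percentile of observed `X`,
  a robust stand-in for "the minimum excluding outliers" (the exact
  outlier rule is a free choice; a low quantile is the standard one);
* non-dormant hours ← least-squares prediction of `X` from `Y` fitted
  on completely observed hours, clipped below at the floor so no
  imputed magnitude is ever less physically plausible than the quietest
  observed hour.

Observed values are never altered, and imputed hours are flagged so the
original missingness pattern stays available downstream.

## The mixed-effect CT-HMM

Hourly screen-on counts are emitted from a latent 2-state chain — rest
(Poisson mean `mu_rest ≈ 0`) and active (`mu_active > 0`) — that evolves
in continuous time with exponential proportional-hazard transition
rates carrying `x(t)` as a time-varying covariate and a normal random
intercept for each of the 24 clock hours:

    lambda_1(t) = exp(alpha_1 + beta_1 x(t) + b_1[h(t)]),  b_1[h] ~ N(0, sigma_1²)   (rest → active)
    lambda_2(t) = exp(alpha_2 + beta_2 x(t) + b_2[h(t)]),  b_2[h] ~ N(0, sigma_2²)   (active → rest)

Over a one-hour step the transition matrix is the matrix exponential of
the generator `Q = [[-l1, l1], [l2, -l2]]`, computed in the 2-state
closed form `Gamma = [[1-l1·A, l1·A], [l2·A, 1-l2·A]]` with
`A = (1-e^{-s})/s`, `s = l1+l2` (evaluated via `expm1` for small `s`;
agreement with a general numerical matrix exponential is itself a
tested property). Log-rates are clamped to ±30 to guard overflow.

Runs of ≥ 24 consecutive originally-missing hours split the series into
segments whose likelihoods are treated as independent and multiplied;
hours missing in shorter runs are imputed and then contribute to the E-
and M-steps exactly like observed hours. `b_1` and `b_2` are treated as
independent intercept sets, penalized separately.

### Estimation

Fitting is per participant, in two phases.

**Phase 1 — penalized EM.** The E-step is scaled forward–backward over
the time-varying `Gamma(t)`, exact for the discretely observed chain.
The M-step updates, in order: the Poisson means (posterior-weighted
count means, with `mu_rest` floored at 0.01 because a hard zero
annihilates the likelihood at any stray rest-state count); the initial
distribution (segment-start posteriors); and the hazard parameters
`(alpha, beta, b)`, obtained by maximizing the exact expected transition
log-likelihood `sum_t sum_ij xi_t(i,j) log Gamma_t(i,j)` plus the ridge
penalty `-b²/(2 sigma²)` with L-BFGS using the closed-form gradient of
the 2×2 matrix exponential, warm-started and accepted only on
improvement. Because every sub-update is a coordinate ascent of the
expected complete-data penalized log-likelihood, the traced objective
(marginal log-likelihood plus penalty, ridge strength held fixed at
`sigma_init = 1`) is non-decreasing — a generalized EM. An earlier
variant that replaced the transition M-step with a weighted
Poisson-hazard regression was rejected precisely because that surrogate
is not a minorizer and broke the ascent guarantee.

**Phase 2 — variance calibration.** The quantities of interest are the
intercept variances. The textbook in-loop MAP update
`sigma² ← mean(b̂²)` is degenerate here: ridge shrinkage feeds back into
the penalty and, for moderate rhythms, spirals both `b̂` and `sigma²`
to zero (in simulations, participants generated at total variance 1
collapsed to the floor most of the time). The package therefore
estimates the variances after EM by iterating the empirical-Bayes
fixed point

    sigma² ← mean_h( b̂[h]² + v[h] ),   v[h] = 1 / (H_h + 1/sigma²),

refitting `(alpha, beta, b)` under each new ridge, where `H_h` is the
per-hour curvature proxy `sum_{t: h(t)=h} gamma_t(i) · lambda(t)`. The
`v[h]` term is the Laplace-approximate posterior variance of the
intercept — the mass the ridge removed — and restores a stable non-zero
fixed point. This is a Laplace-style approximation to marginal ML, not
full marginal ML; its path is recorded in `sigma_trace` separately from
the EM objective trace, because the calibration does not ascend the
phase-1 objective (no alternating scheme of this kind does — the same
reason PQL has no objective function).

Label switching is resolved by canonical ordering `mu_active >
mu_rest`, swapping transition directions when emission means cross.
A fit is flagged `converged = False` — and the participant's ARM
withheld and the participant excluded from the cohort — on state
collapse (`mu_active - mu_rest < 0.1`, the situation of a phone used
too rarely for the two states to be distinguishable), on reaching 500
iterations, or on any numerical failure. Series with fewer than 336
usable hours (14 days) after segment splitting are not fitted at all.
Convergence is a relative objective change below 1e-6.

### The Activity Rhythm Metric

`ARM = sigma_1² + sigma_2²`. A person who rests and wakes at consistent
clock hours needs widely dispersed hour-of-day intercepts to explain
their data, so a large ARM means a regular routine. The ARM is
invariant to state relabeling. The estimator is shrunken (ridge plus
Laplace calibration), so absolute ARM values sit below the generating
variances in simulations — by roughly a factor of two at six weeks of
data — but the *ranking* of participants is preserved (Spearman ≈ 0.9
in the recovery experiments), and ranking is what the association
stage consumes.

## Association stage

For each covariate the full Gaussian linear model
`ARM ~ age + sex + covariate` is compared to `ARM ~ age + sex` with a
1-df likelihood ratio test (both fitted by ML, so the LRT is valid;
`2·(ll_full - ll_null)` against chi-square). Age and sex are each
tested controlling only for the other. Tests are two-sided and
reported unadjusted (a Benjamini–Hochberg column is available but off
by default); each covariate uses complete cases. Raw and
age/sex-partial Pearson correlations are reported alongside, labeled,
since either scale may be wanted.

## Synthetic cohorts

The generator runs the same CT-HMM forward: an hour-by-hour latent
chain advanced with `Gamma(t)` built from that hour's simulated `x` and
clock hour; `Y ~ Poisson(state mean)`, `X` log-normal per state
(medians 0.02 m/s² at rest, 1.0 active); `X` deleted with
state-dependent probability (defaults 0.55 at rest, 0.05 active ⇒
roughly 25% missing overall, concentrated at night the way real
dormancy is). Default intercepts use a deterministic diurnal template —
settling (active→rest) peaking 0:00–6:00, activation (rest→active)
peaking 7:00–10:00 — standardized and scaled so the population variance
over the 24 hours equals the requested `sigma²` exactly, which makes
recovery experiments free of template-sampling noise; i.i.d. normal
intercepts are available instead. Defaults are `mu_active = 5`,
`mu_rest = 0.05`, base rates 0.25/h, `beta_1 = 0.5`, `beta_2 = -0.5`,
42 days.

Cohorts default to 38 participants, ages ~N(23.4, 3.5²), about
one-third male. Each participant's true total intercept variance is
`1.5 + 0.18·(age - 23.4) + 1.31·male + N(0, 0.6²)` (floored at 0.05),
and EMA summaries are generated from it with linear links whose signs
encode the expected directions — sleep duration +0.6 h per ARM unit
around a 7.43 h base, bed/wake-time SDs −0.45 around 1.92/2.17 h,
mood −0.6 around 3.12, BDI −2.5 around 7 — with Gaussian noise. EMA
outcomes are generated at the participant level, since only their
summaries enter the association stage; daily generation exists behind
a flag for testing the summarizer. Setting every link to zero yields
the null cohort used for type-I-error calibration.

What the synthetic data does *not* emulate: device heterogeneity,
travel and DST, non-stationary routines (shift work, weekends),
informative missingness beyond the rest link, and EMA response biases.
Passing recovery tests therefore show the estimator is sound under the
model's own assumptions, not that those assumptions hold in any
particular real cohort.

## Problem sizes and numerical choices

Recovery experiments use 18–20 participants × 42 days across generating
variances {0.25, 1, 4} plus a no-rhythm group; state recovery uses the
default emission separation (5 vs 0.05); LRT calibration uses 400–500
null replicates at n = 38 — sizes at which each check's Monte-Carlo
error is small relative to its acceptance margin while a full run stays
in the minutes. Variance components at 0.25 with six weeks of data sit
at the edge of identifiability and often calibrate to the floor
(1e-4); they still rank below the stronger groups, which is the
property the ARM needs. Ties in two-means initialization, constant-`Y`
series and constant covariates are handled as explicit degenerate
cases (collapse flag, errors naming the offender).

## Known limitations

* The variance calibration is approximate (Laplace); absolute ARM
  values are shrunken and should be compared within, not across,
  fitting configurations.
* `beta_2` (accelerometer effect on settling) is weakly identified when
  `x` separates the states sharply, since active→rest transitions all
  start from hours with similar `x`; its sign is not guaranteed to
  recover. `beta_1` recovery is tested.
* Single imputation only: imputation uncertainty is not propagated, and
  missing-not-at-random mechanisms are not modeled.
* Hours are assumed participant-local with a fixed UTC offset; travel
  and DST shifts are not handled.
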