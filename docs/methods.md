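# Methods

## Model

The trajectory model is a hierarchical linear–linear ("broken-stick")
growth curve with a random change point.  The level-1 mean is the
*continuous* form

    mu_ij = b0_i + b1_i (age_ij − a_ref) + b2_i (age_ij − CP_i)_+  + Σ_t β_t TVC_tij

so the curve is continuous at the change point by construction, `b1` is the
first-phase slope, and `b2` is the **change** in slope after the change
point (adult-phase slope = `b1 + b2`).  A discontinuous variant — indicator
functions switching between two unrelated lines — also appears in the
literature; we use the continuous form because only it makes slope
arithmetic like 0.67 − 0.49 = 0.18 kg/m²/yr meaningful, and a discontinuous
mean would let the two groups "diverge" by jumping.

Level 2 decomposes each of the four subject parameters into population
value + optional group shift + optional TIC effects + random effect.  Ages
are centred at `a_ref` (default: grand mean of observed ages), but the
change point is always parameterised, stored and reported on the raw-age
scale — a centred change point is uninterpretable as an age at divergence.

**Divergence mechanisms.**  Freeing only `β2_grp` is Type I (same timing,
different adult rate); freeing only `CP_grp` is Type II (same rates,
later transition); freeing both is Type III.  The candidate suite A–H
(unconditional; intercept; childhood slope; adult slope; CP; CP+adult
slope; CP+intercept; all four) is compared by DIC with posterior predictive
checks; the reference-group `CP` in the winning Type II/III model is the
age at divergence, with its posterior credible interval.

## Priors

Fixed effects and group shifts get independent `N(0, 1e4)` priors — vague
on the kg/m² scale so the likelihood dominates and shifts may take either
sign.  The change-point mean prior is `N(μ_cp, 1e4)` with `μ_cp` taken by
default from the profile-log-likelihood estimate of the population break
(empirical anchoring that shortens burn-in; the huge variance keeps it
non-informative).  Variance components get `InvGamma(0.001, 0.001)` priors
when independent and an `InvWishart(I, dim+1)` prior on unstructured
blocks; the covariance structure can be fully unstructured, independent, or
block-diagonal with one free correlation between the two slope random
effects (the structure selected in the motivating analysis).  The
missing-TVC model uses a Gaussian covariate likelihood with a vague normal
prior on its mean (variance 1e6) and `Gamma(0.001, 0.001)` on its
precision.

Some sources state covariate priors as `N(0, 0.001)`; read literally as a
variance this would be strongly informative, so we interpret all normal
priors in mean/variance form with default variance 1e4 and treat 0.001 as a
precision.  Every hyperparameter is overridable through `PriorSet`.

## Sampler

Metropolis-within-Gibbs, independent chains with seeds spawned per chain
from one `SeedSequence` (bit-reproducible).

* Conditionally linear block (fixed effects, TIC/TVC coefficients):
  one joint conjugate Gaussian draw given the current change points.
* Linear random effects: per-subject conjugate Gaussian draws, batched;
  under the full structure their prior is the partitioned-normal
  conditional given the subject's change-point deviation.
* Variances: Inverse-Gamma; unstructured blocks: Inverse-Wishart.
* Change-point block (population CP, group CP shift, CP-level TIC effects,
  subject deviations `v_cp_i`): scalar adaptive random-walk Metropolis,
  Robbins–Monro scaling toward 0.44 acceptance with decay `t^-0.6`, frozen
  at the end of burn-in so the post-burn-in kernel is fixed.
* Support: subject change points are truncated to the observed age window
  (asserted on every draw) and population-CP proposals are reflected at the
  window boundary.  Without truncation, subjects observed on one side of
  their change point make it unidentifiable.  When CP-level TIC effects are
  present the TIC contribution itself is unbounded and the per-draw window
  assertion is skipped.
* Missing TVC entries are drawn each sweep from their full conditional
  (covariate model × response likelihood); the covariate-model mean and
  precision are updated from observed entries only.  An entirely missing
  TVC column triggers a warning and is imputed from the covariate model
  alone.  Note that even then its regression coefficient does not simply
  reproduce its prior: the imputed values still enter the response
  likelihood, which penalises large coefficients.

Initial values are deterministic two-stage least squares: the change point
from the profile log-likelihood (per group when a group shift is free),
slopes/intercept from a ridge-regularised fit at that break, the
random-intercept variance by method of moments.  Deviance (−2 log level-1
likelihood, conditional on the random effects) is recorded at every kept
draw.

**Numerical guards.**  Gamma draws with tiny shape (vague variance priors
with no data) can underflow to 0; inverse-gamma draws are floored at
1e−290.  The profile likelihood floors the residual variance at
`1e-15 · SS_total/n` so noiseless data give finite, shift-stable curves,
and declares the profile *flat* (no break) when no grid point improves on
the straight line beyond `1e-9 · SS_total`.

## Model comparison

`pD = mean(deviance) − deviance(at posterior means)` and
`DIC = mean(deviance) + pD`, with the plug-in deviance evaluated at
posterior means of the fixed effects, the random effects, and the imputed
TVC values — a level-1 (conditional) DIC focus, the natural one when
subject trajectories are the inferential target.  The posterior predictive
p-value uses the *signed sum of residuals* as its discrepancy (a
sum-of-squares alternative is available but non-default); given a draw both
discrepancies have known sampling distributions, so the replicate value is
drawn exactly instead of via a full replicate response vector.  Group
effects are "significant" when the central 95% credible interval excludes
zero.  The best model in a suite is the lowest-DIC converged fit,
preferring posterior predictive p-values in [0.2, 0.8]; near-ties go to the
model with fewer free group shifts.

The Gelman–Rubin diagnostic defaults to the classic two-or-more-chain PSRF
(floored at 1, so identical chains report exactly 1.0); a split-chain
variant is available via `split=True`.  Parameters with R-hat > 1.1 are
flagged.

## LS-means baseline

`response ~ C(age) × group + (1 | subject)` by REML (statsmodels MixedLM,
cell-means coding so coefficients are the LS-means; covariates, if any, are
centred).  Optimisers occasionally terminate at degenerate points with
absurd standard errors; fits are accepted only if all fixed-effect SEs are
finite and below `1e3 · sd(y)`, otherwise the next optimiser in
lbfgs → bfgs → cg → powell is tried.  Age levels observed in only one group
are excluded from contrasts with a warning.

The Tukey adjustment family is the set of per-age group contrasts (m of
them), not all cell pairs.  Because the studentized-range machinery is
indexed by a number of means k, m is mapped to the smallest k with
k(k−1)/2 ≥ m — the number of pairwise comparisons among k means then
matches the family's multiplicity, and m = 1 reduces exactly to the
unadjusted two-sided t test.  Degrees of freedom are the residual
`N − p`.

Divergence-age read-outs: *earliest* = smallest age with adjusted p < α
(taken literally, even if non-monotone); *midway* = midpoint of the
consecutive-age cut minimising misclassifications (significant ages before
the cut + non-significant after), earliest cut on ties, first age level if
everything is significant, none if nothing is.  The midway tie rules are
this package's own convention; the verbal definition in the literature
admits several.

## Synthetic-data generator

The generator emulates a six-cohort accelerated longitudinal design:
entry ages uniform on {3, 6, 9, 12, 15, 18} yr, six measurements per
subject at 3, 6, 9, 21, 27 and 31 years after entry (observed ages 6–49).
The default scenario is the published Type II condition: β0 = 26.5 kg/m²
at a_ref = 25 yr, β1 = 0.67, β2 = −0.49 kg/m²/yr, CP = 16.02 yr, group CP
shift +12.37 yr, participant-level random-intercept variance 2.77 and
residual variance 2.47 (kg/m²)², at sample sizes 100/100, 50/100 or
30/100.  Only the random intercept is non-zero in the default scenario;
slope and change-point random effects and a full 4×4 covariance are
available for sampler stress tests.  Optional extras: a Gaussian
visit-level covariate entering the response (default 17% missing
completely at random — the masking is independent of the covariate value,
consistent with the MAR analysis assumption), and per-cohort shifts of any
trajectory parameter (cohort = entry age, as in a single-entry multi-cohort
study).

What the generator does **not** emulate: unbalanced/missing visits,
dropout, age measurement error, skewed or heteroscedastic residuals,
AR(1) within-subject correlation, and cohort-by-age sampling imbalance
beyond the entry-age mechanism.  Passing recovery tests therefore shows
correctness of the estimator under the stated design, not robustness to
those real-data features.

## Problem sizes and observed behaviour of the checks

Replicate experiments use 20 replicates for recovery/selection checks
(short chains: 2 × (1500 + 1500), thin 3 — adequate for posterior means)
and 100 replicates for the LS-means bias direction; the recovery experiment
in `scripts/acceptance.py` uses the reduced protocol 2 × (5000 + 5000),
thin 5.  Full-length chains (4 × 50000 burn-in, 20000 kept, thin 10) remain
the `SamplerConfig` defaults.

Two boundary observations worth recording.  (1) The equal-tailed 95%
interval for the population change point is slightly sub-nominal at the
default design (~92–93% coverage over 60 replicates): the kink falls
between observed visit ages (15 and 18), so its posterior is mildly skewed.
(2) The LS-means earliest-significant-age estimator's sample-size bias is
real but modest between 100/100 and 50/100 (≈ +0.5 yr on average); tests of
its direction need ~100 replicates to sit clearly above noise.

## Limitations

One change point per trajectory; Gaussian residuals with a single variance;
no HMC/NUTS backend; LS-means baseline limited to a random intercept and
two groups; TVC effects are constant over age.
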