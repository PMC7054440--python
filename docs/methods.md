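# Methods

`rotdiag` implements a longitudinal cognitive-diagnostic analysis of a
four-module spatial-rotation learning program.  This note documents the
models, the estimation machinery, the synthetic-data generator, the
numerical choices, and the limits of what the package's tests establish.

## The assessment design

548 undergraduates work through four modules of 10 multiple-choice 3-D
rotation items each: a testing module, two learning modules, and a final
testing module.  Four binary skills are tracked, in canonical order
(x90, y90, x180, y180) — 90- and 180-degree rotations about the x and y
axes.  Each item requires 1 or 2 skills, declared in a 40 x 4 Q-matrix
whose per-module pattern counts follow the program blueprint (5/5/5/7
single-skill items for x90/x180/y90/y180 and 7/5/6 two-skill items).
The software records a binary response Y_ij(t) and a response time
L_ij(t) (seconds) for every item.  Observed covariates: gender, country,
intervention arm (colored vs non-colored trainer) and self-reported
rotation strategy (Analytic / Holistic / Combined).

Dummy coding (configurable, fixed defaults for reproducibility):
male = 1, China = 1, color = 1; strategy enters as two dummies with
Combined as the reference (strategy1 = Analytic, strategy2 = Holistic).

## The joint model

**Measurement (DINA).**  At time t a person with profile alpha answers
item j correctly with probability 1 - s_j if alpha dominates q_j
(possesses every required skill) and g_j otherwise.  Each item appears
in exactly one module, so item parameters are time-invariant.  The
discrimination 1 - s_j - g_j is kept positive by validation and by prior
truncation.

**Transitions (higher-order hidden Markov).**  Mastery is absorbing.
For an unmastered skill k,

    logit P(alpha_k(t+1) = 1 | alpha_k(t) = 0) =
        lambda_0 + lambda_theta * theta_i + lambda_alpha * m_i(t)
        + covariate main effects + intervention interactions,

where theta_i ~ N(0, 1) is a general learning ability and m_i(t) the
number of already-mastered other skills.  All three between-module gaps
follow the same law.  The *fitted* initial law is an unstructured
mixing vector over the 16 profiles, shared across persons, with a flat
Dirichlet prior — the published convergence monitoring states that
uniform initial attribute patterns were used, and this matters: when we
instead estimated a theta-driven (higher-order logistic) initial law,
the model systematically reclassified able transitioners as initial
masters (the initial-model slope inflates, transitions survive only for
low-theta persons), flipping the sign of the recovered lambda_theta on
some cohorts.  The *generator* still draws initial profiles from the
higher-order logistic, so recovery tests run under that mild
misspecification, as the original analysis presumably did.

**Response times (lognormal).**  log L_ij(t) is normal with mean
gamma_j - (tau_i + phi_alpha G(alpha_i(t), q_j) + covariate terms) and
variance 1 / a_j; gamma_j is the item time intensity (log-seconds), a_j
the time discrimination read literally as a precision, tau_i a latent
speed.  G = 1 when the person masters all skills the item requires, so
the accuracy and speed sub-models share the latent trajectory.  tau_i
given theta_i is normal with mean kappa * theta_i (kappa = rho *
sigma_tau) and constant variance, both hyperparameters estimated.

**Identifiability.**  theta has fixed location/scale (0, 1); tau's
location is absorbed by the gamma_j; lambda_theta >= 0 is the loading
sign convention that removes the reflection symmetry (theta,
lambda_theta, kappa) -> (-theta, -lambda_theta, -kappa).  lambda slopes
and phi carry N(0, 4) priors — weakly informative on the
logit/log-second scales but essential: with much flatter priors the
transition block drifts along a near-flat ridge (lambda_theta and the
realized spread of theta co-adapt) and wanders to implausible
magnitudes.  The transition intercept lambda_0 gets a flatter N(0, 25)
prior: shrinking an intercept whose true value sits far from zero leaks
into the correlated slope block (the mastered-skill-count coefficient
absorbs the compensation).  gamma_j ~ N(3, 100), a_j ~ Gamma(1, 1),
(s_j, g_j) uniform on the triangle s, g > 0, s + g < 1.

## MCMC

A Metropolis-Hastings-within-Gibbs sweep:

1. **Trajectories**: exact forward-filter backward-sample over the 16
   monotone profiles per person (4 time points).  Because covariates and
   theta are time-constant and the per-skill transition probability
   depends on the current profile only through its popcount, the
   person's 16 x 16 transition matrix is `p^(new skills) (1-p)^(still
   unmastered)` with a person-by-profile p — one matrix for all gaps.
2. **(s_j, g_j)**: truncated-Beta Gibbs given the sampled mastery
   indicators, enforcing s + g < 1.
3. **(gamma_j, a_j)**: conjugate normal and gamma updates.
4. **phi**: a *collapsed* multivariate-normal draw with tau integrated
   out analytically (Woodbury identity per person).  Person-level
   covariate columns are otherwise confounded with tau and the
   conditional Gibbs draw mixes glacially; collapsing restores
   regression-like mixing for the speed coefficients.
5. **tau_i**: conjugate normal given the new phi; then (kappa,
   sigma_tau^2) by conjugate regression updates.
6. **theta_i**: vectorized random-walk MH over persons (transition +
   initial-profile + tau-link + prior terms).
7. **lambda**: a componentwise random-walk scan plus one joint MH move
   along the empirical covariance of the burn-in draws (the 12
   coefficients are strongly correlated; axis-aligned moves cross the
   ridge slowly), truncated to lambda_theta >= 0.  Proposal scales adapt
   only during burn-in and are frozen afterwards, preserving detailed
   balance for the retained draws.
8. **Initial-profile mixture**: conjugate Dirichlet update from the
   sampled t = 1 profiles.

Chains start from empirical values — theta from standardized total
scores, (s, g) from item accuracies among high/low scorers, gamma and a
from log-time moments — jittered per chain.  From neutral common starts
both chains can settle into the same misaligned-theta mode that local
moves never leave.

Defaults: 2 chains, burn-in = first half, thinning 1.  Convergence is
monitored by the multi-chain Gelman-Rubin PSRF, R-hat =
sqrt(var+ / W), var+ = ((n-1)/n) W + B/n, maximized over all structural
parameters (item parameters, lambda, phi, initial-model coefficients,
hyperparameters; person-level theta/tau are excluded from the maximum as
is usual for latent units).  The declared cutoff is 1.2.  On
study-condition synthetic fits the maximum PSRF reaches the cutoff only
toward ~10,000-15,000 total iterations, consistent with the published
monitoring of this model class; short pilot fits (a few thousand sweeps)
still show drift in the transition block.  The acceptance script
therefore runs 2 x 12,000 sweeps per fit.

**Posterior summaries.**  Mean, SD and central 95% credible interval per
parameter; a coefficient is flagged significant when its interval
excludes zero.  Trajectory estimates: marginal posterior mastery
probabilities per (person, skill, time), thresholded at 0.5 and
re-monotonized for MAP trajectories.

## Synthetic cohorts

The generator reproduces the study's statistical structure so every
stage can be exercised without the (unavailable) original data:

- exact covariate margins: 401/147 female/male, 223/325 US/China,
  264/284 color/non-color, 62/63/423 Analytic/Holistic/Combined;
- (theta, tau) bivariate normal with Var(theta) = 1, sigma_tau = 0.25,
  rho = 0.3 (speed-ability association unreported; a mild positive
  default);
- transition generators: the two reported significant coefficients
  (lambda_theta = 2.821, lambda_alpha = 0.471), all non-significant
  coefficients set to 0, and intercept lambda_0 = -2.0 (unreported;
  fixed so per-gap transition probabilities stay in a plausible band);
- initial profiles: beta_theta = 1.5 with beta_0 = 2.2379 calibrated so
  the expected initial full-mastery fraction is 0.595, matching the
  study's estimate;
- speed generators: the six reported significant phi values, zero
  interactions;
- item parameters: drawn around the reported per-module means of
  (s, g, a, gamma) with small normal jitter, truncated to 1 - s - g >
  0.02.  Within each module, single-skill items guess high / slip low /
  run fast and two-skill items the opposite (guessing ratio 2.0,
  slipping ratio 2.5, +-0.25 log-seconds, +-0.1 precision), balanced so
  module means stay exactly at the reported values.  This matches the
  published item-parameter pattern and is what makes skill transitions
  identifiable: a module of interchangeable items would carry much less
  diagnostic information than the real heterogeneous bank.

What the generator does *not* emulate: engagement filtering, a hard
90-to-180-degree skill hierarchy (only the soft association through
theta), item-position or fatigue effects, and missing data (supported by
the mask machinery but not generated).  Passing recovery tests therefore
demonstrates internal consistency of model and sampler under the study's
design, not robustness to those real-data features.

**Identification limits under the study conditions.**  With ~60% initial
full masters and lambda_0 = -2, only a few hundred 0 -> 1 transitions
occur in a cohort, so the transition coefficients are weakly identified:
posterior SDs are ~0.5-1.2 for lambda_theta / lambda_alpha (the
published SDs, 0.703 and 0.217, are of the same order).  The speed
coefficients, by contrast, draw on 21,920 response times and are
recovered to ~+-0.02.  Recovery assertions are therefore interval
coverage for lambda and absolute bias only for phi.

## The other stages

**Measurement-model selection.**  Per module, marginal-ML EM over an
unstructured 16-class mixture for DINA, DINO, ACDM (identity link), LLM
(logit), RRUM (log) and saturated GDINA.  M-steps are closed-form where
possible (DINA/DINO/saturated) and Nelder-Mead with a generalized-EM
guard for the additive links; each model is initialized inside its own
parameter space (starting from a DINA-shaped point would break EM
monotonicity for non-conjunctive models).  Five jittered restarts guard
against multimodality.  Test level: AIC = -2l + 2p, BIC = -2l + p ln n
with p = per-item parameters + 15 mixing weights.  Item level: Wald
tests of each reduced model against the saturated item, covariance from
the full-model outer-product-of-gradients (inverting only an item's own
block understates the variance and over-rejects), restrictions expressed
as contrasts on the identity/logit/log scale, df = number of
restrictions, alpha = 0.05.  Retained-model tie-break: DINA, then DINO,
then largest p-value.  Single-attribute items are DINA by construction.

**Item clustering.**  K-prototypes (squared Euclidean + weighted
categorical mismatch, weight default 0.5 x mean numeric SD) with
best-of-n restarts, cluster count chosen by the Global Silhouette (mean
per-item silhouette under the mixed dissimilarity; singletons score 0 by
convention, ties go to the smaller count).  Default features are
per-item summaries (accuracy overall and by gender/country stratum,
mean/SD log RT); raw person-indexed vectors are available.  The
cluster/Q cross-tab labels the cluster holding most single-skill items
'simple' and flags items whose declared complexity disagrees with their
empirical group.

**Reliability.**  The classification consistency index of a module:
exact enumeration of all 2^10 response patterns, MAP classification
under the module's own EM estimates (ties to the lowest profile index),
per-class consistency sum_c' P(c'|c)^2, weighted by the mixing
proportions.  Tests >= 15 items fall back to seeded Monte Carlo.

**Test assembly.**  Hard constraints: the blueprint's per-module skill
pattern counts, enforced exactly.  Soft constraints: qualitative bands
('easy', 'balanced', ...) mapped to quantile intervals of the bank for
the module mean of difficulty/discrimination/shape, plus a parallelism
penalty between the two testing modules.  Greedy seeding + 2-swap local
search among same-pattern items; the published Phase-II assembly
algorithm is not described in enough detail to reproduce, so this
package implements its own clearly-labeled heuristic with the same
contract.  Items are presented in ascending difficulty, ties by ID.

**Evaluation.**  Non-masters = persons whose MAP initial profile lacks a
skill.  Pre/post module scores: paired t with r = sqrt(t^2/(t^2+df)).
Per-skill mastery-rate change: McNemar's paired-proportion chi-square
with continuity correction (the standard paired-proportion test; the
original analysis names only "a chi-square test on paired proportions"),
and Cohen's h = |2 asin sqrt(p2) - 2 asin sqrt(p1)|.  Note the published
per-skill h values do not match this standard formula applied to the
published rates (which gives 0.177-0.249); the package reports the
formula's value.  Ability groups: quartiles of posterior-mean theta
(type-7 quantiles), mean mastered-skill count per group and time.

## Problem sizes and runtimes

The test suite runs cohorts of 548 persons for study-scale checks and
60-80 persons for structural checks; the monitored MCMC fit in the
acceptance tests uses 2 x 5000 sweeps (~1.5 min) with two 2 x 1500
replicates, and the acceptance script runs four replicate cohort+fit
pairs at 2 x 10,000 sweeps (~3 min each), reporting
replicate-averaged posterior means.  EM fits converge in well under a
second per module-model pair at n <= 3000.

## Known limitations

- The transition block's posterior is diffuse under the study
  conditions; single-cohort point estimates of lambda scatter around the
  generating values with SD comparable to the published posterior SDs.
- The Wald covariance uses the outer-product-of-gradients; with very
  sparse reduced-profile groups an item can be flagged unstable rather
  than tested.
- The k-prototypes implementation targets module-sized item sets (tens
  of objects); it enumerates nothing, but it is not tuned for large
  feature matrices.
- CCI is computed from cross-sectional module estimates; feeding
  joint-model item parameters instead changes the numbers (the original
  report does not say which source it used).
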