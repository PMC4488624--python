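# Methods

## The task and its structure

The pipeline models a hypothetical-reward delay-discounting (DD) task:
binary choices between a smaller-but-sooner (SbS) monetary option, delayed at
most 14 days, and a larger-but-later (LL) option, delayed at most 365 days.
A session holds 110 trials; 10 are control trials that show the identical
option on both sides of the screen and only probe left/right response bias,
the remaining 100 are experimental. Subjects complete three sessions whose
stimulus sets are matched on four statistics (mean SbS amount, mean LL
amount, mean SbS delay, mean LL delay) so that sessions are interchangeable.

The generator enforces matching by rejection sampling: a candidate session is
accepted only if its four experimental-trial means lie within the configured
tolerances (defaults 0.5 EUR for amounts, 2 days for delays) of every
previously accepted session, with an attempt cap (default 1000) after which
generation fails naming the worst-violating mean. Amount and delay grids are
configurable; the defaults draw SbS amounts from whole euro in [1, 15], LL
amounts as the SbS amount times Uniform[1.5, 5] rounded to whole euro
(floored at SbS + 1), SbS delays from {0..14} days (0 = "immediately") and LL
delays from {15..365} days, with calendar-month conversions at 30 days/month.
These grids span the canonical stimuli of this task family while admitting
both immediate and merely-sooner SbS options. The SbS screen side is exactly
counterbalanced (50 left / 50 right) within each session.

## Valuation models and the choice rule

Two per-subject valuation models are compared.

*Discounted utility* (du, 3 free parameters K, r, beta):

    V(M, d) = (1 - exp(-r M)) / (r (1 + K d))

a nonlinear utility of amount M (concave for r > 0, convex for r < 0, linear
in the r -> 0 limit) under hyperbolic delay discounting with rate K per day.

*Standard hyperbolic* (hyp, 2 free parameters K, beta):

    V(M, d) = M / (1 + K d)

Choice probabilities follow a binary softmax on unnormalized values with
inverse temperature beta:

    P(SbS) = 1 / (1 + exp(-beta (V_SbS - V_LL)))

Numerical choices: the utility numerator is evaluated with `expm1`; for
|r| < 1e-12 it switches to the two-term series M - r M^2/2 (relative error
O((rM)^2)), making du exactly continuous through r = 0 where it equals the
hyperbolic value. The sigmoid is computed on |x| so that
P(a,b) + P(b,a) = 1 to the last bit, and probabilities are clamped
symmetrically to [1e-12, 1 - 1e-12] before any logarithm, so likelihoods stay
finite for saturated choices. r may be negative (convex utility); K and beta
are constrained positive.

## Maximum-likelihood fitting

Each subject's non-control choices are pooled across the three sessions (300
trials) and fit per model by minimizing the Bernoulli negative log-likelihood
with L-BFGS-B in a transformed space (log K, r, log beta), because K and beta
are positive and heavy-tailed across subjects. Box bounds are
K in [1e-6, 100] /day, r in [-1, 1] /EUR, beta in [1e-3, 100] — an order of
magnitude beyond the cohort dispersions. Ten restarts (first at a canonical
mid-range point, the rest drawn from the cohort priors below) guard against
local optima; `n_starts_agreeing` counts restarts ending within 1e-3 nats of
the best and `boundary_flag` marks estimates within 1e-6 of a (transformed)
bound. Degenerate inputs (e.g. an all-SbS choice vector) return a flagged
boundary fit rather than raising. Fits are scored by AIC = 2k + 2 NLL with
k = 3 (du) or k = 2 (hyp). A per-session fitting option exists, but pooled
fitting is the default since the behavioral K is a single per-subject trait
value and pooling maximizes trials per fit.

## Random-effects Bayesian model selection

Group-level model comparison treats the generating model as a random effect:
population model frequencies carry a Dirichlet prior (alpha0 = 1 per model)
and a variational fixed point

    u_nk ∝ exp(L_nk + psi(alpha_k) - psi(sum alpha)),   row-normalized
    alpha = alpha0 + sum_n u_n

is iterated until max|delta alpha| < 1e-6 (cap 1000 iterations, convergence
flagged). Per-subject log-evidence is approximated from AIC as -AIC/2, the
standard information-criterion evidence convention. Two summaries are
emitted: the posterior model probability phi_k = alpha_k / sum(alpha)
(the expected population frequency) and the exceedance probability
P(model k is the most frequent), computed exactly from the Beta CDF at 1/2
for two models and by Monte-Carlo Dirichlet sampling (1e6 draws, seeded) for
three or more. Note the posterior probability is capped at
(alpha0 + N) / (K alpha0 + N) — 71/72 ≈ 0.986 for N = 70 subjects and two
models — so decisive evidence is expressed by the exceedance probability
approaching 1 while phi approaches its cap. The subject-wise weights are
invariant to row shifts of the log-evidence matrix and to subject order.

## Behavioral metrics

The behavioral impulsivity score is the per-session count of SbS choices
over the 100 experimental trials, averaged over the three sessions (count
and percentage coincide on a 100-trial base). Fitted K is heavy-tailed, so
parametric tests use ln K; a one-sample Kolmogorov–Smirnov test against a
normal with the sample's own mean and SD documents the non-normality of raw
K. Control trials feed an exact two-sided binomial test of left responses
against 1/2. Pearson correlations use the t reference with df = n - 2;
group contrasts use the Student two-sample t test. Subjects with boundary
fits are retained and flagged downstream rather than excluded.

## Structural association battery

Each battery cell is a partial correlation between one DD parameter
(SbS score or ln K) and one subcortical region-hemisphere volume: both
variables are residualized on an intercept plus the covariates by least
squares, the residuals correlated, and the p-value taken from a t reference
with df = n - 2 - n_covariates. Covariate presets mirror a two-step
analysis: whole-brain volume alone ("wbv") or whole-brain volume, gender and
age ("wbv+gender+age", the default). With the default 6 regions x 2
hemispheres x 2 parameters, the battery runs 24 tests and the Bonferroni
threshold is alpha/m computed from the number of tests actually run
(0.05/24 ≈ 0.002). Subjects missing from either table or with missing values
are dropped with a logged reason; rank-deficient covariate sets raise an
error naming the collinear columns.

## Synthetic cohort generator

Because the target dataset is not publicly deposited, validation runs on a
synthetic cohort whose population marginals match the reported descriptives:

| parameter | distribution | defaults | rationale |
|---|---|---|---|
| K (/day) | log-normal | median 0.03, log-scale 1.5 | heavy right tail; cohort median at 0.03 |
| r (/EUR) | truncated normal | N(0.03, 0.10) on [-0.25, 0.5] | admits convex (r < 0) utilities without pathological values |
| beta | gamma, moment-matched | mean 7.04, SD 8.28 | dispersed choice stochasticity (shape ≈ 0.72) |
| gender | fixed split | 51 female / 19 male of 70 | cohort composition |
| age (years) | uniform | 19–44 | observed range |

Volume tables mimic Freesurfer subcortical segmentations: whole-brain volume
is N(1.15e6, 1.1e5) mm^3; each region-hemisphere volume is the region's
population mean (caudate 3700, putamen 5500, pallidum 1800, hippocampus
4200, amygdala 1700, accumbens 600 mm^3) scaled by relative brain size plus
Gaussian noise (SD = 6% of the mean). A caudate–SbS association is planted
by adding c·z to both caudate volumes, where z is the covariate-residualized
and standardized SbS score and c = sigma·rho/sqrt(1 - rho^2), so the
expected partial correlation equals the target rho exactly by construction.
All generators fan per-component seeds out of one master seed through a
`SeedSequence`-based scheme, so every artifact is reproducible bit-for-bit.

What the generator does *not* emulate: session-order and learning effects,
response times, within-subject parameter drift across the month of testing,
non-Gaussian volume noise, and any volume association beyond the planted
caudate effect. Passing tests therefore demonstrate that the estimators and
the battery behave correctly under the assumed generative family — not that
the same effect sizes would be observed in new empirical data.

## Calibration results the test suite recomputes

- Model attribution: on a 70-subject cohort generated from the du model
  (300 trials each), the BMS exceedance probability of du reaches ~1.0 and
  phi ~0.985, at its theoretical cap.
- Parameter recovery: true-vs-fitted log-K correlation on the default cohort
  is ~0.79–0.97 across seeds (median ≈ 0.92). The limiting factor is the
  gamma beta prior: ~13% of agents draw beta < 0.5 and respond near-randomly,
  leaving K unidentifiable at 300 trials; the fitted NLL never exceeded the
  NLL at the generating parameters for any subject, so the residual error is
  statistical, not an optimization artifact.
- Association calibration: with no planted effect the uncorrected
  false-positive rate per cell is 0.05 and the family-wise error at the
  Bonferroni threshold stays below 0.05 (1000 replicates, n = 40); a planted
  caudate effect of rho = 0.3 at n = 70 is recovered with mean partial r
  within 0.02 of the target (200 replicates), and at rho = 0.4 at least one
  caudate row survives Bonferroni in ~80% of replicates.

Problem sizes in the test suite (cohort of 70 x 300 trials fit once and
shared across tests; calibration at 1000 null replicates of n = 40 and 200
planted replicates of n = 70) were chosen to keep the full suite in the
one-minute range on a single core while leaving the Monte-Carlo error well
inside the asserted bands.

## Known limitations

- The AIC-to-evidence conversion (-AIC/2) is a convention, not an exact
  marginal likelihood; BMS conclusions inherit its penalty structure.
- The du model's r and K are partially collinear at small delays; recovery
  of r individually is noisier than K and is not a headline claim.
- The battery treats hemispheric volumes as separate tests, as in the
  24-test design; it does not model their within-subject correlation.
- Bonferroni control is conservative for correlated cells; no
  false-discovery-rate alternative is provided.
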