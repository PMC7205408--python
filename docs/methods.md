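# Methods

This note documents the data-generating model, the estimators, the decision
rule, the design tools, and the numerical and design choices behind them. It
states no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Trial generator

**Population and randomization.** A trial of expected size `2·n_per_arm` is
drawn with iid Bernoulli(0.5) allocation — each participant has a 50% chance
of the experimental arm — so arm sizes are random around `n_per_arm` rather
than forced 1:1 blocks. Participant characteristics are K iid confounders
`C_k ~ Beta(a, b)` on [0, 1]; the default Beta(2, 2) is symmetric with mean
0.5 and no boundary pile-up, consistent with a disease-risk-score reading.
The shapes are configurable because nothing in the problem fixes them.

**Counterfactual outcomes.** Failure probabilities follow a clipped linear
probability model with a common confounder slope γ across treatments:

```
p_a(C) = clip(μ_a + γ·Σ_k (C_k − E[C]), 0, 1)
μ_{a0} = p0,  μ_{a1} = p0 + θ,  μ_{a2} = max(μ_{a0}, μ_{a1}) + δ_alt
```

The shared slope makes `E[p_{a1}(C) − p_{a0}(C)] = θ` exactly whenever no
individual is clipped. γ is defined *pre-clipping* so that a stated "slope of
failure on the confounder" of 1, 5 or 9 is directly interpretable; slopes of
5 or 9 imply heavy clipping (most individuals sit at 0 or 1), which is
intentional — they model a confounder that nearly determines outcome. Note
one second-order consequence used by the test suite: at the defaults
(γ = 1, θ = 0.1, Beta(2, 2)), `p_{a0} = clip(C − 0.1)` clips at zero for
C < 0.1, so the realized average contrast is θ − E[(0.1 − C)⁺] ≈ 0.0990
rather than 0.1000. The attenuation oracle test accounts for this with an
independent quadrature.

**Alternative treatment.** `μ_{a2} = max(μ_{a0}, μ_{a1}) + δ_alt` makes the
alternative inferior to *both* trial treatments by at least `δ_alt`
(default 0.1). With θ = 0.1 this gives control/experimental/alternative mean
failure 0.4/0.5/0.6 (alternative 0.2 worse than control, 0.1 worse than
experimental); with θ = 0, 0.4/0.4/0.5. This is the only reading under which
"inferior to both" holds for every θ, and it is the package's resolution of
the ambiguity in how the two alternative-treatment contrasts pair up.

**Adherence.** Adherence is binary. Only arms targeted by the scenario can be
non-adherent; within a targeted arm the adherence proportion is ρ. Two modes:

- *threshold* (default): exactly `ceil((1−ρ)·n_arm)` participants are
  non-adherent. Under confounded mechanisms they are the ones with the most
  extreme mean-confounder score in the scenario's direction — e.g. in the
  discordant direction (confounder lowers experimental-treatment uptake and
  raises failure risk) the highest scores in the experimental arm and the
  lowest scores in the control arm deviate. Under non-confounded mechanisms
  the exact-count subset is chosen uniformly at random, independent of C.
- *stochastic*: non-adherence is drawn per participant. Non-confounded:
  iid Bernoulli(1−ρ). Confounded: a propensity monotone in the same score,
  `P(non-adherent) = expit(λ + δ·key)` with the intercept λ solved by
  bisection so the arm-level mean equals 1−ρ; a clipped linear link
  (`clip(λ + δ·key, 0, 1)`) is available via `link="linear"`.

The logistic link is the default for the stochastic mode because it
guarantees positivity (every participant has adherence probability strictly
between 0 and 1) for any slope δ, and because it keeps the generating
propensity inside the family the IPW analysis model fits; the clipped linear
link either violates positivity once clipping bites or forces δ to be small.
The default δ = 3 on the log-odds scale gives roughly a 20-fold odds ratio of
non-adherence across the confounder's full range — a strong but not
pathological confounder.

The *direction* factor of a confounded scenario fixes only the *sign
relation* between the confounder's uptake and outcome effects (concordant =
same sign, discordant = opposite). With the outcome slope positive (the
default), concordant means the confounder raises experimental-treatment
uptake; flipping the sign of γ flips both, without changing scenario
identity.

**Consistency and validation.** The observed outcome is the counterfactual of
the received treatment; every generated trial is validated row-wise for
consistency, adherent-implies-allocated, and a2-only-in-alternative-scenarios
before it is returned.

**Seeding.** Monte-Carlo drivers derive one child generator per iteration as
`default_rng([master_seed, iteration])`, so results are independent of
execution order and the same iteration uses common random numbers across
adherence levels and candidate sample sizes (variance reduction for
monotonicity comparisons and the required-n search).

## Estimators

All four report the absolute risk difference with a two-sided interval
(default 95%, normal quantile 1.959964).

- **ITT / PP:** unpooled Wald intervals,
  `SE = sqrt(p̂1(1−p̂1)/n1 + p̂0(1−p̂0)/n0)`, no continuity correction —
  the same convention as the closed-form sample-size formula. Degenerate arms
  (0 or 100% failures) keep the plain formula, possibly with SE 0. An arm
  with no analyzable participants raises an estimation-failure signal rather
  than returning a number.
- **IPW:** one logistic regression per allocation arm (adherent indicator on
  a configurable subset of confounders; arm-specific models match the notion
  of adherence *to a particular arm*; a pooled model with Z as covariate was
  the alternative). Adherent participants are weighted by the inverse fitted
  adherence probability; the estimate is the difference of Hajek weighted
  means. The default interval uses a sandwich variance treating weights as
  known — fast enough for thousand-iteration sweeps — with a within-arm
  nonparametric bootstrap (weight model refit per resample, percentile
  interval) as a check. Non-convergence, non-finite fits, or a numerically
  zero fitted probability for an adherent participant signal failure.
- **IV:** the single-instrument linear structural mean model, which for
  binary Z and binary A is the Wald ratio
  `[Ȳ₁ − Ȳ₀] / [D̄₁ − D̄₀]` (D = received the experimental treatment).
  Variance by the delta method including the within-arm covariance of Y and
  D; Fieller intervals are not implemented. IV is restricted to crossover
  scenarios (with an alternative treatment the received treatment is not
  binary and the single-IV SMM does not apply); calling it there is a usage
  error, distinct from the estimation-failure signal raised when the
  compliance difference is below 0.01 in absolute value (the "near-zero
  denominator" guard; at the trial sizes of interest the sampling SD of the
  denominator is ≈ 0.03, so this guard only trips when the instrument is
  essentially dead).

**IPW under the threshold mechanism.** Rank-based (threshold) confounded
non-adherence makes the true adherence propensity an indicator function of
the score: positivity fails, and a perfectly fitted adherence model would
collapse IPW onto PP. In practice the logistic fit is smooth and IPW removes
much — not all — of the PP bias there. Claims about IPW *consistency* are
therefore tested under the stochastic mode, where positivity holds and the
weight model is correctly specified; even there, a residual finite-sample
bias of order 0.005 at 505/arm remains (Hajek ratio plus estimated weights),
which is why the unbiasedness test uses an absolute tolerance of 0.01 rather
than a pure Monte-Carlo band.

## Non-inferiority decision and experiments

Non-inferiority is concluded iff the CI upper bound is *strictly* below the
margin (a measure-zero boundary, fixed for determinism). The engine simulates
each iteration once and analyzes it with every requested method, so methods
are compared on identical data. Iterations where an estimator signals failure
are excluded from that estimator's conclusion-rate denominator and reported
in a `failed` column (default); a conservative policy counting failures as
"not non-inferior" is available by flag, since how such iterations should be
tallied is a genuinely open convention. IV rows for alternative-destination
scenarios are emitted as not-applicable (NaN statistics) rather than
silently dropped.

Default study conditions: 505 participants per arm, margin 0.1, 95% CI, 1000
iterations, adherence grid 0.60–1.00 in steps of 0.05 (the step is a package
choice; only the range is inherent to the problem).

## Design tools

The closed-form sample size is the unpooled normal-approximation formula

```
n/arm = ceil((z_{1−α} + z_{1−β})² · [p_c(1−p_c) + p_e(1−p_e)] / (M − (p_e − p_c))²)
```

chosen because it reproduces the canonical 505/arm for p = 0.4, M = 0.1,
α = 0.025 one-sided, 90% power; feasibility requires M > p_e − p_c (checked
with a 1e-12 float tolerance). `required_n` searches the smallest n on a
5-participant lattice whose empirical power reaches the target, by bisection
with the same seed at every candidate (common random numbers); a candidate
whose estimated power exactly equals the target is accepted. The bracket is
checked first so configuration errors surface before any long simulation.

## What the generator does and does not emulate

The generator reproduces the mechanisms that drive the phenomena of interest:
randomized allocation, confounders affecting both adherence and outcome,
crossover vs alternative-treatment deviation, and exact consistency between
counterfactual and observed outcomes. It does **not** model time-varying
treatment or adherence, partial/graded adherence, missing outcomes or
censoring, measurement error in confounders, correlated confounders (the K
confounders are iid and enter through their sum with shared slopes), or mixed
deviation patterns within one trial (crossover and alternative are separate
extreme cases). Passing tests therefore demonstrate the estimators' behavior
under these idealized mechanisms — e.g. that ITT type-I inflation follows the
attenuation law, or that IV is unbiased when the exclusion restriction holds
by construction — not their performance under the richer violations real
trials exhibit.

## Problem sizes used in the shipped checks

The test suite and acceptance script use the reference design (505/arm) with
1000 iterations for the headline type-I-error and power numbers, 10,000
replicates for the attenuation law, and 200–400 iterations for the
qualitative bias-direction and monotonicity properties, where the effects
being detected are an order of magnitude larger than the Monte-Carlo noise at
those counts. The required-n searches use 400 iterations per candidate with
common random numbers.
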