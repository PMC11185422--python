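# Methods

This note documents the models, estimators and numerical choices behind
`vernier2ifc`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the methodology left room.

## Task and data model

One trial of the 2IFC Vernier task records: the true offset orientation
(left/right), which interval carried the offset (OP first or second), the
orientation response given after each interval, and the forced choice of the
interval with the more visible offset. Analyses consume counts collapsed
across offset orientation, interval order and session into per participant ×
level joint-outcome tables: n11/n10/n01/n00 for (orientation correct ×
interval correct), with the same four counts kept separately for OP-first
and OP-second trials. Correctness flags are derived at load time and never
stored, so files cannot carry inconsistent flags.

Levels are indexed 1-based with 1 the hardest condition. The masked task has
six inter-stimulus intervals linearly spaced over 16.7–100 ms; the unmasked
task eight durations log-spaced over 980–3000 µs. Covariates enter every
regression scaled by the largest level value, giving values in (0, 1].

Participants are screened per task: correctness (orientation; interval
selection) is regressed on scaled level per participant by maximum
likelihood, the slope summarized as (estimate, SE), and scored with a Bayes
factor — H1 a positive slope (upper half-Gaussian, sd 2.30), H0 a point
null. BF10 ≤ 1/3 on either response type flags exclusion; a cross-task
policy (excluded anywhere → excluded everywhere) is available in the
pipeline configuration.

## Hierarchical logistic model

Performance at level *i* for participant *j* is modelled as

    Correct ~ Bernoulli(p),  logit p = a_j + b_j·level_i
    a_j ~ Normal(ā, σ_a),  b_j ~ Normal(b̄, σ_b)
    ā ~ Normal(0, 0.25),  b̄ ~ Normal(0, 1),  σ_a, σ_b ~ Exponential(1)

The ā prior corresponds to a group-level threshold between 0.38 and 0.62 on
the probability scale with 95% probability (`prior_threshold_interval`). The
intercept-only variant of the same model serves the response-bias analyses.

The posterior is sampled with emcee's affine-invariant ensemble sampler:
non-centered parameterization (participant effects as standardized offsets),
log-scale σ with the Exponential(1) prior's Jacobian, differential-evolution
moves (80% DEMove, 20% DESnookerMove), and a vectorized log posterior over
the walker ensemble. Defaults are 64 walkers × 2000 steps with the first
half discarded; heavier analyses in the drivers use longer chains. Walkers
are treated as chains for split-R̂ and bulk-ESS via arviz; runs that do not
reach R̂ < 1.01 carry an explicit diagnostics warning on the posterior
object rather than failing, because interacting-walker R̂ decays slowly even
when the posterior summaries are stable. Population-level predictions are
summaries of inverse-logit(ā + b̄·level) over draws.

## Bayes factors

Every inferential claim uses the same calculator: the effect of interest is
summarized as a Normal likelihood by the posterior predictive (mean, sd) and
integrated against each hypothesis' prior; BF10 is the ratio of marginal
likelihoods. Priors per family:

| family | H0 | H1 | easiest-level H1 sd |
|---|---|---|---|
| above-chance performance | Normal(0.5, 0.005) | upper half-Normal at 0.5, sd = (pred. performance at level i+1 − 0.5)/2 | 0.25 |
| Type-2 HR−FAR, conditional | point at 0 | upper half-Normal at 0, sd = predicted difference at level i+1 / 2 | 0.5 |
| interval order | point at 0 | Normal(0, 0.1) | — |
| exclusion slope | point at 0 | upper half-Normal at 0, sd 2.30 | — |
| response bias | point at 0.5 | Normal(0.5, 0.025) | — |

The level-dependent sds encode that a harder condition cannot outperform its
easier neighbour; when the neighbour's prediction shows no excess, the sd is
floored at 1e-3 and a warning is logged. Marginal likelihoods are computed
in log space: the integrand (a possibly truncated Gaussian product) is
shifted by its log maximum at the product mode and integrated by adaptive
quadrature over ±15 product-sds clipped to the prior support (relative
tolerance 1e-10); `log_bf10` therefore stays finite even when one
hypothesis sits hundreds of log units into its tail. Normal-prior marginals
agree with the closed form Normal(obs; center, √(obs_sd² + sd²)) to
relative 1e-6 (tested).

The bias analyses are additionally summarized by a one-sample two-tailed t
test of per-participant response percentages against 50%. The source
describes these as independent-samples tests but reports t(n−1) against
chance; the arithmetic matches the one-sample form, which is what is
implemented.

## Observer models

Seven Bayesian observers in a 2D evidence space (axes: evidence for a
leftward/rightward offset; all sources have identity covariance):

| id | neutral source | strategy | judgment |
|---|---|---|---|
| 1 | origin | marginalize | confidence |
| 2 | origin | hierarchical | confidence |
| 3 | diagonal | marginalize | confidence |
| 4 | diagonal | hierarchical | confidence |
| 5 | origin | — | visibility |
| 6 | diagonal | marginalize | visibility |
| 7 | diagonal | hierarchical | visibility |

Marginalizing observers place a uniform prior over the discrete strength
grid (0…5 step 0.1; uniform is the only structure-free choice, the source
never states one). Hierarchical observers estimate ĉ per orientation by
argmax of the sample density on the grid (ties to the smaller strength) and
normalize the orientation posterior over the two orientations' ĉ-densities.
The no-stimulus hypothesis has prior 0 in the orientation decision;
orientation-posterior ties are broken by a seeded fair coin.

Visibility observers weigh the neutral-source hypothesis (prior 0.5)
against the oriented-source hypothesis (prior 0.5, split evenly between
orientations). Model 5 evaluates the neutral density at the origin; model 6
marginalizes the diagonal neutral source over the strength grid; model 7
evaluates all hypotheses at the chosen orientation's ĉ — the denominator
normalizes over {neutral at ĉ: 0.5, left at ĉ: 0.25, right at ĉ: 0.25},
i.e. model 6's construction restricted to a single strength. Model 5 has a
single neutral source, so the marginalize/hierarchical distinction does not
apply; it is implemented as one computation and its `strategy` attribute is
None.

`D` is a log ratio in all seven models with threshold 0 (the visibility
models are sometimes written as plain ratios thresholded at 1; the log form
preserves choices and gives the read-out noise a common additive scale).
Read-out noise δ ~ N(0, σ_D) is added to D only; orientation responses are
untouched. The OP interval is chosen iff D + δ > 0, with an exact tie broken
by a fair coin. The tie rule is a deliberate design choice: hierarchical
observers collapse their confidence to exactly 0.5 whenever both evidence
coordinates are negative (ĉ = 0 for both orientations), so at zero signal
the event D = 0 has probability ≈ 1/16 and any deterministic tie rule would
bias the 2IFC choice away from chance — contradicting the models' intended
unbiasedness at zero evidence. With c > 0 or σ_D > 0 ties are
measure-zero and the rule is inert.

Prediction tables are Monte Carlo: per strength, `n_sim` trials are
simulated once and the same noise draws are reused across the σ_D grid
(common random numbers), so the orientation-correct marginal is identical
down the σ axis and interval-accuracy comparisons across σ are paired.
Default grids: c 0…5 step 0.1; σ_D 0…1 step 0.01 (confidence observers) and
0…10 step 0.1 (visibility observers, whose D scale is more robust to
additive noise). Default `n_sim` is 10^5; the test suite and analysis
drivers use 2×10^4, which bounds per-cell Monte-Carlo error at ~0.0035 —
small against every tolerance used. The vectorized posterior machinery is
tested to 1e-10 against brute-force density-sum oracles.

## Fitting and comparison

Per participant and task:

1. **Percent correct.** Orientation accuracy per level is smoothed by a
   two-parameter logistic psychometric fit (ML; separation falls back to a
   half-count-smoothed refit) and floored at 0.5, since the observers only
   produce accuracies in [0.5, 1]. Smoothed accuracies are converted to
   effective integer counts (round(n·p̂) correct) — the source specifies
   both a parametric preprocessing step and a count-based likelihood without
   saying how they connect; rounding the smoothed proportions is the
   simplest reconciliation.
2. **Strengths.** One strength per level maximizes the binomial likelihood
   of the effective counts against the observer's orientation-accuracy curve
   at σ_D = 0, constrained nondecreasing from hardest to easiest. The
   discrete constrained optimum is found *exactly* by dynamic programming
   over the 51-point grid (O(L·K)); a genetic or any other global optimizer
   would be an implementation detail, not a different estimator. Exhaustive
   enumeration serves as the test oracle.
3. **Noise.** σ_D maximizes the four-outcome multinomial log likelihood of
   the actual joint counts by grid search, strengths held fixed; ties take
   the smaller σ. Probabilities are floored at 1e-6 before logs (logged when
   hit). Ideal fits clamp σ_D = 0.
4. **Scores.** BIC = −2 ln L + k ln n with k = number of levels (+1 for the
   noisy variant). Cross-validation splits trials into 10 folds balanced per
   level (fold sizes differ by ≤1 within a level), refits σ_D on 9 folds
   (strengths fixed at the full-data estimate) and scores the held-out fold;
   fold likelihoods combine by default as log of their mean via log-sum-exp,
   with mean-of-fold-log-likelihoods behind the `combine` flag. Note the
   default combination yields a single-fold-scale score for noisy fits,
   whereas the ideal observer — having nothing to refit — scores the
   full-data log likelihood exactly; the two variants' CV scores are
   therefore not on a common scale under the default and should be compared
   within variant (or with the alternative combination).

Subset refits: `incorrect_only` restricts the likelihood to the two
incorrect-orientation outcomes using probabilities conditional on an
incorrect response (the renormalization isolates Type-2 false-alarm
structure from orientation accuracy); `easy`/`hard` restrict to the two
easiest/hardest levels with a 70% orientation-accuracy eligibility screen
(easy requires ≥70%, hard requires <70%; ineligible participants raise a
typed error that drivers catch, drop and log).

## Synthetic data

The generator emulates the study design exactly: 12 participants; 6 masked /
8 unmasked levels; 128 or 144 trials per level per participant in the
published 5/7 (masked) and 7/5 (unmasked) split, making the
participant-weighted means 137 and 135; offset orientations and interval
orders balanced exactly within level; responses produced end-to-end by a
chosen observer at per-participant strengths and σ_D (optionally one σ_D
per level, e.g. to concentrate noise in hard conditions). The default
cohort uses observer 3 with strengths rising 0.3→2.5 (hardest-level
orientation accuracy ≈ 0.58, matching the near-threshold regime the task
targets) plus N(0, 0.1) per-participant jitter, and σ_D = 0.2 — the
small-but-nonzero access noise regime the fitted models favor. Lapses and
left/first response biases exist as generator-only extensions with defaults
of zero, so the core generator *is* the observer; with defaults, generated
joint-outcome frequencies converge to the observer's prediction-table cell
(tested at 3 Monte-Carlo SEs).

A master seed spawns per-participant substreams (`SeedSequence.spawn`), so
datasets are bit-reproducible and participants are independent.

What the generator does **not** emulate: session fatigue or learning,
serial dependencies, finger errors beyond the lapse model, or any
idiosyncrasy of real observers (unequal variances, criterion drift,
evidence correlations between intervals). Passing recovery tests therefore
shows the estimators are correct and well-calibrated *under the models'
assumptions* — not that real data satisfy those assumptions.

## Known limitations

* The ensemble sampler's split-R̂ (walkers as chains) typically sits above
  1.01 at default lengths even when posterior summaries are stable;
  the diagnostics warning is informative, not fatal. Chains several times
  longer reach conventional thresholds.
* Bayes factors depend on posterior-predictive summaries and hence mildly on
  MCMC settings; seeded runs are repeatable on a platform, but values are
  not bit-portable across BLAS builds.
* σ_D is estimated on the simulation grid; its resolution (0.01 / 0.1)
  bounds the attainable precision.
* The incorrect-only refit conditions on an event whose probability the
  model also predicts; its scores are comparable across models but not with
  full-data scores.
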