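# Methods

## The model

A single logistic output unit over four binary cue inputs (A, B, X, Y):
`a = σ(w·x + θ)` with `σ` the logistic function. Interpreted as a
reinforcement learner, the unit's activity is its estimate of the
probability that the current cue configuration will be rewarded; a trial is
"rewarded" when the training target is 1. The unit has no hidden layer and
no interaction inputs, so it is structurally committed to treating each cue
as a conditionally independent source of reward information. Everything the
package measures flows from that commitment.

Training is per-pattern ("stochastic") gradient descent: every epoch
presents all trials in a fresh uniform permutation, updating after each
trial by `w_i += η δ x_i`, `θ += η δ`. Two error signals are implemented:

- `cross_entropy` (default): δ = t − a, the exact gradient of the Bernoulli
  log-likelihood. With this choice the stationary point of the expected
  update is the maximum-likelihood logistic regression of the training set,
  which is the structural-equivalence result the package quantifies.
- `squared_error`: δ = (t − a)·a(1 − a), the gradient of ½(t − a)². Provided
  for comparison; it converges to a different (non-MLE) fixed point in
  general and is not used by the study drivers.

With a constant learning rate the iterate does not converge to a point: it
reaches a stationary *distribution* around the MLE whose spread grows with
η. Consequences we account for explicitly:

- Final-epoch snapshots of the 16 responses carry jitter (matching R²
  fluctuates by roughly ±0.02 at η = 0.05 and more at η = 0.25).
- Where a *behavioral level* rather than a snapshot is the quantity of
  interest (learning-rate robustness, invariance to row order of the stored
  sample), we use the response averaged over the recorded epochs in the
  second half of training (`TrajectoryRecord.mean_response`), which
  estimates the mean of the stationary distribution.

## The reward world

A `RewardModel` is a set of independent reward sources: per-cue lotteries,
optionally one AND/XOR gate over a cue pair (shipped presets gate (X, Y)),
and a baseline lottery that applies only to the all-cues-absent pattern (it
is *not* a background lottery on every trial). A trial's reward probability
is the union probability `1 − Π(1 − p_s)` over its active sources; reward is
granted at most once regardless of how many sources fire.

Two presets define the study conditions:

- **Independent**: A, B, X, Y pay 0.20, 0.40, 0.60, 0.80; baseline 0 (or
  0.05/0.10 in the baseline variants).
- **Gated**: A at 0.20 and B at 0.40 independent; X and Y carry *no*
  independent probability and pay only through the gate (AND or XOR of their
  presence bits) at 0.6 or 0.1.

Sampling a training set draws, for each of the 16 configurations × 100
replicates, one uniform number per active source in the fixed order
a, b, x-or-gate, y (baseline last); the trial is rewarded if any draw falls
at or below its source probability. One explicitly seeded `numpy` Generator
drives the whole set, making generation byte-reproducible. Rows are stored
in enumeration order; shuffling is entirely the trainer's responsibility,
so sampling reproducibility and training reproducibility are independent.

Every generated set can be screened by a per-configuration 1-df Pearson
goodness-of-fit χ² of observed (reward, no-reward) counts against the
union-rule expectation (default α = 0.05, no continuity correction; cells
with zero expected count are skipped and such configurations pass only if
their observed counts are exactly degenerate). Screening is report-only by
default; `generate_validated_training_set` retries with successive seeds
(max 20) for callers that want accept/reject semantics.

## Measurements

- **Matching R²**: squared Pearson correlation between the unit's 16
  responses and the *observed* per-configuration reward rates of its own
  training set. Observed rates, not population values, are the primary
  yardstick (the population version is exposed as a secondary diagnostic,
  `population_matching_r2`). Being a squared correlation it is affine
  invariant — it measures co-variation, not calibration.
- **Logistic MLE** (`fit_logistic`): main-effects-only binomial GLM fitted
  by IRLS (statsmodels), grouped by configuration; the grouped likelihood
  equals the 1600-row Bernoulli likelihood up to a constant. Coefficients
  beyond ±15 on the log-odds scale are flagged as quasi-separation and the
  fit is reported non-converged rather than iterated further.
- **Structure R²**: squared Pearson correlation over the 5 paired values
  (θ ↔ intercept, w_i ↔ slope_i). This is the operational test of the
  SGD ↔ logistic-regression equivalence.
- **Odds ratios**: `exp(w_i)` — the multiplicative effect of cue i's
  presence on the reward odds, other cues held constant.
- **Conditional-dependence score**: split trials by reward outcome; in each
  stratum build the 2×2 table of X-presence × Y-presence (collapsing A and
  B); sum the two uncorrected Pearson χ² statistics. Zero-margin tables and
  empty strata contribute 0 (the convention only triggers in degenerate
  hand-built sets). No continuity correction: the score is a descriptive
  effect-size-like quantity, not a test statistic.

## Study drivers and inference

`run_simulation1` generates 5 independent-cue sets (100 replicates each),
trains 20 networks per set, and summarizes matching R², structure R² and
the no-cue response. `run_simulation2` does the same over the 2×2 factorial
{AND, XOR} × {0.6, 0.1}, attaching each set's dependence score to its 20
networks. The two-way fixed-effects ANOVA (with interaction, df 1 and
N − 4) is computed from cell sums of squares — it is part of the analysis
proper, so it is implemented, with a statsmodels `anova_lm` cross-check in
the tests. The two competing predictors of per-network matching R² —
continuous dependence score vs the XOR/AND dichotomy — are compared by
simple OLS regressions (R², F = (N−2)R²/(1−R²) on (1, N−2) df); each
network contributes one observation carrying its training set's score.

Seed management throughout uses `numpy.random.SeedSequence` spawning
(master → condition → set → network), with recorded integer seeds truncated
to 31 bits. Identical master seeds reproduce every number exactly.

## Numerical choices

- Logistic evaluated in the stable two-branch form; responses never reach
  0 or 1 for finite inputs.
- The SGD inner loop is numba-compiled. Epoch permutations are drawn by a
  numpy Generator on the Python side and passed to the kernel in chunks of
  500 epochs, so the kernel is a pure function of its inputs; a pure-Python
  loop over `update_step` with the same streams reproduces it to 1e-12
  (tested). Weight initialization and shuffling use two SeedSequence
  children of the config seed, so either can be varied alone.
- A non-finite parameter aborts training with the offending epoch and row
  (with the bounded delta rule this requires absurd learning rates, but the
  guard is tested).
- Trajectories are recorded after an epoch completes, never mid-epoch;
  default schedule 1, 5, 10, 15, 20, 25, 50, 75, 100, then every 100.

## What the generator does and does not emulate

The synthetic worlds are exactly the study conditions: binary cues, known
per-source reward probabilities, conditional independence except through
one explicit gate, stationary schedules, balanced configuration counts.
They do not emulate drifting reward probabilities, correlated or continuous
cues, more than one interaction, or unbalanced designs — so passing tests
show that the learner recovers the structure of *this* family of worlds,
not that it would match probabilities under nonstationarity or richer cue
statistics.

## Problem sizes

The test suite runs the studies at reduced scale (2 sets × 10 nets for the
independent-cue checks; 5 sets × 5 nets per cell for the factorial; 250
epochs — justified by the convergence property that matching is established
within the first ~50 epochs and maintained thereafter, which is itself
tested). The acceptance script runs the full protocol: 2500 epochs, 5 sets
× 20 networks per condition, and 40 generation-only sets per condition for
the dependence means, chosen to shrink the Monte-Carlo standard error of
those means well below their between-set spread.

## Known limitations

- The no-cue overestimation (~0.15 at baseline 0) is inherent to the
  main-effects structure, not a training failure; raising the baseline to
  0.05–0.10 improves calibration of that cell only.
- At large learning rates (η ≥ 0.25) single-snapshot matching R² is noisy;
  conclusions at such rates should use time-averaged responses.
- The dependence score grows linearly with the number of trials; scores are
  comparable only between sets of equal size (all shipped designs use
  1600).
- The ANOVA F statistics at full scale are enormous and sampling-sensitive;
  signs, orderings and significance levels are stable, exact F magnitudes
  are not.
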