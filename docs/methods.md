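# Methods

## The model

A subject who ranks J labeled items produces J(J−1)/2 forced pairwise
decisions, one per item pair (j, k), j < k in label order: y_jk = +1 if j
is placed above k and −1 otherwise.  Because the decisions come from one
ordering, the pattern y = (y_12, …, y_{J−1,J}) is always transitive, and
exactly J! distinct patterns can occur (120 for the five-item sets this
package is built around).

The Bradley–Terry model assigns item j a worth π_j on the unit simplex;
the probability of preferring j over k is π_j / (π_j + π_k).  On the log
scale, π_j = exp(2λ_j) / Σ_k exp(2λ_k) with the identifiability constraint
Σλ = 0.  Treating the whole pattern as the observation gives the pattern
model

    p(y | λ) = exp(λ·x(y)) / Z(λ),   Z(λ) = Σ_y' exp(λ·x(y')),

where x(y) is the item-score vector: x_j is the signed number of pairwise
wins of item j, which for a complete ranking is always the arithmetic
sequence J−1, J−3, …, −(J−1) along the ranking order.  The sum runs over
the J! transitive patterns.  This is a regular exponential family in the
J−1 free coordinates of λ with sufficient statistic x.

The same model is often written as a Poisson loglinear model over the
subject-expanded pattern design (an intercept per block absorbing the
normalization, 987 × 120 = 118,440 rows at the study's scale).  The two
formulations have identical MLEs; the test suite asserts this against a
statsmodels Poisson GLM on a small table instead of maintaining the
loglinear path in production.

### Estimation

The log-likelihood over a pattern count table, ℓ(θ) = Σ_p n_p θ·u_p −
n log Σ_p exp(θ·u_p) in the reduced coordinates u_p = x_p[:J−1] − x_p[J],
is concave; a Newton iteration with analytic gradient and Hessian and
step-halving converges quadratically.  Convergence is declared when the
gradient max-norm falls below max(1e−8, 1e−12·n); iteration is capped at
200 steps and the `converged` flag reports the truth.  Pattern
enumeration, and hence fitting, is supported for J ≤ 7 (5040 patterns):
the design grows factorially and larger item sets should be avoided at
the design stage, not papered over computationally.

**Separation.**  When some item is (essentially) always ranked first or
last, the MLE diverges.  If any |λ| exceeds 15 during iteration the fit is
flagged, a warning is raised, and a ridge-penalized fit (penalty
1e−4·n·‖λ‖²) is returned so a finite, near-degenerate worth vector is
still available — ranking data can legitimately produce worths of order
1e−5, so graceful degradation matters more than refusing to answer.

**Confidence intervals.**  Worth intervals are delta-method intervals
computed on the log-odds of π_j and back-transformed.  This keeps bounds
inside (0, 1) and guarantees the point estimate is inside the interval; a
plain delta method on the π scale can violate both near the simplex
boundary.  The interval level is a parameter (default 0.95).

**Focal groups.**  A grouping such as expert vs. novice enters as a
saturated item-by-group interaction: group g has item parameters
λ_j + λ_js(g) with the reference group's offsets fixed at zero.  Because
the interaction is saturated, the grouped likelihood factorizes and each
group's parameters are the MLE of its own table; the total log-likelihood
equals the sum of per-group fits (asserted numerically in the tests).  The
group variable is never a splitting candidate.

## Recursive partitioning

At each node the pattern model is fitted and each subject's score
contribution s_i = x(y_i) − E_λ̂[x] is computed (these sum to ~0 at the
MLE).  For every candidate covariate a parameter-instability test asks
whether the scores drift systematically along that covariate:

- **numeric/ordinal** — the supLM statistic: subjects are ordered by the
  covariate (ties broken by input order, so runs are deterministic),
  scores are whitened by the inverse square root of the empirical
  information, and the maximum of ‖cumsum‖²/(t(1−t)) is taken over
  cut fractions t in [trim, 1−trim] with trim = max(0.1, minsize/n).
- **nominal** — within-category score sums aggregated into a chi-square
  statistic with (C−1)(J−1) degrees of freedom.

The supLM limit distribution (sup over the trimmed interval of the
squared norm of a (J−1)-dimensional Brownian bridge over t(1−t)) has no
closed form.  p-values are computed against a Monte-Carlo sample of that
limit (20,000 replicates on a 200-point grid, fixed internal seed), cached
per (dimension, trim).  The simulated 95th percentile for four degrees of
freedom and trim 0.1 is ~16.2, matching published critical values for the
sup-LM functional to within grid resolution; a type-I simulation (400
independent nodes, n = 400) gives a rejection rate of ~0.05 at α = 0.05.

Within a node, p-values are Bonferroni-adjusted across the candidate
covariates (configurable).  If the smallest adjusted p-value beats α
(default 0.05) the node splits on that covariate at the cutpoint
maximizing the sum of the two children's maximized log-likelihoods, over
all cutpoints leaving both children at least `minsize` subjects.  The
cutpoint is reported as the left child's largest observed value, so rules
read "age ≤ 15"; a value exactly at the cutpoint routes left.  Nominal
covariates search all binary partitions of their (≤ 10) levels.  Likert
items are ordinal: ordered for testing, threshold splits like "IP ≤ 2".

Recursion stops when no covariate is significant, the node is smaller
than 2·minsize, or `max_depth` (default 10) is reached.  The study design
this package emulates used minsize 40 for its ~1000-student sample and 4
for its ~50-participant expert/novice sample.  Subjects missing any
candidate covariate (or group label) are dropped at tree entry with the
count recorded on the tree.

**AIC post-pruning** (default on) walks the tree bottom-up and collapses
any split whose subtree AIC — −2·Σ terminal logliks + 2·Σ terminal
parameter counts — is not strictly below the parent node's own AIC.  The
operation never increases total AIC and is idempotent.  Note the α gate
does most of the overfitting control: a cutpoint chosen by maximizing the
children's log-likelihood is biased upward, so AIC alone prunes little.

## Bootstrap stability

B subject-level resamples (with replacement, original size n; study
default B = 1000) re-run the entire grow-and-prune pipeline.  Per
covariate we record the selection probability — the fraction of resamples
whose pruned tree uses it in at least one split — and the empirical
cutpoint distribution (numeric/ordinal rules only).

A resample is represented as integer case weights over the unique
subjects rather than as duplicated rows.  This is not cosmetic: with
duplicated rows, tied copies of a subject sit adjacent in the covariate
ordering with identical score vectors, the cumulative-sum process gains
positive local correlation, and the supLM test over-rejects badly (decoy
covariates were "selected" in well over half the resamples).  With case
weights, fits, node sizes and cut admissibility use weighted counts while
the fluctuation test treats each unique subject as one exchangeable unit
(its score row multiplied by its weight), which restores the permutation
null.  The trimming fraction inside the test uses the unique-subject
count, a mild approximation at bootstrap scale.

Randomness: one master `SeedSequence` spawns an independent substream per
resample, so summaries are identical under any execution order and
enlarging B leaves earlier resamples unchanged.

## The synthetic-data generator

The generator exists so every stage is testable without the (unreleased)
study data.  A design is items + covariate distributions + leaf rules:

- numeric covariates are normal or log-normal (natural-scale mean/sd,
  converted internally), optionally rounded and truncated by rejection
  (no boundary atom);
- ordinal (Likert) and nominal covariates are categorical draws;
- leaves are conjunctions of threshold/membership conditions, mutually
  exclusive and exhaustive (validated empirically on the sampled table
  before any ranking is drawn), each carrying a worth vector and
  optionally per-focal-group worths.

Rankings are drawn from the **exact pattern distribution** p(y | λ(π)) by
enumerating the J! patterns and making one categorical draw.  A
Plackett–Luce sequential draw would induce a different law on rankings
for J ≥ 3; sampling from the fitted model's own law is what makes the
recovery tests meaningful.  The generator never emits ties or incomplete
rankings.

The bundled `study_emulation.yaml` fixes the defaults to the emulated
study's marginals: n = 987; age ~ round(N(15.35, 2.96²)) truncated at 13;
task time log-normal with natural mean 23.01 s and sd 10.26 s; gender
52/48; art grade ~ round(N(1.96, 0.84²)) in 1–6; five 1–5 Likert columns
(S1–S5) and five 1–4 columns (PM, SO, LM, IM, IP) with category
probabilities chosen to match the reported means; four leaves defined by
task time (≤/> 20 s) and IP thresholds carrying the four reported
subgroup worth vectors.  Covariates are sampled independently — the
partitioning analysis conditions on covariates, so marginal realism is
what matters; correlated covariates, response-time-as-outcome effects and
item-level image features are out of scope.  Passing tests on this
generator show the pipeline recovers structure *of the kind the model
assumes*; they cannot show anything about model misspecification in real
rankings (e.g. intransitive judgment processes collapsed by the forced
ranking, or covariate measurement error).

## Problem sizes used in the test suite

Simulation-backed checks run at the sizes a desk analysis of this design
actually needs: parameter recovery at n = 2000 (100 replicates), split
recovery and tree-level type-I control at n = 1000 (50 replicates each),
bootstrap stability at B = 50 on n = 1000, generator goodness-of-fit at
n = 50,000 for J = 3.  The analysis drivers use the full n = 987 cohort
and B = 200 resamples.

## Known limitations

- supLM p-values are Monte-Carlo (resolution ~5e−5); they are not the
  Hansen response-surface approximation other implementations use, though
  they agree at the quantiles that matter for α ∈ [0.01, 0.1].
- Ordinal covariates are tested with the same supLM functional as numeric
  ones (ordered by level), not with a dedicated weighted-chi-square over
  level boundaries.
- No surrogate splits: subjects with missing covariates are dropped at
  tree entry, as the emulated analysis did (987 of 1020 usable).
- The ridge fallback under separation biases |λ| downward by design;
  flagged fits should be read as "an item is (almost) unanimously
  first/last", not as precise worths.
- Multiway splits, partial rankings/ties, and covariate-on-worth
  regression are out of scope.
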