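# bttrees

Bradley–Terry pattern models for complete rankings, recursively
partitioned over subject covariates, with AIC post-pruning and bootstrap
stability analysis.

## The problem

When people rank a set of J images (or any items) on a latent attribute —
say, visual abstraction — each ranking induces J(J−1)/2 forced pairwise
decisions.  The Bradley–Terry model places every item at a worth π_j on a
0–1 scale with Σπ = 1, so that

    P(j preferred over k) = π_j / (π_j + π_k),
    π_j = exp(2λ_j) / Σ_k exp(2λ_k).

Because a ranking's decisions are made jointly, the model is fitted to
whole response *patterns*: the J! transitive patterns form a multinomial
whose cell probabilities are exp(λ·x(y))/Z, with x(y) the vector of signed
pairwise win counts per item (for the identity ranking of five items,
x = (4, 2, 0, −2, −4)).

Judgment is rarely homogeneous.  Model-based recursive partitioning asks,
at every node, whether the fitted worths are *stable* across each subject
covariate (age, time on task, Likert-scale self-reports, …) using
score-fluctuation tests; where they are not, subjects are split at the
log-likelihood-maximizing cutpoint and the model is refitted per
subgroup.  Weak splits are collapsed by AIC, and a nonparametric
bootstrap of the whole pipeline reports how often each covariate would be
selected again and where it would cut — the difference between a finding
and an artifact.

This package implements the full pipeline — pattern algebra, exponential-
family MLE with worth CIs and a focal-group extension, supLM/chi-square
instability tests, tree growth with AIC pruning, case-weighted bootstrap
— plus a synthetic-data generator that emulates a ~1000-subject ranking
study so every stage is testable without any data download.  It is aimed
at quantitative researchers in psychometrics, sensory science and
educational assessment who work with forced complete rankings.

## Worked example

```python
import numpy as np
from bttrees import (ItemSet, TreeConfig, fit_llbt, grow_tree,
                     tabulate_patterns, worth_ci)
from bttrees.simulate import (covariates_from_frame, simulate_study,
                              study_emulation_design)

items = ItemSet(("a", "b", "c", "d", "e"), "abstraction",
                intended_order=("a", "b", "c", "d", "e"))

# 987 synthetic students; 4 latent subgroups driven by task time and
# interest in visual puzzles (IP)
rankings, cov_df = simulate_study(study_emulation_design(seed=20220810))

fit = fit_llbt(tabulate_patterns(rankings, items))
print(np.round(fit.pi, 3))          # pooled worths

covs = covariates_from_frame(cov_df, [
    ("age", "numeric"), ("game_time", "numeric"), ("gender", "nominal"),
    ("IP", "ordinal"), ("LM", "ordinal"),
])
tree = grow_tree(rankings, covs, items, TreeConfig(alpha=0.05, minsize=40))
for node in tree.terminal_nodes():
    print(node.id, node.n, np.round(node.fit.pi, 3))
```

Running the bundled analysis drivers end to end:

```sh
python analysis/01_simulate_study.py
python analysis/02_fit_pooled_model.py
python analysis/03_grow_partition_tree.py
python analysis/04_bootstrap_stability.py
```

prints (step 02, pooled model over all 987 subjects)

```
pooled fit over n=987: loglik=-3842.7, AIC=7693.4
item  worth   95% CI
  a   0.369  (0.354, 0.384)
  ...
```

and (step 03) the pruned partition tree, which recovers the four
generating subgroups:

```
pruned tree: 4 terminal node(s)
node 3  n=167  worths: 0.441  0.235  0.137  0.114  0.074
node 4  n=235  worths: 0.310  0.261  0.173  0.141  0.115
node 6  n=57   worths: 0.255  0.264  0.209  0.169  0.103
node 7  n=528  worths: 0.408  0.211  0.187  0.121  0.074
split rules: game_time <= 19.3777, IP <= 2, IP <= 1
```

The pooled worths decline smoothly a → e, but the tree shows *why*: fast
low-IP subjects separate the items sharply (node 3), slow low-IP subjects
barely at all (node 6).  Worths within every node sum to 1; each node is
a complete Bradley–Terry model for its subgroup.  Step 04 then reports,
per covariate, the probability of splitting any of 200 bootstrap
resamples and the mean cutpoint: 0.69 for `game_time` (mean cutpoint
19.6 s, near the generating 20 s), 0.39 for `IP`, and at most 0.01 for
each of the twelve decoy covariates.

A `bttrees` console script exposes the same pipeline on CSV inputs
(`bttrees simulate / fit / tree / bootstrap / render`); see `--help`.

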