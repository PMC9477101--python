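# Study-emulation design: a synthetic cohort with the marginal structure of
# the ranking study this package models.  ~987 students rank five images
# (a..e) by visual abstraction; age is a rounded truncated normal, task time
# log-normal, ten Likert columns and gender/art grade round out the
# covariates.  Four leaves defined by task time and interest in visual
# puzzles (IP) carry distinct worth vectors, so the partitioning pipeline
# has real subgroup structure to recover.
items:
  labels: [a, b, c, d, e]
  attribute: abstraction
  intended_order: [a, b, c, d, e]
n: 987
seed: 0
covariates:
  - {name: age, kind: numeric, mean: 15.35, sd: 2.96, round: true, minimum: 13}
  - {name: game_time, kind: numeric, mean: 23.01, sd: 10.26, lognormal: true}
  - {name: gender, kind: nominal, levels: [f, m], probs: [0.52, 0.48]}
  - {name: art_grade, kind: numeric, mean: 1.96, sd: 0.84, round: true, minimum: 1, maximum: 6}
  - {name: S1, kind: ordinal, levels: [1, 2, 3, 4, 5], probs: [0.03, 0.08, 0.30, 0.41, 0.18]}
  - {name: S2, kind: ordinal, levels: [1, 2, 3, 4, 5], probs: [0.02, 0.07, 0.28, 0.45, 0.18]}
  - {name: S3, kind: ordinal, levels: [1, 2, 3, 4, 5], probs: [0.04, 0.13, 0.37, 0.38, 0.08]}
  - {name: S4, kind: ordinal, levels: [1, 2, 3, 4, 5], probs: [0.04, 0.10, 0.22, 0.40, 0.24]}
  - {name: S5, kind: ordinal, levels: [1, 2, 3, 4, 5], probs: [0.07, 0.15, 0.36, 0.29, 0.13]}
  - {name: PM, kind: ordinal, levels: [1, 2, 3, 4], probs: [0.12, 0.33, 0.41, 0.14]}
  - {name: SO, kind: ordinal, levels: [1, 2, 3, 4], probs: [0.03, 0.13, 0.45, 0.39]}
  - {name: LM, kind: ordinal, levels: [1, 2, 3, 4], probs: [0.08, 0.30, 0.46, 0.16]}
  - {name: IM, kind: ordinal, levels: [1, 2, 3, 4], probs: [0.30, 0.41, 0.23, 0.06]}
  - {name: IP, kind: ordinal, levels: [1, 2, 3, 4], probs: [0.10, 0.30, 0.36, 0.24]}
leaves:
  - conditions:
      - {covariate: game_time, op: "<=", value: 20}
      - {covariate: IP, op: "<=", value: 2}
    worth: [0.415, 0.241, 0.143, 0.120, 0.081]
  - conditions:
      - {covariate: game_time, op: "<=", value: 20}
      - {covariate: IP, op: ">", value: 2}
    worth: [0.318, 0.237, 0.184, 0.144, 0.117]
  - conditions:
      - {covariate: game_time, op: ">", value: 20}
      - {covariate: IP, op: "<=", value: 1}
    worth: [0.280, 0.233, 0.230, 0.158, 0.099]
  - conditions:
      - {covariate: game_time, op: ">", value: 20}
      - {covariate: IP, op: ">", value: 1}
    worth: [0.403, 0.223, 0.184, 0.116, 0.074]
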