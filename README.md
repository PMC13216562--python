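# truthsdt

Signal-detection analysis of binary truth judgments, for researchers
studying who accepts misinformation and why.

When people judge a mix of true and false claims as "true" or "false",
their error pattern can be decomposed with equal-variance Gaussian signal
detection theory into three distinct dispositions:

- **Truth sensitivity** — `d′ = z(H) − z(FA)`, the ability to tell true
  from false claims (H = hit rate on true items, FA = false-alarm rate on
  false items, z = probit);
- **Acceptance threshold** — `c = −0.5·[z(H) + z(FA)]`, the general
  tendency to reject (high c) versus accept (low c) claims;
- **Myside bias** — `c_incongruent − c_congruent`, the criterion gap
  between claims that clash with versus flatter one's prior views; positive
  values mean a lower bar for congruent claims.

Rates of exactly 0 or 1 are replaced by `1/(2N)` and `1 − 1/(2N)` before
the probit transform. Around this core the package provides:

- a **synthetic cohort generator** (`truthsdt.cohort`) that draws
  participants from the exact generative inverse of the estimators —
  P("true") = Φ(d/2 − c) for true items and Φ(−d/2 − c) for false items —
  together with 15 trait covariates at configurable latent correlations,
  so every downstream estimator can be validated by parameter recovery;
- **scale scoring** (`truthsdt.scales`) for the 15 individual-difference
  measures (reverse coding, mean/sum/difference aggregation, Cronbach's
  alpha, parcel-based reliability of the SDT indices themselves);
- **association analyses** (`truthsdt.association`): split-half (odd/even
  item) multiple regressions predicting misinformation acceptance from the
  three indices computed on the opposite half, trait correlation screens
  with Holm adjustment, and partial correlations controlling for group;
- a **bifactor structural model** (`truthsdt.bifactor`): a general
  reflective-open-mindedness factor plus orthogonal specific factors
  (cognitive reflection, bullshit receptivity, conspiracy mentality,
  actively open-minded thinking) predicting split-half truth sensitivity,
  fit by maximum likelihood on the observed covariance matrix;
- a **pipeline and CLI** (`truthsdt.pipeline`, `truthsdt` command) running
  exclusions → scoring → SDT → associations → bifactor end to end on
  simulated or imported CSV data, deterministically given a seed.

## Worked example

```python
from truthsdt import (CohortConfig, apply_exclusions, generate_cohort,
                      score_cohort, split_half_fa_regression)

cfg = CohortConfig(seed=42, n_attention_failures=21, n_inconsistent=5)
cohort = generate_cohort(cfg)                   # 300 participants, 80 items
kept, report = apply_exclusions(cohort.participants)
print(report)

groups = kept["group"]
judgments = cohort.judgments.loc[kept.index]
scores = score_cohort(judgments, cohort.bank, groups)
print(scores[["d_prime", "c_overall", "myside"]].agg(["mean", "std"]).round(2))

odd = score_cohort(judgments, cohort.bank, groups, split="odd")
even = score_cohort(judgments, cohort.bank, groups, split="even")
for res in split_half_fa_regression(odd, even)[:2]:
    print(res.outcome_name, res.direction, res.betas.round(2).to_dict())
```

prints

```
ExclusionReport(n_started=300, n_completed=300, n_failed_attention=21,
                n_inconsistent_group=5, n_final=274,
                per_group={'side_A': 134, 'side_B': 140})
      d_prime  c_overall  myside
mean     0.52       0.37    0.66
std      0.55       0.46    0.76
fa_congruent even_to_odd {'d_prime': -0.13, 'c_overall': -0.5, 'myside': 0.32}
fa_incongruent even_to_odd {'d_prime': -0.18, 'c_overall': -0.53, 'myside': -0.48}
```

The exclusion cascade removes attention failures first and then, among the
remainder, participants whose reported group contradicts the prescreen,
leaving 274 of 300. The recovered index means match the generator's
configured distributions (d′ ~ N(0.52, 0.49), c ~ N(0.38, 0.50),
myside ~ N(0.66, 0.70)). The cross-half regressions show the signature
pattern: acceptance of congruent misinformation falls with sensitivity and
threshold but **rises** with myside bias, while acceptance of incongruent
misinformation falls with all three.

The same pipeline is available from the shell:

```bash
truthsdt simulate --seed 42 --out cohort_dir
truthsdt analyze --data cohort_dir --out results_dir
truthsdt analyze --seed 42 --bifactor --out results_dir
truthsdt power --reps 100 --seed 0
```

## Layout

```
src/truthsdt/
  sdt.py          rate correction, probit, d′/c/myside, cohort scoring
  cohort.py       generative model, item bank, trait covariates, CSV I/O
  scales.py       scale registry, scoring, Cronbach's alpha, parcel alpha
  association.py  correlations, partial correlations, standardized OLS,
                  split-half regressions, Holm adjustment
  bifactor.py     bifactor SEM: implied covariance, ML fit, standardization
  pipeline.py     exclusions and end-to-end orchestration
  cli.py          command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
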