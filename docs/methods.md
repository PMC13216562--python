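# Methods

## Measurement model

Participants judge items that are either true or false and either slanted
toward their own group's position (congruent) or the opposing one
(incongruent). Judgments are scored under the equal-variance Gaussian
signal-detection model. For each participant and item subset, the hit rate
H (true items judged true) and false-alarm rate FA (false items judged
true) give

    d′ = z(H) − z(FA)
    c  = −0.5 · [z(H) + z(FA)]

with z the probit. Rates of exactly 0 or 1 are replaced by 1/(2N) and
1 − 1/(2N), where N is the number of trials in the subset from which the
rate was computed — including within odd/even halves, where N is the
half's own trial count. Myside bias is c_incongruent − c_congruent, each
criterion computed from that congruence subset's own H and FA. The sign is
chosen so that positive values mean a lower threshold for accepting
congruent claims; the verbal phrase "congruent versus incongruent
difference" would suggest the opposite order, but that order contradicts
the construct's intended interpretation, so the interpretation-consistent
sign is used throughout.

The overall criterion `c_overall` (used in trait screens) is computed from
all-items rates; congruence-specific false-alarm rates are the outcomes of
the split-half regressions only.

## Generative model

The synthetic cohort inverts the estimators exactly: a participant with
latent (d, c, m) responds "true" to a true item with probability
Φ(d/2 − c*) and to a false item with probability Φ(−d/2 − c*), where
c* = c − m/2 on congruent and c + m/2 on incongruent items. The symmetric
±m/2 split keeps the overall criterion centered on c and makes the three
latent parameters orthogonal in meaning. Scoring the exact response
probabilities therefore returns (d, c) — and m via the congruence-specific
criteria — to machine precision, which is the basis of the closed-form
round-trip tests.

One caveat is intentional and documented rather than "fixed": the overall
d′ and c are computed from rates pooled across the two congruence subsets.
Because the probit of a mixture is not the mixture of probits, these
pooled estimators converge to slightly shrunken values when m ≠ 0 (for
d = 1, c = 0.3, m = 0.6: plug-in limits ≈ 0.956 and 0.287). This mirrors
the scored data exactly as the scoring rules define it; consistency tests
assert recovery within ±0.05, which includes this deterministic component.

Latent (d, c, m) and 15 trait covariates are jointly Gaussian. Defaults
emulate a published political-misinformation cohort: two groups of 150,
20 items per veracity × slant cell presented in a seeded fixed order,
d′ ~ N(0.52, 0.49), c ~ N(0.38, 0.50), m ~ N(0.66, 0.70); trait marginals
and trait–index correlation targets follow the same study's descriptive
and correlation tables. The three SDT latents are mutually orthogonal and
traits are mutually uncorrelated by default; the implied correlation
matrix is validated positive semi-definite at configuration time, and a
singular target (e.g. a trait correlated 1.0 with d) is handled by an
eigendecomposition square root.

Trait covariates are emitted twice: as exact latent values (for tests that
must separate attenuation from estimator bias) and as discretized Likert
item responses. Item responses add Gaussian noise calibrated to a target
scale reliability (default 0.85, matching typical published alphas), then
round and clip to the response range; reverse-keyed items are stored in
reversed direction so standard scoring recodes them. Binary sum scales
(cognitive reflection, the narcissism inventory) draw items Bernoulli with
probability score/k; their reliability is governed by item count rather
than the noise parameter. The generator emulates marginal distributions
and trait–index correlations; it does not emulate item-level difficulty
variation, response styles, careless responding beyond a binary attention
flag, or trait–trait correlations, so passing recovery tests demonstrate
estimator correctness under the model, not robustness to violations of it.

## Scale scoring and reliability

Likert scales are scored as the item mean after recoding reverse-keyed
items (r → min + max − r); performance scales are summed 0/1 counts;
identification with likeminded people is the mean item-wise difference
between the "people who share my views" and "all humanity" rating blocks.
Missing or out-of-range responses are rejected, never imputed — the
analysis is defined for completers. The bundled scale registry (lengths,
ranges, aggregation, reverse-key sets) is an editable JSON stand-in for
the cited instruments: lengths and ranges follow the instruments, but
exact reverse-key sets belong to the source instruments and should be
replaced when scoring real administrations.

Internal consistency is Cronbach's alpha, k/(k−1) · (1 − Σ item variances
/ total-score variance), which is KR-20 for binary items. Reliability of
the SDT indices themselves is estimated by splitting each veracity × slant
cell into k order-based contiguous parcels (default k = 4 with 20 items
per cell), scoring the index per parcel, and taking alpha across parcel
scores. The published tables do not state how index reliabilities were
computed; the parcel method is this package's stated approximation, and on
default simulated cohorts it reproduces the published magnitude for truth
sensitivity (≈ 0.7).

## Association analyses

Split-half regressions z-score the outcome and predictors and fit ordinary
least squares with classical standard errors (the published analysis does
not state robust errors; with a single predictor the beta equals the
Pearson correlation, which is tested). Outcomes are the extreme-corrected
congruent and incongruent false-alarm rates of one item half; predictors
are (d′, c, myside) from the other half, in both directions — four
regressions. Computing predictors and outcome from disjoint item halves
removes the arithmetic dependence of FA-based predictors on the outcome.

The trait screen correlates each trait with the overall false-alarm rate
and the three indices. Multiplicity adjustment defaults to Holm step-down
— it dominates Bonferroni at identical family-wise guarantees — over the
trait × SDT-factor family (45 tests with 15 traits); the FA-rate column is
its own family. Partial correlations controlling for group use the
first-order recursion formula with a 0/1 dummy (which group is 1 is
irrelevant to |r|) and n − 3 degrees of freedom.

## Bifactor model

The bifactor model has a general factor on all indicators, orthogonal
specific factors on disjoint indicator blocks, and outcome variables
(odd/even-half truth sensitivity) regressed on every factor. With factor
covariance fixed to identity and structural paths folded into the outcome
rows of Λ, the implied covariance is Σ = ΛΛᵀ + Θ. The ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by L-BFGS-B with analytic
gradients (∂F = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)∂Σ]), residual variances bounded below
at 1e−8 (a residual at the bound flags a Heywood case), 20 seeded random
starts with best-discrepancy selection, and a 1e−8 gradient tolerance.
Identification fixes factor variances at 1 with all loadings free; the
per-factor sign indeterminacy is resolved by making each factor's summed
indicator loading nonnegative. Standard errors are delta-method values
from the numerically differentiated discrepancy Hessian,
acov = 2/(n−1)·H⁻¹; standardized estimates rescale each observed row by
its implied standard deviation (their SEs are scaled the same way, an
approximation that ignores the sampling variability of the implied
variances). The default specification uses three order-based item parcels
per construct (cognitive reflection 3+2+2 of 7 items, bullshit receptivity
4+3+3 of 10, conspiracy mentality 2+2+1 of 5, actively open-minded
thinking 5+4+4 of 13); the published indicator-level specification lives
in supplemental materials not reproduced here, so the spec object accepts
arbitrary bifactor structures instead of hard-coding one. At N = 5,000 the
measurement loadings are recovered within ±0.05; the structural paths on
three-indicator specific factors carry sampling errors of similar or
larger magnitude and are reported with their standard errors rather than
held to that band.

## Pipeline

Exclusions remove attention-check failures first and then, among the
survivors, participants whose reported group membership contradicts their
prescreen value — the order implied by the study's "an additional"
phrasing; the report's identity n_final = n_completed − n_attention −
n_inconsistent is validated on construction. All tables are emitted as
full-precision CSVs plus 3-decimal display copies. The manifest hashes the
analysis-relevant configuration (excluding output path and verbosity) so
that a seed fully determines every output byte, which the determinism test
checks literally.

## Problem sizes and numerical choices

Simulation-based checks use: 100 replicate cohorts (N = 300, 20 items per
cell) for the regression sign pattern; 200 replicates (N = 274) each for
the screen's family-wise error and power; 20 participants at 5,000 items
per cell for estimator consistency; N = 5,000 for bifactor sample
recovery. These sizes give Monte Carlo standard errors comfortably inside
the asserted tolerances while keeping a full run on one CPU around a
minute. Probit and its inverse come from scipy; closed-form identities are
asserted at 1e−10 relative tolerance, population-covariance SEM recovery
at 1e−4.

## Known limitations

- The generative model is the exact inverse of the estimators; it cannot
  detect misspecification of the equal-variance assumption (no
  unequal-variance or ROC-based variants are provided).
- Trait–trait correlations are zero by default, so the default cohort is
  not a realistic basis for fitting the bifactor model to *generated trait
  scores* (the bifactor recovery tests simulate from the bifactor model
  directly).
- Scale-item generation reproduces score-level moments, not item response
  theory structure.
- Cronbach's alpha for SDT indices depends on the parceling; alternatives
  (split replicates, all splits) would give somewhat different values.
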