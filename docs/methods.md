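# Methods

`limbmr` emulates, end to end, a biobank Mendelian-randomization (MR) study
of a glycaemic exposure on upper-limb musculoskeletal conditions (frozen
shoulder, Dupuytren's disease, trigger finger, carpal tunnel syndrome). The
original analyses of this kind run on individual-level biobank data that
cannot be redistributed, so every stage here is exercised against a
synthetic cohort generator whose structure matches the assumptions the
estimators make. This note records the models, the defaults and why, the
numerical choices, and what the synthetic data can and cannot tell you.

## Generative model

For individual *i* and SNP *j* (dosage `g_ij ~ Binomial(2, f_j)`, i.e.
Hardy–Weinberg equilibrium, no LD):

```
X_i = Σ_j w_j g_ij + γ_X U_i + carrier_i · s + ε_i,     ε ~ N(0, σ²)
logit P(Y_i = 1) = β₀ + β X_i + γ_Y U_i + Σ_j α_j g_ij
```

`U ~ N(0,1)` is a latent confounder, kept on the cohort object for oracle
checks only and never shown to an estimator. `β` is the causal estimand
(log-odds per exposure unit), `α_j` are per-SNP direct (pleiotropic)
effects on the outcome — all zero means every instrument is valid — and
`carrier` flags a rare large-effect variant class (frequency ≤ 1%, exposure
shift `s`), emulating glucokinase-type monogenic hyperglycaemia. Age and
sex are drawn independently of genotype, so the MR independence assumption
holds by construction; `independence_break_effect` couples age to the
allele score for negative testing.

Defaults (in `default_config`): allele frequencies uniform on (0.1, 0.9);
equal per-allele weights sized so the genetic score explains R² = 2% of an
exposure of total variance ≈ 1 (the weak-but-many-variants regime of
polygenic instruments — at n = 20 000 this gives a first-stage F of
several hundred); confounder paths 0.4/0.4; carrier frequency 0.4% with a
+2 SD exposure shift; ~2.5% of the cohort in related pairs with kinship
coefficients in [0.0625, 0.25]. Exposure units are standardized, so
"per SD" and "per exposure unit" coincide up to sampling noise.

Condition prevalences in the packaged study configuration (0.5–3%) follow
the case fractions typical of these diagnoses in biobank populations; the
per-SD causal odds ratios default to 1.5 / 1.17 / 1.3 / 1.2 for frozen
shoulder, Dupuytren's, trigger finger and carpal tunnel respectively, the
effect-size regime this class of study reports for glycaemia.

Every random draw comes from a named stream seeded as
`(seed, crc32(stream))`, and the pipeline fans a single study seed out to
per-stage child seeds, so any stage can be reproduced in isolation and two
runs under one seed are byte-identical.

## Phenotype curation

Coded health records (ICD-10, OPCS4, GP, self-report) are matched against
per-condition code lists, case-insensitively and dot-insensitively, with
prefix matching for the ICD-10/OPCS4 hierarchy. Two definition tiers are
derived: *broad* (all four vocabularies, maximizing case count) and
*specific* (hospital ICD-10/OPCS4 only, maximizing case certainty); the
specific case set is a subset of the broad one by construction. The
packaged code lists use representative anchors (M75.0, M72.0, M65.3,
G56.0) and are illustrative, not an authoritative clinical code set.

Relatedness is removed by greedy pruning of the kinship graph at the
third-degree threshold (coefficient 0.0442): while any related pair
remains, the individual with the most remaining relatives is removed, ties
broken by removing the larger id. This maximizes retained sample size for
star-shaped families and returns an independent set of the kinship graph.

## Instruments and harmonization

A genetic risk score (GRS) is the weighted allele-dosage sum using
published per-allele weights, then z-scored across the cohort. Published
weights refer to a named effect allele, so before scoring each weight is
aligned to the genotype file's counted allele: sign-flipped when the
coding is swapped, strand-complemented when the raw alleles only match
after complementing, and dropped as irreconcilable otherwise. Palindromic
variants (A/T, C/G) are resolved by comparing which side of 0.5 the two
allele frequencies fall on, and only when both are more than 0.08 from 0.5
(a common convention); otherwise they are excluded with an explicit
reason. Missing dosages are mean-imputed per SNP before weighting.
Instrument strength is summarized by the first-stage partial F,
`F = (n − p − 2)·R²_p/(1 − R²_p)`, which equals the squared t statistic of
the GRS coefficient.

## Estimators

**One-sample MR (two-stage).** Stage one: linear regression of the
exposure on the normalized GRS adjusted for five genetic principal
components. Stage two: regression of the binary outcome on the normalized
first-stage prediction, adjusted for the first-stage residuals (residual
inclusion, 2SRI — the residual proxies the unmeasured confounder), age and
sex. Two second-stage modes are provided:

* `linear` (default): a linear-probability fit whose coefficient is a risk
  difference δ per SD of the predicted exposure, converted to an OR
  through the baseline odds, `OR = ((p₀+δ)/(1−p₀−δ)) / (p₀/(1−p₀))` with
  p₀ the sample prevalence. This mirrors the linear-second-stage-plus-
  rescaling convention of large biobank analyses. The conversion is exact
  only to first order in δ: it needs δ small relative to p₀, and it is
  undefined (raises, advising the logistic mode) when |δ| ≥ p₀ — which
  does happen for 0.5%-prevalence conditions at desk-scale n.
* `logistic-2sri` (recommended): the same design fitted by logistic
  regression, giving a log-OR directly with no conversion step. This is
  the mode the recovery analyses assert on, because it is consistent for
  the conditional log-OR without a small-effect approximation.

Rescaling: the raw coefficient is per 1 SD of the *predicted* exposure;
dividing by that SD gives a per-exposure-unit effect, which is then
expressed per SD of the exposure or per any stated number of units (e.g.
"per 10 mmol/mol" when the exposure is HbA1c). Confidence intervals are
normal-theory on the working scale and transformed through the identical
map.

**Two-sample MR.** Per-variant genotype–outcome effects come from
covariate-adjusted logistic regressions of the outcome on each instrument
SNP (a deliberate plain-regression substitution for a mixed-model GWAS:
relatedness has already been pruned, and only instrument SNPs are tested).
After aligning outcome effects to the exposure effect alleles:

* **IVW**: weighted regression of `β_y` on `β_x` through the origin with
  weights `1/se_y²`; the SE uses multiplicative random effects with the
  residual dispersion floored at 1, so the fixed-effect SE is the lower
  bound; Cochran's Q is reported.
* **MR-Egger**: the same regression with a free intercept, variants
  re-oriented to non-negative `β_x`; the intercept estimates average
  directional pleiotropy and the slope is consistent under InSIDE.
* **Weighted median / penalized weighted median**: the 50% point of the
  inverse-variance weight CDF over sorted per-variant Wald ratios (delta-
  method ratio variances, linear interpolation); the penalized form
  down-weights variant *j* by `min(1, χ²₁(0.95)/Q_j)` with `Q_j` its
  contribution to Cochran's Q about the unpenalized estimate. SEs by
  seeded parametric bootstrap (B = 1000 by default).
* **Meta-analysis**: fixed-effect inverse-variance pooling of per-cohort
  estimates, with Q and I² reported; a single cohort passes through with a
  warning.

**Rare-variant carrier tests.** Carrier status × case status 2×2 tables
per condition and tier, tested with Fisher's exact test (two-sided,
minimum-likelihood rule). The headline OR is the conditional maximum-
likelihood estimate with an exact CI from the non-central hypergeometric
(scipy); the sample OR `ad/bc` is reported alongside. A zero margin yields
p = 1 with the OR flagged undefined rather than an error.

**Observational reference.** Logistic regression of case status on the
z-scored exposure adjusted for age and sex (OR per SD), with a natural
cubic spline (five knots at exposure quantiles 0.05, 0.275, 0.5, 0.725,
0.95) and a likelihood-ratio test of spline vs linear as the
non-linearity check. The spline basis (patsy `cr`) spans constants and
linear functions, so the linear model is strictly nested and the LR
statistic is non-negative.

## Numerical choices

* Logistic fits use IRLS with step-halving, convergence on the score norm
  (max |Xᵀ(y−p)| < 1e-8), Wald SEs from the observed information, and
  explicit errors for rank-deficient designs (naming the collinear
  columns), constant outcomes, and complete separation (diverging linear
  predictor, or |η| > 20 at convergence, where fitted probabilities are
  0/1 to ~1e-9).
* The per-variant scan batches one IRLS Newton system per variant per
  iteration (the designs share all columns but the dosage), keeping
  simulation studies with tens of thousands of fits on one CPU tractable.
  Monomorphic or non-converging variants are flagged missing, never zero.
* Weighted least squares exposes three dispersion conventions: estimated
  residual dispersion (ordinary SEs), unit dispersion (fixed-weight
  inverse-variance problems), and floored-at-1 dispersion (multiplicative
  random effects).
* The weighted-median penalty threshold is the upper 5% χ²₁ quantile
  (3.84); ratio weights guard against division by zero, and variants with
  `β_x = 0` are excluded with a warning rather than producing infinite
  ratios.

## What the simulations show — and what they cannot

The generator reproduces the *statistical* structure MR relies on:
HWE genotypes, a polygenic weak-instrument first stage, logistic outcomes,
confounding, directional and balanced pleiotropy, kinship, multi-source
coded records, and rare carriers. It deliberately omits LD between
instruments, population stratification beyond placeholder principal
components, imputation uncertainty, X-chromosome conventions,
time-resolved records and selection/participation bias. Passing tests
therefore demonstrate the estimators' correctness and calibration under
the assumed model, not robustness to the full messiness of real biobank
data.

Two estimator properties surface in the recovery studies and are expected,
not bugs:

* IVW on a binary outcome targets a *marginal* (population-averaged)
  log-OR; logistic non-collapsibility attenuates it relative to the
  conditional simulated effect by roughly `1/√(1 + β²Var(X|g)/2.89)` — a
  few percent at OR 1.5 — so recovery is asserted within 0.04 on the
  log-OR scale rather than pure Monte-Carlo error.
* Through-origin WLS with noisy `β_x` carries an O(1/m) ratio bias
  (≲1% here), visible at 500 replicates.

The weighted-median simulations use consortium-GWAS-like instrument
precision (per-variant ratio SE ≈ 0.05). The median-of-ratios estimator is
consistent as summary-statistic noise vanishes; with substantially noisier
ratios, the invalid-instrument weight shifts the weight-CDF median and no
implementation attains a bias below 0.05 — a regime worth knowing about
when instruments are weak.

## Problem sizes

The packaged study configuration simulates two cohorts of 20 000
individuals and 50 instrument SNPs (a deliberate desk-scale stand-in for
biobank cohorts of several hundred thousand); a full run takes roughly ten
seconds on one CPU. The replication studies use 200 replicates at
n = 20 000 for parameter recovery, 1000 replicates at n = 4000 for type-I
error, and 500 summary-level replicates for the pleiotropy analyses. At
these sizes the per-SD causal OR of 1.5 is recovered with a CI-coverage
check at the nominal 95% level; the very rare conditions (prevalence 0.5%)
produce visibly noisy single-run estimates, which is the expected
behaviour at 1/20th of biobank scale.
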