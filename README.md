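# limbmr

A Mendelian-randomization (MR) pipeline for testing whether glycaemic and
adiposity exposures cause upper-limb musculoskeletal conditions — frozen
shoulder, Dupuytren's disease, trigger finger and carpal tunnel syndrome —
built for epidemiologists and methodologists who want the full biobank
analysis chain as tested, reusable code. Because individual-level biobank
data cannot be redistributed, the package ships a synthetic cohort
generator with the exact statistical structure the estimators assume, so
every stage runs and is validated without any data access.

## What it implements

- **Synthetic biobank cohorts**: Hardy–Weinberg genotypes, an exposure
  linear in a weighted allele score plus a latent confounder *U*, logistic
  binary outcomes with a specified causal effect β (log-odds per exposure
  unit), optional per-SNP pleiotropy, rare large-effect carrier variants
  (glucokinase-like), kinship pairs and multi-source coded health records.
- **Phenotype curation**: case ascertainment from ICD-10/OPCS4/GP/self-report
  code lists under *broad* and *specific* (hospital-only) definition tiers;
  greedy maximal unrelated-set selection on the kinship graph at the
  third-degree threshold.
- **Instruments**: weight-table loading, allele harmonization (sign flips,
  strand complements, EAF-resolved or excluded palindromic variants),
  normalized genetic risk scores (GRS), first-stage partial
  F = (n−p−2)·R²/(1−R²).
- **One-sample MR**: two-stage regression — exposure ~ GRS + 5 PCs, then
  outcome ~ predicted + first-stage residuals (2SRI) + age + sex — with a
  linear-probability second stage converted to an OR through the baseline
  odds, or a logistic second stage giving the log-OR directly; effects
  reported per SD or per stated exposure unit.
- **Two-sample MR**: IVW (multiplicative random effects, Q), MR-Egger
  (directional-pleiotropy intercept), weighted median and penalized
  weighted median (bootstrap SEs), and fixed-effect meta-analysis across
  cohorts.
- **Rare variants**: Fisher's exact carrier tests (conditional-MLE OR,
  exact CI) per condition and tier.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Run the full study emulation (two cohorts of 20 000, 50 instrument SNPs,
four conditions) and inspect the one-sample MR table:

```bash
limbmr run-all --seed 7 --n 20000 --out study/
```

`study/onesample_mr.tsv` (specific-tier outcomes, both second-stage modes):

```
      condition          mode       or   ci_low  ci_high        p       F
frozen_shoulder        linear 2.401280 1.106120  3.71946 0.033830 346.501
frozen_shoulder logistic-2sri 4.069870 1.125330 14.71910 0.032356 346.501
      dupuytren        linear 1.305030 0.281362  2.35144 0.562214 346.501
      dupuytren logistic-2sri 1.359900 0.486479  3.80144 0.557797 346.501
 trigger_finger        linear      NaN      NaN      NaN      NaN     NaN
 trigger_finger logistic-2sri 1.834090 0.357920  9.39842 0.466889 346.501
  carpal_tunnel        linear 0.700369 0.038249  1.38479 0.386429 346.501
  carpal_tunnel logistic-2sri 0.743965 0.375264  1.47492 0.396975 346.501
```

Reading it: `or` is the causal odds ratio per SD of the exposure with its
95% CI and p-value; `F` ≈ 347 says the GRS is a strong instrument (weak-
instrument bias negligible). The simulated true per-SD ORs are 1.5, 1.17,
1.3 and 1.2 — at 1/20th of biobank scale and 0.5–3% prevalence the
estimates are correctly centred but individually noisy, which is the point
of the replicate studies below. The `linear` row for trigger finger is NaN
with a note in the TSV: at 0.5% prevalence the linear-probability risk
difference can exceed the baseline risk, so the OR conversion is undefined
and the logistic mode is the one to read. The same run writes the
observational table, per-variant association scans, per-cohort IVW /
Egger / weighted-median results, the cross-cohort meta-analysis, carrier
Fisher tests (e.g. carpal tunnel broad-tier carrier OR 2.39, p = 0.026 in
this run) and a manifest of every stage seed — rerunning with the same
seed reproduces every file byte for byte.

Library use mirrors the CLI:

```python
import numpy as np
from limbmr import default_config, simulate_cohort, simulate_binary_outcome, run_one_sample_mr
from limbmr.pipeline import make_instrument_table

cfg = default_config(20_000, 50, seed=1, causal_effect=np.log(1.5),
                     outcome_intercept=-3.0)
cohort = simulate_cohort(cfg)
y = simulate_binary_outcome(cohort.exposure, cfg, confounder=cohort.confounder)
instruments = make_instrument_table(cfg, cohort.coding, seed=7)
est = run_one_sample_mr(cohort, instruments, y, mode="logistic-2sri")
print(f"OR {est.or_:.2f} (95% CI {est.or_ci_low:.2f}-{est.or_ci_high:.2f}), "
      f"F = {est.diagnostics['F']:.0f}")
```

which prints `OR 1.17 (95% CI 0.84-1.63), F = 401` for this seed — one
draw from an estimator whose 200-replicate mean is 1.5 (the default
configuration keeps confounding on, so single-run spread is wide; the
replicate studies quantify it).

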