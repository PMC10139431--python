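# mrkit

Two-sample Mendelian randomization (2SMR) from GWAS summary statistics, built
around a fully reproducible case study: is celiac disease a causal risk factor
for lymphoma — in particular mature T/NK-cell lymphoma, the family that
contains enteropathy-associated T-cell lymphoma (EATL)?

2SMR uses genetic variants as instrumental variables: a variant associated
with an exposure (here, celiac disease) that affects an outcome (a lymphoma
subtype) only through that exposure supports a causal interpretation of the
exposure-outcome association. Because alleles are randomized at meiosis,
these estimates are protected from the confounding and reverse causation that
plague observational comorbidity studies. The package is aimed at
statistical-genetics practitioners who have summary-level association tables
(betas and p-values per SNP) for one exposure and one or more outcomes.

## What it implements

For harmonized instruments with exposure effects $\hat\gamma_i \pm
\sigma_{X i}$ and outcome effects $\hat\Gamma_i \pm \sigma_{Y i}$:

- **Wald ratio** (per SNP): $\hat\theta_i = \hat\Gamma_i / \hat\gamma_i$,
  SE $\sigma_{Y i}/|\hat\gamma_i|$ (first-order delta method).
- **Random-effects IVW**: weighted regression of $\hat\Gamma$ on $\hat\gamma$
  through the origin with weights $1/\sigma_{Y i}^2$; the slope SE carries a
  multiplicative residual scale floored at 1; normal p-values.
- **MR-Egger**: the same regression with a free intercept after orienting
  every instrument to $\hat\gamma_i \ge 0$; the intercept estimates average
  directional pleiotropy and its t test (nsnp − 2 df) is the pleiotropy
  diagnostic.
- **Weighted median**: interpolated weighted median of the Wald ratios
  (consistent when up to half the weight sits on invalid instruments), SE by
  seeded parametric bootstrap.
- **MR-PRESSO**: simulation-based global test on the leave-one-out residual
  sum of squares, Bonferroni-adjusted per-SNP outlier tests,
  outlier-corrected estimate and distortion test.
- **Multivariable MR (MVMR-IVW)**: joint weighted regression on several
  exposures' effects, with union or exposure-specific instrument selection.
- **Instrument construction**: SE reconstruction from p-values
  ($\mathrm{se} = |\beta| / \Phi^{-1}(1 - p/2)$), extended-HLA-region
  masking (chr6:20–40 Mb), palindromic-SNP handling, allele harmonization,
  and greedy LD clumping ($r^2 \le 0.001$, ±5 Mb by default).
- **Diagnostics**: Cochran's Q, per-SNP and combined F statistics, BH-FDR,
  an analytic power approximation, leave-one-out / confounder-removal /
  bidirectional sensitivity analyses.
- **Synthetic data**: seeded generators of two-sample summary statistics
  with known causal effect, configurable pleiotropy, planted outliers and
  LD-block structure, used throughout the test suite.

The complete instrument-level inputs of the case study (11 non-HLA
celiac-disease SNPs × 8 outcomes) ship with the package, so the entire
published analysis re-runs offline in seconds.

## Worked example

```python
from mrkit import (EXPOSURE_TRAIT, build_instrument_set, instrument_strength,
                   ivw, load_table1)

table1 = load_table1()
insts = build_instrument_set(table1[EXPOSURE_TRAIT],
                             table1["Mature T/NK-cell lymphomas"])
fit = ivw(insts)
print(f"IVW: OR={fit.odds_ratio:.2f} [{fit.ci_low:.2f}, {fit.ci_high:.2f}], "
      f"p={fit.pval:.2e}")
print(f"combined F = {instrument_strength(insts).combined_f:.0f}")
```

prints

```
IVW: OR=1.72 [1.18, 2.53], p=5.31e-03
combined F = 559
```

i.e. genetic liability to celiac disease raises the odds of mature T/NK-cell
lymphoma an estimated 1.72-fold (95% CI 1.18–2.53), and the 11 instruments
are jointly strong (combined F ≫ 10, so weak-instrument bias is not a
concern). The same instrument set through MR-PRESSO flags no outliers and
returns the matching estimate:

```sh
$ mrkit presso --n-sim 1000 --seed 1
global p = 0.5105; outliers: none
estimate: OR=1.72 [1.18, 2.52] p=0.0179
```

`mrkit reproduce-paper` re-runs all 8 outcomes × 4 methods from the packaged
fixture and writes the results grid plus a cell-by-cell diff against the
published table; `mrkit run --config study.yaml` does the same for your own
summary-statistic TSVs; `mrkit loo`, `mrkit mvmr` and `mrkit simulate` cover
the sensitivity analyses and the synthetic generator.

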