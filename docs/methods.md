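# Methods

## Model and assumptions

All estimators operate on the standard two-sample summary-data
instrumental-variable model. For SNP $i$, let $\gamma_i$ be its true effect
on the exposure and $\Gamma_i$ its true effect on the outcome, with

$$\Gamma_i = \theta\,\gamma_i + \alpha_i,$$

where $\theta$ is the causal effect of the exposure on the outcome (log-odds
scale for case-control traits) and $\alpha_i$ is a direct (horizontally
pleiotropic) effect. Observed summary statistics are
$\hat\gamma_i \sim N(\gamma_i, \sigma_{Xi}^2)$ and
$\hat\Gamma_i \sim N(\Gamma_i, \sigma_{Yi}^2)$, estimated in non-overlapping
samples. IVW is consistent when all $\alpha_i = 0$ (or balanced with mean
zero and uncorrelated with $\gamma_i$); MR-Egger relaxes this to the InSIDE
condition (pleiotropy independent of instrument strength) and estimates the
mean directional pleiotropy as its intercept; the weighted median is
consistent when valid instruments carry more than half the weight; MR-PRESSO
targets the case of a few strongly pleiotropic outliers.

## Statistical conventions

These conventions reproduce the packaged case study's published values from
its packaged per-SNP inputs, and follow the estimators' source publications.

- **SE reconstruction.** Published instrument tables often print betas and
  p-values only; every analysis here reconstructs
  $\mathrm{se} = |\beta| / \Phi^{-1}(1 - p/2)$. The reconstruction is exact
  for Wald-type tests; p-values below 1e-300 are refused (the caller must
  supply the SE) rather than clamped, to avoid fabricating instrument
  strength.
- **IVW.** Origin-constrained WLS with weights $1/\sigma_{Yi}^2$. The
  random-effects (default) SE multiplies the fixed-effect SE by the residual
  standard deviation floored at 1: overdispersion widens intervals,
  underdispersion never narrows them. p-values from the normal.
- **MR-Egger.** Instruments are re-oriented so $\hat\gamma_i \ge 0$ before
  fitting (the intercept is not orientation-invariant). Slope and intercept
  use the same floored residual scale; p-values from $t_{n-2}$.
- **Weighted median.** Ratios sorted, cumulative standardized weights
  $s_j = (\sum_{i\le j} w_i - w_j/2)/\sum_i w_i$, linear interpolation at
  0.5. SE from a parametric bootstrap (default 1000 draws) resampling both
  $\hat\gamma$ and $\hat\Gamma$; a seed is mandatory in the pipeline so
  reported p-values are reproducible.
- **MR-PRESSO.** The observed statistic is the weighted leave-one-out
  residual sum of squares. The null distribution comes from parametric
  simulation (default 1000 draws) under the no-pleiotropy model with
  expectations at the leave-one-out slopes; Monte-Carlo p-values use the
  $(k+1)/(n_{\mathrm{sim}}+1)$ estimator so they are never zero. Outliers
  are called at Bonferroni-adjusted p < 0.05. The accompanying causal
  estimate is the origin-constrained WLS slope with *unfloored* residual
  scale and a $t_{n-1}$ reference — the source implementation's convention;
  with no outliers its point estimate equals IVW's exactly. Random draws are
  tied to per-SNP substreams keyed on (seed, rsID), so instrument order
  cannot change any result. The distortion test compares the raw-minus-
  corrected slope shift against shifts from removing random subsets of the
  outlier set's size; it is exercised on synthetic data only, since the
  packaged study yields no outliers.
- **MVMR-IVW.** WLS of the outcome betas on the $k \times m$ exposure-beta
  matrix, no intercept, weights $1/\sigma_{Yi}^2$, floored residual scale,
  normal p-values. Exposure-side measurement error is ignored (standard
  MVMR-IVW); with the default synthetic SE regime this attenuates estimates
  by roughly 5%, well inside the reported SEs. No MVMR-Egger.
- **Diagnostics.** Cochran's Q over the Wald ratios at the IVW estimate,
  $\chi^2_{n-1}$; per-SNP F as $(\hat\gamma/\sigma_X)^2$ with the combined F
  defined as their sum; BH-FDR (via statsmodels) applied per method across
  outcomes by default, with a global-family switch — for the packaged study
  neither choice changes which results are significant. Confidence intervals
  are fixed at 95% (normal quantile 1.959964), the only level the source
  study reports; `StudyConfig.ci_level` exists for interface completeness
  but accepts only 0.95.
- **Power.** Non-centrality approximation for a binary outcome:
  $\mathrm{power} = \Phi(\kappa - z_{1-\alpha/2}) + \Phi(-\kappa -
  z_{1-\alpha/2})$ with $\kappa = \sqrt{n\,R^2_X\,\phi(1-\phi)}\,
  |\ln \mathrm{OR}|$, where $\phi$ is the case fraction and $R^2_X$ the
  exposure variance explained by the instruments; two-sided, returns
  $\alpha$ at OR = 1.

## Instrument construction

Records are masked against configurable regions — by default the extended
HLA region, chr6:20,000,000–40,000,000 (GRCh37, 1-based inclusive), whose
strong and complex LD with celiac-disease risk alleles would otherwise bias
the analysis. Selection keeps records with $p < 5\times10^{-8}$ and greedily
clumps them (ascending p, ties broken by chromosome and position for
determinism): a record survives if its $r^2$ with every previously kept
record on the same chromosome within ±5 Mb is at most 0.001. LD is supplied
by the caller (square labelled matrix or long-format TSV); unlisted pairs
count as $r^2 = 0$ — the package never queries reference panels.

Harmonization aligns outcome to exposure effect alleles: direct match
copies, swapped labels negate the outcome beta (and reflect the EAF), and a
strand-complement rescue is attempted for non-palindromic SNPs. Palindromic
(A/T, C/G) SNPs are rejected by default unless the outcome allele frequency
falls outside [0.3, 0.7]; the source study states only that its final
instruments were non-palindromic, so both the frequency cutoff and the
strand-rescue are configurable rather than fixed at a guessed value. The
optional MAF > 0.05 common-variant filter is off by default, since the study
reports it as a property of the selected instruments rather than
unambiguously as a selection step. Proxy instruments are accepted in
pre-matched form (`rs2327832 (rs6920220)` in the packaged table); proxy
*discovery* from LD panels is out of scope. Every filtering decision is
recorded in a provenance log.

UK Biobank-derived outcome tables in the packaged fixture carry
linear-probability-scale betas (~1e-4); the pipeline performs no scale
conversion, mirroring the source analysis, so those odds ratios print as
1.00 — flagged here so nobody mistakes them for evidence of exactly null
effects on the odds scale.

## Synthetic-data generator

`generate_two_sample` draws exposure effects in the exposure-increasing
orientation with magnitudes uniform on 0.1–0.35, exposure SEs on 0.03–0.04
and outcome SEs on 0.12–0.19 — matching the reconstructed values of the
packaged 11-instrument study, so simulations run in the same signal-to-noise
regime as the real analysis. Pleiotropy $\alpha_i$ is normal with
configurable mean (directional when nonzero) and SD, applied in that
oriented frame; a configurable fraction of instruments receives an extra
outlier shift measured in outcome-SE units. Each SNP's reported effect
allele is then a random labeling that flips both betas jointly, reproducing
the mixed signs of real tables without altering any estimand. One shared
entropy source spawns a named substream per SNP, so outputs are bit-identical
for a given seed. Emitted association records carry p-values computed from
their betas and SEs, so SE reconstruction round-trips exactly.

What the generator does *not* emulate: genuine LD between instruments
(`generate_ld_blocks` provides an idealized block-diagonal $r^2$ for
clumping tests only), allele-frequency-dependent effect sizes, sample
overlap between exposure and outcome studies, winner's-curse selection of
instruments, and non-normal sampling error. Passing simulation-based tests
therefore demonstrates correctness of the estimators under the linear IV
model, not robustness to those additional features of real data.

Some property tests use sharper outcome SEs (0.04–0.10) than the study
defaults: contamination-robustness and directionality checks need the
valid-instrument ratio cluster to be distinguishable above sampling noise
for the property to be visible at all; the operating-characteristic checks
(coverage, type-I error, outlier detection, MVMR recovery at the study's
91-instrument scale) run at the study-like defaults.

## Design choices on open questions

- The source study reports "Q_IVW = 0.47" without units; recomputation from
  its own instrument table gives Q = 9.71 on 10 df, i.e. p = 0.466, so the
  printed number is treated as the heterogeneity p-value.
- The F statistic is taken as $z^2$ per SNP with the combined value defined
  as the sum — this reproduces the reported bounds (combined > 500, each
  individual ≈ 30 or more) for the packaged instruments.
- The power calculation uses the two-sided form; the study cites an external
  calculator without restating its sidedness.
- BH-FDR family: per method across outcomes by default (the study does not
  state its family; no choice alters significance for these data).

## Known limitations

- One outcome block of the packaged study ("Non-follicular lymphoma") is
  internally inconsistent in the source publication: its printed per-SNP
  inputs yield IVW OR 0.99 (p 0.92) against a printed 0.96 (p 0.58), with
  the same disagreement under every method, while the other seven outcomes
  reproduce to printed precision. The regression tests therefore cover the
  seven consistent outcomes; nothing in the package's headline claims rests
  on the inconsistent block.
- Wald-ratio SEs use the first-order delta method and ignore exposure-side
  noise; this matches the study's reported single-SNP p-values but slightly
  understates uncertainty for weak instruments.
- The bidirectional and multivariable analyses of the original study require
  external summary statistics (reverse-direction lymphoma instruments;
  GIANT/UK Biobank anthropometric and smoking GWAS) that are not
  redistributable here; the machinery is validated on synthetic data, and
  real-data runs are a matter of pointing `StudyConfig` / `build_union_ivset`
  at the downloaded TSVs.
- X/Y chromosomes, genome-build liftover, genotype-level QC and LD-panel
  queries are out of scope by design.
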