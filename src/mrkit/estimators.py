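"""Univariable two-sample MR estimators and diagnostics.

Implements the four causal estimators used in the packaged study — per-SNP
Wald ratio, random-effects inverse-variance-weighted (IVW) regression,
MR-Egger regression with its intercept (pleiotropy) test, and the
interpolated weighted median with a parametric-bootstrap SE — plus Cochran's
Q heterogeneity test, per-instrument F statistics, Benjamini-Hochberg FDR
adjustment, and an analytic power approximation for binary outcomes.

Conventions (chosen to match the estimators' source publications):

* IVW: weighted regression of the outcome effects on the exposure effects
  through the origin, weights 1/se_out^2.  Under the multiplicative
  random-effects model the residual scale is floored at 1 — underdispersion
  is never allowed to shrink the SE.  p-values come from the normal.
* MR-Egger: instruments are re-oriented so every exposure effect is
  non-negative (the intercept is not orientation-invariant), then fitted with
  a free intercept; p-values use Student's t with nsnp - 2 df.
* Weighted median: interpolated weighted median of the per-SNP Wald ratios
  with inverse-variance weights; SE from a seeded parametric bootstrap.
* Confidence intervals are 95% normal-quantile intervals on the log-odds
  scale, exponentiated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MREstimate",
    "EggerResult",
    "HeterogeneityResult",
    "InstrumentStrength",
    "Z_95",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_median_point",
    "cochran_q",
    "instrument_strength",
    "bh_fdr",
    "mr_power_binary",
]

#: Normal quantile for two-sided 95% intervals.
Z_95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds scale, with its OR transform."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    odds_ratio: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta_se(
        cls, method: str, nsnp: int, beta: float, se: float, pval: float
    ) -> "MREstimate":
        return cls(
            method=method,
            nsnp=nsnp,
            beta=float(beta),
            se=float(se),
            pval=float(min(pval, 1.0)),
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
        )


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float


@dataclass(frozen=True)
class InstrumentStrength:
    per_snp_f: tuple[float, ...]
    combined_f: float


def _require(insts: InstrumentSet, minimum: int, what: str) -> None:
    if len(insts) < minimum:
        raise ValueError(f"{what} requires >= {minimum} instruments, got {len(insts)}")


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate: variant-outcome over variant-exposure effect.

    The SE uses the first-order delta approximation se_out/|beta_exp|, which
    ignores exposure-side noise; as a consequence the two-sided p-value equals
    the outcome association's own p-value.
    """
    if inst.beta_exp == 0:
        raise ZeroDivisionError(f"{inst.snp_id}: Wald ratio undefined for beta_exp = 0")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate.from_beta_se("wald_ratio", 1, beta, se, pval)


def _ivw_fit(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray, floor_scale: bool
) -> tuple[float, float, float]:
    """Origin-constrained WLS; returns (slope, se, residual scale sigma^2)."""
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    n = len(bx)
    if n > 1:
        sigma2 = float(np.sum(w * (by - slope * bx) ** 2)) / (n - 1)
    else:
        sigma2 = 1.0
    scale = max(1.0, sigma2) if floor_scale else sigma2
    se = float(np.sqrt(scale / sxx))
    return slope, se, sigma2


def ivw(insts: InstrumentSet, variance_model: str = "multiplicative_re") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of beta_out on beta_exp through
    the origin, weights 1/se_out^2.

    ``variance_model='multiplicative_re'`` (default) scales the slope SE by
    the residual standard deviation floored at 1; ``'fixed'`` uses unit scale.
    A single instrument reduces exactly to the Wald ratio.
    """
    _require(insts, 1, "ivw")
    if variance_model not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    bx, _, by, sy = insts.arrays()
    w = 1.0 / sy**2
    if variance_model == "fixed":
        slope, _, _ = _ivw_fit(bx, by, w, floor_scale=True)
        se = float(np.sqrt(1.0 / np.sum(w * bx * bx)))
    else:
        slope, se, _ = _ivw_fit(bx, by, w, floor_scale=True)
    pval = 2.0 * stats.norm.sf(abs(slope) / se)
    return MREstimate.from_beta_se("ivw", len(insts), slope, se, pval)


def egger(insts: InstrumentSet) -> EggerResult:
    """MR-Egger: weighted regression WITH a free intercept.

    The intercept estimates the average directional pleiotropic effect; its
    two-sided t test (nsnp - 2 df) is the standard horizontal-pleiotropy
    diagnostic.  Instruments are first oriented to beta_exp >= 0.
    """
    _require(insts, 3, "egger")
    bx, _, by, sy = insts.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    n = len(bx)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = max(1.0, sigma2) * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))
    df = n - 2
    slope_p = 2.0 * stats.t.sf(abs(coef[1] / se_slope), df)
    int_p = 2.0 * stats.t.sf(abs(coef[0] / se_int), df)
    slope = MREstimate.from_beta_se("egger", n, coef[1], se_slope, slope_p)
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_pval=float(int_p),
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    Sorts the ratios, standardizes cumulative weights as
    s_j = (cum_j - w_j/2) / total, and linearly interpolates at 0.5.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - w / 2.0) / total
    return float(np.interp(0.5, s, r))


def weighted_median(
    insts: InstrumentSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate, robust to up to 50% invalid
    instruments by weight.

    Point estimate: interpolated weighted median of the per-SNP Wald ratios
    with inverse-variance weights 1/se_wald^2.  SE: parametric bootstrap —
    beta_exp and beta_out are resampled from normal(beta, se) ``n_boot``
    times, the median recomputed, and the bootstrap SD taken.  Deterministic
    given ``seed``.
    """
    _require(insts, 3, "weighted_median")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = insts.arrays()
    se_wald = sy / np.abs(bx)
    point = weighted_median_point(by / bx, 1.0 / se_wald**2)

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_sim = rng.normal(by, sy, size=(n_boot, len(by)))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ratios = by_sim[b] / bx_sim[b]
        w = (bx_sim[b] / sy) ** 2
        boots[b] = weighted_median_point(ratios, w)
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    pval = 2.0 * stats.norm.sf(abs(point) / se) if se > 0 else 1.0
    return MREstimate.from_beta_se("weighted_median", len(insts), point, se, pval)


def cochran_q(insts: InstrumentSet, theta: float) -> HeterogeneityResult:
    """Cochran's Q over the per-SNP Wald ratios around a pooled estimate.

    Q = sum_i w_i (r_i - theta)^2 with w_i = 1/se_wald_i^2; the reference is
    chi-square with nsnp - 1 df (``theta`` is typically the IVW estimate).
    """
    _require(insts, 2, "cochran_q")
    bx, _, by, sy = insts.arrays()
    r = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (r - theta) ** 2))
    df = len(insts) - 1
    return HeterogeneityResult(q_stat=q, df=df, pval=float(stats.chi2.sf(q, df)))


def instrument_strength(insts: InstrumentSet) -> InstrumentStrength:
    """Per-SNP F = (beta_exp/se_exp)^2 and their sum as the combined F."""
    bx, sx, _, _ = insts.arrays()
    f = (bx / sx) ** 2
    return InstrumentStrength(per_snp_f=tuple(float(x) for x in f), combined_f=float(f.sum()))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mr_power_binary(
    n: float,
    case_fraction: float,
    r2_x: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of an MR test for a binary outcome.

    Non-centrality approximation: the test statistic for a true causal odds
    ratio ``or_alt`` is roughly normal with mean
    sqrt(n * r2_x * cf * (1 - cf)) * |ln(or_alt)|, where ``r2_x`` is the
    variance in the exposure explained by the instruments and ``cf`` the case
    fraction.  At or_alt = 1 the returned value is the test size ``alpha``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0 < r2_x < 1):
        raise ValueError("r2_x must lie in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    ncp = np.sqrt(n * r2_x * case_fraction * (1.0 - case_fraction)) * abs(np.log(or_alt))
    z_crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))
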