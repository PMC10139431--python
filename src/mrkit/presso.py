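"""MR-PRESSO: pleiotropy residual sum and outlier analysis.

A simulation-based test for horizontal pleiotropy.  The observed
leave-one-out residual sum of squares (RSS) is compared against its null
distribution generated by parametric simulation under the no-pleiotropy
model; per-SNP squared residuals give Bonferroni-adjusted outlier tests, and
when outliers are found the causal effect is re-estimated without them and a
distortion test quantifies how much the outliers moved the estimate.

The main causal estimate reported alongside (the "raw" estimate) is the
origin-constrained WLS slope with the residual scale NOT floored and a
Student-t reference with nsnp - 1 df, the convention of the method's source
implementation; with no outliers its point estimate coincides exactly with
IVW's.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z_95
from .summary_data import InstrumentSet

__all__ = ["PressoResult", "run_presso"]


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outliers: tuple[str, ...]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None
    distortion_pval: float | None


def _substream(seed: int, snp_id: str) -> np.random.Generator:
    # Per-SNP substream keyed on (seed, rsID) so instrument order cannot
    # change any draw.
    digest = hashlib.sha256(snp_id.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-constrained WLS slopes, one per instrument.

    Vectorized over trailing simulation axes: bx/by may be (n,) or (n, s).
    """
    sxy = np.sum(w * bx * by, axis=0)
    sxx = np.sum(w * bx * bx, axis=0)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _raw_estimate(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> MREstimate:
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    n = len(bx)
    sigma2 = float(np.sum(w * (by - slope * bx) ** 2)) / (n - 1)
    se = float(np.sqrt(sigma2 / sxx))
    pval = float(2.0 * stats.t.sf(abs(slope / se), n - 1))
    # CI uses the normal quantile, matching the companion estimators.
    return MREstimate(
        method="presso",
        nsnp=n,
        beta=slope,
        se=se,
        pval=min(pval, 1.0),
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(slope - Z_95 * se)),
        ci_high=float(np.exp(slope + Z_95 * se)),
    )


def run_presso(
    insts: InstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Run the full MR-PRESSO procedure on a harmonized instrument set.

    Steps: (a) observed leave-one-out weighted RSS; (b) ``n_sim`` parametric
    simulations of the instrument set under the no-pleiotropy null to build
    the RSS null distribution (global test, Monte-Carlo p with the
    (k+1)/(n_sim+1) continuity estimator); (c) per-SNP outlier tests on the
    simulated squared-residual distributions, Bonferroni-multiplied by nsnp
    and called at ``outlier_alpha``; (d) if outliers are found, an
    outlier-corrected estimate on the remaining SNPs and a distortion test of
    raw vs corrected slope against slopes from random outlier-sized subsets.

    Deterministic given ``seed``; draws are tied to per-SNP substreams so the
    result is invariant to instrument order.
    """
    if len(insts) < 4:
        raise ValueError(f"MR-PRESSO requires >= 4 instruments, got {len(insts)}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        seed = 0

    # Work in sorted-rsID order internally so float reductions are also
    # order-invariant; report per-SNP results keyed by rsID.
    order = np.argsort(np.array(insts.snp_ids))
    snp_ids = [insts.snp_ids[i] for i in order]
    bx_all, sx_all, by_all, sy_all = insts.arrays()
    bx, sx, by, sy = (a[order] for a in (bx_all, sx_all, by_all, sy_all))
    n = len(bx)
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid_obs = by - theta_loo * bx
    sq_obs = w * resid_obs**2
    rss_obs = float(np.sum(sq_obs))

    # Simulated null: per-SNP substreams, expectations from the LOO slopes.
    bx_sim = np.empty((n, n_sim))
    by_sim = np.empty((n, n_sim))
    for i, snp in enumerate(snp_ids):
        rng = _substream(seed, snp)
        bx_sim[i] = rng.normal(bx[i], sx[i], size=n_sim)
        by_sim[i] = rng.normal(theta_loo[i] * bx[i], sy[i], size=n_sim)

    theta_loo_sim = _loo_slopes(bx_sim, by_sim, w[:, None])
    sq_sim = w[:, None] * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(sq_sim, axis=0)

    global_pval = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    per_snp_raw = (np.sum(sq_sim >= sq_obs[:, None], axis=1) + 1.0) / (n_sim + 1.0)
    per_snp_adj = np.minimum(per_snp_raw * n, 1.0)
    per_snp_pvals = dict(zip(snp_ids, per_snp_adj.astype(float)))
    outlier_ids = tuple(s for s, p in per_snp_pvals.items() if p < outlier_alpha)

    raw = _raw_estimate(bx, by, sy)

    corrected: MREstimate | None = None
    distortion_pval: float | None = None
    if outlier_ids:
        keep = np.array([s not in outlier_ids for s in snp_ids])
        if keep.sum() < 2:
            raise ValueError("all (or nearly all) instruments flagged as outliers")
        corrected = _raw_estimate(bx[keep], by[keep], sy[keep])
        # Distortion null: slopes after removing random subsets of the same
        # size as the outlier set.
        rng = _substream(seed, "__distortion__")
        n_out = len(outlier_ids)
        obs_shift = abs(raw.beta - corrected.beta)
        shifts = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(n, size=n_out, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[drop] = False
            w_m = 1.0 / sy[mask] ** 2
            slope = np.sum(w_m * bx[mask] * by[mask]) / np.sum(w_m * bx[mask] ** 2)
            shifts[b] = abs(raw.beta - slope)
        distortion_pval = float((np.sum(shifts >= obs_shift) + 1.0) / (n_sim + 1.0))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        per_snp_pvals=per_snp_pvals,
        outliers=outlier_ids,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
    )
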