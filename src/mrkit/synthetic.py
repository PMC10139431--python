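"""Seeded generators of two-sample GWAS summary statistics with known truth.

The generating model is the linear instrumental-variable model the MR
estimators assume: each variant i has a true effect gamma_i on the exposure
and a true effect on the outcome

    Gamma_i = theta * gamma_i + alpha_i,

where theta is the causal effect of interest and alpha_i a direct
(horizontally pleiotropic) effect — zero for valid instruments, drawn from a
normal with configurable mean (directional when nonzero) and SD otherwise,
with an optional planted-outlier fraction receiving an extra shift measured
in outcome-SE units.  Observed summary statistics are the truth plus
sampling noise at the study SEs: beta_exp ~ N(gamma, se_exp),
beta_out ~ N(Gamma, se_out).

Default magnitudes mirror the packaged celiac-disease study: 11 instruments,
exposure effects of magnitude 0.1-0.35, exposure SEs around 0.03-0.04 and
outcome SEs around 0.12-0.19, so synthetic tests exercise the same
signal-to-noise regime as the real analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .mvmr import MVMRInput
from .summary_data import (
    AssociationRecord,
    HarmonizedInstrument,
    InstrumentSet,
    LDMatrix,
    pval_from_beta_se,
)

__all__ = [
    "SyntheticTruth",
    "generate_two_sample",
    "generate_ld_blocks",
    "generate_multivariable",
    "instrument_set_to_records",
    "write_truth_yaml",
]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters attached to a simulated dataset."""

    theta: float = 0.0
    n_snps: int = 11
    gamma_range: tuple[float, float] = (0.1, 0.35)  # |gamma| magnitude
    se_exp_range: tuple[float, float] = (0.03, 0.04)
    se_out_range: tuple[float, float] = (0.12, 0.19)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_frac: float = 0.0
    outlier_shift: float = 0.0  # in units of the outlier's se_out
    maf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    # filled in by the generator:
    gamma: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    outlier_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("gamma_range", "se_exp_range", "se_out_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if not (0.0 <= self.outlier_frac < 1.0):
            raise ValueError("outlier_frac must lie in [0, 1)")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    # One shared entropy source, one named substream per SNP (stable under
    # any later reordering of the instruments).
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_two_sample(truth: SyntheticTruth) -> tuple[InstrumentSet, SyntheticTruth]:
    """Simulate one two-sample summary-statistics dataset.

    Returns the harmonized instrument set and a copy of ``truth`` with the
    realized per-SNP parameters (gamma, alpha, planted outliers) filled in.
    Deterministic given ``truth.seed``.
    """
    n = truth.n_snps
    streams = _spawn(truth.seed, n + 1)
    head = streams[0]
    n_out = int(round(truth.outlier_frac * n))
    outlier_idx = set(head.choice(n, size=n_out, replace=False).tolist()) if n_out else set()

    instruments = []
    gammas, alphas, outlier_snps = [], [], []
    for i in range(n):
        rng = streams[i + 1]
        snp_id = f"rs9{i:07d}"
        # gamma is drawn in the exposure-increasing orientation (the frame in
        # which directional pleiotropy is defined); the reported effect allele
        # is then a random labeling that flips both betas jointly, mirroring
        # the mixed signs of real summary tables.
        gamma = rng.uniform(*truth.gamma_range)
        se_exp = rng.uniform(*truth.se_exp_range)
        se_out = rng.uniform(*truth.se_out_range)
        alpha = 0.0
        if truth.pleiotropy_sd > 0 or truth.pleiotropy_mean != 0:
            alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd)
        if i in outlier_idx:
            alpha += truth.outlier_shift * se_out
            outlier_snps.append(snp_id)
        big_gamma = truth.theta * gamma + alpha
        orient = 1.0 if rng.random() < 0.5 else -1.0
        beta_exp = rng.normal(orient * gamma, se_exp)
        beta_out = rng.normal(orient * big_gamma, se_out)
        gamma = orient * gamma  # record in the observed orientation
        eaf = rng.uniform(*truth.maf_range)
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp_id,
                beta_exp=beta_exp,
                se_exp=se_exp,
                beta_out=beta_out,
                se_out=se_out,
                eaf_out=eaf,
            )
        )
        gammas.append(gamma)
        alphas.append(alpha)

    realized = SyntheticTruth(**{**asdict(truth)})
    realized.gamma = gammas
    realized.alpha = alphas
    realized.outlier_snps = outlier_snps
    insts = InstrumentSet(
        exposure_id="synthetic_exposure",
        outcome_id="synthetic_outcome",
        instruments=instruments,
        provenance=[f"simulated, seed={truth.seed}, theta={truth.theta}"],
    )
    return insts, realized


def instrument_set_to_records(
    insts: InstrumentSet,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Emit (exposure, outcome) association records in the pipeline's TSV
    dialect, with p-values computed from the betas and SEs so that SE
    reconstruction from the p-value round-trips."""
    exp_records, out_records = [], []
    for i, inst in enumerate(insts):
        chrom = (i % 22) + 1
        pos = 1_000_000 + 10_000_000 * (i // 22) + 1000 * i
        common = dict(
            snp_id=inst.snp_id,
            chrom=chrom,
            pos_bp=pos,
            effect_allele="A",
            other_allele="G",  # non-palindromic by construction
        )
        exp_records.append(
            AssociationRecord(
                beta=inst.beta_exp,
                se=inst.se_exp,
                pval=pval_from_beta_se(inst.beta_exp, inst.se_exp),
                trait_id=insts.exposure_id,
                **common,
            )
        )
        out_records.append(
            AssociationRecord(
                beta=inst.beta_out,
                se=inst.se_out,
                pval=pval_from_beta_se(inst.beta_out, inst.se_out),
                eaf=inst.eaf_out,
                trait_id=insts.outcome_id,
                **common,
            )
        )
    return exp_records, out_records


def generate_ld_blocks(
    n_blocks: int,
    snps_per_block: int,
    r2_within: float,
    seed: int = 0,
) -> tuple[list[AssociationRecord], LDMatrix]:
    """Exposure records in a block-diagonal LD structure for clumping tests.

    Every within-block pair has r-squared ``r2_within``; cross-block pairs
    have none.  All records pass genome-wide significance, so clumping at any
    r2_max below ``r2_within`` keeps exactly one SNP per block (the smallest
    p), and at r2_within = 0 keeps everything.
    """
    if not (0.0 <= r2_within < 1.0):
        raise ValueError("r2_within must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[AssociationRecord] = []
    pairs: dict[frozenset, float] = {}
    for b in range(n_blocks):
        chrom = (b % 22) + 1
        start = 1_000_000 + 12_000_000 * (b // 22)
        block_ids = []
        for s in range(snps_per_block):
            snp_id = f"rs{b:04d}{s:04d}"
            log10p = rng.uniform(-30.0, -8.5)
            beta = rng.uniform(0.1, 0.35) * (1.0 if rng.random() < 0.5 else -1.0)
            records.append(
                AssociationRecord(
                    snp_id=snp_id,
                    chrom=chrom,
                    pos_bp=start + 1000 * s,
                    effect_allele="A",
                    other_allele="G",
                    beta=beta,
                    pval=10.0**log10p,
                    trait_id="synthetic_exposure",
                )
            )
            block_ids.append(snp_id)
        if r2_within > 0:
            for i in range(len(block_ids)):
                for j in range(i + 1, len(block_ids)):
                    pairs[frozenset((block_ids[i], block_ids[j]))] = r2_within
    return records, LDMatrix(pairs)


def generate_multivariable(
    k: int,
    m: int,
    true_effects,
    correlation_between_exposures: float = 0.0,
    seed: int = 0,
    gamma_sd: float = 0.15,
    se_exp_range: tuple[float, float] = (0.03, 0.04),
    se_out_range: tuple[float, float] = (0.12, 0.19),
) -> tuple[MVMRInput, SyntheticTruth]:
    """Simulate a multivariable MR design with k instruments and m exposures.

    True per-SNP exposure effects are drawn jointly normal with SD
    ``gamma_sd`` and equicorrelation ``correlation_between_exposures`` across
    exposures; the true outcome effect is the linear combination under
    ``true_effects``.  Observed betas add sampling noise at the drawn SEs.
    """
    true_effects = np.asarray(true_effects, dtype=float)
    if true_effects.shape != (m,):
        raise ValueError("true_effects must have length m")
    if k <= m:
        raise ValueError("need k > m")
    rho = correlation_between_exposures
    if abs(rho) >= 1.0:
        raise ValueError("|correlation| must be < 1")
    cov = gamma_sd**2 * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))
    rng = np.random.default_rng(seed)
    gamma = rng.multivariate_normal(np.zeros(m), cov, size=k)
    se_x = rng.uniform(*se_exp_range, size=(k, m))
    se_y = rng.uniform(*se_out_range, size=k)
    beta_x = rng.normal(gamma, se_x)
    big_gamma = gamma @ true_effects
    beta_y = rng.normal(big_gamma, se_y)
    mv = MVMRInput(
        snp_ids=[f"rs8{i:07d}" for i in range(k)],
        exposure_ids=[f"exposure_{j}" for j in range(m)],
        exposure_betas=beta_x,
        exposure_ses=se_x,
        outcome_beta=beta_y,
        outcome_se=se_y,
        provenance=[f"simulated, seed={seed}"],
    )
    truth = SyntheticTruth(theta=float(true_effects[0]), n_snps=k, seed=seed)
    truth.gamma = [float(x) for x in np.ravel(gamma[:, 0])]
    return mv, truth


def write_truth_yaml(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the generating parameters alongside the simulated data."""
    d = asdict(truth)
    for key in ("gamma_range", "se_exp_range", "se_out_range", "maf_range"):
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
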