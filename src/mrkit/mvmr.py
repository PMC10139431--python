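"""Multivariable MR: joint IVW regression on several exposures at once.

Regresses the variant-outcome associations on the variant-exposure
associations of m exposures simultaneously (no intercept), weighting by the
inverse outcome variance.  Each fitted coefficient is the direct effect of
that exposure on the outcome conditional on the others — the standard tool
for asking whether one risk factor's effect survives adjustment for
correlated risk factors instrumented by overlapping variants.

Measurement error in the exposure betas is ignored (standard MVMR-IVW); the
residual scale of the SEs is floored at 1, matching the univariable IVW
convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate
from .summary_data import AssociationRecord, LDMatrix, select_instruments

__all__ = ["MVMRInput", "mvmr_ivw", "build_union_ivset", "read_mvmr_tsv", "write_mvmr_tsv"]


@dataclass
class MVMRInput:
    """Design matrices for a multivariable MR fit (k SNPs x m exposures)."""

    snp_ids: list[str]
    exposure_ids: list[str]
    exposure_betas: np.ndarray  # (k, m)
    exposure_ses: np.ndarray  # (k, m)
    outcome_beta: np.ndarray  # (k,)
    outcome_se: np.ndarray  # (k,)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_betas = np.asarray(self.exposure_betas, dtype=float)
        self.exposure_ses = np.asarray(self.exposure_ses, dtype=float)
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float)
        self.outcome_se = np.asarray(self.outcome_se, dtype=float)
        k, m = self.exposure_betas.shape
        if len(self.snp_ids) != k or len(self.exposure_ids) != m:
            raise ValueError("label lengths do not match matrix shape")
        if self.exposure_ses.shape != (k, m) or self.outcome_beta.shape != (k,):
            raise ValueError("inconsistent MVMR input shapes")
        if k <= m:
            raise ValueError(f"need more instruments ({k}) than exposures ({m})")
        if np.any(self.exposure_ses <= 0) or np.any(self.outcome_se <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def k(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def m(self) -> int:
        return self.exposure_betas.shape[1]


def _collinear_exposures(X: np.ndarray, exposure_ids: Sequence[str]) -> list[str]:
    """Name exposures involved in a rank deficiency (for the error message)."""
    rank = np.linalg.matrix_rank(X)
    offenders = []
    for j, name in enumerate(exposure_ids):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            offenders.append(name)
    return offenders or list(exposure_ids)


def mvmr_ivw(mv_input: MVMRInput) -> list[MREstimate]:
    """Multivariable IVW: WLS of the outcome betas on the m exposure-beta
    columns with no intercept, weights 1/outcome_se^2.

    Returns one estimate per exposure (conditional on the others), in the
    order of ``exposure_ids``.  With m = 1 this reduces exactly to the
    univariable IVW estimate on the same instruments.
    """
    X = mv_input.exposure_betas
    y = mv_input.outcome_beta
    w = 1.0 / mv_input.outcome_se**2
    k, m = X.shape
    if np.linalg.matrix_rank(X) < m:
        offenders = _collinear_exposures(X, mv_input.exposure_ids)
        raise np.linalg.LinAlgError(
            f"exposure-beta matrix is rank deficient; collinear exposures: {offenders}"
        )
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - m)
    cov = max(1.0, sigma2) * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    out = []
    for j, name in enumerate(mv_input.exposure_ids):
        pval = 2.0 * stats.norm.sf(abs(coef[j] / ses[j]))
        est = MREstimate.from_beta_se("mvmr_ivw", k, coef[j], ses[j], pval)
        out.append(est)
    return out


def build_union_ivset(
    per_exposure_records: Mapping[str, Sequence[AssociationRecord]],
    outcome_assoc: Mapping[str, AssociationRecord],
    cross_assoc: Mapping[str, Mapping[str, AssociationRecord]],
    ld: LDMatrix | None = None,
    r2_max: float = 0.001,
    window_bp: int = 5_000_000,
    mode: str = "union",
) -> MVMRInput:
    """Assemble the multivariable design from per-exposure instrument lists.

    ``per_exposure_records`` holds each exposure's candidate instruments
    (already filtered to its own significance threshold upstream).  In
    ``union`` mode the candidates are pooled and clumped jointly; in
    ``exposure_specific`` mode each exposure's list is clumped on its own and
    the union of survivors is taken.  ``cross_assoc[e][snp]`` must supply
    every exposure's association for every surviving SNP, and
    ``outcome_assoc[snp]`` the outcome association — nothing is imputed;
    missing entries raise a completeness error listing them.
    """
    if mode not in ("union", "exposure_specific"):
        raise ValueError(f"unknown mode {mode!r}")
    exposure_ids = list(per_exposure_records)
    if mode == "union":
        pool: dict[str, AssociationRecord] = {}
        for recs in per_exposure_records.values():
            for r in recs:
                if r.snp_id not in pool or r.pval < pool[r.snp_id].pval:
                    pool[r.snp_id] = r
        survivors = select_instruments(
            list(pool.values()), p_threshold=1.1, ld=ld, r2_max=r2_max, window_bp=window_bp
        )
        snp_ids = [r.snp_id for r in survivors]
    else:
        snp_ids_set: dict[str, None] = {}
        for recs in per_exposure_records.values():
            kept = select_instruments(
                list(recs), p_threshold=1.1, ld=ld, r2_max=r2_max, window_bp=window_bp
            )
            for r in kept:
                snp_ids_set.setdefault(r.snp_id, None)
        snp_ids = list(snp_ids_set)

    missing = []
    for snp in snp_ids:
        if snp not in outcome_assoc:
            missing.append(f"{snp} (outcome)")
        for e in exposure_ids:
            if snp not in cross_assoc.get(e, {}):
                missing.append(f"{snp} ({e})")
    if missing:
        raise KeyError(f"missing associations, cannot build MVMR input: {missing}")

    k, m = len(snp_ids), len(exposure_ids)
    xb = np.empty((k, m))
    xs = np.empty((k, m))
    yb = np.empty(k)
    ys = np.empty(k)
    for i, snp in enumerate(snp_ids):
        orec = outcome_assoc[snp].with_se()
        yb[i], ys[i] = orec.beta, orec.se
        for j, e in enumerate(exposure_ids):
            erec = cross_assoc[e][snp].with_se()
            xb[i, j], xs[i, j] = erec.beta, erec.se
    return MVMRInput(
        snp_ids=snp_ids,
        exposure_ids=exposure_ids,
        exposure_betas=xb,
        exposure_ses=xs,
        outcome_beta=yb,
        outcome_se=ys,
        provenance=[f"mode={mode}, k={k}, m={m}"],
    )


def write_mvmr_tsv(mv_input: MVMRInput, path: str | Path) -> None:
    """Wide-format TSV: one row per SNP, beta/se pair per exposure, outcome last."""
    data: dict[str, object] = {"snp": mv_input.snp_ids}
    for j, e in enumerate(mv_input.exposure_ids):
        data[f"beta_{e}"] = mv_input.exposure_betas[:, j]
        data[f"se_{e}"] = mv_input.exposure_ses[:, j]
    data["beta_outcome"] = mv_input.outcome_beta
    data["se_outcome"] = mv_input.outcome_se
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_mvmr_tsv(path: str | Path) -> MVMRInput:
    df = pd.read_csv(path, sep="\t")
    exposure_ids = [
        c[len("beta_"):]
        for c in df.columns
        if c.startswith("beta_") and c != "beta_outcome"
    ]
    xb = df[[f"beta_{e}" for e in exposure_ids]].to_numpy(float)
    xs = df[[f"se_{e}" for e in exposure_ids]].to_numpy(float)
    return MVMRInput(
        snp_ids=list(df["snp"]),
        exposure_ids=exposure_ids,
        exposure_betas=xb,
        exposure_ses=xs,
        outcome_beta=df["beta_outcome"].to_numpy(float),
        outcome_se=df["se_outcome"].to_numpy(float),
    )
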