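"""Data model, file I/O, and instrument construction for two-sample MR.

Everything upstream of estimation lives here: summary-association records,
standard-error reconstruction from p-values, genomic region masking (e.g. the
extended HLA region), palindromy checks, allele harmonization between the
exposure and outcome studies, and greedy LD clumping.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationRecord",
    "HarmonizedInstrument",
    "HarmonizationRejection",
    "InstrumentSet",
    "GenomicRegion",
    "LDMatrix",
    "EXTENDED_HLA_REGION",
    "EXPOSURE_TRAIT",
    "OUTCOME_TRAITS",
    "se_from_pval",
    "pval_from_beta_se",
    "filter_region",
    "records_in_region",
    "is_palindromic",
    "complement_allele",
    "harmonize",
    "select_instruments",
    "build_instrument_set",
    "read_summary_tsv",
    "write_summary_tsv",
    "load_table1",
    "load_table2_expected",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Extended HLA region excluded from instrument selection (GRCh37).
EXTENDED_HLA_REGION: "GenomicRegion"

#: Trait label of the exposure rows in the packaged fixture.
EXPOSURE_TRAIT = "Celiac disease"

#: The eight outcome traits of the packaged fixture, in table order.
OUTCOME_TRAITS = (
    "Diffuse large B-cell lymphoma",
    "Follicular lymphoma",
    "Hodgkin lymphoma",
    "Non-follicular lymphoma",
    "Other and unspecified types of non-Hodgkin lymphoma",
    "Mature T/NK-cell lymphomas",
    "Lymphomas",
    "Small intestine/small bowel cancer",
)

# rsID possibly followed by a parenthesized proxy rsID, e.g. "rs2327832 (rs6920220)"
_SNP_WITH_PROXY = re.compile(r"^\s*(\S+)\s*(?:\(\s*(\S+?)\s*\))?\s*$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele effect size (log-odds for case-control
    traits; linear-model scale is permitted and left unconverted). ``se`` is
    optional because published tables often omit it; use :func:`se_from_pval`
    or :meth:`with_se` to reconstruct it from the two-sided p-value.
    """

    snp_id: str
    chrom: int
    pos_bp: int
    effect_allele: str
    other_allele: str
    beta: float
    pval: float
    se: float | None = None
    eaf: float | None = None
    trait_id: str = ""
    proxy_id: str | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (1 <= self.chrom <= 22):
            raise ValueError(f"{self.snp_id}: chromosome {self.chrom} out of range 1-22")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.snp_id}: standard error must be positive")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: EAF {self.eaf} outside (0, 1)")

    def with_se(self) -> "AssociationRecord":
        """Return a copy whose ``se`` is filled in, reconstructing it from
        the p-value when absent."""
        if self.se is not None:
            return self
        return replace(self, se=se_from_pval(self.beta, self.pval))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument whose exposure and outcome effects share one effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_out: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exp > 0 or not self.se_out > 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class HarmonizationRejection:
    """Records why a SNP could not be harmonized (kept for provenance)."""

    snp_id: str
    reason: str


@dataclass
class InstrumentSet:
    """An ordered, rsID-unique collection of harmonized instruments."""

    exposure_id: str
    outcome_id: str
    instruments: list[HarmonizedInstrument]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rsIDs in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def subset(self, keep: Iterable[str]) -> "InstrumentSet":
        keep = set(keep)
        unknown = keep - set(self.snp_ids)
        if unknown:
            raise KeyError(f"unknown rsIDs: {sorted(unknown)}")
        return InstrumentSet(
            self.exposure_id,
            self.outcome_id,
            [i for i in self.instruments if i.snp_id in keep],
            provenance=list(self.provenance),
        )

    def drop(self, drop: Iterable[str]) -> "InstrumentSet":
        drop = set(drop)
        unknown = drop - set(self.snp_ids)
        if unknown:
            raise KeyError(f"unknown rsIDs: {sorted(unknown)}")
        out = self.subset(set(self.snp_ids) - drop)
        out.provenance.append(f"dropped: {sorted(drop)}")
        return out

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([i.beta_exp for i in self.instruments], dtype=float)
        sx = np.array([i.se_exp for i in self.instruments], dtype=float)
        by = np.array([i.beta_out for i in self.instruments], dtype=float)
        sy = np.array([i.se_out for i in self.instruments], dtype=float)
        return bx, sx, by, sy


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, inclusive genomic interval on one chromosome."""

    chrom: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    def contains(self, chrom: int, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp


EXTENDED_HLA_REGION = GenomicRegion(chrom=6, start_bp=20_000_000, end_bp=40_000_000)


class LDMatrix:
    """Pairwise r-squared lookup, defaulting to 0 for unlisted pairs.

    Construct from a square labelled matrix (`pandas.DataFrame`), a long-format
    table with columns ``snp_a, snp_b, r2``, or nothing (no LD at all).
    """

    def __init__(self, pairs: Mapping[frozenset, float] | None = None):
        self._pairs: dict[frozenset, float] = dict(pairs) if pairs else {}

    @classmethod
    def from_square(cls, df: pd.DataFrame) -> "LDMatrix":
        pairs: dict[frozenset, float] = {}
        for a in df.index:
            for b in df.columns:
                if a != b and float(df.loc[a, b]) > 0:
                    pairs[frozenset((a, b))] = float(df.loc[a, b])
        return cls(pairs)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "LDMatrix":
        pairs = {
            frozenset((row.snp_a, row.snp_b)): float(row.r2)
            for row in df.itertuples()
            if row.snp_a != row.snp_b
        }
        return cls(pairs)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t"))

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get(frozenset((snp_a, snp_b)), 0.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def se_from_pval(beta: float, pval: float) -> float:
    """Reconstruct a standard error from an effect size and its two-sided p.

    Uses the identity se = |beta| / z with z the upper-(p/2) standard-normal
    quantile. p-values at (or numerically indistinguishable from) 0 or 1 are
    refused rather than clamped: a fabricated z would silently distort
    instrument strength, so the caller must supply the SE directly.
    """
    if not (0.0 < pval < 1.0):
        raise ValueError(f"p-value {pval} outside the open interval (0, 1)")
    if beta == 0.0:
        raise ValueError("SE is undefined for beta = 0 with p < 1")
    if pval < 1e-300:
        raise ValueError(
            f"p-value {pval} too small to invert reliably; supply the SE directly"
        )
    z = stats.norm.isf(pval / 2.0)
    if not np.isfinite(z) or z <= 0:
        raise ValueError(f"cannot invert p-value {pval}; supply the SE directly")
    return abs(beta) / z


def pval_from_beta_se(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se (the inverse of se_from_pval)."""
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def filter_region(
    records: Sequence[AssociationRecord], region: GenomicRegion
) -> list[AssociationRecord]:
    """Return the records lying OUTSIDE ``region``, preserving order."""
    return [r for r in records if not region.contains(r.chrom, r.pos_bp)]


def records_in_region(
    records: Sequence[AssociationRecord], region: GenomicRegion
) -> list[AssociationRecord]:
    """Complement of :func:`filter_region` (the masked records)."""
    return [r for r in records if region.contains(r.chrom, r.pos_bp)]


def complement_allele(allele: str) -> str:
    if allele not in _VALID_ALLELES:
        raise ValueError(f"invalid allele {allele!r}")
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is a strand-ambiguous pair: {A,T} or {C,G}."""
    if a1 not in _VALID_ALLELES or a2 not in _VALID_ALLELES:
        raise ValueError(f"invalid allele pair ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exp_rec: AssociationRecord,
    out_rec: AssociationRecord,
    drop_palindromic: bool = True,
    ambiguity_maf: float = 0.3,
    try_strand_flip: bool = True,
) -> HarmonizedInstrument | HarmonizationRejection:
    """Align an outcome association to the exposure's effect allele.

    Returns a :class:`HarmonizedInstrument`, or a
    :class:`HarmonizationRejection` when the alleles cannot be reconciled or
    the SNP is palindromic with an ambiguous allele frequency.  Palindromic
    SNPs are rejected (when ``drop_palindromic``) unless the outcome EAF lies
    outside [ambiguity_maf, 1 - ambiguity_maf], in which case frequency can in
    principle orient the strand; missing EAF counts as ambiguous.
    """
    if exp_rec.snp_id != out_rec.snp_id:
        raise ValueError(
            f"snp_id mismatch: {exp_rec.snp_id!r} vs {out_rec.snp_id!r}"
        )
    snp = exp_rec.snp_id
    palindromic = is_palindromic(exp_rec.effect_allele, exp_rec.other_allele)
    if palindromic and drop_palindromic:
        eaf = out_rec.eaf
        if eaf is None or ambiguity_maf <= eaf <= 1.0 - ambiguity_maf:
            return HarmonizationRejection(
                snp, "palindromic SNP with ambiguous allele frequency"
            )

    ea, oa = exp_rec.effect_allele, exp_rec.other_allele
    candidates = [(out_rec.effect_allele, out_rec.other_allele, False)]
    if try_strand_flip and not palindromic:
        candidates.append(
            (
                complement_allele(out_rec.effect_allele),
                complement_allele(out_rec.other_allele),
                False,
            )
        )
    flipped: bool | None = None
    for o_ea, o_oa, _ in candidates:
        if (o_ea, o_oa) == (ea, oa):
            flipped = False
            break
        if (o_ea, o_oa) == (oa, ea):
            flipped = True
            break
    if flipped is None:
        return HarmonizationRejection(
            snp,
            f"unresolvable alleles: exposure {ea}/{oa} vs outcome "
            f"{out_rec.effect_allele}/{out_rec.other_allele}",
        )

    beta_out = -out_rec.beta if flipped else out_rec.beta
    eaf_out = out_rec.eaf
    if flipped and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    exp_rec = exp_rec.with_se()
    out_rec = out_rec.with_se()
    return HarmonizedInstrument(
        snp_id=snp,
        beta_exp=exp_rec.beta,
        se_exp=exp_rec.se,
        beta_out=beta_out,
        se_out=out_rec.se,
        eaf_out=eaf_out,
        flipped=flipped,
    )


def select_instruments(
    records: Sequence[AssociationRecord],
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_max: float = 0.001,
    window_bp: int = 5_000_000,
) -> list[AssociationRecord]:
    """Greedy LD clumping of genome-wide-significant records.

    Records passing ``p_threshold`` are visited in ascending p-value order
    (ties broken by (chrom, pos) for determinism); a record is kept iff its
    r-squared with every previously kept record on the same chromosome within
    +/- ``window_bp`` is <= ``r2_max``.
    """
    if ld is None:
        ld = LDMatrix()
    passing = [r for r in records if r.pval < p_threshold]
    passing.sort(key=lambda r: (r.pval, r.chrom, r.pos_bp))
    kept: list[AssociationRecord] = []
    for rec in passing:
        independent = all(
            not (
                k.chrom == rec.chrom
                and abs(k.pos_bp - rec.pos_bp) <= window_bp
                and ld.r2(k.snp_id, rec.snp_id) > r2_max
            )
            for k in kept
        )
        if independent:
            kept.append(rec)
    return kept


def build_instrument_set(
    exp_records: Sequence[AssociationRecord],
    out_records: Sequence[AssociationRecord],
    exposure_id: str = EXPOSURE_TRAIT,
    outcome_id: str = "",
    drop_palindromic: bool = True,
    ambiguity_maf: float = 0.3,
) -> InstrumentSet:
    """Join selected exposure records with outcome associations by rsID and
    harmonize each pair, recording every drop in provenance."""
    out_by_id = {r.snp_id: r for r in out_records}
    provenance: list[str] = []
    instruments: list[HarmonizedInstrument] = []
    for exp_rec in exp_records:
        out_rec = out_by_id.get(exp_rec.snp_id)
        if out_rec is None:
            provenance.append(f"{exp_rec.snp_id}: no outcome association, dropped")
            continue
        if out_rec.proxy_id:
            provenance.append(f"{exp_rec.snp_id}: outcome uses proxy {out_rec.proxy_id}")
        result = harmonize(
            exp_rec,
            out_rec,
            drop_palindromic=drop_palindromic,
            ambiguity_maf=ambiguity_maf,
        )
        if isinstance(result, HarmonizationRejection):
            provenance.append(f"{result.snp_id}: rejected ({result.reason})")
            continue
        if result.flipped:
            provenance.append(f"{result.snp_id}: outcome alleles flipped to match exposure")
        instruments.append(result)
    outcome_id = outcome_id or (out_records[0].trait_id if out_records else "")
    return InstrumentSet(exposure_id, outcome_id, instruments, provenance)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "snp": "snp",
    "chr": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "eaf": "eaf",
    "trait": "trait",
}
_MANDATORY = ("snp", "chr", "pos", "effect_allele", "other_allele", "beta", "pval")


def read_summary_tsv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[AssociationRecord]:
    """Read summary associations from a tab-separated file.

    ``column_map`` maps the canonical field names (snp, chr, pos,
    effect_allele, other_allele, beta, se, pval, eaf, trait) to the file's
    header names; the default matches the packaged fixture.  rsIDs of the form
    ``rs123 (rs456)`` record ``rs456`` as the pre-matched proxy and keep the
    first rsID.  Malformed rows raise with the 1-based data line number.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _MANDATORY if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    def opt(row, key):
        name = cols.get(key)
        if name is None or name not in df.columns:
            return None
        val = row[name].strip()
        return val or None

    records: list[AssociationRecord] = []
    for line_no, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            m = _SNP_WITH_PROXY.match(row[cols["snp"]])
            if not m:
                raise ValueError(f"unparsable SNP id {row[cols['snp']]!r}")
            snp_id, proxy_id = m.group(1), m.group(2)
            se = opt(row, "se")
            eaf = opt(row, "eaf")
            records.append(
                AssociationRecord(
                    snp_id=snp_id,
                    chrom=int(row[cols["chr"]]),
                    pos_bp=int(row[cols["pos"]].replace(",", "")),
                    effect_allele=row[cols["effect_allele"]].strip().upper(),
                    other_allele=row[cols["other_allele"]].strip().upper(),
                    beta=float(row[cols["beta"]]),
                    pval=float(row[cols["pval"]]),
                    se=float(se) if se else None,
                    eaf=float(eaf) if eaf else None,
                    trait_id=opt(row, "trait") or "",
                    proxy_id=proxy_id,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
    return records


def write_summary_tsv(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write records in the same TSV dialect :func:`read_summary_tsv` reads."""
    rows = []
    for r in records:
        snp = f"{r.snp_id} ({r.proxy_id})" if r.proxy_id else r.snp_id
        rows.append(
            {
                "snp": snp,
                "chr": r.chrom,
                "pos": r.pos_bp,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": repr(r.beta),
                "se": "" if r.se is None else repr(r.se),
                "pval": repr(r.pval),
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "trait": r.trait_id,
            }
        )
    pd.DataFrame(rows, columns=list(_DEFAULT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _data_path(name: str):
    return resources.files("mrkit.data").joinpath(name)


def load_table1() -> dict[str, list[AssociationRecord]]:
    """Load the packaged instrument-level study fixture.

    Returns a mapping from trait label to its association records: the
    exposure (celiac disease, 11 SNPs) plus the eight lymphoma / small bowel
    cancer outcomes (11 SNPs each).
    """
    with resources.as_file(_data_path("table1.tsv")) as p:
        records = read_summary_tsv(p)
    by_trait: dict[str, list[AssociationRecord]] = {}
    for rec in records:
        by_trait.setdefault(rec.trait_id, []).append(rec)
    return by_trait


def load_table2_expected() -> pd.DataFrame:
    """Published study-level results grid, for regression comparisons."""
    with resources.as_file(_data_path("table2_expected.csv")) as p:
        return pd.read_csv(p)
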