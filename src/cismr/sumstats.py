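"""Shared data model, file formats, configuration, and validation.

Conventions
-----------
* Genomic coordinates are 1-based and inclusive throughout; windows are
  closed intervals.
* Summary statistics travel as tab-separated files with a header naming at
  least ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta,
  se, pval`` (a GWAS-catalog-like dialect).  ``beta`` is the additive
  per-effect-allele effect: log-odds for binary traits, SD units for
  continuous traits.
* Floats are serialized with 6 significant digits; missing values are the
  literal ``NA``.
* Duplicate variant keys (same chrom, pos and unordered allele pair) keep
  the first occurrence; later rows are dropped and counted.
* A missing effect-allele frequency is allowed at load time; any
  frequency-based filter downstream treats such a record as failing
  (fail-closed).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
]

VALID_BASES = frozenset("ACGT")

TRAIT_TYPES = ("continuous", "binary")


class SumstatsFormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


def zscore_pvalue(beta: float, se: float) -> float:
    """Two-sided normal p-value for ``beta/se``."""
    if se <= 0 or not math.isfinite(se):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait.

    ``beta`` is per effect-allele copy; ``eaf`` may be NaN when the source
    file did not report a frequency.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float

    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Duplicate-detection key: position plus unordered allele pair."""
        pair = tuple(sorted((self.effect_allele, self.other_allele)))
        return (self.chrom, int(self.pos), pair)  # type: ignore[return-value]

    @property
    def maf(self) -> float:
        """Minor allele frequency; NaN when EAF is missing."""
        if not np.isfinite(self.eaf):
            return float("nan")
        return float(min(self.eaf, 1.0 - self.eaf))

    @property
    def is_snp(self) -> bool:
        """True for single-base substitutions (both alleles length 1)."""
        return len(self.effect_allele) == 1 and len(self.other_allele) == 1

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return (
            self.is_snp
            and comp.get(self.effect_allele) == self.other_allele
        )

    def regenerated_pval(self) -> float:
        return zscore_pvalue(self.beta, self.se)


@dataclass
class LoadReport:
    """Accounting of rows retained and dropped during validation."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def add_drop(self, reason: str, count: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + count


@dataclass
class SummaryStatsTable:
    """Validated GWAS summary statistics for one trait.

    ``records`` is a DataFrame with :data:`SUMSTATS_COLUMNS`; rows are
    unique on (chrom, pos, unordered allele pair).
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def variant(self, variant_id: str) -> VariantAssoc:
        row = self.records.loc[self.records["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return row_to_assoc(row.iloc[0])


def row_to_assoc(row: Mapping) -> VariantAssoc:
    return VariantAssoc(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=float(row["eaf"]) if pd.notna(row["eaf"]) else float("nan"),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
    )


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) >= 1 and set(a) <= VALID_BASES


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Apply row-level invariants, returning the clean table and a report.

    Checks, in order: mandatory fields present and numeric, alleles are
    non-empty A/C/G/T strings and distinct (biallelic), ``pos >= 1``,
    ``se > 0`` finite, ``pval`` in (0, 1], ``eaf`` in (0, 1) when present,
    and uniqueness of the (chrom, pos, allele-pair) key (keep first).
    """
    report = LoadReport(n_input=len(df))
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok_allele = df["effect_allele"].map(_valid_allele) & df["other_allele"].map(
        _valid_allele
    )
    biallelic = ok_allele & (df["effect_allele"] != df["other_allele"])
    ok_pos = df["pos"].notna() & (df["pos"] >= 1) & (df["pos"] % 1 == 0)
    ok_beta = np.isfinite(df["beta"].to_numpy(dtype=float))
    ok_se = np.isfinite(df["se"].to_numpy(dtype=float)) & (df["se"] > 0)
    ok_pval = df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
    # missing EAF is allowed; out-of-range EAF is not
    ok_eaf = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))

    for mask, reason in [
        (~biallelic, "bad_alleles"),
        (~ok_pos, "bad_pos"),
        (~ok_beta, "bad_beta"),
        (~ok_se, "bad_se"),
        (~ok_pval, "bad_pval"),
        (~ok_eaf, "bad_eaf"),
    ]:
        n = int(mask.sum())
        if n:
            report.add_drop(reason, n)
    keep = biallelic & ok_pos & ok_beta & ok_se & ok_pval & ok_eaf
    # a row failing several checks is only retained-or-not once; reasons may
    # overcount multiply-invalid rows, which is acceptable for a load report
    clean = df.loc[keep].copy()
    clean["pos"] = clean["pos"].astype(np.int64)

    pair = [
        tuple(sorted(t))
        for t in zip(clean["effect_allele"], clean["other_allele"])
    ]
    key = pd.MultiIndex.from_arrays(
        [clean["chrom"], clean["pos"], pd.Series(pair, index=clean.index)]
    )
    dup = pd.Series(key.duplicated(keep="first"), index=clean.index)
    n_dup = int(dup.sum())
    if n_dup:
        report.add_drop("duplicate_key", n_dup)
        logger.warning("dropped %d duplicate variant keys (kept first)", n_dup)
        clean = clean.loc[~dup]

    clean = clean[SUMSTATS_COLUMNS].reset_index(drop=True)
    report.n_retained = len(clean)
    return clean, report


def read_sumstats(
    path: str | Path, trait_type: str, trait_id: str | None = None
) -> SummaryStatsTable:
    """Read and validate a summary-statistics TSV.

    Raises :class:`SumstatsFormatError` for an empty file or a missing
    mandatory column; invalid rows are dropped (not fatal) and counted in
    the returned table's :class:`LoadReport`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise SumstatsFormatError(f"empty summary-statistics file: {path}") from exc
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise SumstatsFormatError(
                f"missing mandatory column {col!r} in {path}"
            )
    if df.empty:
        raise SumstatsFormatError(f"no data rows in summary-statistics file: {path}")
    records, report = validate_records(df)
    return SummaryStatsTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        records=records,
        report=report,
    )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, SummaryStatsTable):
        return records.records
    rows = list(records)
    if rows and dataclasses.is_dataclass(rows[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return pd.DataFrame(rows)


def write_results(records, path: str | Path) -> None:
    """Write any result table as TSV with a stable column order.

    Floats carry 6 significant digits and NaN is serialized as ``NA`` so the
    file round-trips through :func:`read_results` bit-identically at that
    precision.  An empty table is an error and nothing is written.
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("refusing to write an empty result table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results` (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})


# ---------------------------------------------------------------------------
# gene annotation


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene/protein annotation with canonicalized transcription bounds.

    ``tss``/``tes`` are stored as min/max genomic coordinates regardless of
    strand, so ``tss <= tes`` always holds.
    """

    gene_id: str
    protein_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = sorted((int(self.tss), int(self.tes)))
        object.__setattr__(self, "tss", lo)
        object.__setattr__(self, "tes", hi)


GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "protein_id", "strand"]


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED-like (but 1-based, closed) gene annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in GENE_COLUMNS:
        if col not in df.columns:
            raise SumstatsFormatError(f"missing mandatory column {col!r} in {path}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            protein_id=str(r.protein_id),
            chrom=str(r.chrom),
            tss=int(r.start),
            tes=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Analysis thresholds and grids.

    Defaults are the study settings: a 5 x 6 multiverse grid of LD r^2 and
    instrument p-value thresholds, a primary analysis at (r^2 = 0.4,
    p = 1e-4), a conventional comparison at (r^2 = 0.05, p = 5e-8), a
    200 kbp cis flank around the transcription unit, a MAF floor of 0.01,
    and a family-wise alpha of 0.05.  ``pval_grid`` entry 1.0 means "no
    p-value filter".
    """

    r2_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.6)
    pval_grid: tuple[float, ...] = (5e-8, 1e-5, 1e-4, 1e-3, 1e-2, 1.0)
    primary_r2: float = 0.4
    primary_pval: float = 1e-4
    conventional_r2: float = 0.05
    conventional_pval: float = 5e-8
    cis_flank_bp: int = 200_000
    maf_min: float = 0.01
    alpha_family: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.r2_grid = tuple(float(x) for x in self.r2_grid)
        self.pval_grid = tuple(float(x) for x in self.pval_grid)
        for name in ("primary_r2", "conventional_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if not all(0 < x <= 1 for x in self.r2_grid):
            raise ValueError("r2_grid entries must be in (0,1]")
        if not all(0 < x <= 1 for x in self.pval_grid):
            raise ValueError("pval_grid entries must be in (0,1]")
        if self.cis_flank_bp < 0:
            raise ValueError("cis_flank_bp must be >= 0")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")

    def selection_grid(self) -> list[tuple[float, float]]:
        """All (r2_threshold, pval_threshold) combinations, row-major."""
        return [(r2, p) for r2 in self.r2_grid for p in self.pval_grid]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["r2_grid"] = list(self.r2_grid)
        data["pval_grid"] = list(self.pval_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
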