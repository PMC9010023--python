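"""cis-window definition, variant filtering, harmonization, LD estimation,
and greedy p-value clumping for instrument selection.

The cis window is the transcription unit plus a symmetric flank (200 kbp by
default), clamped at position 1.  Candidate instruments are biallelic SNPs
present in both the exposure and outcome summary statistics, inside the
window, with exposure-table MAF strictly above the floor.  Clumping follows
the PLINK greedy definition: take the smallest-p remaining variant as an
index, discard remaining variants whose r^2 with it exceeds the threshold,
repeat.  p-value ties break by genomic position, then allele string, so
selection is fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypePanel
from .sumstats import (
    GeneAnnotation,
    PipelineConfig,
    SummaryStatsTable,
    VariantAssoc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CisWindow",
    "LDMatrix",
    "InstrumentSet",
    "HarmonizedCandidates",
    "MonomorphicVariantError",
    "define_cis_window",
    "filter_variants",
    "harmonize",
    "estimate_ld",
    "clump",
    "build_candidates",
]


class MonomorphicVariantError(ValueError):
    """LD is undefined for a variant with zero dosage variance."""


@dataclass(frozen=True)
class CisWindow:
    gene_id: str
    chrom: str
    start: int
    end: int

    def contains(self, pos) -> np.ndarray:
        pos = np.asarray(pos)
        return (pos >= self.start) & (pos <= self.end)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def define_cis_window(gene: GeneAnnotation, flank: int) -> CisWindow:
    """Closed interval [tss - flank, tes + flank], clamped at base 1."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return CisWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=max(1, gene.tss - flank),
        end=gene.tes + flank,
    )


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) among an ordered variant set."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("r must be square and match variant_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("LD matrix must have unit diagonal")
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)

    @property
    def r2(self) -> np.ndarray:
        return self.r * self.r

    def index(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids)
        df.to_csv(path, sep="\t", index_label="variant_id", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def estimate_ld(panel: GenotypePanel, variants: Sequence[str]) -> LDMatrix:
    """Signed Pearson correlation of reference-panel dosage columns."""
    ids = panel.variant_ids()
    lookup = {v: i for i, v in enumerate(ids)}
    missing = [v for v in variants if v not in lookup]
    if missing:
        raise KeyError(f"variants not in panel: {missing[:5]}")
    cols = [lookup[v] for v in variants]
    g = panel.dosages[:, cols].astype(float)
    sd = g.std(axis=0)
    for v, s in zip(variants, sd):
        if s == 0:
            raise MonomorphicVariantError(
                f"variant {v} is monomorphic in the reference panel"
            )
    r = np.corrcoef(g, rowvar=False)
    if r.ndim == 0:  # single variant
        r = np.array([[1.0]])
    return LDMatrix(list(variants), r)


def filter_variants(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    window: CisWindow,
    maf_min: float,
) -> pd.DataFrame:
    """Candidate variants: in both tables, inside the window, biallelic
    SNPs, exposure MAF strictly above ``maf_min``.

    Returns the merged exposure/outcome rows (suffixes ``_x``/``_y``); the
    allele-level reconciliation is left to :func:`harmonize`.  A missing
    exposure EAF fails the MAF filter (fail-closed).
    """
    ex = exposure.records
    ex = ex[(ex["chrom"] == window.chrom) & window.contains(ex["pos"].to_numpy())]
    snp = (ex["effect_allele"].str.len() == 1) & (ex["other_allele"].str.len() == 1)
    ex = ex[snp]
    maf = np.minimum(ex["eaf"], 1.0 - ex["eaf"])
    ex = ex[maf.notna() & (maf > maf_min)]

    out = outcome.records[outcome.records["chrom"] == window.chrom]
    snp_y = (out["effect_allele"].str.len() == 1) & (
        out["other_allele"].str.len() == 1
    )
    out = out[snp_y]
    merged = ex.merge(
        out, on=["chrom", "pos"], suffixes=("_x", "_y"), how="inner"
    )
    if merged.empty:
        warnings.warn(
            f"no candidate variants for {window.gene_id} "
            f"({window.chrom}:{window.start}-{window.end})",
            stacklevel=2,
        )
    return merged.reset_index(drop=True)


def harmonize(
    exposure_rec: VariantAssoc, outcome_rec: VariantAssoc
) -> tuple[VariantAssoc, VariantAssoc] | str:
    """Align one exposure/outcome record pair on the exposure effect allele.

    Returns the aligned pair, or a drop-reason string.  Identical allele
    pairs pass through; swapped pairs flip the outcome beta's sign and
    complement its EAF; any other allele combination is dropped.
    Palindromic variants are treated by allele labels only (callers wanting
    the conservative behaviour filter them out beforehand).
    """
    if (exposure_rec.chrom, exposure_rec.pos) != (outcome_rec.chrom, outcome_rec.pos):
        return "position_mismatch"
    ex_pair = (exposure_rec.effect_allele, exposure_rec.other_allele)
    out_pair = (outcome_rec.effect_allele, outcome_rec.other_allele)
    if ex_pair == out_pair:
        return exposure_rec, outcome_rec
    if ex_pair == out_pair[::-1]:
        flipped = VariantAssoc(
            variant_id=outcome_rec.variant_id,
            chrom=outcome_rec.chrom,
            pos=outcome_rec.pos,
            effect_allele=outcome_rec.other_allele,
            other_allele=outcome_rec.effect_allele,
            eaf=1.0 - outcome_rec.eaf,
            beta=-outcome_rec.beta,
            se=outcome_rec.se,
            pval=outcome_rec.pval,
        )
        return exposure_rec, flipped
    return "allele_mismatch"


@dataclass
class HarmonizedCandidates:
    """All harmonized candidate instruments of one protein, with their LD.

    ``table`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    eaf, beta_x, se_x, pval_x, beta_y, se_y, pval_y (outcome aligned to the
    exposure effect allele).
    """

    protein_id: str
    table: pd.DataFrame
    ld: LDMatrix
    drop_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return len(self.table)


@dataclass
class InstrumentSet:
    """Clumped, harmonized instruments of one protein at one grid setting."""

    protein_id: str
    variants: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    pval_x: np.ndarray
    ld: LDMatrix
    r2_threshold: float
    pval_threshold: float

    @property
    def J(self) -> int:
        return len(self.variants)


def _harmonize_table(merged: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized allele reconciliation over a merged candidate table."""
    same = (merged["effect_allele_x"] == merged["effect_allele_y"]) & (
        merged["other_allele_x"] == merged["other_allele_y"]
    )
    swapped = (merged["effect_allele_x"] == merged["other_allele_y"]) & (
        merged["other_allele_x"] == merged["effect_allele_y"]
    )
    drop_log = {"allele_mismatch": int((~same & ~swapped).sum())}
    kept = merged[same | swapped].copy()
    sign = np.where(same[same | swapped], 1.0, -1.0)
    out = pd.DataFrame(
        {
            "variant_id": kept["variant_id_x"],
            "chrom": kept["chrom"],
            "pos": kept["pos"],
            "effect_allele": kept["effect_allele_x"],
            "other_allele": kept["other_allele_x"],
            "eaf": kept["eaf_x"],
            "beta_x": kept["beta_x"],
            "se_x": kept["se_x"],
            "pval_x": kept["pval_x"],
            "beta_y": kept["beta_y"] * sign,
            "se_y": kept["se_y"],
            "pval_y": kept["pval_y"],
        }
    )
    n_bad = int((~np.isfinite(out["se_y"]) | ~np.isfinite(out["beta_y"])).sum())
    if n_bad:
        drop_log["missing_outcome_stats"] = n_bad
        out = out[np.isfinite(out["se_y"]) & np.isfinite(out["beta_y"])]
    return out.reset_index(drop=True), drop_log


def build_candidates(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    gene: GeneAnnotation,
    panel: GenotypePanel,
    config: PipelineConfig,
    drop_palindromic: bool = False,
) -> HarmonizedCandidates:
    """Window, filter, harmonize, and attach reference-panel LD.

    The one-stop preparation step ahead of clumping: returns every
    candidate instrument of the protein with exposure/outcome effects on a
    common effect allele and the signed LD among them.
    """
    window = define_cis_window(gene, config.cis_flank_bp)
    merged = filter_variants(exposure, outcome, window, config.maf_min)
    if merged.empty:
        empty = pd.DataFrame(
            columns=[
                "variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "eaf", "beta_x", "se_x", "pval_x", "beta_y", "se_y", "pval_y",
            ]
        )
        return HarmonizedCandidates(
            protein_id=gene.protein_id,
            table=empty,
            ld=LDMatrix([], np.zeros((0, 0))),
            drop_log={"no_candidates": 1},
        )
    table, drop_log = _harmonize_table(merged)
    if drop_palindromic:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pal = table.apply(
            lambda r: comp.get(r["effect_allele"]) == r["other_allele"], axis=1
        )
        drop_log["palindromic"] = int(pal.sum())
        table = table[~pal].reset_index(drop=True)
    ld = (
        estimate_ld(panel, list(table["variant_id"]))
        if len(table)
        else LDMatrix([], np.zeros((0, 0)))
    )
    return HarmonizedCandidates(
        protein_id=gene.protein_id, table=table, ld=ld, drop_log=drop_log
    )


def clump(
    candidates: HarmonizedCandidates,
    r2_threshold: float,
    pval_threshold: float,
) -> InstrumentSet:
    """Greedy PLINK-style clumping of the candidate table.

    Variants with exposure p-value above ``pval_threshold`` are dropped
    first (a threshold of 1.0 keeps all).  The smallest-p remaining variant
    becomes an index; remaining variants with r^2 strictly above
    ``r2_threshold`` to the index are removed; repeat until exhausted.
    Ties on p break by position, then allele string.  The retained set is
    returned sorted by exposure p-value ascending; it may be empty.
    """
    df = candidates.table
    df = df[df["pval_x"] <= pval_threshold]
    if df.empty:
        warnings.warn(
            f"no instruments for {candidates.protein_id} at "
            f"p<={pval_threshold:g}",
            stacklevel=2,
        )
        return InstrumentSet(
            protein_id=candidates.protein_id,
            variants=[],
            beta_x=np.array([]),
            se_x=np.array([]),
            beta_y=np.array([]),
            se_y=np.array([]),
            pval_x=np.array([]),
            ld=LDMatrix([], np.zeros((0, 0))),
            r2_threshold=r2_threshold,
            pval_threshold=pval_threshold,
        )
    order = df.sort_values(
        ["pval_x", "pos", "effect_allele", "other_allele"], kind="mergesort"
    )
    r2 = candidates.ld.r2
    pos_of = {v: i for i, v in enumerate(candidates.ld.variant_ids)}
    remaining = list(order["variant_id"])
    retained: list[str] = []
    while remaining:
        index_variant = remaining.pop(0)
        retained.append(index_variant)
        i = pos_of[index_variant]
        remaining = [
            v for v in remaining if not (r2[i, pos_of[v]] > r2_threshold)
        ]
    sel = order[order["variant_id"].isin(retained)]
    return InstrumentSet(
        protein_id=candidates.protein_id,
        variants=list(sel["variant_id"]),
        beta_x=sel["beta_x"].to_numpy(dtype=float),
        se_x=sel["se_x"].to_numpy(dtype=float),
        beta_y=sel["beta_y"].to_numpy(dtype=float),
        se_y=sel["se_y"].to_numpy(dtype=float),
        pval_x=sel["pval_x"].to_numpy(dtype=float),
        ld=candidates.ld.subset(list(sel["variant_id"])),
        r2_threshold=r2_threshold,
        pval_threshold=pval_threshold,
    )
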