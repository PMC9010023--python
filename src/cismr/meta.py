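"""Fixed-effect meta-analysis of study-level protein-disease associations.

Study estimates are log risk ratios per 1 SD of standardized protein level
(hazard and odds ratios from the contributing studies are pooled as a
common log RR under the rare-outcome equivalence, without conversion).
Heterogeneity is assessed with Cochran's Q; family-wise error is
controlled by Bonferroni correction over the number of proteins tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import zscore_pvalue

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "fixed_effect_meta",
    "meta_analyze_all",
    "bonferroni_threshold",
    "bonferroni_screen",
    "summarize_effect_distribution",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One study's association of one protein with incident disease."""

    protein_id: str
    study_id: str
    log_rr: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"se must be a positive finite number, got {self.se}")


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity diagnostics.

    For a single-study protein the heterogeneity test is undefined:
    ``q_stat = 0``, ``q_df = 0`` and ``p_het`` is reported as 1 with the
    ``het_undefined`` flag set, keeping the protein in the pipeline.
    """

    protein_id: str
    pooled_log_rr: float
    pooled_se: float
    pval: float
    q_stat: float
    q_df: int
    p_het: float
    n_studies: int
    het_undefined: bool = False
    passes_bonferroni: bool = False

    @property
    def rr(self) -> float:
        return math.exp(self.pooled_log_rr)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (
            math.exp(self.pooled_log_rr - z * self.pooled_se),
            math.exp(self.pooled_log_rr + z * self.pooled_se),
        )


def fixed_effect_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooling of one protein.

    pooled = sum(w_i theta_i) / sum(w_i) with w_i = 1/se_i^2;
    pooled SE = 1/sqrt(sum w_i); Q = sum w_i (theta_i - pooled)^2 compared
    to chi-square with k-1 degrees of freedom.
    """
    if not estimates:
        raise ValueError("need at least one study estimate")
    proteins = {e.protein_id for e in estimates}
    if len(proteins) != 1:
        raise ValueError(f"mixed protein ids in one meta-analysis: {sorted(proteins)}")
    protein_id = estimates[0].protein_id

    theta = np.array([e.log_rr for e in estimates], dtype=float)
    w = np.array([1.0 / e.se**2 for e in estimates], dtype=float)
    pooled = float(w @ theta / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    pval = zscore_pvalue(pooled, pooled_se)

    k = len(estimates)
    q = float(w @ (theta - pooled) ** 2)
    if k == 1:
        return MetaResult(
            protein_id=protein_id,
            pooled_log_rr=pooled,
            pooled_se=pooled_se,
            pval=pval,
            q_stat=0.0,
            q_df=0,
            p_het=1.0,
            n_studies=1,
            het_undefined=True,
        )
    p_het = float(stats.chi2.sf(q, df=k - 1))
    return MetaResult(
        protein_id=protein_id,
        pooled_log_rr=pooled,
        pooled_se=pooled_se,
        pval=pval,
        q_stat=q,
        q_df=k - 1,
        p_het=p_het,
        n_studies=k,
    )


def meta_analyze_all(estimates: Iterable[StudyEstimate]) -> list[MetaResult]:
    """Group study estimates by protein and pool each group."""
    groups: dict[str, list[StudyEstimate]] = {}
    for e in estimates:
        groups.setdefault(e.protein_id, []).append(e)
    return [fixed_effect_meta(v) for v in groups.values()]


def _round_one_sig(x: float) -> float:
    """Round to one significant figure (display convention for thresholds)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """Exact and display-rounded Bonferroni threshold alpha / n_tests.

    The rounded value follows the convention of reporting thresholds to one
    significant figure (0.05/90 -> 6e-4; 0.05/56 -> 9e-4 i.e. 0.0009).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    return exact, _round_one_sig(exact)


def bonferroni_screen(
    results: Sequence[MetaResult], alpha: float, n_tests: int
) -> list[MetaResult]:
    """Flag results passing the family-wise threshold (strict ``<``)."""
    exact, _ = bonferroni_threshold(alpha, n_tests)
    return [replace(r, passes_bonferroni=bool(r.pval < exact)) for r in results]


def summarize_effect_distribution(
    results: Sequence[MetaResult],
) -> tuple[float, tuple[float, float]]:
    """Median risk ratio and IQR over a set of pooled results.

    Quantiles use linear interpolation between order statistics.
    """
    if not results:
        raise ValueError("need at least one result to summarize")
    rrs = np.array([r.rr for r in results], dtype=float)
    q1, med, q3 = np.percentile(rrs, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def results_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    """Tabulate meta-analysis results for writing with ``write_results``."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "pooled_log_rr": r.pooled_log_rr,
                "pooled_se": r.pooled_se,
                "rr": r.rr,
                "pval": r.pval,
                "q_stat": r.q_stat,
                "q_df": r.q_df,
                "p_het": r.p_het,
                "n_studies": r.n_studies,
                "passes_bonferroni": r.passes_bonferroni,
            }
            for r in results
        ]
    )
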