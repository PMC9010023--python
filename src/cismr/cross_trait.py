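"""Cross-trait MR for prioritized proteins: effects on auxiliary traits,
Z-score conversion, and family-wise Bonferroni control.

Each protein-trait pair is analysed with the primary instrument-selection
strategy and MR model; instrument selection is re-run against each trait's
summary statistics (availability differs by trait).  Effect estimates are
converted to Z scores (log OR, or SD-unit beta for continuous traits,
divided by SE) for comparison across pairs; significance is judged against
alpha / (n_proteins x n_traits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import InapplicableModelError
from .instruments import build_candidates
from .meta import bonferroni_threshold
from .multiverse import _setting_estimate
from .simulate import GenotypePanel
from .sumstats import GeneAnnotation, PipelineConfig, SummaryStatsTable

logger = logging.getLogger(__name__)

__all__ = ["CrossTraitResult", "cross_trait_mr", "render_effect_matrix"]


@dataclass
class CrossTraitResult:
    """Primary-model MR estimate of one protein on one auxiliary trait."""

    protein_id: str
    trait_id: str
    theta: float
    se: float
    z: float
    pval: float
    significant: bool
    n_instruments: int = 0
    estimable: bool = True


def cross_trait_mr(
    exposures: Mapping[str, tuple[SummaryStatsTable, GeneAnnotation]],
    trait_tables: Mapping[str, SummaryStatsTable],
    panel: GenotypePanel,
    config: PipelineConfig,
) -> list[CrossTraitResult]:
    """Primary-setting MR of every protein against every trait.

    ``exposures`` maps protein id to (exposure summary stats, gene
    annotation); ``panel`` supplies the LD reference.  Pairs where the
    trait lacks cis coverage are reported as not estimable with missing
    effect and Z.  Significance threshold: alpha / (n_proteins * n_traits).
    """
    n_pairs = len(exposures) * len(trait_tables)
    if n_pairs == 0:
        raise ValueError("need at least one protein and one trait")
    exact, _ = bonferroni_threshold(config.alpha_family, n_pairs)
    results: list[CrossTraitResult] = []
    for pid, (exp_table, gene) in exposures.items():
        for tid, trait_table in trait_tables.items():
            cand = build_candidates(exp_table, trait_table, gene, panel, config)
            est = None
            if cand.n_candidates:
                try:
                    est = _setting_estimate(
                        cand, config.primary_r2, config.primary_pval
                    )
                except InapplicableModelError:
                    est = None
            if est is None:
                results.append(
                    CrossTraitResult(
                        protein_id=pid,
                        trait_id=tid,
                        theta=float("nan"),
                        se=float("nan"),
                        z=float("nan"),
                        pval=float("nan"),
                        significant=False,
                        n_instruments=0,
                        estimable=False,
                    )
                )
                continue
            z = est.theta / est.se
            results.append(
                CrossTraitResult(
                    protein_id=pid,
                    trait_id=tid,
                    theta=est.theta,
                    se=est.se,
                    z=z,
                    pval=est.pval,
                    significant=bool(est.pval < exact),
                    n_instruments=est.n_instruments,
                )
            )
    return results


def render_effect_matrix(results: Sequence[CrossTraitResult]) -> pd.DataFrame:
    """Long-format protein x trait table for bullet-matrix plotting.

    One row per pair with |Z| (bullet size), direction (color) and
    significance (shade); not-estimable pairs carry missing Z.
    """
    if not results:
        raise ValueError("no results to render")
    rows = []
    for r in results:
        if r.estimable and np.isfinite(r.z):
            direction = "risk" if r.z > 0 else "protective"
        else:
            direction = None
        rows.append(
            {
                "protein_id": r.protein_id,
                "trait_id": r.trait_id,
                "z": r.z,
                "abs_z": abs(r.z) if np.isfinite(r.z) else float("nan"),
                "direction": direction,
                "significant": r.significant,
                "estimable": r.estimable,
            }
        )
    return pd.DataFrame(rows)
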