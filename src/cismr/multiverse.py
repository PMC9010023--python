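"""Multiverse sensitivity analysis: the full instrument-selection x model
grid per protein, Tukey outlier trimming, and sign-concordance robustness.

For each of the 30 (LD r^2, p-value) selection settings, every applicable
model is evaluated: up to 120 model-parameter combinations per protein.
Point estimates lying outside 1.5 x IQR beyond the quartiles of the
protein's pooled estimate distribution are flagged as outliers and
excluded before the robustness verdict: an association is robust when all
retained estimates share the sign of the primary-analysis estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    InapplicableModelError,
    MREstimate,
    applicable_models,
    estimate_auto,
    run_model,
)
from .instruments import HarmonizedCandidates, clump
from .meta import bonferroni_threshold
from .sumstats import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MultiverseCell",
    "MultiverseSummary",
    "run_grid",
    "remove_outliers",
    "classify_robustness",
    "run_multiverse",
    "mr_screen",
    "cells_frame",
]

SIGN_TOL = 1e-12


@dataclass
class MultiverseCell:
    """One (selection setting, model) evaluation for one protein."""

    protein_id: str
    r2_threshold: float
    pval_threshold: float
    model: str | None
    n_selected: int
    estimate: MREstimate | None = None
    failure: str | None = None
    outlier: bool = False

    @property
    def ok(self) -> bool:
        return self.estimate is not None


@dataclass
class MultiverseSummary:
    """Per-protein digest of the grid: counts, spread, and the verdict."""

    protein_id: str
    n_cells_attempted: int
    n_estimates: int
    n_outliers_removed: int
    median_theta: float
    primary: MREstimate
    conventional: MREstimate | None
    robust: bool | None


def run_grid(
    candidates: HarmonizedCandidates, config: PipelineConfig
) -> list[MultiverseCell]:
    """Evaluate every applicable model at every selection setting.

    Selection failures (no instruments at a setting) and estimation
    failures (e.g. singular LD) become cells carrying the failure reason,
    never exceptions; the grid is deterministic given its inputs.
    """
    cells: list[MultiverseCell] = []
    for r2_t, p_t in config.selection_grid():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inst = clump(candidates, r2_t, p_t)
        if inst.J == 0:
            cells.append(
                MultiverseCell(
                    protein_id=candidates.protein_id,
                    r2_threshold=r2_t,
                    pval_threshold=p_t,
                    model=None,
                    n_selected=0,
                    failure="no_instruments",
                )
            )
            continue
        for model in applicable_models(inst.J):
            cell = MultiverseCell(
                protein_id=candidates.protein_id,
                r2_threshold=r2_t,
                pval_threshold=p_t,
                model=model,
                n_selected=inst.J,
            )
            try:
                cell.estimate = run_model(inst, model)
            except (np.linalg.LinAlgError, InapplicableModelError, ValueError) as exc:
                cell.failure = f"{type(exc).__name__}: {exc}"
            cells.append(cell)
    return cells


def remove_outliers(cells: Sequence[MultiverseCell]) -> list[MultiverseCell]:
    """Flag estimates outside the Tukey fences of the protein's pooled
    theta distribution (Q1 - 1.5 IQR, Q3 + 1.5 IQR; linear-interpolation
    quartiles).  Failed cells contribute nothing to the fences.
    """
    estimates = [c for c in cells if c.ok]
    if not estimates:
        return list(cells)
    thetas = np.array([c.estimate.theta for c in estimates])
    q1, q3 = np.percentile(thetas, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    for c in cells:
        c.outlier = bool(c.ok and not (lo <= c.estimate.theta <= hi))
    return list(cells)


def _sign_concordant(theta: float, reference_sign: float) -> bool:
    if abs(theta) < SIGN_TOL:
        return True
    return np.sign(theta) == reference_sign


def classify_robustness(
    cells: Sequence[MultiverseCell],
    primary: MREstimate,
    conventional: MREstimate | None = None,
) -> MultiverseSummary:
    """Sign-concordance verdict over the outlier-trimmed grid.

    Robust iff every retained (non-outlier, successfully estimated) theta
    has the same sign as the primary estimate.  Near-zero estimates
    (|theta| < 1e-12) are treated as concordant with either sign.  With no
    retained cells the verdict is undefined (None).
    """
    attempted = [c for c in cells if c.model is not None]
    estimates = [c for c in attempted if c.ok]
    retained = [c for c in estimates if not c.outlier]
    n_outliers = sum(1 for c in estimates if c.outlier)
    if not retained:
        logger.warning(
            "robustness undefined for %s: no retained estimates", primary.protein_id
        )
        return MultiverseSummary(
            protein_id=primary.protein_id,
            n_cells_attempted=len(attempted),
            n_estimates=len(estimates),
            n_outliers_removed=n_outliers,
            median_theta=float("nan"),
            primary=primary,
            conventional=conventional,
            robust=None,
        )
    ref_sign = np.sign(primary.theta) if abs(primary.theta) >= SIGN_TOL else 0.0
    if ref_sign == 0.0:
        robust = True  # primary itself is numerically zero: any sign concords
    else:
        robust = all(
            _sign_concordant(c.estimate.theta, ref_sign) for c in retained
        )
    median_theta = float(np.median([c.estimate.theta for c in retained]))
    return MultiverseSummary(
        protein_id=primary.protein_id,
        n_cells_attempted=len(attempted),
        n_estimates=len(estimates),
        n_outliers_removed=n_outliers,
        median_theta=median_theta,
        primary=primary,
        conventional=conventional,
        robust=robust,
    )


def _setting_estimate(
    candidates: HarmonizedCandidates, r2_t: float, p_t: float
) -> MREstimate | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inst = clump(candidates, r2_t, p_t)
    if inst.J == 0:
        return None
    try:
        return estimate_auto(inst)
    except (np.linalg.LinAlgError, InapplicableModelError):
        return None


def run_multiverse(
    candidates: HarmonizedCandidates, config: PipelineConfig
) -> tuple[MultiverseSummary, list[MultiverseCell]]:
    """Full per-protein sensitivity analysis.

    Runs the grid, trims outliers, computes the primary (r^2 = 0.4,
    p = 1e-4 by default) and conventional (r^2 = 0.05, p = 5e-8) estimates,
    and classifies robustness.
    """
    primary = _setting_estimate(candidates, config.primary_r2, config.primary_pval)
    if primary is None:
        raise InapplicableModelError(
            f"no primary-setting instruments for {candidates.protein_id}"
        )
    conventional = _setting_estimate(
        candidates, config.conventional_r2, config.conventional_pval
    )
    cells = remove_outliers(run_grid(candidates, config))
    return classify_robustness(cells, primary, conventional), cells


def mr_screen(
    protein_candidates: Mapping[str, HarmonizedCandidates],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Primary MR estimate per protein with Bonferroni screening.

    The family size is the number of screened proteins with at least one
    primary-setting instrument; proteins with none are reported but
    excluded from the family and the flag.
    """
    rows = []
    for pid, cand in protein_candidates.items():
        est = _setting_estimate(cand, config.primary_r2, config.primary_pval)
        rows.append(
            {
                "protein_id": pid,
                "theta": est.theta if est else float("nan"),
                "se": est.se if est else float("nan"),
                "pval": est.pval if est else float("nan"),
                "model": est.model if est else None,
                "n_instruments": est.n_instruments if est else 0,
                "has_instruments": est is not None,
            }
        )
    df = pd.DataFrame(rows)
    n_family = int(df["has_instruments"].sum())
    if n_family:
        exact, _ = bonferroni_threshold(config.alpha_family, n_family)
    else:
        exact = float("nan")
    df["n_family"] = n_family
    df["threshold"] = exact
    df["passes_bonferroni"] = df["has_instruments"] & (df["pval"] < exact)
    return df


def cells_frame(cells: Sequence[MultiverseCell]) -> pd.DataFrame:
    """Long-format per-cell table (violin-plot-ready)."""
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "r2_threshold": c.r2_threshold,
                "pval_threshold": c.pval_threshold,
                "model": c.model,
                "n_selected": c.n_selected,
                "theta": c.estimate.theta if c.ok else float("nan"),
                "se": c.estimate.se if c.ok else float("nan"),
                "pval": c.estimate.pval if c.ok else float("nan"),
                "outlier": c.outlier,
                "failure": c.failure,
            }
            for c in cells
        ]
    )
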