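"""Mendelian randomization point estimators for correlated cis instruments.

Four estimator families operate on a harmonized
:class:`~cismr.instruments.InstrumentSet`:

* Wald ratio (single instrument): theta = beta_Y / beta_X with a
  first-order delta-method SE (outcome SE only).
* Correlation-aware IVW: generalized weighted least squares of beta_Y on
  beta_X through the origin, with weight matrix
  Omega = (se_Y se_Y^T) o r built from the instrument LD correlation r.
* Correlation-aware Egger: the same GLS with a free intercept capturing
  directional pleiotropy, after orienting instruments to beta_X >= 0.
* PCA-MR: the IVW formula in the space of leading principal components of
  a weighted instrument matrix, for near-collinear instrument sets.

SEs follow a fixed-effect model for 3 or fewer instruments and a
multiplicative random-effects model (overdispersion factor floored at 1)
otherwise; for the PCA models the rule is applied to the number of
retained components.  p-values are two-sided normal throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .instruments import InstrumentSet
from .sumstats import zscore_pvalue

__all__ = [
    "MREstimate",
    "DegenerateInstrumentError",
    "InapplicableModelError",
    "SingularLDError",
    "CollinearDesignError",
    "wald_ratio",
    "ivw_correlated",
    "egger_correlated",
    "pca_mr",
    "applicable_models",
    "estimate_auto",
]

CONDITION_CAP = 1e10
RIDGE_EPS = 1e-8


class DegenerateInstrumentError(ValueError):
    """Wald ratio with a zero exposure effect."""


class InapplicableModelError(ValueError):
    """Model requested with fewer instruments than it supports."""


class SingularLDError(np.linalg.LinAlgError):
    """Weight matrix numerically singular even after ridge conditioning."""


class CollinearDesignError(np.linalg.LinAlgError):
    """Egger design with no variation in the exposure effects."""


@dataclass
class MREstimate:
    """A causal-effect estimate (log OR per 1 SD / per doubling of protein)."""

    protein_id: str
    model: str
    theta: float
    se: float
    pval: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    re_scaling: float = 1.0

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.theta - z * self.se, self.theta + z * self.se


def wald_ratio(
    bx: float,
    sx: float,
    by: float,
    sy: float,
    protein_id: str = "",
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate theta = by/bx.

    The default SE is the first-order delta method, sy/|bx| (outcome
    uncertainty only); ``second_order=True`` adds the exposure-uncertainty
    term sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise DegenerateInstrumentError("exposure effect is exactly zero")
    theta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return MREstimate(
        protein_id=protein_id,
        model="wald",
        theta=theta,
        se=se,
        pval=zscore_pvalue(theta, se),
        n_instruments=1,
    )


def _weight_matrix(se_y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Omega = (se_y se_y^T) o r, ridge-conditioned once if ill-conditioned."""
    omega = np.outer(se_y, se_y) * r
    cond = np.linalg.cond(omega)
    if cond > CONDITION_CAP:
        omega = omega + RIDGE_EPS * np.diag(np.diag(omega))
        cond = np.linalg.cond(omega)
        if cond > CONDITION_CAP:
            off = np.abs(r - np.eye(len(r)))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise SingularLDError(
                f"LD weight matrix singular after ridge; worst pair "
                f"({i}, {j}) with |r| = {abs(r[i, j]):.6f}"
            )
    return omega


def _solve(omega: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(omega)
        return linalg.cho_solve((c, low), b)
    except np.linalg.LinAlgError:
        return linalg.solve(omega, b, assume_a="sym")


def _ivw_core(
    bx: np.ndarray,
    by: np.ndarray,
    omega: np.ndarray,
    random_effects: bool,
    df: int,
) -> tuple[float, float, float]:
    """GLS through the origin; returns (theta, se, phi)."""
    w_bx = _solve(omega, bx)
    denom = float(bx @ w_bx)
    if denom <= 0:
        raise SingularLDError("non-positive precision in IVW weighting")
    theta = float(w_bx @ by) / denom
    se = 1.0 / math.sqrt(denom)
    phi = 1.0
    if random_effects and df > 0:
        resid = by - theta * bx
        q = float(resid @ _solve(omega, resid))
        phi = max(1.0, math.sqrt(q / df))
        se *= phi
    return theta, se, phi


def ivw_correlated(
    inst: InstrumentSet, effects: str = "auto"
) -> MREstimate:
    """Correlation-aware inverse-variance-weighted estimate.

    ``effects``: "auto" applies the fixed-effect model for J <= 3 and the
    multiplicative random-effects model otherwise; "fixed" or "random"
    force the choice (the random-effects scaling is floored at 1 and
    requires J >= 2).
    """
    J = inst.J
    if J < 1:
        raise InapplicableModelError("IVW needs at least one instrument")
    if effects not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown effects mode {effects!r}")
    omega = _weight_matrix(inst.se_y, inst.ld.r)
    random = (effects == "random") or (effects == "auto" and J > 3)
    theta, se, phi = _ivw_core(inst.beta_x, inst.beta_y, omega, random, J - 1)
    return MREstimate(
        protein_id=inst.protein_id,
        model="ivw",
        theta=theta,
        se=se,
        pval=zscore_pvalue(theta, se),
        n_instruments=J,
        re_scaling=phi,
    )


def egger_correlated(inst: InstrumentSet, effects: str = "auto") -> MREstimate:
    """Correlation-aware Egger regression: slope = effect, intercept =
    average directional pleiotropy.

    Instruments are oriented so every exposure effect is non-negative
    (the coded allele is relabelled: both betas change sign and the signed
    LD r is conjugated accordingly).  Requires J >= 3.
    """
    J = inst.J
    if J < 3:
        raise InapplicableModelError(f"Egger regression needs J >= 3, got {J}")
    sign = np.where(inst.beta_x < 0, -1.0, 1.0)
    bx = inst.beta_x * sign
    by = inst.beta_y * sign
    r = inst.ld.r * np.outer(sign, sign)
    if np.ptp(bx) < 1e-14 * max(1.0, np.abs(bx).max()):
        raise CollinearDesignError("all exposure effects equal after orientation")
    omega = _weight_matrix(inst.se_y, r)
    X = np.column_stack([np.ones(J), bx])
    wX = np.column_stack([_solve(omega, X[:, 0]), _solve(omega, X[:, 1])])
    xtwx = X.T @ wX
    try:
        coef = linalg.solve(xtwx, wX.T @ by, assume_a="sym")
        cov = linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise CollinearDesignError(str(exc)) from exc
    intercept, theta = float(coef[0]), float(coef[1])
    phi = 1.0
    random = (effects == "random") or (effects == "auto" and J > 3)
    if random and J > 2:
        resid = by - X @ coef
        q = float(resid @ _solve(omega, resid))
        phi = max(1.0, math.sqrt(q / (J - 2)))
    se = math.sqrt(cov[1, 1]) * phi
    int_se = math.sqrt(cov[0, 0]) * phi
    return MREstimate(
        protein_id=inst.protein_id,
        model="egger",
        theta=theta,
        se=se,
        pval=zscore_pvalue(theta, se),
        n_instruments=J,
        egger_intercept=intercept,
        egger_intercept_se=int_se,
        egger_intercept_pval=zscore_pvalue(intercept, int_se),
        re_scaling=phi,
    )


def pca_mr(inst: InstrumentSet, var_explained: float) -> MREstimate:
    """IVW on principal components of the weighted instrument matrix.

    Psi_ij = (beta_Xi beta_Xj / (se_Yi se_Yj)) r_ij is eigendecomposed;
    the smallest k components whose cumulative eigenvalue share reaches
    ``var_explained`` define the projection W; the IVW formula is applied
    to W^T beta_X, W^T beta_Y with weight W^T Omega W.  The fixed/random
    SE rule is applied to k.
    """
    J = inst.J
    if J < 2:
        raise InapplicableModelError(f"PCA-MR needs J >= 2, got {J}")
    if not 0 < var_explained <= 1:
        raise ValueError("var_explained must be in (0, 1]")
    w = inst.beta_x / inst.se_y
    psi = np.outer(w, w) * inst.ld.r
    vals, vecs = np.linalg.eigh(psi)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    total = vals.sum()
    if total <= 0:
        raise InapplicableModelError("zero exposure signal: Psi has no spectrum")
    if vals.min() < -1e-8 * vals.max():
        raise np.linalg.LinAlgError(
            "weighted instrument matrix not positive semidefinite"
        )
    shares = np.cumsum(np.clip(vals, 0.0, None)) / np.clip(vals, 0.0, None).sum()
    k = int(np.searchsorted(shares, var_explained - 1e-12) + 1)
    k = min(k, J)
    W = vecs[:, :k]
    bxp = W.T @ inst.beta_x
    byp = W.T @ inst.beta_y
    omega = np.outer(inst.se_y, inst.se_y) * inst.ld.r
    omega_p = W.T @ omega @ W
    theta, se, phi = _ivw_core(bxp, byp, omega_p, k > 3, k - 1)
    label = f"pca{int(round(var_explained * 100))}"
    return MREstimate(
        protein_id=inst.protein_id,
        model=label,
        theta=theta,
        se=se,
        pval=zscore_pvalue(theta, se),
        n_instruments=k,
        re_scaling=phi,
    )


def applicable_models(J: int) -> list[str]:
    """Models testable at a given instrument count.

    One instrument admits only the Wald ratio; two admit IVW and the two
    PCA variants; three or more add Egger regression.
    """
    if J < 1:
        raise InapplicableModelError("no instruments available")
    if J == 1:
        return ["wald"]
    if J == 2:
        return ["ivw", "pca90", "pca99"]
    return ["ivw", "pca90", "pca99", "egger"]


def run_model(inst: InstrumentSet, model: str) -> MREstimate:
    """Dispatch a named model on an instrument set."""
    if model == "wald":
        if inst.J != 1:
            raise InapplicableModelError("Wald ratio requires exactly 1 instrument")
        return wald_ratio(
            float(inst.beta_x[0]),
            float(inst.se_x[0]),
            float(inst.beta_y[0]),
            float(inst.se_y[0]),
            protein_id=inst.protein_id,
        )
    if model == "ivw":
        return ivw_correlated(inst)
    if model == "egger":
        return egger_correlated(inst)
    if model == "pca90":
        return pca_mr(inst, 0.90)
    if model == "pca99":
        return pca_mr(inst, 0.99)
    raise ValueError(f"unknown model {model!r}")


def estimate_auto(inst: InstrumentSet) -> MREstimate:
    """Primary-analysis model choice: Wald for J = 1, IVW otherwise."""
    if inst.J < 1:
        raise InapplicableModelError("no instruments available")
    return run_model(inst, "wald" if inst.J == 1 else "ivw")
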