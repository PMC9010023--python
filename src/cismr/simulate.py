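"""Synthetic GWAS data with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: LD-structured cis regions (AR(1) latent-Gaussian haplotypes), a
sparse pQTL architecture for the protein exposure, a liability-threshold
binary disease with a tunable causal protein effect and optional direct
(pleiotropic) variant effects, per-variant GWAS scans producing two-sample
summary statistics, and heterogeneous multi-study observational estimates.

The exposure GWAS, outcome GWAS and LD reference panel are three
independent draws from the same population (same allele frequencies and LD
structure), matching a two-sample MR design with an external LD panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .sumstats import (
    GeneAnnotation,
    LoadReport,
    SUMSTATS_COLUMNS,
    SummaryStatsTable,
)

__all__ = [
    "SimTruth",
    "GenotypePanel",
    "SimStudy",
    "bvn_cdf",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_quantitative_outcome",
    "gwas_scan",
    "simulate_observational_studies",
    "draw_variant_info",
    "simulate_mr_study",
    "ratio_estimand",
]


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated protein-disease system.

    theta
        True causal effect of the protein (per 1 SD) on disease liability;
        the probit-scale analogue of a log odds ratio.
    pqtl_effects
        Map of variant index -> per-allele effect on the protein's genetic
        component.  Only the direction/relative size matters: the residual
        is rescaled so the genetic variance fraction equals ``h2_protein``.
    pleiotropy_effects
        Map of variant index -> direct per-allele effect on disease
        liability, bypassing the protein (horizontal pleiotropy).
    """

    theta: float = 0.3
    pqtl_effects: dict[int, float] = field(default_factory=dict)
    pleiotropy_effects: dict[int, float] = field(default_factory=dict)
    h2_protein: float = 0.3
    prevalence: float = 0.1
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    n_reference: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_protein < 1:
            raise ValueError("h2_protein must be in [0, 1)")
        if not 0 < self.prevalence < 0.5:
            raise ValueError("prevalence must be in (0, 0.5)")

    @classmethod
    def default(
        cls, m: int = 50, n_causal: int = 5, seed: int = 0, **kwargs
    ) -> "SimTruth":
        """Evenly spaced causal pQTLs of equal weight across ``m`` variants."""
        idx = np.linspace(0, m - 1, n_causal).round().astype(int)
        return cls(pqtl_effects={int(i): 1.0 for i in idx}, seed=seed, **kwargs)


@dataclass
class GenotypePanel:
    """Dosage matrix with its generating allele frequencies and LD target.

    ``target_ld`` is the population (latent-Gaussian-implied) signed dosage
    correlation; realized sample correlation converges to it as n grows.
    """

    dosages: np.ndarray  # (n, m) values in {0,1,2}
    mafs: np.ndarray  # (m,) effect-allele frequencies
    target_ld: np.ndarray  # (m, m) signed r
    variant_info: pd.DataFrame | None = None  # variant_id/chrom/pos/alleles

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def variant_ids(self) -> list[str]:
        if self.variant_info is None:
            return [f"v{i}" for i in range(self.m)]
        return list(self.variant_info["variant_id"])


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Standard bivariate normal CDF P(Z1 <= h, Z2 <= k) via Owen's T.

    Vectorized; handles |rho| -> 1 limits explicitly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    near_one = np.isclose(np.abs(rho), 1.0)
    general = ~near_one
    if np.any(general):
        # nudge exact zeros off the removable singularity of the Owen's T form
        eps = 1e-12
        hg = np.where(h[general] == 0, eps, h[general])
        kg = np.where(k[general] == 0, eps, k[general])
        rg = rho[general]
        denom = np.sqrt(1.0 - rg * rg)
        ah = (kg - rg * hg) / (denom * hg)
        ak = (hg - rg * kg) / (denom * kg)
        t_h = special.owens_t(hg, ah)
        t_k = special.owens_t(kg, ak)
        beta = np.where(hg * kg < 0, 0.5, 0.0)
        out[general] = (
            0.5 * (stats.norm.cdf(hg) + stats.norm.cdf(kg)) - t_h - t_k - beta
        )
    if np.any(near_one):
        hn, kn, rn = h[near_one], k[near_one], rho[near_one]
        pos = rn > 0
        out[near_one] = np.where(
            pos,
            stats.norm.cdf(np.minimum(hn, kn)),
            np.clip(stats.norm.cdf(hn) + stats.norm.cdf(kn) - 1.0, 0.0, None),
        )
    return out


def _dosage_correlation(thresholds: np.ndarray, latent_r: np.ndarray) -> np.ndarray:
    """Signed dosage correlation implied by thresholding a latent Gaussian.

    A haplotype carries the effect allele when its latent value falls below
    the frequency quantile; dosages are sums of two independent haplotypes,
    so the dosage correlation equals the haplotype (tetrachoric-Bernoulli)
    correlation.
    """
    p = stats.norm.cdf(thresholds)
    t_i = thresholds[:, None]
    t_j = thresholds[None, :]
    joint = bvn_cdf(t_i, t_j, latent_r)
    pi = p[:, None]
    pj = p[None, :]
    cov = joint - pi * pj
    sd = np.sqrt(p * (1 - p))
    r = cov / (sd[:, None] * sd[None, :])
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def simulate_genotypes(
    n: int,
    m: int,
    ld_decay: float,
    maf_range: tuple[float, float],
    seed: int,
    mafs: np.ndarray | None = None,
    variant_info: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Simulate an LD-structured diploid dosage panel.

    Haplotypes are thresholded draws from a latent Gaussian AR(1) process
    with correlation ``ld_decay**|i-j|``; a haplotype carries the effect
    allele when the latent value is below the allele-frequency quantile,
    and two independent haplotypes sum to a dosage.  Deterministic given
    ``seed``.  ``mafs`` may be supplied to share allele frequencies across
    independently drawn cohorts.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not 0 <= ld_decay < 1:
        raise ValueError("ld_decay must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(lo, hi, size=m)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (m,):
            raise ValueError("mafs must have length m")

    thresholds = stats.norm.ppf(mafs)
    z = rng.standard_normal((2 * n, m))
    if ld_decay > 0:
        scale = np.sqrt(1.0 - ld_decay**2)
        for j in range(1, m):
            z[:, j] = ld_decay * z[:, j - 1] + scale * z[:, j]
    haps = (z < thresholds).astype(np.int8)
    dosages = haps[:n] + haps[n:]

    lag = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
    latent_r = np.where(lag == 0, 1.0, ld_decay ** lag.astype(float))
    target = _dosage_correlation(thresholds, latent_r)
    return GenotypePanel(
        dosages=dosages, mafs=mafs, target_ld=target, variant_info=variant_info
    )


def simulate_traits(
    panel: GenotypePanel, truth: SimTruth, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Protein level and liability-threshold disease status for one cohort.

    protein = standardized(G b + e), with the environmental noise scaled so
    the genetic variance fraction equals ``truth.h2_protein``; liability =
    theta * protein + G gamma + e_L with unit-variance residual; disease is
    liability above the Phi^-1(1 - prevalence) threshold.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n, m = panel.dosages.shape
    b = np.zeros(m)
    for idx, eff in truth.pqtl_effects.items():
        if not 0 <= idx < m:
            raise ValueError(f"pqtl_effects index {idx} out of range for m={m}")
        b[idx] = eff
    gamma = np.zeros(m)
    for idx, eff in truth.pleiotropy_effects.items():
        if not 0 <= idx < m:
            raise ValueError(f"pleiotropy index {idx} out of range for m={m}")
        gamma[idx] = eff

    g_centered = panel.dosages - panel.dosages.mean(axis=0)
    genetic = g_centered @ b
    var_g = float(np.var(genetic))
    if truth.h2_protein == 0 or var_g == 0:
        if np.any(b != 0) and truth.h2_protein == 0:
            warnings.warn(
                "h2_protein = 0 with nonzero pQTL effects: protein is pure noise",
                stacklevel=2,
            )
        protein_raw = rng.standard_normal(n)
    else:
        var_e = var_g * (1.0 - truth.h2_protein) / truth.h2_protein
        protein_raw = genetic + rng.normal(0.0, np.sqrt(var_e), size=n)
    protein = (protein_raw - protein_raw.mean()) / protein_raw.std()

    liability = truth.theta * protein + g_centered @ gamma + rng.standard_normal(n)
    threshold = stats.norm.ppf(1.0 - truth.prevalence)
    disease = (liability > threshold).astype(np.int8)
    return protein, disease


def simulate_quantitative_outcome(
    panel: GenotypePanel,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Continuous outcome trait: theta * protein + direct effects + noise."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    protein, _ = simulate_traits(panel, truth, rng=rng)
    n, m = panel.dosages.shape
    gamma = np.zeros(m)
    for idx, eff in truth.pleiotropy_effects.items():
        gamma[idx] = eff
    g_centered = panel.dosages - panel.dosages.mean(axis=0)
    return truth.theta * protein + g_centered @ gamma + rng.standard_normal(n)


# ---------------------------------------------------------------------------
# GWAS scans


def _linear_scan(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression with intercept, closed form."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ssx = (gc**2).sum(axis=0)
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    poly = ssx > 0
    beta[poly] = (gc[:, poly] * yc[:, None]).sum(axis=0)[poly] / ssx[poly]
    resid_ss = (yc**2).sum() - beta[poly] ** 2 * ssx[poly]
    df = max(n - 2, 1)
    sigma2 = np.clip(resid_ss, 0.0, None) / df
    se[poly] = np.sqrt(sigma2 / ssx[poly])
    return beta, se


def _logistic_scan(
    g: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression (intercept + dosage) by IRLS/Newton.

    All variants are solved simultaneously with explicit 2x2 algebra.
    """
    n, m = g.shape
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        mu = special.expit(eta)
        w = mu * (1 - mu)
        s11 = w.sum(axis=0)
        s12 = (w * g).sum(axis=0)
        s22 = (w * g * g).sum(axis=0)
        r = y[:, None] - mu
        g1 = r.sum(axis=0)
        g2 = (r * g).sum(axis=0)
        det = s11 * s22 - s12 * s12
        det = np.where(det <= 0, np.nan, det)
        da = (s22 * g1 - s12 * g2) / det
        db = (s11 * g2 - s12 * g1) / det
        a += np.nan_to_num(da)
        b += np.nan_to_num(db)
        if np.nanmax(np.abs(np.concatenate([da, db]))) < tol:
            break
    eta = a[None, :] + g * b[None, :]
    mu = special.expit(eta)
    w = mu * (1 - mu)
    s11 = w.sum(axis=0)
    s12 = (w * g).sum(axis=0)
    s22 = (w * g * g).sum(axis=0)
    det = s11 * s22 - s12 * s12
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s11 / det)
    return b, se


def gwas_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    trait_type: str,
    trait_id: str = "trait",
) -> SummaryStatsTable:
    """Per-variant association scan producing a summary-statistics table.

    Continuous traits use simple linear regression; binary traits use
    logistic regression solved by iteratively reweighted least squares.
    p-values are two-sided normal; EAF is computed from the dosages.
    Monomorphic variants are emitted with missing SE and flagged in the
    load report (they fail downstream validation by construction).
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.shape[0] != panel.n:
        raise ValueError("phenotype length must equal panel n")
    g = panel.dosages.astype(float)
    if trait_type == "continuous":
        beta, se = _linear_scan(g, phenotype)
    elif trait_type == "binary":
        beta, se = _logistic_scan(g, phenotype)
        mono = g.std(axis=0) == 0
        beta[mono] = np.nan
        se[mono] = np.nan
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    eaf = g.mean(axis=0) / 2.0

    if panel.variant_info is not None:
        info = panel.variant_info
    else:
        info = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(panel.m)],
                "chrom": "1",
                "pos": np.arange(1, panel.m + 1),
                "effect_allele": "A",
                "other_allele": "G",
            }
        )
    df = pd.DataFrame(
        {
            "variant_id": info["variant_id"].to_numpy(),
            "chrom": info["chrom"].to_numpy(),
            "pos": info["pos"].to_numpy(),
            "effect_allele": info["effect_allele"].to_numpy(),
            "other_allele": info["other_allele"].to_numpy(),
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
        }
    )[SUMSTATS_COLUMNS]
    report = LoadReport(n_input=panel.m, n_retained=panel.m)
    n_flagged = int(np.isnan(se).sum())
    if n_flagged:
        report.add_drop("monomorphic_flagged", n_flagged)
    return SummaryStatsTable(
        trait_id=trait_id, trait_type=trait_type, records=df, report=report
    )


# ---------------------------------------------------------------------------
# observational studies


def simulate_observational_studies(
    k: int,
    true_log_rr: float,
    tau: float,
    ns: Sequence[int],
    seed: int,
    se_scale: float = 3.0,
) -> pd.DataFrame:
    """Study-level observational estimates around a common true log RR.

    Study true effects are Normal(true_log_rr, tau^2); the observed effect
    adds sampling noise with SE = se_scale / sqrt(n).  ``tau`` is the
    between-study heterogeneity SD (0 = homogeneous).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    ns = list(ns)
    if len(ns) != k:
        raise ValueError("ns must have length k")
    rng = np.random.default_rng(seed)
    study_truth = rng.normal(true_log_rr, tau, size=k)
    se = se_scale / np.sqrt(np.asarray(ns, dtype=float))
    observed = rng.normal(study_truth, se)
    return pd.DataFrame(
        {
            "study_id": [f"study_{i + 1}" for i in range(k)],
            "log_rr": observed,
            "se": se,
        }
    )


# ---------------------------------------------------------------------------
# end-to-end study assembly


def draw_variant_info(
    m: int,
    gene: GeneAnnotation,
    maf_range: tuple[float, float],
    seed: int,
    flank: int = 180_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Variant metadata (ids, positions, alleles) and allele frequencies.

    Positions are evenly spread across the gene body plus ``flank`` on each
    side, so all variants fall inside the 200 kbp cis window.
    """
    rng = np.random.default_rng(seed)
    lo = max(1, gene.tss - flank)
    hi = gene.tes + flank
    pos = np.linspace(lo, hi, m).round().astype(np.int64)
    if len(np.unique(pos)) != m:  # tiny region: fall back to consecutive bp
        pos = lo + np.arange(m, dtype=np.int64)
    bases = np.array(list("ACGT"))
    ea_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    oa_idx = (ea_idx + shift) % 4
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    info = pd.DataFrame(
        {
            "variant_id": [f"{gene.chrom}:{p}" for p in pos],
            "chrom": gene.chrom,
            "pos": pos,
            "effect_allele": bases[ea_idx],
            "other_allele": bases[oa_idx],
        }
    )
    return info, mafs


@dataclass
class SimStudy:
    """One synthetic two-sample MR study with its ground truth."""

    truth: SimTruth
    gene: GeneAnnotation
    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    reference: GenotypePanel


_DEFAULT_GENE = GeneAnnotation(
    gene_id="GENE1",
    protein_id="P1",
    chrom="1",
    tss=1_000_000,
    tes=1_020_000,
)


def simulate_mr_study(
    truth: SimTruth,
    m: int = 50,
    ld_decay: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    gene: GeneAnnotation = _DEFAULT_GENE,
    protein_id: str | None = None,
) -> SimStudy:
    """Simulate exposure GWAS, outcome GWAS, and an LD reference panel.

    The three cohorts are independent draws sharing allele frequencies and
    LD structure.  All seeds derive from ``truth.seed``.
    """
    ss = np.random.SeedSequence(truth.seed)
    s_info, s_exp, s_out, s_ref, s_trait_x, s_trait_y = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    ]
    info, mafs = draw_variant_info(m, gene, maf_range, s_info)
    pid = protein_id or gene.protein_id

    exp_panel = simulate_genotypes(
        truth.n_exposure, m, ld_decay, maf_range, s_exp, mafs=mafs, variant_info=info
    )
    protein, _ = simulate_traits(
        exp_panel, truth, rng=np.random.default_rng(s_trait_x)
    )
    exposure = gwas_scan(exp_panel, protein, "continuous", trait_id=pid)

    out_panel = simulate_genotypes(
        truth.n_outcome, m, ld_decay, maf_range, s_out, mafs=mafs, variant_info=info
    )
    _, disease = simulate_traits(
        out_panel, truth, rng=np.random.default_rng(s_trait_y)
    )
    outcome = gwas_scan(out_panel, disease, "binary", trait_id="disease")

    reference = simulate_genotypes(
        truth.n_reference, m, ld_decay, maf_range, s_ref, mafs=mafs, variant_info=info
    )
    return SimStudy(
        truth=truth, gene=gene, exposure=exposure, outcome=outcome, reference=reference
    )


def ratio_estimand(
    truth: SimTruth,
    m: int = 50,
    ld_decay: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_oracle: int = 400_000,
    seed: int = 999_331,
    r2_threshold: float = 0.4,
) -> float:
    """Large-n logistic oracle for the primary MR estimand.

    The per-variant logistic (outcome) and linear (exposure) GWAS
    coefficients are measured in one very large independent cohort, so
    sampling error and selection effects are negligible; they are then
    combined with the same clumping rule (using the analytic population LD
    rather than a sampled panel) and the same correlated-IVW weighting the
    pipeline applies.  The result is the probability limit of the primary
    estimator under the generating model: the logistic-scale disease
    effect of a 1 SD protein shift as seen through the cis instruments,
    attenuated relative to the liability-scale ``truth.theta`` by the
    unmodelled liability variance and the probit-to-logit gap.
    """
    from .instruments import HarmonizedCandidates, LDMatrix, clump

    ss = np.random.SeedSequence((truth.seed, seed))
    s_info, s_g, s_t = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    gene = _DEFAULT_GENE
    info, mafs = draw_variant_info(m, gene, maf_range, s_info)
    panel = simulate_genotypes(
        n_oracle, m, ld_decay, maf_range, s_g, mafs=mafs, variant_info=info
    )
    rng = np.random.default_rng(s_t)
    protein, disease = simulate_traits(panel, truth, rng=rng)
    g = panel.dosages.astype(float)
    bx, sx = _linear_scan(g, protein)
    by, sy = _logistic_scan(g, disease.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        pval_x = 2.0 * stats.norm.sf(np.abs(bx / sx))
    table = pd.DataFrame(
        {
            "variant_id": info["variant_id"],
            "chrom": info["chrom"],
            "pos": info["pos"],
            "effect_allele": info["effect_allele"],
            "other_allele": info["other_allele"],
            "eaf": g.mean(axis=0) / 2.0,
            "beta_x": bx,
            "se_x": sx,
            "pval_x": pval_x,
            "beta_y": by,
            "se_y": sy,
            "pval_y": np.nan,
        }
    )
    ld = LDMatrix(list(info["variant_id"]), panel.target_ld)
    cand = HarmonizedCandidates(protein_id=gene.protein_id, table=table, ld=ld)
    # at oracle n every variant passes any p filter; only the LD thinning acts
    inst = clump(cand, r2_threshold, 1.0)
    w_bx = np.linalg.solve(np.outer(inst.se_y, inst.se_y) * inst.ld.r, inst.beta_x)
    return float(w_bx @ inst.beta_y / (w_bx @ inst.beta_x))
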