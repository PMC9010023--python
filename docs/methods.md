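# Methods

`cismr` implements a triangulation pipeline for circulating-protein drug
targets: observational association and cis-Mendelian-randomization (MR)
evidence are computed by separate stages with different bias structures,
and a conclusion is only called robust when it survives a multiverse of
defensible analysis choices. This note documents the models, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Observational meta-analysis

Study-level estimates are log risk ratios per 1 SD of standardized
protein level (protein measures standardized to mean 0, SD 1 per study;
one normalized protein expression unit represents a doubling of
concentration, so the effect is also "per doubling"). Hazard and odds
ratios are pooled as a common log RR without conversion, relying on the
rare-outcome equivalence of the three measures. Pooling is fixed-effect
inverse-variance: pooled = Σwᵢθᵢ/Σwᵢ with wᵢ = 1/seᵢ², pooled SE =
(Σwᵢ)^(-1/2). Heterogeneity is Cochran's Q against χ²(k−1). A protein
observed in a single study is retained with Q = 0, 0 degrees of freedom
and p_het reported as 1 together with an explicit `het_undefined` flag:
dropping such proteins would silently shrink the screened family.

Family-wise error is Bonferroni-controlled at α = 0.05 over the number of
proteins tested. Thresholds are reported exactly and rounded to one
significant figure for display (0.05/90 → 6e-4, shown as 6.0×10⁻⁴;
0.05/56 → 0.0009), and the comparison is strict (`p < α/n`; a p-value
exactly at the threshold fails). Median and interquartile range of the
passing risk ratios use linear interpolation between order statistics —
the quantile convention must be fixed for reproducibility and this is the
NumPy default.

## Instrument selection

The cis window is the transcription unit (canonicalized so start ≤ end
regardless of strand) plus a symmetric 200 kbp flank, closed and 1-based,
clamped at base 1. Candidate instruments are biallelic single-nucleotide
variants present in both exposure and outcome summary statistics, inside
the window, with exposure minor allele frequency strictly above 0.01. A
record with missing allele frequency fails the filter (fail-closed),
because frequency-unknown variants cannot be shown to pass.

Harmonization aligns the outcome record to the exposure effect allele:
identical allele pairs pass through, swapped pairs flip the outcome beta
and complement its frequency, anything else is dropped with a reason
code. Palindromic (A/T, C/G) variants are harmonized by allele labels
only — the generator is strand-consistent so no frequency inference is
needed — and a `drop_palindromic` flag provides the conservative
alternative for strand-ambiguous real data.

Clumping is the greedy PLINK rule: after discarding variants with
exposure p above the threshold (a threshold of 1.0 means no filter), the
smallest-p remaining variant becomes an index and all remaining variants
with squared correlation strictly above the r² threshold to that index
are removed, repeating until exhausted. Two conventions had to be fixed
where common practice is silent: p-value ties break by genomic position
then allele string (deterministic, PLINK-like), and a variant exactly at
the r² threshold is kept (removal is strict `>`). The step-by-step
reference implementation in the test suite pins both conventions.

LD is the signed Pearson correlation of reference-panel dosages; a
monomorphic variant is an error naming the variant, since its correlation
is undefined.

## MR estimators

All estimators operate on harmonized per-variant effects β_X (exposure,
SD units), β_Y (outcome, log-odds) and the instrument LD correlation
matrix r. The weight matrix is Ω = (se_Y se_Yᵀ)∘r.

* **Wald ratio** (J = 1): θ = β_Y/β_X, SE = se_Y/|β_X| (first-order delta
  method, outcome uncertainty only — the convention of summary-data MR).
  A second-order SE including exposure uncertainty is available behind a
  flag and is strictly larger.
* **Correlated IVW**: generalized least squares of β_Y on β_X through the
  origin, θ = (β_XᵀΩ⁻¹β_Y)/(β_XᵀΩ⁻¹β_X), fixed SE = (β_XᵀΩ⁻¹β_X)^(-1/2).
* **Correlated Egger**: the same GLS with a free intercept measuring
  directional pleiotropy, after orienting every instrument so β_X ≥ 0.
  Orientation is an allele relabeling, so the LD matrix is conjugated by
  the orientation signs (r → DrD); without this the estimator would not
  be equivariant under allele relabeling. Requires J ≥ 3.
* **PCA-MR**: eigendecompose Ψ with Ψᵢⱼ = (β_Xᵢβ_Xⱼ/(se_Yᵢse_Yⱼ))rᵢⱼ,
  keep the smallest k components whose cumulative eigenvalue share
  reaches the target (90% or 99%), project β_X, β_Y and Ω onto them, and
  apply the IVW formula in the projected space. This handles the
  near-collinear instrument sets that a relaxed r² threshold of 0.4
  admits.

SEs use a fixed-effect model for 3 or fewer instruments and a
multiplicative random-effects model otherwise: the SE is inflated by
φ = max(1, √(residᵀΩ⁻¹resid/df)) with df = J−1 for IVW and J−2 for Egger.
For the PCA models the rule is applied to the number of retained
components k, the effective dimension of the fit. The floor at 1 makes
the fixed-effect SE a lower bound for the random-effects SE by
construction. p-values are two-sided normal throughout (not t), matching
summary-data MR convention and keeping the independent oracles exact.

Model applicability by instrument count: J = 1 → Wald only; J = 2 → IVW
and both PCA variants; J ≥ 3 → those plus Egger.

Ω conditioning: if the condition number exceeds 1e10, a single ridge
ε·diag(Ω) with ε = 1e-8 is added; if the matrix is still ill-conditioned
the estimator raises an error naming the worst LD pair rather than
returning an unstable number. The relaxed r² ceiling is exactly the
regime where this matters.

## Multiverse sensitivity analysis

The grid crosses 5 LD r² thresholds (0.05, 0.1, 0.2, 0.4, 0.6) with 6
p-value thresholds (5×10⁻⁸, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², and 1 = no filter):
30 selection settings, each evaluated under every applicable model, up to
120 combinations per protein. The primary analysis sits at (0.4, 10⁻⁴)
with the auto model (Wald if J = 1, else correlated IVW); the
conventional comparison sits at (0.05, 5×10⁻⁸). Selection or estimation
failures become cells carrying the failure reason and are excluded from
everything downstream except the attempt counts.

Outlier trimming applies Tukey fences (1.5×IQR beyond the quartiles) to
the point estimates pooled across all settings and models of one protein.
Pooling within protein (rather than across proteins) is the only reading
under which a single fence rule can act on one protein's estimate
distribution. An association is robust when every retained estimate has
the sign of the primary estimate; trimming precedes the concordance
check, so a sign flip confined to an outlier cannot break robustness,
and removing an outlier can only change a verdict from not-robust to
robust. Estimates with |θ| < 1e-12 are treated as concordant with either
sign — a degenerate case that must be defined, not guessed.

## Cross-trait MR

Each prioritized protein is analysed against each auxiliary trait with
the primary selection strategy and model. Instrument selection is re-run
per trait because availability differs across outcome GWASs; freezing
the disease-analysis instruments would silently drop variants absent
from a trait's summary statistics. Estimates are converted to Z = θ/SE
(one rule for binary log-odds and continuous SD-unit outcomes alike) and
judged against α/(n_proteins × n_traits). A pair whose trait lacks cis
coverage is reported as not estimable rather than omitted.

## Synthetic data generator

The generator produces the three independent cohorts of a two-sample MR
design with an external LD panel — exposure GWAS, outcome GWAS and
reference genotypes — sharing allele frequencies and LD structure.

* **Genotypes**: haplotypes are thresholded draws from a latent Gaussian
  AR(1) process with correlation ρ^|i−j| (default ρ = 0.9); a haplotype
  carries the effect allele when the latent value falls below the
  allele-frequency quantile, and two haplotypes sum to a dosage. One
  parameter gives realistic monotone LD decay with an analytic target:
  the implied dosage correlation is computed exactly through the
  bivariate normal CDF (Owen's T form), which the realized correlation
  must match within ±0.1 at n ≥ 2000.
* **Protein**: a sparse cis architecture (default 5 equal-effect causal
  variants among 50) with the environmental residual scaled so the
  genetic variance fraction equals h² (default 0.3); the protein is then
  standardized, so only the direction of the per-variant weights matters.
* **Disease**: liability threshold. Liability = θ·protein + direct
  variant effects (pleiotropy) + unit-normal residual; disease is
  liability above Φ⁻¹(1−prevalence), default prevalence 0.1. The probit
  model gives clean prevalence control at the null; when θ ≠ 0 the
  liability variance exceeds 1 and realized prevalence slightly exceeds
  the nominal value — accepted, since the threshold definition is part
  of the model.
* **GWAS scans**: per-variant simple linear regression (continuous) or
  logistic regression by iteratively reweighted least squares (binary),
  so the summary-statistics pathway matches real data even though the
  disease model is probit. Monomorphic variants are emitted with missing
  SE and flagged.
* **Observational studies**: study effects Normal(true log RR, τ²),
  observed with SE = c/√n (c = 3.0, giving SEs near 0.1 for cohorts of a
  few hundred to a thousand — the scale of the real study panel).
* Default cohort sizes are n = 20,000 for each GWAS sample and 10,000
  for the LD reference.

Because the disease is probit but the outcome scan is logistic, the MR
estimand is not θ itself: it is the logistic-scale effect of a 1 SD
protein shift as seen through the cis instruments, attenuated by the
unmodelled liability variance and the probit-to-logit scale gap (θ = 0.3
maps to ≈ 0.55 on the log-odds scale under the defaults). Calibration
tests therefore compare estimates to this estimand, measured by a
large-n oracle: one cohort of 400,000 is scanned per variant, and the
resulting near-exact coefficients are combined with the same clumping
rule (using the analytic population LD) and the same correlated-IVW
weighting. Under the null (θ = 0) no mapping is needed.

What the generator does not emulate: imputation noise, population
stratification, sample overlap between exposure and outcome GWAS,
strand ambiguity, allele-frequency mismatch between cohorts, and sex
chromosomes. Passing calibration tests therefore demonstrates
correctness of the statistical machinery under a clean two-sample
design, not robustness to those real-data complications.

## Problem sizes in the test suite and acceptance script

Replicate experiments use 200 replicates for interval coverage and null
calibration (binomial SE ≈ 1.5% at 95%), 20 replicates for robustness
verdicts, 25 for Egger intercept power, and a 90-protein × 4-study panel
(44 true effects drawn around log RR 1.33, cohort sizes 1092/877/550/500)
for the observational screen. These sizes put Monte-Carlo error well
inside the asserted tolerance bands while keeping a full run of the
suite and the acceptance script in the minutes range on one CPU.

## Known limitations

* The Wald SE ignores exposure uncertainty (first-order delta); with
  weak instruments it understates the true sampling variance.
* The random-effects overdispersion factor is floored at 1, which makes
  null-calibration very slightly conservative.
* The outlier rule assumes enough grid cells for meaningful quartiles;
  with two estimates the fences can never exclude either.
* Robustness is a sign-concordance screen, not a formal test; its false
  and true verdict rates under the generator are measured empirically by
  the acceptance script rather than derived.
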