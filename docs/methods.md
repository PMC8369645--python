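# Methods

`txwas` implements a transcriptome-wide association workflow for quantitative
traits measured alongside bulk RNA-seq, together with the simulation
machinery needed to characterize its operating characteristics. This note
records the models, the defaults and why they were chosen, and what the
synthetic data can and cannot tell you about real data.

## Models

**Preprocessing.** Raw gene-level counts are normalized by median-of-ratios
size factors (the DESeq2 estimator): each gene with strictly positive counts
in every sample contributes its count/geometric-mean ratio, and a sample's
factor is the median of those ratios. Normalized counts are transformed as
log2(x+1) by default (`log=False` disables it; the transformation applied to
normalized counts before scaling is a modelling choice, and results
downstream depend only weakly on it because every gene is subsequently
standardized). Every gene and every trait is scaled to mean 0 and sample SD 1
(n−1 denominator, the R `scale` convention) before any association analysis.
Constant genes are dropped with a logged count.

**Expression kinship.** From the standardized samples × genes matrix X the
sample-similarity matrix

    K = (1/d) Σᵢ XᵢXᵢᵀ ,   d = mean diagonal of Σᵢ XᵢXᵢᵀ,

is the transcriptomic analogue of the genomic relationship matrix:
`mean(diag(K)) = 1`, `trace(K) = n`. Its eigendecomposition is computed once
and cached; eigenvalues in [−1e−8, 0) are clipped to 0, anything lower is an
error (a true kinship is PSD by construction).

**Single-gene LMM.** For gene i,

    y = μ1 + bᵢXᵢ + a + e,  a ~ N(0, Kσ²),  e ~ N(0, Iσₑ²).

Rotating by the eigenvectors of K diagonalizes the covariance, so the REML
log-likelihood is profiled over the single ratio δ = σ²/σₑ² on
log δ ∈ [−10, 10]: a 64-point grid bracket followed by bounded scalar
refinement (ties broken toward smaller δ; `xatol` 1e−6 for the per-gene scan,
1e−8 for `reml_fit`). δ is re-estimated for every tested gene (the exact
Wald mode of GWAS LMM software); with K = I the procedure reduces exactly to
single-predictor OLS, which is the oracle used in tests. The Wald statistic
W = b²/var(b) is referred to χ²₁, and genome-wide significance uses
Bonferroni α/m. Genes collinear with the intercept are reported as NA rather
than dropped. With K = I the two variance components are unidentifiable
individually; only their sum is meaningful, which the tests document.

**Penalized multi-gene models.** LASSO (α=1), ridge (α=0), and elastic net
(0<α<1) minimize

    (1/2n)‖y − μ1 − Xb‖² + λ[α‖b‖₁ + (1−α)/2 ‖b‖₂²].

This is the glmnet/scikit-learn scaling; the textbook objectives without the
1/(2n) and 1/2 factors differ only by a reparameterization of λ. The
mapping is pinned by tests: ridge solves (XᵀX + nλI)b = Xᵀy, and on
orthonormal designs LASSO soft-thresholds the univariate OLS estimates at
nλ. Coordinate descent (scikit-learn) is used for α>0; ridge uses the exact
SVD/dual closed form. λ is tuned by 10-fold cross-validation on a 100-point
log-spaced grid from λ_max (the smallest λ zeroing all coefficients,
max|Xᵀy_c|/(n·max(α,10⁻³))) down to 10⁻⁴·λ_max; folds come from a seeded
permutation and are shared across the α grid (default α ∈ {0.1,…,0.9}; α is
chosen by Min-rule error, then λ by the requested rule on that α's curve).
Two tuning rules: **Min** (λ at the minimum CV mean squared prediction
error) and **1SE** (the largest λ whose error is within one fold-to-fold
standard error, SD/√folds, of that minimum). Fold-level path fits use
coordinate-descent tolerance 1e−3 (the CV curve is insensitive at this
level); final full-data fits use 1e−6.

**Bootstrap Wald tests.** The penalized solvers provide no var(bᵢ), so it is
estimated by a nonparametric bootstrap at *fixed* tuning: resamples of 200
individuals (with replacement; `min(200, n)` in scaled-down runs), 1000
replications by default, coefficient variance taken across resamples, Wald
numerator from the full-data fit, p from χ²₁ at threshold 0.05 (the joint
model needs no multiplicity correction). Re-selecting λ inside resamples is
deliberately not done: the test is conditional on the chosen model. A
resample containing a constant gene column is redrawn (≤10 times).
Candidate declaration for LASSO/EN supports both strategies: all
nonzero-coefficient genes, or nonzero genes passing the Wald filter.

**Pseudo-phenotype benchmark.** Genes are classified once into
trait-relevant/trait-neutral sets by an EN-Min analysis of the base trait.
Per replicate, a fresh pair of neutral genes is drawn: the first is spiked
onto the standardized trait with b = √(h/(1−h)) — calibrated so a
unit-variance independent predictor contributes exactly the fraction h of
the resulting variance (h=0.20 ↔ b=0.50) — and the second has its column
permuted, a distribution-preserving null probe. The pseudo-phenotype is
re-standardized (configurable), every method re-tunes from scratch, K is
rebuilt from the modified matrix, and detection follows each method's rule
(LMM: Bonferroni over all m genes; 1SE variants: nonzero coefficient; Min
variants: nonzero, optionally plus Wald; ridge: Wald). Power and type-I
error are detection fractions over replicates for the spiked and shuffled
gene respectively. The default grid is the 23 variance proportions
0.01–0.50.

## Synthetic data

The generator produces the structure the models assume rather than mimicking
any particular count distribution:

- **Expression**: a Gaussian latent-factor layer — 20 modules of 50 genes by
  default, each member gene = 0.7·module factor + independent noise, scaled
  to unit variance (loading 0.7 gives within-module correlations ≈ 0.5,
  typical of tight co-expression modules); remaining genes independent.
  Optionally the latent layer is pushed through an exp link onto
  negative-binomial counts (gene-level baseline ~ logNormal(log 100, 1),
  dispersion 0.1), which then flow through the full normalization path.
- **Traits**: y = Σbⱼxⱼ + a + e with a ~ N(0, h²·K) drawn against the
  *generated* data's own kinship (making REML variance-component recovery
  well-posed), and noise filling the unit-variance budget. Defaults: five
  causal genes at 2% of variance each, polygenic h² = 0.3 — a sparse-plus-
  polygenic architecture on the scale of a moderately heritable production
  trait. The primary trait is rescaled to mean 83.68, SD 11.66 (CV 13.93%,
  a realistic body-composition scale); extra traits can be given a
  prescribed correlation with the first.
- **Reproducibility**: one master seed; every consumer (expression, counts,
  polygenic draw, noise, extra traits, per-replicate shuffles) gets its own
  `SeedSequence` spawn key, so sub-streams are independently reproducible.

Default sizes are desk-scale: n = 400 samples and m = 2000 genes (m = 1000
in the benchmark), not the ~15k genes of a full transcriptome; m is
configurable. What passing tests on these data show: correctness of the
estimators, calibration of the tests under the generator's assumptions, and
the relative ordering of methods. What they do not show: behavior under
batch effects, count-level artifacts, non-Gaussian expression tails, or
linkage-like correlation between causal and proxy genes in real tissue.

## Numerical and design choices

- REML criterion drops additive constants; only differences in δ matter.
- The benchmark evaluates the per-gene LMM only at the two manipulated genes
  (the only detections that enter power/type-I); the Bonferroni denominator
  is still the full m. Full scans are available via `lmm_scan`.
- Scenario-level scaled-down defaults: 50 replicates, 200 bootstrap
  replications, EN α grid {0.1, 0.5, 0.9}; full-scale settings
  (100 replicates, B = 1000, the full α grid) remain plain config values.
- The nonzero-coefficient detection rule's false-positive rate scales with
  the selected fraction of genes (≈ #selected/m), while bootstrap-Wald rates
  are roughly m-independent; method-ordering comparisons are therefore only
  meaningful in the m ≫ n regime the benchmark defaults target.
- `resample_size` defaults to min(200, n) so bootstrap tests stay valid on
  small synthetic studies.
- Tie-breaks: δ grid ties toward smaller δ; CV-error ties toward larger λ
  (the first index on the descending grid); dendrogram ties by input order.
- Trait correlations use pairwise-complete observations (traits may be
  measured on different sample subsets); the dendrogram standardizes trait
  columns before Euclidean/complete-linkage clustering, the only scaling
  that makes differently-united traits comparable.
- BED-like gene positions are read as 0-based half-open and converted to
  1-based inclusive in human-readable tables.

## Known limitations

- The bootstrap Wald test ignores selection/shrinkage bias in the numerator;
  penalized estimates are biased toward zero (the benchmark quantifies this:
  the mean EN-1SE estimate of a true 0.50-SD effect sits well below 0.50),
  so effect sizes from penalized fits understate true effects.
- Per-gene REML assumes the asymptotic χ²₁ for the Wald statistic; no
  small-sample t/F correction is applied.
- The elastic-net α search uses the Min-rule error to pick α even when λ is
  then chosen by the 1SE rule; the order of the two searches is a
  convention.
- With K = I (or any kinship proportional to the identity) δ is
  unidentifiable; downstream quantities that depend only on total variance
  remain valid.
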