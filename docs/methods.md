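# Methods

This note documents the statistical procedures implemented in `methx`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Study design assumed

An unpaired two-group comparison: tumor vs normal tissue, with possibly
different subsets of cases available per assay (methylation array vs
RNA-seq). All thresholds live in one `RunConfig`: significance level
α = 0.05, minimum |Δβ| = 0.3, β bin edges (0.3, 0.7), CPM threshold 1,
expressed fraction 0.8, enhancer window 500 kb with k = 10 nearest genes.
Integration stages run on the subset of cases with both assays.

## Differential methylation

**Binning.** β ∈ [0, 1] is the fraction of methylated signal at a CpG.
Samples are binned per probe: low (β ≤ 0.3), moderate (0.3 < β < 0.7), high
(β ≥ 0.7). Boundaries are closed outward, so β = 0.3 is low and β = 0.7 is
high. Binning discards within-bin variation by design: with a handful of
samples per group and FFPE-grade noise, the bin occupancy pattern is a
robust summary, and it admits an exact test.

**Test.** The 2 (group) × 3 (bin) table is tested with a two-sided Fisher
exact test: conditioning on both margins, the p-value is the total
multivariate-hypergeometric probability of all tables whose probability does
not exceed the observed table's (the standard probability-mass rule for
r × c tables). Because each table probability is a ratio of products of
binomial coefficients, the implementation sums exact integers and divides
once at the end — there is no floating-point tie-breaking tolerance to tune,
and agreement with enumeration oracles is exact. Tables are cached, since
with ≤ 14 samples the same occupancy patterns recur across probes. A probe
with zero variance yields a single admissible table and p = 1; such probes
are still counted in the multiple-testing burden so that the number of tests
does not depend on the data.

**Calling.** Raw p-values are Benjamini–Hochberg adjusted across all tested
probes jointly (no stratification by context). A probe is significant iff
adjusted p < α and |Δβ| ≥ 0.3, where Δβ = median(tumor β) − median(normal
β); the sign of Δβ gives the direction (hyper/hypomethylated in tumor).
Using group medians (not per-pair differences) reflects the unpaired design.
Probes with any missing β among retained samples are dropped before testing
and counted in the log — the upstream normalization pipeline is assumed to
have produced a complete matrix for the retained cohort, and imputation of
array β values is out of scope.

**Probe filters.** Before testing, probes flagged as cross-reactive, at
polymorphic sites with minor-allele frequency > 5%, or on chrX/chrY are
removed (sex-mixed cohorts make sex-chromosome methylation a confound).
Removal counts are reported per reason, first matching reason wins.

## Differential expression

**Expressed-gene filter.** CPM = count × 10⁶ / library size; a gene is kept
iff CPM > 1 in strictly more than 80% of the samples of at least one group.
With 10 tumors and 4 normals this means ≥ 9 tumors or all 4 normals.

**Test.** Per gene, a negative-binomial GLM (log link) with an intercept,
a tumor indicator, and an offset of log total library size. The NB
dispersion α (var = μ + αμ²) is estimated by method of moments on
library-size-normalized counts, pooling the two groups' (ddof = 1) moment
estimates, floored at 10⁻⁸ — and additionally floored at the median of the
per-gene estimates across the matrix. The second floor matters: with ~14
samples the per-gene moment estimator is noisy, and its downward errors
alone inflate the Wald statistic; flooring at the genome-wide median borrows
strength across genes (the same motivation as the moderated estimators in
edgeR/DESeq2, in a far simpler form) and restores type-I error control
without meaningfully costing power at the planted effect sizes used here.
The Wald statistic on the group coefficient is referred to a t distribution
with n − 2 degrees of freedom rather than the normal, a small-sample
calibration choice. log2 fold change = coefficient / ln 2. Genes whose fit
fails or does not converge are flagged and assigned p = 1 rather than
dropped. BH adjustment across tested genes; significant iff adjusted
p < α, direction by the sign of the fold change.

This test is a transparent stand-in for full DE frameworks: no dispersion
shrinkage curve, no fold-change shrinkage, no outlier refitting. Its
contract is calibrated type-I error and BH-controlled calls. Note that the
total-count offset (like any total-count normalization) absorbs part of a
strongly asymmetric global expression shift; a median-of-ratios size factor
would be the next refinement.

## Signature scores

**Thyroid differentiation score (TDS).** For each sample, the mean over the
signature genes of (log2 expression − mean log2 expression in the normal
group). Zero means "expression of thyroid-function genes like normal
thyroid"; negative values indicate dedifferentiation. The normal-centered
mean was chosen for transparency; it is linear, so a uniform halving of
signature expression moves the score by exactly −1, and the normal samples
average to 0 by construction. The signature list is user-supplied.

**BRAF–RAS score (BRS).** Pearson correlation of the sample's log
expression with a RAS-like centroid minus correlation with a BRAF-like
centroid, over the genes shared between matrix and centroid file; score < 0
classifies the sample BRAF-like (matching the convention that BRAF-V600E-
like tumors score negative). Correlation-difference was chosen as an
operationalization because it is affine-invariant in the sample vector;
centroid provenance (e.g. cohort-derived mean profiles) is the caller's
responsibility, and the centroids packaged under `methx/data/` are
synthetic toys for tests only. A constant sample vector has no defined
correlation and is classified NA.

log2 expression throughout is log2(CPM + 1); the pseudocount of 1 keeps
zeros at zero and is the field's common default.

## Integration

**Quadrants.** Each significant probe in a promoter or gene body is paired
with its mapped gene's DE record. Four concordant patterns are kept:
promoter hypomethylation with upregulation, promoter hypermethylation with
downregulation, gene-body hypermethylation with upregulation, and gene-body
hypomethylation with downregulation — gene-body methylation tracks
expression positively, the reverse of promoters. Membership requires both
the probe's and the gene's significance; direction mismatches are counted
as discordant and probes whose gene is absent or non-significant as
unpaired. Counts are reported both as probes and as distinct genes, since a
gene can carry several probes. "Promoter" follows the array-manifest
vocabulary (TSS1500, TSS200, 5′UTR, 1st exon), "body" is Body/ExonBnd, and
everything else — including 3′UTR — is treated as intergenic for probe
context.

**Promoter Δβ vs fold change.** For genes with multiple significant
promoter probes, the median Δβ is used; the per-gene (Δβ, log2FC) pairs are
summarized by Pearson correlation (requires ≥ 3 matched genes and
non-constant inputs).

**Enhancer pairing.** A simplified supervised distal stage: for each
significant probe flagged as enhancer, up to k = 10 genes whose approximate
TSS (minimum promoter-probe position, falling back to the gene's first
probe) lies within 500 kb on the same chromosome are tested with a
one-sided exact Mann–Whitney rank-sum test on log2 CPM — hypomethylated
probes may only pair with genes higher in tumors, hypermethylated probes
only with genes lower (direction lock). BH adjustment is applied across all
probe–gene pairs and pairs with q < 0.05 are kept, with signed distance
(gene TSS − probe position). This deliberately replaces the full
permutation-based enhancer–gene machinery of dedicated tools: no empirical
p from random probe sets, no methylation-quantile grouping, and log2 CPM in
place of length-normalized expression.

## Synthetic data generator

The generator's defaults encode the emulated study: 10 tumors vs 4 normals,
2,000 probes and 2,000 genes, 10% hyper- and 10% hypomethylated probes, 10%
up- and 10% downregulated genes, full probe–gene linkage.

* **β baselines** come from a 50/50 mixture of a low Beta mode (mean ≈ 0.15)
  and a high mode (mean ≈ 0.85), reproducing typical array bimodality.
  Planted hypermethylated probes draw their baseline from the low mode
  (truncated so baseline + Δ ≤ 0.98) and shift the tumor mean up by exactly
  `delta_effect`; hypomethylated probes mirror this. Per-sample noise is
  Beta with concentration `beta_precision` (default 300, i.e. sd ≈ 0.02 at
  the modes), parameterized by mean/concentration so the planted shift is an
  exact mean shift before clipping.
* **DM is planted at the gene level**: all promoter (or body) probes of a
  chosen gene share one label and a gene carries at most one planted probe
  block, so quadrant ground truth is unambiguous.
* **Counts** use gene baselines from a log-normal prior (median 150,
  log-sd 1), library factors log-uniform over a 3-fold range (so CPM
  normalization is non-trivial), and NB noise (dispersion 0.1). Linked
  genes shift by `lfc_effect` (default 2 in log2) in tumors; enhancer-
  hypomethylated probes recruit the nearest otherwise-untouched gene within
  100 kb as an upregulated target. The per-sample library factors are kept
  in the ground truth so planted fold changes can be verified free of the
  compositional bias of total-count normalization.
* All draws flow from one seed through named substreams (manifest,
  methylation, counts, sample sheet), so adding a stage never perturbs an
  earlier stage's data.

**What passing tests show — and don't.** The recovery tests (sensitivity
≥ 0.85 / FDR ≤ 0.10 for DM, ≥ 0.8 / ≤ 0.10 for DE, quadrant sensitivity and
precision ≥ 0.8 at fixed seed) demonstrate that the implementation detects
the effects it is pointed at under the emulated design, and the permutation
tests that it stays calibrated under the null. The generator does not model
tumor-purity dilution of Δβ, FFPE degradation artifacts, probe-level
cross-hybridization noise, batch structure, or correlated probes beyond
shared gene blocks — real cohorts will sit well below these recovery
numbers, and the tests make no claim about them.

## Numerical choices and edge cases

* Fisher p-values are exact rationals evaluated once as a float; BH is the
  textbook step-up with monotonicity enforced from the largest rank.
* Degenerate inputs fail loudly: β outside [0, 1], negative or fractional
  counts, unknown context labels, groups with fewer than two samples, zero
  library sizes, empty signatures, constant correlation inputs.
* PCA (a convenience for cohort QC plots) uses the 1,000 highest-variance
  features, full SVD, and a deterministic sign convention (the largest-
  magnitude loading of each component is made positive).
* Problem sizes in the test suite and acceptance study (2,000 probes /
  2,000 genes) were chosen so that every planted structure is represented
  tens to hundreds of times while a full run stays in the seconds range;
  the callers scale linearly in probes/genes.

## Known limitations

* The binned Fisher test is conservative (exact tests on tiny tables), so
  with 4 normals the raw-p null fraction sits well below nominal; power
  comes from the |Δβ| effect rule rather than fine p resolution.
* BH across all tested probes treats probes as exchangeable; no context
  stratification or probe-correlation correction.
* The DE stand-in makes no claim of matching shrinkage-based frameworks
  gene-for-gene.
* Enhancer pairing inherits every simplification listed above; its pair
  lists are not comparable to full enhancer-analysis pipelines.
* Gene TSS positions are approximated from probe coordinates; with sparse
  promoter coverage the approximation degrades.
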