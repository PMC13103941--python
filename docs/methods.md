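# Methods

This note documents the statistical procedures `oscellkit` implements, the
generative models behind its synthetic data, the numerical and design
choices that were genuinely open, and the limits of what the test suite
demonstrates.

## Barcode quality control

Filtering is applied to each sample independently, as one conjunction of
three filters on the sample's original BarcodeQC table (no sequential
re-fitting after removals — the filters are described as successive steps,
but re-fitting after each removal would make the result order-dependent;
the joint decision is logged per step so users can compare).

**Two-step regression filter.**  Both an ordinary least-squares line and a
LOESS curve are fit with log *nUMI* as predictor and log *nGene* as
response (natural logarithms; the residual cutoff is therefore in
natural-log units).  A barcode is a low-complexity outlier iff

* its LOESS residual is below `loess_cut` (default −4), and
* its OLS Cook's distance D_i = e_i²·h_ii / (p·MSE·(1−h_ii)²), p = 2,
  exceeds `cooks_multiplier / N` (default 4/N).

The conjunction matters: a deep residual with no influence (a point near
the x-center of a tight cloud) or influence without a deep residual never
flags.  Cook's distance computed by this hat-matrix formula equals the
leave-one-out refit definition; the test suite verifies agreement to 1e-8
on random regressions.  When the fit is essentially perfect
(SSE ≤ 1e-12 × TSS) Cook's distance is a 0/0 ratio and is resolved to 0.

LOESS uses the classical algorithm: tricube weights over the
⌈span·n⌉ nearest neighbors, local polynomial of degree 2, no robustness
iterations (span 0.75 and degree 2 are defaults, config-exposed; they are
conventional values, chosen here because the procedure itself does not pin
them down).  For tables above 2,000 barcodes the curve is evaluated on a
401-point x-quantile grid and interpolated linearly; on exactly collinear
input this is still exact.

**Fixed cutoffs** are strict inequalities: keep requires nUMI > 1000,
nGene > 200, %mito < 25, %hemoglobin < 25.  A barcode at exactly 1,000
UMIs fails.

**MAD cutoffs**: %mito above median + k·MAD and nUMI below median − k·MAD,
k = 2.5, MAD = `mad_scale` × median(|x − median|).  `mad_scale` defaults to
1.4826 (consistency with the normal distribution, the default of the usual
statistical environments) but is exposed because the plain phrase "median
absolute deviation" is ambiguous about the constant.  A zero MAD
degenerates the threshold to the median; the code warns and still applies
it (values strictly beyond the median are flagged).

## Marker and module scores

Markers are one-vs-rest per cluster: pct.1/pct.2 are expressing-cell
fractions ("expressing" = normalized value > 0, no minimum threshold),
avg_log2FC = log2((m₁+1)/(m₂+1)) on de-logged (expm1) means with
pseudocount 1 — documented as approximate, not bit-compatible with any
particular release of the common single-cell toolkits — and p-values come
from the Wilcoxon rank-sum normal approximation with tie and continuity
correction, BH-adjusted within cluster.  The marker priority score is
(pct.1 − pct.2) × avg_log2FC, which zeroes out genes expressed everywhere
no matter how large their fold change.

The module score bins all genes into `n_bins` = 24 near-equal bins by mean
expression (stable order breaks ties) and, for each member gene, samples
`n_ctrl` = 100 control genes uniformly from its bin (without replacement
when the bin is large enough).  score(cell) = mean member expression −
mean control expression, computed relative to an anchor member row so a
constant matrix scores exactly zero in floating point.  The score is
invariant to adding a constant to the whole matrix and is deterministic
under a fixed seed via a dedicated child RNG stream.

Cell-cycle phase: S if the S score leads and is positive, G2M if the G2M
score is at least as large and positive, else G1.  Responder-high cells are
those strictly above the median score of the pooled malignant population —
pooled across all samples, never per sample, so between-sample shifts in
the score translate into between-sample responder proportions.

## Pseudobulk and compositional statistics

All group comparisons run at the replicate (sample) level.  Pseudobulk
matrices are exact integer UMI sums per sample for one cell type.
Expression comparisons use Welch t-tests on log2(CPM+1) with BH control and
report log2 fold changes of mean CPM (pseudocount 1); this is a documented
substitute for negative-binomial likelihood-ratio machinery, and the
interfaces equally accept an externally produced DE table in the same
schema.  The three-group design is handled as pairwise contrasts, each with
its own BH pass, mirroring how such designs are usually reported.

Composition testing transforms per-sample unit proportions with
t(p) = asin √p and compares groups per unit with a **pooled-variance**
two-sample t-test, BH-adjusted across units within each pair.  Pooled
rather than Welch is a deliberate choice: the arcsine-square-root transform
stabilizes the sampling variance (≈ 1/(4n) regardless of p), so group
variances are equal by construction under the null, where the pooled t is
exact-level; at 3–4 replicates the Welch–Satterthwaite approximation is
measurably conservative (the reproduction script puts its null rejection
rate near 0.08 at nominal 0.1 versus ~0.095 pooled).  Both-groups-constant
rows resolve to p = 1 when means agree and p = 0 otherwise.

Fisher's exact test sums hypergeometric probabilities (margins fixed) of
all tables at most as probable as the observed one (with the customary
(1+1e-7) tie guard) and reports the cross-product odds ratio; a zero margin
returns p = 1 with a warning.  The suite checks it against full enumeration
for every 2×2 table with positive margins and N ≤ 40.

## Differential CNV analyses

Inputs are cells × genes matrices over the 6-state alphabet
{0, ½, 1, 1½, 2, 3} (1 copy-neutral; 0 a deep two-copy deletion; ≥ 2 a
high-level amplification) as emitted by HMM CNV callers.  Copy-neutral
reference cells (e.g. macrophages) are expected to be excluded upstream by
a metadata filter; the module is agnostic.

* **Burden**: per cell, the number of genes with state ≠ 1, and the extreme
  counts (state 0; state ≥ 2).
* **PCA**: top `n_features` = 1000 genes by plain variance (not
  dispersion-normalized — state values are already on a common scale),
  centered per gene, SVD projection.
* **Centroid-distance heterogeneity test**: replicate centroid = mean PC
  coordinates of the replicate's cells; group centroid = unweighted mean of
  replicate centroids; each replicate's Euclidean distance to its group
  centroid is the heterogeneity measure, compared between groups by
  two-sample t-test over K = 10 components (K is exposed; the procedure
  itself does not fix it).
* **DiffAmps_mean**: per-sample mean state per gene, exact two-sided
  Wilcoxon rank-sum between groups (full enumeration of the midrank-sum
  distribution whenever the smaller group has ≤ 10 replicates; normal
  approximation with tie correction above).  At 3-vs-3 the smallest
  attainable two-sided p is 2/C(6,3) = 0.1 and at 4-vs-3 it is
  2/C(7,3) = 2/35 ≈ 0.057 — an intrinsic floor that explains asymmetric
  detection between unequal designs and motivates the exploratory p < 0.1
  threshold.
* **DiffAmps_count**: per-sample proportion of cells with state ≥ 2 (amp
  mode) or state 0 (del mode) per gene, asin √p transformed, pooled
  two-sample t-test (same variance-stabilization rationale as above).
* **Candidate selection**: genes with DiffAmps p < 0.1 that the matching
  expression contrast also calls significantly up (fdr < 0.05, positive
  direction) — amplification without over-expression is not reported.

**Known small-sample behavior of the centroid-distance test.**  Distances
from replicate centroids to a group centroid *fitted from the same
replicates* are negatively correlated, follow a chi-type rather than normal
distribution, and are deflated by a group-size-dependent factor
(√(1−1/n_g)), so a t-test on them rejects a true null more often than its
nominal level at 3–4 replicates per group; the effect shrinks as replicate
counts grow and is not an artifact of any particular data generator.  The
reproduction script measures this rejection rate (typically 0.08–0.11 at
nominal 0.05 for the 4-vs-3 design) alongside the test's power, which is
high.  Users should read the test's p-values as descriptive of relative
heterogeneity, not as exactly calibrated — consistent with its use at a
secondary, exploratory stage.

## Subtype calling and cross-species scoring

Atlas labels are simplified by stripping a trailing space-plus-integer
suffix (only that pattern; punctuation variants are left untouched).  A
tumor's pathologic subtype is the argmax of transferred-label proportions
over its malignant cells; exact ties break lexicographically with a tie
flag.  Ortholog tables are filtered to strictly one-to-one pairs (a source
kept iff it maps to a single target mapped from no other source).
Cross-species scoring translates each source marker set through the
filtered orthologs, module-scores it per target cell, averages within
target cell type, and clusters the Pearson correlation of the source-set
rows (average linkage on 1 − r; Pearson and average linkage are
conventional defaults, config-exposed).  Constant score rows are excluded
from the correlation with a warning.

## Survival

Per-patient signature scores reuse the module-score procedure on the bulk
matrix with the same binning parameters.  Patients strictly above the
median score form the high stratum (at an atomless score distribution this
equals "≥").  Kaplan–Meier estimation and the log-rank test delegate to
`lifelines`; events precede censoring at tied times.  Zero events overall
make the log-rank test undefined; p = 1 with a warning.

## Proteomics

Intensities are log2-transformed and each sample is centered at its
observed mean.  Missing cells are imputed from
N(μ_s − `shift_sd`·σ_s, (`width_frac`·σ_s)²) per sample, with
`shift_sd` = 2 fixed by the procedure and `width_frac` = 0.3 a common
downshifted-imputation convention (the width is otherwise unspecified);
a global pooled mode exists.  The imputation mask marks exactly the
originally missing cells and observed values are never altered.  The PCA
outlier screen flags a sample whose distance from the remaining samples'
centroid exceeds 3× their own mean distance — advisory only; dropping a
sample requires an explicit flag, keeping the decision with the analyst.
Differential abundance is a per-protein Welch t-test on processed values
with BH control.

## Synthetic data: what it emulates, and what it does not

All generators derive their randomness from a single seed through fixed,
named child streams, so outputs are bit-for-bit reproducible and adding one
generator never perturbs another.

* **Counts**: good barcodes draw totals from LogNormal(meanlog 8,
  sdlog 0.6) (median ≈ 3,000 UMIs) and spread them over a rank-power-law
  profile (exponent 1.2), which yields the approximately log-linear
  nGene–nUMI relation the QC regression assumes.  Mitochondrial fractions
  follow Beta(2, 48) (mean 4%); planted high-mito barcodes draw
  Uniform(0.25, 0.75).  Planted RBC-like barcodes are transcript-rich
  (totals from LogNormal(meanlog 8.5, sdlog 0.4)) and nearly pure
  hemoglobin — 4 Hb genes plus ~Poisson(0.5) stray UMIs.  That purity is a
  requirement of the physics of the −4 natural-log residual cutoff, not a
  tuning knob: at e⁴ ≈ 55× below the expected gene count, only droplets
  detecting a handful of genes can qualify, which is what real erythrocytes
  look like.  Differential expression (50 genes at ±2 log2 units by
  default) is planted in the first group's malignant cells on a fixed gene
  block shared with the CNV simulator, so amplified genes are also
  over-expressed and the candidate-intersection step has planted truth.
* **CNV states**: background genes are state 1 in ≥ 95% of cells with
  symmetric mild noise and a small extreme rate; planted genes carry
  state ≥ 2 in a per-group fraction of cells.  Replicate heterogeneity
  enters as Normal(0, dispersion) perturbations of each replicate's
  per-gene amplification probability; within a sample, per-gene state
  counts are assigned to round(p·n) randomly chosen cells, so zero
  dispersion gives exactly identical replicate mean profiles and the
  planted fraction is hit exactly.
* **Survival**: latent standard-normal patient scores shift signature-gene
  expression additively and set the event hazard to
  baseline·exp(effect·score); censoring is an independent exponential plus
  an optional administrative horizon.
* **Proteomics**: true log2 abundances are Normal(22, 2.5) with
  Normal(0, 0.3) sample noise; dropout probability is a decreasing logistic
  in abundance whose intercept is solved (Brent) to hit the target overall
  missing rate, giving missing-not-at-random structure.  The planted
  group shift is 3 log2 units: an a priori power analysis (noncentral t at
  3-vs-3 with BH across ~1,500 mostly-null proteins) shows smaller shifts
  cannot clear fdr < 0.05 with useful frequency at these replicate counts,
  and the recovery test asserts the recall actually achievable (≥ 0.25
  overall, with ≥ 95% sign accuracy among discoveries).

The generators deliberately omit doublets, ambient RNA, batch effects,
sequencing-read-level noise and real transcriptome covariance.  Passing
recovery tests therefore demonstrates that the procedures are implemented
correctly and behave as designed under their own assumptions — not that
they are robust to every artifact of real droplet data.

## Study sizes used by the checks

The test suite and reproduction script run the QC study at 10,000 barcodes
(one sample), the DiffAmps and centroid studies at 4-vs-3 samples × 300
cells with 60–100 CNV genes and 200 Monte-Carlo replicates, composition at
4-vs-3 × 500 cells × 200 replicates, survival at 200 patients × 200
replicates, and proteomics at 1,500 proteins × 10 samples — sizes chosen so
each study estimates its rate with useful precision while the whole battery
stays a desk-scale computation.

## Known limitations

* The LOESS fit is the classical non-robust variant; heavy contamination
  (≫ 5% planted outliers) will bend the curve toward the outliers and cost
  sensitivity.
* Expression DE is a t-test substitute, intentionally simpler than
  negative-binomial engines; it needs ≥ 2 replicates per group and has no
  dispersion shrinkage.
* The centroid-distance heterogeneity test is anti-conservative at few
  replicates (see above).
* Exact Wilcoxon enumeration caps at C(n, n_a) ≤ 200,000 combinations;
  beyond that the tie-corrected normal approximation is used.
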