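# Methods

## Scope and model of the data

The package analyzes digital gene expression (DGE) matrices from
droplet-based single-cell RNA-seq of multi-animal, two-arm cohorts: a
tumor compartment forming a differentiation continuum (granule-neuron
progenitor–like cells maturing toward a neuronal phenotype) embedded in
discrete stromal populations (astrocytes, oligodendrocytes, microglia,
endothelium, fibroblasts, pericytes). Counts are nonnegative integers
(UMIs); each barcode belongs to one animal and one treatment arm. All
cohort-level inference treats the **animal as the unit of replication**:
per-cell labels are collapsed to per-animal fractions before any arm
comparison. Per-cell tests (the ANCOVA interaction on imputed expression)
carry an explicit pseudo-replication caveat in their output.

## Quality control

Filters apply in a fixed order — species purity, barcode QC, gene floor —
and the QC report reconciles counts exactly against that order.

* **Species purity** (species-mixed runs): a barcode is kept when its
  target-species fraction strictly exceeds 0.90; foreign gene rows are
  dropped afterwards. Single-species matrices pass through unchanged.
* **Barcode QC**: removed when totals ≤ 500 UMIs, detected genes ≤ 500,
  either quantity exceeds center + 4.5·SD, or the mitochondrial count
  *fraction* exceeds center + 4.5·SD. The conventional criterion is a 4–5
  SD band tuned per sample by inspection; we resolve it to a single configurable
  multiplier (default 4.5) and warn when configured outside [4, 5]. The
  center is the median by default (mean optional) and the spread is the
  classical SD; both statistics are computed within one animal's sample
  (batch scope). Lower bounds are strict; in the degenerate SD = 0 case
  ties at the center are kept. Removal categories are assigned
  sequentially (low content → high content → high mito) so they sum
  exactly.
* **Gene floor**: genes detected in < 30 barcodes are dropped, except
  transgene-flagged genes (lineage-reporter calls need them even when
  rare). The 500-gene barcode floor is evaluated on the raw matrix,
  independent of the gene floor.
* **Normalization** (a package choice — the original protocol leaves it
  unstated): per-cell scaling to 10,000 counts followed
  by log1p, so zero counts map to zero and the transform is scale
  invariant per cell.

## Reduction and clustering

Variable genes: per-gene mean and dispersion (variance/mean) of the
log-normalized values; genes sorted into 20 equal-width mean bins (the bin
count is a package default; configurable) and dispersion z-scored within
bins; selection by mean ∈ (0.125, 3) and z ≥ 0.5.

PCA: exact SVD of the centered, unit-scaled variable-gene matrix.
Component signs are fixed (largest-|loading| gene positive) for
determinism. Cell embeddings are the variance-weighted scores (U·S), so
distances in PC space reflect each component's variance. Significant
components are those whose share-of-variance z-score exceeds 2; a
configured exclusion list supports manual rejection of technical axes
(the mechanism for rejecting a batch-effect component by hand); there
is deliberately no automatic batch detection. An explicit component count
may be supplied instead, mirroring manual curation.

**Library-size residualization.** The workflow layer regresses log total
counts out of each scaled gene before the SVD (optional, on by default).
Without it, the log1p transform leaves a depth-dependent shift on every
expressed gene, and community detection splits homogeneous populations
into sequencing-depth strata — the familiar nUMI artifact that
regression-based scaling in contemporary toolkits exists to remove. The
reference-projection path fits its PCA without residualization so that
projecting a reference cell's own expression reproduces its stored
embedding exactly.

Clustering: kNN graph (k = 30, Euclidean, in significant-PC space), edge
weights = Jaccard index of self-inclusive neighbor lists, edges below 1/15
pruned; modularity maximization (RB-configuration, Leiden refinement of
the Louvain scheme, recorded in metadata) at resolution 0.8, seeded and
deterministic. Labels are re-indexed by cluster size.

Nodes: cluster centroids in significant-PC space are merged by
average-linkage agglomerative clustering (linkage recorded in the result);
the dendrogram is cut to a requested number of nodes, optionally within a
designated subtree (the tumor multi-cluster complex). Average linkage
guarantees non-decreasing merge heights.

## Differential expression and doublet clusters

Expression of a gene is modeled as a point mass at zero mixed with a
log-scale normal. Group fits use the MLE (detection probability, positive
mean, positive variance; variance floored at 1e-6 for the single-positive
degenerate case); the LRT compares pooled vs per-group fits on 3 df.
Genes silent in both groups report p = 1 and logFC = 0; logFC is the
difference of group means of normalized expression; BH adjustment
throughout (the correction method is a package choice). A null
simulation (zero-inflated log-normal, 200 genes × 100 replicates, 100
cells per group) shows the nominal 5% level is held (~0.05) with uniform
p-values.

Doublet clusters: for each cluster and each candidate parent pair, count
genes that are significant (adj. p < 0.05) with |logFC| < 0.5 and
detection > 0.25 in both groups, against *both* parents; ≥ 50 such genes
flags the cluster. The qualitative signature — many genes of low
fold-change with high percent expressing — needs explicit thresholds;
these defaults make
it explicit and configurable, and the flag carries its evidence.

## Reference projection

A frozen reference holds variable-gene scaling constants, gene loadings,
per-component variances, the significant-component list, embeddings, 2-D
layout and labels. Query cells: restrict to shared variable genes (error
below 50% overlap), rescale with the *reference* constants (missing genes
contribute the centered zero value), multiply by the loadings. Because the
reference embeddings are the variance-weighted scores, this reproduces
them exactly on reference cells. Placement: K nearest reference cells by
Euclidean distance over significant components (ties broken by reference
index, stable and deterministic); the placed coordinate is the arithmetic
mean of the neighbors' layout rows; the label is the majority vote
(confidence = vote fraction; vote ties resolve to the nearest neighbor's
label). K defaults to 5; K = 3 is an equally defensible convention for
this placement, and the K actually used is recorded in the output
metadata rather than silently assumed.

## ICA trajectory

Stromal clusters are removed, variable genes are re-selected on the tumor
subset, and fixed-point ICA (logcosh contrast, deflation, seeded) runs on
the per-gene z-scaled matrix, whitened to unit-variance sources.
Components are sign-oriented so the heavier weight tail is positive and
ordered by score kurtosis. The component count defaults to the number of
significant PCA dimensions of the same subset; the pipeline pins it to 4
because a dominant gradient axis can leave the z > 2 rule overly
conservative on the subset, and four components reliably separate the
gradient, cycle and pathway axes in this setting. The
differentiation component maximizes differentiation-marker enrichment in
the top-50 positive vs negative weight tails (proliferation markers act
only as a tie-break, expected at the opposite end); orientation makes the
differentiated end positive. Cell-cycle phases: mean z-scored expression
of four canonical phase gene lists (editable YAML resource); argmax
assignment, "low-cycling" when no score is positive.

## Imputation and correlation

Dropout masks gene–gene relationships; information is shared across
transcriptomically similar cells. Operator: kNN graph (k = 12, as in the
source; self-inclusive) in significant-PC space; adaptive Gaussian kernel
with bandwidth = distance to the ⌈k/3⌉-th neighbor (uniform fallback for
coincident points); symmetrized and row-normalized. Imputation multiplies
expression by the operator's t-th power (t = 3 by default;
configurable and reported in the output). Row-stochasticity preserves
constants and makes per-gene variance non-increasing in t. Correlation:
Pearson r with t = r·√((n−2)/(1−r²)) and a two-sided t-test on n−2 df;
zero-variance inputs are flagged rather than silently dropped. The ANCOVA
`target ~ regulator × arm` reports per-arm slopes and the interaction
F-test.

## Cohort statistics

Fractional population tables divide each animal's group counts by its
total; rows sum to one. Arm comparisons: one-way ANOVA or two-sample t
(identical for two arms, F = t²), with p = 1 by convention for degenerate
zero-variance equal-mean inputs. Marker-positive fractions are
count-backed; a group absent in an animal is missing, not zero. The
two-way ANOVA on rates uses cluster-group and animal as fixed factors
(animal as the second factor keeps the replicate structure explicit) with Bonferroni-adjusted pairwise group contrasts.
Fisher's exact test follows the standard two-sided convention (sum of
table probabilities ≤ the observed table's) with the conditional-MLE odds
ratio; a zero margin gives p = 1. The signature-overlap test is the
upper-tail hypergeometric. Fold change is offered both as ratio-of-means
and mean-of-per-animal-ratios with SEM (the two differ slightly, and fold changes reported in the literature
are often the mean-of-ratios rather than the plain ratio); an observed-zero
denominator is reported as a lower bound against the one-count fraction.

## The synthetic cohort generator

The generator draws, per cell, a library size (negative binomial;
dispersion 0 yields a constant library) allocated by a multinomial over a
per-cell probability vector: the population program, mixed with an
ambient pool (fraction 0.02, the pooled fraction-weighted program average)
and a mitochondrial component (per-cell fraction from a Beta(2.5, 60)
base with a 3% Beta(40, 10) "dying cell" tail). Default cohort: five
animals per arm, ~300 cells per animal — six stromal populations (25
cells each) and one trajectory population (150), matching the replicate
structure of the emulated study at desk scale.

Programs share one housekeeping profile (800 genes, log-normal weights)
and differ through: a strong on/off 32-gene marker block per stromal
population (includes the canonical markers used for cell typing); 100
moderately expressed genes drawn per population from a shared 400-gene
pool (their graded overlap produces the low-fold-change doublet
signature); 130-gene early and late trajectory blocks interpolated
linearly along pseudotime, with the non-canonical fill genes also present
in stroma at the trajectory-average level (differentiation-stage genes
are tissue-wide, so the continuum appears as a gradient axis rather than
a tumor-identity axis); four 12-gene cell-cycle phase sets boosted in
cycling cells (cycling probability declines along pseudotime); a
100-gene pathway module and the regulator/target pair (Sufu, Gli1)
jointly modulated by a per-cell latent z — the module identically in both
arms, the target with an arm-dependent sign. Pseudotime is drawn from a
three-tier mixture: each cell's tier is sampled from the arm's tier
weights and its position within the tier from a Beta(3,3) hump occupying
the central 70% of the tier's span, leaving a real density gap between
tiers — the emulated continuum presents as distinct stage clusters along
a gradient, which is what makes tiers recoverable as dendrogram nodes. Every gene also
carries a leaky 2e-5 baseline. Per-cell log-normal program noise
(σ = 0.35, comparable to the biological-CV parameters of standard
scRNA-seq simulators) gives populations realistic internal spread. Treatment
multiplies population fractions (tumor × 0.45), shifts tier weights
toward the differentiated end, and flips the coupling sign. Doublets are
within-animal sums of two distinct singlets (rate 0.05); spike-in
barcodes (4%) draw from a human-gene program, chimeric barcodes (2%) from
a 20–80% species mixture; the Yfp lineage reporter is expressed with
population-specific probability (0.8 tumor, 0.08 astro/oligo). Ambient
and doublet rates have no canonical values; these defaults are explicit,
configurable placeholders.

**What the generator does not emulate** — and therefore what passing
tests do not certify on real data: read- and UMI-level artifacts
(barcode errors, UMI collisions), batch chemistry beyond a per-animal
library-size scalar, cross-population library-size differences (cell
size), gene–gene correlation structure beyond the programmed pathway
module, empty droplets, and the long-tailed cluster-size imbalance of
real tissue.

## Numerical and reproducibility choices

All randomness flows from numpy `default_rng` seeds; the pipeline derives
fixed per-stage offsets from one global seed and reruns are byte
identical (the t-SNE runs single-threaded Barnes-Hut with a fixed seed).
Nearest-neighbor ties break by index via stable argsort. Problem sizes in
the validation suite — ~3,300-barcode cohorts, 20-seed doublet trials,
100-replicate calibration nulls — were chosen as the smallest scales at
which the recovery properties are stable, and are stated in each test.

## Known limitations

The variance z > 2 component rule is sensitive to a single dominant axis
(a spectrum with one large and several medium components can under-select);
the explicit-count override exists for exactly that case. The pooled
library-size regression under-corrects population-specific genes (≈ the
population's share of the slope remains). The bimodal LRT treats cells as
independent within groups. Diffusion imputation can only recover
correlations whose latent drivers are encoded in the kNN geometry;
coupling invisible to the embedding is smoothed away, and imputed values
must never be fed back into differential-expression testing.
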