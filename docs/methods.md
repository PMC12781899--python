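# Methods

`spotmap` maps annotated single cells from scRNA-seq onto the spots of a
sequencing-based spatial-transcriptomics (ST) section, producing a
single-cell-resolution spatial map and per-spot cell-type proportions. This
note documents the model, its assumptions, the tunable parameters, the
synthetic-data generator, and the numerical choices made where the design
was genuinely open.

## Pipeline model

Inputs are a reference expression matrix `X` (m genes × n cells) with one
cell-type label per cell (k types), and an ST matrix `S` (p genes × q spots)
with 2D spot coordinates. Both are library-size normalised to a fixed total
(default 10,000) and log1p transformed; any other variance-stabilising
transform can be plugged in by writing the `norm` layer directly, since
every downstream step consumes only that layer and relies on
correlation/cosine structure, which is robust to the exact transform.

### 1. Feature genes

*Seed genes.* Expression is averaged per type into `Y` (m × k). The fold
change of gene i in type j is

    FC[i,j] = Y[i,j] / (Σ_l Y[i,l] − Y[i,j]) · (k − 1),

the ratio of the type's mean to the average of the other types' means. A
gene expressed in exactly one type has a zero denominator; ε = 1e-9 is
substituted only in that case so that equal-expression genes keep FC exactly
1 while single-type genes stay finite and dominant. Because ratios of small
means are noisy, FC is damped by `tanh(λ·W_i)` with λ = 0.1, where `W_i` is
the gene's median per-type expression divided by the median of those medians
over genes. The factor approaches 0 for lowly expressed genes and saturates
at 1 for abundant ones; note that `W` is a ratio, so a global rescaling of
the data leaves the weighted fold change unchanged. The top `seed_num`
genes per type (default 30, following the sensitivity analysis optimum; 10
is available via config) are that type's seeds, ties broken by gene id.

*Signal matrix.* Genes are z-scored across cells (population s.d.;
zero-variance genes are zeroed and excluded from the tests below) and the
cells × genes matrix is reduced by PCA. The gene representation
`Q = diag(σ)·Vᵗ` (t components × m genes, principal axes scaled by singular
values) preserves the gene–gene cosine structure of the z-scored data while
discarding low-variance noise directions. t is the smallest number of
components explaining 90% of the variance, capped at 50 and floored at 4
(the Fisher test below needs t > 3).

*Co-expression expansion.* For each type, every gene's Q column is
correlated with the mean Q column of the type's seeds (a single well-defined
target that stays stable when seeds are few). The correlation is Fisher-z
transformed, `z′ = artanh(r)` with |r| clamped below 1 − 1e-12, and referred
two-sided to N(0, 1/(t−3)); the effective sample size of the test is the
number of retained components. Genes with p < 0.01 join the type's set; a
gene may belong to several types. The union G of seeds and significant
genes is the only gene set used downstream.

### 2. Label transfer

Spots are clustered on expression (PCA → shared-nearest-neighbour graph →
Leiden at resolution 0.8). Leiden is used rather than classic Louvain
because it is the current default of the major single-cell toolchains and
its implementation takes an explicit seed, which the pipeline's determinism
contract requires; with fewer than three spots a single cluster is
returned.

Cells and spots are integrated over G with a CCA-style projection: each
gene is standardised within its dataset (removing per-gene batch offsets),
and the SVD of the cell-by-spot cross-product yields paired canonical
vectors (d = 20 components by default), each L2-normalised. UMAP
(n_neighbors = 30, min_dist = 0.3, fixed seed) projects the joint space to
2D. A config switch (`distance_space="pca"`) computes distances in the
shared space directly instead; the 2D embedding is the default because it
separates populations more cleanly in practice.

Each spot's k nearest cells in the 2D embedding (k = 1 for high-resolution
platforms, 5 for low-resolution) inherit the spot's cluster label; a cell
wanted by several spots keeps the nearest spot's label, exact ties going to
the lexicographically first spot id. A random forest (1000 trees, fixed
seed) trained on the labelled cells' normalised G-gene expression then
predicts a cluster for every cell in the reference. With a single training
label the classifier degenerates to a constant predictor with a warning.

### 3. Cell counts per spot

Genes whose raw-count variance across spots is below 0.5 (unbiased, n−1
convention) are "stable genes" — consistently expressed sentinels of
cellular content. The summed stable-gene counts per spot, relative to the
across-spot mean, scale the platform prior `mean_cell_num` (1
high-resolution, 5 low-resolution) into a per-spot count:

    n_s = round(spot_expr / spot_mean · mean_cell_num),

rounded half-up and clamped to ≥ 1 so every spot can receive a cell. If no
gene passes the threshold, the 5% lowest-variance expressed genes are used
instead (with a warning). Raw counts follow the formula literally; a
normalised-layer option exists because raw-count variance is
sequencing-depth sensitive.

### 4. Assignment

Within each cluster, the cosine similarity between every cell and every
spot is computed over G (zero-norm vectors score 0 with a warning). Each
spot is expanded into `n_s` sub-spots by replicating its similarity column;
cost is `1 − similarity`. Cells are matched to sub-spots by a rectangular
linear sum assignment (scipy's Jonker–Volgenant-class solver, no square
padding):

* n′ ≥ N: every sub-spot receives exactly one distinct cell; surplus cells
  are reported unassigned rather than silently dropped (assigning *every*
  cell is infeasible in this regime).
* n′ < N: the one-to-one problem is solved first so every cell is placed at
  least once, then each remaining sub-spot takes the cell most similar to
  its spot (duplicates permitted and flagged; argmax ties go to the
  smallest cell id).

Unassigned cells are not recycled across clusters. If a cluster contains
spots but no predicted cells, all cells are offered to it (with a warning)
rather than leaving its spots empty. Assigned cells inherit their spot's
coordinates (an optional seeded jitter is available for plotting only);
per-spot type proportions come from the assigned cells' annotations, and
spots with no cell are excluded from the proportion table with a warning.

## Benchmark metrics

Per cell type across spots: Pearson correlation; SSIM on
min-max-scaled columns with constants C1 = 0.01 and C2 = 0.03 entering as
C1², C2² (the numerator uses the plain product of means — identical inputs
still score exactly 1, but users comparing against image-SSIM
implementations should expect different intermediate values); RMSE on
z-scored columns (invariant to affine maps; a raw-proportion RMSE is also
reported because the simulation benchmark's error is on the proportion
scale — z-scored RMSE is numerically incompatible with error magnitudes
like 0.03 at correlation 0.97); Jensen–Shannon divergence of the
column-normalised spatial distributions (natural log by default, base-2
option, bounded by log 2). Dataset-level: ACCU, the fraction of spots whose
dominant predicted type matches the truth; and AS, the mean over the five
per-metric ranks across methods (best = N), divided by N so a method
dominating every metric scores exactly 1 — the plain rank mean is available
via `normalize=False`.

The ground-truth-free evaluation correlates, per spot across types, the
predicted proportion vector with marker-signature scores: markers are the
top 100 genes per type by log fold change among rank-sum-significant genes,
and a signature score is the mean marker expression minus the mean of an
equal-sized background drawn (seeded) from 25 expression bins matched to
the markers. Spatial layering is quantified by the k-distance: the mean
Euclidean distance of each query cell to its k = 10 nearest reference
cells.

## Synthetic data

The generator plants k disjoint marker blocks (25 genes per type by
default) elevated 8-fold over a negative-binomial background (size 2).
Background gene means are log-normal with median 0.05 and σ = 1.5 on the
log scale, spanning the several orders of magnitude of real references —
the heavy low-expression tail matters because the stable-gene count
estimator needs genes whose across-spot variance stays small even when
spots sum many cells. Default fixture: 2000 cells, 6 types, 1000 genes,
500 spots.

The Poisson protocol draws each spot's cell count from Poisson(λ) clamped
to ≥ 1 (no empty spots), samples cells uniformly — or, with
`dominant_frac > 0`, biased toward the spot's stripe of a type-blocked grid,
emulating spatially organised tissue — sums their counts and applies the
perturbation. The template protocol splits the reference per type 1:1
(train takes the ceiling on odd counts), selects the top 2000 variable
genes by binned dispersion on the train half, integrates train cells with
the template via the same CCA + UMAP embedding as the pipeline, aggregates
each spot's k nearest train cells into the spot's expression, applies
noise, and returns the held-out test half as the mapping reference.

"Transcriptional perturbation" multiplies each count by `1 + e`,
`e ~ N(0, level)`, rounding half-up and clamping at zero; an additive mode
is available. On desk-scale fixtures most counts are small integers, so 5%
and even 20% multiplicative noise frequently rounds back to the original
value: recovery is tie-dominated at these levels, and the noise-degradation
checks therefore assert that noise never *improves* recovery beyond a
0.002 jitter allowance rather than a strict decline (the full-scale
original analysis shows the same plateau between 0% and 5% noise).

What the generator does **not** emulate: continuous transcriptional
gradients and intermediate cell states, platform-specific capture noise,
segmentation errors, histology-realistic spatial patterns beyond blocked
stripes, and ambient/background contamination. Passing tests demonstrate
the correctness of the algorithmic chain under the stated model, not
performance on any particular tissue.

## Problem sizes and determinism

The shipped study fixtures are deliberately desk-scale: 2000 cells ×
1000 genes × 500 spots for the recovery and label-transfer analyses, 200
spots per λ for count estimation, and 200 random instances (≤ 7 cells,
≤ 7 sub-spots) for the exhaustive optimality check. One global seed drives
every stochastic step (generators, PCA/UMAP, Leiden, the forest, background
draws); two runs with the same config and seed produce byte-identical
output files.

## Known limitations

* Per-cluster assignment confines each cell to spots of its predicted
  cluster; when clusters align perfectly with cell types the predicted
  spot compositions become one-type-dominated, which slightly sharpens
  mixtures (visible on well-separated synthetic data).
* The duplication fallback fills all of a spot's remaining sub-spots with
  the single most similar cell, which under-represents minority types
  within a spot when cells are scarce.
* Raw-count stable-gene variance is depth-sensitive; the normalised option
  is preferable when spot depths vary strongly.
* The AS score's normalisation (divide by the number of methods) makes
  scores comparable across panels of different size but is not the only
  convention in use; the raw rank mean is exposed for compatibility.
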