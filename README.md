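# spotmap

Sequencing-based spatial transcriptomics (10x Visium, classic ST, and their
high-resolution successors) measures expression at capture spots that mix
one to many cells, while scRNA-seq resolves individual cells but loses
their positions. `spotmap` joins the two: given an annotated single-cell
reference and an ST section, it assigns each cell to a specific spot —
producing a single-cell-resolution spatial map and, as a by-product, the
cell-type composition of every spot. It is aimed at computational
biologists dissecting tissue architecture (tumour microenvironments,
cortical layering, zonated organs) who have paired SC/ST data from the
same tissue.

## Method

1. **Feature genes.** Per-type mean expression `Y` (genes × types) yields a
   fold change `FC_i = Y_i / (Σ_j Y_ij − Y_i) · (k−1)`, damped by
   `tanh(λ·W_i)` where `W_i` is the gene's median expression relative to
   the global median of medians (λ = 0.1) — suppressing noisy ratios of
   lowly expressed genes. The top 30 genes per type are *seed genes*.
   Genes whose PCA-space profiles correlate with a type's seed profile
   (Fisher z-test, `z′ = artanh(r)`, SE = 1/√(t−3), p < 0.01) join the
   set; the union G drives everything downstream.
2. **Label transfer.** Spots are Leiden-clustered on expression; cells and
   spots are integrated over G by a CCA-style SVD of the cell–spot
   cross-product and projected to 2D with UMAP. Each spot's k nearest
   cells (k = 1 high-resolution / 5 low-resolution) inherit its cluster
   label, and a 1000-tree random forest generalises those labels to every
   cell.
3. **Cell counts.** Low-variance "stable genes" (count variance < 0.5
   across spots) proxy cellular content:
   `n_s = round(spot_expr / spot_mean · mean_cell_num)`, clamped to ≥ 1.
4. **Assignment.** Within each cluster, cells are matched to `n_s`
   replicated sub-spots by a rectangular linear sum assignment
   (Jonker–Volgenant-class solver) on cost `1 − cosine(cell, spot)`; when
   sub-spots outnumber cells, every cell is placed first and remaining
   slots take the most similar cell (flagged duplicates).

A benchmark module implements the standard composition metrics (per-type
PCC, SSIM, z-scored RMSE, Jensen–Shannon divergence; dataset-level ACCU
and the rank-aggregated AS score), a ground-truth-free per-spot
correlation against marker-signature scores, and spatial k-distance. A
synthetic-data module generates paired SC/ST fixtures with planted marker
blocks and two simulation protocols (Poisson cell numbers; template-driven
spots with train/test splitting), so the whole method is testable without
downloads.

## Worked example

```python
import spotmap as sm
from spotmap import synthetic as syn

spec = syn.GeneratorSpec(n_cells=400, n_genes=400, n_types=6, seed=11)
sc = syn.make_sc(spec)
st, truth = syn.simulate_st_poisson(sc, n_spots=100, lam=5, perturbation=0.01,
                                    seed=12, dominant_frac=0.7)

res = sm.SpotMapper(sc, st, sm.PipelineConfig(resolution_mode="low", rng_seed=11)).fit()
print(res.summary())
```

```
Single-cell -> spot mapping results
===========================================
cells mapped                 376
spots occupied               100
sub-spots filled             499
duplicated placements        123
unassigned cells              24
feature genes |G|            158
spot clusters                  6
estimated total cells N      499
RF training accuracy       1.000
-------------------------------------------
mode=low mean_cell_num=5 knn_k=5 seed_num=30 seed=11
```

499 sub-spots were created for 100 spots (≈ 5 cells/spot, matching the
Poisson λ = 5 of the simulation); 376 distinct cells were placed, 123
slots re-used a cell because its cluster held fewer cells than sub-spots,
and 24 cells of over-represented clusters stayed unassigned. Scoring the
recovered compositions against the generator's truth:

```python
from spotmap import metrics as M
rep = M.benchmark_report(truth.proportions.loc[res.proportions.index], res.proportions)
print(rep.per_type.round(3)); print(rep.accu)
```

```
         pcc   ssim   rmse     js
type0  0.906  0.890  0.435  0.107
type1  0.919  0.904  0.402  0.093
type2  0.912  0.886  0.419  0.104
type3  0.911  0.872  0.422  0.119
type4  0.947  0.935  0.324  0.062
type5  0.916  0.865  0.409  0.067
0.95
```

Per-type spatial composition is recovered at PCC ≈ 0.91–0.95 and the
dominant type is called correctly in 95% of spots, on a deliberately tiny
fixture. `res.assignment` holds the per-cell table (cell, spot, sub-spot,
type, x, y), `res.proportions` the per-spot composition, and
`res.save(outdir)` writes both plus a config snapshot and run manifest.

The same pipeline is available from a shell:

```bash
spotmap simulate --n-cells 400 --n-genes 400 --n-spots 100 --seed 11 --outdir fix
spotmap map --sc fix/sc --annotations fix/sc/annotations.tsv \
            --st fix/st_noise0.01 --coords fix/st_noise0.01/coords.csv \
            --mode low --seed 11 --outdir out
```

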