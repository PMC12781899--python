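"""Synthetic paired single-cell / spatial data.

The generator emulates the structure the mapping pipeline relies on: cell
types are defined by disjoint blocks of marker genes elevated over a
negative-binomial background, and spots are sums of sampled cells.  Two
simulation protocols are provided:

* ``simulate_st_poisson`` — per spot, draw a Poisson(lambda) cell count
  (clamped to >= 1), sample that many cells, sum their counts and apply a
  configurable transcriptional perturbation.  Used to validate per-spot
  cell-count estimation.
* ``simulate_st_template`` — split the reference per type 1:1 into train and
  test halves, integrate the train half with a spatial template over the top
  variable genes, aggregate each spot's k nearest train cells (2D-embedding
  distance) into the spot's expression, apply noise, and return the test
  half as the mapping reference.  Used to validate proportion recovery.

"Transcriptional perturbation" multiplies each count by ``1 + e`` with
``e ~ Normal(0, level)`` (rounded half-up, clamped at zero); an additive
variant is available behind ``mode="additive"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnnotatedSC, SpatialDataset
from .preprocess import normalize

__all__ = [
    "GeneratorSpec",
    "SyntheticTruth",
    "make_sc",
    "apply_noise",
    "grid_coords",
    "simulate_st_poisson",
    "simulate_st_template",
    "split_train_test",
    "highly_variable_genes",
    "make_paired_fixture",
]


@dataclass
class GeneratorSpec:
    """Parameters of the single-cell generator.

    Defaults produce the standard study fixture: 2000 cells across 6 types,
    1000 genes of which 25 per type are markers elevated 8-fold over their
    background mean.  Background means are log-normal so the gene pool spans
    lowly expressed (near-stable) and abundant genes, as in real references.
    """

    n_types: int = 6
    n_genes: int = 1000
    markers_per_type: int = 25
    n_cells: int = 2000
    marker_fold: float = 8.0
    bg_mean_log_mu: float = np.log(0.05)
    bg_mean_log_sigma: float = 1.5
    marker_base_mean: float = 1.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the gene pool (must be disjoint)")
        if self.n_types < 2:
            raise ValueError("need at least two cell types")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while simulating spots."""

    cells_per_spot: dict                   # spot_id -> list of cell ids
    n_true: pd.Series                      # spot_id -> int
    proportions: pd.DataFrame              # spots x types, rows sum to 1
    params: dict = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size ``dispersion``."""
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def make_sc(spec: GeneratorSpec) -> AnnotatedSC:
    """Generate an annotated single-cell dataset with planted markers."""
    rng = np.random.default_rng(spec.seed)
    types = [f"type{t}" for t in range(spec.n_types)]

    # disjoint marker blocks at the start of the gene list
    marker_of = np.full(spec.n_genes, -1, dtype=int)
    for t in range(spec.n_types):
        lo = t * spec.markers_per_type
        marker_of[lo : lo + spec.markers_per_type] = t

    base_mean = rng.lognormal(spec.bg_mean_log_mu, spec.bg_mean_log_sigma, spec.n_genes)
    base_mean[marker_of >= 0] = spec.marker_base_mean

    counts_per_type = np.full(spec.n_types, spec.n_cells // spec.n_types, dtype=int)
    counts_per_type[: spec.n_cells % spec.n_types] += 1

    blocks, labels, cell_ids = [], [], []
    cell_no = 0
    for t, n_t in enumerate(counts_per_type):
        mean_t = base_mean.copy()
        mean_t[marker_of == t] *= spec.marker_fold
        block = _nb_draw(rng, np.tile(mean_t[:, None], (1, n_t)), spec.dispersion)
        blocks.append(block)
        labels.extend([types[t]] * n_t)
        cell_ids.extend([f"cell{cell_no + i:05d}" for i in range(n_t)])
        cell_no += n_t

    counts = np.concatenate(blocks, axis=1).astype(float)
    gene_ids = np.array([f"gene{g:04d}" for g in range(spec.n_genes)], dtype=object)
    return AnnotatedSC(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=np.array(cell_ids, dtype=object),
        cell_type=pd.Series(labels, index=cell_ids),
    )


def planted_markers(spec: GeneratorSpec) -> dict:
    """The marker gene ids each type was generated with."""
    out = {}
    for t in range(spec.n_types):
        lo = t * spec.markers_per_type
        out[f"type{t}"] = [f"gene{g:04d}" for g in range(lo, lo + spec.markers_per_type)]
    return out


def apply_noise(
    counts: np.ndarray,
    level: float,
    rng: np.random.Generator,
    mode: str = "multiplicative",
) -> np.ndarray:
    """Transcriptional perturbation of a count matrix (see module docstring)."""
    if level <= 0:
        return counts.copy()
    if mode == "multiplicative":
        noisy = counts * (1.0 + rng.normal(0.0, level, counts.shape))
    elif mode == "additive":
        scale = max(counts.mean(), 1.0)
        noisy = counts + rng.normal(0.0, level * scale, counts.shape)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return np.maximum(np.floor(noisy + 0.5), 0.0)


def grid_coords(n_spots: int, spacing: float = 1.0) -> pd.DataFrame:
    """Square-grid spot coordinates, row-major."""
    side = int(np.ceil(np.sqrt(n_spots)))
    ids = [f"spot{i:04d}" for i in range(n_spots)]
    xs = [(i % side) * spacing for i in range(n_spots)]
    ys = [(i // side) * spacing for i in range(n_spots)]
    return pd.DataFrame({"x": xs, "y": ys}, index=ids)


def _stripe_regions(coords: pd.DataFrame, types: list) -> pd.Series:
    """Assign each spot a dominant type by vertical stripe of the grid."""
    x = coords["x"].to_numpy()
    edges = np.quantile(x, np.linspace(0, 1, len(types) + 1))
    region = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(types) - 1)
    return pd.Series([types[r] for r in region], index=coords.index)


def simulate_st_poisson(
    sc: AnnotatedSC,
    n_spots: int = 200,
    lam: float = 5.0,
    perturbation: float = 0.01,
    seed: int = 0,
    dominant_frac: float = 0.0,
    noise_mode: str = "multiplicative",
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Simulate spots as sums of Poisson(lambda)-many sampled cells.

    With ``dominant_frac > 0`` the grid is split into vertical stripes, one
    per cell type, and each sampled cell comes from the stripe's type with
    that probability (uniform otherwise) — producing the cluster-blocked
    layouts the mapping pipeline expects from real tissue.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    coords = grid_coords(n_spots)
    types = sc.types
    labels = sc.cell_type.to_numpy()
    by_type = {t: np.flatnonzero(labels == t) for t in types}
    region = _stripe_regions(coords, types) if dominant_frac > 0 else None

    n_true = np.maximum(rng.poisson(lam, n_spots), 1)
    st_counts = np.zeros((sc.n_genes, n_spots))
    cells_per_spot, prop_rows = {}, []
    for s, sid in enumerate(coords.index):
        picks = []
        for _ in range(n_true[s]):
            if region is not None and rng.uniform() < dominant_frac:
                pool = by_type[region.loc[sid]]
            else:
                pool = np.arange(sc.n_cells)
            picks.append(int(rng.choice(pool)))
        st_counts[:, s] = sc.counts[:, picks].sum(axis=1)
        cells_per_spot[sid] = [sc.cell_ids[i] for i in picks]
        picked_types = pd.Series([labels[i] for i in picks])
        prop_rows.append(picked_types.value_counts(normalize=True))

    st_counts = apply_noise(st_counts, perturbation, rng, mode=noise_mode)
    proportions = (
        pd.DataFrame(prop_rows, index=coords.index).reindex(columns=types).fillna(0.0)
    )
    st = SpatialDataset(
        counts=st_counts,
        gene_ids=sc.gene_ids.copy(),
        spot_ids=np.array(coords.index, dtype=object),
        coords=coords,
    )
    truth = SyntheticTruth(
        cells_per_spot=cells_per_spot,
        n_true=pd.Series(n_true, index=coords.index),
        proportions=proportions,
        params={"lambda": lam, "perturbation": perturbation, "seed": seed,
                "dominant_frac": dominant_frac},
    )
    return st, truth


def split_train_test(sc: AnnotatedSC, ratio: float = 0.5, seed: int = 0):
    """Stratified per-type split; train takes the ceiling on odd counts."""
    rng = np.random.default_rng(seed)
    labels = sc.cell_type.to_numpy()
    train_idx, test_idx = [], []
    for ctype in sc.types:
        idx = np.flatnonzero(labels == ctype)
        if idx.size < 2:
            raise ValueError(f"type {ctype!r} has fewer than 2 cells; cannot split")
        perm = rng.permutation(idx)
        n_train = int(np.ceil(idx.size * ratio))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    return (
        sc.subset_cells([sc.cell_ids[i] for i in train_idx]),
        sc.subset_cells([sc.cell_ids[i] for i in test_idx]),
    )


def highly_variable_genes(sc: AnnotatedSC, n_top: int = 2000, n_bins: int = 20) -> list:
    """Top variable genes by within-bin standardised dispersion (var/mean of
    counts, binned by mean expression)."""
    mean = sc.counts.mean(axis=1)
    var = sc.counts.var(axis=1)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(sc.n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(sc.n_genes) * n_bins) // sc.n_genes, n_bins - 1)
    z = np.zeros(sc.n_genes)
    for b in range(n_bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        mu, sd = disp[sel].mean(), disp[sel].std()
        if sd > 0:
            z[sel] = (disp[sel] - mu) / sd
    ranked = sorted(range(sc.n_genes), key=lambda i: (-z[i], str(sc.gene_ids[i])))
    return [sc.gene_ids[i] for i in ranked[: min(n_top, sc.n_genes)]]


def simulate_st_template(
    sc: AnnotatedSC,
    template: SpatialDataset,
    knn_k: int = 5,
    noise_levels=(0.0,),
    n_hvg: int = 2000,
    seed: int = 0,
    cca_dim: int = 20,
    umap_neighbors: int = 30,
    umap_min_dist: float = 0.3,
    noise_mode: str = "multiplicative",
):
    """Template-driven simulation with a held-out mapping reference.

    Returns ``(st_by_noise, truth, test_sc, train_sc)`` where ``st_by_noise``
    maps each noise level to a SpatialDataset sharing the same aggregated
    cells (so the datasets differ only in the applied perturbation).
    """
    from . import transfer

    train, test = split_train_test(sc, ratio=0.5, seed=seed)
    train = normalize(train)
    template = normalize(template, inplace=False)

    hvg = highly_variable_genes(train, n_top=n_hvg)
    shared = [g for g in hvg if g in set(template.gene_ids)]
    tr_idx = train.gene_index(shared)
    st_idx = template.gene_index(shared)

    emb = transfer.integrate(
        train.norm[tr_idx], template.norm[st_idx], train.cell_ids, template.spot_ids,
        d=cca_dim,
    )
    emb = transfer.embed_2d(
        emb, seed=seed, n_neighbors=umap_neighbors, min_dist=umap_min_dist
    )

    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(knn_k, train.n_cells)).fit(emb.cell_coords)
    _, idx = nn.kneighbors(emb.spot_coords)

    labels = train.cell_type.to_numpy()
    base = np.zeros((sc.n_genes, template.n_spots))
    cells_per_spot, prop_rows = {}, []
    for s, sid in enumerate(template.spot_ids):
        picks = idx[s]
        base[:, s] = train.counts[:, picks].sum(axis=1)
        cells_per_spot[sid] = [train.cell_ids[i] for i in picks]
        prop_rows.append(pd.Series(labels[picks]).value_counts(normalize=True))

    types = sc.types
    proportions = (
        pd.DataFrame(prop_rows, index=template.spot_ids)
        .reindex(columns=types)
        .fillna(0.0)
    )
    truth = SyntheticTruth(
        cells_per_spot=cells_per_spot,
        n_true=pd.Series(int(idx.shape[1]), index=template.spot_ids),
        proportions=proportions,
        params={"knn_k": knn_k, "seed": seed, "noise_levels": tuple(noise_levels)},
    )

    st_by_noise = {}
    for level in noise_levels:
        rng = np.random.default_rng(seed + int(round(level * 1000)) + 1)
        st_by_noise[level] = SpatialDataset(
            counts=apply_noise(base, level, rng, mode=noise_mode),
            gene_ids=sc.gene_ids.copy(),
            spot_ids=np.array(template.spot_ids, dtype=object),
            coords=template.coords.copy(),
        )
    return st_by_noise, truth, test, train


def make_paired_fixture(
    seed: int = 0,
    n_cells: int = 2000,
    n_types: int = 6,
    n_genes: int = 1000,
    n_spots: int = 500,
    lam: float = 5.0,
    dominant_frac: float = 0.7,
    marker_fold: float = 8.0,
):
    """The default study fixture: an annotated reference plus a spatially
    patterned template built from it.  Returns ``(spec, sc, template,
    template_truth)``."""
    spec = GeneratorSpec(
        n_types=n_types, n_genes=n_genes, n_cells=n_cells,
        marker_fold=marker_fold, seed=seed,
    )
    sc = make_sc(spec)
    template, truth = simulate_st_poisson(
        sc, n_spots=n_spots, lam=lam, perturbation=0.01,
        seed=seed + 1, dominant_frac=dominant_frac,
    )
    return spec, sc, template, truth
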