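"""Normalisation and spot clustering.

Expression is library-size normalised and log1p transformed (the classic
log-CPM-style transform).  Spot clusters come from a shared-nearest-neighbour
graph on the top principal components partitioned with the Leiden algorithm,
which is what current single-cell toolchains use for graph community
detection and, unlike classic Louvain, takes an explicit seed.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import AnnotatedSC, SpatialDataset

__all__ = ["normalize", "cluster_spots"]


def normalize(data, target_sum: float = 10_000.0, inplace: bool = True):
    """Fill the ``norm`` layer: counts scaled to ``target_sum`` per column,
    then log1p.  All-zero columns stay all-zero (with a warning).

    A different transform (e.g. Pearson residuals) can be plugged in by
    assigning ``data.norm`` directly; every downstream step only reads the
    layer.
    """
    counts = data.counts
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero column(s); norm left at zero")
    safe = np.where(zero, 1.0, totals)
    norm = np.log1p(counts / safe * target_sum)
    norm[:, zero] = 0.0
    if not inplace:
        import copy

        data = copy.copy(data)
    data.norm = norm
    return data


def _snn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbour graph: kNN edges weighted by neighbour-set
    Jaccard overlap (edges with zero overlap are dropped)."""
    n = coords.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = shared / union
            if w > 0:
                edges.append((i, int(j)))
                weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_spots(
    st: SpatialDataset,
    resolution: float = 0.8,
    n_pcs: int = 30,
    snn_neighbors: int = 15,
    seed: int = 0,
    inplace: bool = True,
) -> SpatialDataset:
    """Cluster spots on expression (not spatial position).

    PCA on the normalised matrix (spots x genes), SNN graph, Leiden with the
    given resolution and seed.  Labels are contiguous integers from 0,
    ordered by cluster size (largest first).  Fewer than three spots yield a
    single cluster.
    """
    if st.norm is None:
        raise ValueError("normalize() must run before cluster_spots()")
    q = st.n_spots
    if q < 3:
        labels = np.zeros(q, dtype=int)
    else:
        X = st.norm.T  # spots x genes
        ncomp = min(n_pcs, q - 1, st.n_genes)
        pcs = PCA(n_components=ncomp, svd_solver="full", random_state=seed).fit_transform(
            X - X.mean(axis=0)
        )
        g = _snn_graph(pcs, snn_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=g.es["weight"] if g.ecount() else None,
            resolution_parameter=resolution,
            seed=seed,
        )
        raw = np.array(part.membership)
        # relabel contiguously by descending cluster size (ties by old label)
        sizes = pd.Series(raw).value_counts()
        order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
        remap = {old: new for new, old in enumerate(order)}
        labels = np.array([remap[c] for c in raw], dtype=int)
    if not inplace:
        import copy

        st = copy.copy(st)
    st.cluster = pd.Series(labels, index=st.spot_ids)
    return st
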