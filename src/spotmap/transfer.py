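"""Joint embedding and cluster-label transfer.

The two modalities are integrated over the feature genes with a CCA-style
projection: each gene is standardised within its dataset, the SVD of the
cell-by-spot cross-product yields paired canonical vectors, and each
cell/spot vector is L2-normalised.  UMAP then projects the shared space to
2D, spot cluster labels are transferred to each spot's k nearest cells, and
a random forest trained on those labelled cells predicts a cluster for every
cell in the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "integrate",
    "embed_2d",
    "transfer_labels",
    "train_rf",
    "predict_clusters",
    "JointEmbedding",
    "TransferSet",
    "ClusterModel",
]

MIN_SHARED_GENES = 10


@dataclass
class JointEmbedding:
    """Shared-space and 2D coordinates of cells and spots."""

    cell_ids: np.ndarray
    spot_ids: np.ndarray
    cell_shared: np.ndarray        # n x d
    spot_shared: np.ndarray        # q x d
    d_cca: int
    cell_coords: np.ndarray | None = field(default=None, repr=False)  # n x 2
    spot_coords: np.ndarray | None = field(default=None, repr=False)  # q x 2


@dataclass
class TransferSet:
    """Cells that received a spot's cluster label, plus their features."""

    pairs: pd.DataFrame            # cell_id, spot_id, label, distance
    features: np.ndarray           # len(pairs) x g
    gene_ids: np.ndarray


@dataclass
class ClusterModel:
    """Trained cluster classifier over the feature genes."""

    clf: object
    gene_ids: np.ndarray
    classes: np.ndarray
    training_accuracy: float
    n_trees: int
    seed: int


def _standardize_genes(mat: np.ndarray) -> np.ndarray:
    """Z-score each gene (row) across its dataset's columns."""
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)


def integrate(
    sc_norm: np.ndarray,
    st_norm: np.ndarray,
    cell_ids,
    spot_ids,
    d: int = 20,
) -> JointEmbedding:
    """CCA-style projection of cells and spots into a shared d-space.

    Both matrices are genes x columns, restricted to the same ordered gene
    list.  The SVD of ``X_std^T S_std`` gives the canonical vectors; the sign
    of each component is fixed deterministically and every cell/spot vector
    is L2-normalised.
    """
    if sc_norm.shape[0] != st_norm.shape[0]:
        raise ValueError("gene dimensions differ between the two matrices")
    g = sc_norm.shape[0]
    if g < MIN_SHARED_GENES:
        raise ValueError(
            f"only {g} shared feature genes; at least {MIN_SHARED_GENES} required"
        )
    X = _standardize_genes(sc_norm)
    S = _standardize_genes(st_norm)
    K = X.T @ S  # cells x spots
    d_eff = min(d, K.shape[0], K.shape[1], g)
    U, sv, Vt = np.linalg.svd(K, full_matrices=False)
    U, V = U[:, :d_eff], Vt[:d_eff].T
    # deterministic sign: largest-|.| element of each cell vector positive
    for j in range(d_eff):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1

    def _l2(rows: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(rows, axis=1, keepdims=True)
        return rows / np.where(nrm > 0, nrm, 1.0)

    return JointEmbedding(
        cell_ids=np.asarray(cell_ids, dtype=object),
        spot_ids=np.asarray(spot_ids, dtype=object),
        cell_shared=_l2(U),
        spot_shared=_l2(V),
        d_cca=d_eff,
    )


def embed_2d(
    emb: JointEmbedding,
    seed: int = 0,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
) -> JointEmbedding:
    """2D UMAP of the concatenated shared space (deterministic given seed)."""
    import umap

    joint = np.vstack([emb.cell_shared, emb.spot_shared])
    n_total = joint.shape[0]
    if n_neighbors >= n_total:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= {n_total} points; reduced to {n_total - 1}"
        )
        n_neighbors = max(2, n_total - 1)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    coords = np.asarray(reducer.fit_transform(joint), dtype=np.float64)
    n = emb.cell_shared.shape[0]
    emb.cell_coords = coords[:n]
    emb.spot_coords = coords[n:]
    return emb


def use_shared_space(emb: JointEmbedding) -> JointEmbedding:
    """Alternative distance space: skip UMAP, use the shared CCA space
    directly for cell-spot distances."""
    emb.cell_coords = emb.cell_shared.copy()
    emb.spot_coords = emb.spot_shared.copy()
    return emb


def transfer_labels(
    emb: JointEmbedding,
    spot_cluster: pd.Series,
    k: int = 5,
) -> pd.DataFrame:
    """Give each spot's k nearest cells the spot's cluster label.

    A cell picked by several spots keeps the label of the nearest one; exact
    distance ties go to the lexicographically first spot id.  Returns a
    DataFrame (cell_id, spot_id, label, distance).
    """
    if emb.cell_coords is None or emb.spot_coords is None:
        raise ValueError("run embed_2d() (or use_shared_space()) first")
    n = emb.cell_coords.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(emb.cell_coords)
    dist, idx = nn.kneighbors(emb.spot_coords)

    best: dict[int, tuple[float, str, str]] = {}
    for s_pos in range(len(emb.spot_ids)):
        sid = emb.spot_ids[s_pos]
        label = spot_cluster.loc[sid]
        for d, c_pos in zip(dist[s_pos], idx[s_pos]):
            key = (float(d), str(sid))
            cur = best.get(c_pos)
            if cur is None or key < cur[:2]:
                best[c_pos] = (key[0], key[1], label)
    rows = [
        {
            "cell_id": emb.cell_ids[c_pos],
            "spot_id": sid,
            "label": label,
            "distance": d,
        }
        for c_pos, (d, sid, label) in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["cell_id", "spot_id", "label", "distance"])


class _ConstantModel:
    """Degenerate stand-in when training saw a single label."""

    def __init__(self, label):
        self.label = label
        self.classes_ = np.array([label])

    def predict(self, X):
        return np.full(X.shape[0], self.label, dtype=object)


def train_rf(
    features: np.ndarray,
    labels,
    gene_ids,
    n_trees: int = 1000,
    seed: int = 0,
) -> ClusterModel:
    """Train the random-forest cluster classifier on transferred cells.

    ``features`` is cells x genes (normalised expression over the feature
    genes).  With a single distinct label the model degenerates to a constant
    predictor (with a warning).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        warnings.warn("single cluster label in training set; constant model")
        clf = _ConstantModel(uniq[0])
        acc = 1.0
    else:
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        clf.fit(features, labels)
        acc = float((clf.predict(features) == labels).mean())
    return ClusterModel(
        clf=clf,
        gene_ids=np.asarray(gene_ids, dtype=object),
        classes=np.asarray(clf.classes_),
        training_accuracy=acc,
        n_trees=n_trees,
        seed=seed,
    )


def predict_clusters(
    model: ClusterModel,
    features: np.ndarray,
    cell_ids,
    gene_ids,
) -> pd.Series:
    """Predict a cluster label for every cell (features cells x genes)."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    if len(gene_ids) != len(model.gene_ids) or (gene_ids != model.gene_ids).any():
        raise ValueError("feature genes do not match the trained model")
    pred = model.clf.predict(features)
    return pd.Series(pred, index=np.asarray(cell_ids, dtype=object))
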