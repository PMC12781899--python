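"""Cell-spot similarity and per-spot cell-count estimation.

Within each cluster the similarity between a cell and a spot is the cosine
of their feature-gene expression vectors.  The number of cells in a spot is
proxied by "stable genes" — genes whose count variance across spots falls
below a threshold — whose summed expression scales with cellular content:
``n_s = round(spot_expr / spot_mean * mean_cell_num)``, clamped to >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpatialDataset

__all__ = ["cosine_similarity", "stable_genes", "estimate_counts", "SpotCellCounts"]


@dataclass
class SpotCellCounts:
    """Estimated cells per spot and the quantities behind the estimate."""

    n_s: pd.Series            # spot_id -> int >= 1
    spot_expr: pd.Series      # summed stable-gene counts per spot
    spot_mean: float
    stable_genes: list        # sorted by variance ascending
    mean_cell_num: int

    @property
    def N(self) -> int:
        return int(self.n_s.sum())


def cosine_similarity(
    X: np.ndarray,
    S: np.ndarray,
    cell_ids=None,
    spot_ids=None,
) -> pd.DataFrame:
    """Cosine similarity between cell columns of X and spot columns of S.

    Both matrices are genes x columns over the same ordered gene list.
    Zero-norm columns yield similarity 0 (with a warning).
    """
    if X.shape[0] != S.shape[0]:
        raise ValueError("gene dimensions differ")
    xn = np.linalg.norm(X, axis=0)
    sn = np.linalg.norm(S, axis=0)
    if (xn == 0).any() or (sn == 0).any():
        warnings.warn("zero-norm column(s); similarity set to 0 there")
    sim = (X.T @ S) / np.outer(np.where(xn > 0, xn, 1.0), np.where(sn > 0, sn, 1.0))
    sim[xn == 0, :] = 0.0
    sim[:, sn == 0] = 0.0
    if cell_ids is None:
        cell_ids = np.arange(X.shape[1])
    if spot_ids is None:
        spot_ids = np.arange(S.shape[1])
    return pd.DataFrame(sim, index=list(cell_ids), columns=list(spot_ids))


def stable_genes(
    st: SpatialDataset,
    var_threshold: float = 0.5,
    layer: str = "counts",
) -> list:
    """Genes with across-spot variance below the threshold.

    Variance uses the unbiased (n-1) convention on the raw counts (a
    normalised-layer option exists because raw-count variance is sequencing-
    depth sensitive).  If no gene qualifies, the 5% lowest-variance expressed
    genes are returned instead (with a warning).  Sorted ascending by
    variance, ties by gene id.
    """
    mat = st.counts if layer == "counts" else st.norm
    if mat is None:
        raise ValueError(f"layer {layer!r} not available")
    ddof = 1 if st.n_spots > 1 else 0
    var = mat.var(axis=1, ddof=ddof)
    order = sorted(range(st.n_genes), key=lambda i: (var[i], str(st.gene_ids[i])))
    stable = [st.gene_ids[i] for i in order if var[i] < var_threshold]
    if not stable:
        expressed = [i for i in order if mat[i].sum() > 0]
        n_take = max(1, int(np.ceil(0.05 * len(expressed))))
        warnings.warn(
            "no gene below the variance threshold; falling back to the 5% "
            "lowest-variance expressed genes"
        )
        stable = [st.gene_ids[i] for i in expressed[:n_take]]
    return stable


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def estimate_counts(
    st: SpatialDataset,
    stable: list | None = None,
    mean_cell_num: int = 5,
    var_threshold: float = 0.5,
) -> SpotCellCounts:
    """Estimate the number of cells in each spot from stable-gene content."""
    if stable is None:
        stable = stable_genes(st, var_threshold=var_threshold)
    if not stable:
        raise ValueError("stable gene set is empty")
    idx = st.gene_index(stable)
    expr = st.counts[idx].sum(axis=0)
    spot_mean = float(expr.mean())
    if spot_mean == 0:
        raise ValueError("stable genes carry no signal (spot_mean = 0)")
    n = _round_half_up(expr / spot_mean * mean_cell_num)
    n = np.maximum(n, 1).astype(int)
    return SpotCellCounts(
        n_s=pd.Series(n, index=st.spot_ids),
        spot_expr=pd.Series(expr, index=st.spot_ids),
        spot_mean=spot_mean,
        stable_genes=list(stable),
        mean_cell_num=mean_cell_num,
    )
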