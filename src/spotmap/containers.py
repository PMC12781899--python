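"""In-memory containers for the two input modalities.

Both containers keep genes as rows.  ``counts`` holds raw (integer) UMI/read
counts; ``norm`` is filled by :func:`spotmap.preprocess.normalize` and is the
layer every downstream step consumes.  Matrices are stored dense — the
pipeline targets feature-gene subsets of at most a few thousand genes, where
dense linear algebra is both simpler and faster than sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_dense(mat) -> np.ndarray:
    if sp.issparse(mat):
        mat = mat.toarray()
    return np.asarray(mat, dtype=np.float64)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class AnnotatedSC:
    """Annotated single-cell expression matrix (genes x cells).

    Attributes
    ----------
    counts : ndarray (m, n)
        Non-negative raw counts.
    gene_ids, cell_ids : ndarray of str
        Unique identifiers for rows / columns.
    cell_type : pandas.Series
        Cell-type label per cell, indexed by ``cell_ids``.
    norm : ndarray (m, n) or None
        Normalised layer (library-size scaled, log1p).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: pd.Series
    norm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        m, n = self.counts.shape
        if m < 1 or n < 1:
            raise ValueError("need at least one gene and one cell")
        if len(self.gene_ids) != m or len(self.cell_ids) != n:
            raise ValueError("id lengths do not match the matrix shape")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.cell_type = pd.Series(self.cell_type).reindex(self.cell_ids)
        if self.cell_type.isna().any():
            missing = self.cell_type.index[self.cell_type.isna()].tolist()
            raise ValueError(f"cells without a cell_type label: {missing[:5]}")

    # -- basic geometry ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def types(self) -> list:
        return sorted(self.cell_type.unique().tolist())

    @property
    def n_types(self) -> int:
        return len(self.cell_type.unique())

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as err:
            raise KeyError(f"gene not present: {err.args[0]!r}") from None

    def subset_genes(self, genes) -> "AnnotatedSC":
        idx = self.gene_index(genes)
        return AnnotatedSC(
            counts=self.counts[idx],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            cell_type=self.cell_type.copy(),
            norm=None if self.norm is None else self.norm[idx],
        )

    def subset_cells(self, cells) -> "AnnotatedSC":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return AnnotatedSC(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            cell_type=self.cell_type.iloc[idx].copy(),
            norm=None if self.norm is None else self.norm[:, idx],
        )


@dataclass
class SpatialDataset:
    """Spatial expression matrix (genes x spots) with 2D coordinates.

    ``coords`` is a DataFrame indexed by spot id with columns ``x`` and ``y``
    in platform units.  ``cluster`` is filled by
    :func:`spotmap.preprocess.cluster_spots` with contiguous labels 0..c-1.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: pd.DataFrame
    norm: np.ndarray | None = field(default=None, repr=False)
    cluster: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        p, q = self.counts.shape
        if p < 1 or q < 1:
            raise ValueError("need at least one gene and one spot")
        if len(self.gene_ids) != p or len(self.spot_ids) != q:
            raise ValueError("id lengths do not match the matrix shape")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.spot_ids, "spot_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.coords = pd.DataFrame(self.coords).reindex(self.spot_ids)
        if not {"x", "y"}.issubset(self.coords.columns):
            raise ValueError("coords needs columns 'x' and 'y'")
        self.coords = self.coords[["x", "y"]].astype(float)
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("coordinates must be finite")
        if self.cluster is not None:
            self.cluster = pd.Series(self.cluster).reindex(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as err:
            raise KeyError(f"gene not present: {err.args[0]!r}") from None

    def subset_genes(self, genes) -> "SpatialDataset":
        idx = self.gene_index(genes)
        return SpatialDataset(
            counts=self.counts[idx],
            gene_ids=self.gene_ids[idx],
            spot_ids=self.spot_ids.copy(),
            coords=self.coords.copy(),
            norm=None if self.norm is None else self.norm[idx],
            cluster=None if self.cluster is None else self.cluster.copy(),
        )

    def subset_spots(self, spots) -> "SpatialDataset":
        lookup = {s: i for i, s in enumerate(self.spot_ids)}
        idx = np.array([lookup[s] for s in spots], dtype=int)
        return SpatialDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            spot_ids=self.spot_ids[idx],
            coords=self.coords.iloc[idx].copy(),
            norm=None if self.norm is None else self.norm[:, idx],
            cluster=None if self.cluster is None else self.cluster.iloc[idx].copy(),
        )
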