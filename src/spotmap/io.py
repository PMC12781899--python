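"""Readers and writers for the supported on-disk formats.

Single-cell and spatial matrices can arrive as 10x-style MTX triplets
(``matrix.mtx[.gz]`` + ``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``), dense
CSV/TSV (genes as rows), or an AnnData ``.h5ad`` container.  Cell-type
annotations are a TSV with columns ``cell_id`` and ``cell_type``; spot
coordinates a CSV with columns ``spot_id``, ``x``, ``y``.  Duplicate gene
symbols are collapsed by summation so that all dialects agree.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AnnotatedSC, SpatialDataset

__all__ = [
    "read_sc",
    "read_st",
    "read_annotations",
    "read_coords",
    "write_sc",
    "write_st",
    "write_outputs",
]


# ---------------------------------------------------------------------------
# low-level matrix loading
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(base: Path, stem: str) -> Path:
    for cand in (base / stem, base / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}[.gz] not found under {base}")


def _read_mtx_dir(path: Path):
    mtx = _find(path, "matrix.mtx")
    feats = _find(path, "features.tsv")
    if not feats.exists():  # pragma: no cover - legacy name
        feats = _find(path, "genes.tsv")
    barcodes = _find(path, "barcodes.tsv")
    mat = scipy.io.mmread(str(mtx))
    with _open_maybe_gz(feats) as fh:
        gene_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(barcodes) as fh:
        col_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(gene_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match features "
            f"({len(gene_ids)}) x barcodes ({len(col_ids)})"
        )
    return mat.toarray().astype(np.float64), gene_ids, col_ids


def _read_dense(path: Path):
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=np.float64), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def _read_h5(path: Path):
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    mat = adata.X
    if sp.issparse(mat):
        mat = mat.toarray()
    # AnnData stores cells x genes; internal convention is genes as rows
    mat = np.asarray(mat, dtype=np.float64).T
    gene_ids = adata.var_names.astype(str).tolist()
    col_ids = adata.obs_names.astype(str).tolist()
    obs = adata.obs
    return mat, gene_ids, col_ids, obs


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    if path.suffix in {".h5", ".h5ad"}:
        return "h5"
    return "csv"


def _collapse_duplicates(mat: np.ndarray, gene_ids):
    """Sum rows sharing a gene symbol; keeps first-occurrence order."""
    idx = pd.Index(gene_ids)
    if idx.is_unique:
        return mat, list(gene_ids)
    order = list(dict.fromkeys(gene_ids))
    pos = {g: i for i, g in enumerate(order)}
    out = np.zeros((len(order), mat.shape[1]), dtype=mat.dtype)
    for row, g in zip(mat, gene_ids):
        out[pos[g]] += row
    return out, order


def _floor_counts(mat: np.ndarray, what: str) -> np.ndarray:
    if not np.allclose(mat, np.round(mat)):
        warnings.warn(f"non-integer {what} counts encountered; flooring", stacklevel=3)
        mat = np.floor(mat)
    return mat


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, annotation_col: str = "cell_type") -> pd.Series:
    """Read the per-cell annotation TSV (columns ``cell_id``, ``cell_type``)."""
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError(f"annotation file {path} lacks required column 'cell_id'")
    if annotation_col not in df.columns:
        raise ValueError(
            f"annotation file {path} lacks required column {annotation_col!r}"
        )
    return pd.Series(
        df[annotation_col].astype(str).to_numpy(), index=df["cell_id"].astype(str)
    )


def read_coords(path: str | Path) -> pd.DataFrame:
    """Read spot coordinates (CSV with columns ``spot_id``, ``x``, ``y``)."""
    df = pd.read_csv(path)
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinate file {path} lacks required column {col!r}")
    return df.set_index("spot_id")[["x", "y"]].astype(float)


def read_sc(
    path: str | Path,
    fmt: str | None = None,
    annotations: str | Path | pd.Series | None = None,
    annotation_col: str = "cell_type",
) -> AnnotatedSC:
    """Load a single-cell count matrix plus its cell-type annotation.

    Parameters
    ----------
    path : path
        MTX directory, dense CSV/TSV (genes x cells) or ``.h5ad`` file.
    fmt : {"mtx", "csv", "h5"}, optional
        Inferred from ``path`` when omitted.
    annotations : path or Series, optional
        cell_id -> cell_type.  Required unless the h5 container already
        carries ``annotation_col`` in its per-cell table.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    obs = None
    if fmt == "mtx":
        mat, gene_ids, cell_ids = _read_mtx_dir(path)
    elif fmt == "csv":
        mat, gene_ids, cell_ids = _read_dense(path)
    elif fmt == "h5":
        mat, gene_ids, cell_ids, obs = _read_h5(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if annotations is None:
        if obs is not None and annotation_col in obs.columns:
            cell_type = pd.Series(obs[annotation_col].astype(str).to_numpy(), index=cell_ids)
        else:
            raise ValueError(
                f"no annotation source: pass `annotations` or provide column "
                f"{annotation_col!r} in the h5 container"
            )
    elif isinstance(annotations, (str, Path)):
        cell_type = read_annotations(annotations, annotation_col)
    else:
        cell_type = pd.Series(annotations)

    missing = [c for c in cell_ids if c not in cell_type.index]
    if missing:
        raise ValueError(f"cells missing from annotation {annotation_col!r}: {missing[:5]}")

    mat = _floor_counts(mat, "single-cell")
    mat, gene_ids = _collapse_duplicates(mat, gene_ids)
    return AnnotatedSC(
        counts=mat,
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        cell_type=cell_type.loc[list(cell_ids)],
    )


def read_st(
    path: str | Path,
    coords: str | Path | pd.DataFrame,
    fmt: str | None = None,
) -> SpatialDataset:
    """Load a spatial count matrix and its spot coordinates."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        mat, gene_ids, spot_ids = _read_mtx_dir(path)
    elif fmt == "csv":
        mat, gene_ids, spot_ids = _read_dense(path)
    elif fmt == "h5":
        mat, gene_ids, spot_ids, _ = _read_h5(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if isinstance(coords, (str, Path)):
        coords = read_coords(coords)
    missing = [s for s in spot_ids if s not in coords.index]
    if missing:
        raise ValueError(f"spots missing from coordinates: {missing[:5]}")

    mat = _floor_counts(mat, "spatial")
    mat, gene_ids = _collapse_duplicates(mat, gene_ids)
    return SpatialDataset(
        counts=mat,
        gene_ids=np.array(gene_ids, dtype=object),
        spot_ids=np.array(spot_ids, dtype=object),
        coords=coords.loc[list(spot_ids)],
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_mtx_dir(outdir: Path, counts: np.ndarray, gene_ids, col_ids) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(counts.astype(int)))
    with open(outdir / "features.tsv", "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for c in col_ids:
            fh.write(f"{c}\n")


def write_sc(sc: AnnotatedSC, outdir: str | Path, fmt: str = "mtx") -> dict:
    """Write a single-cell dataset (matrix + annotation TSV); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        _write_mtx_dir(outdir, sc.counts, sc.gene_ids, sc.cell_ids)
        matrix_path = outdir
    elif fmt == "csv":
        matrix_path = outdir / "sc_counts.csv"
        pd.DataFrame(sc.counts.astype(int), index=sc.gene_ids, columns=sc.cell_ids).to_csv(
            matrix_path
        )
    else:
        raise ValueError(f"unsupported write format {fmt!r}")
    ann_path = outdir / "annotations.tsv"
    pd.DataFrame({"cell_id": sc.cell_ids, "cell_type": sc.cell_type.to_numpy()}).to_csv(
        ann_path, sep="\t", index=False
    )
    return {"matrix": matrix_path, "annotations": ann_path}


def write_st(st: SpatialDataset, outdir: str | Path, fmt: str = "mtx") -> dict:
    """Write a spatial dataset (matrix + coordinate CSV); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        _write_mtx_dir(outdir, st.counts, st.gene_ids, st.spot_ids)
        matrix_path = outdir
    elif fmt == "csv":
        matrix_path = outdir / "st_counts.csv"
        pd.DataFrame(st.counts.astype(int), index=st.gene_ids, columns=st.spot_ids).to_csv(
            matrix_path
        )
    else:
        raise ValueError(f"unsupported write format {fmt!r}")
    coords_path = outdir / "coords.csv"
    coords = st.coords.copy()
    coords.insert(0, "spot_id", coords.index)
    coords.to_csv(coords_path, index=False)
    return {"matrix": matrix_path, "coords": coords_path}


def write_outputs(assignment, proportions: pd.DataFrame, outdir: str | Path) -> dict:
    """Write the mapping results.

    ``assignment`` is the final assignment table
    (cell_id, spot_id, sub_spot, cell_type, x, y, ...); ``proportions`` the
    per-spot cell-type composition whose rows sum to 1 for non-empty spots.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assign_path = outdir / "assignment.tsv"
    cols = ["cell_id", "spot_id", "sub_spot", "cell_type", "x", "y"]
    table = assignment if isinstance(assignment, pd.DataFrame) else assignment.to_frame()
    extra = [c for c in table.columns if c not in cols]
    table = table.reindex(columns=cols + extra)
    table.to_csv(assign_path, sep="\t", index=False, float_format="%.6f")

    prop_path = outdir / "proportions.csv"
    nonempty = proportions.sum(axis=1) > 0
    if nonempty.any():
        sums = proportions.loc[nonempty].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("proportion rows of non-empty spots must sum to 1")
    proportions.to_csv(prop_path, float_format="%.9f")
    return {"assignment": assign_path, "proportions": prop_path}
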