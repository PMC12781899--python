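"""Globally optimal allocation of cells to sub-spots.

A spot estimated to hold ``n_s`` cells is expanded into ``n_s`` sub-spots by
replicating its similarity column.  Within each cluster the cells are matched
to sub-spots by a rectangular linear sum assignment (Jonker-Volgenant-class
solver) on cost ``1 - similarity``:

* more cells than sub-spots: every sub-spot gets exactly one distinct cell,
  leftover cells are reported unassigned;
* fewer cells than sub-spots: the one-to-one problem is solved first so every
  cell is used, then each remaining sub-spot is filled with the cell most
  similar to its spot (duplicates permitted and flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import SpatialDataset

__all__ = ["expand", "solve", "aggregate", "CostExpansion", "CellAssignment"]


@dataclass
class CostExpansion:
    """Cells x sub-spots similarity matrix of one cluster."""

    mat: np.ndarray                       # n' x N similarity values
    cell_ids: np.ndarray
    subspots: list                        # column -> (spot_id, replicate)

    @property
    def cost(self) -> np.ndarray:
        return 1.0 - self.mat


@dataclass
class CellAssignment:
    """Assignment table plus the cells that could not be placed."""

    pairs: pd.DataFrame                   # cell_id, spot_id, sub_spot, duplicated
    unassigned_cells: list = field(default_factory=list)
    total_cost: float = 0.0


def expand(simi: pd.DataFrame, n_s: pd.Series) -> CostExpansion:
    """Replicate each spot's similarity column ``n_s`` times.

    Columns are ordered by (spot_id, replicate); every spot of the cluster
    must have a count.
    """
    missing = [s for s in simi.columns if s not in n_s.index]
    if missing:
        raise ValueError(f"spots without a cell count: {missing[:5]}")
    cols, subspots = [], []
    for sid in sorted(simi.columns, key=str):
        reps = int(n_s.loc[sid])
        col = simi[sid].to_numpy()
        for r in range(reps):
            cols.append(col)
            subspots.append((sid, r))
    mat = np.column_stack(cols) if cols else np.zeros((simi.shape[0], 0))
    return CostExpansion(
        mat=mat,
        cell_ids=np.asarray(simi.index, dtype=object),
        subspots=subspots,
    )


def _argmax_by_cell_id(col: np.ndarray, cell_ids: np.ndarray) -> int:
    """Index of the maximum; exact ties go to the smallest cell id."""
    top = col.max()
    cand = np.flatnonzero(col == top)
    return int(min(cand, key=lambda i: str(cell_ids[i])))


def solve(exp: CostExpansion) -> CellAssignment:
    """Solve one cluster's assignment problem (see module docstring)."""
    n_cells, n_sub = exp.mat.shape
    if n_sub == 0:
        return CellAssignment(
            pairs=pd.DataFrame(columns=["cell_id", "spot_id", "sub_spot", "duplicated"]),
            unassigned_cells=list(exp.cell_ids),
        )
    cost = exp.cost
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())

    records = []
    for r, c in zip(rows, cols):
        sid, rep = exp.subspots[c]
        records.append((exp.cell_ids[r], sid, rep, False))

    if n_cells < n_sub:
        filled = set(cols)
        for c in range(n_sub):
            if c in filled:
                continue
            r = _argmax_by_cell_id(exp.mat[:, c], exp.cell_ids)
            sid, rep = exp.subspots[c]
            records.append((exp.cell_ids[r], sid, rep, True))
            total += float(cost[r, c])
        unassigned: list = []
    else:
        used = set(rows)
        unassigned = [exp.cell_ids[r] for r in range(n_cells) if r not in used]

    pairs = pd.DataFrame(records, columns=["cell_id", "spot_id", "sub_spot", "duplicated"])
    pairs = pairs.sort_values(["spot_id", "sub_spot"], kind="stable").reset_index(drop=True)
    return CellAssignment(pairs=pairs, unassigned_cells=unassigned, total_cost=total)


def aggregate(
    cluster_assignments: dict,
    st: SpatialDataset,
    cell_type: pd.Series,
    jitter_radius: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Combine per-cluster solutions into the slice-wide result.

    Returns ``(assignment table, per-spot type proportions, unassigned)``.
    Assigned cells inherit their spot's coordinates (plus an optional
    deterministic jitter for plotting); proportions come from the assigned
    cells' annotated types.  Spots with no assigned cell are excluded from
    the proportion table with a warning.
    """
    frames, unassigned = [], []
    for cluster_id, ca in sorted(cluster_assignments.items(), key=lambda kv: str(kv[0])):
        tbl = ca.pairs.copy()
        tbl["cluster"] = cluster_id
        frames.append(tbl)
        unassigned.extend(ca.unassigned_cells)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["cell_id", "spot_id", "sub_spot", "duplicated", "cluster"])

    table["cell_type"] = table["cell_id"].map(cell_type).to_numpy()
    coords = st.coords
    table["x"] = table["spot_id"].map(coords["x"]).to_numpy()
    table["y"] = table["spot_id"].map(coords["y"]).to_numpy()
    if jitter_radius > 0 and len(table):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, size=len(table))
        rad = jitter_radius * np.sqrt(rng.uniform(0, 1, size=len(table)))
        table["x"] = table["x"] + rad * np.cos(theta)
        table["y"] = table["y"] + rad * np.sin(theta)
    table = table.sort_values(["spot_id", "sub_spot"], kind="stable").reset_index(drop=True)
    table = table[["cell_id", "spot_id", "sub_spot", "cell_type", "x", "y", "cluster", "duplicated"]]

    types = sorted(pd.Series(cell_type).unique().tolist())
    counts = (
        table.groupby(["spot_id", "cell_type"]).size().unstack(fill_value=0)
        if len(table)
        else pd.DataFrame()
    )
    counts = counts.reindex(columns=types, fill_value=0)
    empty = [s for s in st.spot_ids if s not in counts.index]
    if empty:
        warnings.warn(f"{len(empty)} spot(s) received no cell; excluded from proportions")
    occupied = [s for s in st.spot_ids if s in counts.index]
    counts = counts.reindex(occupied)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    proportions.index.name = "spot_id"
    return table, proportions, unassigned
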