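"""Model-style front end: ``SpotMapper(sc, st, config).fit() -> MappingResults``.

The mapper orchestrates the full pipeline — normalisation, spot clustering,
feature-gene selection, joint embedding and label transfer, random-forest
cluster prediction, per-spot cell-count estimation, and the per-cluster
linear-assignment allocation — and packages estimates plus diagnostics into
a results object with a ``summary()``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as assign_mod
from . import features as features_mod
from . import io as io_mod
from . import similarity as sim_mod
from . import transfer as transfer_mod
from .config import PipelineConfig
from .containers import AnnotatedSC, SpatialDataset
from .preprocess import cluster_spots, normalize

__all__ = ["SpotMapper", "MappingResults"]


@dataclass
class MappingResults:
    """Fitted mapping: cell -> (spot, sub-spot) plus derived quantities."""

    assignment: pd.DataFrame          # cell_id, spot_id, sub_spot, cell_type, x, y, ...
    proportions: pd.DataFrame         # occupied spots x cell types
    counts: sim_mod.SpotCellCounts
    feature_sets: features_mod.FeatureGeneSets
    seed_table: features_mod.SeedGeneTable
    embedding: transfer_mod.JointEmbedding
    transfer_pairs: pd.DataFrame
    cluster_model: transfer_mod.ClusterModel
    cell_clusters: pd.Series          # predicted cluster per cell
    spot_clusters: pd.Series
    unassigned_cells: list
    cluster_diagnostics: pd.DataFrame
    config: PipelineConfig
    timings: dict = field(default_factory=dict)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        dup = int(self.assignment["duplicated"].sum()) if len(self.assignment) else 0
        lines = [
            "Single-cell -> spot mapping results",
            "=" * 43,
            f"cells mapped            {self.assignment['cell_id'].nunique():>8d}",
            f"spots occupied          {self.assignment['spot_id'].nunique():>8d}",
            f"sub-spots filled        {len(self.assignment):>8d}",
            f"duplicated placements   {dup:>8d}",
            f"unassigned cells        {len(self.unassigned_cells):>8d}",
            f"feature genes |G|       {len(self.feature_sets.G):>8d}",
            f"spot clusters           {self.spot_clusters.nunique():>8d}",
            f"estimated total cells N {self.counts.N:>8d}",
            f"RF training accuracy    {self.cluster_model.training_accuracy:>8.3f}",
            "-" * 43,
            f"mode={cfg.resolution_mode} mean_cell_num={cfg.mean_cell_num} "
            f"knn_k={cfg.knn_k} seed_num={cfg.seed_num} seed={cfg.rng_seed}",
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write assignment TSV, proportions CSV, config snapshot and a run
        manifest; returns the artifact paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = io_mod.write_outputs(self.assignment, self.proportions, outdir)
        cfg_path = outdir / "config.yaml"
        self.config.save(cfg_path)
        diag_path = outdir / "cluster_diagnostics.tsv"
        self.cluster_diagnostics.to_csv(diag_path, sep="\t", index=False)
        manifest = {
            "artifacts": {k: str(v) for k, v in paths.items()},
            "config": str(cfg_path),
            "diagnostics": str(diag_path),
            "seed": self.config.rng_seed,
            "stage_seconds": {k: round(v, 3) for k, v in self.timings.items()},
            "n_feature_genes": len(self.feature_sets.G),
            "n_unassigned": len(self.unassigned_cells),
        }
        manifest_path = outdir / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths.update({"config": cfg_path, "manifest": manifest_path,
                      "diagnostics": diag_path})
        return paths

    def plot_spatial(self, ax=None, **scatter_kw):
        """Scatter of mapped cells at their spot coordinates, coloured by
        cell type (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        for ctype, grp in self.assignment.groupby("cell_type"):
            ax.scatter(grp["x"], grp["y"], s=scatter_kw.pop("s", 8),
                       label=str(ctype), **scatter_kw)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.legend(markerscale=2, fontsize=8)
        return ax


class SpotMapper:
    """Maps annotated single cells onto spatial spots.

    Parameters
    ----------
    sc : AnnotatedSC
        Reference cells with cell-type labels.
    st : SpatialDataset
        Spatial counts with coordinates.
    config : PipelineConfig, optional
        All pipeline parameters; defaults follow the low-resolution preset.
    """

    def __init__(self, sc: AnnotatedSC, st: SpatialDataset,
                 config: PipelineConfig | None = None):
        self.sc = sc
        self.st = st
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, sc_path, st_path, coords_path, annotations_path=None,
                   config: PipelineConfig | None = None) -> "SpotMapper":
        sc = io_mod.read_sc(sc_path, annotations=annotations_path)
        st = io_mod.read_st(st_path, coords=coords_path)
        return cls(sc, st, config)

    # -- pipeline ------------------------------------------------------
    def fit(self) -> MappingResults:
        cfg = self.config
        timings: dict[str, float] = {}

        def _tic():
            return time.perf_counter()

        # 1. preprocessing
        t0 = _tic()
        sc, st = self.sc, self.st
        if sc.norm is None:
            normalize(sc, target_sum=cfg.target_sum)
        if st.norm is None:
            normalize(st, target_sum=cfg.target_sum)
        if st.cluster is None:
            cluster_spots(
                st, resolution=cfg.cluster_resolution, n_pcs=cfg.n_pcs,
                snn_neighbors=cfg.snn_neighbors, seed=cfg.rng_seed,
            )
        timings["preprocess"] = _tic() - t0

        # 2. feature genes
        t0 = _tic()
        feature_sets, seed_table, _ = features_mod.select_feature_genes(
            sc, seed_num=cfg.seed_num, lambda_weight=cfg.lambda_weight,
            p_cutoff=cfg.p_cutoff, var_explained=cfg.var_explained,
            t_max=cfg.t_max, seed=cfg.rng_seed,
        )
        st_genes = set(st.gene_ids)
        G = [g for g in feature_sets.G if g in st_genes]
        if len(G) < transfer_mod.MIN_SHARED_GENES:
            raise ValueError(
                f"only {len(G)} feature genes shared with the spatial data"
            )
        timings["features"] = _tic() - t0

        # 3. joint embedding + label transfer
        t0 = _tic()
        sc_idx = sc.gene_index(G)
        st_idx = st.gene_index(G)
        emb = transfer_mod.integrate(
            sc.norm[sc_idx], st.norm[st_idx], sc.cell_ids, st.spot_ids,
            d=cfg.cca_dim,
        )
        if cfg.distance_space == "umap":
            emb = transfer_mod.embed_2d(
                emb, seed=cfg.rng_seed, n_neighbors=cfg.umap_neighbors,
                min_dist=cfg.umap_min_dist,
            )
        else:
            emb = transfer_mod.use_shared_space(emb)
        pairs = transfer_mod.transfer_labels(emb, st.cluster, k=cfg.knn_k)
        timings["embedding"] = _tic() - t0

        # 4. random-forest cluster prediction for all cells
        t0 = _tic()
        cell_pos = {c: i for i, c in enumerate(sc.cell_ids)}
        feat_cells = [cell_pos[c] for c in pairs["cell_id"]]
        X_G = sc.norm[sc_idx].T  # cells x |G|
        model = transfer_mod.train_rf(
            X_G[feat_cells], pairs["label"].to_numpy(), G,
            n_trees=cfg.n_trees, seed=cfg.rng_seed,
        )
        cell_clusters = transfer_mod.predict_clusters(model, X_G, sc.cell_ids, G)
        timings["classifier"] = _tic() - t0

        # 5. per-spot cell counts
        t0 = _tic()
        counts = sim_mod.estimate_counts(
            st, mean_cell_num=cfg.mean_cell_num, var_threshold=cfg.var_threshold
        )
        timings["counts"] = _tic() - t0

        # 6. per-cluster similarity + assignment
        t0 = _tic()
        S_G = st.norm[st_idx]
        cluster_assignments, diag_rows = {}, []
        for z in sorted(st.cluster.unique()):
            spot_sel = np.flatnonzero(st.cluster.to_numpy() == z)
            cell_sel = np.flatnonzero(cell_clusters.to_numpy() == z)
            if cell_sel.size == 0:
                warnings.warn(
                    f"no cells predicted into cluster {z}; using all cells"
                )
                cell_sel = np.arange(sc.n_cells)
            simi = sim_mod.cosine_similarity(
                X_G.T[:, cell_sel], S_G[:, spot_sel],
                cell_ids=sc.cell_ids[cell_sel],
                spot_ids=st.spot_ids[spot_sel],
            )
            exp = assign_mod.expand(simi, counts.n_s)
            ca = assign_mod.solve(exp)
            cluster_assignments[z] = ca
            diag_rows.append(
                {
                    "cluster": z,
                    "n_cells": int(cell_sel.size),
                    "n_subspots": exp.mat.shape[1],
                    "total_cost": ca.total_cost,
                    "n_duplicated": int(ca.pairs["duplicated"].sum()),
                    "n_unassigned": len(ca.unassigned_cells),
                }
            )
        table, proportions, unassigned = assign_mod.aggregate(
            cluster_assignments, st, sc.cell_type,
            jitter_radius=cfg.jitter_radius, seed=cfg.rng_seed,
        )
        timings["assignment"] = _tic() - t0

        return MappingResults(
            assignment=table,
            proportions=proportions,
            counts=counts,
            feature_sets=feature_sets,
            seed_table=seed_table,
            embedding=emb,
            transfer_pairs=pairs,
            cluster_model=model,
            cell_clusters=cell_clusters,
            spot_clusters=st.cluster.copy(),
            unassigned_cells=unassigned,
            cluster_diagnostics=pd.DataFrame(diag_rows),
            config=cfg,
            timings=timings,
        )
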