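"""Pipeline configuration.

All tunable parameters of the mapping pipeline live in one dataclass so that a
run is fully described by (inputs, config, seed).  The two resolution presets
follow common platform conventions: high-resolution platforms (Slide-seq V2,
Visium HD, Stereo-seq, MERFISH) capture roughly one cell per spot, while
low-resolution platforms (10x Visium, classic ST) capture mixtures of about
five cells on average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: presets: resolution_mode -> (mean_cell_num, knn_k)
RESOLUTION_PRESETS = {"high": (1, 1), "low": (5, 5)}


@dataclass
class PipelineConfig:
    """Parameters of the single-cell -> spot mapping pipeline.

    Parameters
    ----------
    resolution_mode : {"high", "low"}
        Platform preset.  Sets ``mean_cell_num`` and ``knn_k`` to (1, 1) for
        high-resolution and (5, 5) for low-resolution data unless those are
        given explicitly.
    mean_cell_num : int
        Assumed average number of cells per spot; scales the stable-gene
        expression ratio into a per-spot cell count.
    knn_k : int
        Number of nearest-neighbour cells that represent each spot during
        label transfer.
    seed_num : int
        Seed genes per cell type (top genes by weighted fold change).
    lambda_weight : float
        λ of the tanh(λ·W) weight that damps the fold change of lowly
        expressed genes.
    var_threshold : float
        Across-spot count-variance threshold below which a gene counts as
        "stable" for cell-number estimation.
    p_cutoff : float
        Two-sided p-value cutoff of the Fisher-z co-expression test.
    n_trees : int
        Trees in the random-forest cluster classifier.
    rng_seed : int
        Global seed; every stochastic step derives its state from it.
    """

    resolution_mode: str = "low"
    mean_cell_num: int | None = None
    knn_k: int | None = None
    seed_num: int = 30
    lambda_weight: float = 0.1
    var_threshold: float = 0.5
    p_cutoff: float = 0.01
    n_trees: int = 1000
    rng_seed: int = 0

    # normalisation / clustering
    target_sum: float = 10_000.0
    n_pcs: int = 30
    cluster_resolution: float = 0.8
    snn_neighbors: int = 15

    # feature selection
    var_explained: float = 0.90
    t_max: int = 50

    # integration / embedding
    cca_dim: int = 20
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    distance_space: str = "umap"  # "umap" (2D embedding) or "pca"

    # assignment / output
    jitter_radius: float = 0.0

    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution_mode not in RESOLUTION_PRESETS:
            raise ValueError(
                f"resolution_mode must be one of {sorted(RESOLUTION_PRESETS)}, "
                f"got {self.resolution_mode!r}"
            )
        preset_mcn, preset_k = RESOLUTION_PRESETS[self.resolution_mode]
        if self.mean_cell_num is None:
            self.mean_cell_num = preset_mcn
        if self.knn_k is None:
            self.knn_k = preset_k
        if self.mean_cell_num < 1:
            raise ValueError("mean_cell_num must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValueError("p_cutoff must be in (0, 1)")

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        """Write the config as a YAML key-value file."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        return cls(**kwargs)
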