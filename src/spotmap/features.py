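"""Cell-type-specific feature-gene selection.

The selection proceeds in three steps:

1. *Seed genes.*  Per-type mean expression Y (genes x types) gives a fold
   change ``FC[i,j] = Y[i,j] / (sum_l Y[i,l] - Y[i,j]) * (k-1)`` — the ratio
   of a gene's expression in one type to its average over the other types.
   Each gene's FC row is damped by ``tanh(lambda * W_i)`` where ``W_i`` is the
   gene's per-type median expression relative to the global median of those
   medians, so that lowly expressed genes (whose ratios are noisy) are
   suppressed while highly expressed genes keep a factor near 1.  The top
   ``seed_num`` genes per type by weighted fold change are the seeds.

2. *Signal matrix.*  Genes are z-scored across cells and the matrix is
   projected on its top principal components; the component-space gene
   representation Q (components x genes, loadings scaled by the singular
   values) retains the co-expression structure while shedding noise.

3. *Co-expression expansion.*  For every gene, the Pearson correlation of its
   Q column with the mean seed column of each type is Fisher-z transformed
   (artanh) and tested against N(0, 1/(t-3)); genes significant at
   ``p_cutoff`` join that type's set.  The union over types is the feature
   gene list G used by all downstream stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import AnnotatedSC

__all__ = [
    "type_means",
    "fold_change",
    "seed_weights",
    "select_seeds",
    "signal_matrix",
    "coexpression_expand",
    "select_feature_genes",
    "SeedGeneTable",
    "SignalMatrix",
    "FeatureGeneSets",
]

#: guard on the fold-change denominator for genes expressed in a single type
FC_EPS = 1e-9
#: |r| is clamped below 1 before artanh
R_CLAMP = 1.0 - 1e-12


@dataclass
class SeedGeneTable:
    """Fold changes, weights and the per-type ordered seed lists."""

    fc: pd.DataFrame          # genes x types
    w: pd.Series              # genes
    fc_prime: pd.DataFrame    # genes x types
    seeds: dict               # type -> ordered list of gene ids

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (gene_id, type, fc, w, fc_prime, rank)."""
        rows = []
        for ctype, genes in self.seeds.items():
            for rank, g in enumerate(genes, start=1):
                rows.append(
                    {
                        "gene_id": g,
                        "type": ctype,
                        "fc": self.fc.loc[g, ctype],
                        "w": self.w.loc[g],
                        "fc_prime": self.fc_prime.loc[g, ctype],
                        "rank": rank,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SignalMatrix:
    """PCA-space gene representation (t components x m genes)."""

    Q: np.ndarray
    gene_ids: np.ndarray
    valid: np.ndarray          # genes with non-zero variance across cells
    explained: np.ndarray = field(default=None, repr=False)

    @property
    def t(self) -> int:
        return self.Q.shape[0]


@dataclass
class FeatureGeneSets:
    """Per-type feature genes (seeds plus co-expressed) and their union G."""

    per_type: dict            # type -> list of gene ids
    G: list                   # union, sorted
    seeds: dict | None = None

    def __post_init__(self) -> None:
        if not self.G:
            raise ValueError("feature gene list G is empty")


# ---------------------------------------------------------------------------
# seed genes
# ---------------------------------------------------------------------------

def type_means(sc: AnnotatedSC) -> pd.DataFrame:
    """Mean normalised expression per cell type (genes x types)."""
    if sc.norm is None:
        raise ValueError("normalize() must run before type_means()")
    types = sc.types
    if len(types) < 2:
        raise ValueError("fold change needs at least two cell types")
    cols = {}
    labels = sc.cell_type.to_numpy()
    for ctype in types:
        mask = labels == ctype
        cols[ctype] = sc.norm[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=sc.gene_ids)


def fold_change(Y: pd.DataFrame) -> pd.DataFrame:
    """Per-type fold change of each gene against the other types' average."""
    k = Y.shape[1]
    if k < 2:
        raise ValueError("fold change needs at least two cell types")
    vals = Y.to_numpy(dtype=float)
    rowsum = vals.sum(axis=1, keepdims=True)
    denom = rowsum - vals
    # epsilon only where a gene is expressed in a single type (denominator 0)
    fc = vals / np.where(denom > 0, denom, FC_EPS) * (k - 1)
    return pd.DataFrame(fc, index=Y.index, columns=Y.columns)


def seed_weights(Y: pd.DataFrame, lambda_weight: float = 0.1):
    """Expression weights W and the damped fold-change matrix FC'."""
    fc = fold_change(Y)
    med = np.median(Y.to_numpy(dtype=float), axis=1)
    global_med = np.median(med)
    if global_med == 0:
        raise ValueError(
            "median of per-gene medians is zero; data too sparse for weighting"
        )
    w = pd.Series(med / global_med, index=Y.index)
    factor = np.tanh(lambda_weight * w.to_numpy())
    fc_prime = pd.DataFrame(
        factor[:, None] * fc.to_numpy(), index=Y.index, columns=Y.columns
    )
    return w, fc, fc_prime


def select_seeds(fc_prime: pd.DataFrame, seed_num: int = 30) -> dict:
    """Top ``seed_num`` genes per type by FC', ties broken by gene id."""
    m = fc_prime.shape[0]
    if m < seed_num:
        warnings.warn(f"only {m} genes available; seed lists truncated")
    n_take = min(seed_num, m)
    seeds = {}
    gene_ids = fc_prime.index.to_numpy()
    for ctype in fc_prime.columns:
        col = fc_prime[ctype].to_numpy()
        order = sorted(range(m), key=lambda i: (-col[i], str(gene_ids[i])))
        seeds[ctype] = [gene_ids[i] for i in order[:n_take]]
    return seeds


def build_seed_table(
    sc: AnnotatedSC, seed_num: int = 30, lambda_weight: float = 0.1
) -> SeedGeneTable:
    Y = type_means(sc)
    w, fc, fc_prime = seed_weights(Y, lambda_weight)
    seeds = select_seeds(fc_prime, seed_num)
    return SeedGeneTable(fc=fc, w=w, fc_prime=fc_prime, seeds=seeds)


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

def zscore_genes(norm: np.ndarray):
    """Z-score each gene across cells (population s.d.); zero-variance genes
    become all-zero rows and are flagged invalid."""
    mean = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, keepdims=True)  # population convention
    valid = (sd[:, 0] > 0)
    z = np.where(sd > 0, (norm - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, valid


def signal_matrix(
    sc: AnnotatedSC,
    var_explained: float = 0.90,
    t_max: int = 50,
    n_components: int | None = None,
    seed: int = 0,
) -> SignalMatrix:
    """Project genes into PCA component space.

    The number of retained components t is the smallest explaining
    ``var_explained`` of the variance, capped at ``t_max`` (or forced via
    ``n_components``).  Q rows are the principal axes scaled by their
    singular values, so correlations between Q columns approximate gene-gene
    correlations of the z-scored matrix with the noise components removed.
    """
    if sc.norm is None:
        raise ValueError("normalize() must run before signal_matrix()")
    z, valid = zscore_genes(sc.norm)
    A = z.T  # cells x genes
    max_comp = min(A.shape[0], A.shape[1])
    n_fit = max_comp if n_components is not None else min(max(t_max, 4), max_comp)
    n_fit = min(n_fit, max_comp)
    pca = PCA(n_components=n_fit, random_state=seed)
    pca.fit(A)
    if n_components is not None:
        t = min(n_components, n_fit)
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        reach = np.flatnonzero(cum >= var_explained)
        t = int(reach[0]) + 1 if reach.size else n_fit
        t = min(t, t_max)
        t = max(t, min(4, n_fit))
    Q = pca.components_[:t] * pca.singular_values_[:t, None]
    return SignalMatrix(
        Q=Q,
        gene_ids=sc.gene_ids.copy(),
        valid=valid,
        explained=pca.explained_variance_ratio_[:t],
    )


# ---------------------------------------------------------------------------
# co-expression expansion
# ---------------------------------------------------------------------------

def artanh_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform, 0.5[ln(1+r) - ln(1-r)], with |r| clamped below 1."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLAMP, R_CLAMP)
    return np.arctanh(r)


def coexpression_expand(
    sig: SignalMatrix,
    seeds: dict,
    p_cutoff: float = 0.01,
) -> FeatureGeneSets:
    """Expand each type's seeds by genes significantly correlated with them.

    The correlation target of type j is the mean Q column of its seed genes;
    the Fisher-z statistic z' * sqrt(t-3) is referred to a standard normal
    (two-sided).
    """
    t = sig.t
    if t <= 3:
        raise ValueError(
            f"co-expression test needs more than 3 components (t={t}); "
            "increase the number of retained components"
        )
    Q = sig.Q
    gene_ids = sig.gene_ids
    pos = {g: i for i, g in enumerate(gene_ids)}

    # centred, unit-norm columns for vectorised Pearson correlation
    Qc = Q - Q.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Qc, axis=0)
    col_valid = sig.valid & (norms > 0)
    safe = np.where(norms > 0, norms, 1.0)
    U = Qc / safe

    se_inv = np.sqrt(t - 3)
    per_type = {}
    for ctype, seed_genes in seeds.items():
        if not seed_genes:
            raise ValueError(f"type {ctype!r} has no seed genes")
        sidx = [pos[g] for g in seed_genes]
        target = Q[:, sidx].mean(axis=1)
        tc = target - target.mean()
        tn = np.linalg.norm(tc)
        if tn == 0:
            warnings.warn(f"degenerate seed profile for type {ctype!r}")
            sig_genes = []
        else:
            r = U.T @ (tc / tn)
            z = artanh_z(r)
            pvals = 2.0 * stats.norm.sf(np.abs(z) * se_inv)
            hits = col_valid & (pvals < p_cutoff)
            sig_genes = [g for g in gene_ids[hits]]
        members = list(dict.fromkeys(list(seed_genes) + sig_genes))
        per_type[ctype] = members

    union = sorted(set().union(*per_type.values()))
    return FeatureGeneSets(per_type=per_type, G=union, seeds=seeds)


def select_feature_genes(
    sc: AnnotatedSC,
    seed_num: int = 30,
    lambda_weight: float = 0.1,
    p_cutoff: float = 0.01,
    var_explained: float = 0.90,
    t_max: int = 50,
    seed: int = 0,
):
    """Full selection: seeds -> signal matrix -> co-expression expansion.

    Returns ``(FeatureGeneSets, SeedGeneTable, SignalMatrix)``.
    """
    table = build_seed_table(sc, seed_num=seed_num, lambda_weight=lambda_weight)
    sig = signal_matrix(sc, var_explained=var_explained, t_max=t_max, seed=seed)
    sets = coexpression_expand(sig, table.seeds, p_cutoff=p_cutoff)
    return sets, table, sig
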