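"""Benchmark metrics for spot-level cell-type composition.

Six ground-truth metrics (per cell type unless noted): Pearson correlation
(PCC), a structural-similarity index (SSIM) on min-max-scaled compositions,
RMSE on z-scored compositions, Jensen-Shannon divergence (JS) of the spatial
distribution of a type, a per-spot label accuracy (ACCU), and a composite
rank-aggregated accuracy score (AS) for comparing methods.  A ground-truth-
free evaluation — the per-spot correlation between predicted proportions and
marker-signature scores — and the spatial k-distance complete the suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "pcc",
    "ssim",
    "rmse_z",
    "rmse_raw",
    "js",
    "accu",
    "argmax_types",
    "as_score",
    "benchmark_report",
    "find_markers",
    "signature_scores",
    "spot_level_correlation",
    "k_distance",
    "MetricsReport",
]

SSIM_C1 = 0.01
SSIM_C2 = 0.03


def _col(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def pcc(truth, pred) -> float:
    """Pearson correlation between the two composition vectors."""
    t, p = _col(truth), _col(pred)
    if t.size < 2:
        raise ValueError("need at least two spots")
    if np.std(t) == 0 or np.std(p) == 0:
        return float("nan")
    return float(stats.pearsonr(t, p)[0])


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def ssim(truth, pred, C1: float = SSIM_C1, C2: float = SSIM_C2) -> float:
    """Structural similarity of the two columns after min-max scaling.

    Means, s.d. and covariance enter as ``(2*u1*u2 + C1^2)(2*cov + C2^2) /
    ((u1^2 + u2^2 + C1^2)(s1^2 + s2^2 + C2^2))`` with the printed constants
    C1=0.01, C2=0.03 squared inside the formula.  Note the numerator carries
    the plain product of means (not the squared-mean form of image SSIM);
    identical inputs still give exactly 1.
    """
    t = _minmax(_col(truth))
    p = _minmax(_col(pred))
    u_t, u_p = t.mean(), p.mean()
    s_t, s_p = t.std(), p.std()  # population
    cov = ((t - u_t) * (p - u_p)).mean()
    num = (2 * u_p * u_t + C1**2) * (2 * cov + C2**2)
    den = (u_p**2 + u_t**2 + C1**2) * (s_p**2 + s_t**2 + C2**2)
    return float(num / den)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        warnings.warn("constant column; z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def rmse_z(truth, pred) -> float:
    """Root mean squared difference of the z-scored compositions."""
    t, p = _col(truth), _col(pred)
    if t.size < 2:
        raise ValueError("need at least two spots")
    return float(np.sqrt(np.mean((_zscore(p) - _zscore(t)) ** 2)))


def rmse_raw(truth, pred) -> float:
    """Root mean squared difference of the raw proportions (the scale on
    which the simulation benchmark reports its errors)."""
    t, p = _col(truth), _col(pred)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def _kl(a: np.ndarray, b: np.ndarray, log_base: float) -> float:
    mask = a > 0
    return float(np.sum(a[mask] * (np.log(a[mask] / b[mask]) / np.log(log_base))))


def js(truth, pred, base: float = np.e) -> float:
    """Jensen-Shannon divergence between the spatial distributions.

    Both columns are normalised to probability vectors first; 0*log(0/.) is
    taken as 0.  Bounded by log(2) in the chosen base.
    """
    t, p = _col(truth), _col(pred)
    ts, ps = t.sum(), p.sum()
    if ts <= 0 or ps <= 0:
        raise ValueError("zero-sum composition column")
    t, p = t / ts, p / ps
    m = (t + p) / 2.0
    return 0.5 * _kl(p, m, base) + 0.5 * _kl(t, m, base)


def accu(truth_types, pred_types) -> float:
    """Fraction of spots whose predicted dominant type matches the truth."""
    t = np.asarray(truth_types)
    p = np.asarray(pred_types)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    return float((t == p).mean())


def argmax_types(proportions: pd.DataFrame) -> pd.Series:
    """Dominant cell type per spot (ties go to the first column)."""
    return proportions.idxmax(axis=1)


def as_score(means: pd.DataFrame, normalize: bool = True) -> pd.Series:
    """Rank-aggregated accuracy score across methods.

    ``means`` has one row per method and columns pcc, ssim, accu, rmse, js
    (per-dataset metric means).  PCC/SSIM/ACCU rank ascending (best method
    gets rank N), RMSE/JS descending (lowest gets N); AS is the mean of the
    five ranks, divided by N when ``normalize`` so a method dominating every
    metric scores exactly 1.
    """
    required = ["pcc", "ssim", "accu", "rmse", "js"]
    missing = [c for c in required if c not in means.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    if len(means) < 2:
        raise ValueError("AS needs at least two methods to rank")
    n = len(means)
    ranks = pd.DataFrame(index=means.index)
    for col in ("pcc", "ssim", "accu"):
        ranks[col] = stats.rankdata(means[col].to_numpy())
    for col in ("rmse", "js"):
        ranks[col] = stats.rankdata(-means[col].to_numpy())
    score = ranks.mean(axis=1)
    return score / n if normalize else score


@dataclass
class MetricsReport:
    """Per-type metrics plus the dataset-level accuracy."""

    per_type: pd.DataFrame     # index: cell type; columns: pcc, ssim, rmse, js
    accu: float
    rmse_raw: float
    log_base: float

    def means(self) -> pd.Series:
        out = self.per_type.mean()
        out["accu"] = self.accu
        return out

    def to_csv(self, path) -> None:
        table = self.per_type.copy()
        table.index.name = "cell_type"
        table.to_csv(path)


def _align(truth: pd.DataFrame, pred: pd.DataFrame):
    if set(truth.index) != set(pred.index):
        extra = sorted(set(truth.index) ^ set(pred.index))
        raise ValueError(f"spot sets differ: {extra[:5]}")
    common_types = [c for c in truth.columns if c in pred.columns]
    truth = truth.loc[sorted(truth.index, key=str), common_types]
    pred = pred.reindex(index=truth.index, columns=common_types).fillna(0.0)
    return truth, pred


def benchmark_report(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    base: float = np.e,
) -> MetricsReport:
    """Evaluate predicted against true per-spot type proportions."""
    truth, pred = _align(truth, pred)
    rows = {}
    for ctype in truth.columns:
        t, p = truth[ctype], pred[ctype]
        rows[ctype] = {
            "pcc": pcc(t, p),
            "ssim": ssim(t, p),
            "rmse": rmse_z(t, p),
            "js": js(t, p, base=base) if t.sum() > 0 and p.sum() > 0 else np.nan,
        }
    per_type = pd.DataFrame(rows).T
    acc = accu(argmax_types(truth), argmax_types(pred))
    raw = rmse_raw(truth.to_numpy(), pred.to_numpy())
    return MetricsReport(per_type=per_type, accu=acc, rmse_raw=raw, log_base=base)


# ---------------------------------------------------------------------------
# ground-truth-free spot-level correlation
# ---------------------------------------------------------------------------

def find_markers(sc, n_markers: int = 100, alpha: float = 0.05) -> dict:
    """Top marker genes per type: two-sided rank-sum test of each type
    against the rest on the normalised layer, significant genes ranked by
    log fold change."""
    if sc.norm is None:
        raise ValueError("normalize() must run before find_markers()")
    labels = sc.cell_type.to_numpy()
    markers = {}
    for ctype in sc.types:
        mask = labels == ctype
        grp, rest = sc.norm[:, mask], sc.norm[:, ~mask]
        res = stats.mannwhitneyu(grp, rest, axis=1, alternative="two-sided")
        lfc = grp.mean(axis=1) - rest.mean(axis=1)
        sig = np.flatnonzero((res.pvalue < alpha) & (lfc > 0))
        order = sorted(sig, key=lambda i: (-lfc[i], str(sc.gene_ids[i])))
        markers[ctype] = [sc.gene_ids[i] for i in order[:n_markers]]
    return markers


def signature_scores(
    st,
    markers: dict,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-spot signature score per type: mean expression of the signature
    genes minus the mean of an equal-sized, expression-bin-matched background
    draw (seeded)."""
    if st.norm is None:
        raise ValueError("normalize() must run before signature_scores()")
    rng = np.random.default_rng(seed)
    gene_mean = st.norm.mean(axis=1)
    order = np.argsort(gene_mean, kind="stable")
    bins = np.empty(st.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(st.n_genes) * n_bins) // max(st.n_genes, 1), n_bins - 1
    )
    by_bin = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    scores = {}
    for ctype, genes in markers.items():
        present = [g for g in genes if g in set(st.gene_ids)]
        if not present:
            scores[ctype] = np.full(st.n_spots, np.nan)
            continue
        idx = st.gene_index(present)
        background = []
        for i in idx:
            pool = by_bin[bins[i]]
            background.append(int(rng.choice(pool)))
        sig_mean = st.norm[idx].mean(axis=0)
        bg_mean = st.norm[background].mean(axis=0)
        scores[ctype] = sig_mean - bg_mean
    return pd.DataFrame(scores, index=st.spot_ids)


def spot_level_correlation(
    proportions: pd.DataFrame,
    st,
    sc=None,
    markers: dict | None = None,
    n_markers: int = 100,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.Series:
    """Per-spot Pearson correlation, across cell types, between the predicted
    proportion vector and the marker-signature score vector.  Spots with a
    degenerate score or proportion vector are reported as NaN."""
    if markers is None:
        if sc is None:
            raise ValueError("pass either `markers` or the annotated reference `sc`")
        markers = find_markers(sc, n_markers=n_markers)
    types = [t for t in proportions.columns if t in markers]
    if len(types) < 2:
        raise ValueError("need at least two cell types for per-spot correlation")
    scores = signature_scores(st, {t: markers[t] for t in types}, n_bins=n_bins, seed=seed)
    out = {}
    for sid in proportions.index:
        p = proportions.loc[sid, types].to_numpy(dtype=float)
        s = scores.loc[sid, types].to_numpy(dtype=float)
        if np.isnan(s).any() or np.std(p) == 0 or np.std(s) == 0:
            out[sid] = np.nan
        else:
            out[sid] = float(stats.pearsonr(p, s)[0])
    return pd.Series(out, name="spot_correlation")


def k_distance(query_coords, reference_coords, k: int = 10) -> np.ndarray:
    """Mean Euclidean distance from each query point to its k nearest
    reference points (k reduced with a warning if the reference is small)."""
    ref = np.asarray(reference_coords, dtype=float)
    qry = np.asarray(query_coords, dtype=float)
    if k > ref.shape[0]:
        warnings.warn(f"k={k} exceeds reference size {ref.shape[0]}; reduced")
        k = ref.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, _ = nn.kneighbors(qry)
    return dist.mean(axis=1)
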