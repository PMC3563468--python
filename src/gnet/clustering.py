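"""Initial co-expression clustering and knee-based choice of k.

DEG profiles are clustered by standard k-means on Euclidean distance.  The
number of clusters is chosen from a grid by the knee rule: for each k the
mean within-cluster pairwise Pearson correlation and mean cluster size are
computed, and the k at the point of maximum perpendicular distance to the
chord joining the curve's endpoints (axes normalized to [0, 1]) is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import ExpressionMatrix, GnetError

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = list(range(10, 151, 10))


@dataclass
class ClusterAssignment:
    """A k-means partition of genes with per-cluster coherence summaries."""

    k: int
    labels: pd.Series  # gene_id -> cluster index in [0, k)
    per_cluster_mean_corr: np.ndarray
    mean_cluster_size: float
    inertia: float


def _pairwise_corr_mean(rows: np.ndarray) -> float:
    """Mean pairwise Pearson r among rows; zero-variance pairs contribute 0."""
    m = rows.shape[0]
    if m < 2:
        return float("nan")
    sd = rows.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    n_pairs = m * (m - 1) // 2
    c = np.corrcoef(rows[ok])
    iu = np.triu_indices(int(ok.sum()), k=1)
    total = float(np.nansum(c[iu]))
    # pairs involving a zero-variance row contribute 0 to the sum
    return total / n_pairs


def kmeans_cluster(matrix: ExpressionMatrix, k: int, seed: int = 0,
                   n_restarts: int = 10) -> ClusterAssignment:
    """K-means on gene expression profiles, best of ``n_restarts`` by SSE."""
    if k > matrix.n_genes:
        raise GnetError(f"k={k} exceeds gene count {matrix.n_genes}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(matrix.values)
    per_corr = np.array([
        _pairwise_corr_mean(matrix.values[lab == c]) for c in range(k)])
    sizes = np.bincount(lab, minlength=k)
    labels = pd.Series(lab, index=matrix.gene_ids, name="cluster")
    return ClusterAssignment(k, labels, per_corr, float(sizes.mean()),
                             float(km.inertia_))


def _mean_within_cluster_corr(matrix: ExpressionMatrix, lab: np.ndarray) -> float:
    """Mean Pearson r pooled over all within-cluster gene pairs."""
    total, n_pairs = 0.0, 0
    for c in np.unique(lab):
        rows = matrix.values[lab == c]
        m = rows.shape[0]
        if m < 2:
            continue
        sd = rows.std(axis=1)
        ok = sd > 0
        if (~ok).any():
            logger.warning("cluster %d: %d zero-variance gene(s) contribute "
                           "correlation 0", c, int((~ok).sum()))
        if ok.sum() >= 2:
            cmat = np.corrcoef(rows[ok])
            iu = np.triu_indices(int(ok.sum()), k=1)
            total += float(np.nansum(cmat[iu]))
        n_pairs += m * (m - 1) // 2
    return total / n_pairs if n_pairs else 0.0


def knee_point(xs: np.ndarray, ys: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the endpoint chord.

    Both axes are rescaled to [0, 1] first so the distance is not dominated
    by the axis with larger units.  Ties break to the smallest index.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    xr = x.max() - x.min()
    yr = y.max() - y.min()
    xn = (x - x.min()) / xr if xr > 0 else np.zeros_like(x)
    yn = (y - y.min()) / yr if yr > 0 else np.zeros_like(y)
    x0, y0, x1, y1 = xn[0], yn[0], xn[-1], yn[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 0
    dist = np.abs(dy * (xn - x0) - dx * (yn - y0)) / norm
    return int(np.argmax(dist > dist.max() - 1e-12))


def choose_k(matrix: ExpressionMatrix, k_grid=None, seed: int = 0,
             n_restarts: int = 10) -> int:
    """Choose the cluster count at the knee of the size/correlation curve."""
    grid = list(k_grid) if k_grid is not None else list(DEFAULT_K_GRID)
    if len(grid) < 3:
        raise GnetError("k_grid must contain at least 3 values")
    if sorted(grid) != grid:
        raise GnetError("k_grid must be sorted ascending")
    grid = [k for k in grid if k <= matrix.n_genes]
    if len(grid) < 3:
        raise GnetError("k_grid has fewer than 3 feasible values for this matrix")
    sizes, corrs = [], []
    for k in grid:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(matrix.values)
        sizes.append(matrix.n_genes / k)
        corrs.append(_mean_within_cluster_corr(matrix, lab))
    # mean size decreases with k; traverse the curve in grid order
    idx = knee_point(np.array(sizes), np.array(corrs))
    return grid[idx]
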