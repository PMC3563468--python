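"""Differentially expressed gene selection and TF profile discretization.

DEG selection follows the absolute-threshold rule: a gene is differentially
expressed if its normalized log-expression exceeds +threshold or falls below
-threshold in at least one condition (strict inequalities; default 3).

TF profiles are discretized per condition into expression levels
{-1: lowly, 0: normally, +1: highly expressed} by one-dimensional k-means
with k = 2 or 3.  k is chosen per TF by which of the three expression
situations (> threshold, < -threshold, in between) actually occur in the
profile.  The 1-D k-means is solved exactly by exhaustive search over
contiguous partitions of the sorted values (1-D optima are contiguous),
which removes initialization nondeterminism.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GnetError

logger = logging.getLogger(__name__)


class DegenerateProfileError(GnetError):
    """Raised when a TF profile has too few distinct values to discretize."""


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

@dataclass
class DEGSelection:
    """Result of differential-expression filtering."""

    threshold: float
    selected_gene_ids: list
    per_condition_counts: pd.DataFrame  # columns: up, down; index: condition

    @property
    def n_selected(self) -> int:
        return len(self.selected_gene_ids)

    def write_gene_list(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.selected_gene_ids:
                fh.write(f"{g}\n")


def select_degs(matrix: ExpressionMatrix, threshold: float = 3.0) -> DEGSelection:
    """Select genes with |expression| > threshold in at least one condition.

    Inequalities are strict: a value exactly equal to the threshold does not
    qualify.  Also tabulates per-condition up/down-regulated gene counts.
    """
    if not threshold > 0:
        raise GnetError(f"threshold must be positive, got {threshold}")
    up = matrix.values > threshold
    down = matrix.values < -threshold
    mask = (up | down).any(axis=1)
    selected = [g for g, m in zip(matrix.gene_ids, mask) if m]
    counts = pd.DataFrame({"up": up.sum(axis=0), "down": down.sum(axis=0)},
                          index=matrix.condition_ids)
    counts.index.name = "condition_id"
    return DEGSelection(threshold, selected, counts)


# ---------------------------------------------------------------------------
# TF discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscreteTFProfile:
    """A TF's per-condition expression level in {-1, 0, +1}."""

    tf_id: str
    levels: np.ndarray
    n_levels: int

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        if not set(np.unique(self.levels)) <= {-1, 0, 1}:
            raise GnetError("levels must lie in {-1, 0, +1}")


def choose_n_levels(profile, threshold: float = 3.0) -> int:
    """Number of discretization levels: how many expression situations occur.

    Returns 3 iff the profile contains values above +threshold AND below
    -threshold AND strictly in between; otherwise 2.
    """
    if not threshold > 0:
        raise GnetError(f"threshold must be positive, got {threshold}")
    x = np.asarray(profile, dtype=float)
    high = bool((x > threshold).any())
    low = bool((x < -threshold).any())
    between = bool(((x <= threshold) & (x >= -threshold)).any())
    return 3 if (high and low and between) else 2


def _exact_1d_kmeans(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means labels (0..k-1 by ascending centroid).

    Optimal 1-D clusters are contiguous in sorted order; we exhaustively try
    every choice of k-1 cut points between *distinct* adjacent sorted values
    and keep the partition minimizing within-cluster SSE.  Restricting cuts
    to distinct-value boundaries guarantees equal values share a label.
    """
    order = np.argsort(values, kind="stable")
    svals = values[order]
    # candidate cut positions: i such that svals[i-1] < svals[i]
    cuts = [i for i in range(1, len(svals)) if svals[i - 1] < svals[i]]
    if len(cuts) < k - 1:
        raise DegenerateProfileError(
            f"profile has fewer than {k} distinct values")
    best_sse, best_bounds = np.inf, None
    for combo in itertools.combinations(cuts, k - 1):
        bounds = (0, *combo, len(svals))
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = svals[a:b]
            sse += float(((seg - seg.mean()) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best_bounds = sse, bounds
    labels_sorted = np.empty(len(svals), dtype=int)
    for ci, (a, b) in enumerate(zip(best_bounds[:-1], best_bounds[1:])):
        labels_sorted[a:b] = ci
    labels = np.empty(len(values), dtype=int)
    labels[order] = labels_sorted
    return labels


def discretize_tf(profile, n_levels: int, tf_id: str = "", seed=None) -> DiscreteTFProfile:
    """Discretize a TF's continuous profile into {-1, 0, +1} levels.

    Clusters with exact 1-D k-means (k = ``n_levels``) and relabels clusters
    by ascending centroid.  With three levels the mapping is -1/0/+1.  With
    two levels the pair of labels is chosen by the centroids' signs: both
    non-negative -> {0, +1}; both non-positive -> {-1, 0}; mixed -> {-1, +1},
    preserving the highly/normally/lowly-expressed semantics.

    ``seed`` is accepted for interface symmetry but unused: the exact solver
    is deterministic.
    """
    x = np.asarray(profile, dtype=float)
    if n_levels not in (2, 3):
        raise GnetError(f"n_levels must be 2 or 3, got {n_levels}")
    raw = _exact_1d_kmeans(x, n_levels)  # 0..k-1 ascending centroid
    if n_levels == 3:
        mapping = {0: -1, 1: 0, 2: +1}
    else:
        c0 = x[raw == 0].mean()
        c1 = x[raw == 1].mean()
        if c0 >= 0 and c1 >= 0:
            mapping = {0: 0, 1: +1}
        elif c0 <= 0 and c1 <= 0:
            mapping = {0: -1, 1: 0}
        else:
            mapping = {0: -1, 1: +1}
    levels = np.vectorize(mapping.get)(raw)
    return DiscreteTFProfile(tf_id, levels, n_levels)


def discretize_tf_matrix(matrix: ExpressionMatrix, tf_ids, threshold: float = 3.0
                         ) -> list[DiscreteTFProfile]:
    """Discretize every candidate TF present in the matrix.

    TFs absent from the matrix or with constant (degenerate) profiles are
    skipped with a warning and excluded from candidacy.
    """
    profiles = []
    for tf in tf_ids:
        if tf not in matrix._gene_index:
            logger.warning("TF %s not in expression matrix; skipped", tf)
            continue
        row = matrix.row(tf)
        try:
            k = choose_n_levels(row, threshold)
            profiles.append(discretize_tf(row, k, tf_id=tf))
        except DegenerateProfileError:
            logger.warning("TF %s has a degenerate (near-constant) profile; "
                           "excluded from candidacy", tf)
    return profiles


# ---------------------------------------------------------------------------
# TF list IO
# ---------------------------------------------------------------------------

def read_tf_list(path) -> pd.DataFrame:
    """Read a candidate TF table (TSV, columns tf_id[, family])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "tf_id" not in df.columns:
        raise GnetError("TF list must have a tf_id column")
    if "family" not in df.columns:
        df["family"] = ""
    return df[["tf_id", "family"]]


def write_tf_list(tf_ids, path, families=None) -> None:
    fam = families if families is not None else [""] * len(tf_ids)
    pd.DataFrame({"tf_id": list(tf_ids), "family": fam}).to_csv(
        path, sep="\t", index=False)
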