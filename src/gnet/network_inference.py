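"""Iterative regulatory-tree construction and maximum-likelihood reassignment.

The core procedure alternates two steps until gene assignments stabilize:

1. *Tree construction* — for each gene cluster, greedily build a binary
   decision tree over the experimental conditions.  Each internal node
   queries one TF's discretized level (+1 or -1); the conditions where the
   TF holds that level go to the yes branch, the rest to the no branch.  The
   split maximizing the summed Gaussian log-likelihood of the cluster's
   genes over the two resulting subgroups is chosen at every node.
2. *Gene reassignment* — every gene is moved to the tree under which its
   full expression profile has maximum log-likelihood (leaf parameters
   frozen during this step).

The public surface follows the statsmodels convention: build a
:class:`GeneModuleNetworkModel` from data, call :meth:`~GeneModuleNetworkModel.fit`,
and inspect the returned :class:`FitResult`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (ConditionSubgroup, ExpressionMatrix, GnetError, Module,
                   RegulatoryTree, TreeNode, fit_gaussian, gene_tree_loglik,
                   subgroup_fit)
from .preprocess import DiscreteTFProfile
from . import validation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Candidate splits
# ---------------------------------------------------------------------------

@dataclass
class CandidateSplit:
    """One TF/level query applied to a parent condition set."""

    tf_id: str
    queried_level: int
    yes_conditions: frozenset
    no_conditions: frozenset
    score: float = float("nan")


def _side_loglik(matrix: ExpressionMatrix, gene_indices, condition_indices) -> float:
    """Summed per-gene log-likelihood of one side under its pooled Gaussian fit."""
    gi = sorted(gene_indices)
    ci = sorted(condition_indices)
    cells = matrix.values[np.ix_(gi, ci)]
    mu, sigma = fit_gaussian(cells)
    return float(np.sum(-((cells - mu) ** 2) / (2.0 * sigma ** 2))
                 - cells.size * np.log(sigma))


def score_split(matrix: ExpressionMatrix, cluster_genes, split: CandidateSplit) -> float:
    """Log-likelihood of the cluster's genes under the two fitted subgroups.

    Each side's (mu, sigma) is estimated by pooling the cluster genes' values
    in that side's conditions; the score sums the Gaussian log-likelihood of
    every gene over both sides.
    """
    if not split.yes_conditions or not split.no_conditions:
        raise GnetError("both split sides must be non-empty")
    gi = sorted(cluster_genes)
    return (_side_loglik(matrix, gi, split.yes_conditions)
            + _side_loglik(matrix, gi, split.no_conditions))


def enumerate_splits(matrix: ExpressionMatrix, cluster_genes, conditions,
                     tf_profiles: list[DiscreteTFProfile],
                     exclude_tfs=()) -> list[CandidateSplit]:
    """All scored TF/level splits of ``conditions`` with two non-empty sides.

    For each TF, up to two candidates: query level +1 (conditions where the
    TF is highly expressed vs the rest) and level -1.  Candidates leaving
    either side empty are omitted.
    """
    if not conditions:
        raise GnetError("conditions must be non-empty")
    cond = frozenset(conditions)
    out: list[CandidateSplit] = []
    for prof in tf_profiles:
        if prof.tf_id in exclude_tfs:
            continue
        for level in (+1, -1):
            yes = frozenset(c for c in cond if prof.levels[c] == level)
            no = cond - yes
            if yes and no:
                s = CandidateSplit(prof.tf_id, level, yes, no)
                s.score = score_split(matrix, cluster_genes, s)
                out.append(s)
    return out


# ---------------------------------------------------------------------------
# Greedy tree construction
# ---------------------------------------------------------------------------

def build_tree(matrix: ExpressionMatrix, cluster_genes,
               tf_profiles: list[DiscreteTFProfile], max_depth: int = 5,
               min_leaf_conditions: int = 2, min_gain: float = 0.0,
               exclude_tfs=()) -> RegulatoryTree:
    """Greedy regulatory decision tree for one gene cluster.

    At each node the best-scoring candidate split is taken and both sides are
    recursed on.  Recursion stops when the depth cap is reached, the
    condition set is at most ``min_leaf_conditions``, no candidate exists, or
    the best split's gain over the unsplit leaf falls below ``min_gain`` (the
    "similar enough" stopping rule).  Score ties break by TF id
    (lexicographic) then queried level (+1 first) for reproducibility.
    """
    gi = sorted(cluster_genes)
    if not gi:
        raise GnetError("cluster_genes must be non-empty")
    if max_depth < 0:
        raise GnetError("max_depth must be >= 0")

    def _grow(conditions: frozenset, depth: int):
        leaf = subgroup_fit(matrix, gi, conditions)
        if depth >= max_depth or len(conditions) <= min_leaf_conditions:
            return leaf
        cands = enumerate_splits(matrix, gi, conditions, tf_profiles,
                                 exclude_tfs=exclude_tfs)
        if not cands:
            return leaf
        best = min(cands, key=lambda s: (-s.score, s.tf_id, -s.queried_level))
        leaf_ll = _side_loglik(matrix, gi, conditions)
        if best.score - leaf_ll < min_gain:
            return leaf
        return TreeNode(best.tf_id, best.queried_level,
                        _grow(best.yes_conditions, depth + 1),
                        _grow(best.no_conditions, depth + 1))

    return RegulatoryTree(_grow(frozenset(range(matrix.n_conditions)), 0))


def refit_tree(matrix: ExpressionMatrix, cluster_genes,
               tree: RegulatoryTree) -> RegulatoryTree:
    """Same tree structure with leaf (mu, sigma) refit to the given genes."""
    gi = sorted(cluster_genes)

    def _re(node):
        if isinstance(node, ConditionSubgroup):
            return subgroup_fit(matrix, gi, node.condition_indices)
        return TreeNode(node.tf_id, node.queried_level,
                        _re(node.yes_child), _re(node.no_child))

    return RegulatoryTree(_re(tree.root))


def _cluster_loglik(matrix: ExpressionMatrix, gene_indices,
                    tree: RegulatoryTree) -> float:
    return sum(gene_tree_loglik(matrix.values[i], tree)
               for i in gene_indices)


# ---------------------------------------------------------------------------
# Reassignment
# ---------------------------------------------------------------------------

def reassign_genes(matrix: ExpressionMatrix,
                   trees: list[RegulatoryTree]) -> np.ndarray:
    """Map every gene to the tree with maximal log-likelihood.

    Leaf parameters are frozen.  Ties break to the lowest tree index.
    Returns an int array of tree indices, one per matrix gene.
    """
    if not trees:
        raise GnetError("at least one tree is required")
    cond_sets = {t.condition_indices for t in trees}
    if len(cond_sets) != 1 or next(iter(cond_sets)) != frozenset(
            range(matrix.n_conditions)):
        raise GnetError("all trees must cover the matrix's full condition set")
    ll = np.empty((matrix.n_genes, len(trees)))
    for j, tree in enumerate(trees):
        for leaf in tree.leaves:
            idx = sorted(leaf.condition_indices)
            x = matrix.values[:, idx]
            contrib = (-((x - leaf.mu) ** 2) / (2.0 * leaf.sigma ** 2)
                       - np.log(leaf.sigma)).sum(axis=1)
            if leaf is tree.leaves[0]:
                ll[:, j] = contrib
            else:
                ll[:, j] += contrib
    return ll.argmax(axis=1)  # argmax takes the first (lowest) index on ties


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FitResult:
    """Fitted regulatory modules: gene assignments, trees, and diagnostics.

    Attributes
    ----------
    modules : list of Module
        Final gene clusters, each with its regulatory tree, coherence (mean
        pairwise Pearson r) and summed member log-likelihood.
    assignments : pandas.Series
        gene_id -> module_id.
    trace : list of float
        Total log-likelihood after each tree-refitting pass (non-decreasing).
    n_iterations : int
    converged : bool
        True iff one more reassignment pass changes no labels.
    """

    def __init__(self, model, modules, assignments, trace, n_iterations,
                 converged):
        self.model = model
        self.modules: list[Module] = modules
        self.assignments: pd.Series = assignments
        self.trace: list[float] = trace
        self.n_iterations = n_iterations
        self.converged = converged

    @property
    def total_log_likelihood(self) -> float:
        return float(sum(m.log_likelihood for m in self.modules))

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def trees(self) -> list[RegulatoryTree]:
        return [m.tree for m in self.modules]

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = ["Gene regulatory module fit",
                 "=" * 62,
                 f"genes: {len(self.assignments):>6}    "
                 f"conditions: {self.model.matrix.n_conditions:>4}    "
                 f"candidate TFs: {len(self.model.tf_profiles):>4}",
                 f"modules: {self.n_modules:>4}    iterations: "
                 f"{self.n_iterations:>3}    converged: {self.converged}",
                 f"total log-likelihood: {self.total_log_likelihood:.4f}",
                 "-" * 62,
                 f"{'module':>6} {'genes':>6} {'TFs':>4} {'depth':>6} "
                 f"{'coherence':>10} {'loglik':>12}"]
        for m in self.modules:
            lines.append(
                f"{m.module_id:>6} {m.n_genes:>6} {len(m.tree.tf_ids):>4} "
                f"{m.tree.depth:>6} {m.coherence:>10.4f} "
                f"{m.log_likelihood:>12.2f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot the per-iteration total log-likelihood trace."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(1, len(self.trace) + 1), self.trace, marker="o")
        ax.set_xlabel("iteration")
        ax.set_ylabel("total log-likelihood")
        return ax

    # -- artifact IO --------------------------------------------------------

    def to_dict(self) -> dict:
        return {"modules": [m.to_dict() for m in self.modules],
                "n_iterations": self.n_iterations,
                "converged": self.converged,
                "total_log_likelihood": self.total_log_likelihood}

    def write_modules_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def write_assignments_tsv(self, path) -> None:
        df = self.assignments.rename("module_id").to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    def write_trace_tsv(self, path) -> None:
        pd.DataFrame({"iteration": range(1, len(self.trace) + 1),
                      "total_log_likelihood": self.trace}).to_csv(
            path, sep="\t", index=False)


class GeneModuleNetworkModel:
    """Regulatory-module model over an expression matrix and candidate TFs.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized log-expression of the genes to assign to modules (usually
        the DEG subset; may include the TF genes themselves).
    tf_profiles : list of DiscreteTFProfile
        Discretized candidate regulators (levels indexed by the matrix's
        condition positions).
    max_depth : int
        Maximum number of TF levels per tree (default 5).
    min_leaf_conditions : int
        Do not split condition sets at or below this size (default 2).
    min_gain : float
        Minimum likelihood gain over the unsplit leaf to accept a split.
    exclude_self : bool
        If True, a cluster containing a TF's own gene never queries that TF.
    """

    def __init__(self, matrix: ExpressionMatrix,
                 tf_profiles: list[DiscreteTFProfile], *, max_depth: int = 5,
                 min_leaf_conditions: int = 2, min_gain: float = 0.0,
                 exclude_self: bool = False):
        self.matrix = matrix
        self.tf_profiles = list(tf_profiles)
        self.max_depth = max_depth
        self.min_leaf_conditions = min_leaf_conditions
        self.min_gain = min_gain
        self.exclude_self = exclude_self
        for p in self.tf_profiles:
            if len(p.levels) != matrix.n_conditions:
                raise GnetError(f"TF {p.tf_id} level vector length "
                                f"{len(p.levels)} != {matrix.n_conditions}")

    @classmethod
    def from_tsv(cls, expression_path, tf_list_path, *, threshold: float = 3.0,
                 **kwargs) -> "GeneModuleNetworkModel":
        """Build from an expression TSV and TF list TSV.

        Selects DEGs at ``threshold``, restricts the matrix to them, and
        discretizes the candidate TFs found in the full matrix.
        """
        from .preprocess import discretize_tf_matrix, read_tf_list, select_degs
        full = ExpressionMatrix.from_tsv(expression_path)
        degs = select_degs(full, threshold)
        if not degs.selected_gene_ids:
            raise GnetError("no differentially expressed genes at this threshold")
        tfs = read_tf_list(tf_list_path)["tf_id"].tolist()
        profiles = discretize_tf_matrix(full, tfs, threshold)
        return cls(full.subset_genes(degs.selected_gene_ids), profiles, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _build_for_cluster(self, gene_indices, incumbent: RegulatoryTree | None
                           ) -> RegulatoryTree:
        exclude = ()
        if self.exclude_self:
            member_ids = {self.matrix.gene_ids[i] for i in gene_indices}
            exclude = tuple(member_ids)
        tree = build_tree(self.matrix, gene_indices, self.tf_profiles,
                          self.max_depth, self.min_leaf_conditions,
                          self.min_gain, exclude_tfs=exclude)
        if incumbent is not None:
            # keep the previous structure (leaves refit) if the greedy
            # rebuild scores lower: guarantees a monotone likelihood trace
            old = refit_tree(self.matrix, gene_indices, incumbent)
            if _cluster_loglik(self.matrix, gene_indices, old) > \
                    _cluster_loglik(self.matrix, gene_indices, tree):
                return old
        return tree

    def fit(self, initial=None, *, k: int | None = None, seed: int = 0,
            n_restarts: int = 10, max_iterations: int = 50) -> FitResult:
        """Alternate tree construction and gene reassignment to convergence.

        Parameters
        ----------
        initial : ClusterAssignment or array of int, optional
            Starting partition.  If omitted, k-means with ``k`` clusters
            (``k`` defaults to the knee rule's choice over the default grid).
        max_iterations : int
            Hard cap on construct/reassign cycles.

        Returns
        -------
        FitResult
        """
        from .clustering import choose_k, kmeans_cluster

        n = self.matrix.n_genes
        if initial is None:
            if k is None:
                k = choose_k(self.matrix, seed=seed, n_restarts=n_restarts)
            initial = kmeans_cluster(self.matrix, k, seed=seed,
                                     n_restarts=n_restarts)
        if hasattr(initial, "labels"):
            assign = np.asarray(
                [initial.labels[g] for g in self.matrix.gene_ids], dtype=int)
        else:
            assign = np.asarray(initial, dtype=int)
            if assign.shape != (n,):
                raise GnetError("initial assignment must cover every gene")

        trees: list[RegulatoryTree] = []
        cluster_ids = [int(c) for c in np.unique(assign)]
        incumbents: dict[int, RegulatoryTree | None] = {c: None for c in cluster_ids}
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iterations + 1):
            trees = []
            for c in cluster_ids:
                members = np.flatnonzero(assign == c)
                tree = self._build_for_cluster(members, incumbents[c])
                incumbents[c] = tree
                trees.append(tree)
            total = sum(_cluster_loglik(self.matrix, np.flatnonzero(assign == c), t)
                        for c, t in zip(cluster_ids, trees))
            trace.append(float(total))
            new_idx = reassign_genes(self.matrix, trees)
            new_assign = np.asarray([cluster_ids[j] for j in new_idx], dtype=int)
            if np.array_equal(new_assign, assign):
                converged = True
                break
            assign = new_assign
            survivors = [c for c in cluster_ids if (assign == c).any()]
            if len(survivors) < len(cluster_ids):
                dropped = sorted(set(cluster_ids) - set(survivors))
                logger.info("dropping emptied cluster(s) %s", dropped)
            cluster_ids = survivors

        modules = []
        assignments = pd.Series(index=self.matrix.gene_ids, dtype=int,
                                name="module_id")
        for new_id, (c, tree) in enumerate(zip(cluster_ids, trees)):
            members = np.flatnonzero(assign == c)
            gene_ids = [self.matrix.gene_ids[i] for i in members]
            assignments[gene_ids] = new_id
            coherence = (validation.mean_pairwise_correlation(
                self.matrix, gene_ids) if len(gene_ids) >= 2 else float("nan"))
            modules.append(Module(new_id, gene_ids, tree, coherence,
                                  _cluster_loglik(self.matrix, members, tree)))
        return FitResult(self, modules, assignments, trace, it, converged)
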