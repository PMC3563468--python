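"""Domain types and Gaussian likelihood arithmetic.

The central model: a *regulatory decision tree* partitions experimental
conditions into subgroups by querying the discretized expression level of
transcription factors (TFs); within each condition subgroup the expression of
member genes is modeled as a Gaussian with parameters (mu, sigma) estimated
from the member cells.  The log-likelihood of a gene under a tree is the sum,
over the tree's leaves, of the normal log-density of the gene's values in the
leaf's conditions — with the constant -0.5*ln(2*pi) dropped, since all trees
cover the same condition set and the constant cancels in every comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd

#: Lower clamp on leaf standard deviations.  A zero-variance condition
#: subgroup (e.g. a single condition, or perfectly coherent genes) would make
#: the log-density infinite; clamping keeps likelihoods finite and comparable.
SIGMA_FLOOR = 1e-4


class GnetError(ValueError):
    """Base class for invalid-argument errors raised by this package."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Genes x conditions matrix of normalized log-expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    condition_ids : sequence of str
        Unique column identifiers.
    values : (n_genes, n_conditions) array_like of float
        Normalized log-scale expression values.
    """

    def __init__(self, gene_ids: Sequence[str], condition_ids: Sequence[str],
                 values) -> None:
        self.gene_ids = list(map(str, gene_ids))
        self.condition_ids = list(map(str, condition_ids))
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise GnetError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise GnetError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GnetError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise GnetError("duplicate condition ids")
        if not np.isfinite(self.values).any(axis=1).all():
            raise GnetError("every gene row must contain at least one finite value")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def gene_index(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.condition_ids, self.values[idx])

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.condition_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index.astype(str), df.columns.astype(str), df.to_numpy(float))

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_conditions} conditions)"


# ---------------------------------------------------------------------------
# Gaussian leaf arithmetic
# ---------------------------------------------------------------------------

def gaussian_leaf_loglik(values, mu: float, sigma: float) -> float:
    """Log-likelihood of ``values`` under N(mu, sigma^2), constant dropped.

    Returns sum_j [ -(x_j - mu)^2 / (2 sigma^2) - ln sigma ].  Additive over
    values; the -0.5*ln(2*pi) term is omitted throughout the package.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise GnetError("values must be non-empty")
    if not np.isfinite(x).all():
        raise GnetError("values must be finite")
    if not sigma > 0:
        raise GnetError(f"sigma must be positive, got {sigma}")
    return float(np.sum(-((x - mu) ** 2) / (2.0 * sigma ** 2)) - x.size * math.log(sigma))


@dataclass(frozen=True)
class ConditionSubgroup:
    """A leaf of a regulatory tree: a condition subset with Gaussian params.

    ``mu``/``sigma`` are the sample mean and population (1/n) standard
    deviation of member-gene expression in these conditions, with ``sigma``
    clamped below at :data:`SIGMA_FLOOR`.
    """

    condition_indices: frozenset
    mu: float
    sigma: float

    def __post_init__(self):
        if not self.condition_indices:
            raise GnetError("condition subgroup must be non-empty")
        if self.sigma < SIGMA_FLOOR:
            raise GnetError(f"sigma {self.sigma} below floor {SIGMA_FLOOR}")

    def loglik(self, profile: np.ndarray) -> float:
        """Log-likelihood of a gene profile restricted to this leaf."""
        idx = sorted(self.condition_indices)
        return gaussian_leaf_loglik(profile[idx], self.mu, self.sigma)


def fit_gaussian(cells) -> tuple[float, float]:
    """Sample mean and floored population std of a cell array."""
    x = np.asarray(cells, dtype=float)
    return float(x.mean()), max(float(x.std(ddof=0)), SIGMA_FLOOR)


def subgroup_fit(matrix: ExpressionMatrix, gene_indices, condition_indices) -> ConditionSubgroup:
    """Fit a :class:`ConditionSubgroup` from the selected matrix cells.

    ``mu`` is the mean of all selected cells (genes x conditions block);
    ``sigma`` the population standard deviation, floored.
    """
    gi = sorted(gene_indices)
    ci = sorted(condition_indices)
    if not gi or not ci:
        raise GnetError("gene and condition index sets must be non-empty")
    cells = matrix.values[np.ix_(gi, ci)]
    mu, sigma = fit_gaussian(cells)
    return ConditionSubgroup(frozenset(ci), mu, sigma)


# ---------------------------------------------------------------------------
# Regulatory trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Internal tree node querying one TF's discretized level.

    The *yes* branch collects the conditions where the TF's level equals
    ``queried_level`` (+1 highly expressed, -1 lowly expressed); every other
    condition goes to the *no* branch.
    """

    tf_id: str
    queried_level: int
    yes_child: Union["TreeNode", ConditionSubgroup]
    no_child: Union["TreeNode", ConditionSubgroup]

    def __post_init__(self):
        if self.queried_level not in (+1, -1):
            raise GnetError(f"queried_level must be +1 or -1, got {self.queried_level}")


class RegulatoryTree:
    """Binary decision tree of TF queries whose leaves partition conditions."""

    def __init__(self, root: Union[TreeNode, ConditionSubgroup]) -> None:
        self.root = root
        self.leaves: list[ConditionSubgroup] = list(self._iter_leaves(self.root))
        covered: set[int] = set()
        for leaf in self.leaves:
            if covered & leaf.condition_indices:
                raise GnetError("leaf condition sets overlap")
            covered |= leaf.condition_indices
        self.condition_indices = frozenset(covered)

    @staticmethod
    def _iter_leaves(node) -> Iterator[ConditionSubgroup]:
        if isinstance(node, ConditionSubgroup):
            yield node
        else:
            yield from RegulatoryTree._iter_leaves(node.yes_child)
            yield from RegulatoryTree._iter_leaves(node.no_child)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_indices)

    @property
    def depth(self) -> int:
        """Number of TF levels (0 for a single-leaf tree)."""
        def _d(node):
            if isinstance(node, ConditionSubgroup):
                return 0
            return 1 + max(_d(node.yes_child), _d(node.no_child))
        return _d(self.root)

    @property
    def tf_ids(self) -> set[str]:
        def _collect(node, out):
            if isinstance(node, TreeNode):
                out.add(node.tf_id)
                _collect(node.yes_child, out)
                _collect(node.no_child, out)
        out: set[str] = set()
        _collect(self.root, out)
        return out

    def validate_partition(self, n_conditions: int) -> None:
        """Assert the leaves exactly partition range(n_conditions)."""
        if self.condition_indices != frozenset(range(n_conditions)):
            raise GnetError("tree leaves do not partition the condition set")

    # -- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def _ser(node):
            if isinstance(node, ConditionSubgroup):
                return {"leaf": True,
                        "conditions": sorted(node.condition_indices),
                        "mu": node.mu, "sigma": node.sigma}
            return {"leaf": False, "tf_id": node.tf_id,
                    "queried_level": node.queried_level,
                    "yes": _ser(node.yes_child), "no": _ser(node.no_child)}
        return _ser(self.root)

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatoryTree":
        def _de(node):
            if node["leaf"]:
                return ConditionSubgroup(frozenset(node["conditions"]),
                                         node["mu"], node["sigma"])
            return TreeNode(node["tf_id"], node["queried_level"],
                            _de(node["yes"]), _de(node["no"]))
        return cls(_de(d))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RegulatoryTree(depth={self.depth}, leaves={len(self.leaves)}, "
                f"tfs={sorted(self.tf_ids)})")


def gene_tree_loglik(gene_profile, tree: RegulatoryTree) -> float:
    """Log-likelihood of a full gene profile under a fitted tree.

    The profile is split across the tree's leaves; leaf parameters are *not*
    refit to the query gene.
    """
    profile = np.asarray(gene_profile, dtype=float)
    if profile.ndim != 1 or profile.size != tree.n_conditions:
        raise GnetError(
            f"profile length {profile.size} != tree condition count {tree.n_conditions}")
    return sum(leaf.loglik(profile) for leaf in tree.leaves)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

@dataclass
class Module:
    """A gene set, its regulatory tree, and summary statistics."""

    module_id: int
    gene_ids: list = field(default_factory=list)
    tree: RegulatoryTree | None = None
    coherence: float = float("nan")
    log_likelihood: float = float("nan")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_dict(self) -> dict:
        return {"module_id": self.module_id,
                "gene_ids": sorted(map(str, self.gene_ids)),
                "tree": self.tree.to_dict() if self.tree is not None else None,
                "coherence": self.coherence,
                "log_likelihood": self.log_likelihood}

    @classmethod
    def from_dict(cls, d: dict) -> "Module":
        tree = RegulatoryTree.from_dict(d["tree"]) if d.get("tree") else None
        return cls(d["module_id"], list(d["gene_ids"]), tree,
                   d.get("coherence", float("nan")),
                   d.get("log_likelihood", float("nan")))
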