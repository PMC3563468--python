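import numpy as np
import pytest

from gnet.core import (ConditionSubgroup, ExpressionMatrix, RegulatoryTree,
                       TreeNode)


@pytest.fixture
def small_matrix():
    """4 genes x 4 conditions with simple hand-checkable values."""
    values = np.array([
        [1.0, 1.0, -1.0, -1.0],
        [2.0, 2.0, -2.0, -2.0],
        [-1.0, -1.0, 1.0, 1.0],
        [0.5, 0.0, -0.5, 0.0],
    ])
    return ExpressionMatrix(["g1", "g2", "g3", "g4"],
                            ["c1", "c2", "c3", "c4"], values)


def make_random_tree(rng, n_conditions, max_depth=2, sigma_range=(0.5, 2.0)):
    """Random valid tree over range(n_conditions) with random leaf params."""
    def grow(cond, depth):
        cond = frozenset(cond)
        if depth >= max_depth or len(cond) < 2 or rng.random() < 0.3:
            return ConditionSubgroup(cond, float(rng.normal(0, 2)),
                                     float(rng.uniform(*sigma_range)))
        items = sorted(cond)
        cut = rng.integers(1, len(items))
        chosen = rng.permutation(items)[:cut]
        yes = frozenset(int(c) for c in chosen)
        return TreeNode(f"TF{depth}{len(cond)}", 1,
                        grow(yes, depth + 1), grow(cond - yes, depth + 1))
    return RegulatoryTree(grow(range(n_conditions), 0))


def loglik_oracle(profile, tree):
    """Independent per-condition summation of the tree log-likelihood."""
    import math
    total = 0.0
    for leaf in tree.leaves:
        for c in sorted(leaf.condition_indices):
            x = profile[c]
            total += -((x - leaf.mu) ** 2) / (2 * leaf.sigma ** 2) \
                - math.log(leaf.sigma)
    return total
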