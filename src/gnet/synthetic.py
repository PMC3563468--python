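"""Synthetic expression data with planted regulatory modules.

The generator inverts the inference's likelihood model into a sampler: it
draws discrete TF level vectors over conditions, builds a random regulatory
decision tree per module, assigns each leaf a mean from a grid with spacing
``leaf_mean_separation``, and draws every member gene's expression value
from Normal(leaf mean, noise_sigma).  TF genes get continuous profiles of
``level * (deg_threshold + 1) + jitter`` so that discretization recovers the
planted levels exactly (the jitter is far below the level spacing).

Ground truth (module labels, trees, TF levels) is returned for recovery
tests.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (ConditionSubgroup, ExpressionMatrix, GnetError,
                   RegulatoryTree, TreeNode, SIGMA_FLOOR)
from .preprocess import DiscreteTFProfile
from .validation import AnnotationTable

#: Study-condition defaults for planted-recovery experiments.
DEFAULTS = dict(n_modules=5, genes_per_module=40, n_conditions=30, n_tfs=10,
                max_depth=2, leaf_mean_separation=3.0, noise_sigma=1.0)

DEG_THRESHOLD = 3.0   # |level| * (threshold + 1) puts TF rows past the cutoff
TF_JITTER = 0.25      # << separation/4, so discretization is exact


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    true_module_labels: dict          # target gene id -> module index
    true_trees: list                  # RegulatoryTree per module
    tf_levels: list                   # DiscreteTFProfile per TF
    noise_sigma: float
    leaf_mean_separation: float
    seed: int

    @property
    def root_tf_ids(self) -> list:
        return [t.root.tf_id if isinstance(t.root, TreeNode) else None
                for t in self.true_trees]


def _sample_tf_levels(rng, n_tfs, n_conditions) -> list[DiscreteTFProfile]:
    profiles = []
    for i in range(n_tfs):
        for _ in range(200):
            lv = rng.choice([-1, 0, 1], size=n_conditions, p=[0.3, 0.4, 0.3])
            if len(np.unique(lv)) == 3:
                break
        profiles.append(DiscreteTFProfile(f"TF{i:03d}", lv, 3))
    return profiles


def _random_tree(rng, tf_profiles, conditions, max_depth, mean_grid,
                 sigma=1.0, min_leaf=2):
    """Random decision tree over ``conditions`` with leaf means off a grid."""
    def _grow(cond: frozenset, depth: int):
        if depth < max_depth and len(cond) > 2 * min_leaf:
            # viable splits: both sides at least min_leaf conditions
            options = []
            for prof in tf_profiles:
                for level in (+1, -1):
                    yes = frozenset(c for c in cond if prof.levels[c] == level)
                    no = cond - yes
                    if len(yes) >= min_leaf and len(no) >= min_leaf:
                        options.append((prof.tf_id, level, yes, no))
            if options:
                tf_id, level, yes, no = options[rng.integers(len(options))]
                return TreeNode(tf_id, level, _grow(yes, depth + 1),
                                _grow(no, depth + 1))
        mu = float(rng.choice(mean_grid))
        return ConditionSubgroup(cond, mu, max(sigma, SIGMA_FLOOR))
    return RegulatoryTree(_grow(frozenset(conditions), 0))


def _leaf_mean_profile(tree: RegulatoryTree, n_conditions: int) -> np.ndarray:
    prof = np.zeros(n_conditions)
    for leaf in tree.leaves:
        prof[sorted(leaf.condition_indices)] = leaf.mu
    return prof


def generate(n_modules: int = DEFAULTS["n_modules"],
             genes_per_module: int = DEFAULTS["genes_per_module"],
             n_conditions: int = DEFAULTS["n_conditions"],
             n_tfs: int = DEFAULTS["n_tfs"],
             max_depth: int = DEFAULTS["max_depth"],
             leaf_mean_separation: float = DEFAULTS["leaf_mean_separation"],
             noise_sigma: float = DEFAULTS["noise_sigma"],
             seed: int = 0):
    """Generate a planted-module dataset.

    Returns
    -------
    (ExpressionMatrix, list of tf ids, SyntheticTruth)
        The matrix contains the target genes followed by the TF genes (TFs
        are themselves differentially expressed and clusterable).
    """
    if n_tfs < max_depth:
        raise GnetError("need at least max_depth TFs")
    if n_conditions < 2 ** max_depth:
        raise GnetError("need at least 2^max_depth conditions")
    if n_modules < 1 or genes_per_module < 1:
        raise GnetError("module counts must be positive")
    rng = np.random.default_rng(seed)
    tf_profiles = _sample_tf_levels(rng, n_tfs, n_conditions)

    sep = leaf_mean_separation
    mean_grid = np.array([-2, -1, 1, 2], dtype=float) * sep
    trees, profiles = [], []
    for _ in range(n_modules):
        for _attempt in range(200):
            tree = _random_tree(rng, tf_profiles, range(n_conditions),
                                max_depth, mean_grid, sigma=noise_sigma)
            prof = _leaf_mean_profile(tree, n_conditions)
            distinct_leaves = len({leaf.mu for leaf in tree.leaves}) >= 2
            # modules must be distinguishable: require the condition-mean
            # profiles to differ clearly from every previous module's
            far = all(np.linalg.norm(prof - q) >= sep * np.sqrt(n_conditions) / 2
                      for q in profiles)
            if distinct_leaves and far:
                break
        else:
            raise GnetError("could not plant distinguishable modules; "
                            "increase conditions or TFs")
        trees.append(tree)
        profiles.append(prof)

    gene_ids, rows, labels = [], [], {}
    for m, prof in enumerate(profiles):
        for g in range(genes_per_module):
            gid = f"G{m:02d}_{g:03d}"
            gene_ids.append(gid)
            labels[gid] = m
            rows.append(prof + rng.normal(0.0, noise_sigma, n_conditions)
                        if noise_sigma > 0 else prof.copy())
    for prof_tf in tf_profiles:
        gene_ids.append(prof_tf.tf_id)
        rows.append(prof_tf.levels * (DEG_THRESHOLD + 1.0)
                    + rng.uniform(-TF_JITTER, TF_JITTER, n_conditions))
    matrix = ExpressionMatrix(
        gene_ids, [f"C{j:02d}" for j in range(n_conditions)], np.vstack(rows))
    truth = SyntheticTruth(labels, trees, tf_profiles, noise_sigma,
                           leaf_mean_separation, seed)
    return matrix, [p.tf_id for p in tf_profiles], truth


def generate_annotations(truth: SyntheticTruth,
                         enriched_term_fraction: float = 0.8,
                         seed: int = 0, background_rate: float = 0.02,
                         n_noise_terms: int = 5) -> AnnotationTable:
    """Annotations with one planted enriched term per module.

    Per module m, term ``MOD{m}_FUNC`` is assigned to the stated fraction of
    its genes; every (gene, noise term) pair is additionally annotated with
    probability ``background_rate``.  The background is all target genes.
    """
    if not 0 < enriched_term_fraction <= 1:
        raise GnetError("enriched_term_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.true_module_labels)
    g2t: dict = {}
    names: dict = {}
    by_module: dict = {}
    for g in genes:
        by_module.setdefault(truth.true_module_labels[g], []).append(g)
    for m, members in sorted(by_module.items()):
        term = f"MOD{m}_FUNC"
        names[term] = f"planted function of module {m}"
        n_annot = max(1, int(round(enriched_term_fraction * len(members))))
        chosen = rng.choice(members, size=n_annot, replace=False)
        for g in chosen:
            g2t.setdefault(g, set()).add(term)
    for t in range(n_noise_terms):
        term = f"NOISE{t}_FUNC"
        names[term] = f"background term {t}"
        hits = rng.random(len(genes)) < background_rate
        for g, h in zip(genes, hits):
            if h:
                g2t.setdefault(g, set()).add(term)
    return AnnotationTable(g2t, names, set(genes))
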