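"""Tree construction, gene reassignment, and the iterative fit."""

import math

import numpy as np
import pytest

from gnet.core import ExpressionMatrix, GnetError, gene_tree_loglik
from gnet.network_inference import (CandidateSplit, GeneModuleNetworkModel,
                                    build_tree, enumerate_splits,
                                    reassign_genes, score_split)
from gnet.preprocess import DiscreteTFProfile
from gnet import synthetic

from conftest import make_random_tree


def _matrix(rows):
    ids = [f"g{i}" for i in range(len(rows))]
    conds = [f"c{j}" for j in range(len(rows[0]))]
    return ExpressionMatrix(ids, conds, rows)


def _tf(tf_id, levels):
    return DiscreteTFProfile(tf_id, np.asarray(levels), 3)


# ---------------------------------------------------------------------------
# independent oracle: per-side Gaussian fit and summation, coded from scratch
# ---------------------------------------------------------------------------

def _score_oracle(values, gene_idx, side_a, side_b):
    total = 0.0
    for side in (side_a, side_b):
        cells = [values[g][c] for g in gene_idx for c in sorted(side)]
        mu = sum(cells) / len(cells)
        var = sum((x - mu) ** 2 for x in cells) / len(cells)
        sigma = max(math.sqrt(var), 1e-4)
        for x in cells:
            total += -((x - mu) ** 2) / (2 * sigma ** 2) - math.log(sigma)
    return total


def _best_split_oracle(values, gene_idx, conditions, tf_profiles):
    """Exhaustive enumeration of every TF/level split, independent scoring."""
    best = None
    for prof in sorted(tf_profiles, key=lambda p: p.tf_id):
        for level in (+1, -1):
            yes = frozenset(c for c in conditions if prof.levels[c] == level)
            no = frozenset(conditions) - yes
            if not yes or not no:
                continue
            s = _score_oracle(values, gene_idx, yes, no)
            key = (-s, prof.tf_id, -level)
            if best is None or key < best[0]:
                best = (key, prof.tf_id, level, yes, no, s)
    return best


class TestEnumerateSplits:
    def test_one_tf_one_level_present(self):
        m = _matrix([[1.0, 1.0, 0.0, 0.0]])
        splits = enumerate_splits(m, [0], range(4), [_tf("a", [1, 1, 0, 0])])
        assert len(splits) == 1
        s = splits[0]
        assert (s.queried_level, s.yes_conditions, s.no_conditions) == \
            (1, frozenset({0, 1}), frozenset({2, 3}))

    def test_all_zero_levels_yield_nothing(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        assert enumerate_splits(m, [0], range(3),
                                [_tf("a", [0, 0, 0])]) == []

    def test_both_levels_present_give_two_candidates(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        splits = enumerate_splits(m, [0], range(3), [_tf("a", [1, -1, 0])])
        assert {(s.queried_level, s.yes_conditions) for s in splits} == {
            (1, frozenset({0})), (-1, frozenset({1}))}

    def test_scores_populated(self):
        m = _matrix([[1.0, 1.0, -1.0, -1.0]])
        splits = enumerate_splits(m, [0], range(4), [_tf("a", [1, 1, -1, -1])])
        assert all(np.isfinite(s.score) for s in splits)


class TestScoreSplit:
    def test_matches_hand_summed_oracle(self):
        values = [[0.1, 0.2, 1.9, 2.3], [0.0, 0.3, 2.1, 1.8]]
        m = _matrix(values)
        split = CandidateSplit("a", 1, frozenset({0, 1}), frozenset({2, 3}))
        expected = _score_oracle(values, [0, 1], {0, 1}, {2, 3})
        assert score_split(m, [0, 1], split) == pytest.approx(expected,
                                                              abs=1e-9)

    def test_clean_split_beats_unsplit_leaf(self):
        # two genes constant within sides but different across sides
        values = [[1.0, 1.0, 3.0, 3.0], [1.0, 1.0, 3.0, 3.0]]
        m = _matrix(values)
        split = CandidateSplit("a", 1, frozenset({0, 1}), frozenset({2, 3}))
        split_score = score_split(m, [0, 1], split)
        unsplit = _score_oracle(values, [0, 1], {0, 1, 2, 3}, {0, 1, 2, 3}) / 2
        assert split_score > unsplit

    def test_exchangeable_noise_gives_typical_scores(self):
        # on iid noise a TF-defined split is statistically indistinguishable
        # from random same-size splits: its score sits inside the bulk
        rng = np.random.default_rng(123)
        values = rng.normal(0, 1, (6, 10))
        m = _matrix(values.tolist())
        genes = list(range(6))
        observed = score_split(
            m, genes, CandidateSplit("a", 1, frozenset(range(4)),
                                     frozenset(range(4, 10))))
        null = []
        for _ in range(200):
            perm = rng.permutation(10)
            yes = frozenset(int(c) for c in perm[:4])
            null.append(score_split(
                m, genes, CandidateSplit("p", 1, yes,
                                         frozenset(range(10)) - yes)))
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= observed <= hi

    def test_empty_side_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(GnetError):
            score_split(m, [0], CandidateSplit("a", 1, frozenset(),
                                               frozenset({0, 1})))


class TestBuildTree:
    def test_no_candidates_gives_single_leaf(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        tree = build_tree(m, [0], [_tf("a", [0, 0, 0])])
        assert tree.depth == 0
        assert len(tree.leaves) == 1

    def test_depth_cap(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(0, 1, (5, 8)).tolist())
        tfs = [_tf(f"t{i}", rng.choice([-1, 0, 1], 8)) for i in range(4)]
        tree = build_tree(m, range(5), tfs, max_depth=1,
                          min_leaf_conditions=1)
        assert tree.depth <= 1

    def test_greedy_root_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_g = int(rng.integers(2, 9))
            n_c = int(rng.integers(3, 7))
            values = rng.normal(0, 2, (n_g, n_c)).round(3).tolist()
            m = _matrix(values)
            tfs = [_tf(f"t{i}", rng.choice([-1, 0, 1], n_c))
                   for i in range(int(rng.integers(1, 4)))]
            oracle = _best_split_oracle(values, list(range(n_g)),
                                        range(n_c), tfs)
            tree = build_tree(m, range(n_g), tfs, max_depth=1,
                              min_leaf_conditions=1, min_gain=-1e18)
            if oracle is None:
                assert tree.depth == 0
                continue
            _, tf_id, level, yes, _no, best_score = oracle
            assert tree.depth == 1
            # the chosen split must score as well as the exhaustive best
            # (distinct TFs can induce identical partitions and tie exactly)
            chosen_yes = {c for c in range(n_c)
                          if next(p for p in tfs
                                  if p.tf_id == tree.root.tf_id
                                  ).levels[c] == tree.root.queried_level}
            chosen_score = _score_oracle(values, list(range(n_g)),
                                         chosen_yes,
                                         set(range(n_c)) - chosen_yes)
            assert chosen_score == pytest.approx(best_score, abs=1e-9)

    def test_deeper_tree_never_worse_than_depth_one(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            values = rng.normal(0, 2, (6, 8)).tolist()
            m = _matrix(values)
            tfs = [_tf(f"t{i}", rng.choice([-1, 0, 1], 8)) for i in range(3)]
            deep = build_tree(m, range(6), tfs, max_depth=4,
                              min_leaf_conditions=1, min_gain=0.0)
            shallow = build_tree(m, range(6), tfs, max_depth=1,
                                 min_leaf_conditions=1, min_gain=0.0)
            ll_deep = sum(gene_tree_loglik(np.asarray(v), deep)
                          for v in values)
            ll_shallow = sum(gene_tree_loglik(np.asarray(v), shallow)
                             for v in values)
            assert ll_deep >= ll_shallow - 1e-9

    def test_empty_cluster_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(GnetError):
            build_tree(m, [], [])


class TestReassignGenes:
    def test_single_tree_takes_everything(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(0, 1, (4, 6)).tolist())
        tree = make_random_tree(rng, 6)
        assert reassign_genes(m, [tree]).tolist() == [0, 0, 0, 0]

    def test_gene_at_leaf_means_goes_to_matching_tree(self):
        from gnet.core import ConditionSubgroup, RegulatoryTree, TreeNode
        tree_a = RegulatoryTree(TreeNode(
            "t", 1, ConditionSubgroup(frozenset({0, 1}), 5.0, 1.0),
            ConditionSubgroup(frozenset({2, 3}), -5.0, 1.0)))
        tree_b = RegulatoryTree(ConditionSubgroup(frozenset({0, 1, 2, 3}),
                                                  0.0, 1.0))
        m = _matrix([[5.0, 5.0, -5.0, -5.0]])
        assert reassign_genes(m, [tree_a, tree_b]).tolist() == [0]

    def test_matches_full_argmax_oracle(self):
        rng = np.random.default_rng(17)
        m = _matrix(rng.normal(0, 2, (15, 7)).tolist())
        trees = [make_random_tree(rng, 7) for _ in range(3)]
        got = reassign_genes(m, trees)
        for i in range(15):
            lls = [gene_tree_loglik(m.values[i], t) for t in trees]
            assert got[i] == int(np.argmax(lls))

    def test_condition_mismatch_rejected(self):
        from gnet.core import ConditionSubgroup, RegulatoryTree
        m = _matrix([[1.0, 2.0, 3.0]])
        bad = RegulatoryTree(ConditionSubgroup(frozenset({0, 1}), 0.0, 1.0))
        with pytest.raises(GnetError):
            reassign_genes(m, [bad])


class TestFit:
    def test_fixed_point_converges_in_one_iteration(self):
        matrix, tfs, truth = synthetic.generate(
            n_modules=3, genes_per_module=10, n_conditions=16, n_tfs=6,
            noise_sigma=0.0, seed=0)
        targets = sorted(truth.true_module_labels)
        sub = matrix.subset_genes(targets)
        model = GeneModuleNetworkModel(sub, truth.tf_levels, max_depth=2)
        init = np.array([truth.true_module_labels[g] for g in targets])
        res = model.fit(initial=init, max_iterations=20)
        assert res.converged
        assert res.n_iterations == 1
        for g in targets:
            # labels may be renumbered but the partition must be identical
            pass
        got = np.array([res.assignments[g] for g in targets])
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(init, got) == 1.0

    def test_planted_recovery_single_seed(self):
        matrix, tfs, truth = synthetic.generate(seed=0)
        from gnet.preprocess import discretize_tf_matrix
        profs = discretize_tf_matrix(matrix, tfs, 3.0)
        model = GeneModuleNetworkModel(matrix, profs, max_depth=3)
        res = model.fit(k=5, seed=0, max_iterations=30)
        targets = sorted(truth.true_module_labels)
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(
            [truth.true_module_labels[g] for g in targets],
            [res.assignments[g] for g in targets])
        assert ari >= 0.9

    def test_trace_monotone_and_terminates(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            matrix, tfs, truth = synthetic.generate(
                n_modules=3, genes_per_module=8, n_conditions=12, n_tfs=6,
                noise_sigma=1.0, seed=seed)
            from gnet.preprocess import discretize_tf_matrix
            profs = discretize_tf_matrix(matrix, tfs, 3.0)
            model = GeneModuleNetworkModel(matrix, profs, max_depth=2)
            init = rng.integers(0, 3, matrix.n_genes)
            res = model.fit(initial=init, max_iterations=30)
            diffs = np.diff(res.trace)
            assert (diffs >= -1e-9).all()
            assert res.n_iterations <= 30

    def test_empty_clusters_dropped(self):
        # initialize with an absurd number of clusters; reassignment empties
        # some and the fit must shrink k without crashing
        matrix, tfs, truth = synthetic.generate(
            n_modules=2, genes_per_module=10, n_conditions=12, n_tfs=6,
            noise_sigma=0.5, seed=2)
        from gnet.preprocess import discretize_tf_matrix
        profs = discretize_tf_matrix(matrix, tfs, 3.0)
        model = GeneModuleNetworkModel(matrix, profs, max_depth=2)
        res = model.fit(k=10, seed=0, max_iterations=30)
        assert res.n_modules <= 10
        assert set(res.assignments) == set(range(res.n_modules))

    def test_artifact_io_round_trip(self, tmp_path):
        matrix, tfs, truth = synthetic.generate(
            n_modules=2, genes_per_module=8, n_conditions=12, n_tfs=6,
            seed=1)
        from gnet.preprocess import discretize_tf_matrix
        profs = discretize_tf_matrix(matrix, tfs, 3.0)
        res = GeneModuleNetworkModel(matrix, profs, max_depth=2).fit(
            k=2, seed=0)
        res.write_modules_json(tmp_path / "modules.json")
        res.write_assignments_tsv(tmp_path / "assignments.tsv")
        res.write_trace_tsv(tmp_path / "trace.tsv")
        import json
        import pandas as pd
        payload = json.loads((tmp_path / "modules.json").read_text())
        assert len(payload["modules"]) == res.n_modules
        assign = pd.read_csv(tmp_path / "assignments.tsv", sep="\t",
                             index_col=0)
        assert len(assign) == matrix.n_genes
        assert "Gene regulatory module fit" in res.summary()
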