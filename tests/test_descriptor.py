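"""CART descriptor: splits, surrogates, importance, segments, profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from prodesc.exceptions import ContractError
from prodesc.schema import VariableSchema
from prodesc.synthetic import generate_two_dead_subgroups
from prodesc.tree import (
    Split,
    extract_segments,
    fit_tree,
    profile_group,
    tree_to_json,
    tree_to_text,
    variable_importance,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracle: exhaustive split enumeration


def gini(y):
    if len(y) == 0:
        return 0.0
    p = np.mean(y == 1)
    return 1 - p * p - (1 - p) * (1 - p)


def exhaustive_best_split(X, y, kinds, n_root, min_leaf):
    """Try every threshold and every code subset; same tie-break as fit_tree."""
    best = None
    nt = len(y)
    for j, name in enumerate(X.columns):
        v = X[name].to_numpy()
        candidates = []
        if kinds[j] == "continuous":
            u = np.unique(v)
            for a, b in zip(u, u[1:]):
                thr = (a + b) / 2
                candidates.append((v <= thr, (j, (float(thr),))))
        else:
            present = sorted(set(int(c) for c in v))
            for r in range(1, len(present)):
                for combo in itertools.combinations(present[1:], r - 1):
                    left = frozenset({present[0], *combo})
                    if len(left) == len(present):
                        continue
                    candidates.append((np.isin(v, sorted(left)), (j, tuple(sorted(left)))))
        for mask, key in candidates:
            nl = int(mask.sum())
            if nl < min_leaf or nt - nl < min_leaf:
                continue
            gain = (nt / n_root) * (
                gini(y) - (nl / nt) * gini(y[mask]) - ((nt - nl) / nt) * gini(y[~mask])
            )
            if best is None or gain > best[0] + 1e-12 or (
                abs(gain - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (gain, key)
    return best


def split_key(split: Split):
    return split.sort_key()


class TestFitTree:
    def test_separable_one_dimensional(self):
        table = make_table({"x": [1.0, 2.0, 8.0, 9.0]})
        tree = fit_tree(table, np.array([-1, -1, 1, 1]), max_depth=3, min_leaf=1)
        root = tree.root
        assert not root.is_leaf
        assert 2.0 < root.split.threshold < 8.0
        left, right = tree.nodes[root.left], tree.nodes[root.right]
        assert left.is_leaf and right.is_leaf
        assert left.impurity == 0.0 and right.impurity == 0.0
        assert {left.prediction, right.prediction} == {-1, 1}

    def test_uniform_labels_give_single_leaf(self):
        table = make_table({"x": [1.0, 2.0, 3.0]})
        tree = fit_tree(table, np.array([1, 1, 1]), max_depth=3, min_leaf=1)
        assert tree.root.is_leaf
        assert tree.n_leaves == 1

    def test_unlabeled_rows_rejected(self):
        table = make_table({"x": [1.0, 2.0]})
        with pytest.raises(ContractError):
            fit_tree(table, np.array([1, 0]), max_depth=2, min_leaf=1)

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(0)
        table = make_table({"x": rng.normal(size=40)})
        tree = fit_tree(table, rng.choice([-1, 1], size=40), max_depth=6, min_leaf=8)
        for node in tree.nodes:
            if node.is_leaf:
                assert node.n >= 8

    def test_children_counts_sum_to_parent(self):
        rng = np.random.default_rng(1)
        table = make_table({"x": rng.normal(size=60), "c": rng.integers(1, 5, size=60)})
        tree = fit_tree(table, rng.choice([-1, 1], size=60), max_depth=4, min_leaf=5)
        for node in tree.internal_nodes():
            assert tree.nodes[node.left].n + tree.nodes[node.right].n == node.n

    def test_improvements_nonnegative(self):
        rng = np.random.default_rng(2)
        table = make_table({"x": rng.normal(size=50), "c": rng.integers(1, 6, size=50)})
        tree = fit_tree(table, rng.choice([-1, 1], size=50), max_depth=5, min_leaf=3)
        for node in tree.internal_nodes():
            assert node.improvement > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_chosen_splits_match_exhaustive_oracle(self, seed):
        """Every internal node's split equals brute-force enumeration's best."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        table = make_table({
            "a": rng.normal(size=n),
            "b": rng.integers(1, 6, size=n),
            "c": rng.normal(size=n),
        })
        y = rng.choice([-1, 1], size=n)
        if len(set(y)) < 2:
            y[0] = -y[0]
        min_leaf = 2
        tree = fit_tree(table, y, max_depth=4, min_leaf=min_leaf)
        kinds = tree.feature_kinds
        leaf_of_rows = {}

        def rows_at(node_id, rows):
            node = tree.nodes[node_id]
            leaf_of_rows[node_id] = rows
            if node.is_leaf:
                return
            mask = node.split.goes_left(table.X[node.split.variable].to_numpy()[rows])
            rows_at(node.left, rows[mask])
            rows_at(node.right, rows[~mask])

        rows_at(0, np.arange(n))
        for node in tree.internal_nodes():
            rows = leaf_of_rows[node.node_id]
            expected = exhaustive_best_split(
                table.X.iloc[rows], y[rows], kinds, n_root=n, min_leaf=min_leaf
            )
            assert expected is not None
            gain, key = expected
            assert node.improvement == pytest.approx(gain, abs=1e-10)
            assert split_key(node.split) == key


class TestSurrogates:
    def test_exact_duplicate_has_association_one_and_equal_improvement(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        table = make_table({"x1": x, "x2": x.copy()})
        y = np.where(x > 0, 1, -1)
        tree = fit_tree(table, y, max_depth=1, min_leaf=5)
        root = tree.root
        assert root.split.variable == "x1"  # tie broken by lower variable index
        surr = {s.split.variable: s for s in root.surrogates}
        assert "x2" in surr
        assert surr["x2"].association == pytest.approx(1.0)
        assert not surr["x2"].reversed
        assert surr["x2"].improvement == pytest.approx(root.improvement, abs=1e-12)

    def test_anticorrelated_copy_is_reversed_with_association_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        table = make_table({"x1": x, "x2": -x})
        y = np.where(x > 0, 1, -1)
        tree = fit_tree(table, y, max_depth=1, min_leaf=5)
        surr = {s.split.variable: s for s in tree.root.surrogates}
        assert surr["x2"].association == pytest.approx(1.0)
        assert surr["x2"].reversed

    def test_independent_variable_excluded(self):
        """An independent binary variable cannot beat the majority baseline.

        With an unbalanced primary partition (150/50), always guessing the
        majority side agrees on 150 rows; a balanced independent code agrees
        on about 100 in either orientation, so it is simulated to fall below
        the baseline rate and must be excluded.
        """
        excluded = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.linspace(-1, 1, 200)
            noise = rng.permutation(np.repeat([1, 2], 100))
            table = make_table({"x1": x, "noise": noise})
            y = np.where(x > 0.5, 1, -1)
            tree = fit_tree(table, y, max_depth=1, min_leaf=10)
            surr_vars = {s.split.variable for s in tree.root.surrogates}
            excluded += "noise" not in surr_vars
        assert excluded == 10


class TestVariableImportance:
    def test_single_split_tree(self):
        table = make_table({"x1": [1.0, 2.0, 8.0, 9.0], "x2": [5.0, 5.0, 5.0, 5.0]})
        tree = fit_tree(table, np.array([-1, -1, 1, 1]), max_depth=1, min_leaf=1)
        vi = variable_importance(tree)
        assert vi.VI["x1"] == 1.0
        assert vi.VI["x2"] == 0.0

    def test_depth_zero_tree_all_zero(self):
        table = make_table({"x": [1.0, 2.0]})
        tree = fit_tree(table, np.array([1, 1]), max_depth=3, min_leaf=1)
        vi = variable_importance(tree)
        assert all(v == 0.0 for v in vi.VI.values())

    def test_normalization_bounds(self):
        rng = np.random.default_rng(6)
        table = make_table({
            "a": rng.normal(size=80),
            "b": rng.integers(1, 5, size=80),
            "c": rng.normal(size=80),
        })
        y = np.where(table.X["a"].to_numpy() + rng.normal(scale=0.5, size=80) > 0, 1, -1)
        tree = fit_tree(table, y, max_depth=4, min_leaf=5)
        vi = variable_importance(tree)
        vals = list(vi.VI.values())
        assert max(vals) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_hidden_duplicate_gets_nonzero_importance(self):
        """A masked near-copy never splits primarily but scores VI > 0."""
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=120)
        x2 = x1 + rng.normal(scale=0.01, size=120)  # slightly noisier copy
        table = make_table({"x1": x1, "x2": x2})
        y = np.where(x1 > 0, 1, -1)
        tree = fit_tree(table, y, max_depth=3, min_leaf=10)
        primaries = {node.split.variable for node in tree.internal_nodes()}
        assert "x2" not in primaries
        vi = variable_importance(tree)
        assert vi.VI["x1"] == 1.0
        assert vi.VI["x2"] > 0.0

    def test_planted_effect_ranking(self):
        """beta = (2, 1, 0): importance ranks x1 >= x2 > x3 across seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            X = rng.normal(size=(n, 3))
            score = 2 * X[:, 0] + 1 * X[:, 1] + rng.normal(scale=0.5, size=n)
            y = np.where(score > 0, 1, -1)
            table = make_table({"x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2]})
            tree = fit_tree(table, y, max_depth=4, min_leaf=15)
            vi = variable_importance(tree)
            if vi.VI["x1"] >= vi.VI["x2"] > vi.VI["x3"]:
                wins += 1
        assert wins >= 8


class TestSegments:
    def test_depth_zero_single_segment(self):
        table = make_table({"x": [1.0, 2.0, 3.0]})
        labels = np.array([1, 1, 1])
        tree = fit_tree(table, labels, max_depth=2, min_leaf=1)
        segs = extract_segments(tree, table, labels)
        assert len(segs) == 1
        assert segs[0].path_conditions == []
        assert segs[0].size == 3
        assert segs[0].purity == 1.0

    def test_two_leaf_conditions_complementary(self):
        table = make_table({"x": [1.0, 2.0, 8.0, 9.0]})
        labels = np.array([-1, -1, 1, 1])
        tree = fit_tree(table, labels, max_depth=1, min_leaf=1)
        segs = extract_segments(tree, table, labels)
        assert len(segs) == 2
        (v1, r1, t1), = segs[0].path_conditions
        (v2, r2, t2), = segs[1].path_conditions
        assert v1 == v2 == "x"
        assert {r1, r2} == {"<=", ">"}
        assert t1 == t2

    def test_segments_partition_rows(self):
        rng = np.random.default_rng(8)
        table = make_table({"a": rng.normal(size=100), "b": rng.integers(1, 6, size=100)})
        labels = rng.choice([-1, 1], size=100)
        tree = fit_tree(table, labels, max_depth=3, min_leaf=5)
        segs = extract_segments(tree, table, labels)
        all_ids = np.concatenate([s.member_ids for s in segs])
        assert len(all_ids) == 100
        assert len(set(all_ids.tolist())) == 100
        for s in segs:
            assert 0.5 <= s.purity <= 1.0

    def test_tightest_bounds_kept_along_path(self):
        # force two successive splits on the same variable
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        labels = np.array([-1, -1, 1, 1, 1, 1, -1, -1])
        table = make_table({"x": x})
        tree = fit_tree(table, labels, max_depth=2, min_leaf=1)
        segs = extract_segments(tree, table, labels)
        for s in segs:
            vars_seen = [v for v, _, _ in s.path_conditions]
            # at most one lower and one upper bound survive simplification
            assert vars_seen.count("x") <= 2

    def test_two_planted_dead_subgroups_recovered(self):
        """Dead class separates into high-primaries and late-stage segments."""
        table, labels, subgroup = generate_two_dead_subgroups(n=600, seed=0)
        tree = fit_tree(table, labels, max_depth=4, min_leaf=15)
        segs = extract_segments(tree, table, labels)
        dead = [s for s in segs if s.class_label == "dead"]
        assert len(dead) >= 2
        # each planted mechanism dominates a distinct dead segment
        doms = set()
        for s in dead:
            subs = subgroup[np.isin(table.ids, s.member_ids)]
            vals, counts = np.unique(subs, return_counts=True)
            if counts.max() / counts.sum() >= 0.8:
                doms.add(vals[counts.argmax()])
        assert {"dead_high_primaries", "dead_late_stage"} <= doms


class TestProfiles:
    def test_full_table_profile_is_overall_average(self):
        rng = np.random.default_rng(9)
        table = make_table({"a": rng.normal(size=30), "b": rng.integers(1, 4, size=30)})
        prof = profile_group(table, np.arange(30))
        a = table.X["a"].to_numpy()
        expected = (a.mean() - a.min()) / (a.max() - a.min())
        assert prof["a"] == pytest.approx(expected)

    def test_subset_at_minimum_scales_to_zero(self):
        table = make_table({"a": [1.0, 1.0, 5.0, 9.0]})
        prof = profile_group(table, np.array([0, 1]))
        assert prof["a"] == 0.0

    def test_zero_range_variable_maps_to_half(self):
        table = make_table({"a": [3.0, 3.0, 3.0]})
        assert profile_group(table, np.array([0]))["a"] == 0.5

    def test_hand_computed_four_row_example(self):
        # spreadsheet arithmetic: a = (2+4)/2 = 3, range 1..9 -> (3-1)/8 = 0.25
        table = make_table({"a": [1.0, 2.0, 4.0, 9.0], "b": [10.0, 20.0, 30.0, 40.0]})
        prof = profile_group(table, np.array([1, 2]))
        assert prof["a"] == pytest.approx(0.25)
        assert prof["b"] == pytest.approx(((25.0) - 10.0) / 30.0)

    def test_empty_subset_rejected(self):
        table = make_table({"a": [1.0]})
        with pytest.raises(ContractError):
            profile_group(table, np.array([], dtype=int))


class TestExport:
    def test_text_and_json_exports(self):
        table = make_table({"x": [1.0, 2.0, 8.0, 9.0]})
        tree = fit_tree(table, np.array([-1, -1, 1, 1]), max_depth=1, min_leaf=1)
        text = tree_to_text(tree)
        assert "x <=" in text
        doc = tree_to_json(tree)
        assert doc["n_root"] == 4
        assert len(doc["nodes"]) == 3
        root = doc["nodes"][0]
        assert root["split"]["variable"] == "x"
        assert root["children"] == [1, 2]
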