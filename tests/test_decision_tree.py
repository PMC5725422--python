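"""Gini tree growing, splitting, pruning and prediction."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diliforest.decision_tree import (
    TreeNode,
    TreeParams,
    best_split,
    gini_impurity,
    grow_tree,
    prune_tree,
    tree_depth,
    tree_from_dict,
    tree_predict,
    tree_predict_array,
    tree_to_dict,
    used_columns,
)


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 5), 0.5),
            ((10, 0), 0.0),
            ((3, 1), 0.375),  # 1 - (0.75^2 + 0.25^2)
            ((1, 1, 1), 2.0 / 3.0),  # uniform 3-class maximum
        ],
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_errors(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


def exact_best_split(X, y):
    """Exhaustive rational-arithmetic split search (independent oracle).

    Returns the set of (column, threshold) candidates achieving the exact
    maximum weighted impurity decrease, plus the tie-rule winner
    (smallest column, then smallest threshold).
    """
    m = len(y)
    total_pos = int(np.sum(y))

    def gini_frac(pos, n):
        return 1 - (Fraction(pos, n) ** 2 + Fraction(n - pos, n) ** 2)

    parent = gini_frac(total_pos, m)
    best_gain = None
    candidates: list[tuple[int, float]] = []
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            mask = X[:, j] <= thr
            nl = int(mask.sum())
            pl = int(y[mask].sum())
            gain = parent - (nl * gini_frac(pl, nl) + (m - nl) * gini_frac(total_pos - pl, m - nl)) / m
            if best_gain is None or gain > best_gain:
                best_gain = gain
                candidates = [(j, thr)]
            elif gain == best_gain:
                candidates.append((j, thr))
    if best_gain is None or best_gain <= 0:
        return None, set()
    return candidates[0], set(candidates)


class TestBestSplit:
    def test_midpoint_example(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        col, thr, dec = best_split(X, y, [0])
        assert (col, thr) == (0, 5.0)
        assert dec == pytest.approx(0.5)

    def test_pure_node_returns_none(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        assert best_split(X, np.zeros(6, dtype=int), [0]) is None

    def test_identical_columns_tie_breaks_to_first(self):
        x = np.array([1.0, 2.0, 8.0, 9.0])
        X = np.column_stack([x, x])
        y = np.array([0, 0, 1, 1])
        col, thr, _ = best_split(X, y, [0, 1])
        assert (col, thr) == (0, 5.0)
        winner, ties = exact_best_split(X, y)
        assert (0, 5.0) in ties and winner == (0, 5.0)

    def test_matches_exact_enumeration_on_random_instances(self):
        """On ~1000 random small instances the chosen root split attains the
        exact maximum gain; unique maxima are matched exactly."""
        rng = np.random.default_rng(2024)
        checked = unique_maxima = 0
        for _ in range(1000):
            n = int(rng.integers(4, 13))
            d = int(rng.integers(1, 4))
            X = rng.integers(0, 4, size=(n, d)).astype(float)  # small grid => frequent ties
            y = rng.integers(0, 2, size=n)
            winner, ties = exact_best_split(X, y)
            got = best_split(X, y, list(range(d)))
            if winner is None:
                assert got is None
                continue
            assert got is not None
            assert (got[0], got[1]) in ties
            if len(ties) == 1:
                assert (got[0], got[1]) == winner
                unique_maxima += 1
            checked += 1
        assert checked > 500 and unique_maxima > 100  # the sweep was non-trivial


class TestGrowTree:
    def test_separable_gives_depth_one_and_perfect_training_accuracy(self):
        x = np.concatenate([np.arange(10), np.arange(10) + 10]).astype(float)
        y = np.array([0] * 10 + [1] * 10)
        tree = grow_tree(x.reshape(-1, 1), y, TreeParams(), [0], ["D1"])
        assert tree_depth(tree) == 1
        pred = tree_predict_array(tree, x.reshape(-1, 1))
        assert np.array_equal((pred >= 0.5).astype(int), y)

    def test_min_samples_split_stops(self):
        X = np.arange(9, dtype=float).reshape(-1, 1)
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0])
        tree = grow_tree(X, y, TreeParams(min_samples_split=10), [0], ["D1"])
        assert tree.is_leaf

    def test_pure_input_single_leaf(self):
        X = np.arange(12, dtype=float).reshape(-1, 1)
        tree = grow_tree(X, np.ones(12, dtype=int), TreeParams(), [0], ["D1"])
        assert tree.is_leaf
        assert tree.probability == 1.0

    def test_empty_candidate_set_errors(self):
        with pytest.raises(ValueError):
            grow_tree(np.zeros((5, 1)), np.zeros(5, dtype=int), TreeParams(), [], ["D1"])

    def test_child_counts_sum_to_parent(self, separable_2class):
        t = separable_2class.table
        y = np.array([lab == t.scheme.positive for lab in t.labels], dtype=int)
        tree = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))

        def check(node):
            if node.is_leaf:
                return
            assert np.array_equal(node.class_counts, node.left.class_counts + node.right.class_counts)
            check(node.left)
            check(node.right)

        check(tree)

    def test_deterministic(self, noise_2class):
        t = noise_2class
        y = np.array([lab == t.scheme.positive for lab in t.labels], dtype=int)
        t1 = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))
        t2 = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))
        assert tree_to_dict(t1) == tree_to_dict(t2)


def _leaf(neg, pos):
    return TreeNode(class_counts=np.array([neg, pos]))


def _internal(name, col, thr, left, right):
    return TreeNode(
        class_counts=left.class_counts + right.class_counts,
        split_descriptor=name,
        column=col,
        threshold=thr,
        left=left,
        right=right,
    )


class TestPruneTree:
    def test_levels_zero_is_identity(self):
        tree = _internal("D1", 0, 0.5, _leaf(3, 0), _leaf(0, 3))
        before = tree_to_dict(tree)
        assert tree_to_dict(prune_tree(tree, 0)) == before

    def test_same_majority_siblings_collapse(self):
        # both children vote negative: the split changes no decision
        tree = _internal("D1", 0, 0.5, _leaf(3, 1), _leaf(4, 2))
        prune_tree(tree, 2)
        assert tree.is_leaf

    def test_noise_split_below_good_split_collapses(self):
        # root split is decisive; the left child's split is noise (both
        # grandchildren vote negative) and is removed at depth budget 2
        noisy = _internal("D2", 1, 0.3, _leaf(3, 1), _leaf(4, 0))
        tree = _internal("D1", 0, 0.5, noisy, _leaf(1, 7))
        prune_tree(tree, 2)
        assert tree.left.is_leaf
        assert not tree.is_leaf  # the decisive root split survives
        assert tree_depth(tree) == 1

    def test_useful_split_survives(self):
        tree = _internal("D1", 0, 0.5, _leaf(5, 0), _leaf(0, 5))
        prune_tree(tree, 2)
        assert not tree.is_leaf

    def test_misclassification_never_increases(self, noise_2class):
        t = noise_2class
        y = np.array([lab == t.scheme.positive for lab in t.labels], dtype=int)
        tree = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))
        before = _errors(tree, t.values, y)
        for levels in (1, 2, 3):
            pruned = prune_tree(
                grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names)),
                levels,
            )
            assert _errors(pruned, t.values, y) <= before


def _errors(tree, X, y):
    pred = (tree_predict_array(tree, X) >= 0.5).astype(int)
    return int(np.sum(pred != y))


class TestTreePredict:
    def test_single_leaf_probability(self):
        assert tree_predict(_leaf(1, 3), {"anything": 0.0}) == 0.75

    def test_boundary_value_routes_left(self):
        tree = _internal("D1", 0, 2.0, _leaf(4, 0), _leaf(0, 4))
        assert tree_predict(tree, {"D1": 2.0}) == 0.0  # <= goes left
        assert tree_predict(tree, {"D1": 2.0000001}) == 1.0

    def test_missing_descriptor_named(self):
        tree = _internal("D7", 0, 1.0, _leaf(1, 0), _leaf(0, 1))
        with pytest.raises(KeyError, match="D7"):
            tree_predict(tree, {"D1": 0.0})

    def test_array_and_scalar_paths_agree(self, separable_2class):
        t = separable_2class.table
        y = np.array([lab == t.scheme.positive for lab in t.labels], dtype=int)
        tree = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))
        arr = tree_predict_array(tree, t.values)
        for i in (0, 17, 99):
            sample = dict(zip(t.descriptor_names, t.values[i]))
            assert tree_predict(tree, sample) == arr[i]


class TestSerialization:
    def test_json_round_trip(self, separable_2class):
        t = separable_2class.table
        y = np.array([lab == t.scheme.positive for lab in t.labels], dtype=int)
        tree = grow_tree(t.values, y, TreeParams(), list(range(t.d)), list(t.descriptor_names))
        clone = tree_from_dict(tree_to_dict(tree))
        assert tree_to_dict(clone) == tree_to_dict(tree)
        assert np.array_equal(tree_predict_array(clone, t.values), tree_predict_array(tree, t.values))


@given(
    counts=st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=4).filter(
        lambda c: sum(c) > 0
    )
)
@settings(deadline=None, max_examples=200)
def test_gini_bounds(counts):
    """0 <= gini <= 1 - 1/k, with 0 exactly for pure nodes."""
    g = gini_impurity(counts)
    k = len(counts)
    assert 0.0 <= g <= 1 - 1 / k + 1e-12
    if sum(1 for c in counts if c > 0) == 1:
        assert g == 0.0
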