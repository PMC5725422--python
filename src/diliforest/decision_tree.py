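"""Binary classification tree with Gini-impurity splitting.

This is the member model of the Decision Forest: a deep CART-style binary
tree grown on *all* training samples, restricted to a candidate descriptor
pool, with a minimum-samples-to-split stopping rule and a limited bottom-up
pruning pass.  Leaves carry raw class fractions (no smoothing), so that the
forest consensus is a plain average of leaf probabilities.

Conventions (the tree is deterministic given its input):

* split thresholds are midpoints between consecutive distinct sorted values;
* a sample with value <= threshold is routed to the left child;
* among equal-gain splits the smallest column index wins, then the smallest
  threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "TreeParams",
    "TreeNode",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "prune_tree",
    "tree_predict",
    "tree_predict_array",
    "used_columns",
    "tree_depth",
    "tree_to_dict",
    "tree_from_dict",
]

_GAIN_EPS = 1e-12  # guards against float noise masquerading as positive gain


@dataclass(frozen=True)
class TreeParams:
    """Growth and pruning parameters.

    min_samples_split:
        A node with fewer samples becomes a leaf (default 10).
    prune_levels:
        How far above the deepest frontier a subtree may be collapsed
        during pruning (default 2; 0 disables pruning).
    max_depth:
        Optional hard depth cap; None = unbounded.
    """

    min_samples_split: int = 10
    prune_levels: int = 2
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.prune_levels < 0:
            raise ValueError("prune_levels must be >= 0")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")


@dataclass
class TreeNode:
    """One node of a binary tree; a leaf iff it has no children.

    ``class_counts`` is ``(negatives, positives)`` among the training
    samples reaching the node; ``probability`` is the positive fraction.
    """

    class_counts: np.ndarray
    split_descriptor: Optional[str] = None
    column: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def total(self) -> int:
        return int(self.class_counts.sum())

    @property
    def probability(self) -> float:
        return float(self.class_counts[1]) / self.total

    def collapse(self) -> None:
        """Turn an internal node into a leaf."""
        self.split_descriptor = None
        self.column = None
        self.threshold = None
        self.left = None
        self.right = None


def gini_impurity(class_counts) -> float:
    """Gini diversity index ``1 - sum_i p_i**2`` of a count vector.

    0 for a pure node, maximal (``1 - 1/k``) for a uniform k-class mix.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("gini impurity undefined for an empty node")
    p = counts / total
    return float(1.0 - np.dot(p, p))


def best_split(X: np.ndarray, y: np.ndarray, candidate_columns: Sequence[int]):
    """Exhaustive Gini split search over candidate columns.

    Scans every midpoint between consecutive distinct sorted values of every
    candidate column and returns ``(column, threshold, impurity_decrease)``
    for the split maximizing the weighted impurity decrease, or ``None`` if
    no split yields a positive decrease.  Ties go to the smallest column
    index, then the smallest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m = len(y)
    cols = np.asarray(sorted(candidate_columns), dtype=int)
    if m < 2 or cols.size == 0:
        return None
    total_pos = int(y.sum())
    parent = gini_impurity((m - total_pos, total_pos))

    Xc = X[:, cols]
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order]

    n_left = np.arange(1, m, dtype=float)[:, None]
    pos_left = np.cumsum(ys, axis=0)[:-1].astype(float)
    neg_left = n_left - pos_left
    n_right = m - n_left
    pos_right = total_pos - pos_left
    neg_right = n_right - pos_right

    gini_left = 1.0 - (pos_left**2 + neg_left**2) / n_left**2
    gini_right = 1.0 - (pos_right**2 + neg_right**2) / n_right**2
    decrease = parent - (n_left * gini_left + n_right * gini_right) / m
    decrease[xs[1:] <= xs[:-1]] = -np.inf  # only between distinct values

    # first max along thresholds = smallest threshold; first max across
    # (ascending) columns = smallest column index
    pos_best = np.argmax(decrease, axis=0)
    col_best_val = decrease[pos_best, np.arange(cols.size)]
    j = int(np.argmax(col_best_val))
    gain = float(col_best_val[j])
    if not np.isfinite(gain) or gain <= _GAIN_EPS:
        return None
    i = int(pos_best[j])
    threshold = float((xs[i, j] + xs[i + 1, j]) / 2.0)
    return int(cols[j]), threshold, gain


def _counts(y: np.ndarray) -> np.ndarray:
    pos = int(y.sum())
    return np.array([len(y) - pos, pos], dtype=int)


def _grow(X, y, params: TreeParams, candidate_columns, names, depth: int) -> TreeNode:
    node = TreeNode(class_counts=_counts(y))
    m = len(y)
    if (
        m < params.min_samples_split
        or node.class_counts[0] == 0
        or node.class_counts[1] == 0
        or (params.max_depth is not None and depth >= params.max_depth)
    ):
        return node
    split = best_split(X, y, candidate_columns)
    if split is None:
        return node
    col, threshold, _ = split
    mask = X[:, col] <= threshold
    node.column = col
    node.split_descriptor = names[col]
    node.threshold = threshold
    node.left = _grow(X[mask], y[mask], params, candidate_columns, names, depth + 1)
    node.right = _grow(X[~mask], y[~mask], params, candidate_columns, names, depth + 1)
    return node


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: TreeParams,
    candidate_columns: Sequence[int],
    descriptor_names: Sequence[str],
) -> TreeNode:
    """Grow a binary tree on ``(X, y)`` using only ``candidate_columns``.

    ``y`` is 0/1 (1 = positive class).  Recursion stops when a node is
    smaller than ``min_samples_split``, pure, or no split has positive gain.
    Pruning is a separate pass (:func:`prune_tree`).
    """
    if len(candidate_columns) == 0:
        raise ValueError("empty candidate descriptor set")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot grow a tree on an empty dataset")
    return _grow(X, y, params, list(candidate_columns), list(descriptor_names), 0)


def _height(node: TreeNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_height(node.left), _height(node.right))


def _subtree_errors(node: TreeNode) -> int:
    """Training misclassifications of the subtree's leaves (majority vote)."""
    if node.is_leaf:
        return int(node.class_counts.min())
    return _subtree_errors(node.left) + _subtree_errors(node.right)


def prune_tree(root: TreeNode, levels: int) -> TreeNode:
    """Bottom-up collapse of low subtrees that do not help on training data.

    A subtree whose root lies within ``levels`` of its deepest frontier is
    replaced by a leaf when doing so does not increase the training
    misclassification count — this removes splits that merely re-partition
    samples without changing any majority vote.  ``levels=0`` is a no-op.
    Operates in place and returns the root.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if levels == 0:
        return root

    def visit(node: TreeNode) -> None:
        if node.is_leaf:
            return
        visit(node.left)
        visit(node.right)
        if _height(node) <= levels:
            as_leaf_errors = int(node.class_counts.min())
            if as_leaf_errors <= _subtree_errors(node):
                node.collapse()

    visit(root)
    return root


def tree_predict(root: TreeNode, sample: Mapping[str, float]) -> float:
    """Route a single sample (descriptor-name mapping) to its leaf probability."""
    node = root
    while not node.is_leaf:
        name = node.split_descriptor
        if name not in sample:
            raise KeyError(f"sample is missing descriptor {name!r}")
        node = node.left if sample[name] <= node.threshold else node.right
    return node.probability


def tree_predict_array(root: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vectorized prediction for a matrix laid out like the training matrix."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=float)
    stack = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = node.probability
        else:
            mask = X[idx, node.column] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
    return out


def used_columns(root: TreeNode) -> set[int]:
    """Column indices used by any internal node of the tree."""
    cols: set[int] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            cols.add(node.column)
            stack.extend([node.left, node.right])
    return cols


def tree_depth(root: TreeNode) -> int:
    return _height(root)


def tree_to_dict(node: TreeNode) -> dict:
    """JSON-serializable representation of a tree."""
    d = {"class_counts": [int(c) for c in node.class_counts]}
    if not node.is_leaf:
        d.update(
            split_descriptor=node.split_descriptor,
            column=int(node.column),
            threshold=float(node.threshold),
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(class_counts=np.asarray(d["class_counts"], dtype=int))
    if "column" in d:
        node.split_descriptor = d["split_descriptor"]
        node.column = int(d["column"])
        node.threshold = float(d["threshold"])
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node
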