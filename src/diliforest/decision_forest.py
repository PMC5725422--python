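"""Decision Forest: descriptor-disjoint consensus tree ensemble.

Unlike Random Forests, which bag samples and subsample features into many
shallow trees, a Decision Forest builds a *small* number of deep trees, each
on **all** training samples, and forces heterogeneity by giving every tree a
descriptor pool disjoint from the descriptors already consumed by earlier
trees.  The consensus probability is the unweighted mean of the member
trees' leaf probabilities.

The multi-class variant trains one binary (one-vs-rest) forest per class and
assigns the class with the largest probability — "winner takes all" — with a
distinctive rejection output: when two or more class probabilities are
equally the largest the compound is called ``unknown`` rather than forced
into a class.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .decision_tree import (
    TreeNode,
    TreeParams,
    grow_tree,
    prune_tree,
    tree_predict,
    tree_predict_array,
    tree_from_dict,
    tree_to_dict,
    used_columns,
)
from .io_types import UNKNOWN, ClassScheme, DataError, DescriptorTable, LabeledDescriptorTable

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 5

#: Probabilities are rounded to this many decimals before the winner-takes-all
#: comparison; averages of small-integer leaf fractions can tie exactly.
TIE_DECIMALS = 12


class DegenerateModelError(DataError):
    """Raised when no tree with at least one split can be built."""


@dataclass
class Prediction:
    """One compound's prediction: class probabilities, assigned class
    (possibly ``unknown`` in multi-class mode) and a confidence score."""

    compound_id: Optional[str]
    probabilities: dict[str, float]
    assigned_class: str
    confidence: float


@dataclass
class DFModel:
    """A fitted 2-class Decision Forest.

    ``descriptor_names`` records the training column layout; every tree's
    column indices refer to it.  ``used_descriptors`` are per-tree name sets
    and are pairwise disjoint by construction.
    """

    trees: list[TreeNode]
    used_descriptors: list[frozenset[str]]
    positive_class: str
    scheme: ClassScheme
    descriptor_names: tuple[str, ...]
    params: TreeParams = field(default_factory=TreeParams)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def all_used_descriptors(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.used_descriptors:
            out |= s
        return frozenset(out)


@dataclass
class MultiClassDFModel:
    """One-vs-rest composite: one 2-class DF per class, in scheme order."""

    submodels: dict[str, DFModel]
    scheme: ClassScheme
    descriptor_names: tuple[str, ...]

    @property
    def all_used_descriptors(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.submodels.values():
            out |= m.all_used_descriptors
        return frozenset(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    descriptor_names: Sequence[str],
    positive_class: str,
    scheme: ClassScheme,
    n_trees: int,
    params: TreeParams,
) -> DFModel:
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("both classes must be present to fit a Decision Forest")
    pool = list(range(X.shape[1]))
    trees: list[TreeNode] = []
    used_sets: list[frozenset[str]] = []
    for i in range(n_trees):
        if not pool:
            logger.warning("descriptor pool exhausted after %d trees (requested %d)", i, n_trees)
            break
        tree = grow_tree(X, y, params, pool, descriptor_names)
        prune_tree(tree, params.prune_levels)
        cols = used_columns(tree)
        if not cols:
            if i == 0:
                raise DegenerateModelError(
                    "no descriptor yields a positive-gain split; cannot build any tree"
                )
            break  # a bare leaf adds nothing to the consensus; stop here
        trees.append(tree)
        used_sets.append(frozenset(descriptor_names[c] for c in cols))
        pool = [c for c in pool if c not in cols]
    return DFModel(trees, used_sets, positive_class, scheme, tuple(descriptor_names), params)


def fit_df(
    table: LabeledDescriptorTable,
    n_trees: int = DEFAULT_N_TREES,
    params: TreeParams | None = None,
) -> DFModel:
    """Fit a 2-class Decision Forest on a labeled table.

    Trees are grown sequentially; the descriptors used by each pruned tree
    are removed from the candidate pool before the next tree is grown, so
    member trees never share descriptors.  Building stops early when the
    pool is exhausted or a tree degenerates to a bare leaf.
    """
    if table.scheme.n_classes != 2 or table.scheme.positive is None:
        raise DataError("fit_df expects a 2-class table with a positive class")
    params = params or TreeParams()
    y = np.fromiter((lab == table.scheme.positive for lab in table.labels), dtype=int, count=table.n)
    return _fit_arrays(
        table.values, y, table.descriptor_names, table.scheme.positive, table.scheme, n_trees, params
    )


def fit_mcdf(
    table: LabeledDescriptorTable,
    n_trees: int = DEFAULT_N_TREES,
    params: TreeParams | None = None,
) -> MultiClassDFModel:
    """Fit the one-vs-rest multi-class Decision Forest on a 3-class table.

    For each class a binary forest is trained with that class as positive
    and the union of the other classes as negative.
    """
    if table.scheme.n_classes != 3:
        raise DataError("fit_mcdf expects a 3-class table")
    params = params or TreeParams()
    counts = table.class_counts()
    absent = [c for c, k in counts.items() if k == 0]
    if absent:
        raise DataError(f"classes {absent} absent from training data")
    submodels: dict[str, DFModel] = {}
    for cls in table.scheme.classes:
        y = np.fromiter((lab == cls for lab in table.labels), dtype=int, count=table.n)
        submodels[cls] = _fit_arrays(
            table.values, y, table.descriptor_names, cls, table.scheme, n_trees, params
        )
    return MultiClassDFModel(submodels, table.scheme, table.descriptor_names)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def df_predict(model: DFModel, sample: Mapping[str, float]) -> float:
    """Consensus probability for one sample: the unweighted mean of the
    member trees' probabilities."""
    return float(np.mean([tree_predict(t, sample) for t in model.trees]))


def _align(model_names: tuple[str, ...], needed: frozenset[str], table: DescriptorTable) -> np.ndarray:
    """Lay out a new table's columns like the training matrix.

    Only descriptors actually used by some tree must be present; unused
    training columns are filled with NaN and never consulted by routing.
    """
    have = {name: j for j, name in enumerate(table.descriptor_names)}
    missing = sorted(needed - have.keys())
    if missing:
        raise DataError(f"prediction input is missing descriptors: {missing}")
    X = np.full((table.n, len(model_names)), np.nan)
    for i, name in enumerate(model_names):
        if name in have:
            X[:, i] = table.values[:, have[name]]
    return X


def df_predict_table(model: DFModel, table: DescriptorTable | LabeledDescriptorTable) -> np.ndarray:
    """Consensus probabilities for every row of a table (columns matched by name)."""
    X = _align(model.descriptor_names, model.all_used_descriptors, table)
    return df_predict_aligned(model, X)


def df_predict_aligned(model: DFModel, X: np.ndarray) -> np.ndarray:
    """Fast path: ``X`` already uses the training column layout."""
    probs = np.stack([tree_predict_array(t, X) for t in model.trees])
    return probs.mean(axis=0)


def classify_2class(p: float, scheme: ClassScheme) -> str:
    """Binary decision rule: positive class iff p >= 0.5 (boundary included)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return scheme.positive if p >= 0.5 else scheme.negative


def _confidence(p: float) -> float:
    return abs(p - 0.5) / 0.5


def predict_2class(model: DFModel, table: DescriptorTable | LabeledDescriptorTable) -> list[Prediction]:
    """Per-compound 2-class predictions with confidence scores."""
    probs = df_predict_table(model, table)
    return [
        Prediction(cid, {model.positive_class: float(p)}, classify_2class(float(p), model.scheme), _confidence(float(p)))
        for cid, p in zip(table.compound_ids, probs)
    ]


def _assign_multiclass(prob_by_class: dict[str, float], tie_tol: float | None) -> tuple[str, float]:
    probs = np.array(list(prob_by_class.values()))
    if tie_tol is None:
        keys = np.round(probs, TIE_DECIMALS)
        winners = np.flatnonzero(keys == keys.max())
    else:
        winners = np.flatnonzero(probs >= probs.max() - tie_tol)
    p_max = float(probs.max())
    if winners.size > 1:
        return UNKNOWN, _confidence(p_max)
    return list(prob_by_class)[int(winners[0])], _confidence(p_max)


def mcdf_predict(
    model: MultiClassDFModel, sample: Mapping[str, float], tie_tol: float | None = None
) -> Prediction:
    """Winner-takes-all prediction for one sample.

    The class with the largest one-vs-rest probability wins; if two or more
    probabilities are equally the largest (after rounding to
    ``TIE_DECIMALS`` decimals, or within ``tie_tol`` when given) the output
    is ``unknown``.  Confidence derives from the maximum probability.
    """
    prob_by_class = {cls: df_predict(m, sample) for cls, m in model.submodels.items()}
    assigned, conf = _assign_multiclass(prob_by_class, tie_tol)
    return Prediction(None, prob_by_class, assigned, conf)


def predict_3class(
    model: MultiClassDFModel,
    table: DescriptorTable | LabeledDescriptorTable,
    tie_tol: float | None = None,
) -> list[Prediction]:
    """Per-compound winner-takes-all predictions for every row of a table."""
    X = _align(model.descriptor_names, model.all_used_descriptors, table)
    per_class = {cls: df_predict_aligned(m, X) for cls, m in model.submodels.items()}
    out = []
    for i, cid in enumerate(table.compound_ids):
        prob_by_class = {cls: float(p[i]) for cls, p in per_class.items()}
        assigned, conf = _assign_multiclass(prob_by_class, tie_tol)
        out.append(Prediction(cid, prob_by_class, assigned, conf))
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _df_to_dict(model: DFModel) -> dict:
    return {
        "trees": [tree_to_dict(t) for t in model.trees],
        "used_descriptors": [sorted(s) for s in model.used_descriptors],
        "positive_class": model.positive_class,
        "scheme": {"classes": list(model.scheme.classes), "positive": model.scheme.positive},
        "descriptor_names": list(model.descriptor_names),
        "params": {
            "min_samples_split": model.params.min_samples_split,
            "prune_levels": model.params.prune_levels,
            "max_depth": model.params.max_depth,
        },
    }


def _df_from_dict(d: dict) -> DFModel:
    return DFModel(
        trees=[tree_from_dict(t) for t in d["trees"]],
        used_descriptors=[frozenset(s) for s in d["used_descriptors"]],
        positive_class=d["positive_class"],
        scheme=ClassScheme(tuple(d["scheme"]["classes"]), d["scheme"]["positive"]),
        descriptor_names=tuple(d["descriptor_names"]),
        params=TreeParams(**d["params"]),
    )


def save_model(model: DFModel | MultiClassDFModel, path) -> None:
    """Persist a fitted model as a JSON bundle."""
    if isinstance(model, DFModel):
        doc = {"kind": "df2", "model": _df_to_dict(model)}
    else:
        doc = {
            "kind": "mcdf",
            "scheme": {"classes": list(model.scheme.classes), "positive": model.scheme.positive},
            "descriptor_names": list(model.descriptor_names),
            "submodels": {cls: _df_to_dict(m) for cls, m in model.submodels.items()},
        }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> DFModel | MultiClassDFModel:
    doc = json.loads(Path(path).read_text())
    if doc["kind"] == "df2":
        return _df_from_dict(doc["model"])
    return MultiClassDFModel(
        submodels={cls: _df_from_dict(m) for cls, m in doc["submodels"].items()},
        scheme=ClassScheme(tuple(doc["scheme"]["classes"]), doc["scheme"]["positive"]),
        descriptor_names=tuple(doc["descriptor_names"]),
    )
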