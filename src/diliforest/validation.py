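"""Resampling validation engines: repeated k-fold cross-validation,
two bootstrap strategies, and permutation (y-scrambling) tests.

Every engine takes a :class:`ValidationConfig` and returns a
:class:`ValidationResult` holding, per iteration, the pooled test-set
predictions, the fitted models' descriptor-usage sets, and a metric set
(2-class metrics or 3-class recall rates).  Per-iteration randomness
derives from a single master seed through ``numpy`` seed sequences keyed by
``(iteration, attempt)``, so results are bit-reproducible and individual
iterations can be replayed in isolation.

Bootstrap strategies:

* **Strategy A** draws with replacement until a fixed fraction (63.2% by
  default) of *unique* compounds is in the boot, so the out-of-boot test
  set has a constant size while the boot size varies (mean boot size
  follows the coupon-collector expectation, e.g. ~452 draws for n=451).
* **Strategy B** is the classical bootstrap: exactly n draws with
  replacement; the out-of-boot count varies around n/e.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .decision_forest import (
    DEFAULT_N_TREES,
    DegenerateModelError,
    classify_2class,
    df_predict_aligned,
    fit_df,
    fit_mcdf,
    _assign_multiclass,
)
from .decision_tree import TreeParams
from .io_types import ClassScheme, DataError, LabeledDescriptorTable
from .metrics import (
    MetricSet2,
    RecallSet3,
    confusion_2class,
    confusion_3class,
    metrics_2class,
    recall_rates,
)

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class ValidationConfig:
    """Configuration for one validation run.

    mode:
        'crossval', 'bootstrapA', 'bootstrapB' or 'permutation'.
    k:
        Number of cross-validation folds (default 5).
    iterations:
        Number of repeats (1000 in a full-scale study; strategy B is
        conventionally run with 2000).
    unique_fraction:
        Strategy A's stop rule: draw until ceil(unique_fraction * n) unique
        compounds are in the boot (default 0.632).
    stratified:
        Stratify fold assignment by class (off by default: folds are plain
        uniform random partitions).
    """

    mode: str = "crossval"
    k: int = 5
    iterations: int = 1000
    unique_fraction: float = 0.632
    master_seed: int = 0
    n_trees: int = DEFAULT_N_TREES
    tree_params: TreeParams = field(default_factory=TreeParams)
    stratified: bool = False
    tie_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("crossval", "bootstrapA", "bootstrapB", "permutation"):
            raise DataError(f"unknown validation mode {self.mode!r}")
        if self.k < 2:
            raise DataError("k must be >= 2")
        if self.iterations < 1:
            raise DataError("iterations must be >= 1")
        if not 0.0 < self.unique_fraction < 1.0:
            raise DataError("unique_fraction must be in (0, 1)")


@dataclass
class IterationRecord:
    """Everything produced by one validation iteration."""

    index: int
    predictions: pd.DataFrame  # compound_id, actual, p_<class>..., assigned, confidence
    metrics: Union[MetricSet2, RecallSet3]
    descriptor_usage: list[frozenset[str]]  # one set per fitted (sub-)forest
    redraws: int = 0


@dataclass
class ValidationResult:
    """All iterations of one validation run plus the config that made it."""

    mode: str
    scheme: ClassScheme
    iterations: list[IterationRecord]
    config: ValidationConfig
    total_redraws: int = 0

    @property
    def n_classes(self) -> int:
        return self.scheme.n_classes

    def pooled_predictions(self) -> pd.DataFrame:
        return pd.concat([it.predictions for it in self.iterations], ignore_index=True)


# ---------------------------------------------------------------------------
# Resampling primitives
# ---------------------------------------------------------------------------

def _rng(master_seed: int, iteration: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration, attempt))
    )


def kfold_split(n: int, k: int, rng: np.random.Generator | int) -> list[np.ndarray]:
    """Randomly partition ``0..n-1`` into k groups with sizes differing by <= 1."""
    if n < k:
        raise DataError(f"cannot split {n} samples into {k} folds")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _stratified_kfold(labels: Sequence[str], k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        perm = rng.permutation(len(idx))
        for j, part in enumerate(np.array_split(perm, k)):
            folds[j].extend(idx[p] for p in part)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def bootstrap_A(
    n: int, unique_fraction: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw with replacement until ceil(unique_fraction * n) unique indices
    are in the boot.

    Returns ``(boot, out_of_boot)``: the boot is a multiset in draw order;
    the out-of-boot set (complement of the unique boot members) always has
    exactly ``n - ceil(unique_fraction * n)`` indices.
    """
    if n < 2:
        raise DataError("bootstrap needs n >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    target = int(np.ceil(unique_fraction * n))
    seen = np.zeros(n, dtype=bool)
    unique = 0
    draws: list[int] = []
    while unique < target:
        for idx in rng.integers(0, n, size=n):
            draws.append(int(idx))
            if not seen[idx]:
                seen[idx] = True
                unique += 1
                if unique >= target:
                    break
    boot = np.asarray(draws, dtype=int)
    return boot, np.flatnonzero(~seen)


def bootstrap_B(n: int, rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray]:
    """Classical bootstrap: exactly n draws with replacement; the
    out-of-boot set is whatever was never drawn."""
    if n < 2:
        raise DataError("bootstrap needs n >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    boot = rng.integers(0, n, size=n)
    seen = np.zeros(n, dtype=bool)
    seen[boot] = True
    return boot, np.flatnonzero(~seen)


# ---------------------------------------------------------------------------
# Fitting + scoring helpers
# ---------------------------------------------------------------------------

def _fit_and_predict(
    train: LabeledDescriptorTable,
    test_X: np.ndarray,
    test_ids: Sequence[str],
    test_actual: Sequence[str],
    config: ValidationConfig,
) -> tuple[pd.DataFrame, list[frozenset[str]]]:
    """Fit on a training table, predict an aligned test matrix.

    Returns a prediction frame and the descriptor-usage sets of the fitted
    forest(s) (one per sub-forest in 3-class mode).
    """
    scheme = train.scheme
    if scheme.n_classes == 2:
        model = fit_df(train, config.n_trees, config.tree_params)
        p = df_predict_aligned(model, test_X)
        frame = pd.DataFrame(
            {
                "compound_id": list(test_ids),
                "actual": list(test_actual),
                f"p_{scheme.positive}": p,
                "assigned": [classify_2class(float(x), scheme) for x in p],
                "confidence": np.abs(p - 0.5) / 0.5,
            }
        )
        return frame, [model.all_used_descriptors]
    model = fit_mcdf(train, config.n_trees, config.tree_params)
    per_class = {cls: df_predict_aligned(m, test_X) for cls, m in model.submodels.items()}
    assigned, conf = [], []
    for i in range(len(test_ids)):
        a, c = _assign_multiclass({cls: float(p[i]) for cls, p in per_class.items()}, config.tie_tol)
        assigned.append(a)
        conf.append(c)
    frame = pd.DataFrame({"compound_id": list(test_ids), "actual": list(test_actual)})
    for cls in scheme.classes:
        frame[f"p_{cls}"] = per_class[cls]
    frame["assigned"] = assigned
    frame["confidence"] = conf
    return frame, [m.all_used_descriptors for m in model.submodels.values()]


def _score(frame: pd.DataFrame, table: LabeledDescriptorTable) -> Union[MetricSet2, RecallSet3]:
    if table.scheme.n_classes == 2:
        cm = confusion_2class(frame["assigned"], frame["actual"], table.scheme)
        return metrics_2class(cm)
    cm = confusion_3class(frame["assigned"], frame["actual"])
    return recall_rates(cm)


def _folds_ok(table: LabeledDescriptorTable, folds: list[np.ndarray]) -> bool:
    """Every training complement must contain every class."""
    labels = np.asarray(table.labels)
    classes = set(table.scheme.classes)
    for fold in folds:
        train_mask = np.ones(table.n, dtype=bool)
        train_mask[fold] = False
        if set(labels[train_mask]) != classes:
            return False
    return True


def _one_cv_iteration(
    table: LabeledDescriptorTable,
    config: ValidationConfig,
    iteration: int,
    permute: bool,
) -> IterationRecord:
    labels = np.asarray(table.labels)
    for attempt in range(_MAX_REDRAWS):
        rng = _rng(config.master_seed, iteration, attempt)
        if permute:
            labels = np.asarray(table.labels)[rng.permutation(table.n)]
            work = LabeledDescriptorTable(
                table.compound_ids, table.descriptor_names, table.values, tuple(labels), table.scheme
            )
        else:
            work = table
        if config.stratified:
            folds = _stratified_kfold(work.labels, config.k, rng)
        else:
            folds = kfold_split(work.n, config.k, rng)
        if not _folds_ok(work, folds):
            logger.warning("iteration %d attempt %d: fold missing a class; re-drawing", iteration, attempt)
            continue
        frames, usage = [], []
        try:
            for fold in folds:
                train_mask = np.ones(work.n, dtype=bool)
                train_mask[fold] = False
                train = work.select_rows(np.flatnonzero(train_mask))
                frame, sets = _fit_and_predict(
                    train,
                    work.values[fold],
                    [work.compound_ids[i] for i in fold],
                    [work.labels[i] for i in fold],
                    config,
                )
                frames.append(frame)
                usage.extend(sets)
        except DegenerateModelError:
            logger.warning("iteration %d attempt %d: degenerate fit; re-drawing", iteration, attempt)
            continue
        predictions = pd.concat(frames, ignore_index=True)
        predictions.insert(0, "iteration", iteration)
        return IterationRecord(iteration, predictions, _score(predictions, work), usage, attempt)
    raise DataError(f"iteration {iteration}: exceeded {_MAX_REDRAWS} re-draws")


def run_cross_validation(table: LabeledDescriptorTable, config: ValidationConfig) -> ValidationResult:
    """Repeated k-fold cross-validation.

    Per iteration the table is randomly partitioned into k folds; each fold
    is held out once; the pooled held-out predictions are scored once.
    Iterations whose folds leave a class out of some training set are
    re-drawn (with a logged count).
    """
    records = [
        _one_cv_iteration(table, config, i, permute=False) for i in range(config.iterations)
    ]
    return ValidationResult(
        "crossval", table.scheme, records, config, sum(r.redraws for r in records)
    )


def run_permutation_tests(table: LabeledDescriptorTable, config: ValidationConfig) -> ValidationResult:
    """Permutation (y-scrambling) tests: per iteration the labels are
    uniformly shuffled (label multiset conserved, descriptors untouched) and
    one k-fold cross-validation is run on the permuted table."""
    records = [
        _one_cv_iteration(table, config, i, permute=True) for i in range(config.iterations)
    ]
    return ValidationResult(
        "permutation", table.scheme, records, config, sum(r.redraws for r in records)
    )


def run_bootstrap_validation(table: LabeledDescriptorTable, config: ValidationConfig) -> ValidationResult:
    """Bootstrap validation (strategy A or B per ``config.mode``).

    Per iteration: fit on the boot multiset (a compound drawn twice counts
    twice), score on the out-of-boot compounds.  Degenerate resamples
    (empty test set or single-class boot) are re-drawn with a logged count.
    """
    if config.mode not in ("bootstrapA", "bootstrapB"):
        raise DataError(f"mode {config.mode!r} is not a bootstrap mode")
    records = []
    for i in range(config.iterations):
        records.append(_one_bootstrap_iteration(table, config, i))
    return ValidationResult(
        config.mode, table.scheme, records, config, sum(r.redraws for r in records)
    )


def _one_bootstrap_iteration(
    table: LabeledDescriptorTable, config: ValidationConfig, iteration: int
) -> IterationRecord:
    labels = np.asarray(table.labels)
    classes = set(table.scheme.classes)
    for attempt in range(_MAX_REDRAWS):
        rng = _rng(config.master_seed, iteration, attempt)
        if config.mode == "bootstrapA":
            boot, oob = bootstrap_A(table.n, config.unique_fraction, rng)
        else:
            boot, oob = bootstrap_B(table.n, rng)
        if oob.size == 0 or set(labels[boot]) != classes:
            logger.warning("iteration %d attempt %d: degenerate resample; re-drawing", iteration, attempt)
            continue
        train = table.select_rows(boot)
        try:
            frame, usage = _fit_and_predict(
                train,
                table.values[oob],
                [table.compound_ids[i] for i in oob],
                [table.labels[i] for i in oob],
                config,
            )
        except DegenerateModelError:
            logger.warning("iteration %d attempt %d: degenerate fit; re-drawing", iteration, attempt)
            continue
        frame.insert(0, "iteration", iteration)
        return IterationRecord(iteration, frame, _score(frame, table), usage, attempt)
    raise DataError(f"iteration {iteration}: exceeded {_MAX_REDRAWS} re-draws")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize(result: ValidationResult, bins: int = 20) -> dict:
    """Mean, sample SD (ddof=1) and a fixed-grid histogram per metric.

    Iterations where a metric was undefined are excluded from that metric's
    summary, with the excluded count reported.
    """
    if not result.iterations:
        raise DataError("cannot summarize a result with zero iterations")
    metric_names = list(result.iterations[0].metrics.as_dict())
    out: dict = {"mode": result.mode, "iterations": len(result.iterations), "metrics": {}}
    for name in metric_names:
        vals = [it.metrics.as_dict()[name] for it in result.iterations]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        undefined = len(vals) - len(defined)
        lo, hi = (-1.0, 1.0) if name == "mcc" else (0.0, 1.0)
        if defined.size == 0:
            out["metrics"][name] = {"mean": None, "sd": None, "undefined": undefined}
            continue
        counts, edges = np.histogram(defined, bins=bins, range=(lo, hi))
        out["metrics"][name] = {
            "mean": float(defined.mean()),
            "sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
            "undefined": undefined,
            "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
        }
    return out
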