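"""Post-validation analyses: prediction-confidence profiling and
informative-descriptor identification.

Confidence of a prediction is ``|p - 0.5| / 0.5`` where p is the (maximum)
class probability — 0 at maximal uncertainty (p = 0.5) and 1 at the
extremes.  Pooled validation predictions are placed into ten even
confidence bins and re-scored per bin, which shows whether high-confidence
calls are actually more reliable.

Descriptor importance is usage frequency: across all forests fitted during
a validation run, each descriptor is counted once per model whose trees use
it; descriptors that the Gini split search keeps selecting under resampling
are the informative ones.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io_types import DataError
from .metrics import (
    MetricSet2,
    RecallSet3,
    confusion_2class,
    confusion_3class,
    metrics_2class,
    recall_rates,
)
from .validation import ValidationResult

__all__ = [
    "confidence",
    "ConfidenceProfile",
    "build_confidence_profile",
    "DescriptorFrequencyTable",
    "descriptor_frequency",
    "top_k",
]

N_BINS = 10


def confidence(p: float) -> float:
    """Map a class probability to a confidence score in [0, 1].

    ``confidence(p) = |p - 0.5| / 0.5``; symmetric around 0.5, so for a
    binary model the positive and negative probabilities give the same
    confidence.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return abs(p - 0.5) / 0.5


def _bin_index(c: np.ndarray) -> np.ndarray:
    """Half-open bins [0,0.1), ..., [0.9,1.0]; confidence 1.0 joins the last bin."""
    return np.minimum((np.asarray(c) * N_BINS).astype(int), N_BINS - 1)


@dataclass
class ConfidenceProfile:
    """Pooled predictions re-scored within ten even confidence bins."""

    bin_edges: np.ndarray  # length 11
    counts: np.ndarray  # length 10
    metrics: list[Optional[Union[MetricSet2, RecallSet3]]]  # None for empty bins
    n_classes: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(N_BINS):
            row: dict = {
                "bin_low": self.bin_edges[i],
                "bin_high": self.bin_edges[i + 1],
                "count": int(self.counts[i]),
            }
            if self.metrics[i] is not None:
                row.update(self.metrics[i].as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def build_confidence_profile(result: ValidationResult) -> ConfidenceProfile:
    """Assign every pooled prediction to a confidence bin and score each bin."""
    pooled = result.pooled_predictions()
    if "confidence" not in pooled.columns:
        raise DataError("validation predictions carry no confidence column")
    idx = _bin_index(pooled["confidence"].to_numpy())
    counts = np.bincount(idx, minlength=N_BINS)
    metrics: list = []
    for b in range(N_BINS):
        sub = pooled[idx == b]
        if len(sub) == 0:
            metrics.append(None)
        elif result.n_classes == 2:
            cm = confusion_2class(sub["assigned"], sub["actual"], result.scheme)
            metrics.append(metrics_2class(cm))
        else:
            metrics.append(recall_rates(confusion_3class(sub["assigned"], sub["actual"])))
    return ConfidenceProfile(np.linspace(0, 1, N_BINS + 1), counts, metrics, result.n_classes)


@dataclass
class DescriptorFrequencyTable:
    """Descriptor -> number of fitted models using it, ranked descending
    (ties broken by descriptor name)."""

    frame: pd.DataFrame  # columns: descriptor, models
    total_models: int

    def __len__(self) -> int:
        return len(self.frame)


def descriptor_frequency(result: ValidationResult) -> DescriptorFrequencyTable:
    """Count, for each descriptor, the models (across all validation
    iterations) whose trees used it.

    One fitted forest = one model; in 3-class mode each one-vs-rest
    sub-forest counts separately.  A descriptor appearing in several trees
    of one model is still counted once for that model (under descriptor
    disjointness it cannot appear twice anyway).
    """
    counts: dict[str, int] = {}
    total = 0
    for it in result.iterations:
        for used in it.descriptor_usage:
            total += 1
            for name in used:
                counts[name] = counts.get(name, 0) + 1
    frame = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), columns=["descriptor", "models"]
    )
    return DescriptorFrequencyTable(frame, total)


def top_k(table: DescriptorFrequencyTable, k: int = 10) -> pd.DataFrame:
    """The k most frequently used descriptors (whole table if k exceeds it)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        import logging

        logging.getLogger(__name__).warning(
            "requested top %d of a %d-descriptor table; returning all", k, len(table)
        )
    return table.frame.head(k).reset_index(drop=True)
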