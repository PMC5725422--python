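"""Synthetic descriptor-table generator with controlled class structure.

Real descriptor matrices (e.g. Mold2 exports for the DILIrank drugs) are
not redistributable, so every pipeline stage is exercised on generated
tables instead: Gaussian class-conditional *informative* columns whose
means are shifted between classes by a chosen effect size, pure-noise
columns with no class dependence, and optionally planted constant columns
for testing the preprocessing filter.  The generator records which columns
play which role, so descriptor-importance recovery tests are
self-validating.

Presets mirror the DILIrank study composition: 183 most-DILI vs 268
no-DILI for the binary problem (n=451) and 268/270/183 no/less/most for
the ternary one (n=721).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_types import (
    LESS_DILI,
    MOST_DILI,
    NO_DILI,
    THREE_CLASS,
    TWO_CLASS,
    ClassScheme,
    DataError,
    LabeledDescriptorTable,
)

__all__ = ["GeneratorSpec", "SyntheticDataset", "generate", "generate_dilirank_null"]

#: Class sizes of the DILIrank-style study datasets.
PRESET_TWO_CLASS_SIZES = {NO_DILI: 268, MOST_DILI: 183}
PRESET_THREE_CLASS_SIZES = {NO_DILI: 268, LESS_DILI: 270, MOST_DILI: 183}

#: Descriptor count for the all-noise presets.  The calibration of null
#: distributions is insensitive to this number; 100 columns keep the
#: descriptor-disjoint forest well supplied with candidate descriptors.
PRESET_D_NOISE = 100


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic table.

    class_sizes:
        Mapping class name -> row count; 2 or 3 classes.
    d_informative / d_noise / constant_columns:
        Numbers of class-shifted, class-independent and constant columns.
    effect_size:
        Standardized mean shift between consecutive classes on informative
        columns (class j has mean ``j * effect_size``, unit SD).
    heavy_tailed:
        Draw from a Student-t (3 df, rescaled to unit variance) instead of
        a Gaussian, for robustness experiments.
    """

    class_sizes: dict[str, int]
    d_informative: int = 0
    d_noise: int = 50
    effect_size: float = 1.0
    constant_columns: int = 0
    heavy_tailed: bool = False
    seed: int = 0
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.class_sizes) not in (2, 3):
            raise DataError("class_sizes must define 2 or 3 classes")
        if any(v < 1 for v in self.class_sizes.values()):
            raise DataError("every class needs at least one compound")
        if min(self.d_informative, self.d_noise, self.constant_columns) < 0:
            raise DataError("column counts must be >= 0")
        if self.d_informative + self.d_noise + self.constant_columns < 1:
            raise DataError("the table needs at least one column")

    def scheme(self) -> ClassScheme:
        classes = tuple(self.class_sizes)
        if len(classes) == 2:
            pos = self.positive_class or (MOST_DILI if MOST_DILI in classes else classes[-1])
            return ClassScheme(classes, positive=pos)
        return ClassScheme(classes)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated table plus the ground-truth role of every column."""

    table: LabeledDescriptorTable
    informative: tuple[str, ...]
    noise: tuple[str, ...]
    constant: tuple[str, ...]

    def write_truth_sidecar(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "informative": list(self.informative),
                    "noise": list(self.noise),
                    "constant": list(self.constant),
                },
                indent=2,
            )
        )


def _draw(rng: np.random.Generator, size, heavy_tailed: bool) -> np.ndarray:
    if heavy_tailed:
        # t(3) scaled to unit variance
        return rng.standard_t(3, size=size) / np.sqrt(3.0)
    return rng.standard_normal(size)


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate a labeled descriptor table from a spec, deterministically
    in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme()
    labels: list[str] = []
    for cls, size in spec.class_sizes.items():
        labels.extend([cls] * size)
    n = len(labels)
    class_index = np.array([scheme.classes.index(lab) for lab in labels])

    blocks = []
    names: list[str] = []
    informative = [f"INF{i + 1:03d}" for i in range(spec.d_informative)]
    noise = [f"NSE{i + 1:03d}" for i in range(spec.d_noise)]
    constant = [f"CST{i + 1:03d}" for i in range(spec.constant_columns)]
    if spec.d_informative:
        shift = class_index[:, None] * spec.effect_size
        blocks.append(_draw(rng, (n, spec.d_informative), spec.heavy_tailed) + shift)
        names.extend(informative)
    if spec.d_noise:
        blocks.append(_draw(rng, (n, spec.d_noise), spec.heavy_tailed))
        names.extend(noise)
    if spec.constant_columns:
        blocks.append(np.zeros((n, spec.constant_columns)))
        names.extend(constant)
    values = np.hstack(blocks)

    ids = tuple(f"cmpd{i + 1:04d}" for i in range(n))
    table = LabeledDescriptorTable(ids, tuple(names), values, tuple(labels), scheme)
    return SyntheticDataset(table, tuple(informative), tuple(noise), tuple(constant))


def generate_dilirank_null(
    mode: str, seed: int = 0, d_noise: int = PRESET_D_NOISE
) -> LabeledDescriptorTable:
    """All-noise preset with the DILIrank study's class composition.

    ``mode='two_class'`` gives 451 compounds (268 no-DILI, 183 most-DILI);
    ``mode='three_class'`` gives 721 (268 no, 270 less, 183 most).  All
    descriptors are label-independent noise, so any apparent skill measured
    on these tables is chance correlation.
    """
    if mode == "two_class":
        sizes = dict(PRESET_TWO_CLASS_SIZES)
    elif mode == "three_class":
        sizes = dict(PRESET_THREE_CLASS_SIZES)
    else:
        raise DataError(f"unknown preset mode {mode!r}; use 'two_class' or 'three_class'")
    spec = GeneratorSpec(class_sizes=sizes, d_informative=0, d_noise=d_noise, seed=seed)
    return generate(spec).table
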