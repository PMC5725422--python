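"""Descriptor-table data model, file I/O and dataset preprocessing.

The central container is :class:`LabeledDescriptorTable`: a dense numeric
matrix of molecular descriptors (rows = compounds, columns = descriptors,
e.g. a Mold2 export) together with a per-compound hepatotoxicity class.
Classes follow the DILIrank convention: ``no-DILI``, ``less-DILI`` and
``most-DILI``, with ``most-DILI`` as the positive class in binary mode.

Descriptor tables are read from TSV/CSV with a header row and a compound-ID
column.  Missing or non-numeric cells are rejected at ingestion (descriptor
exports are dense; silently imputing would mask upstream problems).
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_DILI = "no-DILI"
LESS_DILI = "less-DILI"
MOST_DILI = "most-DILI"
UNKNOWN = "unknown"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class ClassScheme:
    """An ordered set of class names, with a designated positive class
    for binary classification.

    Parameters
    ----------
    classes:
        Ordered class names; exactly 2 or 3 of them.
    positive:
        The positive class for a 2-class scheme (ignored in 3-class mode
        except as a one-vs-rest target).
    aliases:
        Optional extra spellings mapping onto canonical class names.
        Matching is always case-insensitive.
    """

    classes: tuple[str, ...]
    positive: str | None = None
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) not in (2, 3):
            raise DataError(f"class scheme must have 2 or 3 classes, got {len(self.classes)}")
        if len(set(self.classes)) != len(self.classes):
            raise DataError("class names must be unique")
        if self.positive is not None and self.positive not in self.classes:
            raise DataError(f"positive class {self.positive!r} not in {self.classes}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def negative(self) -> str:
        """The negative class of a 2-class scheme."""
        if self.n_classes != 2 or self.positive is None:
            raise DataError("negative class is only defined for a 2-class scheme with a positive class")
        return next(c for c in self.classes if c != self.positive)

    def normalize(self, label: str) -> str:
        """Map a raw label string onto its canonical class name."""
        lookup = {c.lower(): c for c in self.classes}
        lookup.update({k.lower(): v for k, v in self.aliases.items()})
        try:
            return lookup[label.strip().lower()]
        except KeyError:
            raise DataError(f"unknown class label {label!r}; expected one of {list(self.classes)}") from None


#: Binary DILIrank scheme: most-DILI vs no-DILI, most-DILI positive.
TWO_CLASS = ClassScheme((NO_DILI, MOST_DILI), positive=MOST_DILI)
#: Ternary DILIrank scheme.
THREE_CLASS = ClassScheme((NO_DILI, LESS_DILI, MOST_DILI))


def _check_matrix(compound_ids, descriptor_names, values) -> None:
    if values.ndim != 2:
        raise DataError("descriptor values must be a 2-D matrix")
    n, d = values.shape
    if len(compound_ids) != n:
        raise DataError(f"{len(compound_ids)} compound ids for {n} matrix rows")
    if len(descriptor_names) != d:
        raise DataError(f"{len(descriptor_names)} descriptor names for {d} matrix columns")
    dupes = _duplicates(compound_ids)
    if dupes:
        raise DataError(f"duplicate compound ids: {sorted(dupes)}")
    if len(set(descriptor_names)) != d:
        raise DataError(f"duplicate descriptor names: {sorted(_duplicates(descriptor_names))}")
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise DataError(
            f"non-finite descriptor value at compound {compound_ids[bad[0]]!r}, "
            f"descriptor {descriptor_names[bad[1]]!r}"
        )


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


@dataclass(frozen=True)
class DescriptorTable:
    """An unlabeled compounds-by-descriptors matrix."""

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_ids", tuple(str(c) for c in self.compound_ids))
        object.__setattr__(self, "descriptor_names", tuple(str(c) for c in self.descriptor_names))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _check_matrix(self.compound_ids, self.descriptor_names, self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabeledDescriptorTable:
    """A descriptor matrix with one class label per compound."""

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]
    scheme: ClassScheme

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_ids", tuple(str(c) for c in self.compound_ids))
        object.__setattr__(self, "descriptor_names", tuple(str(c) for c in self.descriptor_names))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_matrix(self.compound_ids, self.descriptor_names, self.values)
        if len(self.labels) != self.values.shape[0]:
            raise DataError(f"{len(self.labels)} labels for {self.values.shape[0]} rows")
        bad = sorted({lab for lab in self.labels if lab not in self.scheme.classes})
        if bad:
            raise DataError(f"labels {bad} not in class scheme {self.scheme.classes}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels = list(self.labels)
        return {c: labels.count(c) for c in self.scheme.classes}

    def select_rows(self, index) -> "LabeledDescriptorTable":
        """Row subset / multiset by integer index array (multiplicity honored)."""
        index = np.asarray(index, dtype=int)
        ids = [self.compound_ids[i] for i in index]
        # A bootstrap multiset repeats compounds; disambiguate ids to keep them unique.
        if len(set(ids)) != len(ids):
            counts: dict[str, int] = {}
            out = []
            for cid in ids:
                k = counts.get(cid, 0)
                counts[cid] = k + 1
                out.append(cid if k == 0 else f"{cid}#{k}")
            ids = out
        return LabeledDescriptorTable(
            tuple(ids),
            self.descriptor_names,
            self.values[index],
            tuple(self.labels[i] for i in index),
            self.scheme,
        )

    def unlabeled(self) -> DescriptorTable:
        return DescriptorTable(self.compound_ids, self.descriptor_names, self.values)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path, format: str | None) -> str:
    if format is None:
        format = "tsv" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    if format not in ("tsv", "csv"):
        raise DataError(f"unsupported format {format!r}; use 'tsv' or 'csv'")
    return "\t" if format == "tsv" else ","


def read_descriptor_table(path, format: str | None = None, id_column: str = "ID") -> DescriptorTable:
    """Read a descriptor matrix from a delimited text file.

    The file must have a header row containing ``id_column``; every other
    column is parsed as a numeric descriptor.  Duplicate compound ids and
    non-numeric or empty cells are hard errors with coordinates.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise DataError(f"id column {id_column!r} not found in {path} (columns: {list(df.columns)[:5]}...)")
    ids = df[id_column].astype(str).tolist()
    dupes = _duplicates(ids)
    if dupes:
        raise DataError(f"duplicate compound ids in {path}: {sorted(dupes)}")
    desc = df.drop(columns=[id_column])
    numeric = desc.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric descriptor cell in {path}: compound {ids[r]!r}, "
            f"column {desc.columns[c]!r}, value {desc.iat[r, c]!r}"
        )
    return DescriptorTable(tuple(ids), tuple(desc.columns), numeric.to_numpy(dtype=float))


def write_descriptor_table(table, path, format: str | None = None, id_column: str = "ID") -> None:
    """Write a (labeled or unlabeled) descriptor table as TSV/CSV."""
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.DataFrame(table.values, columns=list(table.descriptor_names))
    df.insert(0, id_column, list(table.compound_ids))
    df.to_csv(path, sep=sep, index=False)


def read_label_file(path, format: str | None = None) -> dict[str, str]:
    """Read a two-column (ID, class) label file into an id -> class mapping."""
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"label file {path} needs two columns (ID, class)")
    ids = df.iloc[:, 0].astype(str).tolist()
    dupes = _duplicates(ids)
    if dupes:
        raise DataError(f"duplicate ids in label file {path}: {sorted(dupes)}")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def write_label_file(table: LabeledDescriptorTable, path, format: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, format)
    pd.DataFrame({"ID": list(table.compound_ids), "class": list(table.labels)}).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def join_labels(table: DescriptorTable, labels: Mapping[str, str], scheme: ClassScheme) -> LabeledDescriptorTable:
    """Attach class labels to a descriptor table, preserving row order."""
    missing = [cid for cid in table.compound_ids if cid not in labels]
    if missing:
        raise DataError(f"{len(missing)} compounds without labels, e.g. {missing[:5]}")
    normalized = tuple(scheme.normalize(labels[cid]) for cid in table.compound_ids)
    out = LabeledDescriptorTable(table.compound_ids, table.descriptor_names, table.values, normalized, scheme)
    logger.info("joined labels: %s", out.class_counts())
    return out


def remove_constant_descriptors(table):
    """Drop descriptor columns that are constant over all compounds.

    Returns ``(filtered_table, removed_names)`` with removed names in their
    original column order.  Applying the filter twice equals applying it once.
    """
    if table.values.shape[0] < 2:
        raise DataError("constant-descriptor filtering needs at least 2 compounds")
    varying = np.any(table.values != table.values[0], axis=0)
    if not varying.any():
        raise DataError("all descriptor columns are constant; dataset unusable")
    removed = [name for name, keep in zip(table.descriptor_names, varying) if not keep]
    if not removed:
        return table, []
    kept_names = tuple(name for name, keep in zip(table.descriptor_names, varying) if keep)
    filtered = dataclasses.replace(table, descriptor_names=kept_names, values=table.values[:, varying])
    logger.info("removed %d constant descriptors", len(removed))
    return filtered, removed


def subset_two_class(table3: LabeledDescriptorTable) -> LabeledDescriptorTable:
    """Reduce a 3-class table to the binary most-DILI vs no-DILI problem.

    The intermediate (less-DILI) compounds are dropped; relative row order
    of the remaining compounds is preserved.
    """
    if table3.scheme.n_classes != 3:
        raise DataError("subset_two_class expects a 3-class table")
    keep = [i for i, lab in enumerate(table3.labels) if lab != LESS_DILI]
    return LabeledDescriptorTable(
        tuple(table3.compound_ids[i] for i in keep),
        table3.descriptor_names,
        table3.values[keep],
        tuple(table3.labels[i] for i in keep),
        TWO_CLASS,
    )
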