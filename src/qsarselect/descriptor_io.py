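"""Reading, validating, joining and writing molecular descriptor tables.

The on-disk dialect is the one emitted by PaDEL-style descriptor
calculators: a delimited text file whose first column ("Name") holds the
molecule identifier and whose remaining columns hold one numeric
descriptor each.  Empty cells and NaN/Inf spellings are legal on input;
they survive loading as non-finite values so that cleaning decisions
stay auditable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorTable",
    "LabeledDataset",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_label_file",
    "write_label_file",
    "join_labels",
]


class DescriptorIOError(ValueError):
    """Raised when a descriptor or label file violates the format contract."""


@dataclass
class DescriptorTable:
    """A molecules x descriptors numeric matrix with identifiers.

    Parameters
    ----------
    molecule_ids
        Unique, non-empty molecule identifiers, one per row.
    feature_names
        Unique, non-empty descriptor names, one per column.
    values
        ``(n_molecules, n_features)`` float array; non-finite entries are
        allowed (they are handled by :mod:`qsarselect.preprocessing`).
    source_note
        Free-text provenance, carried through writes.
    """

    molecule_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    source_note: str = ""

    def __post_init__(self) -> None:
        self.molecule_ids = [str(m) for m in self.molecule_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DescriptorIOError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.molecule_ids):
            raise DescriptorIOError(
                f"{len(self.molecule_ids)} molecule ids but {n} value rows"
            )
        if p != len(self.feature_names):
            raise DescriptorIOError(
                f"{len(self.feature_names)} feature names but {p} value columns"
            )
        _check_unique(self.molecule_ids, "molecule id")
        _check_unique(self.feature_names, "feature name")
        if any(not m for m in self.molecule_ids):
            raise DescriptorIOError("empty molecule id")
        if any(not f for f in self.feature_names):
            raise DescriptorIOError("empty feature name")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame indexed by molecule id."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.molecule_ids, name="Name"),
            columns=self.feature_names,
        )

    def select_features(self, names: Sequence[str]) -> "DescriptorTable":
        """Return a copy restricted to ``names`` (kept in the given order)."""
        missing = [f for f in names if f not in set(self.feature_names)]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        idx = [self.feature_names.index(f) for f in names]
        return DescriptorTable(
            molecule_ids=list(self.molecule_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            source_note=self.source_note,
        )


@dataclass
class LabeledDataset:
    """A descriptor table joined with one binary class label per molecule."""

    table: DescriptorTable
    labels: list[str]
    positive_class_name: str
    negative_class_name: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.labels) != self.table.n_molecules:
            raise DescriptorIOError("one label required per molecule")
        classes = sorted(set(self.labels))
        if len(classes) > 2:
            raise DescriptorIOError(f"more than two classes: {classes}")
        if self.positive_class_name not in classes and classes:
            # positive class may be legitimately empty only until training
            logger.warning(
                "positive class %r absent from labels", self.positive_class_name
            )
        negatives = [c for c in classes if c != self.positive_class_name]
        if not self.negative_class_name:
            self.negative_class_name = negatives[0] if negatives else "negative"

    @property
    def n(self) -> int:
        return self.table.n_molecules

    @property
    def n_pos(self) -> int:
        return sum(1 for c in self.labels if c == self.positive_class_name)

    @property
    def n_neg(self) -> int:
        return self.n - self.n_pos

    @property
    def class_counts(self) -> tuple[int, int, int]:
        """(n, n_pos, n_neg)."""
        return (self.n, self.n_pos, self.n_neg)

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 for the positive class, 0 otherwise."""
        return np.fromiter(
            (1 if c == self.positive_class_name else 0 for c in self.labels),
            dtype=int,
            count=self.n,
        )

    def class_fractions(self) -> tuple[float, float]:
        """(positive, negative) class fractions of the dataset."""
        return (self.n_pos / self.n, self.n_neg / self.n)

    def require_both_classes(self) -> None:
        """Raise unless both classes are non-empty (precondition of training)."""
        if self.n_pos == 0 or self.n_neg == 0:
            raise DescriptorIOError(
                f"both classes must be non-empty before training "
                f"(n_pos={self.n_pos}, n_neg={self.n_neg})"
            )

    def select_features(self, names: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(
            table=self.table.select_features(names),
            labels=list(self.labels),
            positive_class_name=self.positive_class_name,
            negative_class_name=self.negative_class_name,
        )


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise DescriptorIOError(f"duplicate {what}: {item!r}")
        seen.add(item)


def read_descriptor_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    source_note: str = "",
) -> DescriptorTable:
    """Read a PaDEL-style descriptor table.

    First column is the molecule identifier; remaining columns are
    numeric.  Empty cells and case-insensitive NaN/Inf spellings are
    parsed to non-finite floats rather than rejected.

    Raises
    ------
    DescriptorIOError
        On duplicate molecule ids, duplicate feature names, or a file
        with no data rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise DescriptorIOError(f"{path}: no data rows")
    if df.shape[1] < 2:
        raise DescriptorIOError(f"{path}: need an id column plus >=1 descriptor")
    ids = df.iloc[:, 0].astype(str).tolist()
    names = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        values[:, j] = _parse_numeric(raw[col], col, path)
    table = DescriptorTable(
        molecule_ids=ids,
        feature_names=names,
        values=values,
        source_note=source_note or str(path),
    )
    logger.info(
        "read %s: %d molecules x %d descriptors", path, table.n_molecules,
        table.n_features,
    )
    return table


_NONFINITE = {
    "": np.nan,
    "nan": np.nan,
    "na": np.nan,
    "inf": np.inf,
    "+inf": np.inf,
    "infinity": np.inf,
    "+infinity": np.inf,
    "-inf": -np.inf,
    "-infinity": -np.inf,
}


def _parse_numeric(col: pd.Series, name: str, path: Path) -> np.ndarray:
    out = np.empty(len(col), dtype=float)
    for i, cell in enumerate(col.astype(str).str.strip()):
        key = cell.lower()
        if key in _NONFINITE:
            out[i] = _NONFINITE[key]
            continue
        try:
            out[i] = float(cell)
        except ValueError:
            raise DescriptorIOError(
                f"{path}: unparseable cell {cell!r} in column {name!r}, row {i}"
            ) from None
    return out


def write_descriptor_table(
    table: DescriptorTable, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a table in the same dialect ``read_descriptor_table`` accepts.

    Finite values round-trip bit-for-bit (written with ``repr`` precision).
    """
    df = table.to_frame()
    df.to_csv(path, sep=delimiter, float_format=None, na_rep="NaN")


def read_label_file(
    path: str | Path, *, delimiter: str = ","
) -> dict[str, str]:
    """Read a two-column (id, class) label file into a mapping."""
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise DescriptorIOError(f"{path}: label file needs (id, class) columns")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids.tolist(), "label id")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def write_label_file(
    labels: Mapping[str, str], path: str | Path, *, delimiter: str = ","
) -> None:
    pd.DataFrame(
        {"Name": list(labels.keys()), "class": list(labels.values())}
    ).to_csv(path, sep=delimiter, index=False)


def join_labels(
    table: DescriptorTable,
    labels: Mapping[str, str],
    positive_class_name: str,
) -> LabeledDataset:
    """Join a descriptor table with an id -> class mapping.

    Every molecule in the table must be labeled; labeled molecules absent
    from the table are reported to the log but tolerated (label files may
    cover a superset of the assayed molecules).
    """
    classes = sorted(set(labels.values()))
    if len(classes) > 2:
        raise DescriptorIOError(f"label mapping uses >2 classes: {classes}")
    missing = [m for m in table.molecule_ids if m not in labels]
    if missing:
        raise DescriptorIOError(
            f"no label for table molecules: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    extra = sorted(set(labels) - set(table.molecule_ids))
    if extra:
        logger.info("%d labeled molecules absent from table: %s", len(extra),
                    extra[:10])
    return LabeledDataset(
        table=table,
        labels=[labels[m] for m in table.molecule_ids],
        positive_class_name=positive_class_name,
    )
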