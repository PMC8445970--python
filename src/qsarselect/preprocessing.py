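"""Feature-space cleaning and inverse-class-size training weights.

Descriptors that repeat a single value across all molecules carry no
information for classification and are discarded before feature
selection.  Descriptors with non-finite entries (missing or overflowed
descriptor computations) are likewise removed rather than imputed, so
the matrix handed to the learners is entirely finite.

Class imbalance is handled with balanced inverse-class-size weights:
w_c = n / (2 * n_c) for each class c, so each class contributes exactly
half of the total training mass (n_pos * w_pos = n_neg * w_neg = n / 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptor_io import DescriptorTable, LabeledDataset

__all__ = [
    "CleaningReport",
    "ClassWeights",
    "drop_constant_features",
    "drop_nonfinite_features",
    "clean_features",
    "compute_class_weights",
]


class PreprocessingError(ValueError):
    pass


@dataclass
class CleaningReport:
    removed_constant: list[str] = field(default_factory=list)
    removed_nonfinite: list[str] = field(default_factory=list)
    n_features_before: int = 0
    n_features_after: int = 0

    @property
    def removed(self) -> set[str]:
        return set(self.removed_constant) | set(self.removed_nonfinite)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        """Combine two sequential cleaning passes into one report."""
        return CleaningReport(
            removed_constant=self.removed_constant + other.removed_constant,
            removed_nonfinite=self.removed_nonfinite + other.removed_nonfinite,
            n_features_before=self.n_features_before,
            n_features_after=other.n_features_after,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_features_before": self.n_features_before,
            "n_features_after": self.n_features_after,
            "removed_constant": self.removed_constant,
            "removed_nonfinite": self.removed_nonfinite,
        }, indent=2))


@dataclass(frozen=True)
class ClassWeights:
    """Balanced inverse-class-size weights w_c = n / (2 n_c)."""

    w_pos: float
    w_neg: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Weights rounded for reporting; training always uses full precision."""
        return (round(self.w_pos, ndigits), round(self.w_neg, ndigits))

    def sample_weights(self, y: np.ndarray) -> np.ndarray:
        """Per-sample training weights for a 0/1 label vector."""
        y = np.asarray(y)
        return np.where(y == 1, self.w_pos, self.w_neg).astype(float)


def _constant_mask(values: np.ndarray) -> np.ndarray:
    """True for columns with fewer than two distinct finite values."""
    n, p = values.shape
    mask = np.zeros(p, dtype=bool)
    for j in range(p):
        finite = values[np.isfinite(values[:, j]), j]
        # exact equality: descriptors are deterministic computations
        mask[j] = np.unique(finite).size < 2
    return mask


def drop_constant_features(
    table: DescriptorTable,
) -> tuple[DescriptorTable, CleaningReport]:
    """Remove descriptors that take a single value for all molecules.

    Constancy is judged on exact value equality over the finite entries.
    Raises if every feature is constant (nothing left to learn on).
    """
    if table.n_features == 0:
        raise PreprocessingError("empty table")
    mask = _constant_mask(table.values)
    if mask.all():
        raise PreprocessingError("all features constant; nothing to learn on")
    removed = [f for f, m in zip(table.feature_names, mask) if m]
    kept = [f for f, m in zip(table.feature_names, mask) if not m]
    report = CleaningReport(
        removed_constant=removed,
        n_features_before=table.n_features,
        n_features_after=len(kept),
    )
    return table.select_features(kept), report


def drop_nonfinite_features(
    table: DescriptorTable,
) -> tuple[DescriptorTable, CleaningReport]:
    """Remove descriptors containing any NaN or infinite entry."""
    mask = ~np.isfinite(table.values).all(axis=0)
    removed = [f for f, m in zip(table.feature_names, mask) if m]
    kept = [f for f, m in zip(table.feature_names, mask) if not m]
    report = CleaningReport(
        removed_nonfinite=removed,
        n_features_before=table.n_features,
        n_features_after=len(kept),
    )
    return table.select_features(kept), report


def clean_features(
    table: DescriptorTable,
) -> tuple[DescriptorTable, CleaningReport]:
    """Full cleaning pass: drop non-finite columns, then constant columns."""
    table, rep_nf = drop_nonfinite_features(table)
    table, rep_const = drop_constant_features(table)
    return table, rep_nf.merge(rep_const)


def compute_class_weights(dataset: LabeledDataset) -> ClassWeights:
    """Inverse-class-size weights for an imbalanced binary dataset.

    With n molecules of which n_pos are positive and n_neg negative,

        w_pos = n / (2 n_pos),   w_neg = n / (2 n_neg)

    e.g. 56 toxic of 171 gives (1.53, 0.74) at two decimals.  Values are
    returned at full precision; round only for reporting.
    """
    dataset.require_both_classes()
    n, n_pos, n_neg = dataset.class_counts
    return ClassWeights(w_pos=n / (2 * n_pos), w_neg=n / (2 * n_neg))
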