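"""Recursive feature elimination (RFE) and the cardinality sweep.

RFE repeatedly trains an estimator on the surviving descriptors, ranks
them by split-gain importance, and discards the least important, until
every descriptor has been ordered.  Because elimination is backward and
one step at a time, slicing the tail of the elimination order yields a
family of *nested* feature sets, which is what the cardinality sweep
(|S| = 2..20) exploits: set(k) is always a subset of set(k+1).

Tie-breaking is deterministic: among descriptors with equal importance
the lexicographically last name is eliminated first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptor_io import LabeledDataset
from .estimators import EstimatorSpec, fit_weighted

__all__ = [
    "FeatureRanking",
    "FeatureSet",
    "rank_features_rfe",
    "cardinality_sweep",
]


@dataclass(frozen=True)
class FeatureSet:
    """An ordered list of selected descriptor names."""

    names: tuple[str, ...]

    def __init__(self, names) -> None:
        object.__setattr__(self, "names", tuple(names))

    @property
    def cardinality(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def without(self, name: str) -> "FeatureSet":
        if name not in self.names:
            raise KeyError(name)
        return FeatureSet(n for n in self.names if n != name)


@dataclass
class FeatureRanking:
    """Full elimination order: first-eliminated to last-surviving."""

    elimination_order: list[str]
    estimator: EstimatorSpec = None

    def top(self, k: int) -> FeatureSet:
        """The k last-surviving (most important) descriptors.

        Ordered as in the elimination order, i.e. least important of the
        k first, the overall survivor last.
        """
        if not 1 <= k <= len(self.elimination_order):
            raise ValueError(f"k={k} outside 1..{len(self.elimination_order)}")
        return FeatureSet(self.elimination_order[-k:])

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV: rank 1 = first eliminated (least important)."""
        pd.DataFrame({
            "rank": np.arange(1, len(self.elimination_order) + 1),
            "feature": self.elimination_order,
        }).to_csv(path, index=False)


def _elimination_round(
    importances: np.ndarray, names: list[str], n_drop: int
) -> list[int]:
    """Indices to eliminate this round, worst first.

    Order: ascending importance; ties broken by eliminating the
    lexicographically last name first.
    """
    order = sorted(
        range(len(names)),
        key=lambda j: (importances[j], _ReverseStr(names[j])),
    )
    return order[:n_drop]


class _ReverseStr(str):
    """str whose comparison order is reversed (for descending tie-break)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def rank_features_rfe(
    dataset: LabeledDataset,
    estimator: EstimatorSpec,
    step: int = 1,
) -> FeatureRanking:
    """Order all descriptors by recursive backward elimination.

    Parameters
    ----------
    dataset
        Cleaned dataset (finite values, no constant descriptors).
    estimator
        Family, hyperparameters, class weights and seed used for every
        refit during elimination.
    step
        Number of descriptors dropped per round (>= 1).  The default of
        one drop per round maximizes ranking resolution and makes the
        sweep sets nested.

    Returns
    -------
    FeatureRanking
        A permutation of the dataset's feature names; deterministic for
        a fixed seed.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    dataset.require_both_classes()
    names = list(dataset.table.feature_names)
    if len(names) < 2:
        raise ValueError("need at least 2 features to rank")
    X_full = dataset.table.values
    y = dataset.y
    col = {f: j for j, f in enumerate(names)}

    remaining = list(names)
    eliminated: list[str] = []
    while len(remaining) > 1:
        X = X_full[:, [col[f] for f in remaining]]
        est = fit_weighted(estimator, X, y)
        importances = np.asarray(est.feature_importances_, dtype=float)
        n_drop = min(step, len(remaining) - 1)
        drop_idx = _elimination_round(importances, remaining, n_drop)
        round_names = [remaining[j] for j in drop_idx]  # worst first
        eliminated.extend(round_names)
        dropped = set(round_names)
        remaining = [f for f in remaining if f not in dropped]
    eliminated.extend(remaining)
    return FeatureRanking(elimination_order=eliminated, estimator=estimator)


def cardinality_sweep(
    ranking: FeatureRanking, k_min: int = 2, k_max: int = 20
) -> dict[int, FeatureSet]:
    """Nested feature sets of cardinality k_min..k_max from one ranking."""
    p = len(ranking.elimination_order)
    if k_max > p:
        raise ValueError(f"k_max={k_max} exceeds number of features {p}")
    if k_min < 1 or k_min > k_max:
        raise ValueError(f"invalid cardinality range {k_min}..{k_max}")
    return {k: ranking.top(k) for k in range(k_min, k_max + 1)}
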