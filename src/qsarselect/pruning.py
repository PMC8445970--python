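"""Greedy backward pruning of a selected descriptor set.

RFE returns a set of a requested cardinality, but that set is not
guaranteed optimal.  Pruning refines it: at each step every reduced set
obtained by dropping a single descriptor is scored by replicated CV, and
the drop that yields the highest mean accuracy is committed.  Pruning
continues past the accuracy peak (to demonstrate the decline) until the
mean accuracy has fallen for ``extra_steps`` consecutive steps or only
two descriptors remain; the returned best set is the argmax over the
trace.

All candidate evaluations within a step share the same replication
seeds, so the comparison between candidate deletions is paired.
Optionally a named hyperparameter (typically ``max_depth``) is retuned
by a 1-D grid at each step, since the best depth shrinks with the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .descriptor_io import LabeledDataset
from .estimators import EstimatorSpec
from .feature_selection import FeatureSet
from .model_evaluation import CVConfig, CVResult, default_grid, repeated_cv

__all__ = ["PruningStep", "PruningTrace", "backward_prune"]


@dataclass
class PruningStep:
    """One row of the pruning trace (the initial row removes nothing)."""

    removed_feature: str | None
    cardinality: int
    max: float
    mean: float
    std: float
    retuned_params: dict[str, Any] = field(default_factory=dict)


@dataclass
class PruningTrace:
    steps: list[PruningStep]
    best_cardinality: int
    best_feature_set: FeatureSet

    def to_frame(self) -> pd.DataFrame:
        """Tabular trace with columns Features, Removed, Max, Mean, Std.Dev."""
        return pd.DataFrame({
            "Features": [s.cardinality for s in self.steps],
            "Removed": [s.removed_feature or "-" for s in self.steps],
            "Max": [s.max for s in self.steps],
            "Mean": [s.mean for s in self.steps],
            "Std.Dev": [s.std for s in self.steps],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _tune_1d(
    dataset: LabeledDataset,
    features: Sequence[str],
    estimator: EstimatorSpec,
    cv: CVConfig,
    param_values: Mapping[str, Sequence[Any]],
) -> EstimatorSpec:
    """Retune the named parameters one at a time over their value lists.

    Ties in mean accuracy prefer the smaller value (None sorts last).
    """
    for name, values in param_values.items():
        best_key, best_value = None, None
        for i, v in enumerate(values):
            candidate = estimator.with_params(**{name: v})
            mean = repeated_cv(dataset, features, candidate, cv).mean
            size = float("inf") if v is None else v
            key = (-mean, size if isinstance(size, (int, float)) else i, i)
            if best_key is None or key < best_key:
                best_key, best_value = key, v
        estimator = estimator.with_params(**{name: best_value})
    return estimator


def backward_prune(
    dataset: LabeledDataset,
    start_set: FeatureSet,
    estimator: EstimatorSpec,
    cv: CVConfig,
    extra_steps: int = 2,
    retune: Sequence[str] = (),
    retune_grid: Mapping[str, Sequence[Any]] | None = None,
) -> PruningTrace:
    """Greedy single-feature backward elimination with per-step CV.

    Parameters
    ----------
    dataset
        Cleaned, labeled dataset containing every feature of ``start_set``.
    start_set
        The RFE-selected set to refine (cardinality >= 2).
    estimator
        Tuned estimator spec for the starting set.
    cv
        Replication config; all candidates in one step share its seeds.
    extra_steps
        Number of consecutive mean-accuracy declines tolerated before
        stopping (the trace then still documents the decline).
    retune
        Names of hyperparameters retuned by a 1-D sweep at each step;
        values are taken from ``retune_grid`` or the family's default
        grid.

    Returns
    -------
    PruningTrace
        All steps, and the feature set with the highest mean accuracy.
    """
    missing = [f for f in start_set if f not in set(dataset.table.feature_names)]
    if missing:
        raise ValueError(f"start set features not in dataset: {missing}")
    if start_set.cardinality < 2:
        raise ValueError("start set must contain at least 2 features")

    retune_values: dict[str, Sequence[Any]] = {}
    if retune:
        grid = dict(retune_grid or {})
        family_default = default_grid(
            estimator.family, start_set.cardinality
        ).grid
        for name in retune:
            retune_values[name] = grid.get(name, family_default[name])

    current = start_set
    if retune_values:
        estimator = _tune_1d(dataset, current, estimator, cv, retune_values)
    first = repeated_cv(dataset, current, estimator, cv)
    steps = [_record(None, current, first, estimator)]
    sets = [current]

    declines = 0
    prev_mean = first.mean
    while current.cardinality > 2 and declines < extra_steps:
        best = None  # (key, feature, result)
        for feat in current:
            candidate = current.without(feat)
            result = repeated_cv(dataset, candidate, estimator, cv)
            key = (-result.mean, result.std, feat)
            if best is None or key < best[0]:
                best = (key, feat, result)
        assert best is not None
        _, feat, result = best
        current = current.without(feat)
        if retune_values:
            retuned = _tune_1d(dataset, current, estimator, cv, retune_values)
            if retuned.params != estimator.params:
                estimator = retuned
                result = repeated_cv(dataset, current, estimator, cv)
        steps.append(_record(feat, current, result, estimator))
        sets.append(current)
        declines = declines + 1 if result.mean < prev_mean else 0
        prev_mean = result.mean

    # argmax of mean accuracy; ties resolved toward the smaller set
    best_i = max(
        range(len(steps)), key=lambda i: (steps[i].mean, i)
    )
    return PruningTrace(
        steps=steps,
        best_cardinality=steps[best_i].cardinality,
        best_feature_set=sets[best_i],
    )


def _record(
    removed: str | None,
    current: FeatureSet,
    result: CVResult,
    estimator: EstimatorSpec,
) -> PruningStep:
    return PruningStep(
        removed_feature=removed,
        cardinality=current.cardinality,
        max=result.max,
        mean=result.mean,
        std=result.std,
        retuned_params=dict(estimator.params),
    )
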