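"""Construction of the four tree-based classifier families.

All four learners (single decision tree, random forest, extremely
randomized trees, gradient-boosted trees) expose split-gain feature
importances and accept per-sample training weights, which is what the
selection and evaluation stages rely on.  Class weights always enter as
per-sample weights so the mechanism is uniform across families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .preprocessing import ClassWeights

__all__ = ["FAMILIES", "EstimatorSpec", "build_estimator", "fit_weighted"]

FAMILIES = ("decision_tree", "random_forest", "extra_trees", "gradient_boosting")

#: Short table-column labels used in reports, by family.
FAMILY_LABELS = {
    "decision_tree": "DTC",
    "random_forest": "RFC",
    "extra_trees": "ETC",
    "gradient_boosting": "XGBC",
}


@dataclass(frozen=True)
class EstimatorSpec:
    """A classifier family plus hyperparameters, class weights and a seed."""

    family: str
    params: Mapping[str, Any] = field(default_factory=dict)
    class_weights: ClassWeights | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unsupported estimator family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )

    def with_params(self, **params: Any) -> "EstimatorSpec":
        return replace(self, params={**self.params, **params})

    def with_seed(self, seed: int) -> "EstimatorSpec":
        return replace(self, seed=int(seed))


def build_estimator(spec: EstimatorSpec):
    """Instantiate the scikit-learn / xgboost classifier for a spec.

    Everything runs single-threaded so that repeated runs with the same
    seed are bit-reproducible.
    """
    params = dict(spec.params)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.family == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "extra_trees":
        params.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **params)
    # gradient_boosting
    params.setdefault("n_estimators", 100)
    return XGBClassifier(
        booster="gbtree",
        importance_type="gain",
        random_state=spec.seed,
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
        **params,
    )


def fit_weighted(spec: EstimatorSpec, X: np.ndarray, y: np.ndarray):
    """Fit a fresh estimator with class-weighted samples; return it."""
    est = build_estimator(spec)
    if spec.class_weights is not None:
        sw = spec.class_weights.sample_weights(y)
        est.fit(X, y, sample_weight=sw)
    else:
        est.fit(X, y)
    return est
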