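"""Grid contents, replicated CV accuracy semantics, final validation."""

import numpy as np
import pytest

from qsarselect.estimators import EstimatorSpec
from qsarselect.feature_selection import FeatureSet
from qsarselect.model_evaluation import (
    CVConfig,
    GridSpec,
    _fold_iterator,
    default_grid,
    final_validation,
    grid_search_tune,
    repeated_cv,
)
from qsarselect.preprocessing import compute_class_weights
from qsarselect.synthetic_data import SyntheticSpec, generate_dataset

from conftest import make_dataset


class TestGrids:
    def test_decision_tree_grid(self):
        g = default_grid("decision_tree", 14)
        assert g.grid["max_depth"] == list(range(1, 11)) + [None]
        assert g.grid["min_samples_split"] == list(range(2, 11))
        assert g.grid["min_samples_leaf"] == list(range(1, 11))
        assert g.grid["max_features"] == list(range(1, 15))

    def test_forest_grids(self):
        for family in ("random_forest", "extra_trees"):
            g = default_grid(family, 16)
            assert g.grid["max_depth"] == list(range(1, 7)) + [None]
            assert g.grid["min_samples_split"] == [2, 3, 4, 5]
            assert g.grid["min_samples_leaf"] == [1, 2, 3, 4, 5]
            assert g.grid["max_features"] == [1, 2, 3, 4]  # floor(sqrt(16))
            assert g.grid["n_estimators"] == [100, 200]

    def test_gradient_boosting_grid(self):
        g = default_grid("gradient_boosting", 15)
        assert g.grid == {
            "learning_rate": [0.01, 0.1],
            "max_depth": [3, 5, 7, 10],
            "min_child_weight": [1, 3, 5],
            "subsample": [0.5, 0.7],
            "colsample_bytree": [0.5, 0.7],
            "n_estimators": [100, 200],
        }

    def test_combination_count(self):
        g = default_grid("gradient_boosting", 10)
        assert g.n_combinations == 2 * 4 * 3 * 2 * 2 * 2


def majority_dataset(rng, n_pos=56, n_neg=115):
    """171 molecules, pure-noise features: only the prior is learnable."""
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    X = rng.standard_normal((n, 3))
    return make_dataset(X, y)


def test_majority_learner_accuracy_is_class_prior(rng):
    """A single-leaf tree predicts the majority class; pooled accuracy is
    exactly n_neg/n in every replication."""
    dataset = majority_dataset(rng)
    # min_samples_split > n forces a single leaf; no class weights, so the
    # leaf predicts the raw majority
    spec = EstimatorSpec(
        "decision_tree", params={"min_samples_split": 400}, seed=0
    )
    cv = CVConfig(k=10, reps=5, base_seed=7)
    result = repeated_cv(dataset, FeatureSet(["f1", "f2", "f3"]), spec, cv)
    expected = 100.0 * 115 / 171
    assert result.per_rep_accuracy == pytest.approx([expected] * 5)


def test_perfect_separation_scores_100(separable_dataset):
    weights = compute_class_weights(separable_dataset)
    spec = EstimatorSpec("decision_tree", class_weights=weights, seed=1)
    cv = CVConfig(k=5, reps=10, base_seed=3)
    result = repeated_cv(separable_dataset, FeatureSet(["f2"]), spec, cv)
    assert result.per_rep_accuracy == [100.0] * 10
    assert result.mean == 100.0 and result.std == 0.0


def test_repeated_cv_deterministic(separable_dataset):
    weights = compute_class_weights(separable_dataset)
    spec = EstimatorSpec("gradient_boosting", params={"n_estimators": 10},
                         class_weights=weights, seed=1)
    cv = CVConfig(k=5, reps=4, base_seed=11)
    features = FeatureSet(["f1", "f2", "f3", "f4"])
    r1 = repeated_cv(separable_dataset, features, spec, cv)
    r2 = repeated_cv(separable_dataset, features, spec, cv)
    assert r1.per_rep_accuracy == r2.per_rep_accuracy


def test_summary_recomputable_from_replications(rng):
    dataset = majority_dataset(rng, 20, 30)
    spec = EstimatorSpec("decision_tree", params={"max_depth": 2}, seed=0)
    result = repeated_cv(
        dataset, FeatureSet(["f1", "f2"]), spec, CVConfig(k=5, reps=8, base_seed=2)
    )
    acc = np.array(result.per_rep_accuracy)
    assert result.mean == pytest.approx(acc.mean())
    assert result.max == pytest.approx(acc.max())
    assert result.std == pytest.approx(acc.std(ddof=1))


def test_stratified_folds_near_global_proportions():
    y = np.array([1] * 27 + [0] * 63)
    cfg = CVConfig(k=10, reps=1, base_seed=5)
    for _, test in _fold_iterator(y, cfg, seed=5):
        n_pos = int(y[test].sum())
        # global proportion is 2.7 positives per fold of 9
        assert n_pos in (2, 3)


class TestGridSearch:
    def test_single_combination_identity(self, separable_dataset):
        grid = GridSpec("decision_tree", {"max_depth": [3]})
        result = grid_search_tune(
            separable_dataset, FeatureSet(["f1", "f2"]), grid,
            CVConfig(k=5, reps=2, base_seed=0),
        )
        assert result.best_params == {"max_depth": 3}
        assert len(result.table) == 1

    def test_xor_needs_depth_beyond_stump(self):
        spec_data = SyntheticSpec(
            n_molecules=80, n_features=2, n_constant=0, n_informative=2,
            n_redundant=0, positive_fraction=0.5, boundary="xor_pair", seed=13,
        )
        dataset, _ = generate_dataset(spec_data)
        grid = GridSpec("decision_tree", {"max_depth": [1, 4]})
        result = grid_search_tune(
            dataset, FeatureSet(dataset.table.feature_names), grid,
            CVConfig(k=5, reps=3, base_seed=1),
        )
        assert result.best_params == {"max_depth": 4}
        stump = result.table.loc[result.table.max_depth == 1, "mean_accuracy"]
        deep = result.table.loc[result.table.max_depth == 4, "mean_accuracy"]
        assert deep.iloc[0] > stump.iloc[0]

    def test_empty_grid_is_error(self, separable_dataset):
        with pytest.raises(ValueError):
            grid_search_tune(
                separable_dataset, FeatureSet(["f1"]),
                GridSpec("decision_tree", {}),
                CVConfig(k=5, reps=1, base_seed=0),
            )

    def test_tie_prefers_smaller_model(self, separable_dataset):
        # f2 separates perfectly at any depth: all combinations tie at 100%
        grid = GridSpec("decision_tree", {"max_depth": [5, 1, None]})
        result = grid_search_tune(
            separable_dataset, FeatureSet(["f2"]), grid,
            CVConfig(k=5, reps=2, base_seed=0),
        )
        assert result.best_params == {"max_depth": 1}


class TestFinalValidation:
    def test_normal_mu_equals_sample_mean(self, separable_dataset, rng):
        dataset = majority_dataset(rng, 15, 25)
        weights = compute_class_weights(dataset)
        spec = EstimatorSpec("decision_tree", params={"max_depth": 3},
                             class_weights=weights, seed=2)
        result, summary = final_validation(
            dataset, FeatureSet(["f1", "f2"]), spec,
            CVConfig(k=5, base_seed=4), reps=25,
        )
        assert summary.mu == pytest.approx(np.mean(result.per_rep_accuracy))
        assert summary.sigma == pytest.approx(
            np.std(result.per_rep_accuracy, ddof=1)
        )

    def test_histogram_counts_conserve_reps(self, separable_dataset):
        weights = compute_class_weights(separable_dataset)
        spec = EstimatorSpec("decision_tree", class_weights=weights, seed=0)
        _, summary = final_validation(
            separable_dataset, FeatureSet(["f1", "f2"]), spec,
            CVConfig(k=5, base_seed=1), reps=10,
        )
        assert summary.bin_counts.sum() == 10
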