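"""End-to-end orchestration: clean -> weights -> RFE sweep -> tune + CV ->
select -> prune -> final validation -> reports.

The stages run in the order of the underlying study design.  Every
source of randomness is derived arithmetically from one base seed, so a
run is exactly reproducible from its config; the derivation scheme is
documented in :func:`derive_seed`.

The choice of classifier family and cardinality from the sweep matrix is
encoded as an explicit parsimony rule rather than a judgment call: among
all (cardinality, family) cells whose mean accuracy is within
``parsimony_tolerance`` percentage points of the matrix maximum, the
smallest cardinality wins (then the higher mean, then family order).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptor_io import (
    LabeledDataset,
    join_labels,
    read_descriptor_table,
    read_label_file,
    write_descriptor_table,
    write_label_file,
)
from .estimators import FAMILIES, FAMILY_LABELS, EstimatorSpec, build_estimator
from .feature_selection import FeatureSet, cardinality_sweep, rank_features_rfe
from .model_evaluation import (
    CVConfig,
    CVResult,
    DistributionSummary,
    GridSpec,
    default_grid,
    final_validation,
    grid_search_tune,
    repeated_cv,
)
from .preprocessing import CleaningReport, ClassWeights, clean_features, compute_class_weights
from .pruning import PruningTrace, backward_prune
from .synthetic_data import GroundTruth, SyntheticSpec, generate_dataset, recovery_score

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_workflow",
    "export_reports",
    "derive_seed",
    "recovery_benchmark_config",
    "shape_benchmark_config",
    "simulate_to_files",
]

_SEED_MOD = 2**31

# stage offsets for seed derivation
_STAGE = {"rfe": 1, "tune": 2, "cv": 3, "prune": 4, "final": 5, "synthetic": 6}


def derive_seed(base_seed: int, stage: str, *indices: int) -> int:
    """Deterministic per-stage seed: base + stage offset + index mixing.

    ``derive_seed(s, stage, i, j)`` = (s + 100_003*stage_offset
    + 7_919*i + 104_729*j) mod 2^31.  Distinct stages and indices get
    well-separated seed ranges; everything reproduces from ``base_seed``.
    """
    value = base_seed + 100_003 * _STAGE[stage]
    for mult, idx in zip((7_919, 104_729, 15_485_863), indices):
        value += mult * idx
    return value % _SEED_MOD


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    # data source: either file paths ...
    descriptor_path: str | None = None
    label_path: str | None = None
    positive_class: str | None = None
    # ... or a synthetic spec
    synthetic: SyntheticSpec | None = None

    families: tuple[str, ...] = FAMILIES
    k_min: int = 2
    k_max: int = 20
    cv_k: int = 10
    cv_reps: int = 100
    tune: bool = True
    tune_reps: int = 1
    grid_overrides: Mapping[str, Mapping[str, Sequence[Any]]] = field(
        default_factory=dict
    )
    # hyperparameters used when tune=False (and by RFE ranking estimators)
    fixed_params: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    parsimony_tolerance: float = 0.5
    prune_extra_steps: int = 2
    prune_retune: Sequence[str] | None = None  # None = auto (max_depth for trees)
    final_reps: int = 10_000
    base_seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown families: {unknown}")
        has_files = self.descriptor_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                "configure exactly one of (descriptor_path, label_path) "
                "or synthetic"
            )
        if has_files and (self.label_path is None or self.positive_class is None):
            raise ValueError("file input needs label_path and positive_class")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["grid_overrides"] = {
            fam: {k: list(v) for k, v in g.items()}
            for fam, g in self.grid_overrides.items()
        }
        d["fixed_params"] = {
            fam: dict(p) for fam, p in self.fixed_params.items()
        }
        d["prune_retune"] = (
            None if self.prune_retune is None else list(self.prune_retune)
        )
        d["families"] = list(self.families)
        return json.dumps(d, indent=2)


@dataclass
class RunReport:
    config: RunConfig
    cleaning: CleaningReport
    class_weights: ClassWeights
    rankings: dict[str, list[str]]
    mean_matrix: pd.DataFrame
    max_matrix: pd.DataFrame
    std_matrix: pd.DataFrame
    tuned_params: dict[tuple[str, int], dict[str, Any]]
    chosen_family: str
    chosen_cardinality: int
    chosen_feature_set: FeatureSet
    pruning_trace: PruningTrace
    final_result: CVResult
    final_summary: DistributionSummary
    selected_features: FeatureSet
    ground_truth: GroundTruth | None = None
    recovery: float | None = None


def _load_dataset(config: RunConfig) -> tuple[LabeledDataset, GroundTruth | None]:
    if config.synthetic is not None:
        dataset, truth = generate_dataset(config.synthetic)
        return dataset, truth
    table = read_descriptor_table(config.descriptor_path)
    labels = read_label_file(config.label_path)
    return join_labels(table, labels, config.positive_class), None


def _grid_for(config: RunConfig, family: str, num_features: int) -> GridSpec:
    override = config.grid_overrides.get(family)
    if override is not None:
        return GridSpec(family, {k: list(v) for k, v in override.items()})
    return default_grid(family, num_features)


def select_cell(
    mean_matrix: pd.DataFrame,
    families: Sequence[str],
    tolerance: float,
) -> tuple[str, int]:
    """Parsimony selection from the cardinality x family mean matrix.

    Candidates within ``tolerance`` points of the global maximum compete;
    the smallest cardinality wins, then the higher mean, then the order
    of ``families``.  The winner is therefore never more than
    ``tolerance`` points below the maximum.
    """
    best_mean = mean_matrix.to_numpy().max()
    candidates = []
    for fam_i, fam in enumerate(families):
        col = FAMILY_LABELS[fam]
        for k, mean in mean_matrix[col].items():
            if mean >= best_mean - tolerance:
                candidates.append((int(k), -float(mean), fam_i, fam))
    candidates.sort()
    k, neg_mean, _, fam = candidates[0]
    return fam, k


def run_workflow(config: RunConfig) -> RunReport:
    """Execute the full pipeline and (optionally) write all reports.

    Stage order: load/generate -> clean -> class weights -> per-family
    RFE ranking + cardinality sweep -> per-cell tuning and replicated CV
    -> parsimony cell selection -> greedy backward pruning -> final
    high-replication validation.  Raises with a stage-labeled message on
    failure; artifacts written so far are left in place.
    """
    stage = "load"
    try:
        dataset, truth = _load_dataset(config)
        dataset.require_both_classes()

        stage = "clean"
        table, cleaning = clean_features(dataset.table)
        dataset = LabeledDataset(
            table=table,
            labels=list(dataset.labels),
            positive_class_name=dataset.positive_class_name,
            negative_class_name=dataset.negative_class_name,
        )
        if config.k_max > table.n_features:
            raise ValueError(
                f"k_max={config.k_max} exceeds cleaned feature count "
                f"{table.n_features}"
            )
        logger.info("cleaned: %d -> %d features", cleaning.n_features_before,
                    cleaning.n_features_after)

        stage = "weights"
        weights = compute_class_weights(dataset)

        stage = "rfe"
        rankings: dict[str, list[str]] = {}
        sweeps: dict[str, dict[int, FeatureSet]] = {}
        for fam_i, family in enumerate(config.families):
            spec = EstimatorSpec(
                family=family,
                params=dict(config.fixed_params.get(family, {})),
                class_weights=weights,
                seed=derive_seed(config.base_seed, "rfe", fam_i),
            )
            ranking = rank_features_rfe(dataset, spec)
            rankings[family] = ranking.elimination_order
            sweeps[family] = cardinality_sweep(ranking, config.k_min, config.k_max)

        stage = "sweep"
        ks = list(range(config.k_min, config.k_max + 1))
        cols = [FAMILY_LABELS[f] for f in config.families]
        mean_m = pd.DataFrame(index=ks, columns=cols, dtype=float)
        max_m = pd.DataFrame(index=ks, columns=cols, dtype=float)
        std_m = pd.DataFrame(index=ks, columns=cols, dtype=float)
        mean_m.index.name = "Features"
        max_m.index.name = "Features"
        std_m.index.name = "Features"
        tuned_params: dict[tuple[str, int], dict[str, Any]] = {}
        for fam_i, family in enumerate(config.families):
            for k in ks:
                features = sweeps[family][k]
                if config.tune:
                    grid = _grid_for(config, family, k)
                    tune_cv = CVConfig(
                        k=config.cv_k, reps=config.tune_reps,
                        base_seed=derive_seed(config.base_seed, "tune", fam_i, k),
                    )
                    tuned = grid_search_tune(dataset, features, grid, tune_cv)
                    params = tuned.best_params
                else:
                    params = dict(config.fixed_params.get(family, {}))
                tuned_params[(family, k)] = params
                spec = EstimatorSpec(
                    family=family, params=params, class_weights=weights,
                    seed=derive_seed(config.base_seed, "cv", fam_i, k),
                )
                cv = CVConfig(
                    k=config.cv_k, reps=config.cv_reps,
                    base_seed=derive_seed(config.base_seed, "cv", fam_i, k),
                )
                result = repeated_cv(dataset, features, spec, cv)
                col = FAMILY_LABELS[family]
                mean_m.loc[k, col] = result.mean
                max_m.loc[k, col] = result.max
                std_m.loc[k, col] = result.std
                logger.debug("%s k=%d mean=%.2f", col, k, result.mean)

        stage = "select"
        chosen_family, chosen_k = select_cell(
            mean_m, config.families, config.parsimony_tolerance
        )
        chosen_set = sweeps[chosen_family][chosen_k]
        logger.info("selected %s with %d features",
                    FAMILY_LABELS[chosen_family], chosen_k)

        stage = "prune"
        retune = config.prune_retune
        if retune is None:
            retune = ("max_depth",) if chosen_family == "decision_tree" else ()
        fam_i = config.families.index(chosen_family)
        prune_spec = EstimatorSpec(
            family=chosen_family,
            params=tuned_params[(chosen_family, chosen_k)],
            class_weights=weights,
            seed=derive_seed(config.base_seed, "prune", fam_i),
        )
        prune_cv = CVConfig(
            k=config.cv_k, reps=config.cv_reps,
            base_seed=derive_seed(config.base_seed, "prune", fam_i),
        )
        retune_grid = None
        override = config.grid_overrides.get(chosen_family)
        if retune and override:
            retune_grid = {p: override[p] for p in retune if p in override}
        trace = backward_prune(
            dataset, chosen_set, prune_spec, prune_cv,
            extra_steps=config.prune_extra_steps,
            retune=retune, retune_grid=retune_grid,
        )

        stage = "final"
        best_step = next(
            s for s in trace.steps
            if s.cardinality == trace.best_cardinality
        )
        final_spec = EstimatorSpec(
            family=chosen_family,
            params=best_step.retuned_params,
            class_weights=weights,
            seed=derive_seed(config.base_seed, "final", fam_i),
        )
        final_cv = CVConfig(
            k=config.cv_k, reps=config.final_reps,
            base_seed=derive_seed(config.base_seed, "final", fam_i),
        )
        result, summary = final_validation(
            dataset, trace.best_feature_set, final_spec, final_cv,
            reps=config.final_reps,
        )

        report = RunReport(
            config=config,
            cleaning=cleaning,
            class_weights=weights,
            rankings=rankings,
            mean_matrix=mean_m,
            max_matrix=max_m,
            std_matrix=std_m,
            tuned_params=tuned_params,
            chosen_family=chosen_family,
            chosen_cardinality=chosen_k,
            chosen_feature_set=chosen_set,
            pruning_trace=trace,
            final_result=result,
            final_summary=summary,
            selected_features=trace.best_feature_set,
            ground_truth=truth,
            recovery=(
                recovery_score(trace.best_feature_set, truth)
                if truth is not None else None
            ),
        )
        if config.outdir is not None:
            export_reports(report, config.outdir)
        return report
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage {stage!r}: {exc}") from exc


def export_reports(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write all run artifacts (CSV/JSON/DOT) to ``outdir``.

    Idempotent: re-exporting a saved report rewrites identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    (_w(out / "config.json")).write_text(report.config.to_json())
    report.cleaning.to_json(_w(out / "cleaning_report.json"))
    (_w(out / "class_weights.json")).write_text(json.dumps({
        "w_pos": report.class_weights.w_pos,
        "w_neg": report.class_weights.w_neg,
        "w_pos_2dp": report.class_weights.rounded()[0],
        "w_neg_2dp": report.class_weights.rounded()[1],
    }, indent=2))
    for family, order in report.rankings.items():
        pd.DataFrame({
            "rank": np.arange(1, len(order) + 1), "feature": order,
        }).to_csv(_w(out / f"rfe_ranking_{FAMILY_LABELS[family]}.csv"),
                  index=False)
    report.mean_matrix.to_csv(_w(out / "accuracy_mean.csv"))
    report.max_matrix.to_csv(_w(out / "accuracy_max.csv"))
    report.std_matrix.to_csv(_w(out / "accuracy_std.csv"))
    report.pruning_trace.to_csv(_w(out / "pruning_trace.csv"))
    report.final_summary.histogram_frame().to_csv(
        _w(out / "final_histogram.csv"), index=False
    )
    (_w(out / "summary.json")).write_text(json.dumps({
        "chosen_family": report.chosen_family,
        "chosen_family_label": FAMILY_LABELS[report.chosen_family],
        "chosen_cardinality": report.chosen_cardinality,
        "tuned_params": {
            str(k): v for k, v in report.tuned_params.items()
        },
        "selected_features": list(report.selected_features.names),
        "final_mean": report.final_result.mean,
        "final_max": report.final_result.max,
        "final_std": report.final_result.std,
        "normal_fit": {"mu": report.final_summary.mu,
                       "sigma": report.final_summary.sigma},
        "recovery_score": report.recovery,
    }, indent=2))
    if report.chosen_family == "decision_tree":
        _export_tree_dot(report, _w(out / "final_tree.dot"))
    return written


def _export_tree_dot(report: RunReport, path: Path) -> None:
    """Refit the final tree on the full dataset and export it as DOT."""
    from sklearn.tree import export_graphviz

    config = report.config
    dataset, _ = _load_dataset(config)
    table, _ = clean_features(dataset.table)
    dataset = LabeledDataset(
        table=table, labels=list(dataset.labels),
        positive_class_name=dataset.positive_class_name,
        negative_class_name=dataset.negative_class_name,
    )
    names = list(report.selected_features.names)
    sub = dataset.table.select_features(names)
    fam_i = config.families.index(report.chosen_family)
    best_step = next(
        s for s in report.pruning_trace.steps
        if s.cardinality == report.pruning_trace.best_cardinality
    )
    spec = EstimatorSpec(
        family="decision_tree",
        params=best_step.retuned_params,
        class_weights=report.class_weights,
        seed=derive_seed(config.base_seed, "final", fam_i),
    )
    est = build_estimator(spec)
    y = dataset.y
    est.fit(sub.values, y, sample_weight=report.class_weights.sample_weights(y))
    export_graphviz(
        est, out_file=str(path), feature_names=names,
        class_names=[dataset.negative_class_name, dataset.positive_class_name],
        filled=True,
    )


def recovery_benchmark_config(seed: int) -> RunConfig:
    """Planted-signal benchmark: can the pipeline recover what was planted?

    171 molecules x 300 descriptors with 8 informative + 20 correlated-copy
    descriptors (additive-threshold boundary, 5% label swaps, 33% positive,
    a 10% constant block).  The pipeline runs with the extremely randomized
    trees family at desk scale (20 trees, 3 CV replications for the sweep
    and pruning, 50 for final validation) so that a multi-seed average
    completes in minutes; the selection logic is identical to a full run.
    """
    spec = SyntheticSpec(
        n_molecules=171, n_features=300, n_constant=30,
        n_informative=8, n_redundant=20, positive_fraction=0.33,
        boundary="additive_threshold", label_noise=0.05, seed=seed,
        positive_class_name="toxic", negative_class_name="non-toxic",
    )
    return RunConfig(
        synthetic=spec, families=("extra_trees",),
        k_min=2, k_max=20, cv_reps=3, tune=False,
        fixed_params={"extra_trees": {"n_estimators": 20}},
        prune_extra_steps=1, final_reps=50, base_seed=seed,
    )


def shape_benchmark_config(seed: int) -> RunConfig:
    """Full four-family pipeline on a 171 x 300 synthetic dataset.

    Exercises every stage in the study layout — the 19-row x 4-family
    sweep matrix, per-step pruning trace, and final-validation histogram
    — at desk scale (small ensembles, 2 sweep replications, 50 final
    replications) so a complete run takes a couple of minutes.
    """
    spec = SyntheticSpec(
        n_molecules=171, n_features=300, n_constant=30,
        n_informative=8, n_redundant=20, positive_fraction=0.33,
        boundary="additive_threshold", label_noise=0.05, seed=seed,
        positive_class_name="toxic", negative_class_name="non-toxic",
    )
    return RunConfig(
        synthetic=spec,
        families=FAMILIES,
        k_min=2, k_max=20, cv_reps=2, tune=False,
        fixed_params={
            "random_forest": {"n_estimators": 20},
            "extra_trees": {"n_estimators": 20},
            "gradient_boosting": {"n_estimators": 30, "max_depth": 3,
                                  "learning_rate": 0.1},
        },
        prune_extra_steps=1, final_reps=50, base_seed=seed,
    )


def simulate_to_files(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write a synthetic dataset as descriptor CSV + label CSV + truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(spec)
    desc_path = out / "descriptors.csv"
    label_path = out / "labels.csv"
    truth_path = out / "ground_truth.json"
    write_descriptor_table(dataset.table, desc_path)
    write_label_file(
        dict(zip(dataset.table.molecule_ids, dataset.labels)), label_path
    )
    truth_path.write_text(json.dumps({
        "informative_features": truth.informative_features,
        "redundant_map": truth.redundant_map,
        "constant_features": truth.constant_features,
        "true_labels_preflip": truth.true_labels_preflip,
    }, indent=2))
    return desc_path, label_path, truth_path
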