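"""Pipeline orchestration: smoke run, determinism, selection rule, CLI."""

import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from qsarselect.cli import main as cli_main
from qsarselect.synthetic_data import SyntheticSpec
from qsarselect.workflow import (
    RunConfig,
    export_reports,
    run_workflow,
    select_cell,
    simulate_to_files,
)


def smoke_config(seed=2, outdir=None):
    spec = SyntheticSpec(
        n_molecules=90, n_features=120, n_constant=20, n_informative=4,
        n_redundant=6, positive_fraction=0.30, label_noise=0.0, seed=seed,
        positive_class_name="lengthener", negative_class_name="no-changer",
    )
    return RunConfig(
        synthetic=spec,
        families=("decision_tree", "gradient_boosting"),
        k_min=2, k_max=8, cv_reps=5, tune=True, tune_reps=1,
        grid_overrides={
            "decision_tree": {"max_depth": [3, None]},
            "gradient_boosting": {"max_depth": [3], "n_estimators": [30],
                                  "learning_rate": [0.1]},
        },
        prune_extra_steps=1, final_reps=50, base_seed=seed,
        outdir=str(outdir) if outdir else None,
    )


@pytest.fixture(scope="module")
def smoke_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    report = run_workflow(smoke_config(outdir=outdir))
    return report, outdir


EXPECTED_FILES = [
    "config.json", "cleaning_report.json", "class_weights.json",
    "accuracy_mean.csv", "accuracy_max.csv", "accuracy_std.csv",
    "pruning_trace.csv", "final_histogram.csv", "summary.json",
]


def test_smoke_run_emits_all_reports(smoke_run):
    report, outdir = smoke_run
    for name in EXPECTED_FILES:
        assert (outdir / name).exists(), name
    assert (outdir / "rfe_ranking_DTC.csv").exists()
    assert (outdir / "rfe_ranking_XGBC.csv").exists()


def test_matrix_layout_matches_sweep(smoke_run):
    report, outdir = smoke_run
    matrix = pd.read_csv(outdir / "accuracy_mean.csv", index_col=0)
    assert list(matrix.index) == list(range(2, 9))
    assert list(matrix.columns) == ["DTC", "XGBC"]
    trace = pd.read_csv(outdir / "pruning_trace.csv")
    assert list(trace.columns) == ["Features", "Removed", "Max", "Mean",
                                   "Std.Dev"]
    hist = pd.read_csv(outdir / "final_histogram.csv")
    assert hist["count"].sum() == 50


def test_chosen_cell_is_within_tolerance_of_max(smoke_run):
    report, _ = smoke_run
    matrix = report.mean_matrix
    best = matrix.to_numpy().max()
    from qsarselect.estimators import FAMILY_LABELS

    chosen = matrix.loc[report.chosen_cardinality,
                        FAMILY_LABELS[report.chosen_family]]
    assert chosen >= best - report.config.parsimony_tolerance


def test_weights_report_values(smoke_run):
    _, outdir = smoke_run
    weights = json.loads((outdir / "class_weights.json").read_text())
    assert weights["w_pos_2dp"] == 1.67  # 27 positives of 90
    assert weights["w_neg_2dp"] == 0.71


def test_rerun_is_byte_identical(tmp_path):
    out1, out2 = tmp_path / "a", tmp_path / "b"
    run_workflow(smoke_config(outdir=out1))
    run_workflow(smoke_config(outdir=out2))
    for name in EXPECTED_FILES:
        if name == "config.json":
            continue  # embeds outdir path
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name


def test_export_is_idempotent(smoke_run, tmp_path):
    report, _ = smoke_run
    export_reports(report, tmp_path / "x")
    first = {
        p.name: p.read_bytes() for p in (tmp_path / "x").iterdir()
    }
    export_reports(report, tmp_path / "x")
    second = {
        p.name: p.read_bytes() for p in (tmp_path / "x").iterdir()
    }
    del first["config.json"], second["config.json"]
    assert first == second


class TestSelectCell:
    def make_matrix(self):
        idx = [2, 3, 4]
        return pd.DataFrame(
            {"DTC": [70.0, 78.49, 78.77], "RFC": [71.0, 72.0, 73.0]},
            index=idx,
        )

    def test_parsimony_prefers_smaller_within_tolerance(self):
        matrix = self.make_matrix()
        fam, k = select_cell(
            matrix, ("decision_tree", "random_forest"), tolerance=0.5
        )
        assert (fam, k) == ("decision_tree", 3)  # 78.49 within 0.28 of max

    def test_zero_tolerance_takes_argmax(self):
        matrix = self.make_matrix()
        fam, k = select_cell(
            matrix, ("decision_tree", "random_forest"), tolerance=0.0
        )
        assert (fam, k) == ("decision_tree", 4)

    def test_cross_family_parsimony(self):
        matrix = pd.DataFrame(
            {"RFC": [83.62, 80.0], "XGBC": [70.0, 83.69]}, index=[16, 15],
        )
        matrix = matrix.sort_index()
        fam, k = select_cell(
            matrix, ("random_forest", "gradient_boosting"), tolerance=0.5
        )
        # the 15-feature cell wins over the 16-feature one within tolerance
        assert (fam, k) == ("gradient_boosting", 15)


def test_config_validation():
    with pytest.raises(ValueError):
        RunConfig()  # no data source
    with pytest.raises(ValueError):
        RunConfig(descriptor_path="x.csv")  # missing labels
    with pytest.raises(ValueError):
        RunConfig(
            synthetic=SyntheticSpec(n_features=30, n_constant=0,
                                    n_informative=2, n_redundant=0),
            families=("nope",),
        )


def test_file_input_equals_synthetic_input(tmp_path):
    """Running from exported CSVs reproduces the generated dataset."""
    spec = SyntheticSpec(
        n_molecules=40, n_features=30, n_constant=5, n_informative=3,
        n_redundant=2, positive_fraction=0.3, seed=6,
    )
    desc, labels, _ = simulate_to_files(spec, tmp_path)
    from qsarselect.descriptor_io import (
        join_labels, read_descriptor_table, read_label_file,
    )
    from qsarselect.synthetic_data import generate_dataset

    loaded = join_labels(
        read_descriptor_table(desc), read_label_file(labels), "positive"
    )
    direct, _ = generate_dataset(spec)
    assert loaded.class_counts == direct.class_counts
    import numpy as np

    np.testing.assert_array_equal(loaded.table.values, direct.table.values)


class TestCLI:
    def test_simulate_and_filter(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "simulate", "--preset", "period", "--n-features", "40",
            "--n-constant", "5", "--n-informative", "3", "--n-redundant", "2",
            "--seed", "4", "--outdir", str(tmp_path / "sim"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sim" / "descriptors.csv").exists()

        props = tmp_path / "props.csv"
        props.write_text(
            "id,hbd,hba,mw,logp,rotatable_bonds,aromatic_rings,total_rings\n"
            "A,2,5,400,3.0,4,3,4\nB,9,5,400,3.0,4,3,4\n"
        )
        res = runner.invoke(cli_main, [
            "filter-library", "--properties", str(props),
            "--outdir", str(tmp_path / "filt"),
        ])
        assert res.exit_code == 0, res.output
        kept = (tmp_path / "filt" / "kept_ids.txt").read_text().split()
        assert kept == ["A"]

    def test_run_all_with_config_file(self, tmp_path):
        config = {
            "synthetic": {
                "n_molecules": 40, "n_features": 30, "n_constant": 5,
                "n_informative": 3, "n_redundant": 2,
                "positive_fraction": 0.3, "label_noise": 0.0, "seed": 3,
            },
            "families": ["decision_tree"],
            "k_min": 2, "k_max": 5, "cv_reps": 3, "tune": False,
            "final_reps": 10, "prune_extra_steps": 1,
        }
        cfg_path = tmp_path / "cfg.yaml"
        import yaml

        cfg_path.write_text(yaml.safe_dump(config))
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "run-all", "--config", str(cfg_path), "--seed", "3",
            "--outdir", str(tmp_path / "out"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "summary.json").exists()
        assert (tmp_path / "out" / "final_tree.dot").exists()
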