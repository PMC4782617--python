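"""Model/Results surface, experiment orchestration, CLI round trips."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from texdirect import (FeatureMode, RunConfig, SyntheticConfig,
                       TextureClassificationModel, compare_modes,
                       generate_dataset, run_comparison, run_experiment)
from texdirect.cli import main

LOO = dict(protocol="loocv", seed=0)


@pytest.fixture(scope="module")
def small_data(request):
    return generate_dataset(SyntheticConfig(image_size=(64, 64), n_per_class=12,
                                            background_smoothness=3.0, seed=3))


def test_feature_table_shape(small_data):
    images, labels, ids = small_data
    model = TextureClassificationModel(images, labels, ids,
                                       mode=FeatureMode.DWT, level=1)
    table = model.features
    assert table.shape == (24, 4)  # image_id, label, E, U
    assert list(table.columns[:2]) == ["image_id", "label"]


def test_fit_returns_results_with_summary(small_data):
    images, labels, ids = small_data
    model = TextureClassificationModel(images, labels, ids,
                                       mode=FeatureMode.DWT, level=1)
    res = model.fit(protocol="tenfold", seed=0)
    text = res.summary()
    assert "CCR" in text and "tenfold" in text
    assert len(res.per_fold) == 10
    assert 0.0 <= res.overall.ccr <= 1.0


def test_compare_modes_schema_and_rows(small_data):
    images, labels, ids = small_data
    table = compare_modes(images, labels, ids, levels=(1, 2),
                          protocol="tenfold", seed=0)
    assert len(table) == 5
    assert set(table["mode"]) == {"dwt", "dwt_gabor", "gabor"}
    for col in ("mode", "level", "ccr_mean", "ccr_sd", "sensitivity_mean",
                "sensitivity_sd", "specificity_mean", "specificity_sd"):
        assert col in table.columns


def test_run_config_json_round_trip():
    config = RunConfig(mode="dwt", level=2, seed=9,
                       synthetic=SyntheticConfig(n_per_class=4))
    restored = RunConfig.from_json(config.to_json())
    assert restored == config


def test_run_experiment_writes_artifacts(tmp_path):
    config = RunConfig(synthetic=SyntheticConfig(image_size=(64, 64),
                                                 n_per_class=5,
                                                 background_smoothness=3.0),
                       mode="dwt", level=1, protocol="loocv", seed=0)
    run_experiment(config, tmp_path)
    for name in ("config.json", "features.csv", "folds.csv", "summary.json",
                 "run.log"):
        assert (tmp_path / name).exists(), name
    summary = json.loads((tmp_path / "summary.json").read_text())
    assert summary["mode"] == "dwt" and summary["protocol"] == "loocv"
    features = pd.read_csv(tmp_path / "features.csv")
    assert features.shape == (10, 4)


def test_run_experiment_is_deterministic(tmp_path):
    config = RunConfig(synthetic=SyntheticConfig(image_size=(64, 64),
                                                 n_per_class=4,
                                                 background_smoothness=3.0),
                       mode="dwt", level=1, protocol="loocv", seed=0)
    run_experiment(config, tmp_path / "a")
    run_experiment(config, tmp_path / "b")
    for name in ("features.csv", "folds.csv", "summary.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes()


def test_run_comparison_shares_folds(tmp_path, small_data):
    config = RunConfig(synthetic=SyntheticConfig(image_size=(64, 64),
                                                 n_per_class=12,
                                                 background_smoothness=3.0,
                                                 seed=3),
                       protocol="tenfold", seed=0, levels=(1,))
    table = run_comparison(config, tmp_path)
    assert len(table) == 3  # dwt L1, dwt_gabor L1, gabor
    assert (tmp_path / "comparison.csv").exists()


def test_cli_synth_then_run_round_trip(tmp_path):
    runner = CliRunner()
    synth_cfg = tmp_path / "synth.json"
    synth_cfg.write_text(json.dumps({
        "image_size": [64, 64], "n_per_class": 4,
        "background_smoothness": 3.0, "seed": 2}))
    data_dir = tmp_path / "data"
    result = runner.invoke(main, ["synth", "--config", str(synth_cfg),
                                  "--out", str(data_dir)])
    assert result.exit_code == 0, result.output
    assert len(list((data_dir / "normal").glob("*.png"))) == 4

    run_cfg = tmp_path / "run.json"
    run_cfg.write_text(json.dumps({
        "input_dir": str(data_dir), "synthetic": None, "mode": "dwt",
        "level": 1, "protocol": "loocv", "seed": 0}))
    out_dir = tmp_path / "out"
    result = runner.invoke(main, ["run", "--config", str(run_cfg),
                                  "--out", str(out_dir)])
    assert result.exit_code == 0, result.output
    assert "CCR" in result.output
    assert (out_dir / "summary.json").exists()


def test_from_directory_labels(tmp_path):
    runner = CliRunner()
    synth_cfg = tmp_path / "synth.json"
    synth_cfg.write_text(json.dumps({
        "image_size": [64, 64], "n_per_class": 3,
        "background_smoothness": 3.0, "seed": 2}))
    data_dir = tmp_path / "data"
    assert runner.invoke(main, ["synth", "--config", str(synth_cfg),
                                "--out", str(data_dir)]).exit_code == 0
    model = TextureClassificationModel.from_directory(
        data_dir, mode=FeatureMode.DWT, level=1)
    assert (model.labels == -1).sum() == 3 and (model.labels == 1).sum() == 3
    assert all(0.0 <= im.min() and im.max() <= 1.0 for im in model.images)
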