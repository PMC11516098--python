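import numpy as np
import pandas as pd
import pytest

from csmol.encoder_model import CSSModel, EncoderConfig, desk_head_config
from csmol.fixtures import FixtureSpec, gen_library, gen_property_task
from csmol.pair_dataset import scaffold_split
from csmol.prop_decoder import (
    DecoderConfig,
    PropTask,
    fit_property,
    load_predictor,
    predict_property,
    save_predictor,
    select_objective,
)


@pytest.fixture(scope="module")
def library():
    return gen_library(FixtureSpec(n_molecules=150, seed=21))


@pytest.fixture(scope="module")
def frozen_model():
    return CSSModel(EncoderConfig(n_layers=2, node_dim=32),
                    head_targets=("MaxSim",),
                    head_cfg_factory=desk_head_config, seed=5)


def _task(labels, task_type, library):
    table = pd.DataFrame({
        "id": [m.id for m in library],
        "smiles": [m.smiles for m in library],
        "label": labels,
    })
    return PropTask("t", task_type, table, scaffold_split(library, seed=3))


@pytest.mark.parametrize(
    "n_pos, n_neg, metric",
    [
        (80, 20, "auprc"),   # ratio 4 > 3
        (20, 80, "auprc"),   # ratio 1/4 < 1/3
        (75, 25, "auroc"),   # ratio exactly 3: strict inequality -> else branch
        (25, 75, "auroc"),   # ratio exactly 1/3
        (50, 50, "auroc"),
        (20, 100, "auprc"),  # ratio 0.2
    ],
)
def test_select_objective_classification_rules(n_pos, n_neg, metric, library):
    labels = [1] * n_pos + [0] * n_neg + [0] * (len(library) - n_pos - n_neg)
    # pad with negatives, keeping the intended ratio only for the exact cases
    labels = labels[: len(library)]
    task = _task(labels, "classification", library)
    # recompute the expected branch from the actual ratio
    ratio = task.pos_neg_ratio
    expected = "auprc" if (ratio > 3 or ratio < 1 / 3) else "auroc"
    loss_spec, got = select_objective(task)
    assert loss_spec == "bce_mse_mean"
    assert got == expected


def test_select_objective_exact_boundaries(library):
    n = len(library)
    # construct exact 3:1 and 1:3 ratios
    for n_pos in (3 * (n // 4), n // 4):
        labels = [1] * n_pos + [0] * (n - n_pos)
        task = _task(labels, "classification", library)
        if task.pos_neg_ratio in (3.0, 1 / 3):
            assert select_objective(task)[1] == "auroc"


def test_select_objective_regression(library):
    task = _task(np.linspace(-1, 1, len(library)), "regression", library)
    assert select_objective(task) == ("mse", "spearman")


def test_select_objective_single_class_errors(library):
    task = _task([1] * len(library), "classification", library)
    with pytest.raises(ValueError):
        select_objective(task)


@pytest.fixture(scope="module")
def linear_classification_task(library, frozen_model):
    return gen_property_task(library, frozen_model, "classification", seed=11)


def test_fit_property_recovers_linear_signal(library, frozen_model,
                                             linear_classification_task):
    cfg = DecoderConfig(epochs=40, seed=0)
    predictor = fit_property(frozen_model, linear_classification_task, cfg)
    assert predictor.metric_name == "auroc"
    assert predictor.test_metric >= 0.95


def test_fit_property_shuffled_labels_near_chance(library, frozen_model,
                                                  linear_classification_task):
    aurocs = []
    for seed in range(5):
        rng = np.random.default_rng(seed + 100)
        table = linear_classification_task.table.copy()
        table["label"] = rng.permutation(table["label"].values)
        task = PropTask("shuffled", "classification", table,
                        linear_classification_task.split)
        cfg = DecoderConfig(epochs=10, seed=seed)
        predictor = fit_property(frozen_model, task, cfg)
        aurocs.append(predictor.test_metric)
    assert 0.35 <= np.mean(aurocs) <= 0.65


def test_fit_property_regression_monotone_signal(library, frozen_model):
    task = gen_property_task(library, frozen_model, "regression", seed=13)
    cfg = DecoderConfig(epochs=40, seed=1)
    predictor = fit_property(frozen_model, task, cfg)
    assert predictor.metric_name == "spearman"
    assert predictor.test_metric >= 0.8


def test_fine_tuning_runs_and_reports(library, frozen_model,
                                      linear_classification_task):
    import copy

    model = CSSModel(EncoderConfig(n_layers=2, node_dim=32),
                     head_targets=("MaxSim",),
                     head_cfg_factory=desk_head_config, seed=6)
    cfg = DecoderConfig(epochs=6, fine_tune_encoder=True, seed=2)
    before = copy.deepcopy(model.encoder.state_arrays())
    predictor = fit_property(model, linear_classification_task, cfg)
    after = model.encoder.state_arrays()
    changed = any(not np.array_equal(before[k], after[k]) for k in before)
    assert changed  # encoder parameters actually updated
    assert np.isfinite(predictor.test_metric)


def test_predict_property_contract(library, frozen_model, linear_classification_task):
    cfg = DecoderConfig(epochs=4, seed=3)
    predictor = fit_property(frozen_model, linear_classification_task, cfg)
    out = predict_property(predictor, [m.smiles for m in library[:10]])
    assert len(out) == 10
    assert out["error"].eq("").all()
    assert ((out["score"] > 0) & (out["score"] < 1)).all()
    # unparseable rows reported, not dropped
    out_bad = predict_property(predictor, ["CCO", "((bad"])
    assert len(out_bad) == 2
    assert out_bad.loc[1, "error"] != ""
    # batch prediction equals per-molecule prediction (eval-mode batch norm)
    single = predict_property(predictor, [library[0].smiles])["score"][0]
    assert single == pytest.approx(out["score"][0], abs=1e-12)


def test_predictor_archive_roundtrip(tmp_path, library, frozen_model,
                                     linear_classification_task):
    cfg = DecoderConfig(epochs=4, seed=4)
    predictor = fit_property(frozen_model, linear_classification_task, cfg)
    path = tmp_path / "predictor.zip"
    save_predictor(predictor, path)
    loaded = load_predictor(path)
    a = predict_property(predictor, [m.smiles for m in library[:5]])["score"]
    b = predict_property(loaded, [m.smiles for m in library[:5]])["score"]
    assert np.allclose(a, b)
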