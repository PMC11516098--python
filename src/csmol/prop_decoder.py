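"""Downstream property modeling (QSAR/ADMET) on molecule encodings.

The property decoder mirrors the pair projection head but takes a single
molecule's encoding: expand ×5 → batch-norm → condense → shrinking cascade
→ one output unit (sigmoid for classification, linear for regression).
Loss/metric selection is rule-based: classification optimizes the mean of
binary cross-entropy and MSE and validates with AUPRC when the
positive:negative ratio is imbalanced (strictly above 3 or below 1/3),
AUROC otherwise; regression optimizes MSE and validates with Spearman. The
encoder can optionally be fine-tuned jointly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from . import _autograd as ag
from ._autograd import Tensor
from .chem_graph import featurize, parse_molecule
from .encoder_model import CSSModel, batch_graphs
from .pair_dataset import SplitAssignment


@dataclass(frozen=True)
class PropTask:
    name: str
    task_type: str  # "classification" | "regression"
    table: pd.DataFrame  # columns: smiles, label
    split: SplitAssignment

    @property
    def pos_neg_ratio(self) -> float:
        labels = self.table["label"].to_numpy()
        pos = int((labels == 1).sum())
        neg = int((labels == 0).sum())
        if neg == 0:
            return np.inf
        return pos / neg


@dataclass(frozen=True)
class DecoderConfig:
    rectifier_expand_factor: int = 5
    rectifier_out: int = 256
    reduction_stages: tuple[int, ...] = (256, 128, 64)
    fine_tune_encoder: bool = False
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 60
    validate_every_epochs: int = 2
    weight_decay: float = 1e-2
    large_dataset_rows: int = 5_000  # size-preset threshold
    seed: int = 0


def size_preset(n_rows: int, base: DecoderConfig) -> DecoderConfig:
    """Scale optimization with dataset size: bigger data → larger lr/batch,
    fewer epochs; small data → gentler lr, more epochs."""
    import dataclasses

    if n_rows >= base.large_dataset_rows:
        return dataclasses.replace(
            base, lr=base.lr * 3, batch_size=256, epochs=max(10, base.epochs // 3)
        )
    return base


def select_objective(task: PropTask) -> tuple[str, str]:
    """(loss spec, validation metric) from the task metadata alone."""
    if task.task_type == "regression":
        return "mse", "spearman"
    labels = set(np.unique(task.table["label"].to_numpy()))
    if not labels <= {0, 1} or len(labels) < 2:
        raise ValueError("classification labels must contain both classes 0 and 1")
    ratio = task.pos_neg_ratio
    metric = "auprc" if (ratio > 3 or ratio < 1 / 3) else "auroc"
    return "bce_mse_mean", metric


class PropDecoderNet(ag.Module):
    def __init__(self, in_dim: int, cfg: DecoderConfig, task_type: str,
                 rng: np.random.Generator):
        wide = cfg.rectifier_expand_factor * in_dim
        self.task_type = task_type
        self.expand = ag.Linear(in_dim, wide, rng)
        self.norm = ag.BatchNorm1d(wide)
        self.condense = ag.Linear(wide, cfg.rectifier_out, rng)
        dims = list(cfg.reduction_stages)
        self.reduction = [ag.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final = ag.Linear(dims[-1], 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.norm(self.expand(x)))
        h = ag.leaky_relu(self.condense(h))
        for lin in self.reduction:
            h = ag.leaky_relu(lin(h))
        out = self.final(h)
        return ag.sigmoid(out) if self.task_type == "classification" else out


@dataclass
class PropPredictor:
    encoder_model: CSSModel
    decoder: PropDecoderNet
    task_type: str
    metric_name: str
    history: list = field(default_factory=list)
    test_metric: float | None = None


def _metric(name: str, scores: np.ndarray, labels: np.ndarray) -> float:
    if name == "auroc":
        return float(roc_auc_score(labels, scores))
    if name == "auprc":
        return float(average_precision_score(labels, scores))
    if name == "spearman":
        rho = spearmanr(scores, labels).statistic
        return 0.0 if np.isnan(rho) else float(rho)
    raise ValueError(name)


def _loss(pred: Tensor, target: np.ndarray, spec: str) -> Tensor:
    if spec == "mse":
        return ag.mse(pred, target[:, None])
    # mean of binary cross-entropy and MSE on sigmoid outputs vs 0/1 labels
    t = target[:, None]
    eps = 1e-12
    log_p = _log(pred, eps)
    log_1mp = _log(1.0 - pred, eps)
    bce = -(Tensor(t) * log_p + Tensor(1.0 - t) * log_1mp).mean()
    return (bce + ag.mse(pred, t)) * 0.5


def _log(x: Tensor, eps: float) -> Tensor:
    data = np.log(np.clip(x.data, eps, None))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / np.clip(x.data, eps, None))

    return x._make(data, (x,), backward)


def fit_property(
    model: CSSModel,
    task: PropTask,
    cfg: DecoderConfig = DecoderConfig(),
) -> PropPredictor:
    """Train a property decoder on encodings, optionally fine-tuning the encoder.

    Best-validation parameters are restored before the test metric is
    reported. Aborts on non-finite loss.
    """
    cfg = size_preset(len(task.table), cfg)
    loss_spec, metric_name = select_objective(task)
    rng = np.random.default_rng(cfg.seed)
    decoder = PropDecoderNet(model.encoder.node_dim, cfg, task.task_type, rng)

    parts = {p: [] for p in ("train", "validation", "test")}
    graphs, labels = [], []
    for i, row in task.table.reset_index(drop=True).iterrows():
        mol_id = str(row.get("id", row["smiles"]))
        part = task.split.partition_of[mol_id]
        parts[part].append(i)
        graphs.append(featurize(parse_molecule(row["smiles"], mol_id)))
        labels.append(float(row["label"]))
    labels = np.asarray(labels)
    if not parts["train"] or not parts["validation"] or not parts["test"]:
        raise ValueError("split must populate train, validation, and test")

    def encode_rows(rows, training: bool):
        batch = batch_graphs([graphs[i] for i in rows])
        if cfg.fine_tune_encoder and training:
            return model.encode_batch(batch)
        enc = model.encoder(batch)
        return Tensor(enc.data)  # detached: frozen encoder

    params = decoder.parameters()
    if cfg.fine_tune_encoder:
        params = params + model.encoder.parameters()
    optimizer = ag.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    def evaluate(rows):
        decoder.eval()
        model.eval()
        pred = decoder(encode_rows(rows, training=False)).data[:, 0]
        decoder.train()
        if cfg.fine_tune_encoder:
            model.train()
        return _metric(metric_name, pred, labels[rows])

    best_score, best_state = -np.inf, None
    history = []
    train_rows = np.array(parts["train"])
    decoder.train()
    if cfg.fine_tune_encoder:
        model.train()
    else:
        model.eval()
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_rows)
        for lo in range(0, len(order), cfg.batch_size):
            rows = order[lo: lo + cfg.batch_size]
            pred = decoder(encode_rows(rows, training=True))
            batch_loss = _loss(pred, labels[rows], loss_spec)
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(f"non-finite loss in epoch {epoch}")
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
        if (epoch + 1) % cfg.validate_every_epochs == 0:
            score = evaluate(np.array(parts["validation"]))
            history.append({"epoch": epoch + 1, "validation_metric": score})
            if score > best_score:
                best_score = score
                best_state = (copy.deepcopy(decoder.state_arrays()),
                              copy.deepcopy(model.encoder.state_arrays())
                              if cfg.fine_tune_encoder else None)
    if best_state is not None:
        decoder.load_state_arrays(best_state[0])
        if best_state[1] is not None:
            model.encoder.load_state_arrays(best_state[1])
    decoder.eval()
    model.eval()
    predictor = PropPredictor(model, decoder, task.task_type, metric_name, history)
    predictor.test_metric = evaluate_rows(predictor, graphs, labels, parts["test"])
    return predictor


def evaluate_rows(predictor: PropPredictor, graphs, labels, rows) -> float:
    batch = batch_graphs([graphs[i] for i in rows])
    enc = predictor.encoder_model.encoder(batch)
    pred = predictor.decoder(Tensor(enc.data)).data[:, 0]
    return _metric(predictor.metric_name, pred, np.asarray(labels)[rows])


def save_predictor(predictor: PropPredictor, path) -> None:
    """Predictor archive: task metadata + decoder parameters + encoder checkpoint."""
    import io
    import json
    import zipfile

    from .encoder_model import save_checkpoint

    with zipfile.ZipFile(str(path), "w") as zf:
        zf.writestr("task.json", json.dumps({
            "task_type": predictor.task_type,
            "metric_name": predictor.metric_name,
            "test_metric": predictor.test_metric,
            "decoder_config": {
                "in_dim": predictor.encoder_model.encoder.node_dim,
                "rectifier_out": predictor.decoder.condense.bias.data.shape[0],
                "reduction_stages": [l.bias.data.shape[0] for l in
                                     [predictor.decoder.condense] + predictor.decoder.reduction],
                "expand": predictor.decoder.expand.bias.data.shape[0],
            },
        }, indent=1))
        buf = io.BytesIO()
        np.savez(buf, **predictor.decoder.state_arrays())
        zf.writestr("decoder.npz", buf.getvalue())
        enc_buf = io.BytesIO()
        import tempfile, os
        with tempfile.NamedTemporaryFile(suffix=".zip", delete=False) as tmp:
            save_checkpoint(predictor.encoder_model, tmp.name)
            tmp_path = tmp.name
        with open(tmp_path, "rb") as fh:
            zf.writestr("encoder.ckpt", fh.read())
        os.unlink(tmp_path)


def load_predictor(path) -> PropPredictor:
    import io
    import json
    import os
    import tempfile
    import zipfile

    from .encoder_model import load_checkpoint

    with zipfile.ZipFile(str(path)) as zf:
        meta = json.loads(zf.read("task.json"))
        decoder_state = dict(np.load(io.BytesIO(zf.read("decoder.npz"))))
        with tempfile.NamedTemporaryFile(suffix=".zip", delete=False) as tmp:
            tmp.write(zf.read("encoder.ckpt"))
            tmp_path = tmp.name
    model, _ = load_checkpoint(tmp_path)
    os.unlink(tmp_path)
    dc = meta["decoder_config"]
    stages = tuple(meta["decoder_config"]["reduction_stages"])
    cfg = DecoderConfig(
        rectifier_expand_factor=dc["expand"] // dc["in_dim"],
        rectifier_out=stages[0], reduction_stages=stages,
    )
    decoder = PropDecoderNet(dc["in_dim"], cfg, meta["task_type"], np.random.default_rng(0))
    decoder.load_state_arrays(decoder_state)
    decoder.eval()
    return PropPredictor(model, decoder, meta["task_type"], meta["metric_name"],
                         test_metric=meta.get("test_metric"))


def predict_property(predictor: PropPredictor, molecules) -> pd.DataFrame:
    """Score molecules; unparseable SMILES are reported in an ``error`` column."""
    rows = []
    parsed, keep = [], []
    for i, item in enumerate(molecules):
        smiles = item if isinstance(item, str) else item.smiles
        try:
            mol = item if not isinstance(item, str) else parse_molecule(smiles)
            parsed.append(featurize(mol))
            keep.append(i)
            rows.append({"smiles": smiles, "score": np.nan, "error": ""})
        except Exception as exc:
            rows.append({"smiles": smiles, "score": np.nan, "error": str(exc)})
    if parsed:
        predictor.decoder.eval()
        enc = predictor.encoder_model.encoder(batch_graphs(parsed))
        scores = predictor.decoder(Tensor(enc.data)).data[:, 0]
        for i, s in zip(keep, scores):
            rows[i]["score"] = float(s)
    return pd.DataFrame(rows)
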