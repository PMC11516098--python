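"""Contrastive training loop for the descriptor-regression model.

Pairs of molecules with CSS/MCS labels are the training unit. Each step
samples a batch of pairs, encodes the batch's unique molecules once, feeds
ordered encoding pairs through every enabled projection head, and minimizes
a weighted MSE summed over heads with AdamW. The learning rate warms up
linearly from 0.1×lr to lr, then oscillates between 0.5×lr and lr on a
periodic cosine. Validation (mean Spearman across heads) runs on a fixed
cadence and drives early stopping; the best-validation parameters are what
the returned checkpoint holds.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import _autograd as ag
from ._autograd import Tensor
from .chem_graph import featurize, parse_molecule
from .encoder_model import CSSModel, GraphBatch, batch_graphs


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_pairs: int = 512
    warmup_steps: int = 30_000
    warmup_start_factor: float = 0.1
    cosine_min_factor: float = 0.5
    cosine_period_steps: int = 10_000
    validate_every_steps: int = 500
    patience_validations: int = 50
    max_steps: int = 200_000
    head_weights: dict = field(default_factory=dict)  # default weight 1.0
    sample_weighting: str = "uniform"  # or "positive_emphasis"
    positive_emphasis_factor: float = 2.0
    positive_threshold: float = 0.6
    weight_decay: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.warmup_start_factor <= 1:
            raise ValueError("warmup_start_factor must be in (0, 1]")
        if not 0 < self.cosine_min_factor <= 1:
            raise ValueError("cosine_min_factor must be in (0, 1]")
        if self.patience_validations < 1:
            raise ValueError("patience must be >= 1")


def desk_train_config(**overrides) -> TrainConfig:
    """CPU-scale preset: short warmup/period scaled with the short run."""
    defaults = dict(
        lr=1e-3, batch_pairs=128, warmup_steps=200, cosine_period_steps=500,
        validate_every_steps=100, patience_validations=10, max_steps=2_000,
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Warmup then periodic cosine between cosine_min_factor×lr and lr."""
    if step < cfg.warmup_steps:
        frac = step / cfg.warmup_steps
        factor = cfg.warmup_start_factor + (1.0 - cfg.warmup_start_factor) * frac
        return cfg.lr * factor
    t = step - cfg.warmup_steps
    lr_min = cfg.cosine_min_factor * cfg.lr
    phase = 2.0 * math.pi * (t % cfg.cosine_period_steps) / cfg.cosine_period_steps
    return lr_min + (cfg.lr - lr_min) * (1.0 + math.cos(phase)) / 2.0


def loss(
    predictions: dict[str, Tensor],
    labels: pd.DataFrame,
    cfg: TrainConfig,
) -> Tensor:
    """Weighted MSE summed over heads.

    Per head: head_weight × mean(sample_weight × (pred − label)²). The
    optional positive-emphasis scheme up-weights pairs whose MaxSim label
    exceeds the positive threshold.
    """
    weights = None
    if cfg.sample_weighting == "positive_emphasis":
        if "MaxSim" not in labels.columns:
            raise ValueError("positive_emphasis weighting needs a MaxSim column")
        weights = np.where(
            labels["MaxSim"].to_numpy() > cfg.positive_threshold,
            cfg.positive_emphasis_factor, 1.0,
        )[:, None]
    total = None
    for name, pred in predictions.items():
        if name not in labels.columns:
            raise ValueError(f"no label column for enabled head {name!r}")
        target = labels[name].to_numpy(dtype=float)[:, None]  # align with (n, 1) preds
        term = ag.mse(pred, target, weights) * cfg.head_weights.get(name, 1.0)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no enabled heads")
    return total


# ---------------------------------------------------------------------------
# Pair dataset plumbing
# ---------------------------------------------------------------------------

class PairData:
    """Label table resolved to featurized-molecule indices."""

    def __init__(self, table: pd.DataFrame):
        smiles = pd.unique(pd.concat([table["smiles_a"], table["smiles_b"]]))
        self.graphs = [featurize(parse_molecule(s)) for s in smiles]
        index = {s: i for i, s in enumerate(smiles)}
        self.idx_a = table["smiles_a"].map(index).to_numpy()
        self.idx_b = table["smiles_b"].map(index).to_numpy()
        self.table = table.reset_index(drop=True)

    def __len__(self):
        return len(self.table)


def _forward(model: CSSModel, data: PairData, rows: np.ndarray,
             head_names: list[str]) -> dict[str, Tensor]:
    used = np.unique(np.concatenate([data.idx_a[rows], data.idx_b[rows]]))
    remap = {g: i for i, g in enumerate(used)}
    batch = batch_graphs([data.graphs[g] for g in used])
    enc = model.encode_batch(batch)
    a_rows = np.array([remap[g] for g in data.idx_a[rows]])
    b_rows = np.array([remap[g] for g in data.idx_b[rows]])
    enc_a = ag.gather_rows(enc, a_rows)
    enc_b = ag.gather_rows(enc, b_rows)
    x = ag.concat([enc_a, enc_b], axis=1)
    return {name: model.head(name)(x) for name in head_names}


def validation_score(model: CSSModel, data: PairData, rows: np.ndarray,
                     head_names: list[str]) -> float:
    """Mean Spearman correlation across heads on the given rows."""
    model.eval()
    preds = _forward(model, data, rows, head_names)
    scores = []
    for name, pred in preds.items():
        target = data.table.loc[rows, name].to_numpy(dtype=float)
        p = pred.data[:, 0]
        if np.ptp(p) == 0 or np.ptp(target) == 0:  # constant: no ranking signal
            scores.append(0.0)
            continue
        rho = spearmanr(p, target).statistic
        scores.append(0.0 if np.isnan(rho) else float(rho))
    model.train()
    return float(np.mean(scores))


@dataclass
class TrainState:
    step: int = 0
    best_validation_score: float = -np.inf
    validations_since_best: int = 0
    best_state: dict | None = None
    log: list = field(default_factory=list)


def train(
    model: CSSModel,
    dataset: pd.DataFrame,
    cfg: TrainConfig,
    head_names: list[str] | None = None,
    partition_column: str = "partition",
) -> TrainState:
    """Train ``model`` on a labeled pair table with train/validation partitions.

    The table needs ``smiles_a``, ``smiles_b``, one label column per enabled
    head, and a partition column containing at least "train" and
    "validation" rows. Stops at ``max_steps`` or when the validation score
    has not improved for ``patience_validations`` checks; the best-scoring
    parameters are restored into the model before returning.
    """
    head_names = head_names or model.head_names
    train_rows_df = dataset[dataset[partition_column] == "train"]
    val_rows_df = dataset[dataset[partition_column] == "validation"]
    if train_rows_df.empty or val_rows_df.empty:
        raise ValueError("dataset must contain train and validation partitions")
    data = PairData(pd.concat([train_rows_df, val_rows_df]).reset_index(drop=True))
    n_train = len(train_rows_df)
    train_rows = np.arange(n_train)
    val_rows = np.arange(n_train, len(data))

    rng = np.random.default_rng(cfg.seed)
    optimizer = ag.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    state = TrainState()
    model.train()

    order = rng.permutation(train_rows)
    cursor = 0
    while state.step < cfg.max_steps:
        if cursor + cfg.batch_pairs > len(order):
            order = rng.permutation(train_rows)  # new epoch: reshuffle
            cursor = 0
        batch_rows = order[cursor: cursor + min(cfg.batch_pairs, len(order))]
        cursor += cfg.batch_pairs

        preds = _forward(model, data, batch_rows, head_names)
        batch_loss = loss(preds, data.table.loc[batch_rows], cfg)
        if not np.isfinite(batch_loss.data):
            raise FloatingPointError(
                f"non-finite loss at step {state.step}; check labels and lr"
            )
        optimizer.zero_grad()
        batch_loss.backward()
        lr = lr_at_step(state.step, cfg)
        optimizer.step(lr=lr)
        state.step += 1

        if state.step % cfg.validate_every_steps == 0:
            score = validation_score(model, data, val_rows, head_names)
            state.log.append(
                {"step": state.step, "lr": lr, "train_loss": float(batch_loss.data),
                 "validation_spearman": score}
            )
            if score > state.best_validation_score:
                state.best_validation_score = score
                state.validations_since_best = 0
                state.best_state = copy.deepcopy(model.state_arrays())
            else:
                state.validations_since_best += 1
                if state.validations_since_best >= cfg.patience_validations:
                    break

    if state.best_state is not None:
        model.load_state_arrays(state.best_state)
    model.eval()
    return state


def write_training_log(state: TrainState, path) -> None:
    pd.DataFrame(state.log).to_csv(path, index=False)
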