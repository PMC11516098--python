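"""Graph encoder and projection heads.

The encoder is a Weisfeiler-Lehman-style message-passing network: each of
``n_layers`` rounds sends, along every directed bond, a learned transform of
(neighbor node features ⊕ bond features), sums incoming messages, and
combines them with a transform of the node's own features. The readout is a
per-node MLP followed by an arithmetic mean over the molecule's nodes, so
the encoding is invariant to atom numbering by construction.

A projection head consumes the ordered concatenation of two encodings and
regresses one descriptor through a "rectifier" block — expand to five times
the input width, batch-normalize, condense — followed by a cascade of
shrinking linear layers and a single sigmoid output. Input order matters,
which is what lets directional (Max*) descriptors be learned; the symmetric
Cross* descriptors are learned from the same ordered input.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .chem_graph import (
    EDGE_FEATURE_DIM,
    NODE_FEATURE_DIM,
    MolGraph,
    Molecule,
    featurize,
)

DEFAULT_HEAD_TARGETS = (
    "MaxSim", "MaxDistance", "MaxOverlap", "MaxAggregation",
    "CrossSim", "CrossDistance", "CrossOverlap", "CrossAggregation", "MCS",
)


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 4
    node_dim: int = 2048
    readout_hidden: int = 0  # 0 → same as node_dim
    activation: str = "leaky_relu"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.node_dim < 8:
            raise ValueError("node_dim must be >= 8")


def desk_encoder_config() -> EncoderConfig:
    """Small configuration for CPU-scale runs (64-dim, 2 layers)."""
    return EncoderConfig(n_layers=2, node_dim=64)


@dataclass(frozen=True)
class HeadConfig:
    target_name: str = "MaxSim"
    rectifier_expand_factor: int = 5
    rectifier_out: int = 1024
    reduction_stages: tuple[int, ...] = (1024, 512, 256, 128)
    use_rectifier: bool = True
    literal_repeat_blocks: bool = False  # three identical expand→out blocks instead

    def __post_init__(self):
        if self.use_rectifier and self.reduction_stages[0] != self.rectifier_out:
            raise ValueError("first reduction stage must equal rectifier_out")


def desk_head_config(target: str) -> HeadConfig:
    return HeadConfig(target_name=target, rectifier_out=256,
                      reduction_stages=(256, 128, 64))


# ---------------------------------------------------------------------------
# Batched graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    node_features: np.ndarray   # (total_nodes, F)
    edge_features: np.ndarray   # (total_directed_edges, E)
    src: np.ndarray             # directed edge source node indices
    dst: np.ndarray             # directed edge destination node indices
    graph_ids: np.ndarray       # (total_nodes,) molecule index per node
    n_graphs: int


def batch_graphs(graphs: list[MolGraph]) -> GraphBatch:
    nodes, edges, srcs, dsts, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        n = len(g.node_features)
        if n == 0:
            raise ValueError("cannot encode an empty graph")
        nodes.append(g.node_features)
        gids.append(np.full(n, gi, dtype=np.int64))
        if len(g.adjacency):
            a = g.adjacency + offset
            srcs.extend([a[:, 0], a[:, 1]])
            dsts.extend([a[:, 1], a[:, 0]])
            edges.extend([g.edge_features, g.edge_features])
        offset += n
    return GraphBatch(
        node_features=np.vstack(nodes),
        edge_features=(np.vstack(edges) if edges else np.zeros((0, EDGE_FEATURE_DIM))),
        src=(np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)),
        dst=(np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class WLNEncoder(ag.Module):
    """Message-passing encoder with mean-MLP readout."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.node_dim
        hidden = cfg.readout_hidden or d
        self.cfg_dict = dict(asdict(cfg))
        self.n_layers = cfg.n_layers
        self.node_dim = d
        self.input_proj = ag.Linear(NODE_FEATURE_DIM, d, rng)
        self.msg_layers = [ag.Linear(d + EDGE_FEATURE_DIM, d, rng) for _ in range(cfg.n_layers)]
        self.self_layers = [ag.Linear(d, d, rng) for _ in range(cfg.n_layers)]
        self.readout_hidden = ag.Linear(d, hidden, rng)
        self.readout_out = ag.Linear(hidden, d, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = ag.leaky_relu(self.input_proj(Tensor(batch.node_features)))
        n_nodes = batch.node_features.shape[0]
        edge_t = Tensor(batch.edge_features)
        for msg_lin, self_lin in zip(self.msg_layers, self.self_layers):
            if len(batch.src):
                neighbor = ag.gather_rows(h, batch.src)
                messages = ag.leaky_relu(msg_lin(ag.concat([neighbor, edge_t], axis=1)))
                agg = ag.segment_sum(messages, batch.dst, n_nodes)
            else:  # single-atom molecules: no messages to pass
                agg = Tensor(np.zeros((n_nodes, self.node_dim)))
            h = ag.leaky_relu(self_lin(h) + agg)
        per_node = self.readout_out(ag.leaky_relu(self.readout_hidden(h)))
        return ag.segment_mean(per_node, batch.graph_ids, batch.n_graphs)


class ProjectionHead(ag.Module):
    """Pair head: rectifier (expand ×5 → BN → condense) then shrinking cascade."""

    def __init__(self, in_dim: int, cfg: HeadConfig, rng: np.random.Generator):
        self.cfg_dict = dict(asdict(cfg))
        self.cfg_dict["reduction_stages"] = list(cfg.reduction_stages)
        self.use_rectifier = cfg.use_rectifier
        layers: list = []
        if cfg.use_rectifier:
            wide = cfg.rectifier_expand_factor * in_dim
            self.expand = ag.Linear(in_dim, wide, rng)
            self.norm = ag.BatchNorm1d(wide)
            self.condense = ag.Linear(wide, cfg.rectifier_out, rng)
            if cfg.literal_repeat_blocks:
                # three direct wide→narrow blocks instead of a gradual cascade
                dims = [cfg.rectifier_out] + [cfg.reduction_stages[-1]] * 3
            else:
                dims = list(cfg.reduction_stages)
            for a, b in zip(dims[:-1], dims[1:]):
                layers.append(ag.Linear(a, b, rng))
            self.final = ag.Linear(dims[-1], 1, rng)
        else:
            self.expand = ag.Linear(in_dim, 256, rng)
            self.norm = ag.BatchNorm1d(256)
            self.final = ag.Linear(256, 1, rng)
        self.reduction = layers

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.norm(self.expand(x)))
        if self.use_rectifier:
            h = ag.leaky_relu(self.condense(h))
            for lin in self.reduction:
                h = ag.leaky_relu(lin(h))
        return ag.sigmoid(self.final(h))


class CSSModel(ag.Module):
    """Encoder plus one projection head per target descriptor."""

    def __init__(
        self,
        encoder_cfg: EncoderConfig | None = None,
        head_targets: tuple[str, ...] = DEFAULT_HEAD_TARGETS,
        head_cfg_factory=None,
        seed: int = 0,
    ):
        encoder_cfg = encoder_cfg or EncoderConfig()
        rng = np.random.default_rng(seed)
        self.encoder = WLNEncoder(encoder_cfg, rng)
        factory = head_cfg_factory or (lambda t: HeadConfig(target_name=t))
        self.head_names = list(head_targets)
        self.heads = [ProjectionHead(2 * encoder_cfg.node_dim, factory(t), rng)
                      for t in head_targets]
        self.seed = seed

    def head(self, name: str) -> ProjectionHead:
        return self.heads[self.head_names.index(name)]

    def encode_batch(self, batch: GraphBatch) -> Tensor:
        return self.encoder(batch)

    def encode_molecules(self, molecules: list[Molecule]) -> np.ndarray:
        """Inference-mode encodings, one row per molecule."""
        self.eval()
        batch = batch_graphs([featurize(m) for m in molecules])
        return self.encoder(batch).data

    def project(self, head_name: str, enc_a: np.ndarray, enc_b: np.ndarray) -> np.ndarray:
        """Predict one descriptor for ordered encoding pairs (inference mode)."""
        enc_a = np.atleast_2d(enc_a)
        enc_b = np.atleast_2d(enc_b)
        if enc_a.shape != enc_b.shape:
            raise ValueError("encoding shapes differ")
        self.eval()
        x = ag.concat([Tensor(enc_a), Tensor(enc_b)], axis=1)
        return self.head(head_name)(x).data[:, 0]


def encode(graph: MolGraph, model: CSSModel) -> np.ndarray:
    """Encoding vector of a single featurized graph."""
    model.eval()
    return model.encoder(batch_graphs([graph])).data[0]


# ---------------------------------------------------------------------------
# Checkpoints and encoding export
# ---------------------------------------------------------------------------

def save_checkpoint(model: CSSModel, path, manifest: dict | None = None) -> None:
    """Single-archive checkpoint: config JSON + parameter arrays + manifest."""
    config = {
        "encoder": model.encoder.cfg_dict,
        "head_names": model.head_names,
        "head_cfgs": [h.cfg_dict for h in model.heads],
        "seed": model.seed,
    }
    state = model.state_arrays()
    with zipfile.ZipFile(str(path), "w") as zf:
        zf.writestr("config.json", json.dumps(config, indent=1))
        zf.writestr("manifest.json", json.dumps(manifest or {}, indent=1))
        buf = io.BytesIO()
        np.savez(buf, **state)
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[CSSModel, dict]:
    with zipfile.ZipFile(str(path)) as zf:
        config = json.loads(zf.read("config.json"))
        manifest = json.loads(zf.read("manifest.json"))
        with zf.open("params.npz") as fh:
            state = dict(np.load(io.BytesIO(fh.read())))
    enc_cfg = EncoderConfig(**config["encoder"])
    head_cfgs = {
        c["target_name"]: HeadConfig(**{**c, "reduction_stages": tuple(c["reduction_stages"])})
        for c in config["head_cfgs"]
    }
    model = CSSModel(
        enc_cfg,
        head_targets=tuple(config["head_names"]),
        head_cfg_factory=lambda t: head_cfgs[t],
        seed=config["seed"],
    )
    model.load_state_arrays(state)
    model.eval()
    return model, manifest


def export_encodings(model: CSSModel, molecules: list[Molecule], path) -> None:
    """Delimited text export: id followed by the encoding values."""
    enc = model.encode_molecules(molecules)
    with open(path, "w") as fh:
        fh.write("id," + ",".join(f"e{i}" for i in range(enc.shape[1])) + "\n")
        for mol, row in zip(molecules, enc):
            fh.write(mol.id + "," + ",".join(f"{v:.8g}" for v in row) + "\n")
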