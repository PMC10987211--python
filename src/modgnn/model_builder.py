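"""Enumerate the 16 son-model configurations and assemble full networks.

A network is: input embedding (74-dim atom features and 12-dim bond features
each mapped linearly to the hidden width), a stack of hybrid message-passing
layers, a permutation-invariant readout, and a small prediction head
(sigmoid probability for binary classification, linear output for
regression). Which of the four optional blocks each layer carries is given
by a :class:`ModuleConfig`; the 16 possible on/off combinations are the son
models M1 (all four, the hybrid HGNN) through M16 (none, plain GCN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, gather, segment_sum
from .featurization import (EDGE_FEATURE_DIM, NODE_FEATURE_DIM, GraphBatch,
                            MolGraph, batch_graphs)
from .gnn_layers import HybridLayer, _glorot, _zeros

#: Son-model names keyed by (node_attention, edge_attention, weave, gru_mpnn).
CONFIG_NAMES = {
    (True, True, True, True): "HGNN (Hybrid GNN)",
    (True, True, True, False): "HGNN without MPNN",
    (True, True, False, True): "HGNN without weave",
    (True, True, False, False): "node and edge attention",
    (True, False, True, True): "HGNN without edge attention",
    (True, False, True, False): "weave + GAT",
    (True, False, False, True): "GAT + MPNN",
    (True, False, False, False): "GAT",
    (False, True, True, True): "HGNN without node attention",
    (False, True, True, False): "edge attention + weave",
    (False, True, False, True): "edge attention + MPNN",
    (False, True, False, False): "edge attention",
    (False, False, True, True): "weave + MPNN",
    (False, False, True, False): "weave",
    (False, False, False, True): "MPNN",
    (False, False, False, False): "GCN",
}


@dataclass(frozen=True)
class ModuleConfig:
    """On/off state of the four optional message-passing blocks."""

    node_attention: bool
    edge_attention: bool
    weave: bool
    gru_mpnn: bool

    @property
    def bits(self) -> tuple[bool, bool, bool, bool]:
        return (self.node_attention, self.edge_attention, self.weave, self.gru_mpnn)

    @property
    def name(self) -> str:
        return CONFIG_NAMES[self.bits]

    @property
    def model_id(self) -> str:
        """M1..M16; M1 is all-true, M16 all-false, in big-endian bit order."""
        rank = sum((not b) << i for i, b in enumerate(reversed(self.bits)))
        return f"M{rank + 1}"


def enumerate_configs() -> list[ModuleConfig]:
    """All 16 son-model configs, M1 (all true) first, M16 (all false) last."""
    configs = []
    for i in range(16):
        bits = tuple(not ((i >> (3 - j)) & 1) for j in range(4))
        configs.append(ModuleConfig(*bits))
    return configs


@dataclass
class ModelSpec:
    """Hyperparameters for one network build."""

    config: ModuleConfig
    hidden_dim: int = 32
    n_layers: int = 2
    readout: str = "mean"
    task: str = "binary_classification"
    head_dims: list[int] = field(default_factory=lambda: [32])
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.task not in ("binary_classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


def readout(node_h: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Permutation-invariant pooling of one graph's node embeddings."""
    node_h = np.asarray(node_h, dtype=np.float64)
    if node_h.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    if mode == "mean":
        return node_h.mean(axis=0)
    if mode == "sum":
        return node_h.sum(axis=0)
    if mode == "max":
        return node_h.max(axis=0)
    raise ValueError(f"unknown readout {mode!r}")


def _segment_readout(h: Tensor, graph_ids: np.ndarray, n_graphs: int,
                     mode: str) -> Tensor:
    if mode == "sum":
        return segment_sum(h, graph_ids, n_graphs)
    if mode == "mean":
        counts = np.bincount(graph_ids, minlength=n_graphs).astype(np.float64)
        return segment_sum(h, graph_ids, n_graphs) * Tensor(1.0 / counts[:, None])
    if mode == "max":
        # subgradient: route gradient to the argmax rows only
        d = h.data.shape[1]
        sel = np.zeros((n_graphs, d), dtype=np.intp)
        for g in range(n_graphs):
            rows = np.flatnonzero(graph_ids == g)
            sel[g] = rows[np.argmax(h.data[rows], axis=0)]
        cols = np.broadcast_to(np.arange(d), (n_graphs, d))
        flat = sel * d + cols
        return gather(h.reshape(-1), flat.reshape(-1)).reshape(n_graphs, d)
    raise ValueError(f"unknown readout {mode!r}")


class GNNModel:
    """A full graph network: embedding -> L hybrid layers -> readout -> head."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d = spec.hidden_dim
        self.node_embed_W = _glorot(rng, NODE_FEATURE_DIM, d)
        self.node_embed_b = _zeros(d)
        self.edge_embed_W = _glorot(rng, EDGE_FEATURE_DIM, d)
        self.edge_embed_b = _zeros(d)
        self.layers = [HybridLayer(spec.config, d, rng=rng)
                       for _ in range(spec.n_layers)]
        self.head: list[tuple[Tensor, Tensor]] = []
        dims = [d] + list(spec.head_dims) + [1]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            self.head.append((_glorot(rng, fan_in, fan_out), _zeros(fan_out)))

    def parameters(self) -> list[Tensor]:
        params = [self.node_embed_W, self.node_embed_b,
                  self.edge_embed_W, self.edge_embed_b]
        for layer in self.layers:
            params.extend(layer.parameters())
        for W, b in self.head:
            params.extend([W, b])
        return params

    def forward_logits(self, batch: GraphBatch | list[MolGraph]) -> Tensor:
        """Per-graph raw scores (logits for classification)."""
        if isinstance(batch, list):
            batch = batch_graphs(batch)
        h = Tensor(batch.node_feats) @ self.node_embed_W + self.node_embed_b
        e = Tensor(batch.edge_feats) @ self.edge_embed_W + self.edge_embed_b
        for layer in self.layers:
            h, e = layer.forward(h, e, batch)
        pooled = _segment_readout(h, batch.graph_ids, batch.n_graphs,
                                  self.spec.readout)
        out = pooled
        for i, (W, b) in enumerate(self.head):
            out = out @ W + b
            if i < len(self.head) - 1:
                out = out.relu()
        return out.reshape(-1)

    def predict(self, graphs: list[MolGraph] | GraphBatch) -> np.ndarray:
        """Probabilities in [0, 1] for classification, raw values for regression."""
        logits = self.forward_logits(graphs)
        if self.spec.task == "binary_classification":
            return logits.sigmoid().data.copy()
        return logits.data.copy()

    def last_layer_attention(self) -> dict[str, np.ndarray | None]:
        return self.layers[-1].last_attention

    # -- checkpointing --------------------------------------------------------

    def _named_params(self) -> dict[str, Tensor]:
        named = {"node_embed_W": self.node_embed_W, "node_embed_b": self.node_embed_b,
                 "edge_embed_W": self.edge_embed_W, "edge_embed_b": self.edge_embed_b}
        for li, layer in enumerate(self.layers):
            for k, t in layer.params.items():
                named[f"layer{li}.{k}"] = t
        for hi, (W, b) in enumerate(self.head):
            named[f"head{hi}.W"] = W
            named[f"head{hi}.b"] = b
        return named

    def save(self, path) -> None:
        """Checkpoint: config + hyperparameters + weights (+ feature scheme)."""
        meta = {
            "feature_scheme": f"canonical-{NODE_FEATURE_DIM}/{EDGE_FEATURE_DIM}-v1",
            "config": list(self.spec.config.bits),
            "hidden_dim": self.spec.hidden_dim,
            "n_layers": self.spec.n_layers,
            "readout": self.spec.readout,
            "task": self.spec.task,
            "head_dims": list(self.spec.head_dims),
            "seed": self.spec.seed,
        }
        arrays = {k: t.data for k, t in self._named_params().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GNNModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            spec = ModelSpec(
                config=ModuleConfig(*meta["config"]),
                hidden_dim=meta["hidden_dim"], n_layers=meta["n_layers"],
                readout=meta["readout"], task=meta["task"],
                head_dims=meta["head_dims"], seed=meta["seed"],
            )
            model = cls(spec)
            for k, t in model._named_params().items():
                t.data = z[k].copy()
        return model


def build_model(spec: ModelSpec) -> GNNModel:
    """Build a network; identical spec + seed gives identical parameters."""
    return GNNModel(spec)
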