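"""The four message-passing blocks and the hybrid layer that composes them.

A hybrid layer is the basic graph-convolution layer with up to four optional
blocks attached, each of which can be present or absent independently:

* **node attention** — GATv2-style softmax attention over neighbor node
  embeddings; when absent, the node branch falls back to the
  degree-normalized unweighted neighbor mean (the plain GCN aggregation).
* **edge attention** — softmax attention of a destination node over its
  incident edges: score ``LeakyReLU(a_e . (W1 h_i + W2 e_j))``, softmax over
  the neighborhood, then ``sigma(sum_j alpha_ij W2 e_j)``. Absent: the edge
  branch contributes nothing to the node update.
* **weave** — coupled node/edge co-update through crossed linear maps: the
  node side mixes a self transform (n2n) with aggregated incident-edge
  transforms (e2n); the edge side adds the transformed source-node embedding
  (n2e) to the edge's self transform (e2e) and passes the sum through a
  combining linear layer (ue). Absent: edge embeddings pass through
  unchanged.
* **GRU/MPNN** — a gated recurrent unit merges the combined message with the
  node's previous embedding, selectively keeping or overwriting information.
  Absent: the combined message replaces the embedding directly (after the
  "un" combining linear layer and a nonlinearity).

The enabled branches are concatenated and mixed by the "un" linear layer.
With all four blocks absent the layer reduces exactly to a GCN layer
(normalized neighbor mean, linear, nonlinearity); with single blocks enabled
it reduces to GAT-, weave- and MPNN-style layers, and with all four it is the
hybrid (HGNN) layer.

Attention coefficients of every forward pass are recorded per directed edge
so the last layer can be exported for substructure mining.

Two API levels are provided: per-node functional operations on NumPy arrays
(`edge_attention_scores`, `gru_update`, ...) for inspection and testing, and
the batched `HybridLayer` used inside models, both backed by the same
autodiff blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather, segment_softmax, segment_sum

LEAKY_SLOPE = 0.2


@dataclass
class LayerState:
    """Node and edge embedding matrices carried between layers."""

    node_h: np.ndarray
    edge_h: np.ndarray
    layer_index: int = 0


def _graph_arrays(graph):
    """(src, dst, n_nodes) from a MolGraph or GraphBatch."""
    n = graph.n_atoms if hasattr(graph, "n_atoms") else graph.n_nodes
    return np.asarray(graph.src, dtype=np.intp), np.asarray(graph.dst, dtype=np.intp), n


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def init_layer_params(rng: np.random.Generator, d: int, config) -> dict[str, Tensor]:
    """Fresh parameter set for one hybrid layer of hidden width ``d``.

    The width of the combining layer ``un_W`` depends on how many branches
    the config enables (node branch always; edge attention and weave each add
    one).
    """
    n_parts = 1 + int(config.edge_attention) + int(config.weave)
    p = {
        "na_Wl": _glorot(rng, d, d), "na_Wr": _glorot(rng, d, d),
        "na_a": Tensor(rng.uniform(-0.3, 0.3, size=d), requires_grad=True),
        "ea_W1": _glorot(rng, d, d), "ea_W2": _glorot(rng, d, d),
        "ea_a": Tensor(rng.uniform(-0.3, 0.3, size=d), requires_grad=True),
        "wv_n2n": _glorot(rng, d, d), "wv_e2n": _glorot(rng, d, d),
        "wv_b_node": _zeros(d),
        "wv_n2e": _glorot(rng, d, d), "wv_e2e": _glorot(rng, d, d),
        "wv_ue": _glorot(rng, d, d), "wv_b_edge": _zeros(d),
        "un_W": _glorot(rng, n_parts * d, d), "un_b": _zeros(d),
        "gru_Wz": _glorot(rng, d, d), "gru_Uz": _glorot(rng, d, d), "gru_bz": _zeros(d),
        "gru_Wr": _glorot(rng, d, d), "gru_Ur": _glorot(rng, d, d), "gru_br": _zeros(d),
        "gru_Wn": _glorot(rng, d, d), "gru_Un": _glorot(rng, d, d), "gru_bn": _zeros(d),
    }
    return p


# ---------------------------------------------------------------------------
# blocks (autodiff level)
# ---------------------------------------------------------------------------

def _neighbor_mean(h: Tensor, src, dst, n: int) -> Tensor:
    """Degree-normalized unweighted neighbor sum; zeros for isolated nodes."""
    deg = np.bincount(dst, minlength=n).astype(np.float64)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    total = segment_sum(gather(h, src), dst, n)
    return total * Tensor(inv[:, None])


def _node_attention_block(h: Tensor, src, dst, n: int, p: dict,
                          slope: float = LEAKY_SLOPE):
    """GATv2-style attention over neighbor nodes.

    Score for edge j->i is ``a . LeakyReLU(Wl h_i + Wr h_j)`` (nonlinearity
    before the attention vector), softmaxed over i's neighborhood; the
    message is ``sum_j alpha_ij (Wr h_j)``.
    """
    hi = gather(h, dst) @ p["na_Wl"]
    hj = gather(h, src) @ p["na_Wr"]
    scores = (hi + hj).leaky_relu(slope) @ p["na_a"]
    alpha = segment_softmax(scores, dst, n)
    msg = segment_sum(hj * alpha.reshape(-1, 1), dst, n)
    return msg, alpha


def _edge_attention_block(h: Tensor, e: Tensor, src, dst, n: int, p: dict,
                          slope: float = LEAKY_SLOPE):
    """Softmax attention of each node over its incident edges, then the
    nonlinear weighted average of transformed edge features."""
    hi = gather(h, dst) @ p["ea_W1"]
    ej = e @ p["ea_W2"]
    scores = ((hi + ej) @ p["ea_a"]).leaky_relu(slope)
    alpha = segment_softmax(scores, dst, n)
    msg = segment_sum(ej * alpha.reshape(-1, 1), dst, n).relu()
    return msg, alpha


def _weave_node_block(h: Tensor, e: Tensor, src, dst, n: int, p: dict) -> Tensor:
    deg = np.bincount(dst, minlength=n).astype(np.float64)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    ebar = segment_sum(e, dst, n) * Tensor(inv[:, None])
    return (h @ p["wv_n2n"] + ebar @ p["wv_e2n"] + p["wv_b_node"]).relu()


def _weave_edge_block(h: Tensor, e: Tensor, src, p: dict) -> Tensor:
    mixed = gather(h, src) @ p["wv_n2e"] + e @ p["wv_e2e"]
    return (mixed @ p["wv_ue"] + p["wv_b_edge"]).relu()


def _gru_block(x: Tensor, h: Tensor, p: dict) -> Tensor:
    z = (x @ p["gru_Wz"] + h @ p["gru_Uz"] + p["gru_bz"]).sigmoid()
    r = (x @ p["gru_Wr"] + h @ p["gru_Ur"] + p["gru_br"]).sigmoid()
    nhat = (x @ p["gru_Wn"] + (h @ p["gru_Un"] + p["gru_bn"]) * r).tanh()
    one = Tensor(1.0)
    return (one - z) * nhat + z * h


class HybridLayer:
    """One message-passing layer composing the enabled blocks.

    Forward order is fixed: node branch (attention or normalized mean), edge
    branch (edge attention, if enabled), weave branch, "un" combining linear,
    then GRU merge or direct replacement. Disabled blocks are replaced by
    their pass-throughs, so the all-false config is exactly a GCN layer.
    """

    def __init__(self, config, d: int, rng: np.random.Generator | None = None,
                 params: dict[str, Tensor] | None = None):
        self.config = config
        self.d = d
        if params is None:
            params = init_layer_params(rng or np.random.default_rng(), d, config)
        self.params = params
        self.last_attention: dict[str, np.ndarray | None] = {"node": None, "edge": None}

    def parameters(self) -> list[Tensor]:
        cfg = self.config
        keys: list[str] = []
        if cfg.node_attention:
            keys += ["na_Wl", "na_Wr", "na_a"]
        if cfg.edge_attention:
            keys += ["ea_W1", "ea_W2", "ea_a"]
        if cfg.weave:
            keys += ["wv_n2n", "wv_e2n", "wv_b_node", "wv_n2e", "wv_e2e",
                     "wv_ue", "wv_b_edge"]
        keys += ["un_W", "un_b"]
        if cfg.gru_mpnn:
            keys += ["gru_Wz", "gru_Uz", "gru_bz", "gru_Wr", "gru_Ur", "gru_br",
                     "gru_Wn", "gru_Un", "gru_bn"]
        return [self.params[k] for k in keys]

    def forward(self, h: Tensor, e: Tensor, graph) -> tuple[Tensor, Tensor]:
        src, dst, n = _graph_arrays(graph)
        cfg, p = self.config, self.params
        self.last_attention = {"node": None, "edge": None}

        if cfg.node_attention:
            node_msg, alpha = _node_attention_block(h, src, dst, n, p)
            self.last_attention["node"] = alpha.data.copy()
        else:
            node_msg = _neighbor_mean(h, src, dst, n)
        parts = [node_msg]

        if cfg.edge_attention:
            edge_msg, alpha_e = _edge_attention_block(h, e, src, dst, n, p)
            self.last_attention["edge"] = alpha_e.data.copy()
            parts.append(edge_msg)

        if cfg.weave:
            parts.append(_weave_node_block(h, e, src, dst, n, p))
            e_new = _weave_edge_block(h, e, src, p)
        else:
            e_new = e

        m = (concat(parts, axis=1) if len(parts) > 1 else parts[0]) @ p["un_W"] + p["un_b"]
        h_new = _gru_block(m, h, p) if cfg.gru_mpnn else m.relu()
        return h_new, e_new


# ---------------------------------------------------------------------------
# per-node functional operations (NumPy in, NumPy out)
# ---------------------------------------------------------------------------

def edge_attention_scores(node_h_i: np.ndarray, incident_edge_feats,
                          params: dict) -> np.ndarray:
    """Softmax-normalized attention of one node over its incident edges.

    ``params`` must hold ``a_e`` (d,), ``W1`` and ``W2`` (d_in x d); optional
    ``leaky_slope`` (default 0.2). An empty neighborhood yields an empty
    coefficient array, never a division by zero.
    """
    if len(incident_edge_feats) == 0:
        return np.zeros(0)
    E = np.asarray(incident_edge_feats, dtype=np.float64).reshape(len(incident_edge_feats), -1)
    slope = params.get("leaky_slope", LEAKY_SLOPE)
    p = {"ea_W1": Tensor(params["W1"]), "ea_W2": Tensor(params["W2"]),
         "ea_a": Tensor(params["a_e"])}
    h = Tensor(np.asarray(node_h_i, dtype=np.float64)[None, :])
    dst = np.zeros(E.shape[0], dtype=np.intp)
    src = dst
    _, alpha = _edge_attention_block(h, Tensor(E), src, dst, 1, p, slope)
    return alpha.data.copy()


def edge_attention_aggregate(weights: np.ndarray, incident_edge_feats,
                             params: dict) -> np.ndarray:
    """``sigma(sum_j alpha_j W2 e_j)`` for one node's neighborhood."""
    E = np.asarray(incident_edge_feats, dtype=np.float64).reshape(len(incident_edge_feats), -1)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != E.shape[0]:
        raise ValueError(
            f"got {weights.shape[0]} weights for {E.shape[0]} incident edges")
    sigma = params.get("sigma", lambda x: np.maximum(x, 0.0))
    if E.shape[0] == 0:
        return sigma(np.zeros(params["W2"].shape[1]))
    return sigma(weights @ (E @ params["W2"]))


def node_attention_aggregate(state: LayerState, graph, params: dict) -> np.ndarray:
    """Attention-weighted neighbor aggregation for every node (GATv2 style)."""
    src, dst, n = _graph_arrays(graph)
    p = {"na_Wl": Tensor(params["Wl"]), "na_Wr": Tensor(params["Wr"]),
         "na_a": Tensor(params["a"])}
    msg, _ = _node_attention_block(Tensor(state.node_h), src, dst, n, p,
                                   params.get("leaky_slope", LEAKY_SLOPE))
    return msg.data.copy()


def weave_update(state: LayerState, graph, params: dict) -> LayerState:
    """Standalone weave co-update of node and edge embeddings.

    Node side: ``sigma(n2n(h_i) + e2n(mean incident e))``. Edge side:
    ``sigma(ue(n2e(h_src) + e2e(e)))``.
    """
    src, dst, n = _graph_arrays(graph)
    p = {f"wv_{k}": Tensor(params[k]) for k in
         ("n2n", "e2n", "n2e", "e2e", "ue")}
    d_node = params["n2n"].shape[1]
    d_edge = params["ue"].shape[1]
    p["wv_b_node"] = Tensor(params.get("b_node", np.zeros(d_node)))
    p["wv_b_edge"] = Tensor(params.get("b_edge", np.zeros(d_edge)))
    h, e = Tensor(state.node_h), Tensor(state.edge_h)
    h_new = _weave_node_block(h, e, src, dst, n, p)
    e_new = _weave_edge_block(h, e, src, p)
    return LayerState(node_h=h_new.data, edge_h=e_new.data,
                      layer_index=state.layer_index)


def gru_update(message: np.ndarray, previous_h: np.ndarray, params: dict) -> np.ndarray:
    """Standard GRU cell: the message is the input, previous_h the hidden state.

    With all parameters zero both gates sit at 0.5 and the candidate at 0, so
    the output is exactly half the previous hidden state.
    """
    p = {f"gru_{k}": Tensor(params[k]) for k in
         ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wn", "Un", "bn")}
    out = _gru_block(Tensor(message), Tensor(previous_h), p)
    return out.data.copy()


def hybrid_layer_forward(state: LayerState, graph, config,
                         params: dict[str, Tensor]) -> LayerState:
    """Functional forward pass of one hybrid layer on a LayerState."""
    layer = HybridLayer(config, d=state.node_h.shape[1], params=params)
    h, e = layer.forward(Tensor(state.node_h), Tensor(state.edge_h), graph)
    return LayerState(node_h=h.data, edge_h=e.data,
                      layer_index=state.layer_index + 1)
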