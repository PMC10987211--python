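"""Independent reference implementations used as oracles by the tests.

Everything here is coded directly from the standard formulas in plain NumPy,
separately from the package's autodiff-based layers, so that agreement is a
genuine two-route check.
"""

import numpy as np


def leaky_relu(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def relu(x):
    return np.maximum(x, 0.0)


def softmax(x):
    z = np.exp(x - x.max())
    return z / z.sum()


def neighbors_of(graph, i):
    """Source nodes of directed edges pointing at i, with edge row indices."""
    rows = np.flatnonzero(graph.dst == i)
    return graph.src[rows], rows


def ref_neighbor_mean(h, graph):
    n = h.shape[0]
    out = np.zeros_like(h)
    for i in range(n):
        nbrs, _ = neighbors_of(graph, i)
        if len(nbrs):
            out[i] = h[nbrs].mean(axis=0)
    return out


def ref_gcn_layer(h, graph, un_W, un_b):
    """Plain GCN layer: normalized neighbor mean, linear, ReLU."""
    return relu(ref_neighbor_mean(h, graph) @ un_W + un_b)


def ref_node_attention(h, graph, Wl, Wr, a, slope=0.2):
    """GATv2-style attention aggregation, per destination node."""
    n = h.shape[0]
    out = np.zeros_like(h)
    alphas = {}
    for i in range(n):
        nbrs, _ = neighbors_of(graph, i)
        if not len(nbrs):
            continue
        scores = np.array([leaky_relu(h[i] @ Wl + h[j] @ Wr, slope) @ a
                           for j in nbrs])
        alpha = softmax(scores)
        out[i] = sum(al * (h[j] @ Wr) for al, j in zip(alpha, nbrs))
        alphas[i] = alpha
    return out, alphas


def ref_gat_layer(h, graph, Wl, Wr, a, un_W, un_b):
    agg, _ = ref_node_attention(h, graph, Wl, Wr, a)
    return relu(agg @ un_W + un_b)


def ref_edge_attention(h, e, graph, W1, W2, a, slope=0.2):
    """Per-node softmax over incident edges, then sigma(sum alpha W2 e)."""
    n = h.shape[0]
    d = W2.shape[1]
    out = np.zeros((n, d))
    alphas = {}
    for i in range(n):
        _, rows = neighbors_of(graph, i)
        if not len(rows):
            continue
        scores = np.array([leaky_relu((h[i] @ W1 + e[r] @ W2) @ a, slope)
                           for r in rows])
        alpha = softmax(scores)
        out[i] = relu(sum(al * (e[r] @ W2) for al, r in zip(alpha, rows)))
        alphas[i] = alpha
    return out, alphas


def ref_weave_node(h, e, graph, n2n, e2n, b):
    n = h.shape[0]
    out = np.zeros((n, n2n.shape[1]))
    for i in range(n):
        _, rows = neighbors_of(graph, i)
        ebar = e[rows].mean(axis=0) if len(rows) else np.zeros(e.shape[1])
        out[i] = relu(h[i] @ n2n + ebar @ e2n + b)
    return out


def ref_weave_edge(h, e, graph, n2e, e2e, ue, b):
    out = np.zeros((e.shape[0], ue.shape[1]))
    for r in range(e.shape[0]):
        src = graph.src[r]
        out[r] = relu((h[src] @ n2e + e[r] @ e2e) @ ue + b)
    return out


def ref_gru(x, h, p):
    """Standard GRU cell equations, elementwise."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    z = sig(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
    r = sig(x @ p["Wr"] + h @ p["Ur"] + p["br"])
    nhat = np.tanh(x @ p["Wn"] + r * (h @ p["Un"] + p["bn"]))
    return (1 - z) * nhat + z * h


def ref_weave_only_layer(h, e, graph, params):
    """GCN framework + weave block: node branch is [neighbor mean, weave
    node update] through the combining linear; edges take the weave update."""
    p = {k: params[k].data for k in params}
    parts = np.concatenate([
        ref_neighbor_mean(h, graph),
        ref_weave_node(h, e, graph, p["wv_n2n"], p["wv_e2n"], p["wv_b_node"]),
    ], axis=1)
    h_new = relu(parts @ p["un_W"] + p["un_b"])
    e_new = ref_weave_edge(h, e, graph, p["wv_n2e"], p["wv_e2e"],
                           p["wv_ue"], p["wv_b_edge"])
    return h_new, e_new


def ref_mpnn_layer(h, graph, params):
    """GCN framework + GRU merge: message from the normalized neighbor mean
    through the combining linear, merged with the previous embedding."""
    p = {k: params[k].data for k in params}
    m = ref_neighbor_mean(h, graph) @ p["un_W"] + p["un_b"]
    gp = {name[4:]: p[name] for name in p if name.startswith("gru_")}
    return ref_gru(m, h, gp)


def ref_hybrid_layer(h, e, graph, params, config):
    """Fully independent recomputation of the composed layer."""
    p = {k: params[k].data for k in params}
    if config.node_attention:
        node_msg, _ = ref_node_attention(h, graph, p["na_Wl"], p["na_Wr"], p["na_a"])
    else:
        node_msg = ref_neighbor_mean(h, graph)
    parts = [node_msg]
    if config.edge_attention:
        em, _ = ref_edge_attention(h, e, graph, p["ea_W1"], p["ea_W2"], p["ea_a"])
        parts.append(em)
    if config.weave:
        parts.append(ref_weave_node(h, e, graph, p["wv_n2n"], p["wv_e2n"],
                                    p["wv_b_node"]))
        e_new = ref_weave_edge(h, e, graph, p["wv_n2e"], p["wv_e2e"],
                               p["wv_ue"], p["wv_b_edge"])
    else:
        e_new = e
    m = np.concatenate(parts, axis=1) @ p["un_W"] + p["un_b"]
    if config.gru_mpnn:
        gp = {name[4:]: p[name] for name in p if name.startswith("gru_")}
        h_new = ref_gru(m, h, gp)
    else:
        h_new = relu(m)
    return h_new, e_new


# -- reference canonical featurizer (independent coding) ----------------------

_ELEMENTS = ("C,N,O,S,F,Si,P,Cl,Br,Mg,Na,Ca,Fe,As,Al,I,B,V,K,Tl,Yb,Sb,Sn,Ag,"
             "Pd,Co,Se,Ti,Zn,H,Li,Ge,Cu,Au,Ni,Cd,In,Mn,Zr,Cr,Pt,Hg,Pb").split(",")


def _onehot_last_fallback(value, choices):
    vec = np.zeros(len(choices))
    vec[choices.index(value) if value in choices else -1] = 1.0
    return vec


def ref_atom_features(atom):
    from rdkit.Chem.rdchem import HybridizationType as HT
    return np.concatenate([
        _onehot_last_fallback(atom.GetSymbol(), _ELEMENTS),
        _onehot_last_fallback(atom.GetDegree(), list(range(11))),
        _onehot_last_fallback(atom.GetImplicitValence(), list(range(7))),
        [atom.GetFormalCharge(), atom.GetNumRadicalElectrons()],
        _onehot_last_fallback(atom.GetHybridization(),
                              [HT.SP, HT.SP2, HT.SP3, HT.SP3D, HT.SP3D2]),
        [1.0 if atom.GetIsAromatic() else 0.0],
        _onehot_last_fallback(atom.GetTotalNumHs(), list(range(5))),
    ])


def ref_bond_features(bond):
    from rdkit.Chem.rdchem import BondStereo as BS
    from rdkit.Chem.rdchem import BondType as BT
    return np.concatenate([
        _onehot_last_fallback(bond.GetBondType(),
                              [BT.SINGLE, BT.DOUBLE, BT.TRIPLE, BT.AROMATIC]),
        [1.0 if bond.GetIsConjugated() else 0.0,
         1.0 if bond.IsInRing() else 0.0],
        _onehot_last_fallback(bond.GetStereo(),
                              [BS.STEREONONE, BS.STEREOANY, BS.STEREOZ,
                               BS.STEREOE, BS.STEREOCIS, BS.STEREOTRANS]),
    ])
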