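"""Attention extraction and continuous-attention-substructure mining.

After a forward pass, the last message-passing layer's attention
coefficients are arranged into an ``n_atoms x n_atoms`` matrix whose entry
(i, j) is the attention destination atom i pays to neighbor j (node
attention) or to the bond i-j (edge attention). The matrix is generally
asymmetric — attention from neighbors and attention to neighbors differ —
and is exactly zero at non-bonded pairs.

A *continuous attention substructure* is a bonded simple path of atoms in
which every consecutive atom pair scores above a threshold (default 0.5)
under the pair rule (default: max of the two directed attentions). Paths
are found by depth-first search; by default only maximal paths are
reported (a path neither of whose endpoints can be extended by another
qualifying atom), with an ``"all"`` mode that reports every qualifying
sub-path as well. Each path is exported as the canonical SMILES of its
atoms and bonds, so substructures mined from different molecules can be
pooled and deduplicated with occurrence counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .featurization import MolGraph, batch_graphs
from .model_builder import GNNModel


class AttentionUnavailableError(RuntimeError):
    """Raised when the requested attention block is disabled in the model."""


@dataclass
class AttentionMatrices:
    """Last-layer attention of one molecule, in dense per-atom-pair form."""

    node_att: np.ndarray | None
    edge_att: np.ndarray | None
    layer_index: int

    def matrix(self, kind: str = "node") -> np.ndarray:
        m = self.node_att if kind == "node" else self.edge_att
        if m is None:
            raise AttentionUnavailableError(f"{kind} attention was not recorded")
        return m


@dataclass
class SubstructureRecord:
    """One mined path: ordered bonded atom indices plus its SMILES."""

    atoms: tuple[int, ...]
    smiles: str | None
    count: int = 1


def _dense_attention(alpha: np.ndarray, graph: MolGraph) -> np.ndarray:
    n = graph.n_atoms
    mat = np.zeros((n, n))
    mat[graph.dst, graph.src] = alpha  # row = destination, col = neighbor
    return mat


def extract_attention(model: GNNModel, graph: MolGraph,
                      kind: str = "node") -> AttentionMatrices:
    """Run a forward pass and export the final layer's attention.

    ``kind`` names the block that must be present ("node" or "edge"); a
    model built without it raises :class:`AttentionUnavailableError`.
    """
    cfg = model.spec.config
    if kind == "node" and not cfg.node_attention:
        raise AttentionUnavailableError(
            f"model {cfg.model_id} ({cfg.name}) has no node-attention block")
    if kind == "edge" and not cfg.edge_attention:
        raise AttentionUnavailableError(
            f"model {cfg.model_id} ({cfg.name}) has no edge-attention block")
    model.forward_logits(batch_graphs([graph]))
    recorded = model.last_layer_attention()
    node = recorded.get("node")
    edge = recorded.get("edge")
    return AttentionMatrices(
        node_att=_dense_attention(node, graph) if node is not None else None,
        edge_att=_dense_attention(edge, graph) if edge is not None else None,
        layer_index=model.spec.n_layers - 1,
    )


def _pair_score(att: np.ndarray, i: int, j: int, rule: str) -> float:
    if rule == "max":
        return max(att[i, j], att[j, i])
    if rule == "mean":
        return 0.5 * (att[i, j] + att[j, i])
    raise ValueError(f"unknown pair rule {rule!r}")


def _qualifying_adjacency(graph: MolGraph, att: np.ndarray, threshold: float,
                          rule: str) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(graph.n_atoms)}
    seen = set()
    for u, v in graph.edge_index:
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        seen.add(key)
        if _pair_score(att, int(u), int(v), rule) > threshold:
            adj[int(u)].append(int(v))
            adj[int(v)].append(int(u))
    return adj


def _enumerate_paths(adj: dict[int, list[int]]) -> set[tuple[int, ...]]:
    """All simple paths with >= 2 atoms, each undirected path counted once."""
    paths: set[tuple[int, ...]] = set()

    def dfs(path: list[int], visited: set[int]):
        if len(path) >= 2:
            t = tuple(path)
            paths.add(min(t, t[::-1]))
        for nb in adj[path[-1]]:
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(path, visited)
                path.pop()
                visited.remove(nb)

    for start in adj:
        dfs([start], {start})
    return paths


def _path_smiles(mol: Chem.Mol | None, path: tuple[int, ...]) -> str | None:
    if mol is None:
        return None
    bonds = [mol.GetBondBetweenAtoms(a, b).GetIdx()
             for a, b in zip(path[:-1], path[1:])]
    return Chem.MolFragmentToSmiles(mol, atomsToUse=list(path),
                                    bondsToUse=bonds, canonical=True)


def mine_substructures(graph: MolGraph, att, threshold: float = 0.5, *,
                       pair_rule: str = "max",
                       mode: str = "maximal") -> list[SubstructureRecord]:
    """Mine continuous attention substructures from one molecule.

    Parameters
    ----------
    att:
        An :class:`AttentionMatrices` (its node matrix is used) or a raw
        ``n_atoms x n_atoms`` matrix.
    threshold:
        Strict lower bound on the pair score, in (0, 1].
    pair_rule:
        How the two directed attentions of a bonded pair combine: ``"max"``
        (default) or ``"mean"``.
    mode:
        ``"maximal"`` reports only paths that cannot be extended at either
        end; ``"all"`` reports every qualifying simple path.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if isinstance(att, AttentionMatrices):
        att = att.matrix("node") if att.node_att is not None else att.matrix("edge")
    att = np.asarray(att, dtype=np.float64)
    adj = _qualifying_adjacency(graph, att, threshold, pair_rule)
    paths = _enumerate_paths(adj)
    if mode == "maximal":
        paths = {p for p in paths
                 if not (set(adj[p[0]]) - set(p)) and not (set(adj[p[-1]]) - set(p))}
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    mol = Chem.MolFromSmiles(graph.smiles) if graph.smiles else None
    return [SubstructureRecord(atoms=p, smiles=_path_smiles(mol, p))
            for p in sorted(paths)]


def dedup_substructures(records: list[SubstructureRecord]) -> list[tuple[str, int]]:
    """Group mined records by substructure SMILES with occurrence counts.

    Counts sum to the number of input records; the result is sorted by
    descending count, then by SMILES.
    """
    counter: Counter[str] = Counter()
    for rec in records:
        if rec.smiles is None:
            raise ValueError(f"record {rec.atoms} has no SMILES; mine from a "
                             "chemistry-backed graph to deduplicate")
        counter[rec.smiles] += rec.count
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
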