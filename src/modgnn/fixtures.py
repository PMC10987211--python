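"""Synthetic labeled molecule sets and random graph fixtures.

Everything here is a pure function of its parameters and seed, so the rest
of the toolkit is testable without downloading any benchmark.

``generate_separable_set`` plants a clean structural rule: class 1
molecules carry a nitro group, class 0 molecules carry a hydroxyl instead,
on otherwise similar randomly decorated scaffolds. A substructure match on
the nitro group recovers the labels exactly, and a trained classifier can
approach that ceiling. ``generate_regression_set`` plants a documented
closed-form target: ``y = 0.5 * n_heavy + 1.5 * n_hydroxyl + noise`` with
Gaussian noise of known sigma, which fixes the best achievable R2 at
``var(signal) / (var(signal) + sigma^2)``.

``random_graph_fixture`` emits MolGraph-shaped graphs with random feature
matrices of the canonical 74/12 widths. These bypass chemical validity on
purpose: layer arithmetic is chemistry-agnostic, and random features
exercise it more broadly than valid molecules do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .featurization import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolGraph


@dataclass
class SyntheticDataset:
    """A generated (SMILES, label) set with its provenance."""

    records: list[tuple[str, float]]
    generator: str
    seed: int
    rule: str

    def __len__(self) -> int:
        return len(self.records)

    def smiles(self) -> list[str]:
        return [s for s, _ in self.records]

    def labels(self) -> np.ndarray:
        return np.asarray([lab for _, lab in self.records], dtype=np.float64)


NITRO = "[N+](=O)[O-]"
NITRO_QUERY = Chem.MolFromSmarts("[N+](=O)[O-]")


def _random_scaffold(rng: np.random.Generator) -> str:
    """A small branched alkyl or aryl scaffold ending in an attachable atom."""
    length = int(rng.integers(2, 7))
    atoms = ["C"] * length
    # sprinkle methyl branches on interior atoms
    parts = []
    for i, a in enumerate(atoms):
        parts.append(a)
        if 0 < i < length - 1 and rng.random() < 0.3:
            parts.append("(C)")
    scaffold = "".join(parts)
    if rng.random() < 0.3:
        scaffold = "c1ccccc1" + scaffold  # aryl head
    return scaffold


def generate_separable_set(n: int, seed: int = 0) -> SyntheticDataset:
    """Two molecule families separated by a planted substructure.

    Class 1 ends in a nitro group, class 0 in a hydroxyl; classes are
    balanced to within one molecule. Every SMILES is checked parseable.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, float]] = []
    n_pos = (n + 1) // 2
    for i in range(n):
        label = 1.0 if i < n_pos else 0.0
        group = NITRO if label else "O"
        while True:
            smiles = _random_scaffold(rng) + group
            if Chem.MolFromSmiles(smiles) is not None:
                break
        records.append((smiles, label))
    order = rng.permutation(n)
    records = [records[i] for i in order]
    return SyntheticDataset(records=records, generator="separable", seed=seed,
                            rule=f"label 1 iff molecule contains {NITRO}")


def match_planted_rule(smiles: str) -> float:
    """The oracle classifier for the separable set: nitro present -> 1."""
    mol = Chem.MolFromSmiles(smiles)
    return float(mol is not None and mol.HasSubstructMatch(NITRO_QUERY))


REGRESSION_COEF_HEAVY = 0.5
REGRESSION_COEF_OH = 1.5


def generate_regression_set(n: int, seed: int = 0,
                            sigma: float = 0.3) -> SyntheticDataset:
    """Molecules with target ``0.5*n_heavy + 1.5*n_OH + N(0, sigma^2)``.

    Scaffolds are alkyl chains of 4-9 carbons decorated with 0-3 hydroxyl
    branches; heavy-atom count and hydroxyl count vary independently enough
    to identify both coefficients.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        length = int(rng.integers(4, 10))
        n_oh = int(rng.integers(0, 4))
        positions = sorted(rng.choice(length - 1, size=n_oh, replace=False)
                           ) if n_oh else []
        parts = []
        for i in range(length):
            parts.append("C")
            if i in positions and i < length - 1:
                parts.append("(O)")
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        heavy = mol.GetNumHeavyAtoms()
        y = (REGRESSION_COEF_HEAVY * heavy + REGRESSION_COEF_OH * n_oh
             + rng.normal(0.0, sigma))
        records.append((smiles, float(y)))
    return SyntheticDataset(
        records=records, generator="regression", seed=seed,
        rule=(f"y = {REGRESSION_COEF_HEAVY}*n_heavy + {REGRESSION_COEF_OH}"
              f"*n_hydroxyl + N(0, {sigma}^2)"))


def random_graph_fixture(n_nodes: int, edge_prob: float = 0.3,
                         seed: int = 0) -> MolGraph:
    """Connected random graph with 74/12-dim random features.

    A random spanning tree guarantees connectivity; every remaining pair
    gains an edge with probability ``edge_prob``. Both directions of each
    edge carry identical features, as in real molecular graphs.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    for v in range(1, n_nodes):
        u = int(rng.integers(0, v))
        pairs.add((u, v))
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            if (u, v) not in pairs and rng.random() < edge_prob:
                pairs.add((u, v))
    edge_index, edge_feats = [], []
    for u, v in sorted(pairs):
        f = rng.random(EDGE_FEATURE_DIM)
        edge_index.extend([(u, v), (v, u)])
        edge_feats.extend([f, f])
    return MolGraph(
        smiles=None, n_atoms=n_nodes,
        node_feats=rng.random((n_nodes, NODE_FEATURE_DIM)),
        edge_index=np.array(edge_index, dtype=np.intp).reshape(-1, 2),
        edge_feats=(np.stack(edge_feats) if edge_feats
                    else np.zeros((0, EDGE_FEATURE_DIM))),
    )
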