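"""Message-passing blocks: closed-form cases, brute-force oracles, and the
reduction of single-block configs to their reference layers."""

import numpy as np
import pytest

from modgnn import (LayerState, ModuleConfig, edge_attention_aggregate,
                    edge_attention_scores, gru_update, hybrid_layer_forward,
                    node_attention_aggregate, random_graph_fixture,
                    weave_update)
from modgnn.autodiff import Tensor
from modgnn.gnn_layers import HybridLayer

import _references as ref
from conftest import layer_params, make_state

D = 5


def _ea_params(rng, d=D):
    return {"a_e": rng.normal(size=d), "W1": rng.normal(size=(d, d)),
            "W2": rng.normal(size=(d, d))}


class TestEdgeAttention:
    def test_single_incident_edge_gets_full_weight(self, rng):
        alpha = edge_attention_scores(rng.normal(size=D), [rng.normal(size=D)],
                                      _ea_params(rng))
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_edges_share_weight_equally(self, rng):
        e = rng.normal(size=D)
        alpha = edge_attention_scores(rng.normal(size=D), [e, e], _ea_params(rng))
        np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-12)

    def test_four_edge_case_matches_softmax_oracle(self, rng):
        h = rng.normal(size=D)
        edges = [rng.normal(size=D) for _ in range(4)]
        p = _ea_params(rng)
        alpha = edge_attention_scores(h, edges, p)
        scores = np.array([ref.leaky_relu((h @ p["W1"] + e @ p["W2"]) @ p["a_e"])
                           for e in edges])
        np.testing.assert_allclose(alpha, ref.softmax(scores), atol=1e-6)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_neighborhood_returns_empty_not_nan(self, rng):
        alpha = edge_attention_scores(rng.normal(size=D), [], _ea_params(rng))
        assert alpha.shape == (0,)

    def test_aggregate_identity_returns_edge_feature(self, rng):
        e = rng.normal(size=D)
        out = edge_attention_aggregate(np.array([1.0]), [e],
                                       {"W2": np.eye(D), "sigma": lambda x: x})
        np.testing.assert_allclose(out, e)

    def test_aggregate_zero_edges_is_zero_before_sigma(self, rng):
        out = edge_attention_aggregate(np.array([0.5, 0.5]),
                                       [np.zeros(D), np.zeros(D)],
                                       {"W2": rng.normal(size=(D, D)),
                                        "sigma": lambda x: x})
        np.testing.assert_allclose(out, np.zeros(D))

    def test_aggregate_three_edge_weighted_sum_oracle(self, rng):
        edges = [rng.normal(size=D) for _ in range(3)]
        W2 = rng.normal(size=(D, D))
        w = np.array([0.2, 0.3, 0.5])
        out = edge_attention_aggregate(w, edges, {"W2": W2, "sigma": lambda x: x})
        expected = sum(wi * (e @ W2) for wi, e in zip(w, edges))
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_aggregate_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="incident edges"):
            edge_attention_aggregate(np.array([1.0]), [np.zeros(D)] * 2,
                                     {"W2": np.eye(D)})


class TestNodeAttention:
    def _params(self, rng):
        return {"Wl": rng.normal(size=(D, D)), "Wr": rng.normal(size=(D, D)),
                "a": rng.normal(size=D)}

    def test_two_node_graph_each_receives_the_other(self, rng):
        g = random_graph_fixture(2, edge_prob=0.0, seed=1)
        h, e = make_state(g, D)
        p = self._params(rng)
        out = node_attention_aggregate(LayerState(h, e), g, p)
        np.testing.assert_allclose(out[0], h[1] @ p["Wr"], atol=1e-10)
        np.testing.assert_allclose(out[1], h[0] @ p["Wr"], atol=1e-10)

    def test_star_graph_identical_leaves_get_equal_thirds(self, rng):
        import modgnn.featurization as fz
        edge_index = np.array([[0, 1], [1, 0], [0, 2], [2, 0], [0, 3], [3, 0]])
        g = fz.MolGraph(smiles=None, n_atoms=4,
                        node_feats=np.zeros((4, 74)),
                        edge_index=edge_index,
                        edge_feats=np.zeros((6, 12)))
        h = np.vstack([rng.normal(size=D), *([rng.normal(size=D)] * 3)])
        p = self._params(rng)
        out = node_attention_aggregate(LayerState(h, np.zeros((6, D))), g, p)
        np.testing.assert_allclose(out[0], h[1] @ p["Wr"], atol=1e-10)

    def test_random_graph_matches_reference_and_rows_sum_to_one(self, rng):
        g = random_graph_fixture(5, edge_prob=0.5, seed=3)
        h, e = make_state(g, D)
        p = self._params(rng)
        out = node_attention_aggregate(LayerState(h, e), g, p)
        expected, alphas = ref.ref_node_attention(h, g, p["Wl"], p["Wr"], p["a"])
        np.testing.assert_allclose(out, expected, atol=1e-6)
        for alpha in alphas.values():
            assert alpha.sum() == pytest.approx(1.0, abs=1e-6)


class TestWeave:
    def _params(self, rng, zero=False, identity=False):
        if zero:
            mk = lambda: np.zeros((D, D))
        elif identity:
            mk = lambda: np.eye(D)
        else:
            mk = lambda: rng.normal(size=(D, D))
        return {k: mk() for k in ("n2n", "e2n", "n2e", "e2e", "ue")}

    def test_zero_maps_give_sigma_of_zero(self, rng, small_graph):
        h, e = make_state(small_graph, D)
        out = weave_update(LayerState(h, e), small_graph, self._params(rng, zero=True))
        np.testing.assert_array_equal(out.node_h, 0.0)
        np.testing.assert_array_equal(out.edge_h, 0.0)

    def test_identity_maps_add_source_node_to_edge(self):
        g = random_graph_fixture(2, edge_prob=0.0, seed=2)
        r = np.random.default_rng(0)
        h = np.abs(r.normal(size=(2, D)))  # positive, so ReLU is identity
        e = np.abs(r.normal(size=(2, D)))
        out = weave_update(LayerState(h, e), g, self._params(r, identity=True))
        for row, (src, _) in enumerate(g.edge_index):
            np.testing.assert_allclose(out.edge_h[row], e[row] + h[src], atol=1e-10)

    def test_random_graph_matches_two_branch_oracle(self, rng, small_graph):
        h, e = make_state(small_graph, D, seed=5)
        p = self._params(rng)
        out = weave_update(LayerState(h, e), small_graph, p)
        exp_nodes = ref.ref_weave_node(h, e, small_graph, p["n2n"], p["e2n"],
                                       np.zeros(D))
        exp_edges = ref.ref_weave_edge(h, e, small_graph, p["n2e"], p["e2e"],
                                       p["ue"], np.zeros(D))
        np.testing.assert_allclose(out.node_h, exp_nodes, atol=1e-6)
        np.testing.assert_allclose(out.edge_h, exp_edges, atol=1e-6)


class TestGRU:
    def _zero_params(self):
        zW = np.zeros((D, D))
        zb = np.zeros(D)
        return {"Wz": zW, "Uz": zW, "bz": zb, "Wr": zW, "Ur": zW, "br": zb,
                "Wn": zW, "Un": zW, "bn": zb}

    def test_zero_parameters_halve_previous_state(self, rng):
        h = rng.normal(size=D)
        out = gru_update(np.zeros(D), h, self._zero_params())
        np.testing.assert_allclose(out, 0.5 * h, atol=1e-12)

    def test_zero_state_and_parameters_give_zero(self):
        out = gru_update(np.ones(D), np.zeros(D), self._zero_params())
        np.testing.assert_allclose(out, np.zeros(D), atol=1e-12)

    def test_random_instance_matches_reference_cell(self, rng):
        p = {k: rng.normal(size=(D, D)) if k[0] in "WU" else rng.normal(size=D)
             for k in self._zero_params()}
        x, h = rng.normal(size=(2, D))
        np.testing.assert_allclose(gru_update(x, h, p), ref.ref_gru(x, h, p),
                                   atol=1e-6)


class TestHybridLayer:
    def _forward(self, graph, bits, d=D, seed=0, zero=False, state_seed=1):
        cfg, params = layer_params(bits, d, seed=seed, zero=zero)
        h, e = make_state(graph, d, seed=state_seed)
        out = hybrid_layer_forward(LayerState(h, e), graph, cfg, params)
        return h, e, out, params, cfg

    def test_all_false_equals_reference_gcn(self, small_graph):
        h, e, out, params, _ = self._forward(small_graph, (0, 0, 0, 0))
        expected = ref.ref_gcn_layer(h, small_graph, params["un_W"].data,
                                     params["un_b"].data)
        np.testing.assert_allclose(out.node_h, expected, atol=1e-6)
        np.testing.assert_array_equal(out.edge_h, e)  # edges pass through

    def test_gat_only_equals_reference_gat(self, small_graph):
        h, _, out, p, _ = self._forward(small_graph, (1, 0, 0, 0))
        expected = ref.ref_gat_layer(h, small_graph, p["na_Wl"].data,
                                     p["na_Wr"].data, p["na_a"].data,
                                     p["un_W"].data, p["un_b"].data)
        np.testing.assert_allclose(out.node_h, expected, atol=1e-6)

    def test_weave_only_equals_reference_weave_layer(self, small_graph):
        h, e, out, p, _ = self._forward(small_graph, (0, 0, 1, 0))
        exp_h, exp_e = ref.ref_weave_only_layer(h, e, small_graph, p)
        np.testing.assert_allclose(out.node_h, exp_h, atol=1e-6)
        np.testing.assert_allclose(out.edge_h, exp_e, atol=1e-6)

    def test_mpnn_only_equals_reference_mpnn_layer(self, small_graph):
        h, e, out, p, _ = self._forward(small_graph, (0, 0, 0, 1))
        np.testing.assert_allclose(out.node_h,
                                   ref.ref_mpnn_layer(h, small_graph, p),
                                   atol=1e-6)
        np.testing.assert_array_equal(out.edge_h, e)

    @pytest.mark.parametrize("bits", [(1, 1, 1, 1), (1, 1, 0, 1), (0, 1, 1, 0),
                                      (1, 0, 1, 1), (0, 1, 0, 1)])
    def test_mixed_configs_match_full_independent_recomputation(self, small_graph, bits):
        h, e, out, p, cfg = self._forward(small_graph, bits, seed=7)
        exp_h, exp_e = ref.ref_hybrid_layer(h, e, small_graph, p, cfg)
        np.testing.assert_allclose(out.node_h, exp_h, atol=1e-6)
        np.testing.assert_allclose(out.edge_h, exp_e, atol=1e-6)

    def test_all_true_zero_parameters_halves_node_state(self, small_graph):
        h, _, out, _, _ = self._forward(small_graph, (1, 1, 1, 1), zero=True)
        np.testing.assert_allclose(out.node_h, 0.5 * h, atol=1e-12)

    @pytest.mark.parametrize("bits", [(0, 0, 0, 0), (1, 1, 1, 1), (1, 0, 1, 0)])
    def test_permutation_equivariance(self, bits):
        g = random_graph_fixture(7, edge_prob=0.4, seed=21)
        cfg, params = layer_params(bits, D, seed=3)
        h, e = make_state(g, D, seed=9)
        out = hybrid_layer_forward(LayerState(h, e), g, cfg, params)

        perm = np.random.default_rng(2).permutation(g.n_atoms)
        import modgnn.featurization as fz
        remap = np.empty_like(perm)
        remap[perm] = np.arange(g.n_atoms)
        g2 = fz.MolGraph(smiles=None, n_atoms=g.n_atoms,
                         node_feats=g.node_feats[perm],
                         edge_index=remap[g.edge_index],
                         edge_feats=g.edge_feats)
        out2 = hybrid_layer_forward(LayerState(h[perm], e), g2, cfg, params)
        np.testing.assert_allclose(out2.node_h, out.node_h[perm], atol=1e-9)

    @pytest.mark.parametrize("bits", [(0, 0, 0, 0), (1, 1, 1, 1)])
    def test_isolated_node_produces_finite_output(self, bits):
        g = random_graph_fixture(1, edge_prob=0.0, seed=4)
        cfg, params = layer_params(bits, D, seed=5)
        h, e = make_state(g, D)
        out = hybrid_layer_forward(LayerState(h, e), g, cfg, params)
        assert np.all(np.isfinite(out.node_h))

    def test_attention_rows_sum_to_one_in_forward(self, small_graph):
        cfg, params = layer_params((1, 1, 0, 0), D, seed=6)
        layer = HybridLayer(cfg, D, params=params)
        h, e = make_state(small_graph, D)
        layer.forward(Tensor(h), Tensor(e), small_graph)
        for kind in ("node", "edge"):
            alpha = layer.last_attention[kind]
            sums = np.zeros(small_graph.n_atoms)
            np.add.at(sums, small_graph.dst, alpha)
            deg = np.bincount(small_graph.dst, minlength=small_graph.n_atoms)
            np.testing.assert_allclose(sums[deg > 0], 1.0, atol=1e-6)
            counts = np.bincount(small_graph.dst, minlength=small_graph.n_atoms)
            assert alpha.shape[0] == counts.sum()
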