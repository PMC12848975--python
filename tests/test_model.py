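"""Attention blocks, convolution, pooling and the full forward pass.

The attention/pooling operations are checked against independent
straight-line evaluations of their defining formulas on small seeded
fixtures, plus the degenerate cases those formulas force (zero weights give
sigmoid gates of exactly 0.5, single-node pooling, permutation symmetry).
"""

import numpy as np
import pytest

from foldgo import model as M
from foldgo.structgraph import ContactGraph


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture
def seeded_weights():
    rng = np.random.default_rng(123)
    c, cr, hs = 4, 2, 3
    return {
        "cbam_cW1": rng.standard_normal((c, cr)),
        "cbam_cb1": rng.standard_normal(cr),
        "cbam_cW2": rng.standard_normal((cr, c)),
        "cbam_cb2": rng.standard_normal(c),
        "cbam_sW1": rng.standard_normal((2, hs)),
        "cbam_sb1": rng.standard_normal(hs),
        "cbam_sW2": rng.standard_normal((hs, 1)),
        "cbam_sb2": rng.standard_normal(1),
    }


class TestChannelAttention:
    def test_matches_straight_line_formula(self, seeded_weights):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((3, 4))
        a_c, x_channel = M.channel_attention(X, seeded_weights)
        # independent re-computation, one formula step at a time
        f_avg = np.array([X[:, j].mean() for j in range(4)])
        f_max = np.array([X[:, j].max() for j in range(4)])
        w = seeded_weights

        def mlp(f):
            h = np.maximum(f @ w["cbam_cW1"] + w["cbam_cb1"], 0)
            return h @ w["cbam_cW2"] + w["cbam_cb2"]

        expected_gate = sigmoid(mlp(f_avg) + mlp(f_max))
        np.testing.assert_allclose(a_c, expected_gate, atol=1e-6)
        np.testing.assert_allclose(
            x_channel, X * expected_gate[None, :], atol=1e-6
        )
        assert np.all((a_c > 0) & (a_c < 1))

    def test_single_node_pooling_degeneracy(self, seeded_weights):
        X = np.array([[1.0, -2.0, 3.0, 0.5]])
        a_c, x_channel = M.channel_attention(X, seeded_weights)
        # with one node, average and max pooling coincide
        w = seeded_weights
        h = np.maximum(X[0] @ w["cbam_cW1"] + w["cbam_cb1"], 0)
        gate = sigmoid(2 * (h @ w["cbam_cW2"] + w["cbam_cb2"]))
        np.testing.assert_allclose(a_c, gate, atol=1e-6)

    def test_zero_weights_force_half_gates(self, seeded_weights):
        zero = {k: np.zeros_like(v) for k, v in seeded_weights.items()}
        X = np.random.default_rng(0).standard_normal((5, 4))
        a_c, x_channel = M.channel_attention(X, zero)
        np.testing.assert_allclose(a_c, 0.5)
        np.testing.assert_allclose(x_channel, 0.5 * X)

    def test_empty_graph_rejected(self, seeded_weights):
        with pytest.raises(ValueError):
            M.channel_attention(np.empty((0, 4)), seeded_weights)


class TestSpatialAttention:
    def test_matches_straight_line_formula(self, seeded_weights):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((3, 4))
        a_s, x_enh = M.spatial_attention(X, seeded_weights)
        w = seeded_weights
        for i in range(3):
            g = np.array([X[i].mean(), X[i].max()])
            h = np.maximum(g @ w["cbam_sW1"] + w["cbam_sb1"], 0)
            gate = sigmoid(h @ w["cbam_sW2"] + w["cbam_sb2"])[0]
            assert a_s[i] == pytest.approx(gate, abs=1e-6)
            np.testing.assert_allclose(x_enh[i], X[i] * gate, atol=1e-6)

    def test_constant_row_statistics(self, seeded_weights):
        X = np.full((2, 4), 3.7)
        a_s, _ = M.spatial_attention(X, seeded_weights)
        # g_avg = g_max for constant rows → both nodes get the same gate
        assert a_s[0] == pytest.approx(a_s[1], abs=1e-12)

    def test_zero_weights_force_half_gates(self, seeded_weights):
        zero = {k: np.zeros_like(v) for k, v in seeded_weights.items()}
        X = np.random.default_rng(1).standard_normal((4, 4))
        a_s, _ = M.spatial_attention(X, zero)
        np.testing.assert_allclose(a_s, 0.5)


class TestGraphCbam:
    def test_disabled_is_identity(self, seeded_weights):
        X = np.random.default_rng(2).standard_normal((4, 4))
        np.testing.assert_array_equal(
            M.graph_cbam(X, seeded_weights, use_cbam=False), X
        )

    def test_composition_equals_two_stage_application(self, seeded_weights):
        X = np.random.default_rng(3).standard_normal((5, 4))
        _, x_channel = M.channel_attention(X, seeded_weights)
        _, expected = M.spatial_attention(x_channel, seeded_weights)
        np.testing.assert_allclose(
            M.graph_cbam(X, seeded_weights), expected, atol=1e-12
        )

    @pytest.mark.parametrize("shape", [(1, 4), (6, 4)])
    def test_output_shape_preserved(self, seeded_weights, shape):
        X = np.random.default_rng(4).standard_normal(shape)
        assert M.graph_cbam(X, seeded_weights).shape == shape


class TestGraphConv:
    def test_hand_computed_three_node_path(self, path_graph):
        # 1-d features, hand-set scalar weights
        X = np.array([[1.0], [2.0], [4.0]])
        w = {"Wself": np.array([[2.0]]), "Wneigh": np.array([[10.0]]),
             "b": np.array([0.5])}
        out = M.graph_conv(path_graph, X, w, activation="identity")
        # node 0: 2·1 + 10·mean(2) + 0.5 = 22.5
        # node 1: 2·2 + 10·mean(1,4) + 0.5 = 29.5
        # node 2: 2·4 + 10·mean(2) + 0.5 = 28.5
        np.testing.assert_allclose(out[:, 0], [22.5, 29.5, 28.5])

    def test_isolated_node_uses_only_self_term(self):
        graph = ContactGraph(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        X = np.array([[3.0], [5.0]])
        w = {"Wself": np.array([[1.0]]), "Wneigh": np.array([[100.0]]),
             "b": np.array([0.0])}
        out = M.graph_conv(graph, X, w, activation="identity")
        np.testing.assert_allclose(out[:, 0], [3.0, 5.0])

    def test_zero_neighbor_weights_reduce_to_perceptron(self, triangle_graph):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((3, 4))
        w = {"Wself": rng.standard_normal((4, 2)),
             "Wneigh": np.zeros((4, 2)), "b": rng.standard_normal(2)}
        out = M.graph_conv(triangle_graph, X, w)
        np.testing.assert_allclose(
            out, np.maximum(X @ w["Wself"] + w["b"], 0), atol=1e-12
        )


class TestDualHeadScores:
    def test_identical_heads_average_to_one_head(self, triangle_graph):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((3, 4))
        head = {"Wself": rng.standard_normal((4, 1)),
                "Wneigh": rng.standard_normal((4, 1)),
                "b": rng.standard_normal(1)}
        z = M.dual_head_scores(triangle_graph, X, head, head)
        s1 = M.graph_conv(triangle_graph, X, head, activation="identity")[:, 0]
        np.testing.assert_allclose(z, s1, atol=1e-12)

    def test_zero_second_head_halves_first(self, triangle_graph):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((3, 4))
        head1 = {"Wself": rng.standard_normal((4, 1)),
                 "Wneigh": rng.standard_normal((4, 1)),
                 "b": rng.standard_normal(1)}
        head2 = {k: np.zeros_like(v) for k, v in head1.items()}
        z = M.dual_head_scores(triangle_graph, X, head1, head2)
        s1 = M.graph_conv(triangle_graph, X, head1, activation="identity")[:, 0]
        np.testing.assert_allclose(z, s1 / 2, atol=1e-12)

    def test_random_heads_equal_mean_of_head_outputs(self, star_graph):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((5, 3))
        mk = lambda: {"Wself": rng.standard_normal((3, 1)),
                      "Wneigh": rng.standard_normal((3, 1)),
                      "b": rng.standard_normal(1)}
        h1, h2 = mk(), mk()
        z = M.dual_head_scores(star_graph, X, h1, h2)
        s1 = M.graph_conv(star_graph, X, h1, activation="identity")[:, 0]
        s2 = M.graph_conv(star_graph, X, h2, activation="identity")[:, 0]
        np.testing.assert_allclose(z, (s1 + s2) / 2, atol=1e-12)


class TestTopKPool:
    def test_enumerated_top_two_of_four(self):
        graph = ContactGraph(n_nodes=4, edges=np.array([[0, 2], [1, 3], [0, 1]]))
        X = np.arange(8.0).reshape(4, 2)
        Z = np.array([0.9, 0.1, 0.8, 0.2])
        pool = M.top_k_pool(graph, X, Z, k=0.5)
        np.testing.assert_array_equal(pool.idx, [0, 2])
        np.testing.assert_array_equal(pool.x_out, X[[0, 2]])
        # only the 0–2 edge survives, reindexed to (0, 1)
        assert pool.subgraph.edge_set() == {(0, 1)}

    def test_k_one_keeps_everything(self, triangle_graph):
        X = np.random.default_rng(9).standard_normal((3, 2))
        pool = M.top_k_pool(triangle_graph, X, np.array([0.1, 0.5, 0.3]), k=1.0)
        np.testing.assert_array_equal(pool.idx, [0, 1, 2])
        assert pool.subgraph.edge_set() == triangle_graph.edge_set()

    def test_ties_prefer_lower_index(self):
        graph = ContactGraph(n_nodes=4, edges=np.empty((0, 2), dtype=int))
        pool = M.top_k_pool(graph, np.zeros((4, 1)), np.zeros(4), k=0.5)
        np.testing.assert_array_equal(pool.idx, [0, 1])

    def test_ceiling_with_floor_of_one(self):
        graph = ContactGraph(n_nodes=3, edges=np.empty((0, 2), dtype=int))
        assert M.top_k_pool(graph, np.zeros((3, 1)), np.zeros(3), k=0.01).idx.size == 1
        assert M.top_k_pool(graph, np.zeros((3, 1)), np.zeros(3), k=0.5).idx.size == 2

    def test_induced_subgraph_matches_brute_force(self):
        rng = np.random.default_rng(10)
        n = 6
        edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                          if rng.random() < 0.5])
        graph = ContactGraph(n_nodes=n, edges=edges)
        Z = rng.standard_normal(n)
        pool = M.top_k_pool(graph, rng.standard_normal((n, 2)), Z, k=0.5)
        kept = set(int(i) for i in pool.idx)
        remap = {int(v): k for k, v in enumerate(pool.idx)}
        expected = {
            (min(remap[i], remap[j]), max(remap[i], remap[j]))
            for i, j in graph.edge_set()
            if i in kept and j in kept
        }
        assert pool.subgraph.edge_set() == expected

    def test_score_gating_scales_rows_by_tanh(self):
        graph = ContactGraph(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Z = np.array([0.7, -0.2])
        pool = M.top_k_pool(graph, X, Z, k=1.0, score_gated=True)
        np.testing.assert_allclose(pool.x_out, X * np.tanh(Z)[:, None])


class TestReadout:
    def test_single_node_mean_equals_max(self):
        graph = ContactGraph(n_nodes=1, edges=np.empty((0, 2), dtype=int))
        X = np.array([[1.0, -2.0, 3.0]])
        pool = M.top_k_pool(graph, X, np.zeros(1), k=1.0)
        np.testing.assert_allclose(M.readout(pool), [1, -2, 3, 1, -2, 3])

    def test_two_node_mean_and_max(self):
        graph = ContactGraph(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        pool = M.top_k_pool(graph, X, np.zeros(2), k=1.0)
        np.testing.assert_allclose(M.readout(pool), [0.5, 0.5, 1.0, 1.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((5, 3))
        graph = ContactGraph(n_nodes=5, edges=np.empty((0, 2), dtype=int))
        pool = M.top_k_pool(graph, X, np.zeros(5), k=1.0)
        base = M.readout(pool)
        for _ in range(5):
            perm = rng.permutation(5)
            pool_p = M.top_k_pool(graph, X[perm], np.zeros(5), k=1.0)
            np.testing.assert_allclose(M.readout(pool_p), base, atol=1e-12)


def make_inputs(n_labels=3, n_nodes=6, seed=0, **cfg_kwargs):
    rng = np.random.default_rng(seed)
    edges = np.array([(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)
                      if rng.random() < 0.5])
    graph = ContactGraph(n_nodes=n_nodes, edges=edges)
    cfg = M.ModelConfig(
        n_labels=n_labels, in_dim=36, embed_dim=10, hidden_dim=8,
        spatial_hidden=4, seq_dim=16, classifier_hidden=12, seed=seed,
        **cfg_kwargs,
    )
    state = M.init_model_state(cfg)
    fused = rng.standard_normal((n_nodes, 36))
    seq = rng.standard_normal(16)
    return graph, fused, seq, state


class TestForward:
    def test_outputs_strictly_inside_unit_interval(self):
        graph, fused, seq, state = make_inputs()
        probs = M.forward(graph, fused, seq, state)
        assert probs.shape == (3,)
        assert np.all((probs > 0) & (probs < 1))

    def test_deterministic_across_calls(self):
        graph, fused, seq, state = make_inputs(seed=1)
        np.testing.assert_array_equal(
            M.forward(graph, fused, seq, state),
            M.forward(graph, fused, seq, state),
        )

    def test_zero_classifier_weights_give_half_everywhere(self):
        graph, fused, seq, state = make_inputs(seed=2)
        state.params["cls_W1"][:] = 0
        state.params["cls_b1"][:] = 0
        state.params["cls_W2"][:] = 0
        state.params["cls_b2"][:] = 0
        np.testing.assert_allclose(M.forward(graph, fused, seq, state), 0.5)

    def test_node_permutation_invariance(self):
        graph, fused, seq, state = make_inputs(seed=3, n_nodes=6)
        base = M.forward(graph, fused, seq, state)
        rng = np.random.default_rng(99)
        for _ in range(3):
            perm = rng.permutation(6)
            inv = np.argsort(perm)
            edges = np.array([[inv[i], inv[j]] for i, j in graph.edges])
            graph_p = ContactGraph(n_nodes=6, edges=edges)
            probs = M.forward(graph_p, fused[perm], seq, state)
            np.testing.assert_allclose(probs, base, atol=1e-6)

    def test_without_structure_ignores_embedding_block(self):
        graph, fused, seq, state = make_inputs(seed=4, use_structure=False)
        other = fused.copy()
        other[:, :10] = np.random.default_rng(5).standard_normal((6, 10))
        np.testing.assert_allclose(
            M.forward(graph, fused, seq, state),
            M.forward(graph, other, seq, state),
            atol=1e-12,
        )

    def test_without_onehot_ignores_onehot_block(self):
        graph, fused, seq, state = make_inputs(seed=6, use_onehot=False)
        other = fused.copy()
        other[:, 10:] = np.random.default_rng(7).standard_normal((6, 26))
        np.testing.assert_allclose(
            M.forward(graph, fused, seq, state),
            M.forward(graph, other, seq, state),
            atol=1e-12,
        )

    def test_label_count_mismatch_raises(self):
        graph, fused, seq, state = make_inputs(seed=8)
        with pytest.raises(ValueError):
            M.forward(graph, fused, seq[:-1], state)


class TestBackward:
    @pytest.mark.parametrize("cfg_kwargs", [
        {},                          # defaults: CBAM on, gated pooling
        {"use_cbam": False},
        {"score_gated_pool": False},
        {"use_structure": False},
    ])
    def test_gradients_match_finite_differences(self, cfg_kwargs):
        graph, fused, seq, state = make_inputs(seed=12, **cfg_kwargs)
        y = np.array([1.0, 0.0, 1.0])
        _, cache = M._forward_cached(graph, fused, seq, state)
        grads = M._backward(cache, state, y)
        rng = np.random.default_rng(13)
        eps = 1e-6
        for key, values in state.params.items():
            flat = values.ravel()
            for _ in range(2):
                i = int(rng.integers(flat.size))
                orig = flat[i]
                flat[i] = orig + eps
                up = M.bce_loss(M.forward(graph, fused, seq, state), y)
                flat[i] = orig - eps
                dn = M.bce_loss(M.forward(graph, fused, seq, state), y)
                flat[i] = orig
                numeric = (up - dn) / (2 * eps)
                g = grads.get(key)  # absent key ⇒ zero gradient
                analytic = 0.0 if g is None else g.ravel()[i]
                assert numeric == pytest.approx(analytic, abs=1e-6), key


class TestCheckpoint:
    def test_roundtrip_preserves_params_and_config(self, tmp_path):
        _, _, _, state = make_inputs(seed=20)
        path = tmp_path / "ckpt.npz"
        M.save_checkpoint(state, path)
        loaded = M.load_checkpoint(path)
        assert loaded.config == state.config
        for k, v in state.params.items():
            np.testing.assert_array_equal(loaded.params[k], v)
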