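"""Biased-walk transitions, walk corpora, skip-gram embeddings, fusion."""

import numpy as np
import pytest

from foldgo.embeddings import (
    Node2VecEmbedder,
    NodeEmbedding,
    WalkParams,
    canonicalize_embedding,
    fuse_features,
    generate_walks,
    load_sequence_embedding,
    read_fasta,
    stub_sequence_embedding,
    train_node_embeddings,
    transition_distribution,
    write_sequence_embeddings,
)
from foldgo.structgraph import ContactGraph, OneHotMatrix


class TestTransitionDistribution:
    """Hand-enumerated second-order walk weights on small graphs."""

    def test_path_graph_hand_values(self, path_graph):
        params = WalkParams(p=0.8, q=1.2)
        dist = transition_distribution(path_graph, previous=0, current=1, params=params)
        z = 1 / 0.8 + 1 / 1.2
        assert dist.probs[0] == pytest.approx((1 / 0.8) / z, abs=1e-12)
        assert dist.probs[2] == pytest.approx((1 / 1.2) / z, abs=1e-12)

    def test_triangle_graph_hand_values(self, triangle_graph):
        # previous=0, current=1: node 0 is the return step (1/p); node 2 is
        # adjacent to the previous node, so its weight is 1.
        params = WalkParams(p=0.8, q=1.2)
        dist = transition_distribution(triangle_graph, 0, 1, params)
        z = 1 / 0.8 + 1.0
        assert dist.probs[0] == pytest.approx((1 / 0.8) / z, abs=1e-12)
        assert dist.probs[2] == pytest.approx(1.0 / z, abs=1e-12)

    def test_star_graph_hand_values(self, star_graph):
        # previous=1, current=0 (the hub): leaf 1 is the return step; the
        # other leaves are not adjacent to 1 → weight 1/q each.
        params = WalkParams(p=0.5, q=2.0)
        dist = transition_distribution(star_graph, 1, 0, params)
        z = 1 / 0.5 + 3 * (1 / 2.0)
        assert dist.probs[1] == pytest.approx((1 / 0.5) / z, abs=1e-12)
        for leaf in (2, 3, 4):
            assert dist.probs[leaf] == pytest.approx((1 / 2.0) / z, abs=1e-12)

    def test_first_step_is_uniform(self, star_graph):
        dist = transition_distribution(star_graph, None, 0, WalkParams())
        assert all(p == pytest.approx(0.25) for p in dist.probs.values())

    def test_single_neighbor_gets_probability_one(self, path_graph):
        dist = transition_distribution(path_graph, 1, 0, WalkParams())
        assert dist.probs == {1: pytest.approx(1.0)}

    def test_unbiased_when_p_and_q_are_one(self, triangle_graph):
        dist = transition_distribution(
            triangle_graph, 0, 1, WalkParams(p=1.0, q=1.0)
        )
        assert all(p == pytest.approx(0.5) for p in dist.probs.values())

    def test_isolated_node_gives_empty_distribution(self):
        graph = ContactGraph(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        dist = transition_distribution(graph, None, 0, WalkParams())
        assert dist.probs == {}


class TestGenerateWalks:
    def test_two_node_graph_alternates(self):
        graph = ContactGraph(n_nodes=2, edges=np.array([[0, 1]]))
        walks = generate_walks(graph, WalkParams(walk_length=3, walks_per_node=2, seed=0))
        assert walks and all(w in ([0, 1, 0], [1, 0, 1]) for w in walks)

    def test_deterministic_under_seed(self, triangle_graph):
        params = WalkParams(seed=42)
        assert generate_walks(triangle_graph, params) == generate_walks(
            triangle_graph, params
        )

    def test_walk_count_and_length(self, star_graph):
        params = WalkParams(walk_length=10, walks_per_node=3, seed=1)
        walks = generate_walks(star_graph, params)
        assert len(walks) == 3 * star_graph.n_nodes
        assert all(len(w) <= 10 for w in walks)

    def test_isolated_node_walks_are_singletons(self):
        graph = ContactGraph(n_nodes=3, edges=np.array([[0, 1]]))
        walks = generate_walks(graph, WalkParams(walks_per_node=1, seed=0))
        assert [2] in walks

    def test_step_frequencies_match_exact_distribution(self, path_graph):
        """Monte-Carlo agreement with the exact transition law within 3 SE.

        Walks of length 3 from node 0 on the path are forced through node 1,
        so their last step samples the (previous=0, current=1) second-order
        distribution; 10,000 seeded walks must match it.
        """
        params = WalkParams(p=0.8, q=1.2, walk_length=3, walks_per_node=10_000, seed=9)
        walks = [w for w in generate_walks(path_graph, params) if w[0] == 0]
        assert len(walks) == 10_000
        exact = transition_distribution(path_graph, 0, 1, params).probs
        p_hat = np.mean([w[2] == 0 for w in walks])
        se = (exact[0] * (1 - exact[0]) / len(walks)) ** 0.5
        assert abs(p_hat - exact[0]) < 3 * se


class TestNodeEmbeddings:
    def test_output_width_default_30(self, triangle_graph):
        params = WalkParams(seed=0, epochs=1)
        corpus = generate_walks(triangle_graph, params)
        emb = train_node_embeddings(corpus, n_nodes=3, params=params)
        assert emb.values.shape == (3, 30)

    def test_isolated_node_gets_zero_vector(self):
        graph = ContactGraph(n_nodes=3, edges=np.array([[0, 1]]))
        params = WalkParams(seed=0, epochs=1)
        corpus = generate_walks(graph, params)
        emb = train_node_embeddings(corpus, n_nodes=3, params=params)
        assert np.all(emb.values[2] == 0.0)
        assert np.any(emb.values[0] != 0.0)

    def test_reproducible_under_seed(self, triangle_graph):
        params = WalkParams(seed=3)
        corpus = generate_walks(triangle_graph, params)
        e1 = train_node_embeddings(corpus, 3, params=params)
        e2 = train_node_embeddings(corpus, 3, params=params)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_disconnected_cliques_separate(self):
        """Intra-clique cosine similarity must exceed inter-clique."""
        k = 6
        edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
        edges += [(k + i, k + j) for i in range(k) for j in range(i + 1, k)]
        graph = ContactGraph(n_nodes=2 * k, edges=np.array(edges))
        emb = Node2VecEmbedder(seed=11).fit_transform(graph)
        unit = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        sim = unit @ unit.T
        intra = np.mean([sim[i, j] for i in range(k) for j in range(i + 1, k)])
        inter = np.mean([sim[i, k + j] for i in range(k) for j in range(k)])
        assert intra > inter

    def test_canonicalization_preserves_geometry(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((12, 5))
        rotated = canonicalize_embedding(values)
        np.testing.assert_allclose(
            values @ values.T, rotated @ rotated.T, atol=1e-9
        )
        # a pre-rotated copy maps to the same canonical form
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        np.testing.assert_allclose(
            np.abs(canonicalize_embedding(values @ q)),
            np.abs(rotated),
            atol=1e-6,
        )


class TestFusion:
    def test_zero_embedding_plus_basis_onehot(self):
        emb = NodeEmbedding(values=np.zeros((1, 30)))
        onehot = OneHotMatrix(values=np.eye(26)[[0]])
        fused = fuse_features(emb, onehot)
        assert fused.width == 56
        assert np.all(fused.values[0, :30] == 0.0)
        assert fused.values[0, 30] == 1.0

    def test_fusion_is_lossless(self):
        rng = np.random.default_rng(1)
        emb = NodeEmbedding(values=rng.standard_normal((4, 30)))
        onehot = OneHotMatrix(values=np.eye(26)[rng.integers(0, 26, 4)])
        fused = fuse_features(emb, onehot)
        np.testing.assert_array_equal(fused.embedding_block, emb.values)
        np.testing.assert_array_equal(fused.onehot_block, onehot.values)

    def test_row_mismatch_raises(self):
        with pytest.raises(ValueError, match="row mismatch"):
            fuse_features(
                NodeEmbedding(values=np.zeros((3, 30))),
                OneHotMatrix(values=np.eye(26)[:2]),
            )


class TestSequenceEmbeddings:
    def test_stub_width_and_determinism(self):
        v1 = stub_sequence_embedding("ACDEFGH", seed=5)
        v2 = stub_sequence_embedding("ACDEFGH", seed=5)
        assert v1.shape == (1024,)
        np.testing.assert_array_equal(v1, v2)
        assert np.any(v1 != stub_sequence_embedding("ACDEFGI", seed=5))

    def test_loader_returns_stored_row(self, tmp_path):
        table = {
            "P1": stub_sequence_embedding("AAA", 0),
            "P2": stub_sequence_embedding("WWW", 0),
        }
        path = tmp_path / "emb.tsv"
        write_sequence_embeddings(table, path)
        np.testing.assert_allclose(
            load_sequence_embedding(path, "P2"), table["P2"], atol=1e-5
        )

    def test_missing_protein_raises(self, tmp_path):
        path = tmp_path / "emb.tsv"
        write_sequence_embeddings({"P1": np.zeros(1024)}, path)
        with pytest.raises(KeyError):
            load_sequence_embedding(path, "P9")

    def test_fasta_reader(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        path.write_text(">P1\nACDE\n>P2\nWWWW\n")
        assert read_fasta(path) == {"P1": "ACDE", "P2": "WWWW"}
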