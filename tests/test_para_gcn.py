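"""Mention graphs, the shared-weight GCN layer, and pair classification."""

import numpy as np
import pytest

from matkg.para_gcn import (
    GCNLayerParams, GraphState, MentionGraph, ParaGCNConfig, ParaGCNModel,
    build_mention_graph, classify_material_pair, embed_graph, gcn_layer,
    mirror_permutation, normalized_adjacency, train_para_re,
)
from matkg._nn import softmax
from conftest import make_paragraph


def para_with_mentions(order):
    """Paragraph whose E mentions follow ``order``, e.g. "ABAB"."""
    sentences, tags = [], []
    for ch in order:
        name = "matA" if ch == "A" else "matB"
        sentences.append([name, "was", "used", "."])
        tags.append(["BE", "O", "O", "O"])
    return make_paragraph("p", sentences, tags)


class TestMentionGraph:
    def test_alternating_a_b_a(self):
        g = build_mention_graph(para_with_mentions("ABA"), "matA", "matB")
        assert len(g.nodes_a) == 2 and len(g.nodes_b) == 1
        # A1-B1 and B1-A2 (B node index = 2)
        assert set(map(frozenset, g.edges)) == {frozenset((0, 2)),
                                                frozenset((2, 1))}

    def test_single_alternation(self):
        g = build_mention_graph(para_with_mentions("AB"), "matA", "matB")
        assert g.edges == [(0, 1)]

    def test_no_interleaving_falls_back_to_boundary_edge(self):
        g = build_mention_graph(para_with_mentions("AABB"), "matA", "matB")
        # single edge between last A (index 1) and first B (index 2)
        assert g.edges == [(1, 2)]

    def test_missing_material_rejected(self):
        with pytest.raises(ValueError, match="no mention"):
            build_mention_graph(para_with_mentions("AA"), "matA", "matB")

    def test_edge_mask_covers_gap_between_mentions(self):
        para = para_with_mentions("AB")
        g = build_mention_graph(para, "matA", "matB")
        (mask,) = g.edge_masks
        # tokens strictly between the two mentions: indices 1..3
        assert mask.tolist() == [0, 1, 1, 1, 0, 0, 0, 0]

    def test_adjacent_mentions_union_mask(self):
        para = make_paragraph("p", [["matA", "matB", "."]],
                              [["BE", "BE", "O"]])
        g = build_mention_graph(para, "matA", "matB")
        (mask,) = g.edge_masks
        assert mask.tolist() == [1, 1, 0]


class TestEmbedAndAdjacency:
    def test_node_vectors_match_pool_mask(self, encoder):
        para = para_with_mentions("ABA")
        g = build_mention_graph(para, "matA", "matB")
        enc = encoder.encode(para.tokens)
        state = embed_graph(g, enc)
        from matkg.encoders import pool_mask
        for i, mask in enumerate(g.node_masks):
            np.testing.assert_allclose(state.H_node[i], pool_mask(enc, mask))
        assert state.H_node.shape[1] == encoder.d
        assert state.H_edge.shape[1] == encoder.d

    def test_adjacency_symmetric_and_spectrally_bounded(self):
        g = build_mention_graph(para_with_mentions("ABABAB"), "matA", "matB")
        S = normalized_adjacency(g)
        np.testing.assert_allclose(S, S.T)
        eigs = np.linalg.eigvalsh(S)
        assert eigs.max() <= 1 + 1e-10 and eigs.min() >= -1 - 1e-10


class TestGCNLayer:
    def test_single_node_identity(self):
        state = GraphState(H_node=np.array([[1.0, -2.0, 3.0]]),
                           H_edge=np.zeros((0, 3)))
        params = GCNLayerParams(W_node=np.eye(3), W_edge=np.eye(3),
                                b_edge=np.zeros(3))
        out = gcn_layer(state, np.array([[1.0]]), params,
                        activation=lambda x: x)
        np.testing.assert_allclose(out.H_node, state.H_node)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            d = 5
            A = np.zeros((n, n))
            for _ in range(int(rng.integers(1, n * 2))):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    A[i, j] = A[j, i] = 1.0
            H = rng.normal(size=(n, d))
            W = rng.normal(size=(d, d))
            # dense oracle: explicit D^-1/2 (A+I) D^-1/2 H W
            A_hat = A + np.eye(n)
            D_inv_sqrt = np.diag(1.0 / np.sqrt(A_hat.sum(axis=1)))
            oracle = np.maximum(D_inv_sqrt @ A_hat @ D_inv_sqrt @ H @ W, 0.0)

            graph = MentionGraph(
                paragraph_id="p", material_a="a", material_b="b",
                nodes_a=[None] * n, nodes_b=[],
                edges=[(i, j) for i in range(n) for j in range(i + 1, n)
                       if A[i, j]],
                node_masks=[], edge_masks=[], n_tokens=0)
            S = normalized_adjacency(graph)
            state = GraphState(H_node=H, H_edge=np.zeros((0, d)))
            params = GCNLayerParams(W_node=W, W_edge=np.eye(d),
                                    b_edge=np.zeros(d))
            out = gcn_layer(state, S, params)
            np.testing.assert_allclose(out.H_node, oracle, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        n, d = 5, 4
        A = np.zeros((n, n))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = A[3, 4] = A[4, 3] = 1.0
        H = rng.normal(size=(n, d))
        W = rng.normal(size=(d, d))

        def run(Amat, Hmat):
            Ah = Amat + np.eye(n)
            dis = 1.0 / np.sqrt(Ah.sum(axis=1))
            S = Ah * dis[:, None] * dis[None, :]
            params = GCNLayerParams(W_node=W, W_edge=np.eye(d),
                                    b_edge=np.zeros(d))
            return gcn_layer(GraphState(H_node=Hmat, H_edge=np.zeros((0, d))),
                             S, params).H_node

        perm = np.array([2, 0, 4, 1, 3])
        P = np.eye(n)[perm]
        out_perm = run(P @ A @ P.T, P @ H)
        np.testing.assert_allclose(out_perm, P @ run(A, H), atol=1e-10)


class TestModel:
    @staticmethod
    def _data(n=60, seed=11):
        from matkg.synth import GeneratorConfig, generate
        bundles = generate(GeneratorConfig(n_paragraphs=n, seed=seed))
        paragraphs = [b.paragraph for b in bundles]
        records = [r for b in bundles for r in b.pair_labels]
        return paragraphs, records

    def test_shared_node_weight_across_materials(self):
        model = ParaGCNModel(d=8, config=ParaGCNConfig(n_layers=2))
        for l in (1, 2):
            p = model.layer_params(l)
            # one matrix serves all nodes; A and B nodes see the same object
            assert p.W_node is model.params[f"Wn{l}"]

    def test_feature_length_matches_layer_count(self, encoder):
        paragraphs, records = self._data(n=5)
        para = next(p for p in paragraphs
                    if p.paragraph_id == records[0].paragraph_id)
        graph = build_mention_graph(para, records[0].material_a,
                                    records[0].material_b)
        enc = encoder.encode(para.tokens)
        for L in (1, 2, 3):
            model = ParaGCNModel(d=encoder.d, config=ParaGCNConfig(n_layers=L))
            h = model.features(graph, enc)
            assert h.shape == (3 * encoder.d * (L + 1),)

    def test_untrained_model_rejected(self, encoder):
        paragraphs, records = self._data(n=5)
        para = next(p for p in paragraphs
                    if p.paragraph_id == records[0].paragraph_id)
        graph = build_mention_graph(para, records[0].material_a,
                                    records[0].material_b)
        model = ParaGCNModel(d=encoder.d, config=ParaGCNConfig())
        with pytest.raises(ValueError, match="trained"):
            classify_material_pair(graph, encoder.encode(para.tokens), model)

    def test_probabilities_sum_to_one(self, encoder):
        paragraphs, records = self._data(n=20)
        model, _ = train_para_re(records, paragraphs, encoder,
                                 ParaGCNConfig(epochs=3, seed=0))
        para = next(p for p in paragraphs
                    if p.paragraph_id == records[0].paragraph_id)
        graph = build_mention_graph(para, records[0].material_a,
                                    records[0].material_b)
        out = classify_material_pair(graph, encoder.encode(para.tokens), model)
        assert abs(out.probabilities.sum() - 1.0) < 1e-6

    def test_mirrored_features_swap_inclusion_probabilities(self, encoder):
        """Swapping the A/B feature blocks and the matching classifier
        blocks swaps the two inclusion-label probabilities exactly."""
        paragraphs, records = self._data(n=10)
        model, _ = train_para_re(records, paragraphs, encoder,
                                 ParaGCNConfig(epochs=2, seed=1))
        para = next(p for p in paragraphs
                    if p.paragraph_id == records[0].paragraph_id)
        graph = build_mention_graph(para, records[0].material_a,
                                    records[0].material_b)
        enc = encoder.encode(para.tokens)
        h = model.features(graph, enc)
        perm = mirror_permutation(encoder.d, model.n_layers)
        Wc, bc = model.params["Wc"], model.params["bc"]
        # label order: A_INCLUDES_B, B_INCLUDES_A, UNRELATED, IDENTICAL
        label_perm = [1, 0, 2, 3]
        p_orig = softmax(h @ Wc + bc)
        p_mirror = softmax(h[perm] @ Wc[perm][:, label_perm] + bc[label_perm])
        np.testing.assert_allclose(p_mirror[0], p_orig[1], atol=1e-12)
        np.testing.assert_allclose(p_mirror[1], p_orig[0], atol=1e-12)

    def test_seeded_training_deterministic(self, encoder):
        paragraphs, records = self._data(n=15)
        cfg = ParaGCNConfig(epochs=3, seed=5)
        m1, r1 = train_para_re(records, paragraphs, encoder, cfg)
        m2, r2 = train_para_re(records, paragraphs, encoder, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        assert r1.accuracy == r2.accuracy

    def test_missing_label_class_rejected(self, encoder):
        paragraphs, records = self._data(n=20)
        only_some = [r for r in records if r.label != "IDENTICAL"]
        with pytest.raises(ValueError, match="missing label"):
            train_para_re(only_some, paragraphs, encoder,
                          ParaGCNConfig(epochs=1))

    def test_stage_averages_invariant_to_node_permutation(self, encoder):
        paragraphs, records = self._data(n=5)
        rec = records[0]
        para = next(p for p in paragraphs if p.paragraph_id == rec.paragraph_id)
        graph = build_mention_graph(para, rec.material_a, rec.material_b)
        enc = encoder.encode(para.tokens)
        model = ParaGCNModel(d=encoder.d, config=ParaGCNConfig(seed=2))
        h = model.features(graph, enc)
        # permute A nodes (and masks) in place: means must not change
        if len(graph.nodes_a) > 1:
            k = len(graph.nodes_a)
            graph.nodes_a = graph.nodes_a[::-1]
            graph.node_masks[:k] = graph.node_masks[:k][::-1]
            remap = {i: k - 1 - i for i in range(k)}
            graph.edges = [(remap.get(u, u), remap.get(v, v))
                           for u, v in graph.edges]
            h2 = model.features(graph, enc)
            np.testing.assert_allclose(h, h2, atol=1e-10)
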