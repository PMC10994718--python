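import numpy as np
import pytest

from negsel import (
    EmbeddingConfig,
    default_config,
    embed_graph,
    generate_walks,
    hope_embed,
    train_line,
    train_word2vec,
    walklets_corpora,
)
from negsel.embeddings import PAD, WalkCorpus

from conftest import graph_from_index_pairs

SMALL = EmbeddingConfig(
    dimension=8, epochs=8, walk_length=12, iterations=10, window_size=3, batch_size=256
)


class TestWalks:
    def test_single_edge_forces_alternation(self):
        g = graph_from_index_pairs([(0, 1)])
        cfg = EmbeddingConfig(walk_length=4, iterations=2, window_size=2, dimension=4)
        walks = generate_walks(g, cfg, seed=0).walks
        for row in walks:
            assert abs(np.diff(row)).tolist() == [1, 1, 1]

    def test_isolated_node_walk_is_single_token(self):
        g = graph_from_index_pairs([(0, 1)], n=3)
        corpus = generate_walks(g, SMALL, seed=0)
        iso = [w for w in corpus.as_lists() if w[0] == 2]
        assert iso and all(w == [2] for w in iso)

    def test_consecutive_tokens_are_edges(self, two_cliques):
        corpus = generate_walks(two_cliques, SMALL, seed=1)
        for walk in corpus.as_lists():
            for u, v in zip(walk, walk[1:]):
                assert two_cliques.has_edges([(u, v)]).all()

    def test_triangle_transitions_uniform(self, triangle):
        cfg = EmbeddingConfig(
            dimension=4, walk_length=100, iterations=40, window_size=3
        )
        corpus = generate_walks(triangle, cfg, seed=2)
        # from node 0 the walker moves to 1 or 2 with probability 1/2 each
        walks = corpus.walks
        from_zero = walks[:, 1:][walks[:, :-1] == 0]
        n = len(from_zero)
        frac = (from_zero == 1).mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_seed_determinism(self, two_cliques):
        a = generate_walks(two_cliques, SMALL, seed=3).walks
        b = generate_walks(two_cliques, SMALL, seed=3).walks
        assert np.array_equal(a, b)


class TestWalklets:
    def test_scale_two_splits_even_and_odd(self):
        walk = np.array([[10, 11, 12, 13, 14]])
        corpus = WalkCorpus(walk, n_nodes=15, walk_length=5, iterations=1, max_neighbors=100)
        subs = walklets_corpora(corpus, 2)
        assert subs[0].walks.tolist() == [[10, 11, 12, 13, 14]]
        scale2 = [row[row != PAD].tolist() for row in subs[1].walks]
        assert sorted(scale2) == [[10, 12, 14], [11, 13]]

    def test_scale_one_is_identity(self, two_cliques):
        corpus = generate_walks(two_cliques, SMALL, seed=1)
        assert np.array_equal(walklets_corpora(corpus, 1)[0].walks, corpus.walks)

    def test_token_multiset_matches_skip_enumeration(self):
        rng = np.random.default_rng(4)
        walks = rng.integers(0, 9, size=(10, 11))
        corpus = WalkCorpus(walks, n_nodes=9, walk_length=11, iterations=1, max_neighbors=100)
        sub = walklets_corpora(corpus, 3)[2]
        expected = []
        for row in walks:
            for off in range(3):
                expected.extend(row[off::3].tolist())
        got = sub.walks[sub.walks != PAD]
        assert sorted(got.tolist()) == sorted(expected)

    def test_short_walks_contribute_nothing(self):
        walks = np.array([[1, 2, PAD, PAD]])  # 2 tokens: nothing at scale 3
        corpus = WalkCorpus(walks, n_nodes=3, walk_length=4, iterations=1, max_neighbors=100)
        assert len(walklets_corpora(corpus, 3)[2].walks) == 0


class TestWord2Vec:
    @pytest.mark.parametrize("objective", ["skipgram", "cbow"])
    def test_cliques_separate(self, two_cliques, objective):
        corpus = generate_walks(two_cliques, SMALL, seed=1)
        emb = train_word2vec(corpus, SMALL, objective, seed=2)
        W = emb.primary / np.linalg.norm(emb.primary, axis=1, keepdims=True)
        sim = W @ W.T
        within = np.mean([sim[i, j] for i in range(4) for j in range(4) if i != j])
        between = np.mean([sim[i, j] for i in range(4) for j in range(4, 8)])
        assert within > between

    def test_single_node_corpus_is_noop(self):
        g = graph_from_index_pairs([], n=1)
        corpus = generate_walks(g, SMALL, seed=0)
        emb = train_word2vec(corpus, SMALL, "skipgram", seed=1)
        assert emb.primary.shape == (1, SMALL.dimension)
        assert emb.loss_history == ()

    def test_fixed_seed_reproducible(self, two_cliques):
        corpus = generate_walks(two_cliques, SMALL, seed=1)
        a = train_word2vec(corpus, SMALL, "cbow", seed=5)
        b = train_word2vec(corpus, SMALL, "cbow", seed=5)
        assert np.array_equal(a.primary, b.primary)

    def test_loss_decreases(self, two_cliques):
        corpus = generate_walks(two_cliques, SMALL, seed=1)
        emb = train_word2vec(corpus, SMALL, "skipgram", seed=2)
        assert emb.loss_history[-1] < emb.loss_history[0]


class TestLine:
    def test_k4_minus_edge_separable(self):
        g = graph_from_index_pairs([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        for order in (1, 2):
            emb = train_line(
                g, order, EmbeddingConfig(dimension=8, epochs=100, learning_rate=0.05, batch_size=16),
                seed=3,
            )
            sec = emb.secondary if emb.secondary is not None else emb.primary
            present = min(float(emb.primary[u] @ sec[v]) for u, v in g.edges)
            absent = float(emb.primary[2] @ sec[3])
            assert present > absent

    def test_single_edge_graph_finite(self):
        g = graph_from_index_pairs([(0, 1)])
        emb = train_line(g, 1, EmbeddingConfig(dimension=4, epochs=5), seed=0)
        assert np.isfinite(emb.primary).all()

    def test_second_order_returns_context_matrix(self, triangle):
        emb = train_line(triangle, 2, EmbeddingConfig(dimension=4, epochs=5), seed=0)
        assert emb.secondary is not None and emb.secondary.shape == emb.primary.shape

    def test_seed_determinism(self, triangle):
        cfg = EmbeddingConfig(dimension=4, epochs=5)
        assert np.array_equal(
            train_line(triangle, 1, cfg, seed=7).primary,
            train_line(triangle, 1, cfg, seed=7).primary,
        )


class TestHope:
    def test_triangle_full_rank_reconstruction(self, triangle):
        emb = hope_embed(triangle, 3)
        A = np.zeros((3, 3))
        A[triangle.edges[:, 0], triangle.edges[:, 1]] = 1
        A += A.T
        S = A @ A  # off-diagonal: one common neighbor; diagonal: degree 2
        assert np.allclose(emb.primary @ emb.secondary.T, S, atol=1e-10)

    def test_edgeless_graph_all_zero(self):
        g = graph_from_index_pairs([], n=4)
        with pytest.warns(UserWarning, match="zero-padding"):
            emb = hope_embed(g, 2)
        assert not emb.primary.any() and not emb.secondary.any()

    def test_rank_k_error_matches_eckart_young(self):
        rng = np.random.default_rng(11)
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12) if rng.random() < 0.35]
        g = graph_from_index_pairs(pairs, n=12)
        A = np.zeros((12, 12))
        A[g.edges[:, 0], g.edges[:, 1]] = 1
        A += A.T
        S = A @ A
        emb = hope_embed(g, 4)
        err = np.linalg.norm(S - emb.primary @ emb.secondary.T, "fro") ** 2
        sv = np.linalg.svd(S, compute_uv=False)
        assert err == pytest.approx((sv[4:] ** 2).sum(), rel=1e-8)

    def test_dimension_above_node_count_errors(self, triangle):
        with pytest.raises(ValueError):
            hope_embed(triangle, 4)


class TestDispatch:
    @pytest.mark.parametrize("method", ["deepwalk-skipgram", "walklets-cbow", "line1", "hope"])
    def test_all_methods_produce_requested_shape(self, two_cliques, method):
        cfg = default_config(
            method, dimension=8, epochs=3, walk_length=10, iterations=4
        )
        emb = embed_graph(two_cliques, method, cfg, seed=1)
        assert emb.primary.shape == (8, 8)
        assert np.isfinite(emb.primary).all()

    def test_walklets_concatenates_scales(self, two_cliques):
        cfg = default_config("walklets-skipgram", dimension=8, epochs=2, walk_length=10, iterations=4)
        emb = embed_graph(two_cliques, "walklets-skipgram", cfg, seed=1)
        assert cfg.window_size == 4  # four scales, dimension split evenly
        assert emb.dimension == 8

    def test_unknown_method_errors(self, triangle):
        with pytest.raises(ValueError, match="unknown method"):
            embed_graph(triangle, "node2vec")

    def test_table_defaults(self):
        assert default_config("deepwalk-cbow").epochs == 30
        assert default_config("deepwalk-cbow").window_size == 5
        assert default_config("walklets-cbow").window_size == 4
        assert default_config("line1").epochs == 100
        assert default_config("line2").learning_rate == 0.050
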