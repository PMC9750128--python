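import numpy as np
import pytest

from rocfec import (
    OneHotFeatures,
    WeightedNetwork,
    shortest_path_propagation,
    tfidf_cosine,
    top_fraction_binarize,
)


def ids(n, prefix="g"):
    return [f"{prefix}{i}" for i in range(n)]


def net_from_edges(n, edges):
    w = np.zeros((n, n))
    for a, b in edges:
        w[a, b] = w[b, a] = 1.0
    return WeightedNetwork(ids(n), w)


class TestShortestPathPropagation:
    def test_path_graph(self):
        out = shortest_path_propagation(net_from_edges(3, [(0, 1), (1, 2)]))
        assert out.weights[0, 1] == 1.0
        assert out.weights[0, 2] == 0.5
        assert out.weights[0, 0] == 1.0

    def test_disconnected_components_get_zero(self):
        out = shortest_path_propagation(net_from_edges(4, [(0, 1), (2, 3)]))
        assert out.weights[0, 2] == 0.0 and out.weights[1, 3] == 0.0
        assert out.weights[0, 1] == 1.0 and out.weights[2, 3] == 1.0

    def test_matches_bfs_oracle(self, rng):
        n = 50
        w = (rng.random((n, n)) < 0.06).astype(float)
        w = np.maximum(w, w.T)
        np.fill_diagonal(w, 0)
        out = shortest_path_propagation(WeightedNetwork(ids(n), w))

        # per-pair BFS oracle
        adj = [np.flatnonzero(w[i]) for i in range(n)]
        for src in range(0, n, 7):
            dist = np.full(n, np.inf)
            dist[src] = 0
            frontier = [src]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if dist[v] == np.inf:
                            dist[v] = d
                            nxt.append(v)
                frontier = nxt
            with np.errstate(divide="ignore"):
                expected = np.where(np.isfinite(dist), 1.0 / np.maximum(dist, 1), 0.0)
            expected[src] = 1.0
            np.testing.assert_allclose(out.weights[src], expected)

    def test_monotone_in_edges_and_bounded(self, rng):
        n = 25
        w = (rng.random((n, n)) < 0.08).astype(float)
        w = np.maximum(w, w.T)
        np.fill_diagonal(w, 0)
        base = shortest_path_propagation(WeightedNetwork(ids(n), w)).weights
        assert base.min() >= 0 and base.max() <= 1
        w2 = w.copy()
        off = np.argwhere(w2 == 0)
        i, j = off[len(off) // 2]
        if i != j:
            w2[i, j] = w2[j, i] = 1.0
        more = shortest_path_propagation(WeightedNetwork(ids(n), w2)).weights
        assert np.all(more >= base - 1e-12)


class TestTfidfCosine:
    def test_identical_feature_sets_have_similarity_one(self):
        ind = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        out = tfidf_cosine(OneHotFeatures(ids(3, "p"), ids(3, "d"), ind))
        assert out.weights[0, 1] == pytest.approx(1.0)

    def test_disjoint_feature_sets_have_similarity_zero(self):
        ind = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        out = tfidf_cosine(OneHotFeatures(ids(2, "p"), ids(4, "d"), ind))
        assert out.weights[0, 1] == pytest.approx(0.0)

    def test_hand_computed_smooth_idf(self):
        ind = np.array([
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [0, 0, 1, 1],
        ], dtype=float)
        n, df = 5, ind.sum(axis=0)
        idf = np.log((1 + n) / (1 + df)) + 1
        tfidf = ind * idf
        norm = tfidf / np.linalg.norm(tfidf, axis=1, keepdims=True)
        expected = norm @ norm.T
        out = tfidf_cosine(OneHotFeatures(ids(5, "p"), ids(4, "d"), ind))
        np.testing.assert_allclose(out.weights, np.clip(expected, 0, 1), atol=1e-12)

    def test_classic_idf_downweights_ubiquitous_feature_to_zero(self):
        # a feature present in every item carries no information under ln(n/df)
        ind = np.array([[1, 1], [1, 0], [1, 0]], dtype=float)
        out = tfidf_cosine(OneHotFeatures(ids(3, "p"), ids(2, "d"), ind), idf="classic")
        assert out.weights[1, 2] == pytest.approx(0.0)

    def test_empty_row_warns_and_zeroes(self):
        ind = np.array([[1, 1], [0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="no features"):
            out = tfidf_cosine(OneHotFeatures(ids(2, "p"), ids(2, "d"), ind))
        assert out.weights[1, 1] == 0.0 and out.weights[0, 1] == 0.0

    def test_output_is_valid_similarity(self, rng):
        ind = (rng.random((12, 8)) < 0.4).astype(float)
        ind[ind.sum(axis=1) == 0, 0] = 1
        out = tfidf_cosine(OneHotFeatures(ids(12, "p"), ids(8, "d"), ind))
        assert out.weights.min() >= 0 and out.weights.max() <= 1
        np.testing.assert_allclose(np.diag(out.weights), 1.0)


class TestTopFractionBinarize:
    def test_fraction_one_keeps_all_nonzero(self):
        s = np.array([[0.5, 0.0], [0.2, 0.9]])
        out = top_fraction_binarize(ids(2, "p"), ids(2, "d"), s, 1.0, min_items=1)
        assert out.indicator.sum() == 3

    def test_top_decile_of_ten_distinct_scores_is_the_max(self):
        s = np.arange(1, 11, dtype=float).reshape(10, 1)
        out = top_fraction_binarize(ids(10, "p"), ids(1, "d"), s, 0.1, min_items=1)
        assert out.indicator.sum() == 1 and out.item_ids == ["p9"]

    def test_retained_count_matches_sort_oracle(self, rng):
        s = rng.random((100, 20))
        frac = 0.1
        nz = s[s > 0]
        thresh = np.sort(nz)[-int(np.ceil(frac * nz.size))]
        expected = int((s >= thresh).sum())
        out = top_fraction_binarize(ids(100, "p"), ids(20, "d"), s, frac, min_items=1)
        assert int(out.indicator.sum()) == expected

    def test_sparse_features_dropped(self):
        s = np.zeros((30, 2))
        s[:25, 0] = np.linspace(0.5, 1, 25)
        s[:3, 1] = 0.99
        out = top_fraction_binarize(ids(30, "p"), ids(2, "d"), s, 1.0, min_items=20)
        assert out.feature_ids == ["d0"]

    @pytest.mark.parametrize("frac", [0.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            top_fraction_binarize(ids(2, "p"), ids(1, "d"), np.ones((2, 1)), frac)
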