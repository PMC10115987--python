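import numpy as np
import pytest

import progclust as pc
from progclust.abundant import SimilarityMatrix, _spectral_partition

from _oracles import gain_oracle, intra_similarity_oracle
from conftest import make_matrix


def _canon(labels):
    seen = {}
    return [seen.setdefault(l, len(seen)) for l in labels]


class TestCosineSimilarity:
    def test_identical_cells_similarity_one(self):
        m = make_matrix(np.array([[2, 2], [3, 3], [0, 0]]))
        fs = pc.FeatureSpace(["g0", "g1", "g2"], origin="fano_top_k")
        S = pc.cosine_similarity_matrix(m, fs)
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports_orthogonal(self):
        m = make_matrix(np.array([[5, 0], [0, 7]]))
        fs = pc.FeatureSpace(["g0", "g1"], origin="fano_top_k")
        S = pc.cosine_similarity_matrix(m, fs)
        assert S.values[0, 1] == pytest.approx(0.0)

    def test_scale_invariance_per_cell(self, rng):
        vals = rng.integers(1, 10, size=(6, 5))
        m = make_matrix(vals)
        fs = pc.FeatureSpace(m.gene_ids, origin="fano_top_k")
        S1 = pc.cosine_similarity_matrix(m, fs)
        vals2 = vals.copy()
        vals2[:, 0] *= 10
        S2 = pc.cosine_similarity_matrix(make_matrix(vals2), fs)
        np.testing.assert_allclose(S1.values, S2.values, atol=1e-12)

    def test_zero_cell_self_similarity_one(self):
        m = make_matrix(np.array([[0, 3], [0, 4]]))
        fs = pc.FeatureSpace(["g0", "g1"], origin="fano_top_k")
        S = pc.cosine_similarity_matrix(m, fs)
        assert S.values[0, 0] == 1.0
        assert S.values[0, 1] == pytest.approx(0.0)


class TestIntraClusterSimilarity:
    def test_worked_four_cell_value(self, toy_similarity):
        s = pc.intra_cluster_similarity(toy_similarity, np.zeros(4, int))
        np.testing.assert_allclose(s, (2 * 0.9 + 4 * 0.1) / 6)

    def test_pair_cluster_gets_pair_similarity(self):
        S = np.array([[1, 0.8], [0.8, 1]])
        sm = SimilarityMatrix(S, ["a", "b"])
        s = pc.intra_cluster_similarity(sm, np.zeros(2, int))
        np.testing.assert_allclose(s, 0.8)

    def test_singleton_convention(self, toy_similarity):
        s = pc.intra_cluster_similarity(toy_similarity, np.array([0, 0, 0, 1]))
        assert s[3] == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 31))
            X = rng.random((n, 4))
            S = X @ X.T
            S /= np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
            sm = SimilarityMatrix(S, [str(i) for i in range(n)])
            labels = rng.integers(0, int(rng.integers(1, 6)), size=n)
            np.testing.assert_allclose(
                pc.intra_cluster_similarity(sm, labels),
                intra_similarity_oracle(S, labels),
                atol=1e-10,
            )


class TestSimilarityGain:
    def test_worked_four_cell_gain(self, toy_similarity):
        s1 = pc.intra_cluster_similarity(toy_similarity, np.zeros(4, int))
        labels2 = np.array([0, 0, 1, 1])
        s2 = pc.intra_cluster_similarity(toy_similarity, labels2)
        assert pc.similarity_gain(s1, s2, labels2) == pytest.approx(
            1.4545, abs=1e-4
        )

    def test_identity_split_gains_nothing(self, toy_similarity):
        labels = np.array([0, 0, 1, 1])
        s = pc.intra_cluster_similarity(toy_similarity, labels)
        assert pc.similarity_gain(s, s, labels) == 0.0

    def test_negative_r_term_arithmetic(self):
        # cluster 0 (10 cells): r = +0.5; cluster 1 (5 cells): r = -0.2
        labels = np.array([0] * 10 + [1] * 5)
        s_k = np.concatenate([np.full(10, 0.4), np.full(5, 0.5)])
        s_k1 = np.concatenate([np.full(10, 0.6), np.full(5, 0.4)])
        assert pc.similarity_gain(s_k, s_k1, labels) == pytest.approx(0.6)

    def test_all_singletons_gain_zero(self):
        s = np.array([0.5, 0.5, 0.5])
        assert pc.similarity_gain(s, np.ones(3), np.arange(3)) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            s_k = rng.random(n) + 0.05
            s_k1 = rng.random(n) + 0.05
            labels = rng.integers(0, int(rng.integers(2, 6)), size=n)
            assert pc.similarity_gain(s_k, s_k1, labels) == pytest.approx(
                gain_oracle(s_k, s_k1, labels), abs=1e-10
            )


class TestSelectKSpectral:
    def test_toy_pairs_recovered(self, toy_similarity):
        labels, trace = pc.select_k_spectral(toy_similarity, ic=0.12, seed=0)
        assert trace.chosen_k == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert trace.records[0]["gain"] == pytest.approx(1.4545, abs=1e-4)

    def test_uniform_similarity_single_cluster(self):
        S = np.ones((8, 8))
        sm = SimilarityMatrix(S, [str(i) for i in range(8)])
        labels, trace = pc.select_k_spectral(sm, seed=0)
        assert trace.chosen_k == 1
        assert len(set(labels)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_blocks_recovered(self, seed):
        S = np.full((30, 30), 0.05)
        for b in range(3):
            S[b * 10:(b + 1) * 10, b * 10:(b + 1) * 10] = 0.9
        np.fill_diagonal(S, 1.0)
        sm = SimilarityMatrix(S, [str(i) for i in range(30)])
        labels, trace = pc.select_k_spectral(sm, seed=seed)
        assert trace.chosen_k == 3
        expected = np.repeat([0, 1, 2], 10)
        assert _canon(labels) == _canon(expected)

    def test_accepted_partitions_met_threshold(self, rng):
        # every accepted expansion recorded a gain >= ic
        X = rng.random((25, 6))
        S = X @ X.T
        S /= np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
        sm = SimilarityMatrix(S, [str(i) for i in range(25)])
        labels, trace = pc.select_k_spectral(sm, ic=0.12, seed=3)
        accepted = [r for r in trace.records if r["k_next"] <= trace.chosen_k]
        assert all(r["gain"] >= 0.12 for r in accepted)


class TestGapStatistic:
    def test_single_blob_one_cluster(self, rng):
        X = rng.normal(0, 1, size=(100, 2))
        assert pc.gap_statistic_k(X, seed=0) == 1

    def test_three_separated_blobs(self):
        hits = 0
        for seed in range(3):
            r = np.random.default_rng(seed)
            centers = np.array([[0, 0], [12, 12], [24, 0]], float)
            X = np.vstack([c + r.normal(0, 1, (100, 2)) for c in centers])
            if pc.gap_statistic_k(X, seed=seed) == 3:
                hits += 1
        assert hits >= 2

    def test_duplicated_data_same_k(self, rng):
        centers = np.array([[0, 0], [15, 15]], float)
        X = np.vstack([c + rng.normal(0, 1, (60, 2)) for c in centers])
        k1 = pc.gap_statistic_k(X, seed=0)
        k2 = pc.gap_statistic_k(np.vstack([X, X]), seed=0)
        assert k1 == k2 == 2


class TestClusterNode:
    def _two_pop_matrix(self, n_per, seed):
        r = np.random.default_rng(seed)
        n_genes = 120
        mu = np.full((n_genes, 2 * n_per), 0.5)
        mu[:50, :n_per] = 20.0
        mu[50:100, n_per:] = 20.0
        vals = r.poisson(mu)
        return make_matrix(vals)

    def test_routing_by_size_threshold(self, rng):
        m40 = self._two_pop_matrix(20, 0)
        fs = pc.select_top_fano(m40, k=100)
        _, trace = pc.cluster_node(m40, fs, size_threshold=50, seed=0)
        assert trace.method == "spectral_gain"
        m60 = self._two_pop_matrix(30, 0)
        fs = pc.select_top_fano(m60, k=100)
        _, trace = pc.cluster_node(m60, fs, size_threshold=50, seed=0)
        assert trace.method == "gap_statistic"

    @pytest.mark.parametrize("seed", [0, 1])
    def test_two_populations_split_perfectly(self, seed):
        m = self._two_pop_matrix(200, seed)
        fs = pc.select_top_fano(m, k=100)
        labels, trace = pc.cluster_node(m, fs, ic=0.12, seed=seed)
        assert trace.chosen_k == 2
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1

    def test_two_identical_cells_single_cluster(self):
        m = make_matrix(np.array([[3, 3], [1, 1]]))
        fs = pc.FeatureSpace(["g0", "g1"], origin="fano_top_k")
        labels, trace = pc.cluster_node(m, fs, seed=0)
        assert trace.chosen_k == 1
        assert list(labels) == [0, 0]

    def test_cell_order_permutation_invariance(self, rng):
        m = self._two_pop_matrix(15, 3)
        fs = pc.select_top_fano(m, k=100)
        labels, _ = pc.cluster_node(m, fs, seed=5)
        perm = rng.permutation(m.n_cells)
        m2 = m.subset_cells(perm)
        fs2 = pc.select_top_fano(m2, k=100)
        labels2, _ = pc.cluster_node(m2, fs2, seed=5)
        assert _canon(np.asarray(labels)[perm]) == _canon(labels2)
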