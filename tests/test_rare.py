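import warnings

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation
from sklearn.metrics.pairwise import cosine_similarity

import progclust as pc
from progclust.abundant import SimilarityMatrix

from conftest import make_matrix


def _canon(labels):
    seen = {}
    return [seen.setdefault(l, len(seen)) for l in labels]


class TestNoiseFilter:
    def test_strictly_below_threshold_is_abundant(self):
        # cell totals on the selected genes: 29, 30, 31
        vals = np.array([[14, 15, 16], [15, 15, 15], [99, 99, 99]])
        m = make_matrix(vals)
        fs = pc.FeatureSpace(["g0", "g1"], origin="local_high_gini")
        retained, abundant = pc.noise_filter(m, fs, 30)
        assert list(abundant) == [True, False, False]
        assert list(retained) == [False, True, True]

    def test_zero_threshold_keeps_everything(self, small_counts):
        fs = pc.FeatureSpace(small_counts.gene_ids, origin="local_high_gini")
        retained, _ = pc.noise_filter(small_counts, fs, 0)
        assert retained.all()

    def test_silent_cell_is_abundant(self):
        vals = np.array([[0, 5], [0, 5]])
        m = make_matrix(vals)
        fs = pc.FeatureSpace(["g0", "g1"], origin="local_high_gini")
        retained, abundant = pc.noise_filter(m, fs, 1)
        assert abundant[0] and retained[1]


class TestAffinityPropagation:
    def test_two_far_groups_recovered(self):
        S = np.full((20, 20), 0.05)
        S[:10, :10] = 0.95
        S[10:, 10:] = 0.95
        np.fill_diagonal(S, 1.0)
        sm = SimilarityMatrix(S, [str(i) for i in range(20)])
        labels = pc.affinity_propagation(sm)
        assert _canon(labels) == _canon(np.repeat([0, 1], 10))

    def test_flat_similarity_low_preference_one_cluster(self):
        n = 12
        S = np.full((n, n), 0.6)
        np.fill_diagonal(S, 1.0)
        sm = SimilarityMatrix(S, [str(i) for i in range(n)])
        with warnings.catch_warnings():
            # perfectly symmetric messages never elect an exemplar; the
            # degenerate fall-back is the single cluster we expect
            warnings.simplefilter("ignore")
            labels = pc.affinity_propagation(sm, preference=0.01)
        assert len(set(labels)) == 1

    def test_permutation_equivariance(self, rng):
        X = rng.random((18, 6))
        S = cosine_similarity(X)
        sm = SimilarityMatrix(S, [str(i) for i in range(18)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = np.asarray(pc.affinity_propagation(sm))
            perm = rng.permutation(18)
            sm_p = SimilarityMatrix(
                S[np.ix_(perm, perm)], [str(i) for i in perm]
            )
            labels_p = pc.affinity_propagation(sm_p)
        assert _canon(labels[perm]) == _canon(labels_p)

    @pytest.mark.parametrize("case", range(5))
    def test_partition_matches_reference_implementation(self, case):
        rng = np.random.default_rng(100 + case)
        n = int(rng.integers(12, 41))
        k = int(rng.integers(2, 5))
        centers = rng.random((k, 10)) * 5
        X = np.abs(centers[rng.integers(0, k, n)] + rng.normal(0, 0.3, (n, 10)))
        S = cosine_similarity(X)
        pref = float(np.median(S[~np.eye(n, dtype=bool)]))
        sm = SimilarityMatrix(S.copy(), [str(i) for i in range(n)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mine = pc.affinity_propagation(sm, preference=pref)
            ref = AffinityPropagation(
                affinity="precomputed", damping=0.5, preference=pref,
                random_state=0,
            ).fit(S.copy())
        assert _canon(mine) == _canon(ref.labels_)


class TestOutlierScores:
    def _node(self):
        # 2-cell subcluster with within 0.95, similarity 0.2 to 3 outside cells
        S = np.full((5, 5), 0.2)
        S[0, 1] = S[1, 0] = 0.95
        S[2:, 2:] = 0.9
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(S, list("abcde"))

    def test_score_arithmetic(self):
        S = self._node()
        retained = np.array([True, True, False, False, False])
        res = pc.outlier_scores(S, np.array([0, 0]), retained)
        sc = res.subclusters[0]
        assert sc.i_m == pytest.approx(0.95)
        assert sc.o_m == pytest.approx(0.2)
        assert sc.outlier_score == pytest.approx(4.75)
        assert set(res.noise_cells) == {"c", "d", "e"}

    def test_homogeneous_subcluster_scores_one(self):
        S = np.full((6, 6), 0.7)
        np.fill_diagonal(S, 1.0)
        sm = SimilarityMatrix(S, list("abcdef"))
        res = pc.outlier_scores(
            sm, np.array([0, 0, 0, 1, 1, 1]), np.ones(6, dtype=bool)
        )
        for sc in res.subclusters:
            assert sc.outlier_score == pytest.approx(1.0)

    def test_singleton_score_undefined(self):
        S = self._node()
        res = pc.outlier_scores(
            S, np.array([0, 1]), np.array([True, True, False, False, False])
        )
        singles = [sc for sc in res.subclusters if sc.is_singleton]
        assert singles and all(np.isnan(sc.outlier_score) for sc in singles)
        assert all(not np.isnan(sc.o_m) for sc in singles)


class TestFlagRare:
    def _result(self, score, size=2, o_m=0.2):
        i_m = score * o_m if size > 1 else float("nan")
        sc = pc.RareSubcluster(
            cell_ids=[f"x{i}" for i in range(size)],
            i_m=i_m, o_m=o_m,
            outlier_score=score if size > 1 else float("nan"),
        )
        return pc.RareCallResult(subclusters=[sc])

    def test_score_above_ros_flagged(self):
        out = pc.flag_rare(self._result(4.75), ros=3.5)
        assert out.subclusters[0].flagged_rare

    def test_exact_threshold_not_flagged(self):
        out = pc.flag_rare(self._result(3.5), ros=3.5)
        assert not out.subclusters[0].flagged_rare

    def test_lowering_ros_flips_borderline_cluster(self):
        assert not pc.flag_rare(self._result(3.0), ros=3.5).subclusters[0].flagged_rare
        assert pc.flag_rare(self._result(3.0), ros=2.5).subclusters[0].flagged_rare

    def test_singleton_uses_o_m_rule(self):
        low = pc.flag_rare(self._result(float("nan"), size=1, o_m=0.1), os=0.5)
        high = pc.flag_rare(self._result(float("nan"), size=1, o_m=0.8), os=0.5)
        assert low.subclusters[0].flagged_rare
        assert not high.subclusters[0].flagged_rare

    def test_raising_ros_never_grows_flagged_set(self, rng):
        scores = rng.uniform(0.5, 8.0, 20)
        results = pc.RareCallResult(
            subclusters=[
                pc.RareSubcluster([f"c{i}a", f"c{i}b"], s * 0.2, 0.2, s)
                for i, s in enumerate(scores)
            ]
        )
        prev = None
        for ros in [1.0, 2.5, 3.5, 5.0, 10.0]:
            flagged = set(pc.flag_rare(results, ros=ros).flagged_cells())
            if prev is not None:
                assert flagged <= prev
            prev = flagged


class TestDetectRare:
    def _planted(self, seed):
        spec = pc.SimSpec(cluster_sizes=[500, 5], n_de_genes_per_cluster=20,
                          seed=seed)
        m, truth = pc.generate(spec)
        target = {c for c, t in truth.items() if t == "type2"}
        return m, target

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_rare_group_flagged_as_one_subcluster(self, seed):
        m, target = self._planted(seed)
        res = pc.detect_rare(m, noise_threshold=30)
        assert res is not None
        assert any(
            set(sc.cell_ids) == target and sc.flagged_rare
            and sc.outlier_score > 3.5
            for sc in res.subclusters
        )

    def test_cell_partition_invariant(self):
        m, _ = self._planted(0)
        res = pc.detect_rare(m, noise_threshold=30)
        in_sub = [c for sc in res.subclusters for c in sc.cell_ids]
        assert sorted(in_sub + res.noise_cells) == sorted(m.cell_ids)
        assert len(set(in_sub)) == len(in_sub)

    def test_homogeneous_node_skipped(self, rng):
        vals = rng.poisson(3.0, size=(100, 60))
        res = pc.detect_rare(make_matrix(vals), noise_threshold=30)
        assert res is None or not res.flagged_cells()
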