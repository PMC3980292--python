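"""Odour features, distance matrices, Ward trees, Mantel permutation test."""

import numpy as np
import pytest
from scipy.stats import kstest

import calcistream as cs


def _protocol(onsets, n_frames, labels=None):
    labels = labels or [f"s{i}" for i in range(len(onsets))]
    return cs.StimulusProtocol(entries=tuple(zip(labels, onsets)),
                               n_frames=n_frames, frame_rate=5.0)


class TestExtractFeatures:
    def test_single_peak_inside_window(self):
        trace = np.zeros(30)
        trace[12] = 4.2
        F = cs.extract_features(trace[:, None], _protocol([5], 30))
        assert F.values[0, 0] == 4.2

    def test_flat_trace_gives_zero_features(self):
        F = cs.extract_features(np.zeros((40, 3)), _protocol([5, 20], 40))
        np.testing.assert_array_equal(F.values, 0.0)

    def test_windows_end_at_next_onset(self):
        trace = np.zeros(40)
        trace[21] = 9.0   # belongs to the second window only
        F = cs.extract_features(trace[:, None], _protocol([5, 20], 40))
        assert F.values[0, 0] == 0.0
        assert F.values[1, 0] == 9.0

    def test_invariant_outside_stimulus_windows(self):
        rng = np.random.default_rng(0)
        T = rng.standard_normal((50, 4))
        proto = _protocol([10, 30], 50)
        F1 = cs.extract_features(T, proto)
        T2 = T.copy()
        T2[:10] += 100.0   # before the first onset
        F2 = cs.extract_features(T2, proto)
        np.testing.assert_array_equal(F1.values, F2.values)

    def test_baseline_subtraction(self):
        trace = np.full(30, 2.0)
        trace[12] = 7.0
        F = cs.extract_features(trace[:, None], _protocol([10], 30),
                                baseline_mode="subtract")
        assert F.values[0, 0] == pytest.approx(5.0)

    def test_recovers_ground_truth_amplitudes(self, small_truth,
                                              small_protocol):
        F = cs.extract_features(small_truth.traces, small_protocol,
                                baseline_mode="subtract")
        for s, (lab, _) in enumerate(small_protocol.entries):
            for u, src in enumerate(small_truth.sources):
                amp = src.stimulus_responses.get(lab, 0.0)
                tol = 3 * src.spontaneous_amplitude
                assert abs(F.values[s, u] - amp) < tol + 0.15 * amp

    def test_onset_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            cs.extract_features(np.zeros((10, 1)), _protocol([15], 20))

    def test_csv_round_trip(self, tmp_path):
        F = cs.FeatureMatrix(values=np.arange(6.0).reshape(2, 3),
                             stimulus_labels=["a", "b"], unit_ids=[0, 1, 2])
        F.to_csv(tmp_path / "f.csv")
        G = cs.FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_array_equal(F.values, G.values)
        assert G.stimulus_labels == ["a", "b"]


class TestEuclideanDistances:
    def test_identical_rows_and_pythagorean_pair(self):
        F = cs.FeatureMatrix(values=np.array([[0.0, 0.0], [0.0, 0.0],
                                              [3.0, 4.0]]),
                             stimulus_labels=["a", "b", "c"],
                             unit_ids=[0, 1])
        D = cs.euclidean_distances(F)
        assert D.d[0, 1] == 0.0
        assert D.d[0, 2] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((7, 5))
        F = cs.FeatureMatrix(values=X, stimulus_labels=[str(i) for i in range(7)],
                             unit_ids=list(range(5)))
        D = cs.euclidean_distances(F)
        for i in range(7):
            for j in range(7):
                assert D.d[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j])**2).sum()), abs=1e-12)


class TestWardCluster:
    def test_far_apart_pairs_merge_first(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        F = cs.FeatureMatrix(values=X, stimulus_labels=list("abcd"),
                             unit_ids=[0])
        res = cs.ward_cluster(F)
        first_two = {frozenset(res.linkage[0, :2].astype(int)),
                     frozenset(res.linkage[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_collinear_points_first_merge(self):
        X = np.array([[0.0], [1.0], [10.0]])
        F = cs.FeatureMatrix(values=X, stimulus_labels=list("abc"),
                             unit_ids=[0])
        res = cs.ward_cluster(F)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        F = cs.FeatureMatrix(values=rng.standard_normal((12, 4)),
                             stimulus_labels=[str(i) for i in range(12)],
                             unit_ids=list(range(4)))
        res = cs.ward_cluster(F)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_pure_subtree_detection(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [20.0]])
        F = cs.FeatureMatrix(values=X, stimulus_labels=list("aabbc"),
                             unit_ids=[0])
        res = cs.ward_cluster(F)
        assert cs.is_pure_subtree(res, [0, 1])
        assert cs.is_pure_subtree(res, [2, 3])
        assert not cs.is_pure_subtree(res, [1, 2])

    def test_newick_output_parses(self):
        X = np.array([[0.0], [1.0], [5.0]])
        F = cs.FeatureMatrix(values=X, stimulus_labels=["a", "b", "c"],
                             unit_ids=[0])
        nwk = cs.to_newick(cs.ward_cluster(F))
        import skbio

        tree = skbio.TreeNode.read([nwk])
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}


class TestMantel:
    def _random_distance(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(X))

    def test_identical_matrices(self):
        D = self._random_distance(8, 0)
        res = cs.mantel_test(D, D, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_matches_scikit_bio(self):
        D1 = self._random_distance(10, 1)
        D2 = self._random_distance(10, 2)
        res = cs.mantel_test(D1, D2, n_permutations=999, seed=0)
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel

        r_sk, p_sk, _ = mantel(SkDM(D1), SkDM(D2), method="pearson",
                               permutations=999, alternative="two-sided")
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert res.p == pytest.approx(float(p_sk), abs=0.05)

    def test_common_relabelling_preserves_r(self):
        D1 = self._random_distance(9, 3)
        D2 = self._random_distance(9, 4)
        perm = np.random.default_rng(5).permutation(9)
        a = cs.mantel_test(D1, D2, n_permutations=499, seed=0)
        b = cs.mantel_test(D1[np.ix_(perm, perm)], D2[np.ix_(perm, perm)],
                           n_permutations=499, seed=0)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert abs(a.p - b.p) < 0.06   # same null up to permutation sampling

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for i in range(200):
            D1 = self._random_distance(8, 100 + i)
            D2 = self._random_distance(8, 500 + i)
            ps.append(cs.mantel_test(D1, D2, n_permutations=199, seed=i).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))
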