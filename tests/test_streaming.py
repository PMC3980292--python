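"""CCIPCA updates, convex-cone selection, S/reconstruction, per-frame loop."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

import calcistream as cs
from calcistream.streaming import StreamConfig, StreamProcessor, run_stream


def naive_convex_cone(M, c):
    """Independent oracle: literal downdating of a dense copy of M."""
    M = np.array(M, dtype=float)
    indices, basis, max_norms = [], [], []
    for _ in range(c):
        norms = np.linalg.norm(M, axis=0)
        p = int(np.argmax(norms))          # ties -> lowest index
        max_norms.append(norms[p])
        b = M[:, p] / norms[p]
        M = M - np.outer(b, b @ M)
        indices.append(p)
        basis.append(b)
    return indices, np.array(basis).T, max_norms


class TestUpdateIPCA:
    def test_fixed_point_of_constant_stream(self):
        v = np.array([3.0, -1.0, 2.0, 0.5])
        V = cs.PCMatrix.empty(1, 4)
        for _ in range(100):
            cs.update_ipca(V, v, copy=False)
            vh = V.normalised()[0]
            assert np.linalg.norm(vh - v / np.linalg.norm(v)) < 1e-12

    def test_converges_to_leading_eigvector(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 3)) * np.sqrt([9.0, 4.0, 1.0])
        V = cs.PCMatrix.empty(1, 3)
        for x in X:
            cs.update_ipca(V, x, copy=False)
        angle = np.degrees(
            subspace_angles(V.normalised()[:1].T, np.eye(3)[:, :1]).max())
        assert angle < 5.0

    def test_input_frame_not_modified(self):
        V = cs.PCMatrix.empty(3, 6)
        x = np.arange(6.0)
        x0 = x.copy()
        for _ in range(5):
            cs.update_ipca(V, x)
        np.testing.assert_array_equal(x, x0)

    def test_converged_rows_near_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4000, 8)) * np.sqrt(
            [16.0, 9.0, 4.0, 1.0, 0.1, 0.1, 0.1, 0.1])
        V = cs.PCMatrix.empty(4, 8)
        for x in X:
            cs.update_ipca(V, x, copy=False)
        Vn = V.normalised()
        G = np.abs(Vn @ Vn.T - np.eye(4))
        assert G.max() < 0.1


class TestConvexCone:
    def test_hand_computed_two_step_example(self):
        # columns (2,0), (0,1), (1,1): first pick index 0 (norm 2); after
        # projecting out (1,0) the residual norms are 0, 1, 1 -> tie, pick 1
        M = np.array([[2.0, 0.0, 1.0],
                      [0.0, 1.0, 1.0]])
        res = cs.convex_cone(M, 2)
        assert res.indices.tolist() == [0, 1]
        np.testing.assert_allclose(res.basis.T @ res.basis, np.eye(2),
                                   atol=1e-12)

    def test_single_step_is_argmax_norm(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((7, 30))
        res = cs.convex_cone(M, 1)
        assert res.indices[0] == np.argmax(np.linalg.norm(M, axis=0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_naive_downdating_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.standard_normal((12, 40))
        c = 6
        res = cs.convex_cone(M, c)
        idx, basis, max_norms = naive_convex_cone(M, c)
        assert res.indices.tolist() == idx
        # residual max norms non-increasing (greedy monotonicity)
        assert np.all(np.diff(max_norms) <= 1e-9)
        np.testing.assert_allclose(np.abs(np.diag(res.basis.T @ basis)),
                                   1.0, atol=1e-8)

    def test_noiseless_mixture_recovers_pure_pixels(self, small_truth,
                                                    small_movie):
        res = cs.convex_cone(small_movie, small_truth.n_units)
        assert set(res.indices.tolist()) == set(small_truth.pure_pixels.values())

    def test_insufficient_columns_warn_and_error_modes(self):
        M = np.outer(np.ones(4), np.arange(1.0, 6.0))  # rank 1
        with pytest.warns(RuntimeWarning):
            res = cs.convex_cone(M, 3)
        assert not res.complete
        assert len(res.indices) == 1
        with pytest.raises(ValueError):
            cs.convex_cone(M, 3, on_insufficient="error")

    def test_selection_is_stateless(self, noisy_movie, noisy_truth):
        cfg = StreamConfig(k=10, c=6, spatial_filter_width=1,
                           select_every=1, compute_recon=False,
                           keep_history=False)
        proc = StreamProcessor(noisy_truth.image_shape, cfg)
        last_inline = None
        for frame in noisy_movie[:200]:
            res = proc.process_frame(frame)
            if res.model is not None:
                last_inline = res.model
        refreshed = proc.current_model(with_T=False)
        np.testing.assert_array_equal(last_inline.selected, refreshed.selected)
        np.testing.assert_array_equal(last_inline.S, refreshed.S)


class TestComputeS:
    def test_axis_basis_reads_off_rows(self):
        A = np.random.default_rng(3).standard_normal((4, 6))
        e1 = np.eye(4)[:, :1]
        S = cs.compute_S(A, e1, nonneg=None)
        np.testing.assert_allclose(S[0], A[0])

    def test_exact_span_reconstruction(self):
        rng = np.random.default_rng(4)
        B = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        A = B @ rng.standard_normal((3, 20))
        S = cs.compute_S(A, B, nonneg=None)
        np.testing.assert_allclose(B @ S, A, atol=1e-10)

    def test_clip_produces_nonnegative(self):
        A = np.array([[1.0, -2.0], [0.5, 3.0]])
        S = cs.compute_S(A, np.eye(2), nonneg="clip")
        assert S.min() == 0.0

    def test_nnls_refit_is_nonnegative_and_at_least_as_sparse(self):
        rng = np.random.default_rng(5)
        B = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        A = rng.standard_normal((8, 15))
        S = cs.compute_S(A, B, nonneg="nnls")
        assert S.min() >= 0.0


class TestReconstruct:
    def test_idempotent_and_exact_in_rowspace(self):
        rng = np.random.default_rng(6)
        S = rng.standard_normal((3, 12))
        frame = S.T @ rng.standard_normal(3)
        rec = cs.reconstruct(frame, S)
        np.testing.assert_allclose(rec.frame_hat, frame, atol=1e-10)
        rec2 = cs.reconstruct(rec.frame_hat, S)
        np.testing.assert_allclose(rec2.frame_hat, rec.frame_hat, atol=1e-10)

    def test_orthogonal_frame_maps_to_zero(self):
        S = np.eye(2, 5)
        frame = np.array([0.0, 0.0, 1.0, -2.0, 0.5])
        rec = cs.reconstruct(frame, S)
        np.testing.assert_allclose(rec.frame_hat, 0.0, atol=1e-12)
        assert rec.residual_norm == pytest.approx(np.linalg.norm(frame))

    def test_non_expansive(self):
        rng = np.random.default_rng(7)
        S = rng.standard_normal((4, 20))
        for _ in range(10):
            f = rng.standard_normal(20)
            rec = cs.reconstruct(f, S)
            assert np.linalg.norm(rec.frame_hat) <= np.linalg.norm(f) + 1e-12

    def test_rank_deficient_rows_handled(self):
        S = np.vstack([np.eye(2, 6), np.eye(2, 6)])  # duplicated rows
        frame = np.arange(6.0)
        rec = cs.reconstruct(frame, S)
        np.testing.assert_allclose(rec.frame_hat[:2], frame[:2], atol=1e-10)
        np.testing.assert_allclose(rec.frame_hat[2:], 0.0, atol=1e-12)


class TestProcessFrame:
    def test_first_frames_are_warmup_passthrough(self, noisy_movie,
                                                 noisy_truth):
        proc = StreamProcessor(noisy_truth.image_shape,
                               StreamConfig(k=5, c=3, spatial_filter_width=1))
        res = proc.process_frame(noisy_movie[0])
        assert res.is_warmup
        np.testing.assert_array_equal(res.recon.frame_hat, res.normalised)
        res2 = proc.process_frame(noisy_movie[1])
        assert res2.is_warmup
        res3 = proc.process_frame(noisy_movie[2])
        assert not res3.is_warmup

    def test_stationary_movie_low_residual(self):
        protocol = cs.generate_protocol(
            [f"o{i}" for i in range(10)], interstimulus_frames=50,
            lead_in_frames=20, frame_rate=5.0, seed=17, total_frames=520,
        )
        truth = cs.generate_ground_truth(
            image_shape=(40, 40), n_units=5, radius_range=(3.0, 5.0),
            protocol=protocol, noise_sigma=0.0, n_background=0, seed=17,
        )
        movie = cs.render_movie(truth)
        cfg = StreamConfig(k=10, c=5, spatial_filter_width=1,
                           select_every=50, compute_recon=True,
                           keep_history=False)
        proc = StreamProcessor(truth.image_shape, cfg)
        last = None
        for frame in movie:
            res = proc.process_frame(frame)
            if res.recon is not None:
                last = res
        ratio = last.recon.residual_norm / np.linalg.norm(last.normalised)
        assert ratio < 0.05

    def test_factor_model_deterministic(self, noisy_movie, noisy_truth):
        cfg = StreamConfig(k=8, c=5, spatial_filter_width=1,
                           select_every=100, compute_recon=False)
        _, m1 = run_stream(noisy_movie[:300], noisy_truth.image_shape, cfg)
        _, m2 = run_stream(noisy_movie[:300], noisy_truth.image_shape, cfg)
        np.testing.assert_array_equal(m1.selected, m2.selected)
        np.testing.assert_array_equal(m1.S, m2.S)
        np.testing.assert_array_equal(m1.T, m2.T)

    def test_model_T_contains_selected_series(self, noisy_movie, noisy_truth):
        cfg = StreamConfig(k=8, c=5, spatial_filter_width=1,
                           select_every=100, compute_recon=False)
        proc, model = run_stream(noisy_movie[:300], noisy_truth.image_shape, cfg)
        H = proc.history_matrix()
        np.testing.assert_allclose(model.T, H[:, model.selected], atol=1e-6)
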