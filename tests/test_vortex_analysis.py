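import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aneuhemo.fields import TimeSeriesVectorField
from aneuhemo.meshes import VolumeMesh
from aneuhemo.synthetic import VortexBlob, make_tet_ball, make_vortex_velocity_series
from aneuhemo.vortex import (
    analyze_vortex_series,
    count_cores,
    degree_of_overlap,
    filter_small_components,
    q_criterion,
    lambda2_criterion,
    velocity_gradient,
    vortex_core_mask,
    vortex_volume,
)
from oracles import q_oracle


class TestVelocityGradient:
    def test_rigid_rotation_exact(self, coarse_ball):
        omega = 2.5
        u = np.cross([0.0, 0.0, omega], coarse_ball.points)
        g = velocity_gradient(coarse_ball, u)
        expected = np.array([[0, -omega, 0], [omega, 0, 0], [0, 0, 0.0]])
        np.testing.assert_allclose(g, np.broadcast_to(expected, g.shape), atol=1e-12)

    def test_constant_field_zero(self, coarse_ball):
        u = np.tile([1.0, -2.0, 0.5], (coarse_ball.n_points, 1))
        g = velocity_gradient(coarse_ball, u)
        np.testing.assert_allclose(g, 0.0, atol=1e-13)

    def test_quadratic_field_converges(self):
        # u = (x^2, 0, 0): du/dx = 2x, cell error is O(h)
        errs = []
        for edge in (0.25, 0.125):
            ball = make_tet_ball(1.0, edge)
            u = np.zeros((ball.n_points, 3))
            u[:, 0] = ball.points[:, 0] ** 2
            g = velocity_gradient(ball, u)
            cent = ball.cell_centroids()
            errs.append(np.abs(g[:, 0, 0] - 2 * cent[:, 0]).mean())
        assert errs[1] < 0.7 * errs[0]

    def test_degenerate_cell_error(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float
        )  # coplanar
        with pytest.raises(ValueError):
            mesh = VolumeMesh(pts, np.array([[0, 1, 2, 3]]))
            mesh.validate()
            velocity_gradient(mesh, np.zeros((4, 3)))


class TestCoreMask:
    def test_rigid_rotation_all_masked(self, coarse_ball):
        omega = 3.0
        u = np.cross([0.0, 0.0, omega], coarse_ball.points)
        g = velocity_gradient(coarse_ball, u)
        q = q_criterion(g)
        np.testing.assert_allclose(q, omega**2, rtol=1e-10)
        assert vortex_core_mask(g, "Q", 0.0).all()

    def test_pure_shear_unmasked(self, coarse_ball):
        gamma = 2.0
        u = np.zeros((coarse_ball.n_points, 3))
        u[:, 0] = gamma * coarse_ball.points[:, 1]
        g = velocity_gradient(coarse_ball, u)
        np.testing.assert_allclose(q_criterion(g), 0.0, atol=1e-12)
        assert not vortex_core_mask(g, "Q", 1e-9).any()

    def test_lambda2_rigid_rotation(self, coarse_ball):
        omega = 3.0
        u = np.cross([0.0, 0.0, omega], coarse_ball.points)
        g = velocity_gradient(coarse_ball, u)
        # S^2+W^2 eigenvalues: (-omega^2, -omega^2, 0) -> lambda2 = -omega^2
        assert vortex_core_mask(g, "lambda2", 0.0).all()

    def test_unknown_criterion(self, coarse_ball):
        with pytest.raises(ValueError, match="criterion"):
            vortex_core_mask(np.zeros((1, 3, 3)), "delta", 0.0)

    def test_mask_matches_bruteforce_oracle(self, coarse_ball):
        # blob + strain background keeps |Q| bounded away from zero
        blob = VortexBlob(center=[0.0, 0.0, 0.0], sigma=0.3, omega=6.0)
        u = blob.velocity(coarse_ball.points, np.zeros(3))
        alpha = 0.5
        u[:, 0] += alpha * coarse_ball.points[:, 0]
        u[:, 1] -= alpha * coarse_ball.points[:, 1]
        g = velocity_gradient(coarse_ball, u)
        q = q_criterion(g)
        q_ref = q_oracle(coarse_ball.points, coarse_ball.tets, u)
        np.testing.assert_allclose(q, q_ref, rtol=1e-9, atol=1e-12)
        assert coarse_ball.n_cells <= 20000
        np.testing.assert_array_equal(q > 0.0, q_ref > 0.0)


class TestVolumesAndCounts:
    def test_vv_all_and_none(self, coarse_ball):
        all_mask = np.ones((2, coarse_ball.n_cells), dtype=bool)
        vv, mean = vortex_volume(all_mask, coarse_ball)
        assert vv[0] == pytest.approx(coarse_ball.total_volume())
        vv0, mean0 = vortex_volume(np.zeros_like(all_mask), coarse_ball)
        assert mean0 == 0.0

    def test_vv_against_dense_grid_oracle(self, medium_ball):
        sigma, omega = 0.25, 5.0
        blob = VortexBlob(center=[0, 0, 0], sigma=sigma, omega=omega)
        field, _ = make_vortex_velocity_series(medium_ball, [blob], phases=2)
        summary = analyze_vortex_series(field, min_cells=0)

        # independent oracle: analytic velocity gradient on a dense grid
        h = 0.02
        ax = np.arange(-1, 1, h) + h / 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], 1)
        pts = pts[np.linalg.norm(pts, axis=1) <= 1]
        rr = (pts * pts).sum(1)
        E = np.exp(-rr / (2 * sigma**2))
        A = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0.0]]) * omega
        axr = np.cross([0, 0, omega], pts)
        J = (
            A[None] * E[:, None, None]
            + axr[:, :, None] * (-pts / sigma**2)[:, None, :] * E[:, None, None]
        )
        S = (J + J.transpose(0, 2, 1)) / 2
        W = (J - J.transpose(0, 2, 1)) / 2
        Q = 0.5 * (
            np.einsum("cij,cij->c", W, W) - np.einsum("cij,cij->c", S, S)
        )
        vv_oracle = (Q > 0).sum() * h**3
        assert summary.vv_mean == pytest.approx(vv_oracle, rel=0.10)

    def test_two_disjoint_blobs_noc2(self, blob_pair_summary):
        summary, truth = blob_pair_summary
        assert (truth.targets["expected_noc"] == 2).all()
        np.testing.assert_array_equal(summary.noc, 2)
        assert summary.noc_std == 0.0

    def test_alternating_core_count_std(self, fine_ball):
        # splice series: even phases one blob, odd phases two
        b1 = VortexBlob(center=[0.55, 0, 0], sigma=0.15, omega=8.0)
        b2 = VortexBlob(center=[-0.55, 0, 0], sigma=0.15, omega=8.0)
        f1, _ = make_vortex_velocity_series(fine_ball, [b1], phases=20)
        f12, _ = make_vortex_velocity_series(fine_ball, [b1, b2], phases=20)
        values = f1.values.copy()
        values[1::2] = f12.values[1::2]
        field = TimeSeriesVectorField(
            fine_ball, values, f1.phase_times, units="m/s"
        )
        summary = analyze_vortex_series(field, threshold=1e-3 * 64.0, min_cells=32)
        np.testing.assert_array_equal(summary.noc, [1, 2] * 10)
        assert summary.noc_std == pytest.approx(0.5)

    def test_count_cores_min_cells_filter(self, coarse_ball):
        mask = np.zeros(coarse_ball.n_cells, dtype=bool)
        mask[0] = True  # single-cell speck
        noc, _ = count_cores(mask[None, :], coarse_ball, min_cells=5)
        assert noc[0] == 0
        noc, _ = count_cores(mask[None, :], coarse_ball, min_cells=0)
        assert noc[0] == 1
        filtered = filter_small_components(mask, coarse_ball, 5)
        assert not filtered.any()


class TestDvo:
    def test_identical_masks(self, coarse_ball):
        mask = coarse_ball.cell_centroids()[:, 0] > 0
        dvo, flag = degree_of_overlap(mask, mask, coarse_ball)
        assert dvo == 1.0 and not flag

    def test_disjoint_masks(self, coarse_ball):
        c = coarse_ball.cell_centroids()
        dvo, _ = degree_of_overlap(c[:, 0] > 0.3, c[:, 0] < -0.3, coarse_ball)
        assert dvo == 0.0

    def test_both_empty_flagged(self, coarse_ball):
        empty = np.zeros(coarse_ball.n_cells, dtype=bool)
        dvo, flag = degree_of_overlap(empty, empty, coarse_ball)
        assert dvo == 1.0 and flag

    def test_one_empty(self, coarse_ball):
        empty = np.zeros(coarse_ball.n_cells, dtype=bool)
        some = ~empty
        assert degree_of_overlap(some, empty, coarse_ball)[0] == 0.0

    def test_known_overlap_bookkeeping(self, coarse_ball):
        # brute-force volume bookkeeping oracle over explicit cell sets
        c = coarse_ball.cell_centroids()
        a = c[:, 0] > 0.0
        b = c[:, 0] > 0.25
        vols = coarse_ball.cell_volumes()
        inter = sum(v for v, in_a, in_b in zip(vols, a, b) if in_a and in_b)
        union = sum(v for v, in_a, in_b in zip(vols, a, b) if in_a or in_b)
        dvo, _ = degree_of_overlap(a, b, coarse_ball)
        assert dvo == pytest.approx(inter / union, rel=1e-12)

    def test_min_mode(self, coarse_ball):
        c = coarse_ball.cell_centroids()
        a = c[:, 0] > 0.0
        b = c[:, 0] > 0.25
        dvo_min, _ = degree_of_overlap(a, b, coarse_ball, mode="min")
        assert dvo_min == pytest.approx(1.0)  # b is a subset of a


class TestSeriesInvariants:
    def test_steady_series(self, blob_single_summary):
        summary = blob_single_summary
        np.testing.assert_array_equal(summary.noc, 1)
        assert summary.noc_std == 0.0
        np.testing.assert_allclose(summary.dvo, 1.0)

    def test_galilean_invariance(self, fine_ball):
        blob = VortexBlob(center=[0, 0, 0], sigma=0.2, omega=6.0)
        f, _ = make_vortex_velocity_series(fine_ball, [blob], phases=3)
        s0 = analyze_vortex_series(f, threshold=1e-3 * 36.0, min_cells=32)
        f_shift, _ = make_vortex_velocity_series(
            fine_ball, [blob], phases=3, background=np.array([0.7, -0.3, 1.1])
        )
        s1 = analyze_vortex_series(f_shift, threshold=1e-3 * 36.0, min_cells=32)
        np.testing.assert_array_equal(s0.core_masks, s1.core_masks)
        np.testing.assert_allclose(s0.vv, s1.vv)

    def test_frame_rotation_invariance(self, coarse_ball, rng):
        values = rng.standard_normal((3, coarse_ball.n_points, 3))
        f = TimeSeriesVectorField(
            coarse_ball, values, np.arange(3) / 3.0, units="m/s"
        )
        q0 = q_criterion(velocity_gradient(coarse_ball, values[0]))

        R = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        mesh_r = VolumeMesh(coarse_ball.points @ R.T, coarse_ball.tets.copy())
        q1 = q_criterion(velocity_gradient(mesh_r, values[0] @ R.T))
        np.testing.assert_allclose(q1, q0, rtol=1e-8, atol=1e-10)

    def test_dvo_decreases_with_step_size(self, fine_ball):
        means = []
        for step in (0.02, 0.06, 0.12):
            P = 6
            path = np.zeros((P, 3))
            path[:, 0] = np.arange(P) * step - (P / 2) * step
            blob = VortexBlob(center=path, sigma=0.2, omega=6.0)
            f, _ = make_vortex_velocity_series(fine_ball, [blob], phases=P)
            s = analyze_vortex_series(f, threshold=1e-3 * 36.0, min_cells=32, cyclic=False)
            means.append(s.dvo_mean)
        assert means[0] >= means[1] >= means[2]
        assert means[2] < means[0]
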