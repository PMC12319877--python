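import numpy as np
import pytest

from rttms.coil import build_figure8_coil
from rttms.grid_interp import interpolate_fields, transform_points
from rttms.mesh_core import extrude_surface
from rttms.metrics import sample_scalp_placements
from rttms.realtime import (build_noise_mode_basis, compute_coefficients,
                            locate_points, precompute_session, realtime_solve,
                            reconstruct_field, sample_modes_at_surface,
                            load_session, save_session)


@pytest.fixture(scope="module")
def session_setup(small_phantom):
    mesh, scalp, evs = small_phantom
    huy = extrude_surface(scalp, 1.0)
    coil = build_figure8_coil(segments_per_turn=16)
    sess = precompute_session(mesh, huy, coil, n_modes=8, seed=5,
                              eval_surface=evs, grid_spacing=8.0)
    return mesh, scalp, huy, coil, sess


class TestPointLocation:
    def test_centroid_found_in_own_tet(self, small_mesh):
        idx = np.array([10, 100, 500])
        found = locate_points(small_mesh, small_mesh.tet_centroid[idx])
        np.testing.assert_array_equal(found, idx)

    def test_outside_point_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="not inside"):
            locate_points(small_mesh, [[500.0, 0.0, 0.0]])

    def test_matches_brute_force(self, small_mesh):
        """KD-tree walk agrees with exhaustive barycentric containment."""
        rng = np.random.default_rng(6)
        pts = rng.uniform(-0.5, 0.5, size=(100, 3)) * 30
        pts = pts[np.linalg.norm(pts, axis=1) < 30]
        found = locate_points(small_mesh, pts)
        p = small_mesh.nodes[small_mesh.tets]  # brute force via barycentric solve
        for q, t_found in zip(pts, found):
            T = np.vstack([np.ones(4), p[t_found].T])
            lam = np.linalg.solve(T, np.concatenate([[1.0], q]))
            assert np.all(lam >= -1e-9)


class TestSessionBuild:
    def test_gram_identity(self, session_setup, small_mesh):
        from rttms.mesh_core import extrude_surface
        from rttms.noise_basis import gram_matrix

        _, scalp, huy, _, _ = session_setup
        basis = build_noise_mode_basis(small_mesh, huy, 6, seed=5,
                                       oversample=1.0, power_iterations=0)
        G = gram_matrix(basis)
        assert np.abs(G - np.eye(6)).max() <= 1e-8

    def test_deterministic_for_seed(self, small_mesh, small_phantom):
        _, scalp, _ = small_phantom
        huy = extrude_surface(scalp, 1.0)
        b1 = build_noise_mode_basis(small_mesh, huy, 4, seed=9, oversample=1.0,
                                    power_iterations=0)
        b2 = build_noise_mode_basis(small_mesh, huy, 4, seed=9, oversample=1.0,
                                    power_iterations=0)
        np.testing.assert_array_equal(b1.modes, b2.modes)

    def test_more_modes_than_realizations_rejected(self, small_mesh, small_phantom):
        from rttms.noise_basis import build_basis

        rng = np.random.default_rng(0)
        arr = rng.standard_normal((int(small_mesh.roi_mask.sum()), 3, 3))
        with pytest.raises(ValueError):
            build_basis(arr, small_mesh, n_keep=5)

    def test_eval_samples_match_containing_tet(self, session_setup, small_phantom):
        mesh, _, huy, _, sess = session_setup
        _, _, evs = small_phantom
        basis = build_noise_mode_basis(mesh, huy, 3, seed=5, oversample=1.0,
                                       power_iterations=0)
        samples, rows = sample_modes_at_surface(basis, mesh, evs)
        tets = locate_points(mesh, evs.facet_center)
        np.testing.assert_array_equal(basis.roi_index[rows], tets)
        np.testing.assert_array_equal(samples[0], basis.modes[rows[0]])


class TestOnlineStage:
    def test_zero_fields_zero_coefficients(self, session_setup):
        *_, sess = session_setup
        n_d = len(sess.huygens_centers)
        a = compute_coefficients(sess, np.zeros((n_d, 3)), np.zeros((n_d, 3)))
        assert np.all(a == 0)

    def test_coefficients_linear_in_fields(self, session_setup):
        *_, sess = session_setup
        rng = np.random.default_rng(7)
        n_d = len(sess.huygens_centers)
        E = rng.standard_normal((n_d, 3))
        H = rng.standard_normal((n_d, 3))
        a1 = compute_coefficients(sess, E, H)
        a2 = compute_coefficients(sess, 3.0 * E, 3.0 * H)
        np.testing.assert_allclose(a2, 3.0 * a1, rtol=1e-5)

    def test_unit_coefficient_returns_first_mode(self, session_setup):
        *_, sess = session_setup
        a = np.zeros(sess.n_modes)
        a[0] = 1.0
        dIdt = sess.dIdt
        E = reconstruct_field(sess, a)
        np.testing.assert_allclose(E, dIdt * sess.modes_at_eval[:, :, 0], rtol=1e-6)

    def test_zero_modes_zero_field(self, session_setup):
        *_, sess = session_setup
        E = reconstruct_field(sess, np.ones(sess.n_modes), n_use=0)
        assert np.all(E == 0)

    def test_composition_matches_stagewise(self, session_setup, small_phantom):
        _, scalp, _ = small_phantom
        *_, sess = session_setup
        T = sample_scalp_placements(scalp, 1, seed=8)[0]
        E, a = realtime_solve(sess, T)
        pts = transform_points(sess.huygens_centers, T, inverse=True)
        E_p, H_p = interpolate_fields(sess.grid, pts)
        R = T.rotation
        a2 = compute_coefficients(sess, E_p @ R.T, H_p @ R.T)
        E2 = reconstruct_field(sess, a2)
        np.testing.assert_array_equal(E, E2)
        np.testing.assert_array_equal(a, a2)

    def test_end_to_end_linearity_in_didt(self, session_setup, small_phantom):
        _, scalp, _ = small_phantom
        *_, sess = session_setup
        T = sample_scalp_placements(scalp, 1, seed=9)[0]
        E1, _ = realtime_solve(sess, T)
        sess.dIdt *= 2.0
        E2, _ = realtime_solve(sess, T)
        sess.dIdt /= 2.0
        np.testing.assert_allclose(E2, 2.0 * E1, rtol=1e-6)

    def test_coil_axis_symmetry(self, session_setup, small_phantom):
        """Rotating the figure-8 180 degrees about its axis flips wing roles;
        the reconstructed |E| is unchanged up to interpolation tolerance."""
        _, scalp, _ = small_phantom
        *_, sess = session_setup
        top = scalp.facet_center[:, 2].argmax()
        from rttms.coil import tangential_placement

        p, n = scalp.facet_center[top], scalp.outward_normal[top]
        T1 = tangential_placement(p, n, angle=0.0)
        T2 = tangential_placement(p, n, angle=np.pi)
        E1, _ = realtime_solve(sess, T1)
        E2, _ = realtime_solve(sess, T2)
        m1, m2 = np.linalg.norm(E1, axis=1), np.linalg.norm(E2, axis=1)
        assert np.linalg.norm(m1 - m2) <= 0.02 * np.linalg.norm(m1)


class TestPersistence:
    def test_save_load_round_trip(self, session_setup, small_phantom, tmp_path):
        _, scalp, _ = small_phantom
        *_, sess = session_setup
        path = tmp_path / "session.h5"
        save_session(sess, path)
        back = load_session(path)
        T = sample_scalp_placements(scalp, 1, seed=10)[0]
        E1, a1 = realtime_solve(sess, T)
        E2, a2 = realtime_solve(back, T)
        # grid is stored single-precision; allow the corresponding round-off
        np.testing.assert_allclose(a2, a1, rtol=5e-3,
                                   atol=1e-6 * np.abs(a1).max())
        np.testing.assert_allclose(E2, E1, rtol=5e-3,
                                   atol=1e-6 * np.abs(E1).max())
        assert back.meta["seed"] == sess.meta["seed"]
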