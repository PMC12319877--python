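import numpy as np
import pytest

from rttms.huygens import (MU0, SurfaceFieldSet, build_reciprocity_operator,
                           equivalent_currents,
                           surface_fields_from_volume_currents)
from rttms.mesh_core import TriSurface
from conftest import single_tet_mesh


def observer_surface(points):
    """Tiny open surface whose facet centers sit near the given points."""
    nodes, tris = [], []
    for i, p in enumerate(points):
        p = np.asarray(p, dtype=float)
        nodes += [p + [0.1, 0, 0], p + [-0.05, 0.1, 0], p + [-0.05, -0.1, 0]]
        tris.append([3 * i, 3 * i + 1, 3 * i + 2])
    surf = TriSurface(np.asarray(nodes), np.asarray(tris))
    return surf


class TestSurfaceFields:
    def test_zero_current_zero_fields(self, small_phantom):
        mesh, scalp, _ = small_phantom
        from rttms.mesh_core import extrude_surface

        huy = extrude_surface(scalp, 1.0)
        out = surface_fields_from_volume_currents(
            mesh, np.zeros((mesh.n_tets, 3)), huy)
        assert np.all(out.E == 0) and np.all(out.H == 0)

    def test_single_tet_hand_biot_savart(self):
        """Unit z current in one tet, far observer on x: H = (V/4pi d^2) (z x x)."""
        mesh = single_tet_mesh()
        d = 500.0
        c = mesh.tet_centroid[0]
        surf = observer_surface([c + [d, 0, 0]])
        J = np.array([[0.0, 0.0, 1.0]])
        out = surface_fields_from_volume_currents(mesh, J, surf, near_depth=0)
        V = mesh.tet_volume[0] * 1e-9
        d_m = np.linalg.norm((surf.facet_center[0] - c)) * 1e-3
        h_mag = V / (4 * np.pi * d_m**2)
        np.testing.assert_allclose(out.H[0], [0.0, h_mag, 0.0], rtol=1e-3)
        e_mag = -MU0 * V / (4 * np.pi * d_m)
        np.testing.assert_allclose(out.E[0], [0.0, 0.0, e_mag], rtol=1e-3)

    def test_linearity(self, small_phantom):
        mesh, scalp, _ = small_phantom
        from rttms.mesh_core import extrude_surface

        huy = extrude_surface(scalp, 1.0)
        rng = np.random.default_rng(0)
        J = rng.standard_normal((mesh.n_tets, 3))
        a = surface_fields_from_volume_currents(mesh, J, huy)
        b = surface_fields_from_volume_currents(mesh, 2.0 * J, huy)
        np.testing.assert_allclose(b.E, 2.0 * a.E, rtol=1e-12)
        np.testing.assert_allclose(b.H, 2.0 * a.H, rtol=1e-12)

    def test_near_field_correction_improves_accuracy(self):
        """Subdivided quadrature approaches a dense sub-tet reference for a
        close observer, beating the pure centroid rule."""
        mesh = single_tet_mesh(scale=10.0)
        c = mesh.tet_centroid[0]
        obs = c + np.array([8.0, 1.0, 2.0])
        surf = observer_surface([obs])
        J = np.array([[0.3, -0.7, 1.1]])
        # dense reference: depth-4 subdivision (4096 points)
        ref = surface_fields_from_volume_currents(mesh, J, surf,
                                                  near_threshold=50.0, near_depth=4)
        plain = surface_fields_from_volume_currents(mesh, J, surf, near_depth=0)
        corr = surface_fields_from_volume_currents(mesh, J, surf,
                                                   near_threshold=50.0, near_depth=2)
        err_plain = np.linalg.norm(plain.H - ref.H)
        err_corr = np.linalg.norm(corr.H - ref.H)
        assert err_corr < 0.2 * err_plain

    def test_surface_touching_head_rejected(self, small_phantom):
        mesh, scalp, _ = small_phantom
        with pytest.raises(ValueError):
            surface_fields_from_volume_currents(
                mesh, np.ones((mesh.n_tets, 3)), scalp, min_gap_mm=2.0)


class TestEquivalentCurrents:
    def make_fields(self, surface, E, H):
        return SurfaceFieldSet(E, H, surface)

    def test_normal_h_gives_zero_js(self, small_phantom):
        _, scalp, _ = small_phantom
        n = scalp.outward_normal
        out = equivalent_currents(self.make_fields(scalp, np.zeros_like(n), n), scalp)
        np.testing.assert_allclose(out.J_S, 0.0, atol=1e-14)

    def test_tangential_e_gives_unit_ks(self, small_phantom):
        _, scalp, _ = small_phantom
        n = scalp.outward_normal
        seed = np.array([0.0, 0.0, 1.0])
        t = np.cross(n, np.where(np.abs(n[:, 2:3]) < 0.9, seed, [1.0, 0, 0]))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        out = equivalent_currents(self.make_fields(scalp, t, np.zeros_like(t)), scalp)
        np.testing.assert_allclose(np.linalg.norm(out.K_S, axis=1), 1.0, rtol=1e-12)
        np.testing.assert_allclose(out.K_S, -np.cross(n, t), atol=1e-12)

    def test_tangency_for_random_fields(self, small_phantom):
        _, scalp, _ = small_phantom
        rng = np.random.default_rng(1)
        E = rng.standard_normal((scalp.facet_count, 3))
        H = rng.standard_normal((scalp.facet_count, 3))
        out = equivalent_currents(self.make_fields(scalp, E, H), scalp)
        n = scalp.outward_normal
        assert np.abs(np.einsum("ij,ij->i", n, out.J_S)).max() <= \
            1e-10 * np.linalg.norm(out.J_S, axis=1).max()
        assert np.abs(np.einsum("ij,ij->i", n, out.K_S)).max() <= \
            1e-10 * np.linalg.norm(out.K_S, axis=1).max()


class TestReciprocityOperator:
    def build(self, surface, n_modes=4, seed=2):
        rng = np.random.default_rng(seed)
        E = rng.standard_normal((surface.facet_count, 3, n_modes))
        H = rng.standard_normal((surface.facet_count, 3, n_modes))
        cur = equivalent_currents(SurfaceFieldSet(E, H, surface), surface)
        return cur, build_reciprocity_operator(cur, surface)

    def test_zero_currents_zero_matrix(self, small_phantom):
        _, scalp, _ = small_phantom
        cur = equivalent_currents(
            SurfaceFieldSet(np.zeros((scalp.facet_count, 3, 2)),
                            np.zeros((scalp.facet_count, 3, 2)), scalp), scalp)
        B = build_reciprocity_operator(cur, scalp)
        assert np.all(B.B == 0)

    def test_matvec_matches_explicit_quadrature_loop(self, small_phantom):
        """B @ [E_p; H_p] equals the per-facet reciprocity sum."""
        _, scalp, _ = small_phantom
        cur, B = self.build(scalp)
        rng = np.random.default_rng(3)
        E_p = rng.standard_normal((scalp.facet_count, 3))
        H_p = rng.standard_normal((scalp.facet_count, 3))
        a = B.coefficients(E_p, H_p)
        areas = scalp.facet_area * 1e-6
        expected = np.array([
            np.sum(areas * (np.einsum("jd,jd->j", E_p, cur.J_S[:, :, i])
                            - np.einsum("jd,jd->j", H_p, cur.K_S[:, :, i])))
            for i in range(4)])
        np.testing.assert_allclose(a, expected, rtol=1e-6)

    def test_facet_permutation_invariance(self, small_phantom):
        _, scalp, _ = small_phantom
        cur, B = self.build(scalp)
        rng = np.random.default_rng(4)
        E_p = rng.standard_normal((scalp.facet_count, 3))
        H_p = rng.standard_normal((scalp.facet_count, 3))
        a = B.coefficients(E_p, H_p)
        perm = rng.permutation(scalp.facet_count)
        surf2 = TriSurface(scalp.nodes, scalp.tris[perm])
        from rttms.huygens import HuygensCurrentSet

        cur2 = HuygensCurrentSet(cur.J_S[perm], cur.K_S[perm], surf2)
        B2 = build_reciprocity_operator(cur2, surf2)
        a2 = B2.coefficients(E_p[perm], H_p[perm])
        np.testing.assert_allclose(a2, a, rtol=1e-5)
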