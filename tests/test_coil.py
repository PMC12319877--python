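import numpy as np
import pytest

from rttms.coil import (MU0, CoilModel, Placement, build_figure8_coil,
                        coil_primary_fields, load_coil_file, save_coil_file,
                        tangential_placement, transform_coil)


class TestFigure8:
    def test_loops_close(self):
        coil = build_figure8_coil(segments_per_turn=20)
        per_loop = coil.weights.reshape(18, 20, 3)
        np.testing.assert_allclose(per_loop.sum(axis=1), 0.0, atol=1e-10)

    def test_element_count(self):
        coil = build_figure8_coil(turns=9, segments_per_turn=24)
        assert coil.n_elements == 2 * 9 * 24

    def test_mirror_symmetric_magnitude(self):
        coil = build_figure8_coil(segments_per_turn=32)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-60, 60, size=(40, 3))
        pts[:, 2] = -rng.uniform(20, 80, size=40)
        E1, _ = coil_primary_fields(coil, pts, dIdt=1.0)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        E2, _ = coil_primary_fields(coil, mirrored, dIdt=1.0)
        np.testing.assert_allclose(np.linalg.norm(E1, axis=1),
                                   np.linalg.norm(E2, axis=1), rtol=1e-8)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            build_figure8_coil(segments_per_turn=8)


class TestCoilFile:
    def test_round_trip(self, tmp_path):
        coil = build_figure8_coil(segments_per_turn=16)
        path = tmp_path / "c.txt"
        save_coil_file(coil, path)
        back = load_coil_file(path)
        np.testing.assert_allclose(back.positions, coil.positions, atol=1e-12)
        np.testing.assert_allclose(back.weights, coil.weights, atol=1e-12)
        assert back.representation == "electric"

    def test_single_line_file(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("# rttms-coil representation=magnetic units=mm name=dip\n"
                        "0 0 0 0 0 1\n")
        coil = load_coil_file(path)
        assert coil.n_elements == 1
        assert coil.representation == "magnetic"

    def test_missing_header_raises(self, tmp_path):
        path = tmp_path / "nohdr.txt"
        path.write_text("0 0 0 0 0 1\n")
        with pytest.raises(ValueError, match="header"):
            load_coil_file(path)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# rttms-coil representation=electric units=mm\n"
                        "0 0 0 0 0 1\n0 0 nope 0 0 1\n")
        with pytest.raises(ValueError, match="line 3"):
            load_coil_file(path)


class TestPrimaryFields:
    def test_single_element_hand_value(self):
        """E of one element w = z-hat (A*mm) at distance d on the x-axis."""
        coil = CoilModel([[0.0, 0, 0]], [[0.0, 0, 1]], "electric")
        d = 50.0
        dIdt = 1e6
        E, H = coil_primary_fields(coil, [[d, 0.0, 0.0]], dIdt=dIdt)
        expected = -MU0 * dIdt * 1e-3 / (4 * np.pi * d * 1e-3)
        np.testing.assert_allclose(E[0], [0.0, 0.0, expected], rtol=1e-12)
        # H = w x r / (4 pi r^3): z-hat x x-hat = y-hat
        h_expected = 1e-3 / (4 * np.pi * (d * 1e-3) ** 2)
        np.testing.assert_allclose(H[0], [0.0, h_expected, 0.0], rtol=1e-12)

    def test_small_loop_far_field_decay(self):
        """|H| of a closed loop decays as 1/r^3 (log-log slope -3 +/- 0.1)."""
        theta = np.linspace(0, 2 * np.pi, 41)
        pts = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta),
                               np.zeros_like(theta)])
        mid = 0.5 * (pts[1:] + pts[:-1])
        dl = pts[1:] - pts[:-1]
        coil = CoilModel(mid, dl, "electric")
        r = np.geomspace(100, 1000, 12)
        obs = np.column_stack([np.zeros_like(r), np.zeros_like(r), -r])
        _, H = coil_primary_fields(coil, obs, dIdt=1.0)
        mag = np.linalg.norm(H, axis=1)
        slope = np.polyfit(np.log(r), np.log(mag), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.1)

    def test_zero_didt(self):
        coil = build_figure8_coil(segments_per_turn=16)
        E, H = coil_primary_fields(coil, [[0.0, 0, -50]], dIdt=0.0)
        assert np.all(E == 0)
        assert np.linalg.norm(H) > 0

    def test_magnetic_dipole_fields(self):
        """Dipole H on-axis: |H| = m / (2 pi r^3); E circulates azimuthally."""
        coil = CoilModel([[0.0, 0, 0]], [[0.0, 0, 1.0]], "magnetic")  # m = 1 A*mm^2
        r = 20.0
        E, H = coil_primary_fields(coil, [[0.0, 0, r]], dIdt=1.0)
        m_si = 1e-6
        np.testing.assert_allclose(H[0], [0, 0, m_si / (2 * np.pi * (r * 1e-3) ** 3)],
                                   rtol=1e-12, atol=1e-18)
        E2, _ = coil_primary_fields(coil, [[r, 0.0, 0]], dIdt=1.0)
        expected = -MU0 * m_si / (4 * np.pi * (r * 1e-3) ** 2)
        np.testing.assert_allclose(E2[0], [0.0, expected, 0.0], rtol=1e-12, atol=1e-20)

    def test_singular_evaluation_rejected(self):
        coil = CoilModel([[0.0, 0, 0]], [[0.0, 0, 1]], "electric")
        with pytest.raises(ValueError):
            coil_primary_fields(coil, [[0.0, 0, 0]], dIdt=1.0)


class TestPlacement:
    def test_non_orthogonal_rejected(self):
        M = np.eye(4)
        M[0, 1] = 0.5
        with pytest.raises(ValueError):
            Placement(M)

    def test_reflection_rejected(self):
        M = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="improper"):
            Placement(M)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = [10.0, -5.0, 30.0]
        T = Placement(M)
        pts = rng.standard_normal((20, 3)) * 40
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)

    def test_tangential_placement_geometry(self):
        p = np.array([0.0, 0.0, 35.0])
        n = np.array([0.0, 0.0, 1.0])
        T = tangential_placement(p, n, standoff=5.0, angle=0.3)
        np.testing.assert_allclose(T.translation, [0, 0, 40.0])
        np.testing.assert_allclose(T.rotation[:, 2], n, atol=1e-12)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0)

    def test_transform_coil_rotates_weights(self):
        coil = CoilModel([[0.0, 0, 0]], [[1.0, 0, 0]], "electric")
        T = tangential_placement([0.0, 0, 35.0], [0.0, 0, 1.0], standoff=5.0)
        placed = transform_coil(coil, T)
        np.testing.assert_allclose(np.linalg.norm(placed.weights, axis=1), 1.0)
        np.testing.assert_allclose(placed.positions[0], [0, 0, 40.0])
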