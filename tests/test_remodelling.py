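"""Surface-remodelling rules: stimulus statistics, the update law, the
convergence criterion and loop-level properties."""

import numpy as np
import pytest

from osteoflux.geometry import build_initial_trabecula, central_width
from osteoflux.remodelling import (
    EmptyInfluenceDiscError,
    RemodellingParams,
    characteristic_velocity,
    characteristic_velocities,
    check_convergence,
    run_remodelling,
    update_positions,
)
from osteoflux.poroelastic import LoadPulse, solve_transient, standard_bcs


class _FakeResult:
    """Minimal stand-in for a transient result: a mesh plus a prescribed
    flux-magnitude history (synthetic; used to test the statistics only)."""

    def __init__(self, mesh, qmag):
        self.mesh = mesh
        self._qmag = qmag

    def flux_magnitude(self):
        return self._qmag


@pytest.fixture()
def tiny_result(coarse_mesh):
    n_inc = 10
    qmag = np.zeros((n_inc + 1, coarse_mesh.n_elements))
    return coarse_mesh, qmag, _FakeResult(coarse_mesh, qmag)


class TestCharacteristicVelocity:
    def test_constant_history_returns_value(self, tiny_result):
        mesh, qmag, res = tiny_result
        qmag[1:, :] = 3.3e-8
        v = characteristic_velocity(res, np.array([0.0, 0.5]), 0.05)
        assert v == pytest.approx(3.3e-8, rel=1e-12)

    def test_time_median_of_ramp_history(self, tiny_result):
        """One element with |q| history (0, 1, ..., 9) u has time median
        4.5 u."""
        mesh, qmag, res = tiny_result
        cent = mesh.element_centroids()
        point = np.array([0.0, 0.5])
        d = np.linalg.norm(cent - point, axis=1)
        target = np.argmin(d)
        radius = d[target] + 1e-6  # disc containing exactly this element
        assert (d <= radius).sum() == 1
        u = 2.0e-8
        qmag[1:, target] = np.arange(10) * u
        v = characteristic_velocity(res, point, radius)
        assert v == pytest.approx(4.5 * u, rel=1e-12)

    def test_empty_disc_raises(self, tiny_result):
        _, _, res = tiny_result
        with pytest.raises(EmptyInfluenceDiscError):
            characteristic_velocity(res, np.array([5.0, 5.0]), 0.01)

    def test_mirror_discs_equal_velocity(self, compression_result, plated_trabecula):
        """Symmetric axial load: a disc on the left spline and its mirror
        on the right spline carry equal characteristic velocities."""
        params = RemodellingParams(mesh_h=0.03)
        vel = characteristic_velocities(compression_result, plated_trabecula, params)
        np.testing.assert_allclose(vel[0], vel[1][:], rtol=1e-6)


class TestUpdateRule:
    params = RemodellingParams()

    def _one_point(self, v):
        g = build_initial_trabecula(1.0, 0.2)
        vel = np.full((2, 12), self.params.V_target)
        vel[1, 5] = v
        left, right, dx = update_positions(
            g.left_points, g.right_points, vel, self.params
        )
        return dx[1, 5], left, right, g

    def test_dead_band_no_motion(self):
        dx, left, right, g = self._one_point(self.params.V_target)
        assert dx == 0.0
        np.testing.assert_array_equal(left, g.left_points)
        np.testing.assert_array_equal(right, g.right_points)

    def test_apposition_step_scales_with_velocity(self):
        """V = 2 V_apposition = 1.04e-7 mm/s moves the point outward by
        0.005 * V / V_target = 0.0104 mm."""
        v = 2 * self.params.V_apposition
        dx, _, right, g = self._one_point(v)
        assert dx == pytest.approx(0.005 * v / self.params.V_target, rel=1e-12)
        assert dx == pytest.approx(0.0104, rel=1e-12)
        assert right[5, 0] == pytest.approx(g.right_points[5, 0] + 0.0104)

    def test_cap_at_max_displacement(self):
        dx, *_ = self._one_point(100 * self.params.V_target)
        assert dx == 0.05

    def test_resorption_moves_inward(self):
        dx, _, right, g = self._one_point(0.5 * self.params.V_resorption)
        assert dx < 0
        assert right[5, 0] < g.right_points[5, 0]

    def test_band_boundaries_move(self):
        """Points exactly at the thresholds remodel (V >= V_app deposits,
        V <= V_res resorbs)."""
        dx_app, *_ = self._one_point(self.params.V_apposition)
        dx_res, *_ = self._one_point(self.params.V_resorption)
        assert dx_app > 0
        assert dx_res < 0

    def test_left_side_outward_is_negative_x(self):
        g = build_initial_trabecula(1.0, 0.2)
        vel = np.full((2, 12), 2 * self.params.V_apposition)
        left, right, dx = update_positions(
            g.left_points, g.right_points, vel, self.params
        )
        assert (left[:, 0] < g.left_points[:, 0]).all()
        assert (right[:, 0] > g.right_points[:, 0]).all()
        assert (left[:, 1] == g.left_points[:, 1]).all()  # horizontal only


class TestConvergence:
    def test_identical_points_converged(self):
        pts = build_initial_trabecula(1.0, 0.2).left_points
        assert check_convergence(pts, pts, 0.2)

    def test_displacement_above_threshold(self):
        pts = build_initial_trabecula(1.0, 0.2).left_points
        moved = pts.copy()
        moved[3, 0] += 0.011
        assert not check_convergence(pts, moved, 0.2)  # 0.011 > 0.05*0.2

    def test_boundary_inclusive(self):
        pts = build_initial_trabecula(1.0, 0.2).left_points
        moved = pts + np.array([0.01, 0.0])
        assert check_convergence(pts, moved, 0.2)


class TestLoop:
    def test_dead_band_geometry_is_fixed_point(
        self, plated_trabecula, bone, f_target
    ):
        """With a huge lazy zone every stimulus is inside the band and the
        loop stops immediately with the geometry unchanged."""
        params = RemodellingParams(
            V_target=1e-7, V_apposition=1.0, V_resorption=1e-12, mesh_h=0.05,
            max_iterations=5,
        )
        pulse = LoadPulse(amplitude=f_target, theta=np.pi)
        hist = run_remodelling(plated_trabecula, bone, pulse, params)
        assert hist.n_iterations == 1
        assert hist.converged
        np.testing.assert_array_equal(
            hist.final_geometry.left_points, plated_trabecula.left_points
        )

    def test_displacement_cap_never_exceeded(self, plated_trabecula, bone, f_target):
        params = RemodellingParams(mesh_h=0.05, max_iterations=4)
        pulse = LoadPulse(amplitude=2 * f_target, theta=np.pi)
        hist = run_remodelling(plated_trabecula, bone, pulse, params)
        for dx in hist.displacements:
            assert np.abs(dx).max() <= 0.05 + 1e-15

    def test_mirror_loads_give_mirror_geometries(self, bone, f_target):
        """theta and pi - theta remodel into mirror images: the stimulus is
        |q| only."""
        from osteoflux.geometry import PlateDimensions

        geom = build_initial_trabecula(1.0, 0.2, 0.0, PlateDimensions())
        params = RemodellingParams(mesh_h=0.05, max_iterations=6)
        th = 3 * np.pi / 16
        h1 = run_remodelling(geom, bone, LoadPulse(f_target, th), params)
        h2 = run_remodelling(geom, bone, LoadPulse(f_target, np.pi - th), params)
        g1, g2 = h1.final_geometry, h2.final_geometry
        np.testing.assert_allclose(
            g1.left_points[:, 0], -g2.right_points[:, 0], atol=1e-6
        )
        np.testing.assert_allclose(
            g1.right_points[:, 0], -g2.left_points[:, 0], atol=1e-6
        )

    def test_determinism(self, plated_trabecula, bone, f_target):
        params = RemodellingParams(mesh_h=0.05, max_iterations=3)
        pulse = LoadPulse(amplitude=1.5 * f_target, theta=np.pi / 8)
        h1 = run_remodelling(plated_trabecula, bone, pulse, params)
        h2 = run_remodelling(plated_trabecula, bone, pulse, params)
        np.testing.assert_array_equal(
            h1.final_geometry.left_points, h2.final_geometry.left_points
        )
        np.testing.assert_array_equal(
            np.array(h1.velocities), np.array(h2.velocities)
        )


def test_params_validation():
    with pytest.raises(ValueError):
        RemodellingParams(V_target=1.0, V_apposition=0.9, V_resorption=0.8)
    with pytest.raises(ValueError):
        RemodellingParams(displacement_increment=0.1, max_displacement=0.05)
    p = RemodellingParams().scaled_band(1e-7)
    assert p.V_target == 1e-7
    assert p.V_apposition == pytest.approx(1.04e-7)
    assert p.V_resorption == pytest.approx(0.96e-7)
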