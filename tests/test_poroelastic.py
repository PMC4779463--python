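"""Transient Biot solver: oracles, linearity, symmetry and flux recovery."""

import numpy as np
import pytest

from osteoflux.consolidation import (
    consolidation_coefficient,
    loading_efficiency,
    terzaghi_reference,
)
from osteoflux.meshing import TRABECULA, rectangle_mesh
from osteoflux.poroelastic import (
    LoadPulse,
    column_bcs,
    darcy_flux,
    solve_transient,
    standard_bcs,
)


def test_zero_load_gives_zero_fields(coarse_mesh, bone):
    pulse = LoadPulse(amplitude=0.0, theta=np.pi)
    res = solve_transient(coarse_mesh, bone, pulse, standard_bcs(coarse_mesh, pulse))
    assert np.allclose(res.displacement, 0.0)
    assert np.allclose(res.pressure, 0.0)
    assert np.allclose(res.flux, 0.0)


def test_linearity_in_amplitude(coarse_mesh, bone, f_target, compression_result):
    """Doubling the load doubles displacement, pressure and flux fields."""
    pulse2 = LoadPulse(amplitude=2 * f_target, theta=np.pi)
    res2 = solve_transient(coarse_mesh, bone, pulse2, standard_bcs(coarse_mesh, pulse2))
    np.testing.assert_allclose(
        res2.displacement, 2 * compression_result.displacement, atol=1e-12
    )
    np.testing.assert_allclose(
        res2.pressure, 2 * compression_result.pressure, atol=1e-12
    )
    np.testing.assert_allclose(res2.flux, 2 * compression_result.flux, atol=1e-18)


def test_tension_compression_antisymmetry(coarse_mesh, bone, f_target, compression_result):
    """theta = 0 and theta = pi at equal amplitude give fields of equal
    magnitude and opposite sign (the coupled system is linear)."""
    pulse = LoadPulse(amplitude=f_target, theta=0.0)
    res = solve_transient(coarse_mesh, bone, pulse, standard_bcs(coarse_mesh, pulse))
    scale = np.abs(compression_result.pressure).max()
    np.testing.assert_allclose(
        res.pressure, -compression_result.pressure, atol=1e-5 * scale
    )
    uscale = np.abs(compression_result.displacement).max()
    np.testing.assert_allclose(
        res.displacement, -compression_result.displacement, atol=1e-5 * uscale
    )


def test_mirror_angle_symmetry(coarse_mesh, bone, f_target):
    """theta and pi - theta mirror each other: |q| fields coincide after
    reflecting elements about the axis."""
    th = 3 * np.pi / 16
    p1 = LoadPulse(amplitude=f_target, theta=th)
    p2 = LoadPulse(amplitude=f_target, theta=np.pi - th)
    r1 = solve_transient(coarse_mesh, bone, p1, standard_bcs(coarse_mesh, p1))
    r2 = solve_transient(coarse_mesh, bone, p2, standard_bcs(coarse_mesh, p2))
    cent = coarse_mesh.element_centroids()
    trab = coarse_mesh.domain == TRABECULA
    q1 = r1.flux_magnitude()[-2, trab]
    q2 = r2.flux_magnitude()[-2, trab]
    # match each element to its mirror image about x1 = 0
    mirrored = cent[trab] * np.array([-1.0, 1.0])
    idx = np.array(
        [np.argmin(np.linalg.norm(cent[trab] - mc, axis=1)) for mc in mirrored]
    )
    np.testing.assert_allclose(q1, q2[idx], rtol=1e-4, atol=1e-5 * q1.max())


def test_pressure_zero_on_free_flow_edges(compression_result):
    """Lateral (drained) nodes hold p = 0 at every increment; the junction
    corner nodes belong to the sealed plate interface and are exempt."""
    mesh = compression_result.mesh
    free = np.union1d(mesh.node_sets["left_spline"], mesh.node_sets["right_spline"])
    junction = np.union1d(
        mesh.node_sets["trab_bottom_edge"], mesh.node_sets["trab_top_edge"]
    )
    free = np.setdiff1d(free, junction)
    assert np.allclose(compression_result.pressure[:, free], 0.0)


def test_initial_state_is_zero(compression_result):
    assert np.allclose(compression_result.displacement[0], 0.0)
    assert np.allclose(compression_result.pressure[0], 0.0)


def test_darcy_flux_from_linear_pressure_field(bone_intrinsic):
    """An imposed linear pressure field with unit gradient gives
    |q| = kappa/mu = 1e-5 mm/s at every element centroid."""
    from osteoflux import fem

    mesh = rectangle_mesh(0.2, 0.2, 0.05)
    p = mesh.nodes[:, 0] * 1.0  # grad p = (1, 0) N/mm^2 per mm
    xy = mesh.nodes[mesh.quads]
    grads = fem.q4_centroid_gradients(xy)
    gp = np.einsum("maj,ma->mj", grads, p[mesh.quads])
    q = -bone_intrinsic.mobility * gp
    np.testing.assert_allclose(q[:, 0], -1e-5, rtol=1e-12)
    np.testing.assert_allclose(q[:, 1], 0.0, atol=1e-18)


def test_uniform_pressure_gives_zero_flux(coarse_mesh, bone):
    from osteoflux import fem

    trab = coarse_mesh.domain == TRABECULA
    xy = coarse_mesh.nodes[coarse_mesh.quads[trab]]
    grads = fem.q4_centroid_gradients(xy)
    p = np.full(coarse_mesh.n_nodes, 3.7)
    gp = np.einsum("maj,ma->mj", grads, p[coarse_mesh.quads[trab]])
    np.testing.assert_allclose(gp, 0.0, atol=1e-9)


class TestTerzaghiOracle:
    def test_limits(self, bone_intrinsic):
        """t -> 0 gives the uniform undrained pressure; t -> infinity
        drains everywhere."""
        z, p = terzaghi_reference(1.0, bone_intrinsic, 1.0, [0.0, 1e4], n_terms=5000)
        p0 = loading_efficiency(bone_intrinsic)
        assert np.allclose(p[0, 10:], p0, rtol=5e-3)  # away from the drain
        assert np.allclose(p[1], 0.0, atol=1e-12)

    def test_series_truncation_converged(self, bone_intrinsic):
        c = consolidation_coefficient(bone_intrinsic)
        t = 0.1 / c  # dimensionless time 0.1
        _, p200 = terzaghi_reference(1.0, bone_intrinsic, 1.0, [t], n_terms=200)
        _, p50 = terzaghi_reference(1.0, bone_intrinsic, 1.0, [t], n_terms=50)
        np.testing.assert_allclose(p200, p50, atol=1e-12)

    def test_fe_column_matches_series(self, bone_intrinsic):
        """The Biot FE solution of the 1D-surrogate column matches the
        consolidation series within 1 % in the L2 norm."""
        mesh = rectangle_mesh(0.06, 1.0, 0.02)
        sigma = 1.0
        pulse = LoadPulse(
            amplitude=0.0, theta=np.pi, total_time=1.0, increment=0.02, profile="step"
        )
        res = solve_transient(mesh, bone_intrinsic, pulse, column_bcs(mesh, sigma))
        left = mesh.node_sets["left"]
        order = np.argsort(mesh.nodes[left, 1])
        left = left[order]
        z = 1.0 - mesh.nodes[left, 1]
        for t in (0.2, 0.5, 1.0):
            i = int(round(t / 0.02))
            _, pref = terzaghi_reference(1.0, bone_intrinsic, sigma, [t], z=z)
            err = np.linalg.norm(res.pressure[i][left] - pref[0]) / np.linalg.norm(
                pref[0]
            )
            assert err < 0.01, f"t={t}: {err:.3%}"


def test_spatial_convergence_toward_oracle(bone_intrinsic):
    """Halving h reduces the consolidation error (first-order elements in
    the pressure gradient, monotone refinement)."""
    errs = []
    for h in (0.1, 0.05):
        mesh = rectangle_mesh(0.06, 1.0, hx=0.03, hy=h)
        pulse = LoadPulse(
            amplitude=0.0, theta=np.pi, total_time=0.5, increment=0.005, profile="step"
        )
        res = solve_transient(mesh, bone_intrinsic, pulse, column_bcs(mesh, 1.0))
        left = mesh.node_sets["left"]
        order = np.argsort(mesh.nodes[left, 1])
        left = left[order]
        z = 1.0 - mesh.nodes[left, 1]
        _, pref = terzaghi_reference(1.0, bone_intrinsic, 1.0, [0.5], z=z)
        errs.append(
            np.linalg.norm(res.pressure[-1][left] - pref[0])
            / np.linalg.norm(pref[0])
        )
    assert errs[1] < errs[0]


def test_mesh_convergence_of_pressure_field(plated_trabecula, bone_intrinsic, f_target):
    """Refining from h = 0.015 to h = 0.0075 changes the peak-load pressure
    field by less than 2 % (L2, compared on the coarse nodes).  Run with the
    intrinsic permeability, whose drainage layer the mesh resolves."""
    bone = bone_intrinsic
    from osteoflux.meshing import generate_mesh
    from scipy.interpolate import LinearNDInterpolator

    pulse = LoadPulse(amplitude=f_target, theta=np.pi)
    fields = {}
    for h in (0.015, 0.0075):
        mesh = generate_mesh(plated_trabecula, h=h)
        res = solve_transient(mesh, bone, pulse, standard_bcs(mesh, pulse))
        tn = mesh.trabecula_nodes()
        fields[h] = (mesh.nodes[tn], res.pressure[5][tn])  # peak-load increment
    pts_c, p_c = fields[0.015]
    pts_f, p_f = fields[0.0075]
    interp = LinearNDInterpolator(pts_f, p_f)
    p_f_on_c = interp(pts_c)
    ok = np.isfinite(p_f_on_c)
    diff = np.linalg.norm(p_f_on_c[ok] - p_c[ok]) / np.linalg.norm(p_f_on_c[ok])
    assert diff < 0.02


def test_darcy_flux_accessor(compression_result):
    q = darcy_flux(compression_result, 0, 5)
    assert q.shape == (2,)
    np.testing.assert_array_equal(q, compression_result.flux[5, 0])


def test_load_pulse_validation():
    with pytest.raises(ValueError):
        LoadPulse(amplitude=-1.0)
    with pytest.raises(ValueError):
        LoadPulse(amplitude=1.0, theta=4.0)
    with pytest.raises(ValueError):
        LoadPulse(amplitude=1.0, total_time=1.0, increment=0.3)
    p = LoadPulse(amplitude=1.0, theta=np.pi / 2)
    assert p.factor(0.5) == pytest.approx(1.0)
    assert p.factor(0.25) == pytest.approx(0.5)
    assert p.factor(1.0) == pytest.approx(0.0)
    assert p.n_increments == 10
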