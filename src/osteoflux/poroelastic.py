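"""Transient 2D Biot poroelasticity on a fixed mesh.

One load pulse is applied to the trabecula-plus-plates assembly and the fully
coupled displacement / pore-pressure problem is integrated with backward
Euler over equal increments.  The trabecula is meshed with equal-order
4-node u-p plane-strain elements (with an optional fluid-pressure-Laplacian
stabilisation against spurious pressure modes at small time steps); the
plates are drained plane-stress elastic.

Discrete system per increment (monolithic, symmetric):

    [ K   -C ] [u]   [ f(t) ]
    [-C^T -(S + beta L + dt H)] [p] = [-C^T u0 - (S + beta L) p0]

with K the drained stiffness, C the coupling, S the storage, H the
permeability (Darcy) matrix and L the stabilisation Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import fem
from .materials import ElasticMaterial, PoroelasticMaterial
from .meshing import Mesh, TRABECULA

__all__ = [
    "LoadPulse",
    "BoundaryConditions",
    "TransientFieldResult",
    "solve_transient",
    "darcy_flux",
    "standard_bcs",
    "column_bcs",
    "SolverError",
]


class SolverError(RuntimeError):
    """Singular or non-convergent linear system."""


@dataclass(frozen=True)
class LoadPulse:
    """A load pulse of amplitude ``amplitude`` (N) applied at angle ``theta``
    (rad, measured from the vertical +x2 axis; theta = 0 pulls upward /
    tension, theta = pi pushes downward / compression).

    ``profile`` is the time course of the load factor over ``total_time``:
    'triangular' ramps linearly to the amplitude over the first half of the
    step and back to zero over the second half; 'ramp' grows linearly to the
    amplitude; 'step' holds the full amplitude throughout.
    """

    amplitude: float
    theta: float = 0.0
    total_time: float = 1.0
    increment: float = 0.1
    profile: str = "triangular"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.theta <= np.pi:
            raise ValueError("theta must lie in [0, pi]")
        n = self.total_time / self.increment
        if abs(n - round(n)) > 1e-9:
            raise ValueError("increment must divide total time")
        if self.profile not in ("triangular", "ramp", "step"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def n_increments(self) -> int:
        return int(round(self.total_time / self.increment))

    @property
    def direction(self) -> np.ndarray:
        """Unit load direction (sin theta, cos theta)."""
        return np.array([np.sin(self.theta), np.cos(self.theta)])

    def factor(self, t: float) -> float:
        """Dimensionless load factor at time t."""
        s = t / self.total_time
        if self.profile == "triangular":
            return float(np.clip(min(2 * s, 2 - 2 * s), 0.0, 1.0))
        if self.profile == "ramp":
            return float(np.clip(s, 0.0, 1.0))
        return 1.0


@dataclass
class BoundaryConditions:
    """Kinematic and flow boundary conditions plus applied nodal loads.

    ``nodal_forces`` are (node indices, per-node force vector) pairs applied
    at full amplitude; the solver scales them by the pulse's load factor.
    No-flow boundaries are natural (no entry needed).
    """

    fixed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    uniaxial: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    shared_component: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    rigid_along: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    zero_pressure: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    nodal_forces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class TransientFieldResult:
    """Per-increment nodal and element fields of one transient solve.

    ``displacement`` (n_inc+1, N, 2) mm and ``pressure`` (n_inc+1, N) N/mm^2
    include the zero initial state at index 0.  ``flux`` (n_inc+1, M, 2)
    holds the Darcy flux vector q = -(kappa/mu) grad p at each element
    centroid (zero for plate elements).
    """

    mesh: Mesh
    material: PoroelasticMaterial
    pulse: LoadPulse
    times: np.ndarray
    displacement: np.ndarray
    pressure: np.ndarray
    flux: np.ndarray

    def flux_magnitude(self) -> np.ndarray:
        """|q| per increment and element, (n_inc+1, M)."""
        return np.linalg.norm(self.flux, axis=2)

    def peak_flux(self) -> float:
        """Peak Darcy flux magnitude over all elements and increments, mm/s."""
        return float(self.flux_magnitude().max())

    def strain(self, increment: int) -> np.ndarray:
        """Centroid strains (eps_11, eps_22, gamma_12) per element, (M, 3)."""
        xy = self.mesh.nodes[self.mesh.quads]
        grads = fem.q4_centroid_gradients(xy)
        ue = self.displacement[increment][self.mesh.quads]  # (M, 4, 2)
        e11 = np.einsum("ma,ma->m", grads[:, :, 0], ue[:, :, 0])
        e22 = np.einsum("ma,ma->m", grads[:, :, 1], ue[:, :, 1])
        g12 = np.einsum("ma,ma->m", grads[:, :, 1], ue[:, :, 0]) + np.einsum(
            "ma,ma->m", grads[:, :, 0], ue[:, :, 1]
        )
        return np.column_stack([e11, e22, g12])

    def zeta(self, increment: int) -> np.ndarray:
        """Variation of fluid content per trabecula element (centroid)."""
        strain = self.strain(increment)
        p_c = self.pressure[increment][self.mesh.quads].mean(axis=1)
        z = p_c / self.material.M + self.material.alpha * (strain[:, 0] + strain[:, 1])
        z[self.mesh.domain != TRABECULA] = 0.0
        return z

    def stress(self, increment: int, effective: bool = False) -> np.ndarray:
        """Centroid stress (sigma_11, sigma_22, sigma_12) per element.

        Plane-strain Biot total stress sigma = sigma' - alpha p I in the
        trabecula; plane-stress elastic in the plates."""
        mat = self.material
        strain = self.strain(increment)
        d_ps = fem.elastic_D(mat.E, mat.nu, "strain")
        d_pl = fem.elastic_D(mat.E, mat.nu, "stress")
        trab = self.mesh.domain == TRABECULA
        out = np.where(trab[:, None], strain @ d_ps.T, strain @ d_pl.T)
        if not effective:
            p_c = self.pressure[increment][self.mesh.quads].mean(axis=1)
            out[trab, 0] -= mat.alpha * p_c[trab]
            out[trab, 1] -= mat.alpha * p_c[trab]
        return out


def darcy_flux(
    result: TransientFieldResult, element: int, increment: int
) -> np.ndarray:
    """Element-centroid Darcy flux vector q = -(kappa/mu) grad p, mm/s."""
    return result.flux[increment, element]


def standard_bcs(mesh: Mesh, pulse: LoadPulse) -> BoundaryConditions:
    """Study boundary conditions for the plated trabecula.

    Bottom edge of the bottom plate fixed; every top-plate node may displace
    only along the load direction; the load is split evenly over the
    top-plate top-edge nodes; pore pressure is zero on the trabecula lateral
    edges (free flow) and no-flow holds at the plate junctions.
    """
    d = pulse.direction
    top_nodes = mesh.node_sets["plate_top_edge"]
    n = len(top_nodes)
    lateral = np.union1d(
        mesh.node_sets["left_spline"], mesh.node_sets["right_spline"]
    )
    # the junction corner nodes belong to both the drained lateral edges and
    # the sealed plate junctions; treat them as sealed (no-flow wins at the
    # corner, avoiding an artificial drainage spike at the re-entrant corner)
    junctions = np.union1d(
        mesh.node_sets["trab_bottom_edge"], mesh.node_sets["trab_top_edge"]
    )
    return BoundaryConditions(
        fixed=mesh.node_sets["plate_bottom_edge"],
        uniaxial=[(mesh.node_sets["top_plate_nodes"], d)],
        zero_pressure=np.setdiff1d(lateral, junctions),
        nodal_forces=[(top_nodes, pulse.amplitude / n * d)],
    )


def column_bcs(
    mesh: Mesh, applied_stress: float, drained: str = "top"
) -> BoundaryConditions:
    """1D consolidation column: rollers on the lateral sides and bottom,
    vertical traction on the top edge, drainage on one edge only."""
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.0, 1.0])
    sides = np.union1d(mesh.node_sets["left"], mesh.node_sets["right"])
    top = mesh.node_sets["top"]
    x = np.sort(mesh.nodes[top, 0])
    hx = np.diff(x).mean()
    forces = np.full((len(top), 2), 0.0)
    forces[:, 1] = -applied_stress * hx
    # trapezoidal rule: end nodes carry half a tributary width
    order = np.argsort(mesh.nodes[top, 0])
    forces[order[0], 1] = -applied_stress * hx / 2
    forces[order[-1], 1] = -applied_stress * hx / 2
    bcs = BoundaryConditions(
        uniaxial=[(sides, e2), (mesh.node_sets["bottom"], e1)],
        zero_pressure=mesh.node_sets[drained],
        nodal_forces=[(top, forces)],
    )
    return bcs


def _element_areas(xy: np.ndarray) -> np.ndarray:
    x = xy[:, :, 0]
    y = xy[:, :, 1]
    return 0.5 * np.abs(
        np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1)
    )


def solve_transient(
    mesh: Mesh,
    material: PoroelasticMaterial,
    pulse: LoadPulse,
    bcs: BoundaryConditions,
    plate_material: ElasticMaterial | None = None,
    stabilized: bool = True,
) -> TransientFieldResult:
    """Backward-Euler integration of the coupled u-p problem for one pulse.

    The system matrix is factorised once and reused for all increments.
    Raises :class:`SolverError` if the constrained system is singular.
    """
    if plate_material is None:
        plate_material = material.drained()

    n_nodes = mesh.n_nodes
    xy = mesh.nodes[mesh.quads]
    trab = mesh.domain == TRABECULA

    # --- displacement stiffness ---------------------------------------
    udofs = np.empty((mesh.n_elements, 8), dtype=int)
    udofs[:, 0::2] = 2 * mesh.quads
    udofs[:, 1::2] = 2 * mesh.quads + 1
    ke = np.zeros((mesh.n_elements, 8, 8))
    if trab.any():
        d_tr = fem.elastic_D(material.E, material.nu, "strain")
        ke[trab] = fem.q4_stiffness(xy[trab], d_tr)
    if (~trab).any():
        d_pl = fem.elastic_D(plate_material.E, plate_material.nu, "stress")
        ke[~trab] = fem.q4_stiffness(xy[~trab], d_pl)
    K = fem.assemble(2 * n_nodes, udofs, ke)

    # --- pressure DOFs on trabecula nodes -----------------------------
    pnodes = mesh.trabecula_nodes()
    n_p = len(pnodes)
    pmap = np.full(n_nodes, -1, dtype=int)
    pmap[pnodes] = np.arange(n_p)

    area = _element_areas(xy[trab])
    confined = material.lam + 2.0 * material.G
    beta = material.alpha**2 * area / (4.0 * confined) if stabilized else 0.0
    C_e, S_e, H_e = fem.q4_biot_matrices(
        xy[trab], material.alpha, 1.0 / material.M, material.mobility, beta
    )
    pdofs = pmap[mesh.quads[trab]]
    C = fem.assemble_rect(2 * n_nodes, n_p, udofs[trab], pdofs, C_e)
    S = fem.assemble(n_p, pdofs, S_e)
    H = fem.assemble(n_p, pdofs, H_e)

    # --- constraints ---------------------------------------------------
    cons = fem.Constraints(
        n_nodes=n_nodes,
        fixed=np.asarray(bcs.fixed, dtype=int),
        uniaxial=bcs.uniaxial,
        shared_component=bcs.shared_component,
        rigid_along=bcs.rigid_along,
    )
    Tu = cons.transformation()
    p_dirichlet = pmap[np.asarray(bcs.zero_pressure, dtype=int)]
    p_dirichlet = p_dirichlet[p_dirichlet >= 0]
    keep = np.setdiff1d(np.arange(n_p), p_dirichlet)
    Tp = sp.coo_matrix(
        (np.ones(len(keep)), (keep, np.arange(len(keep)))), shape=(n_p, len(keep))
    ).tocsr()
    T = sp.block_diag([Tu, Tp], format="csr")

    dt = pulse.increment
    Sdt = S  # storage + stabilisation already folded together
    A = sp.bmat([[K, -C], [-C.T, -(Sdt + dt * H)]], format="csc")
    Ared = (T.T @ A @ T).tocsc()
    try:
        lu = splu(Ared)
    except RuntimeError as exc:  # pragma: no cover - singular assembly
        raise SolverError(f"singular constrained system: {exc}") from exc

    f_full = np.zeros(2 * n_nodes)
    for nodes, force in bcs.nodal_forces:
        nodes = np.atleast_1d(nodes)
        force = np.asarray(force, dtype=float)
        if force.ndim == 1:
            force = np.broadcast_to(force, (len(nodes), 2))
        np.add.at(f_full, 2 * nodes, force[:, 0])
        np.add.at(f_full, 2 * nodes + 1, force[:, 1])

    n_inc = pulse.n_increments
    times = np.arange(n_inc + 1) * dt
    u = np.zeros((n_inc + 1, n_nodes, 2))
    p = np.zeros((n_inc + 1, n_nodes))
    u_prev = np.zeros(2 * n_nodes)
    p_prev = np.zeros(n_p)
    for i in range(1, n_inc + 1):
        b = np.concatenate(
            [f_full * pulse.factor(times[i]), -(C.T @ u_prev) - Sdt @ p_prev]
        )
        x = lu.solve(T.T @ b)
        if not np.all(np.isfinite(x)):
            raise SolverError(f"non-finite solution at increment {i}")
        full = T @ x
        u_prev = full[: 2 * n_nodes]
        p_prev = full[2 * n_nodes :]
        u[i] = u_prev.reshape(-1, 2)
        p[i, pnodes] = p_prev

    # --- centroid Darcy fluxes ----------------------------------------
    flux = np.zeros((n_inc + 1, mesh.n_elements, 2))
    grads = fem.q4_centroid_gradients(xy[trab])  # (Mt, 4, 2)
    conn_tr = mesh.quads[trab]
    mob = material.mobility
    for i in range(1, n_inc + 1):
        pe = p[i][conn_tr]  # (Mt, 4)
        gp = np.einsum("maj,ma->mj", grads, pe)
        flux[i, trab] = -mob * gp

    return TransientFieldResult(
        mesh=mesh,
        material=material,
        pulse=pulse,
        times=times,
        displacement=u,
        pressure=p,
        flux=flux,
    )
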