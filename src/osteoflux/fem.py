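"""Low-level finite-element kernels: batched 4-node quadrilateral matrices
for plane elasticity and Biot poroelasticity, plus linear multi-point
constraint handling via a sparse transformation matrix.

All element integrals use 2 x 2 Gauss quadrature; gradients for flux
recovery are evaluated at the element centre.  Everything is vectorised over
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "elastic_D",
    "q4_stiffness",
    "q4_biot_matrices",
    "q4_centroid_gradients",
    "Constraints",
]

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS = [(xi, eta) for eta in _GP for xi in _GP]  # weight 1 each


def _shape(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Q4 shape functions and parent-space gradients at (xi, eta)."""
    n = 0.25 * np.array(
        [
            (1 - xi) * (1 - eta),
            (1 + xi) * (1 - eta),
            (1 + xi) * (1 + eta),
            (1 - xi) * (1 + eta),
        ]
    )
    dn = 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )
    return n, dn


def elastic_D(E: float, nu: float, plane: str) -> np.ndarray:
    """Constitutive matrix for plane strain or plane stress (Voigt 3x3)."""
    if plane == "strain":
        c = E / ((1 + nu) * (1 - 2 * nu))
        return c * np.array(
            [[1 - nu, nu, 0.0], [nu, 1 - nu, 0.0], [0.0, 0.0, (1 - 2 * nu) / 2]]
        )
    if plane == "stress":
        c = E / (1 - nu**2)
        return c * np.array([[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2]])
    raise ValueError(f"plane must be 'strain' or 'stress', got {plane!r}")


def _grads_and_det(xy: np.ndarray, xi: float, eta: float):
    """Physical shape-function gradients and |J| at one Gauss point.

    xy : (M, 4, 2) element corner coordinates.
    Returns grads (M, 4, 2) and det (M,).
    """
    _, dn = _shape(xi, eta)
    jac = np.einsum("ak,maj->mkj", dn, xy)  # (M, 2, 2)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    grads = np.einsum("ak,mkj->maj", dn, inv)  # dN_a/dx_j
    return grads, det


def q4_stiffness(xy: np.ndarray, D: np.ndarray, thickness: float = 1.0) -> np.ndarray:
    """Batched Q4 stiffness matrices (M, 8, 8) for one constitutive matrix."""
    m = xy.shape[0]
    ke = np.zeros((m, 8, 8))
    for xi, eta in _GAUSS:
        grads, det = _grads_and_det(xy, xi, eta)
        b = np.zeros((m, 3, 8))
        b[:, 0, 0::2] = grads[:, :, 0]
        b[:, 1, 1::2] = grads[:, :, 1]
        b[:, 2, 0::2] = grads[:, :, 1]
        b[:, 2, 1::2] = grads[:, :, 0]
        ke += np.einsum("mia,ij,mjb,m->mab", b, D, b, det) * thickness
    return ke


def q4_biot_matrices(
    xy: np.ndarray,
    alpha: float,
    inv_M: float,
    mobility: float,
    stab_beta: np.ndarray | float = 0.0,
):
    """Batched Biot element matrices for equal-order u-p quadrilaterals.

    Returns
    -------
    C : (M, 8, 4) coupling, int alpha * div(Nu) * Np.
    S : (M, 4, 4) storage, int (1/M) Np Np^T, with the optional
        pressure-Laplacian stabilisation `stab_beta * int grad Np grad Np^T`
        folded in (applies to the pressure increment, see the solver).
    H : (M, 4, 4) permeability, int (kappa/mu) grad Np grad Np^T.
    """
    m = xy.shape[0]
    c = np.zeros((m, 8, 4))
    s = np.zeros((m, 4, 4))
    h = np.zeros((m, 4, 4))
    beta = np.broadcast_to(np.asarray(stab_beta, dtype=float), (m,))
    for xi, eta in _GAUSS:
        n, _ = _shape(xi, eta)
        grads, det = _grads_and_det(xy, xi, eta)
        bvol = np.zeros((m, 8))
        bvol[:, 0::2] = grads[:, :, 0]
        bvol[:, 1::2] = grads[:, :, 1]
        c += alpha * np.einsum("ma,b,m->mab", bvol, n, det)
        nn = np.outer(n, n)
        lap = np.einsum("maj,mbj,m->mab", grads, grads, det)
        s += inv_M * nn[None, :, :] * det[:, None, None] + beta[:, None, None] * lap
        h += mobility * lap
    return c, s, h


def q4_centroid_gradients(xy: np.ndarray):
    """Shape-function gradients at the element centre, (M, 4, 2)."""
    grads, _ = _grads_and_det(xy, 0.0, 0.0)
    return grads


def assemble(n_dofs: int, dofs: np.ndarray, ke: np.ndarray) -> sp.csr_matrix:
    """Assemble batched element matrices.

    dofs : (M, k) global DOF indices per element row/col.
    ke : (M, k, k) element matrices.
    """
    m, k = dofs.shape
    rows = np.repeat(dofs, k, axis=1).ravel()
    cols = np.tile(dofs, (1, k)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dofs, n_dofs)).tocsr()


def assemble_rect(
    n_rows: int, n_cols: int, row_dofs: np.ndarray, col_dofs: np.ndarray, ke: np.ndarray
) -> sp.csr_matrix:
    """Assemble a rectangular coupling block (row_dofs (M,a), col_dofs (M,b))."""
    m, a = row_dofs.shape
    b = col_dofs.shape[1]
    rows = np.repeat(row_dofs, b, axis=1).ravel()
    cols = np.tile(col_dofs, (1, a)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_rows, n_cols)).tocsr()


@dataclass
class Constraints:
    """Linear kinematic constraints on nodal displacement DOFs.

    The admissible displacement space is expressed as ``u = T x`` with ``T``
    sparse; the reduced system is ``T^T A T x = T^T b``.

    Constraint kinds (applied in order; later kinds skip already-handled
    nodes, and a node claimed by two different `uniaxial` directions is
    fully fixed):

    - ``fixed``: both displacement components zero.
    - ``uniaxial``: the node may translate only along a given unit direction
      (one free scalar per node).
    - ``shared_component``: one scalar shared by a node group for the
      displacement component along a given unit direction; the orthogonal
      component stays free per node (a frictionless rigid platen).
    - ``rigid_along``: the whole node group translates together along a
      given unit direction with one shared scalar; the orthogonal
      component is zero (a rigid bonded platen).
    """

    n_nodes: int
    fixed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    uniaxial: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    shared_component: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    rigid_along: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def transformation(self) -> sp.csr_matrix:
        n_full = 2 * self.n_nodes
        fixed = set(int(n) for n in np.atleast_1d(self.fixed))
        uni: dict[int, np.ndarray] = {}
        for nodes, d in self.uniaxial:
            d = np.asarray(d, float)
            d = d / np.linalg.norm(d)
            for n in np.atleast_1d(nodes):
                n = int(n)
                if n in fixed:
                    continue
                if n in uni and not np.allclose(uni[n], d):
                    fixed.add(n)  # two independent directions pin the node
                    uni.pop(n)
                else:
                    uni[n] = d
        shared: list[tuple[list[int], np.ndarray, bool]] = []
        claimed = set(fixed) | set(uni)
        for groups, free_perp in (
            (self.shared_component, True),
            (self.rigid_along, False),
        ):
            for nodes, d in groups:
                d = np.asarray(d, float)
                d = d / np.linalg.norm(d)
                members = [
                    int(n) for n in np.atleast_1d(nodes) if int(n) not in claimed
                ]
                claimed.update(members)
                shared.append((members, d, free_perp))

        rows, cols, vals = [], [], []
        col = 0
        for n in range(self.n_nodes):
            if n in fixed:
                continue
            if n in uni:
                d = uni[n]
                rows += [2 * n, 2 * n + 1]
                cols += [col, col]
                vals += [d[0], d[1]]
                col += 1
                continue
            in_shared = None
            for k, (members, d, free_perp) in enumerate(shared):
                if n in members:
                    in_shared = (k, d, free_perp)
                    break
            if in_shared is not None:
                k, d, free_perp = in_shared
                if free_perp:
                    perp = np.array([-d[1], d[0]])
                    # free orthogonal scalar for this node
                    rows += [2 * n, 2 * n + 1]
                    cols += [col, col]
                    vals += [perp[0], perp[1]]
                    col += 1
                continue
            rows += [2 * n, 2 * n + 1]
            cols += [col, col + 1]
            vals += [1.0, 1.0]
            col += 2
        # one shared column per platen group
        self._shared_cols = []
        for members, d, _free_perp in shared:
            for n in members:
                rows += [2 * n, 2 * n + 1]
                cols += [col, col]
                vals += [d[0], d[1]]
            self._shared_cols.append(col)
            col += 1
        return sp.coo_matrix((vals, (rows, cols)), shape=(n_full, col)).tocsr()
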