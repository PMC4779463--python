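"""Structured quadrilateral meshing of the trabecula-plus-plates region.

The trabecula is meshed by transfinite interpolation between its two lateral
boundary splines: mesh rows follow the spline parameter, columns blend
linearly between the left and right boundary.  The end plates are meshed as
structured blocks whose inner edge contains exactly the trabecula's end-row
nodes, so the tied trabecula-plate interface reduces to node sharing.

Meshing is fully deterministic: the same geometry and target edge length
always produce the same mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TrabeculaGeometry

__all__ = ["Mesh", "MeshingError", "generate_mesh", "rectangle_mesh"]

# element domain codes
TRABECULA = 0
BOTTOM_PLATE = 1
TOP_PLATE = 2


class MeshingError(RuntimeError):
    """Meshing failure; carries the offending geometry for diagnostics."""

    def __init__(self, message: str, geometry: TrabeculaGeometry | None = None):
        super().__init__(message)
        self.geometry = geometry


@dataclass
class Mesh:
    """Conforming 4-node quadrilateral mesh with tagged node sets.

    Attributes
    ----------
    nodes : (N, 2) float array of coordinates, mm.
    quads : (M, 4) int array of anticlockwise connectivity.
    domain : (M,) int array; 0 = trabecula, 1 = bottom plate, 2 = top plate.
    node_sets : named node-index arrays (boundary tags).
    h : target edge length used to build the mesh, mm.
    """

    nodes: np.ndarray
    quads: np.ndarray
    domain: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    h: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.quads.shape[0]

    def element_centroids(self) -> np.ndarray:
        """(M, 2) array of element centroids."""
        return self.nodes[self.quads].mean(axis=1)

    def jacobians(self) -> np.ndarray:
        """(M, 4) corner Jacobian determinants (positive for valid quads)."""
        xy = self.nodes[self.quads]  # (M, 4, 2)
        jac = np.empty((xy.shape[0], 4))
        for c in range(4):
            p = xy[:, c]
            nxt = xy[:, (c + 1) % 4] - p
            prv = xy[:, (c - 1) % 4] - p
            jac[:, c] = nxt[:, 0] * prv[:, 1] - nxt[:, 1] * prv[:, 0]
        return jac

    def trabecula_nodes(self) -> np.ndarray:
        """Sorted indices of nodes belonging to at least one trabecula
        element (the nodes that carry a pore-pressure DOF)."""
        return np.unique(self.quads[self.domain == TRABECULA])


def _merge_nodes(
    blocks: list[np.ndarray],
    tol: float = 1e-9,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Concatenate node blocks, merging coincident nodes.

    Returns the merged (N, 2) array and, per block, the map from local to
    global node index.
    """
    allnodes = np.vstack(blocks)
    key = np.round(allnodes / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # keep deterministic ordering: order unique nodes by first occurrence
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    merged = allnodes[first[order]]
    inverse = rank[inverse]
    maps, start = [], 0
    for b in blocks:
        maps.append(inverse[start : start + len(b)])
        start += len(b)
    return merged, maps


def _grid_quads(n_rows: int, n_cols: int) -> np.ndarray:
    """Connectivity of an (n_rows+1) x (n_cols+1) node grid, row-major."""
    j, i = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    n0 = j * (n_cols + 1) + i
    return np.stack(
        [n0, n0 + 1, n0 + n_cols + 2, n0 + n_cols + 1], axis=-1
    ).reshape(-1, 4)


def _plate_x_coords(
    junction_x: np.ndarray, x_min: float, x_max: float, spacing: float
) -> np.ndarray:
    """Sorted x-grid for a plate: junction abscissae plus uniform fill on the
    overhangs, points closer than spacing/2 to a junction node dropped."""
    xs = [junction_x]
    for lo, hi in ((x_min, junction_x[0]), (junction_x[-1], x_max)):
        span = hi - lo
        if span > spacing / 2:
            n = max(1, int(round(span / spacing)))
            pts = np.linspace(lo, hi, n + 1)
            keep = np.min(np.abs(pts[:, None] - junction_x[None, :]), axis=1) > spacing / 4
            xs.append(pts[keep])
    out = np.unique(np.concatenate(xs))
    return out


def _structured_block(x_coords: np.ndarray, y_coords: np.ndarray):
    """Nodes (row-major, y outer) and quads of a tensor-product block."""
    yy, xx = np.meshgrid(y_coords, x_coords, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    quads = _grid_quads(len(y_coords) - 1, len(x_coords) - 1)
    return nodes, quads


def generate_mesh(
    geometry: TrabeculaGeometry,
    h: float = 0.015,
    plate_h: float | None = None,
) -> Mesh:
    """Mesh the trabecula (and its plates, when present) with quads.

    Parameters
    ----------
    geometry : the spline-bounded region to mesh.
    h : target element edge length in the trabecula, mm (default 0.015).
    plate_h : target edge length in the plates; defaults to 3 h (the plates
        only provide elastic support, so they are meshed coarser).

    Raises
    ------
    MeshingError
        On invalid sizes or if plates are requested on non-horizontal end
        edges (plates only attach to the upright study configuration).
    """
    if h <= 0:
        raise MeshingError(f"target edge length must be positive, got {h}", geometry)
    if plate_h is None:
        plate_h = 3.0 * h

    left = geometry.side_spline("left")
    right = geometry.side_spline("right")
    arc = 0.5 * (geometry.side_arc_length("left") + geometry.side_arc_length("right"))
    t = np.linspace(0.0, 1.0, 200)
    widths = np.linalg.norm(right(t) - left(t), axis=1)

    n_rows = max(2, int(round(arc / h)))
    # resolve the widest cross section (remodelled ends flare outward)
    n_cols = max(2, int(round(float(widths.max()) / h)))

    tj = np.linspace(0.0, 1.0, n_rows + 1)
    si = np.linspace(0.0, 1.0, n_cols + 1)
    pl = left(tj)  # (n_rows+1, 2)
    pr = right(tj)
    # transfinite blend: straight cross-fibres between the two splines
    trab_nodes = (
        pl[:, None, :] * (1.0 - si)[None, :, None]
        + pr[:, None, :] * si[None, :, None]
    ).reshape(-1, 2)
    trab_quads = _grid_quads(n_rows, n_cols)

    def rows_cols(j, i):
        return j * (n_cols + 1) + i

    js = np.arange(n_rows + 1)
    iis = np.arange(n_cols + 1)
    sets_local = {
        "left_spline": rows_cols(js, 0),
        "right_spline": rows_cols(js, n_cols),
        "trab_bottom_edge": rows_cols(0, iis),
        "trab_top_edge": rows_cols(n_rows, iis),
    }

    blocks = [trab_nodes]
    quad_blocks = [trab_quads]
    domains = [np.full(len(trab_quads), TRABECULA)]
    plate_sets: dict[str, tuple[int, np.ndarray]] = {}

    if geometry.plates is not None:
        pd = geometry.plates
        bot_edge = trab_nodes[sets_local["trab_bottom_edge"]]
        top_edge = trab_nodes[sets_local["trab_top_edge"]]
        for name, edge in (("bottom", bot_edge), ("top", top_edge)):
            if np.ptp(edge[:, 1]) > 1e-9:
                raise MeshingError(
                    f"{name} end edge is not horizontal; plates only attach "
                    "to upright configurations",
                    geometry,
                )
        n_thick = max(2, int(round(pd.thickness / plate_h)))
        half_w = pd.width / 2.0

        # bottom plate: below y = y_bot, centred on the initial axis (x = 0)
        y_bot = bot_edge[0, 1]
        xb = _plate_x_coords(np.sort(bot_edge[:, 0]), -half_w, half_w, plate_h)
        yb = np.linspace(y_bot - pd.thickness, y_bot, n_thick + 1)
        nb, qb = _structured_block(xb, yb)
        blocks.append(nb)
        quad_blocks.append(qb)
        domains.append(np.full(len(qb), BOTTOM_PLATE))
        plate_sets["plate_bottom_edge"] = (1, np.arange(len(xb)))  # lowest row
        plate_sets["bottom_plate_nodes"] = (1, np.arange(len(nb)))

        # top plate: above y = y_top
        y_top = top_edge[0, 1]
        xt = _plate_x_coords(np.sort(top_edge[:, 0]), -half_w, half_w, plate_h)
        yt = np.linspace(y_top, y_top + pd.thickness, n_thick + 1)
        nt, qt = _structured_block(xt, yt)
        blocks.append(nt)
        quad_blocks.append(qt)
        domains.append(np.full(len(qt), TOP_PLATE))
        plate_sets["plate_top_edge"] = (2, np.arange(len(nt) - len(xt), len(nt)))
        plate_sets["top_plate_nodes"] = (2, np.arange(len(nt)))

    merged, maps = _merge_nodes(blocks)
    offset_quads = []
    for qb, m in zip(quad_blocks, maps):
        offset_quads.append(m[qb])
    quads = np.vstack(offset_quads)
    domain = np.concatenate(domains)

    node_sets = {name: np.unique(maps[0][idx]) for name, idx in sets_local.items()}
    for name, (block, idx) in plate_sets.items():
        node_sets[name] = np.unique(maps[block][idx])

    mesh = Mesh(nodes=merged, quads=quads, domain=domain, node_sets=node_sets, h=h)
    if np.any(mesh.jacobians() <= 0):
        raise MeshingError("mesh contains non-positive Jacobians", geometry)
    return mesh


def rectangle_mesh(
    width: float, height: float, hx: float, hy: float | None = None
) -> Mesh:
    """Axis-aligned rectangular mesh on [0, width] x [0, height].

    Node sets: 'left', 'right', 'bottom', 'top'.  Used for verification
    problems (consolidation columns) and tests.
    """
    if hy is None:
        hy = hx
    nx = max(1, int(round(width / hx)))
    ny = max(1, int(round(height / hy)))
    nodes, quads = _structured_block(
        np.linspace(0.0, width, nx + 1), np.linspace(0.0, height, ny + 1)
    )
    cols = nx + 1
    rows = ny + 1
    node_sets = {
        "left": np.arange(rows) * cols,
        "right": np.arange(rows) * cols + nx,
        "bottom": np.arange(cols),
        "top": np.arange(cols) + ny * cols,
    }
    return Mesh(
        nodes=nodes,
        quads=quads,
        domain=np.zeros(len(quads), dtype=int),
        node_sets=node_sets,
        h=hx,
    )
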