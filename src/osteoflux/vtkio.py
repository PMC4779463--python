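"""Plain-text output writers: legacy-ASCII VTK snapshots and CSV tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .meshing import Mesh

__all__ = ["write_vtk", "write_points_csv"]


def write_vtk(
    mesh: Mesh,
    path: str,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "osteoflux snapshot",
) -> None:
    """Write a mesh (with optional nodal/element fields) as legacy ASCII VTK.

    Vector point data may be (N, 2); a zero third component is appended.
    """
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(title + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        m = mesh.n_elements
        f.write(f"CELLS {m} {5 * m}\n")
        for q in mesh.quads:
            f.write("4 " + " ".join(str(int(i)) for i in q) + "\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("9\n" * m)  # VTK_QUAD
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        f.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.9g}\n")
        if cell_data:
            f.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    f.write(f"{v:.9g}\n")


def write_points_csv(history, path: str) -> None:
    """Characteristic-point trajectory of a remodelling run as CSV.

    Columns: iteration, side, index, x1, x2, V, displacement.  Iteration k
    rows hold the geometry entering iteration k; velocities/displacements
    are those computed during that iteration (empty for the final state).
    """
    rows = []
    for it, geom in enumerate(history.geometries):
        have_v = it < len(history.velocities)
        for s, (side, pts) in enumerate(
            (("left", geom.left_points), ("right", geom.right_points))
        ):
            for j, (x1, x2) in enumerate(pts):
                rows.append(
                    {
                        "iteration": it,
                        "side": side,
                        "index": j,
                        "x1": x1,
                        "x2": x2,
                        "V": history.velocities[it][s, j] if have_v else np.nan,
                        "displacement": history.displacements[it][s, j]
                        if have_v
                        else np.nan,
                    }
                )
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
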