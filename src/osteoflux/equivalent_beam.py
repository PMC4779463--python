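"""Reduce a remodelled continuum trabecula to an equivalent beam.

The adapted geometry is summarised by the descriptors a mesoscale structural
model needs: the adapted inclination to the vertical, the reorientation
``dphi`` relative to the initial beam, and the cross-section ratio ``R_A``
(adapted over initial width; for a constant-depth 2D trabecula this equals
the 3D area ratio).

Start and end nodes are the midpoints of the bottom and top end edges.  The
apparent radius is half the mean of the horizontal separations of the 12
characteristic point pairs; the remodelled radius is its projection onto the
direction perpendicular to the adapted axis (apparent * cos(phi_f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TrabeculaGeometry

__all__ = ["EquivalentBeam", "equivalent_beam", "NEAR_HORIZONTAL_ANGLES"]

#: Load angles (rad) whose adapted geometries are ambiguous (near-lateral
#: loading) and are excluded from the phenomenological fits.
NEAR_HORIZONTAL_ANGLES = (7 * np.pi / 16, np.pi / 2, 9 * np.pi / 16)


@dataclass(frozen=True)
class EquivalentBeam:
    """Adapted-beam descriptors of a remodelled trabecula.

    Angles in rad (positive tilts toward +x1), widths/radii in mm.
    ``R_A = w_f / w_i`` with ``w_f`` twice the remodelled radius.
    """

    start_node: np.ndarray
    end_node: np.ndarray
    phi_i: float
    phi_f: float
    apparent_radius: float
    remodelled_radius: float
    w_i: float
    w_f: float

    @property
    def dphi(self) -> float:
        """Change of inclination phi_f - phi_i, rad."""
        return self.phi_f - self.phi_i

    @property
    def R_A(self) -> float:
        """Ratio of adapted to initial cross section."""
        return self.w_f / self.w_i


def equivalent_beam(
    final_geometry: TrabeculaGeometry,
    initial_geometry: TrabeculaGeometry,
) -> EquivalentBeam:
    """Equivalent-beam descriptors of a remodelled geometry.

    >>> from osteoflux.geometry import build_initial_trabecula
    >>> g = build_initial_trabecula(1.0, 0.2)
    >>> eb = equivalent_beam(g, g)
    >>> (round(eb.dphi, 12), round(eb.R_A, 12))
    (0.0, 1.0)
    """
    for name, geom in (("final", final_geometry), ("initial", initial_geometry)):
        if geom is None:
            raise ValueError(f"{name} geometry is required")

    def axis_nodes(g: TrabeculaGeometry) -> tuple[np.ndarray, np.ndarray]:
        start = 0.5 * (g.left_points[0] + g.right_points[0])
        end = 0.5 * (g.left_points[-1] + g.right_points[-1])
        return start, end

    start, end = axis_nodes(final_geometry)
    v = end - start
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError("degenerate adapted axis (coincident end nodes)")
    phi_f = float(np.arctan2(v[0], v[1]))
    if not abs(phi_f) < np.pi / 2:
        raise ValueError(f"adapted axis angle out of range: {phi_f:.3f} rad")

    s0, e0 = axis_nodes(initial_geometry)
    v0 = e0 - s0
    phi_i = float(np.arctan2(v0[0], v0[1]))

    # apparent radius from the horizontal separations of the point pairs;
    # the remodelled radius projects the pair vectors onto the adapted
    # cross-axis.  When matched pairs sit at equal heights — which the
    # remodelling loop guarantees for upright initial geometries, since
    # points only ever move horizontally — this equals apparent * cos(phi_f)
    # exactly; the projection form stays exact for inclined initial
    # rectangles too (identity reduction gives R_A = 1).
    pairs = final_geometry.right_points - final_geometry.left_points
    apparent = 0.5 * float(pairs[:, 0].mean())
    cross_f = np.array([np.cos(phi_f), -np.sin(phi_f)])
    remodelled = 0.5 * float((pairs @ cross_f).mean())

    # initial width: pair vectors projected on the initial cross-axis (the
    # un-remodelled rectangle has perpendicular pairs, so this is exact)
    cross_i = np.array([np.cos(phi_i), -np.sin(phi_i)])
    sep_i = (initial_geometry.right_points - initial_geometry.left_points) @ cross_i
    w_i = float(sep_i.mean())

    return EquivalentBeam(
        start_node=start,
        end_node=end,
        phi_i=phi_i,
        phi_f=phi_f,
        apparent_radius=apparent,
        remodelled_radius=remodelled,
        w_i=w_i,
        w_f=2.0 * remodelled,
    )
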