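"""Spline-bounded 2D trabecula geometry.

The trabecula is a planar region bounded laterally by two interpolating cubic
splines, each passing through 12 characteristic boundary points, and closed
top and bottom by straight segments joining the spline extremities.  The
surface-remodelling loop mutates only the horizontal (x1) coordinates of the
24 characteristic points; everything else (plate attachments, end edges) is
derived from them.

Coordinate convention: origin at the centre of the bottom end edge, x1
horizontal, x2 vertical upward.  The incline is the angle of the trabecula
axis to the vertical x2 axis, positive anticlockwise (toward -x1) in the
mathematical sense; in practice we pass the signed angle directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LinearRing

__all__ = [
    "PlateDimensions",
    "TrabeculaGeometry",
    "InvalidGeometryError",
    "DegenerateGeometryError",
    "build_initial_trabecula",
    "geometry_from_points",
    "central_width",
    "N_POINTS_PER_SIDE",
]

#: Characteristic boundary points per lateral side.
N_POINTS_PER_SIDE = 12


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or malformed point lists."""


class DegenerateGeometryError(RuntimeError):
    """Raised when a remodelled boundary self-intersects or the local width
    becomes non-positive; carries enough context to diagnose the run."""


@dataclass(frozen=True)
class PlateDimensions:
    """End-plate block: ``thickness`` (along the axis), ``width`` (in plane,
    across the trabecula) and ``depth`` (out of plane), all in mm."""

    thickness: float = 0.5
    width: float = 1.4
    depth: float = 1.0

    def __post_init__(self) -> None:
        if min(self.thickness, self.width, self.depth) <= 0:
            raise InvalidGeometryError("plate dimensions must be positive")

    @property
    def second_moment(self) -> float:
        """Second moment of area d w^3 / 12 of the plate cross section, mm^4."""
        return self.depth * self.width**3 / 12.0


def _side_spline(points: np.ndarray, incline: float) -> CubicSpline:
    """Natural cubic spline through one side's points.

    Parameterised by the normalised projection of the points onto the fixed
    initial axis direction (t in [0, 1]).  Because remodelling moves points
    only horizontally, this projection stays strictly increasing, and the
    transfinite mesh fibres that connect equal-t stations of the two sides
    can never fold over — even for strongly reoriented geometries.
    """
    axis = np.array([np.sin(incline), np.cos(incline)])
    s = points @ axis
    t = (s - s[0]) / (s[-1] - s[0])
    return CubicSpline(t, points, bc_type="natural", axis=0)


@dataclass(frozen=True)
class TrabeculaGeometry:
    """Spline-bounded trabecula with optional end plates.

    ``left_points`` and ``right_points`` are (12, 2) arrays of characteristic
    point coordinates in mm, ordered bottom to top.  The left side is the one
    at smaller cross-axis coordinate.
    """

    left_points: np.ndarray
    right_points: np.ndarray
    plates: PlateDimensions | None = None
    incline: float = 0.0  # rad, initial axis angle to vertical (bookkeeping)
    initial_width: float = 0.2  # mm, width of the un-remodelled rectangle

    def __post_init__(self) -> None:
        left = np.asarray(self.left_points, dtype=float)
        right = np.asarray(self.right_points, dtype=float)
        object.__setattr__(self, "left_points", left)
        object.__setattr__(self, "right_points", right)
        for name, pts in (("left", left), ("right", right)):
            if pts.shape != (N_POINTS_PER_SIDE, 2):
                raise InvalidGeometryError(
                    f"{name} side needs exactly {N_POINTS_PER_SIDE} planar "
                    f"points, got shape {pts.shape}"
                )
        if np.linalg.norm(self.axis_vector()) <= 0:
            raise InvalidGeometryError("degenerate axis (zero length)")
        # strictly increasing along the (fixed) initial axis direction;
        # remodelling only moves points horizontally, so ordering is taken
        # against the reference frame, not the reorienting current axis
        axis = np.array([np.sin(self.incline), np.cos(self.incline)])
        for name, pts in (("left", left), ("right", right)):
            s = pts @ axis
            if np.any(np.diff(s) <= 0):
                raise InvalidGeometryError(
                    f"{name} points are not strictly increasing along the axis"
                )
        # positive local width at matched points
        cross = np.array([axis[1], -axis[0]])
        width = (right - left) @ cross
        if np.any(width <= 0):
            raise DegenerateGeometryError(
                f"non-positive local width (min {width.min():.4g} mm)"
            )

    # ---- derived quantities -------------------------------------------
    def axis_vector(self) -> np.ndarray:
        """Unit vector from the bottom-edge midpoint to the top-edge midpoint."""
        bottom = 0.5 * (self.left_points[0] + self.right_points[0])
        top = 0.5 * (self.left_points[-1] + self.right_points[-1])
        v = top - bottom
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    @property
    def length(self) -> float:
        """Distance between the end-edge midpoints, mm."""
        bottom = 0.5 * (self.left_points[0] + self.right_points[0])
        top = 0.5 * (self.left_points[-1] + self.right_points[-1])
        return float(np.linalg.norm(top - bottom))

    def side_spline(self, side: str) -> CubicSpline:
        """Interpolating spline of one lateral side ('left' or 'right')."""
        pts = self.left_points if side == "left" else self.right_points
        return _side_spline(pts, self.incline)

    def side_arc_length(self, side: str, n: int = 400) -> float:
        """Polyline approximation of one lateral side's arc length, mm."""
        sp = self.side_spline(side)
        xy = sp(np.linspace(0.0, 1.0, n))
        return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())

    def point_spacing(self, side: str) -> float:
        """Mean arc spacing of the characteristic points along a side, mm."""
        return self.side_arc_length(side) / (N_POINTS_PER_SIDE - 1)

    def boundary_polygon(self, n_per_side: int = 120) -> np.ndarray:
        """Closed boundary polyline (anticlockwise), splines sampled densely."""
        t = np.linspace(0.0, 1.0, n_per_side)
        left = self.side_spline("left")(t)
        right = self.side_spline("right")(t)
        # bottom edge left->right, right spline up, top edge right->left,
        # left spline down
        return np.vstack([left[0], right[0], right[1:], left[::-1]])

    def check_simple(self) -> None:
        """Raise :class:`DegenerateGeometryError` if the boundary
        self-intersects."""
        ring = LinearRing(self.boundary_polygon())
        if not ring.is_simple:
            raise DegenerateGeometryError("boundary polygon self-intersects")

    def with_points(
        self, left_points: np.ndarray, right_points: np.ndarray
    ) -> "TrabeculaGeometry":
        return replace(self, left_points=left_points, right_points=right_points)


def build_initial_trabecula(
    length: float,
    width: float,
    incline: float = 0.0,
    plates: PlateDimensions | None = None,
) -> TrabeculaGeometry:
    """Rectangular (projected-cylinder) trabecula of given dimensions.

    The rectangle's axis makes an angle ``incline`` (rad, |incline| < pi/2)
    with the vertical; characteristic points are spaced uniformly along each
    lateral side, endpoints included (spacing length/11).

    >>> g = build_initial_trabecula(1.0, 0.2)
    >>> central_width(g)
    0.2
    """
    if length <= 0 or width <= 0:
        raise InvalidGeometryError(
            f"length and width must be positive, got {length}, {width}"
        )
    if not abs(incline) < np.pi / 2:
        raise InvalidGeometryError(f"|incline| must be < pi/2, got {incline}")
    a = np.array([np.sin(incline), np.cos(incline)])  # axis direction
    c = np.array([np.cos(incline), -np.sin(incline)])  # cross-axis (to right)
    s = np.linspace(0.0, length, N_POINTS_PER_SIDE)
    centre = np.outer(s, a)
    left = centre - 0.5 * width * c
    right = centre + 0.5 * width * c
    return TrabeculaGeometry(
        left_points=left,
        right_points=right,
        plates=plates,
        incline=incline,
        initial_width=width,
    )


def geometry_from_points(
    left_points: np.ndarray,
    right_points: np.ndarray,
    plates: PlateDimensions | None = None,
    *,
    like: TrabeculaGeometry | None = None,
) -> TrabeculaGeometry:
    """Regenerate a trabecula region from updated characteristic points.

    The lateral boundaries are interpolating splines through the 12 points of
    each side; the end closures are the straight segments joining the spline
    extremities.  ``like`` carries over bookkeeping (incline, initial width,
    plates) from a previous geometry.

    Raises
    ------
    DegenerateGeometryError
        If the local width is non-positive anywhere or the boundary
        self-intersects; the remodelling loop aborts with this diagnostic.
    """
    if like is not None and plates is None:
        plates = like.plates
    geom = TrabeculaGeometry(
        left_points=np.asarray(left_points, dtype=float),
        right_points=np.asarray(right_points, dtype=float),
        plates=plates,
        incline=like.incline if like is not None else 0.0,
        initial_width=like.initial_width if like is not None else 0.2,
    )
    # positive width everywhere on the splines, not only at the points
    t = np.linspace(0.0, 1.0, 200)
    axis = np.array([np.sin(geom.incline), np.cos(geom.incline)])
    cross = np.array([axis[1], -axis[0]])
    width = (geom.side_spline("right")(t) - geom.side_spline("left")(t)) @ cross
    if np.any(width <= 0):
        raise DegenerateGeometryError(
            f"spline width non-positive (min {width.min():.4g} mm)"
        )
    geom.check_simple()
    return geom


def central_width(geometry: TrabeculaGeometry) -> float:
    """Horizontal central width of the trabecula, mm.

    Approximated as the difference in horizontal (x1) position at the middle
    characteristic points.  With 12 points per side there is no single middle
    point, so the mean of points 6 and 7 (indices 5 and 6) is used per side.
    """
    mid = slice(N_POINTS_PER_SIDE // 2 - 1, N_POINTS_PER_SIDE // 2 + 1)
    x_left = geometry.left_points[mid, 0].mean()
    x_right = geometry.right_points[mid, 0].mean()
    return float(x_right - x_left)
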