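"""Symmetry-axis estimation and left/right field splitting.

The facial symmetry axis is estimated geometrically: the convex hull of the
detected edge points gives the external contour; the ellipse best fitting the
hull vertices in the least-squares sense gives the face's orientation; and
the ellipse's major axis is taken as the symmetry axis.  The same procedure
applies unchanged to the mouth-cavity contour.  The axis then splits the
pixels inside the hull into two disjoint side collections whose temperature
statistics are compared downstream.

All geometry uses image coordinates: 0-based (row, col), row 0 at the top.
Hull vertex order is counterclockwise in the (x=col, y=row) plane.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import (
    AmbiguousAxisWarning,
    DegenerateGeometryError,
    DegenerateSplitError,
    EllipseFitError,
)
from .io import Thermogram

__all__ = [
    "Hull",
    "EllipseParams",
    "AxisLine",
    "RegionPair",
    "convex_hull",
    "fit_ellipse",
    "symmetry_axis",
    "split_regions",
]

#: aspect ratio below which the major-axis direction is considered ambiguous
CIRCULARITY_RATIO = 1.02


@dataclasses.dataclass(frozen=True)
class Hull:
    """Convex polygon vertices, (row, col), counterclockwise in the
    (x=col, y=row) plane, starting at the lexicographically smallest vertex."""

    vertices: np.ndarray  # shape (m, 2), float

    def __len__(self) -> int:
        return len(self.vertices)


@dataclasses.dataclass(frozen=True)
class EllipseParams:
    """Geometric parameters of a fitted ellipse.

    ``angle_deg`` is the major-axis orientation in degrees, measured from the
    column axis toward the row axis, normalized to (-90, 90].  ``residual`` is
    the root-mean-square algebraic conic residual at the input points (0 for
    points exactly on the ellipse).  ``ambiguous_axis`` flags near-circular
    fits whose major-axis direction is unreliable.
    """

    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    angle_deg: float
    residual: float = 0.0
    ambiguous_axis: bool = False

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise EllipseFitError("requires semi_major >= semi_minor > 0")


@dataclasses.dataclass(frozen=True)
class AxisLine:
    """A line given by a point on it and a unit (row, col) direction."""

    point: tuple[float, float]
    direction: tuple[float, float]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("axis direction must be a unit vector")


@dataclasses.dataclass(frozen=True)
class RegionPair:
    """Pixel-temperature collections on the two sides of the symmetry axis."""

    side_a_temps: np.ndarray
    side_b_temps: np.ndarray
    side_a_pixels: np.ndarray  # (n, 2) int
    side_b_pixels: np.ndarray
    n_on_axis: int = 0

    def __post_init__(self) -> None:
        if len(self.side_a_temps) == 0 or len(self.side_b_temps) == 0:
            raise DegenerateSplitError("both sides of the split must be nonempty")

    def swapped(self) -> "RegionPair":
        return RegionPair(
            side_a_temps=self.side_b_temps,
            side_b_temps=self.side_a_temps,
            side_a_pixels=self.side_b_pixels,
            side_b_pixels=self.side_a_pixels,
            n_on_axis=self.n_on_axis,
        )


def convex_hull(points: Sequence[tuple[float, float]] | np.ndarray) -> Hull:
    """Minimal convex polygon containing all points.

    Vertices are returned counterclockwise in the (x=col, y=row) plane and
    rotated so the lexicographically smallest (row, col) vertex comes first;
    points interior to the hull or interior to an edge are not vertices.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or an all-collinear point set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateGeometryError("expected an (n, 2) array of (row, col) points")
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("convex hull needs at least 3 distinct points")
    xy = pts[:, ::-1]  # (col, row) so qhull's CCW order is in the (x=col, y=row) plane
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set (collinear?): {exc}") from None
    verts = pts[hull.vertices]  # CCW in the (col, row) plane
    # rotate so the lexicographically smallest (row, col) vertex is first
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    verts = np.roll(verts, -start, axis=0)
    return Hull(vertices=verts)


def _conic_from_points(pts_xy: np.ndarray) -> np.ndarray:
    """Direct least-squares conic fit constrained to an ellipse.

    Numerically stable formulation of the direct method: the scatter matrix
    is split into quadratic and linear blocks and the quartic constraint
    4*A*C - B**2 = 1 is imposed through a reduced 3x3 eigenproblem, giving the
    unique ellipse minimizing the algebraic residual.  Returns conic
    coefficients (A, B, C, D, E, F) for A x^2 + B x y + C y^2 + D x + E y + F = 0.
    """
    x, y = pts_xy[:, 0], pts_xy[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError:
        raise EllipseFitError("degenerate scatter: linear block is singular") from None
    m = s1 + s2 @ t
    # premultiply by the inverse of the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m_red = np.vstack([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m_red)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0 (exactly one)
    a1 = None
    for i in range(3):
        if abs(eigval[i].imag) > 1e-9 * (abs(eigval[i].real) + 1.0):
            continue
        v = np.real(eigvec[:, i])
        if 4.0 * v[0] * v[2] - v[1] ** 2 > 0:
            a1 = v
            break
    if a1 is None:
        raise EllipseFitError("least-squares conic through the points is not an ellipse")
    coeffs = np.concatenate([a1, t @ a1])
    return coeffs


def _conic_to_geometry(coeffs: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Convert conic coefficients (x = col, y = row) to center/axes/angle."""
    A, B, C, D, E, F = coeffs
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise EllipseFitError("conic is not an ellipse (nonnegative discriminant)")
    x0 = (2.0 * C * D - B * E) / disc
    y0 = (2.0 * A * E - B * D) / disc
    f0 = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    m = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(m)
    axes2 = -f0 / lam  # squared semi-axis along each eigenvector
    if np.any(axes2 <= 0):
        raise EllipseFitError("degenerate ellipse (nonpositive axis length)")
    order = np.argsort(axes2)[::-1]  # major first
    semi_major, semi_minor = np.sqrt(axes2[order])
    vx, vy = vec[:, order[0]]  # major-axis direction in (x, y)
    angle = math.degrees(math.atan2(vy, vx))
    angle = (angle + 90.0) % 180.0 - 90.0  # normalize to (-90, 90]
    if angle == -90.0:
        angle = 90.0
    return (float(y0), float(x0)), float(semi_major), float(semi_minor), float(angle)


def fit_ellipse(points: Sequence[tuple[float, float]] | np.ndarray) -> EllipseParams:
    """Least-squares ellipse through a point cloud (typically hull vertices).

    Uses the direct ellipse-constrained conic fit — unique and non-iterative,
    so no initialization is needed.  Points are centered before fitting for
    numerical conditioning; noiseless points on a true ellipse are recovered
    to near machine precision.

    Raises :class:`EllipseFitError` for degenerate scatters and warns with
    :class:`AmbiguousAxisWarning` when the result is nearly circular.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateGeometryError("expected an (n, 2) array of (row, col) points")
    if len(np.unique(pts, axis=0)) < 6:
        raise DegenerateGeometryError("ellipse fit needs at least 6 distinct points")
    xy = pts[:, ::-1].copy()  # (x=col, y=row)
    mean = xy.mean(axis=0)
    coeffs = _conic_from_points(xy - mean)
    (yc, xc), semi_major, semi_minor, angle = _conic_to_geometry(coeffs)
    center = (yc + mean[1], xc + mean[0])  # (row, col)

    # RMS algebraic residual with coefficients normalized to unit quadratic part
    x, y = (xy - mean).T
    vals = (
        coeffs[0] * x * x + coeffs[1] * x * y + coeffs[2] * y * y
        + coeffs[3] * x + coeffs[4] * y + coeffs[5]
    )
    scale = math.hypot(coeffs[0], coeffs[1], coeffs[2])
    residual = float(np.sqrt(np.mean((vals / scale) ** 2)))

    ambiguous = semi_major / semi_minor < CIRCULARITY_RATIO
    if ambiguous:
        warnings.warn(
            "fitted ellipse is nearly circular; major-axis direction is ambiguous",
            AmbiguousAxisWarning,
            stacklevel=2,
        )
    return EllipseParams(
        center=center,
        semi_major=semi_major,
        semi_minor=semi_minor,
        angle_deg=angle,
        residual=residual,
        ambiguous_axis=ambiguous,
    )


def symmetry_axis(ellipse: EllipseParams) -> AxisLine:
    """The symmetry axis: the line through the ellipse center along its major axis.

    For ``angle_deg = 90`` (vertical major axis) the direction is (1, 0) in
    (row, col).  An ambiguity flag from a near-circular fit is propagated.
    """
    theta = math.radians(ellipse.angle_deg)
    direction = (math.sin(theta), math.cos(theta))  # (row, col)
    return AxisLine(point=ellipse.center, direction=direction, ambiguous=ellipse.ambiguous_axis)


def _strictly_inside(hull: Hull, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside the hull polygon.

    For a counterclockwise polygon in the (x=col, y=row) plane, a point is
    strictly interior iff every edge cross product is positive.
    """
    verts = hull.vertices
    x1, y1 = verts[:, 1], verts[:, 0]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    inside = np.ones(rows.shape, dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        cross = (ex2 - ex1) * (rows - ey1) - (ey2 - ey1) * (cols - ex1)
        inside &= cross > 0
    return inside


def split_regions(tg: Thermogram, hull: Hull, axis: AxisLine) -> RegionPair:
    """Assign every pixel strictly inside the hull to one side of the axis.

    Side membership is the sign of the 2-D cross product
    ``(pixel - axis.point) x axis.direction``; pixels exactly on the axis
    (zero cross product) are discarded so the two sides stay disjoint.

    Raises
    ------
    DegenerateSplitError
        If the axis does not pass through the hull, or either side ends up
        empty.
    """
    verts = hull.vertices
    pr, pc = axis.point
    dr, dc = axis.direction
    vert_sign = (verts[:, 0] - pr) * dc - (verts[:, 1] - pc) * dr
    if np.all(vert_sign > 0) or np.all(vert_sign < 0):
        raise DegenerateSplitError("symmetry axis does not intersect the hull polygon")

    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), tg.n_rows - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), tg.n_cols - 1)
    if r1 < r0 or c1 < c0:
        raise DegenerateSplitError("hull does not overlap the image grid")
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = _strictly_inside(hull, rows.astype(float), cols.astype(float))
    rows, cols = rows[inside], cols[inside]
    if rows.size == 0:
        raise DegenerateSplitError("no pixel centers strictly inside the hull")

    s = (rows - pr) * dc - (cols - pc) * dr
    side_a = s > 0
    side_b = s < 0
    temps = tg.values[rows, cols]
    pair = RegionPair(
        side_a_temps=temps[side_a],
        side_b_temps=temps[side_b],
        side_a_pixels=np.column_stack([rows[side_a], cols[side_a]]),
        side_b_pixels=np.column_stack([rows[side_b], cols[side_b]]),
        n_on_axis=int(np.count_nonzero(s == 0)),
    )
    return pair
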