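"""Planar and spatial geometry primitives.

All geometry lives in physical millimetre coordinates; voxel-to-mm
conversion happens at I/O (voxel-centre convention, 0-based indices).
Closed planar contours are represented by :class:`Contour`, 3D nerve
paths by :class:`Centerline`. The free functions below (shoelace area,
perimeter, isoperimetric quotient, arc length, point-to-line distance,
arc-length resampling) are the shared vocabulary of the deviation and
segmentation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import ValidationError

__all__ = [
    "Contour",
    "Centerline",
    "polygon_area",
    "polygon_perimeter",
    "isoperimetric_quotient",
    "arc_length",
    "point_to_line_distance",
    "resample_path",
]

_DEGENERATE_TOL = 1e-12


def _signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (n, 2) vertices."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed, simple planar polygon in mm, attached to an axial position.

    The constructor drops an explicitly repeated closing vertex, rejects
    degenerate (<3 distinct vertices, zero area) and self-intersecting
    inputs, and normalizes the orientation to counter-clockwise so the
    shoelace area is positive.

    Parameters
    ----------
    points
        Ordered (n, 2) vertex array in mm; first and last vertex are
        treated as joined (do not repeat the first vertex).
    slice_position
        Axial (slice-normal) coordinate of the plane, in mm.
    """

    points: np.ndarray
    slice_position: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("contour points must be an (n, 2) array")
        if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        # collapse consecutive duplicates
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > _DEGENERATE_TOL
        pts = pts[keep]
        if len(pts) < 3:
            raise ValidationError(
                f"contour needs >= 3 distinct vertices, got {len(pts)}"
            )
        signed = _signed_area(pts)
        if abs(signed) <= _DEGENERATE_TOL:
            raise ValidationError("degenerate contour: zero enclosed area")
        if signed < 0:  # normalize to counter-clockwise
            pts = pts[::-1].copy()
        poly = _ShapelyPolygon(pts)
        if not poly.is_valid:
            raise ValidationError("contour is self-intersecting")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "slice_position", float(self.slice_position))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.points)

    @property
    def centroid(self) -> np.ndarray:
        """Area (shoelace) centroid, in mm."""
        c = self.shapely.centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D point sequence tracing the optic nerve, anterior→posterior.

    ``on_head`` is the optic-nerve-head reference point from which
    posterior distances are measured; it must coincide with (or lie
    within ``snap_tol_mm`` of) the first path point.
    """

    points: np.ndarray
    on_head: np.ndarray | None = None
    lens_center: np.ndarray | None = None
    snap_tol_mm: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError("centerline points must be an (n, 3) array")
        if len(pts) < 3:
            raise ValidationError(
                f"centerline needs >= 3 points, got {len(pts)}"
            )
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= _DEGENERATE_TOL):
            i = int(np.argmax(steps <= _DEGENERATE_TOL))
            raise ValidationError(
                f"duplicate consecutive centerline points at index {i} and {i + 1}"
            )
        head = pts[0] if self.on_head is None else np.asarray(self.on_head, float)
        if head.shape != (3,):
            raise ValidationError("on_head must be a 3-vector")
        if np.linalg.norm(head - pts[0]) > self.snap_tol_mm:
            raise ValidationError(
                "on_head lies "
                f"{np.linalg.norm(head - pts[0]):.3f} mm from the first path "
                f"point (snap tolerance {self.snap_tol_mm} mm)"
            )
        lens = self.lens_center
        if lens is not None:
            lens = np.asarray(lens, dtype=float)
            if lens.shape != (3,):
                raise ValidationError("lens_center must be a 3-vector")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "on_head", head)
        object.__setattr__(self, "lens_center", lens)

    def __len__(self) -> int:
        return len(self.points)


def polygon_area(contour: Contour) -> float:
    """Shoelace area of a closed contour, in mm² (strictly positive)."""
    return abs(_signed_area(contour.points))


def polygon_perimeter(contour: Contour) -> float:
    """Perimeter of a closed contour including the closing edge, in mm."""
    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def isoperimetric_quotient(contour: Contour) -> float:
    """Roundness Q = 4πA/P²: 1 for a circle, →0 for elongated shapes.

    A discretized circle approaches 1 from below; any polygon satisfies
    0 < Q ≤ 1 up to floating point.
    """
    a = polygon_area(contour)
    p = polygon_perimeter(contour)
    return 4.0 * np.pi * a / (p * p)


def arc_length(path: np.ndarray) -> np.ndarray:
    """Cumulative chordal arc length along an ordered point sequence.

    Returns a monotone non-decreasing array of the same length as
    ``path`` whose first entry is 0. Works for 2D or 3D points.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValidationError("arc_length needs an (n>=2, d) point array")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_to_line_distance(p, a, b) -> float:
    """Perpendicular distance from ``p`` to the infinite line through ``a``, ``b``."""
    p = np.asarray(p, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = b - a
    n = np.linalg.norm(d)
    if n <= _DEGENERATE_TOL:
        raise ValidationError("line endpoints coincide")
    return float(np.linalg.norm(np.cross(d, a - p)) / n)


def resample_path(path: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing ≤ ``step_mm``.

    Both endpoints are preserved exactly; intermediate points are placed
    by linear interpolation along the chordal parameterization.
    """
    if step_mm <= 0:
        raise ValidationError(f"step_mm must be positive, got {step_mm}")
    pts = np.asarray(path, dtype=float)
    s = arc_length(pts)
    total = s[-1]
    n_seg = max(1, int(np.ceil(total / step_mm - 1e-12)))
    targets = np.linspace(0.0, total, n_seg + 1)
    return np.column_stack(
        [np.interp(targets, s, pts[:, k]) for k in range(pts.shape[1])]
    )
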