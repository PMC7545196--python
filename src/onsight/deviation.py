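"""Optic-nerve deviation from a straight-line path.

Deviation is the maximum orthogonal distance between the curved nerve
centerline and the chord joining the optic nerve head (ONH) to the
point 20 mm posterior along the trajectory. Operator-picked points
(~1–2 mm apart) are densified with an interpolating cubic spline
parameterized by cumulative chord length, truncated at the target
trajectory length, and the distance to the infinite line through the
chord endpoints is maximized over the sampled curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .geometry import Centerline, arc_length, point_to_line_distance

__all__ = [
    "DeviationResult",
    "load_centerline_csv",
    "fit_spline",
    "truncate_at_arclength",
    "compute_deviation",
]

log = logging.getLogger(__name__)

DEFAULT_TRAJECTORY_MM = 20.0
DEFAULT_SAMPLE_STEP_MM = 0.1


@dataclass(frozen=True)
class DeviationResult:
    """Outcome of a deviation computation.

    Attributes
    ----------
    deviation_mm
        Maximum orthogonal distance from the curved centerline to the
        ONH→(20 mm point) chord.
    arg_position_mm
        Arc length along the truncated trajectory at which the maximum
        occurs.
    chord_endpoints
        The two chord endpoints (ON head and the posterior trajectory
        point), as a (2, 3) array in mm.
    truncated_length_mm
        Trajectory length actually used (equals the requested length
        when the input path is long enough).
    parameters
        Resolved parameter set, echoed for provenance.
    """

    deviation_mm: float
    arg_position_mm: float
    chord_endpoints: np.ndarray
    truncated_length_mm: float
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "deviation_mm": self.deviation_mm,
            "arg_position_mm": self.arg_position_mm,
            "chord_endpoints": np.asarray(self.chord_endpoints).tolist(),
            "truncated_length_mm": self.truncated_length_mm,
            "parameters": dict(self.parameters),
        }


def load_centerline_csv(
    path,
    on_head=None,
    lens_center=None,
    snap_tol_mm: float = 1.0,
) -> Centerline:
    """Read an (X, Y, Z) centerline point list in mm from a CSV file.

    The file holds one point per row as three comma-separated numbers;
    an optional ``X,Y,Z`` header row is skipped. A comment line of the
    form ``# lens_center: x,y,z`` supplies the lens-center landmark.
    By convention the first point is the ON head unless ``on_head`` is
    given explicitly.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("lens_center"):
                    vals = body.split(":", 1)[1].split(",")
                    lens_center = [float(v) for v in vals]
                continue
            fields = [f.strip() for f in line.split(",")]
            try:
                vals = [float(f) for f in fields]
            except ValueError:
                if lineno == 1 and [f.upper() for f in fields[:3]] == ["X", "Y", "Z"]:
                    continue  # header row
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            if len(vals) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(vals)}"
                )
            rows.append(vals)
    if len(rows) < 3:
        raise ValidationError(
            f"{path}: centerline needs >= 3 points, found {len(rows)}"
        )
    pts = np.asarray(rows, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps <= 1e-12):
        i = int(np.argmax(steps <= 1e-12))
        raise ValidationError(
            f"{path}: duplicate consecutive points at rows {i + 1} and {i + 2}"
        )
    return Centerline(
        pts, on_head=on_head, lens_center=lens_center, snap_tol_mm=snap_tol_mm
    )


def fit_spline(points, sample_step_mm: float = DEFAULT_SAMPLE_STEP_MM) -> np.ndarray:
    """Densify a 3D point sequence with an interpolating cubic spline.

    The spline interpolates every input point (no smoothing) and is
    parameterized by cumulative chord length; the curve is sampled at
    uniform parameter steps so adjacent output points are at most
    ``sample_step_mm`` apart. With fewer than four points a cubic
    spline is under-determined and the function falls back to the
    piecewise-linear path with a warning.
    """
    if sample_step_mm <= 0:
        raise ValidationError(f"sample_step_mm must be positive, got {sample_step_mm}")
    if isinstance(points, Centerline):
        points = points.points
    pts = np.asarray(points, dtype=float)
    s = arc_length(pts)
    if len(pts) < 4:
        msg = "fewer than 4 centerline points: falling back to piecewise-linear path"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        n = max(1, int(np.ceil(s[-1] / sample_step_mm)))
        t = np.linspace(0.0, s[-1], n + 1)
        return np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])
    spline = CubicSpline(s, pts, axis=0)  # not-a-knot ends
    n = max(1, int(np.ceil(s[-1] / sample_step_mm)))
    t = np.linspace(0.0, s[-1], n + 1)
    return spline(t)


def truncate_at_arclength(path, length_mm: float) -> np.ndarray:
    """Prefix of a polyline with total chordal arc length ``length_mm``.

    The final point is linearly interpolated within the last segment so
    the returned path's arc length equals ``length_mm`` exactly (up to
    float). Raises if the path is too short, reporting the available
    length.
    """
    pts = np.asarray(path, dtype=float)
    s = arc_length(pts)
    total = s[-1]
    if total + 1e-9 < length_mm:
        raise ValidationError(
            f"path arc length {total:.3f} mm is shorter than the requested "
            f"{length_mm:.3f} mm"
        )
    if abs(total - length_mm) <= 1e-9:
        return pts.copy()
    i = int(np.searchsorted(s, length_mm, side="right"))
    frac = (length_mm - s[i - 1]) / (s[i] - s[i - 1])
    end = pts[i - 1] + frac * (pts[i] - pts[i - 1])
    return np.vstack([pts[:i], end])


def compute_deviation(
    centerline: Centerline,
    length_mm: float = DEFAULT_TRAJECTORY_MM,
    sample_step_mm: float = DEFAULT_SAMPLE_STEP_MM,
) -> DeviationResult:
    """Maximum orthogonal distance from the nerve path to the ONH chord.

    Pipeline: spline densification → truncation at ``length_mm`` of
    trajectory arc length measured from the ON head → maximum over the
    sampled curve of the perpendicular distance to the infinite line
    through the ON head and the trajectory endpoint. The result is
    invariant under rigid motion of the input.
    """
    pts = centerline.points
    head = centerline.on_head
    if np.linalg.norm(head - pts[0]) > 1e-9:
        pts = np.vstack([head, pts])  # chord is defined from the ON head
    curve = fit_spline(pts, sample_step_mm=sample_step_mm)
    curve = truncate_at_arclength(curve, length_mm)
    s = arc_length(curve)
    a, b = curve[0], curve[-1]
    dist = _distances_to_line(curve, a, b)
    k = int(np.argmax(dist))
    return DeviationResult(
        deviation_mm=float(dist[k]),
        arg_position_mm=float(s[k]),
        chord_endpoints=np.vstack([a, b]),
        truncated_length_mm=float(s[-1]),
        parameters={
            "length_mm": length_mm,
            "sample_step_mm": sample_step_mm,
        },
    )


def _distances_to_line(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized perpendicular distances; same convention as the scalar form."""
    d = b - a
    n = np.linalg.norm(d)
    if n <= 1e-12:
        # fully degenerate chord: fall back to scalar API for its error
        point_to_line_distance(points[0], a, b)
    return np.linalg.norm(np.cross(points - a, d), axis=1) / n
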