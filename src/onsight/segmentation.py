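"""Semi-automated ON/ONS cross-section extraction from coronal T2-like volumes.

Pipeline, per scan: per-slice background estimation from the intensity
histogram mode → cohort-normalized adaptive threshold → cubic in-plane
upsampling → iso-level contour extraction (marching squares) → contour
selection by point count and roundness → inter-slice interpolation to
the station 3 mm posterior to the ON head → cross-sectional areas and
circular-equivalent diameters.

In T2 contrast the cerebrospinal fluid filling the subarachnoid space
between nerve and sheath is bright, so a single iso-level yields two
nested contours: the inner one bounds the optic nerve (ON), the outer
one the optic nerve sheath (ONS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage import measure as _skmeasure

from .errors import SelectionError, ValidationError
from .geometry import Contour, isoperimetric_quotient, polygon_area

__all__ = [
    "ImageVolume",
    "ThresholdContext",
    "SliceMeasurement",
    "MeasureParams",
    "load_nifti",
    "save_nifti",
    "estimate_background",
    "scan_background",
    "compute_threshold",
    "upsample_slice",
    "extract_contours",
    "select_on_ons_contours",
    "resample_contour_radial",
    "interpolate_contour_at_offset",
    "equivalent_diameter",
    "measure_volume",
]

log = logging.getLogger(__name__)

INTENSITY_MAX_12BIT = 4095.0
T2_SPACING_MM = (0.253, 0.253, 0.600)


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar intensity grid with per-axis voxel spacing in mm.

    ``data[i, j, k]`` holds the intensity of the voxel whose centre is
    at ``(i*sx, j*sy, k*sz)`` mm (0-based indices, voxel-centre
    convention); ``k`` indexes coronal slices along the axial
    (slice-normal) axis. Intensities follow the 12-bit convention
    [0, ``intensity_max``].
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = T2_SPACING_MM
    intensity_max: float = INTENSITY_MAX_12BIT

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValidationError("volume data must be 3D")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {spacing}")
        if data.min() < 0 or data.max() > self.intensity_max:
            raise ValidationError(
                "intensities outside [0, "
                f"{self.intensity_max}]: range [{data.min()}, {data.max()}]"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "intensity_max", float(self.intensity_max))

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice_positions(self) -> np.ndarray:
        """Axial positions (mm) of the slice centres."""
        return np.arange(self.n_slices) * self.spacing[2]

    def get_slice(self, k: int) -> np.ndarray:
        return self.data[:, :, k]


def load_nifti(path, intensity_max: float = INTENSITY_MAX_12BIT) -> ImageVolume:
    """Load a NIfTI volume; spacing from the header, 12-bit rescale on demand.

    Volumes whose intensities fall outside [0, ``intensity_max``] are
    linearly rescaled onto that range with a logged provenance note.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    lo, hi = float(data.min()), float(data.max())
    if lo < 0 or hi > intensity_max:
        if hi == lo:
            raise ValidationError(f"{path}: constant volume cannot be rescaled")
        data = (data - lo) / (hi - lo) * intensity_max
        log.info(
            "%s: intensities [%g, %g] rescaled to [0, %g]", path, lo, hi, intensity_max
        )
    return ImageVolume(data, spacing=tuple(zooms), intensity_max=intensity_max)


def save_nifti(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal mm affine."""
    import nibabel as nib

    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# adaptive threshold


def estimate_background(
    slice2d: np.ndarray,
    mode_window: float | None = None,
    intensity_max: float = INTENSITY_MAX_12BIT,
    smooth_sigma: float | None = None,
) -> float:
    """Mean background intensity of one slice via the histogram mode.

    The slice is histogrammed at unit intensity bins; the modal bin
    locates the dominant (background) tissue, and the background level
    is the mean over pixels within ``mode_window`` of the mode
    (default: 10% of ``intensity_max``). To keep the mode stable under
    noise the histogram is smoothed with a Gaussian kernel
    (``smooth_sigma`` bins, default 1% of ``intensity_max``) before the
    argmax; bright CSF lies far outside the window and cannot bias the
    estimate.
    """
    vals = np.asarray(slice2d, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("cannot estimate background of an empty slice")
    if mode_window is None:
        mode_window = 0.10 * intensity_max
    if smooth_sigma is None:
        smooth_sigma = 0.01 * intensity_max
    edges = np.arange(0.0, intensity_max + 2.0)  # unit-width bins
    hist, _ = np.histogram(np.clip(vals, 0, intensity_max), bins=edges)
    if smooth_sigma > 0:
        hist = ndimage.gaussian_filter1d(hist.astype(float), smooth_sigma)
    mode = float(np.argmax(hist)) + 0.5  # bin centre
    mask = np.abs(vals - mode) <= mode_window
    if not mask.any():  # pathological: fall back to the modal bin itself
        return mode
    return float(vals[mask].mean())


def scan_background(volume: ImageVolume, mode_window: float | None = None) -> float:
    """Scan-level background: mean of the per-slice background estimates."""
    return float(
        np.mean(
            [
                estimate_background(
                    volume.get_slice(k), mode_window, volume.intensity_max
                )
                for k in range(volume.n_slices)
            ]
        )
    )


@dataclass(frozen=True)
class ThresholdContext:
    """Cohort context for the adaptive threshold.

    The segmentation threshold for a scan is its cohort-normalized
    offset from a common value C: under the ``literal`` convention
    T = C + (B̄ − B_s) where B_s is the scan's mean background and B̄
    the cohort mean background; ``brightness_tracking`` flips the sign,
    T = C + (B_s − B̄), so the threshold follows a scan's brightness.
    """

    background_per_scan: dict
    common_value: float
    sign_convention: str = "literal"

    def __post_init__(self) -> None:
        if self.common_value <= 0:
            raise ValidationError("common_value must be positive")
        if self.sign_convention not in ("literal", "brightness_tracking"):
            raise ValidationError(
                f"unknown sign convention {self.sign_convention!r}"
            )
        if not self.background_per_scan:
            raise ValidationError("background_per_scan is empty")
        object.__setattr__(
            self, "background_per_scan", dict(self.background_per_scan)
        )

    @property
    def cohort_mean_background(self) -> float:
        return float(np.mean(list(self.background_per_scan.values())))


def compute_threshold(ctx: ThresholdContext, scan_id) -> float:
    """Adaptive threshold for one scan under the context's sign convention."""
    if scan_id not in ctx.background_per_scan:
        raise ValidationError(f"scan {scan_id!r} not present in threshold context")
    b_s = ctx.background_per_scan[scan_id]
    b_bar = ctx.cohort_mean_background
    if ctx.sign_convention == "literal":
        return float(ctx.common_value + (b_bar - b_s))
    return float(ctx.common_value + (b_s - b_bar))


# ---------------------------------------------------------------------------
# contouring


def upsample_slice(slice2d: np.ndarray, factor: int) -> np.ndarray:
    """Cubic in-plane upsampling preserving original pixel-centre positions.

    Output index ``j`` maps to input index ``j/factor``, so original
    pixel centres land exactly on upsampled grid nodes and the mm
    coordinate of output pixel ``j`` is ``j * spacing / factor``.
    Output shape is ``(n-1)*factor + 1`` per axis.
    """
    if int(factor) != factor or factor < 1:
        raise ValidationError(f"upsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    arr = np.asarray(slice2d, dtype=float)
    if factor == 1:
        return arr.copy()
    ny, nx = arr.shape
    yi = np.arange((ny - 1) * factor + 1) / factor
    xi = np.arange((nx - 1) * factor + 1) / factor
    # interpolating bicubic spline: exact at pixel centres and exact for
    # (bi)linear data up to the image border
    spline = RectBivariateSpline(
        np.arange(ny), np.arange(nx), arr, kx=min(3, ny - 1), ky=min(3, nx - 1)
    )
    return spline(yi, xi)


def extract_contours(
    slice2d: np.ndarray,
    level: float,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    slice_position: float = 0.0,
) -> list[Contour]:
    """Closed iso-contours of a slice at an intensity level, in mm.

    Marching squares with linear interpolation along pixel edges
    (``skimage.measure.find_contours``). Open contours touching the
    image border and degenerate fragments are discarded; the empty list
    is a legitimate result.
    """
    arr = np.asarray(slice2d, dtype=float)
    out: list[Contour] = []
    for path in _skmeasure.find_contours(arr, level=level):
        if len(path) < 4 or not np.allclose(path[0], path[-1]):
            continue  # open contour hits the border
        pts_mm = path[:-1] * np.asarray(pixel_spacing_mm)
        try:
            out.append(Contour(pts_mm, slice_position=slice_position))
        except ValidationError:
            continue  # degenerate sliver
    return out


def select_on_ons_contours(
    contours: list[Contour],
    min_points: int = 20,
    q_min: float = 0.6,
) -> tuple[Contour, Contour]:
    """Pick the nested (ON, ONS) contour pair from iso-contour candidates.

    Candidates are filtered by vertex count (``min_points``, at the
    upsampled resolution) and isoperimetric quotient (``q_min``), which
    discards vessels and other elongated structures. Among the
    survivors the nested pair — outer contour containing the inner,
    centroids closer than half the inner equivalent radius — with the
    roundest inner member wins; inner is the ON boundary, outer the
    ONS boundary.
    """
    admissible = [
        c
        for c in contours
        if len(c) >= min_points and isoperimetric_quotient(c) >= q_min
    ]
    best: tuple[Contour, Contour] | None = None
    best_q = -np.inf
    for inner in admissible:
        a_in = polygon_area(inner)
        r_eq = np.sqrt(a_in / np.pi)
        for outer in admissible:
            if outer is inner or polygon_area(outer) <= a_in:
                continue
            if not outer.shapely.contains(inner.shapely):
                continue
            if np.linalg.norm(outer.centroid - inner.centroid) > 0.5 * r_eq:
                continue
            q_in = isoperimetric_quotient(inner)
            if q_in > best_q:
                best_q = q_in
                best = (inner, outer)
    if best is None:
        raise SelectionError(
            f"ON/ONS not found: no nested pair among {len(admissible)} contours "
            f"surviving filters (min_points={min_points}, q_min={q_min})"
        )
    return best


# ---------------------------------------------------------------------------
# inter-slice interpolation and derived measures


def equivalent_diameter(area_mm2: float) -> float:
    """Diameter of the circle with the same area: d = 2·sqrt(A/π)."""
    if area_mm2 <= 0:
        raise ValidationError(f"area must be positive, got {area_mm2}")
    return float(2.0 * np.sqrt(area_mm2 / np.pi))


@dataclass(frozen=True)
class SliceMeasurement:
    """Paired ON and ONS contours at a posterior offset, with derived measures."""

    on_contour: Contour
    ons_contour: Contour
    on_area_mm2: float
    ons_area_mm2: float
    on_diameter_mm: float
    ons_diameter_mm: float
    offset_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.on_area_mm2 < self.ons_area_mm2:
            raise ValidationError(
                f"ON area {self.on_area_mm2:.3f} must be smaller than ONS area "
                f"{self.ons_area_mm2:.3f}"
            )
        if not self.ons_contour.shapely.contains(self.on_contour.shapely):
            raise ValidationError("ON contour must lie strictly inside ONS contour")

    @classmethod
    def from_contours(
        cls, on: Contour, ons: Contour, offset_mm: float, provenance: dict | None = None
    ) -> "SliceMeasurement":
        a_on, a_ons = polygon_area(on), polygon_area(ons)
        return cls(
            on_contour=on,
            ons_contour=ons,
            on_area_mm2=a_on,
            ons_area_mm2=a_ons,
            on_diameter_mm=equivalent_diameter(a_on),
            ons_diameter_mm=equivalent_diameter(a_ons),
            offset_mm=float(offset_mm),
            provenance=provenance or {},
        )

    def to_dict(self) -> dict:
        return {
            "offset_mm": self.offset_mm,
            "on_area_mm2": self.on_area_mm2,
            "ons_area_mm2": self.ons_area_mm2,
            "on_diameter_mm": self.on_diameter_mm,
            "ons_diameter_mm": self.ons_diameter_mm,
            "provenance": dict(self.provenance),
        }


def resample_contour_radial(
    contour: Contour, n_angles: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a near-circular contour to radii at uniform angles.

    Returns ``(centroid, radii)`` where ``radii[k]`` is the distance
    from the area centroid at angle ``2πk/n_angles``. Vertex radii are
    interpolated periodically in angle about the centroid; this assumes
    the contour is star-shaped about its centroid, which the roundness
    filter guarantees in practice.
    """
    c = contour.centroid
    rel = contour.points - c
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    r = np.linalg.norm(rel, axis=1)
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic padding for interpolation across the 0/2π seam
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    targets = 2 * np.pi * np.arange(n_angles) / n_angles
    return c, np.interp(targets, theta_ext, r_ext)


def _radial_contour(center: np.ndarray, radii: np.ndarray, slice_position: float) -> Contour:
    n = len(radii)
    ang = 2 * np.pi * np.arange(n) / n
    pts = center + np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
    return Contour(pts, slice_position=slice_position)


def interpolate_contour_at_offset(
    per_slice: list[tuple[float, Contour, Contour]],
    on_head,
    offset_mm: float = 3.0,
    n_angles: int = 128,
    mode: str = "geometry",
) -> SliceMeasurement:
    """Interpolate the ON/ONS cross-section at a posterior offset.

    ``per_slice`` lists accepted slices as ``(slice_position, on, ons)``
    tuples; the target axial position is the ON-head axial coordinate
    plus ``offset_mm``. If the target coincides with a measured slice,
    that slice's contours are returned unchanged. Otherwise the two
    bracketing slices' contours are resampled to ``n_angles`` radii
    about their centroids and centroid and radii are blended linearly
    by axial weight (``mode="geometry"``); ``mode="area"`` blends the
    areas directly instead, as a cross-check.
    """
    if mode not in ("geometry", "area"):
        raise ValidationError(f"unknown interpolation mode {mode!r}")
    if not per_slice:
        raise ValidationError("no measured slices supplied")
    head = np.asarray(on_head, dtype=float)
    target = float(head[2] + offset_mm)
    entries = sorted(per_slice, key=lambda e: e[0])
    positions = np.array([e[0] for e in entries])

    prov = {"offset_mm": offset_mm, "interp_mode": mode, "n_angles": n_angles}
    exact = np.flatnonzero(np.isclose(positions, target, atol=1e-9))
    if exact.size:
        _, on, ons = entries[int(exact[0])]
        prov["interpolated"] = False
        return SliceMeasurement.from_contours(on, ons, offset_mm, prov)
    if target < positions[0] or target > positions[-1]:
        raise ValidationError(
            f"target position {target:.3f} mm outside measured coverage "
            f"[{positions[0]:.3f}, {positions[-1]:.3f}] mm"
        )
    hi = int(np.searchsorted(positions, target))
    lo = hi - 1
    z0, on0, ons0 = entries[lo]
    z1, on1, ons1 = entries[hi]
    w = (target - z0) / (z1 - z0)
    prov.update(interpolated=True, bracketing_slices=[z0, z1], axial_weight=w)

    blended = []
    for a, b in ((on0, on1), (ons0, ons1)):
        ca, ra = resample_contour_radial(a, n_angles)
        cb, rb = resample_contour_radial(b, n_angles)
        blended.append(
            _radial_contour((1 - w) * ca + w * cb, (1 - w) * ra + w * rb, target)
        )
    on_i, ons_i = blended
    if mode == "geometry":
        return SliceMeasurement.from_contours(on_i, ons_i, offset_mm, prov)
    # area mode: linear blend of the bracketing areas, blended contours kept
    a_on = (1 - w) * polygon_area(on0) + w * polygon_area(on1)
    a_ons = (1 - w) * polygon_area(ons0) + w * polygon_area(ons1)
    return SliceMeasurement(
        on_contour=on_i,
        ons_contour=ons_i,
        on_area_mm2=a_on,
        ons_area_mm2=a_ons,
        on_diameter_mm=equivalent_diameter(a_on),
        ons_diameter_mm=equivalent_diameter(a_ons),
        offset_mm=float(offset_mm),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass(frozen=True)
class MeasureParams:
    """Resolved parameter set for a segmentation run.

    ``common_value`` is the common threshold value C of the adaptive
    rule; the default sits midway between the phantom background and
    CSF intensities and must be chosen explicitly for real data.
    """

    common_value: float = 1850.0
    sign_convention: str = "literal"
    upsample_factor: int = 4
    min_points: int = 20
    q_min: float = 0.6
    offset_mm: float = 3.0
    n_angles: int = 128
    interp_mode: str = "geometry"
    mode_window: float | None = None
    z_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["z_range"] = list(self.z_range) if self.z_range else None
        return d


def measure_volume(
    volume: ImageVolume,
    on_head,
    params: MeasureParams | None = None,
    ctx: ThresholdContext | None = None,
    scan_id="scan",
) -> tuple[SliceMeasurement, pd.DataFrame]:
    """Run the full segmentation pipeline on one scan.

    Per slice: background estimation → (cohort) threshold → cubic
    upsampling → iso-contouring → ON/ONS selection; slices where no
    admissible nested pair exists are logged and excluded. The per-slice
    contour table is returned alongside the interpolated measurement at
    ``params.offset_mm`` posterior to the ON head. Deterministic given
    inputs and parameters.

    When ``ctx`` is None a single-scan context is built from this
    volume's own background (so the threshold reduces to the common
    value C).
    """
    params = params or MeasureParams()
    head = np.asarray(on_head, dtype=float)
    nx, ny, nz = volume.data.shape
    sx, sy, sz = volume.spacing
    extent = (nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz
    if np.any(head < -1e-9) or np.any(head > np.asarray(extent) + 1e-9):
        raise ValidationError(
            f"ON head {head.tolist()} outside volume extent {extent} mm"
        )

    if ctx is None:
        b = scan_background(volume, params.mode_window)
        ctx = ThresholdContext(
            {scan_id: b},
            common_value=params.common_value,
            sign_convention=params.sign_convention,
        )
    threshold = compute_threshold(ctx, scan_id)

    spacing_up = (sx / params.upsample_factor, sy / params.upsample_factor)
    accepted: list[tuple[float, Contour, Contour]] = []
    rows = []
    for k in range(volume.n_slices):
        z = k * sz
        if params.z_range is not None and not (
            params.z_range[0] - 1e-9 <= z <= params.z_range[1] + 1e-9
        ):
            continue
        up = upsample_slice(volume.get_slice(k), params.upsample_factor)
        contours = extract_contours(up, threshold, spacing_up, slice_position=z)
        row = {"slice_position_mm": z, "n_contours": len(contours)}
        try:
            on, ons = select_on_ons_contours(
                contours, min_points=params.min_points, q_min=params.q_min
            )
        except SelectionError as err:
            log.info("slice %d (z=%.2f mm) excluded: %s", k, z, err)
            row.update(
                on_area_mm2=np.nan, ons_area_mm2=np.nan, on_q=np.nan, ons_q=np.nan
            )
            rows.append(row)
            continue
        accepted.append((z, on, ons))
        row.update(
            on_area_mm2=polygon_area(on),
            ons_area_mm2=polygon_area(ons),
            on_q=isoperimetric_quotient(on),
            ons_q=isoperimetric_quotient(ons),
        )
        rows.append(row)

    table = pd.DataFrame(rows)
    measurement = interpolate_contour_at_offset(
        accepted,
        head,
        offset_mm=params.offset_mm,
        n_angles=params.n_angles,
        mode=params.interp_mode,
    )
    prov = dict(measurement.provenance)
    prov.update(
        threshold=threshold,
        scan_background=ctx.background_per_scan[scan_id],
        cohort_mean_background=ctx.cohort_mean_background,
        sign_convention=ctx.sign_convention,
        params=params.to_dict(),
        on_head=head.tolist(),
        n_slices_accepted=len(accepted),
    )
    measurement = SliceMeasurement(
        on_contour=measurement.on_contour,
        ons_contour=measurement.ons_contour,
        on_area_mm2=measurement.on_area_mm2,
        ons_area_mm2=measurement.ons_area_mm2,
        on_diameter_mm=measurement.on_diameter_mm,
        ons_diameter_mm=measurement.ons_diameter_mm,
        offset_mm=measurement.offset_mm,
        provenance=prov,
    )
    return measurement, table
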