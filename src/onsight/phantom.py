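"""Digital phantoms with analytic ground truth.

Synthesizes T2-like volumes of known ON/ONS geometry — a concentric
nerve/sheath tube whose sheath diameter tapers linearly along the axis
— and operator-like centerline point picks of known deviation, so the
deviation, segmentation and reliability modules are testable without
access to restricted subject data.

The idealized geometry follows the printed reference dimensions: sheath
outer diameter 7 mm tapering to 5 mm over a 2 cm axial length, nerve
diameter 3.35 mm, concentric; voxels 253 μm in-plane, 600 μm slices.
Voxel values are partial-volume-weighted region means (3× supersampling
per axis) with optional Rician noise, the magnitude-MRI noise model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import Centerline
from .segmentation import ImageVolume, INTENSITY_MAX_12BIT, T2_SPACING_MM

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_idealized_phantom",
    "generate_subject_like_phantom",
    "generate_deviation_fixture",
    "write_centerline_csv",
]

_SUPERSAMPLE = 3  # partial-volume subdivisions per axis


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition and noise parameters of a digital phantom.

    ``snr`` is the ratio of the CSF mean intensity to the Rician noise
    σ; ``math.inf`` disables noise. ``intensities`` orders the region
    means as (background/fat, nerve, CSF), mimicking T2 contrast where
    CSF is much brighter than fat, which is brighter than nerve.
    ``fov_xy_mm`` sets the in-plane extent of the synthesized grid.
    """

    ons_diameter_wide: float = 7.0
    ons_diameter_narrow: float = 5.0
    on_diameter: float = 3.35
    axial_length: float = 20.0
    spacing: tuple[float, float, float] = T2_SPACING_MM
    intensities: tuple[float, float, float] = (700.0, 500.0, 3000.0)
    snr: float = math.inf
    seed: int = 0
    fov_xy_mm: float = 12.0
    bend_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if not (self.on_diameter < self.ons_diameter_narrow <= self.ons_diameter_wide):
            raise ValidationError(
                "need on_diameter < ons_diameter_narrow <= ons_diameter_wide, got "
                f"{self.on_diameter}, {self.ons_diameter_narrow}, "
                f"{self.ons_diameter_wide}"
            )
        if self.axial_length <= 0:
            raise ValidationError("axial_length must be positive")
        if not self.snr > 0:
            raise ValidationError("snr must be positive (math.inf for noise-free)")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.ons_diameter_wide >= self.fov_xy_mm:
            raise ValidationError(
                f"sheath diameter {self.ons_diameter_wide} mm does not fit the "
                f"{self.fov_xy_mm} mm in-plane field of view"
            )

    def ons_radius_at(self, z: float) -> float:
        """Sheath outer radius at axial position z (linear taper), in mm."""
        z = min(max(z, 0.0), self.axial_length)
        d = self.ons_diameter_wide - (
            self.ons_diameter_wide - self.ons_diameter_narrow
        ) * z / self.axial_length
        return 0.5 * d

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spacing"] = list(self.spacing)
        d["intensities"] = list(self.intensities)
        d["snr"] = None if math.isinf(self.snr) else self.snr
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-slice truth for a generated phantom."""

    slice_positions: np.ndarray
    on_areas_mm2: np.ndarray
    ons_areas_mm2: np.ndarray
    on_diameters_mm: np.ndarray
    ons_diameters_mm: np.ndarray
    centerline: np.ndarray  # straight tube axis, (n, 3) mm
    on_head: np.ndarray  # anterior end of the axis, mm
    deviation_mm: float
    spec: PhantomSpec
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slice_positions": np.asarray(self.slice_positions).tolist(),
            "on_areas_mm2": np.asarray(self.on_areas_mm2).tolist(),
            "ons_areas_mm2": np.asarray(self.ons_areas_mm2).tolist(),
            "on_diameters_mm": np.asarray(self.on_diameters_mm).tolist(),
            "ons_diameters_mm": np.asarray(self.ons_diameters_mm).tolist(),
            "centerline": np.asarray(self.centerline).tolist(),
            "on_head": np.asarray(self.on_head).tolist(),
            "deviation_mm": self.deviation_mm,
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "extras": self.extras,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _grid(spec: PhantomSpec):
    """Supersampled in-plane coordinates and voxel-grid shape."""
    sx, sy, sz = spec.spacing
    nx = int(round(spec.fov_xy_mm / sx))
    ny = int(round(spec.fov_xy_mm / sy))
    nz = int(math.floor(spec.axial_length / sz + 1e-9)) + 1
    cx, cy = (nx - 1) / 2 * sx, (ny - 1) / 2 * sy
    # sub-pixel centres: 3 per voxel at offsets (-s/3, 0, +s/3) about the centre
    xs = ((np.arange(nx * _SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5) * sx
    ys = ((np.arange(ny * _SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5) * sy
    return nx, ny, nz, cx, cy, xs, ys


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex Gaussian perturbation of the clean signal."""
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(clean + n1, n2)


def _render(spec: PhantomSpec, radius_fn) -> np.ndarray:
    """Rasterize a tube whose sheath radius is ``radius_fn(theta, z)``.

    Partial volume by averaging region intensities over a 3×3×3
    supersampled subdivision of every voxel.
    """
    nx, ny, nz, cx, cy, xs, ys = _grid(spec)
    sx, sy, sz = spec.spacing
    i_bg, i_on, i_csf = spec.intensities
    r_on = 0.5 * spec.on_diameter
    X, Y = np.meshgrid(xs - cx, ys - cy, indexing="ij")
    R = np.hypot(X, Y)
    TH = np.arctan2(Y, X)
    vol = np.empty((nx, ny, nz))
    sub_dz = (np.arange(_SUPERSAMPLE) - (_SUPERSAMPLE - 1) / 2) / _SUPERSAMPLE * sz
    for k in range(nz):
        acc = np.zeros_like(R)
        for dz in sub_dz:
            z = np.clip(k * sz + dz, 0.0, spec.axial_length)
            r_ons = radius_fn(TH, z)
            img = np.where(R < r_on, i_on, np.where(R < r_ons, i_csf, i_bg))
            acc += img
        acc /= _SUPERSAMPLE
        vol[:, :, k] = acc.reshape(
            nx, _SUPERSAMPLE, ny, _SUPERSAMPLE
        ).mean(axis=(1, 3))
    return vol


def _finalize(spec: PhantomSpec, vol: np.ndarray) -> ImageVolume:
    if math.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.intensities[2] / spec.snr
        vol = _rician(vol, sigma, rng)
    vol = np.clip(vol, 0.0, INTENSITY_MAX_12BIT)
    return ImageVolume(vol, spacing=spec.spacing)


def _truth(
    spec: PhantomSpec, ons_area_fn, extras: dict | None = None
) -> GroundTruth:
    _, _, nz, cx, cy, _, _ = _grid(spec)
    sz = spec.spacing[2]
    zs = np.arange(nz) * sz
    r_on = 0.5 * spec.on_diameter
    on_areas = np.full(nz, np.pi * r_on**2)
    ons_areas = np.array([ons_area_fn(z) for z in zs])
    axis = np.column_stack([np.full(nz, cx), np.full(nz, cy), zs])
    return GroundTruth(
        slice_positions=zs,
        on_areas_mm2=on_areas,
        ons_areas_mm2=ons_areas,
        on_diameters_mm=2 * np.sqrt(on_areas / np.pi),
        ons_diameters_mm=2 * np.sqrt(ons_areas / np.pi),
        centerline=axis,
        on_head=axis[0],
        deviation_mm=0.0,
        spec=spec,
        seed=spec.seed,
        extras=extras or {},
    )


def generate_idealized_phantom(spec: PhantomSpec | None = None):
    """Concentric nerve/sheath tube with linearly tapering sheath.

    Returns ``(ImageVolume, GroundTruth)``; identical specs (including
    seed) give identical volumes.
    """
    spec = spec or PhantomSpec()
    vol = _render(spec, lambda th, z: spec.ons_radius_at(z))
    truth = _truth(spec, lambda z: np.pi * spec.ons_radius_at(z) ** 2)
    return _finalize(spec, vol), truth


def generate_subject_like_phantom(
    spec: PhantomSpec | None = None, irregularity: float = 0.3
):
    """Tube with angular cross-section irregularity, emulating real sheaths.

    The sheath radius is perturbed by a seeded low-order Fourier series
    in angle, r(θ, z) = r̄(z) + Σₘ aₘ cos(mθ + φₘ) for m = 2..4 with
    amplitudes scaled by ``irregularity`` (mm). The true area follows
    the closed form π r̄² + (π/2) Σ aₘ². Perturbations that would touch
    the nerve are rejected.
    """
    spec = spec or PhantomSpec()
    if irregularity < 0:
        raise ValidationError("irregularity must be >= 0")
    rng = np.random.default_rng(spec.seed + 10_007)
    modes = np.arange(2, 5)
    weights = rng.uniform(0.4, 1.0, len(modes))
    amps = irregularity * weights / np.sqrt(np.sum(weights**2))
    phases = rng.uniform(0.0, 2 * np.pi, len(modes))

    r_min_base = spec.ons_radius_at(spec.axial_length)
    if r_min_base - np.sum(amps) <= 0.5 * spec.on_diameter:
        raise ValidationError(
            f"irregularity {irregularity} mm would let the sheath touch the nerve "
            f"(narrow-end clearance {r_min_base - 0.5 * spec.on_diameter:.3f} mm)"
        )

    def radius_fn(th, z):
        pert = sum(a * np.cos(m * th + p) for a, m, p in zip(amps, modes, phases))
        return spec.ons_radius_at(z) + pert

    fourier_area = 0.5 * np.pi * float(np.sum(amps**2))
    vol = _render(spec, radius_fn)
    truth = _truth(
        spec,
        lambda z: np.pi * spec.ons_radius_at(z) ** 2 + fourier_area,
        extras={
            "irregularity_mm": irregularity,
            "fourier_modes": modes.tolist(),
            "fourier_amplitudes_mm": amps.tolist(),
            "fourier_phases_rad": phases.tolist(),
        },
    )
    return _finalize(spec, vol), truth


def generate_deviation_fixture(
    bend_radius_mm: float | None = 50.0,
    n_points: int = 16,
    jitter_mm: float = 0.0,
    seed: int = 0,
    span_mm: float = 24.0,
    trajectory_mm: float = 20.0,
):
    """Operator-like centerline picks on a circular arc of known deviation.

    Points are placed on a planar arc of the given radius at uniform
    spacing ``span_mm / (n_points - 1)`` (defaults give ~1.6 mm, in the
    1–2 mm range of manual picking), with optional isotropic Gaussian
    jitter. ``bend_radius_mm=None`` (or ``inf``) gives a straight path.
    Returns ``(Centerline, true_deviation_mm)`` where the truth is the
    sagitta R·(1 − cos(L/2R)) of the ``trajectory_mm`` arc.
    """
    if n_points < 4:
        raise ValidationError("n_points must be >= 4")
    if jitter_mm < 0:
        raise ValidationError("jitter_mm must be >= 0")
    if span_mm <= trajectory_mm:
        raise ValidationError(
            f"span_mm ({span_mm}) must exceed trajectory_mm ({trajectory_mm})"
        )
    straight = bend_radius_mm is None or math.isinf(bend_radius_mm)
    if not straight and bend_radius_mm < trajectory_mm / 2 + 0.05:
        raise ValidationError(
            f"bend radius {bend_radius_mm} mm too small: a {trajectory_mm} mm arc "
            "must subtend at most a half circle"
        )
    s = np.linspace(0.0, span_mm, n_points)
    if straight:
        pts = np.column_stack([np.zeros(n_points), np.zeros(n_points), s])
        true_dev = 0.0
    else:
        R = float(bend_radius_mm)
        ang = s / R
        pts = np.column_stack(
            [R * np.sin(ang), np.zeros(n_points), R * (1.0 - np.cos(ang))]
        )
        true_dev = R * (1.0 - math.cos(trajectory_mm / (2 * R)))
    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_mm, pts.shape)
    return Centerline(pts, snap_tol_mm=max(1.0, 5 * jitter_mm)), true_dev


def write_centerline_csv(centerline: Centerline, path) -> None:
    """Write a centerline as an X,Y,Z CSV (header row, mm units)."""
    with open(path, "w") as fh:
        fh.write("X,Y,Z\n")
        if centerline.lens_center is not None:
            lc = ",".join(f"{v:.6f}" for v in centerline.lens_center)
            fh.write(f"# lens_center: {lc}\n")
        for p in centerline.points:
            fh.write(",".join(f"{v:.6f}" for v in p) + "\n")
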