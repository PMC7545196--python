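# Methods

This note documents the models, conventions and numerical choices behind
`onsight`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and intensity conventions

All geometry is carried in physical millimetres. Voxel indices are 0-based;
a voxel's mm coordinate is its centre, `index × spacing`; the axial (slice)
position of coronal slice *k* is `k × slice_spacing`. Conversion happens
once, at I/O, so no half-voxel offsets leak into the geometry. Intensities
follow the 12-bit MRI convention [0, 4095]; volumes outside that range are
linearly rescaled on load with a logged note. Planar contours are normalized
to counter-clockwise orientation and validated as simple polygons (shapely's
validity predicate backs the check); areas are shoelace areas, reported as
absolute values.

## ON deviation

The nerve path is an ordered list of operator-picked 3D points, the first
being the optic nerve head (ONH) by convention (an explicit ONH within a
1 mm snap tolerance of the first point is also accepted and is prepended to
the path, since the chord is defined from the ONH). An interpolating cubic
spline (not-a-knot ends, chord-length parameterization, no smoothing) is
sampled at ≤ 0.1 mm steps, truncated at 20 mm of trajectory arc length, and
the deviation is the maximum perpendicular distance from the sampled curve
to the *infinite line* through the chord endpoints — for points between the
endpoints this equals the distance to the segment, and the infinite-line
reading keeps the functional continuous.

Choices worth noting:

- **Interpolation, not smoothing.** No smoothing parameter is defensible a
  priori; operator jitter is instead characterized by the reliability
  module, which is how repeatability is assessed in practice.
- **Arc length, not Euclidean distance**, defines the 20 mm truncation:
  "trajectory length" denotes path length.
- **Sample step 0.1 mm** makes the discretization error of the maximum far
  below the ~0.5 mm in-plane resolution of T1 picks; tests verify halving
  the step changes the result by < 1e-3 mm, and that the closed-form sagitta
  of circular arcs (R from 15 to 100 mm) is matched to < 1e-3 mm.
- The maximum-distance statistic is **upward biased under pick jitter**
  (the spline amplifies knot noise and the max selects the largest
  excursion): at 0.2 mm isotropic jitter the Monte-Carlo bias is a bit
  under 0.2 mm. This is a property of the definition, not of the
  implementation, and is documented by a test.

## ON/ONS segmentation

T2 contrast orders the tissues CSF ≫ fat > nerve, so one iso-level between
CSF and its surroundings yields two nested contours per slice: inner = ON
boundary, outer = ONS boundary.

1. **Background estimation.** Each slice is histogrammed at unit intensity
   bins; the modal bin locates the dominant background tissue and the
   background level is the mean over pixels within ±10% of the intensity
   ceiling around the mode, which excludes bright CSF by construction. The
   histogram is smoothed with a Gaussian kernel (σ = 1% of the ceiling)
   before the argmax: the raw mode of a noisy slice is unstable, while the
   smoothed mode varies by only a few units. The windowed mean's seed-to-seed
   stability is pure sampling error (σ/√n), so it is tested at a realistic
   slice size (64 mm field of view, ~65k pixels), where it stays within 2
   intensity units at SNR 20.
2. **Adaptive threshold.** T = C + (B̄ − Bₛ) with C a common value, Bₛ the
   scan background and B̄ the cohort mean. C is deliberately explicit
   (default 1850, midway between the phantom's fat and CSF intensities);
   for real data it must be chosen by the user. The literal sign convention
   above is the default; a `brightness_tracking` alternative
   T = C + (Bₛ − B̄) is provided because the literal sign lowers the
   threshold for *brighter* scans, which is arguably inverted; the
   convention used is recorded in output provenance.
3. **Upsampling.** In-plane 4× (≈ 63 μm effective pixels) by an
   interpolating bicubic spline that leaves original pixel centres exact and
   reproduces linear ramps exactly, including at the border. Spline
   interpolation of a step edge rings at ~9% of the step height; a test
   bounds the overshoot.
4. **Contouring and selection.** Marching squares at level T; open contours
   touching the border are discarded. Candidates need ≥ 20 vertices (at the
   upsampled resolution) and isoperimetric quotient Q = 4πA/P² ≥ 0.6 —
   vessels and other elongated structures fail the roundness filter. Among
   survivors, the nested pair (outer strictly contains inner, centroids
   within half the inner equivalent radius) with the roundest inner member
   is selected. The point-count filter is a minimum; both thresholds are
   configurable.
5. **Inter-slice interpolation.** Accepted slices' contours are resampled to
   128 radii by angle about their area centroids (the roundness filter
   guarantees star-shapedness in practice), and centroid and radii are
   blended linearly in axial position to the station 3 mm posterior to the
   ONH; a target falling exactly on a slice returns that slice's contours
   unchanged. "3 mm along the nerve trajectory" is implemented as 3 mm along
   the slice-normal axis: per-slice contours are indexed by axial position
   and the bulbar nerve segment is near-straight over 3 mm (a logged
   approximation). An area-only interpolation mode (linear blend of the two
   bracketing areas) is available as a cross-check.
6. **Derived measures.** Equivalent diameter d = 2√(A/π); the measurement
   record embeds threshold, backgrounds, convention, and the full resolved
   parameter set.

A physical limit worth knowing: a partial-volume edge is one voxel wide, so
moving the threshold across the middle half of the CSF–fat contrast shifts
the boundary by ±0.25 voxel (±63 μm) and the sheath area by ~8–9% — the
pipeline is threshold-robust only on the scale of that bound, which the
property test asserts (middle-quarter sweeps stay below 5%).

## Digital phantoms

The idealized phantom is a concentric tube: nerve diameter 3.35 mm, sheath
outer diameter tapering linearly 7 → 5 mm over a 20 mm axial length,
rendered at (0.253, 0.253, 0.600) mm voxels. Region intensities default to
(700, 500, 3000) for fat/background, nerve and CSF — conventional values
that reproduce T2 contrast ordering, recorded in the ground truth, not a
physical MR simulation (no k-space, bias fields, or material model). Partial
volume comes from 3× supersampling per axis (voxel value = mean region
intensity over 27 sub-voxels); noise is Rician — the magnitude-MRI
distribution, |signal + complex Gaussian| — with σ = CSF mean / SNR and a
mandatory seed. The in-plane grid defaults to a compact 12 mm field around
the 7 mm tube; the full 64 mm acquisition field is available via
`fov_xy_mm` where realistic pixel counts matter (background statistics).

The subject-like variant perturbs the sheath radius by a seeded low-order
Fourier series in angle, r(θ, z) = r̄(z) + Σₘ aₘ cos(mθ + φₘ), m = 2..4,
with amplitudes scaled to a requested irregularity; the true area has the
closed form π r̄² + (π/2) Σ aₘ². Perturbations that would touch the nerve
are rejected. Centerline fixtures place picks at ~1.6 mm spacing on circular
arcs (or a straight line) with optional Gaussian jitter; truth is the
sagitta closed form.

What the phantoms do *not* emulate: orbital anatomy around the sheath,
intensity inhomogeneity, motion, partial Fourier artefacts, or the contrast
mechanism of a physical printed phantom. Passing phantom tests therefore
demonstrates correctness of the geometry→measurement chain under controlled
contrast, not clinical robustness.

## Reliability statistics

Given a complete case × repeat table: the consensus per case is the mean
over repeats (treated as truth in the absence of a gold standard);
differences from it are reported as absolute values with their mean and
population SD over all measurements, plus the same as percentages of the
case consensus. The CV is the per-case sample SD divided by the case mean,
averaged over cases, reported as a fraction. The ICC defaults to ICC(2,1)
(two-way random effects, absolute agreement, single measurement), computed
from ANOVA mean squares; a one-way form is available; a zero-variance table
is defined as ICC 1 with a logged note. The implementation is cross-checked
in tests against an independent sums-of-squares oracle and against
pingouin.

Small-sample behaviour matters here: the ANOVA ICC estimator is consistent
but biased low in tiny designs (≈ −0.08 at 4 cases × 3 raters for a
population ICC of 2/3, ≈ −0.02 at 12 × 4). The test suite documents the
4×3 bias explicitly and checks parameter recovery at the 12×4 scale.

## Study conditions used in the end-to-end checks

- Phantom recovery: printed tube dimensions, noise-free and SNR 20, full
  34-slice stack, measurement at the 3 mm station.
- Two-scan study: six geometries spanning a plausible anatomical sheath
  range (wide diameters 6.0–8.4 mm; three idealized, three subject-like at
  0.3 mm irregularity), two independent noise seeds each at SNR 20. Six
  *distinct* geometries are used because between-case variance is what an
  ICC measures; identical replicas would leave it undefined.
- ICC simulation: 2000 tables of 12 cases × 4 raters from variance
  components (4, 1, 1).

These sizes keep the whole suite at a few seconds on one CPU while leaving
every tolerance comfortably non-trivial.

## Known limitations

- Centerline extraction is out of scope: picks come from files (or the
  fixture generator), as in manual multiplanar workflows.
- Contour interpolation assumes star-shaped contours; grossly non-convex
  sheaths would need a different correspondence scheme.
- The threshold's common value C has no data-driven default for real scans.
- The deviation statistic's jitter bias (above) means averaging repeated
  picks, not single measurements, is the reliable protocol.
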