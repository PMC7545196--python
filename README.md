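# onsight

MRI morphometry of the optic nerve (ON) and optic nerve sheath (ONS).

Long-duration spaceflight — and, clinically, raised intracranial pressure —
can distend the CSF-filled sheath around the optic nerve and kink the nerve
itself. `onsight` implements a reproducible, semi-automated pipeline for
quantifying both effects from research MRI:

- **ON deviation** from T1-type centerline picks: an interpolating cubic
  spline is fit to operator-selected points along the nerve, truncated at a
  trajectory length of *L* = 20 mm posterior to the optic nerve head (ONH),
  and the deviation is the maximum orthogonal distance between the curve and
  the ONH→endpoint chord. For a circular arc this is the sagitta,
  *D* = *R*·(1 − cos(*L*/2*R*)).
- **ON/ONS cross-sections** from coronal T2-type volumes (bright CSF): a
  per-scan background level *B*ₛ is estimated from the intensity-histogram
  mode of each slice; the segmentation threshold is the cohort-normalized
  *T* = *C* + (*B̄* − *B*ₛ) around a common value *C*; slices are cubically
  upsampled and iso-contoured at *T*; the nested (inner, outer) contour pair
  surviving a point-count filter and an isoperimetric-quotient
  (*Q* = 4π*A*/*P*²) roundness filter gives the ON and ONS boundaries; linear
  inter-slice interpolation yields the cross-section 3 mm posterior to the
  ONH, reported as areas (mm²) and circular-equivalent diameters
  *d* = 2·√(*A*/π).
- **Digital phantoms** with analytic ground truth: a concentric nerve/sheath
  tube (sheath 7 mm tapering to 5 mm over 2 cm, nerve 3.35 mm) rendered at
  253 μm/600 μm voxels with partial-volume averaging and Rician noise, plus
  jittered centerline fixtures of known deviation.
- **Reliability statistics** for repeated measurements: ICC(2,1) from ANOVA
  variance components, coefficient of variation, and mean ± SD of case-wise
  differences from the consensus value.

## Worked example

```python
from onsight import PhantomSpec, generate_idealized_phantom, measure_volume

volume, truth = generate_idealized_phantom(PhantomSpec(snr=20.0, seed=1))
measurement, table = measure_volume(volume, truth.on_head)
print(f"ON  area at 3 mm: {measurement.on_area_mm2:.2f} mm^2")
print(f"ONS area at 3 mm: {measurement.ons_area_mm2:.2f} mm^2")
print(f"ONS equivalent diameter: {measurement.ons_diameter_mm:.2f} mm")
```

prints

```
ON  area at 3 mm: 8.88 mm^2
ONS area at 3 mm: 35.31 mm^2
ONS equivalent diameter: 6.71 mm
```

The analytic truths are π·(3.35/2)² = 8.81 mm² for the nerve and
π·(6.7/2)² = 35.26 mm² for the sheath (the 7→5 mm taper reaches 6.7 mm
diameter 3 mm down the tube), so the pipeline recovers both to better than
1% at SNR 20. More narrative scripts live in `examples/` — one per
capability (deviation, segmentation, reliability, and a two-scan phantom
study).

A thin CLI mirrors the library:

```bash
onsight phantom --kind idealized --snr 20 --seed 1 --out vol.nii --truth truth.json
onsight segment vol.nii --on-head 5.8 5.8 0 --out measurement.json
onsight deviation centerline.csv --out deviation.json
onsight reliability ratings.csv --out report.json
```

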