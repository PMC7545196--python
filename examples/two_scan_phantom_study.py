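"""Digital analog of scanning a physical phantom twice.

Six tube geometries (three idealized tapers, three with irregular
subject-like cross-sections) are each synthesized twice with
independent noise at SNR 20 and segmented identically; the two "scans"
form a ratings table whose ICC and difference SD quantify scan-rescan
reliability of the sheath area.
"""

import numpy as np

from onsight import (
    PhantomSpec,
    RatingsTable,
    generate_idealized_phantom,
    generate_subject_like_phantom,
    icc,
    measure_volume,
)

geometries = [(6.0, "idealized"), (7.0, "idealized"), (8.0, "idealized"),
              (6.4, "subject"), (7.2, "subject"), (7.8, "subject")]

rows = []
for i, (wide, kind) in enumerate(geometries):
    row = []
    for scan_seed in (101, 202):
        spec = PhantomSpec(ons_diameter_wide=wide, ons_diameter_narrow=wide - 2.0,
                           snr=20.0, seed=scan_seed + 13 * i)
        if kind == "idealized":
            volume, truth = generate_idealized_phantom(spec)
        else:
            volume, truth = generate_subject_like_phantom(spec, irregularity=0.3)
        m, _ = measure_volume(volume, truth.on_head)
        row.append(m.ons_area_mm2)
    rows.append(row)

arr = np.asarray(rows)
diffs = arr[:, 0] - arr[:, 1]
print("ONS areas (mm^2), scan 1 vs scan 2:")
for (wide, kind), (a, b) in zip(geometries, arr):
    print(f"  {kind:9s} wide {wide:.1f} mm:  {a:6.2f}  {b:6.2f}")
print(f"scan-rescan difference SD: {diffs.std(ddof=1):.3f} mm^2")
print(f"ICC(2,1) across geometries: {icc(RatingsTable(arr)):.4f}")
# Differences of ~0.1 mm^2 against geometry spreads of ~7 mm^2 give an
# ICC near 1: the pipeline's noise floor is far below anatomical spread.
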