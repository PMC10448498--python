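"""Dilution-series calibration: slope, linear range, LOD, detection volume.

Simulates a dilution series spanning four decades, counts double spots in
every frame, fits the weighted calibration line, and derives the limit of
detection (3.3 x blank SD / slope).  The slope doubles as an absolute
measure of the detection volume: slope = N_A x V, so no external standard
is needed.
"""

import numpy as np

from duospot.optics import CameraGeometry
from duospot.simulate import N_A, DetectionSlab, simulate_dilution_series
from duospot.detect import DetectionParams, count_double_spots
from duospot.quantify import (CalibrationSeries, absolute_concentration,
                              disc_volume, fit_calibration,
                              lod_from_calibration, scan_budget)

geom = CameraGeometry(frame_size_px=512)
slab = DetectionSlab.for_geometry(geom)
c_top = 15.0 / (N_A * slab.volume_fL * 1e-15)
levels = [0.0, 0.0] + [c_top * f for f in (1e-4, 1e-3, 1e-2, 0.1, 1.0)]

series = simulate_dilution_series(levels, 40, geom=geom, slab=slab, seed=4)
params = DetectionParams(expected_separation_px=9.4)  # Er full-spectrum pair

rows = []
for stack, _ in series:
    counts, _ = count_double_spots(stack, params)
    half = len(counts) // 2  # two replicate "slides" per level
    reps = np.array([counts[:half].mean(), counts[half:].mean()])
    rows.append((stack.metadata["concentration_mol_per_L"],
                 reps.mean(), reps.std(ddof=1)))
conc, mean, sd = map(np.array, zip(*rows))
for c, m, s in rows:
    print(f"  {c: .3e} mol/L -> {m:6.2f} +/- {s:.2f} counts/frame")

cal = fit_calibration(CalibrationSeries(conc, mean, sd))
print(f"\nslope {cal.slope:.3e} counts/frame per mol/L, R^2 {cal.r_squared:.4f}")
print(f"implied detection volume {cal.slope / (N_A * 1e-15):.0f} fL "
      f"(configured slab: {slab.volume_fL:.0f} fL)")

blanks = mean[conc == 0]
lod = lod_from_calibration(cal, blanks)
print(f"LOD = 3.3 x SD(blank) / slope = {lod:.2e} mol/L")
if lod == 0:
    print("(the 5-sigma detector produced no false positives in the blank "
          "frames, so the blank SD -- and hence the noise-limited LOD -- is "
          "zero here; on a real instrument the blank is never perfectly "
          "clean)")

print(f"\nabsolute counting: 6.02 spots in 1000 fL -> "
      f"{absolute_concentration(6.02, 1000.0)*1e12:.1f} pmol/L")
print(f"full-size geometry disc volume: {disc_volume(111, 0.7):.0f} fL")
n, t = scan_budget(30, 0.7, 10, 2)
print(f"scanning a 30 um droplet in 0.7 um steps: {n} steps, {t:.0f} ms")
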