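"""Render synthetic camera frames of diffusing nanoparticle labels.

Simulates the long-pass imaging regime: Tm-Er bioaffinity clusters appear
as 6.5 px double spots, unbound conjugates as single spots, on a shot-noise
background.  The ground-truth table records every rendered spot.
"""

from duospot.optics import CameraGeometry
from duospot.simulate import (DetectionSlab, FilterConfig, cluster_spec,
                              er_streptavidin_spec, expected_emitters,
                              simulate_stack, tm_biotin_spec,
                              true_pair_counts)

geom = CameraGeometry(frame_size_px=512)
filt = FilterConfig("longpass", cutoff_nm=600.0)
slab = DetectionSlab.for_geometry(geom)  # disc of the field, 0.7 um thick
print(f"detection volume: {slab.volume_fL:.0f} fL "
      f"(disc {slab.disc_diameter_um:.1f} um x {slab.thickness_um} um)")

conc = 10e-12  # 10 pmol/L of clusters
print(f"expected clusters per frame at 10 pmol/L: "
      f"{expected_emitters(conc, slab.volume_fL):.1f}")

mix = [(cluster_spec(filt), conc),
       (tm_biotin_spec(filt), 0.5 * conc),
       (er_streptavidin_spec(filt), 0.5 * conc)]
stack, truth = simulate_stack(mix, 5, slab, geom, filt, seed=1)

counts = true_pair_counts(truth, stack.n_frames)
print(f"rendered {stack.n_frames} frames of {geom.frame_size_px} px; "
      f"true double spots per frame: {counts.tolist()}")
print(f"truth table: {len(truth)} spots, "
      f"{truth.photons.sum():.0f} photons total")
print("each row of the truth table is one rendered spot "
      "(frame, emitter, species, n-mer, position, offsets, photons)")
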