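"""Generate a synthetic beating-heart acquisition and print its ground truth.

The phantom is a stack of contracting annuli with exactly countable
volumes; the printed metrics are the reference against which undersampled
reconstructions are judged.
"""

from cscine import PhantomSpec, generate_phantom

spec = PhantomSpec.scaled(matrix=128, n_frames=20, n_slices=4)
series, truth = generate_phantom(spec)

print(f"slices: {spec.n_slices}, frames/cycle: {spec.n_frames}, "
      f"matrix: {spec.matrix}, pixel {spec.pixel_size_mm*1000:.0f} um")
print(f"EDV  {truth.edv_ul:6.2f} uL   (end-diastolic blood pool, frame {truth.ed_frame})")
print(f"ESV  {truth.esv_ul:6.2f} uL   (end-systolic blood pool, frame {truth.es_frame})")
print(f"SV   {truth.sv_ul:6.2f} uL   (= EDV - ESV)")
print(f"EF   {truth.ef_pct:6.2f} %    (= 100*SV/EDV)")
print(f"LVM  {truth.lvm_mg:6.2f} mg   (myocardium at end-diastole x 1.05 mg/uL)")
print("Volumes are voxel counts of the rasterized masks, so quantifying the")
print("noiseless images reproduces them exactly.")
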