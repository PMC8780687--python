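"""Measure valve morphology from labels + landmarks and compare with truth.

Runs the full measurement pipeline (plane fits, cusp rim splitting, surface
geodesics, cross-section perimeters) on a voxelized phantom and prints each
of the 19 values next to its analytic reference.  Length items recover to
well under 2 voxels, perimeters and geodesics to a few percent.
"""

from valvemorph import PhantomSpec, build_phantom, measure_all

spec = PhantomSpec()
labels, truth = build_phantom(spec)
report = measure_all(labels, truth.landmarks)

print(f"{'item':30s} {'measured':>9s} {'analytic':>9s} {'error':>8s}")
for key, measured in report.to_dict().items():
    ref = truth.measurements[key]
    print(f"{key:30s} {measured:9.2f} {ref:9.2f} {measured - ref:+8.2f}")
print("\nAll values in mm; errors reflect voxelization at "
      f"{spec.voxel_spacing} mm spacing.")
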