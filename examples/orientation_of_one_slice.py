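"""Orientation analysis of a single optical section.

Builds a synthetic fluorescent fiber field with a known dominant
orientation, runs the FFT orientation pipeline on it, and prints the
recovered median angle, the alignment range (angular width of the top 70%
of the orientation-intensity mass; small = well aligned) and the scalar
anisotropy index.
"""

from fibrospect import (
    RunConfig,
    SyntheticConstructSpec,
    analyze_slice,
    anisotropy_index,
    generate_fiber_image,
)

spec = SyntheticConstructSpec(
    n_slices=1,
    orientation_schedule=[35.0],  # true dominant orientation, degrees
    kappa=4.0,                    # axial von Mises concentration
    seed=42,
)
image, truth = generate_fiber_image(spec, slice_idx=0)

profile, summary = analyze_slice(image, RunConfig())

print(f"true mean orientation : {truth['scheduled_angle_deg']:.1f} deg")
print(f"fibers drawn          : {truth['n_fibers']}")
print(f"recovered median angle: {summary.median_angle_deg:.1f} deg")
print(f"alignment range       : {summary.range_deg:.1f} deg (top 70% of mass)")
print(f"anisotropy index      : {anisotropy_index(profile):.3f}")
print()
print("The median angle should sit within a few degrees of the true 35 deg;")
print("the range says how tightly the fibers cluster around it (180 deg")
print("would be fully random, a few degrees near-perfect alignment).")
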