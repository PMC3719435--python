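# fibrospect

FFT-based quantification of fiber and cell orientation in confocal
z-stacks, for tissue-engineering and matrix-biology labs that image
cell-assembled collagenous constructs (e.g. corneal stromal models) as
z-series of fluorescently stained optical sections. The package measures,
per optical section, how strongly fibers or cells are aligned and in which
direction, tracks how that direction rotates with depth through the
construct, and adds the accompanying z-stack morphometrics: construct
thickness from the z-extent of cell visibility, per-plane cell counts from
a nuclear stain, and the group statistics used to compare treatment
conditions. A synthetic construct generator with stored ground truth makes
every estimator testable by parameter recovery.

## Method

For each optical section *I(x, y)* (grayscale; RGB is reduced with
Rec. 709 luminance weights):

1. **Power spectrum.** The mean-subtracted, Hann-windowed section is
   Fourier transformed; *P(u, v) = |F{I}|²* is centred and a small disc
   (radius 3 px) around zero frequency is masked to remove illumination
   leakage. The Hann window suppresses the axis-aligned cross artifact of
   non-periodic boundaries that would otherwise bias orientation toward
   0°/90°.
2. **Polar orientation profile.** Every spectral pixel with radius
   *r* ∈ (3, min(200, inscribed radius)] contributes its intensity to the
   1° angular bin of its polar angle on the 180°-periodic axial circle
   (fiber orientation is direction-less). Because a fiber's spectral
   energy lies perpendicular to the fiber, the histogram is rotated by 90°
   so reported angles are real-space fiber orientations; it is then
   normalized to unit mass.
3. **Orientation summary.** The *alignment range* Δθ is the length of the
   smallest contiguous arc holding 70% of the orientation-intensity mass
   (the "top 70% of the population"): 180° × 0.7 = 126° for a fully random
   section, a few degrees for near-perfect alignment. The *median angle*
   is the angle splitting that arc's mass in half — the dominant
   orientation.
4. **Depth profiles.** Plotting Δθ against z gives the alignment profile.
   The per-slice median angles, unwrapped with the minimal axial
   representative (each step mapped into (−90°, +90°]), give the rotation
   profile; its max − min is the rotation range and steps ≥ 30° are
   flagged as sudden reorientations.

Thickness is (last − first cell-visible section) × z-step under a
stack-global Otsu foreground criterion; counting is per plane-of-focus
with Otsu binarization, small-object removal and distance-transform
watershed splitting; group comparison uses Welch's t-test and Dunnett's
many-to-one adjusted comparison against the control.

## Worked example

`examples/alignment_and_rotation_profiles.py` builds a 40-slice synthetic
construct whose dominant orientation rotates at a programmed 2°/slice and
recovers the depth profiles:

```
slices                : 40 at 0.5 um steps
mean alignment range  : 13.8 deg
rotation rate         : 1.99 deg/slice (true 2.00)
total rotation range  : 78.6 deg (scheduled 78.0)
sudden jumps >= 30 deg: []
```

The mean alignment range of 13.8° says each section is strongly aligned
(126° would be random); the recovered rotation rate and total range match
the programmed schedule to within a few percent, and no spurious sudden
jumps are reported for this smooth twist. The other example scripts cover
single-slice orientation analysis, thickness + cell counting, and group
statistics, each printing the numbers it computes alongside the ground
truth.

The same pipeline runs from the shell on real data:

```sh
fibrospect analyze --stack stack.tif --z-step 0.5 --channel SMA --out results/
fibrospect thickness --stack nuclei.tif --z-step 0.5
fibrospect count --stack nuclei.tif --z-step 0.5
fibrospect compare --csv thickness.csv --control Control
fibrospect simulate --spec spec.json --out synthetic/
```

`analyze` writes per-slice CSV tables (z, median angle, alignment range,
unwrapped angle, empty flag), per-slice polar histograms and a JSON run
manifest.

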