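# Methods

## Scope and model

fibrospect quantifies the planar organization of fluorescently labeled
fibers or cells in confocal z-series. The underlying model is that each
optical section contains a population of roughly straight, elongated
structures whose orientations follow some axial (180°-periodic)
distribution, and that this distribution's location can drift — smoothly
or suddenly — from section to section through the depth of the construct.
The analysis makes no assumption about the distribution's family; the
alignment range and median are order statistics of the measured
orientation histogram.

## Spectral orientation estimation

**Windowing and DC masking.** Sections are mean-subtracted and multiplied
by a separable 2D Hann window before the FFT. Without the window, the
implicit periodic continuation of a non-periodic image creates a bright
axis-aligned cross in the spectrum that systematically biases orientation
histograms toward 0° and 90°. A disc of radius `dc_mask_radius_px`
(default 3 px) around the zero-frequency pixel is zeroed to remove
residual DC and slow illumination gradients. `window="none"` disables the
window for users who want the raw behavior.

**Polar integration.** Orientation mass is accumulated by per-pixel
binning: each spectral pixel inside the annulus
`(dc_mask_radius, min(r_max, inscribed radius)]` adds its full intensity
to the 1° bin of its polar angle. Compared with sampling along rays, this
conserves spectral mass exactly and introduces no interpolation bias; the
mass-conservation property is asserted in the test suite against an
independent binning oracle. The outer radius defaults to 200 spectral
pixels and is clipped (with a logged notice) to the largest inscribed
radius for smaller images. The histogram is rotated 90° so angles refer to
real-space structure orientation, with the convention: degrees in
[0°, 180°), 0° along the image x-axis, counter-clockwise positive with y
up (image rows run along −y). Bin centres sit at 0.5°, 1.5°, …, 179.5°.

**Top-70% summary.** The alignment range is defined through the smallest
contiguous arc on the axial circle holding at least `mass_fraction`
(default 0.70) of the histogram mass. The search is over every (start,
length) circular window; among windows of the minimal qualifying length
the one holding the most mass is selected, since at a 1° resolution
several starts typically tie on length and the heaviest window best
represents the top population (picking, say, the first window after the
peak instead skews the arc to one side and biases the median by 1–3° on
smooth unimodal profiles). Exact mass ties fall back to the start closest
cyclically forward of the peak bin, which makes the result deterministic.
The median angle is the point splitting the selected arc's mass into
halves, linearly interpolated inside the boundary bin. For an exactly
uniform profile these definitions force a range of 0.70 × 180° = 126°.
The alternative reading of "top 70% of the population" — the 70% of bins
with the highest intensity, not necessarily contiguous — was considered
and rejected: it produces disconnected angular sets with no natural width
or median for multimodal profiles.

**Empty sections.** A section whose post-mask annulus mass falls below
`min_signal_fraction` (default 0.001) of its own total spectral power, or
whose variance is zero, is flagged empty. Empty flags propagate: summaries
are NaN, profiles carry per-slice flags, and stack statistics exclude
flagged slices rather than treating them as zeros.

**Anisotropy index.** `1 − range/180°` is provided as a convenience
scalar: 0.30 for a uniform profile at the default mass fraction, → 0.994
as the mass concentrates into a single 1° bin. A Monte Carlo calibration
over 100 seeded white-noise images (run inside the test suite) bounds the
index of structure-free images below 0.35, far from the ≳ 0.8 values of
aligned fiber fields.

## Depth profiles

The per-slice angle fed into the rotation track is the top-70% mass median
(consistent with the alignment statistic); the histogram peak is available
behind `angle_stat="peak"`. Steps between consecutive defined angles are
reduced to the minimal axial representative in (−90°, +90°] — an exact
±90° step resolves to +90° as a deterministic tie-break — and accumulated
into an unwrapped real-valued track, so a slow lamellar twist that crosses
the 0°/180° seam stays continuous. Empty slices inherit the previous
defined angle with a flag and contribute no step, so isolated dark planes
cannot fabricate jumps; leading empty slices are backfilled from the first
defined angle. The rotation range is max − min of the unwrapped track over
defined slices; jumps are steps with |Δ| above a configurable threshold
(default 30°; no canonical value exists, and detected jumps report the
depth of the arriving slice).

## Morphometrics

**Thickness.** A single Otsu threshold computed on the whole stack's
intensity histogram defines foreground; a slice is cell-visible when its
foreground fraction is ≥ `occupancy_threshold` (default 0.005, exposed
because the original criterion is a human observer's "first/last cell
visible"). Thickness is the fence-post distance
(last − first) × z-step between the first and last visible planes; the
alternative (+1 plane) convention was rejected to keep thickness a
distance between plane positions. The measurement is invariant to global
intensity rescaling because the Otsu threshold scales with the data.

**Counting.** Counting is per plane-of-focus with no 3D linking, matching
how confocal cell counts per construct are reported in this setting. Each
slice is Gaussian-smoothed (σ = 1 px), binarized with the stack-global
Otsu threshold, cleaned of components below `min_area_px` (default 20 px),
and touching objects are split by a watershed on the negated distance
transform seeded at distance maxima at least `split_min_distance_px`
(default 5 px) apart. The global (rather than per-slice) threshold is
deliberate: Otsu always splits a histogram, so a per-slice threshold on a
nuclei-free noise slice would fabricate foreground, while the global
threshold leaves such slices at zero counts.

**Group statistics.** `compare_groups` runs two-sided two-sample t-tests
for all pairwise contrasts — Welch's unequal-variance form by default,
pooled Student's behind `equal_var=True` — and Dunnett's many-to-one
comparison of every treatment against the control. Dunnett's procedure
pools variance across all groups by definition, so its adjusted p is
guaranteed not to undercut the unadjusted p of the same pooled contrast
(the test suite checks this, and cross-checks the single-contrast case
against the closed-form Student t tail, which Dunnett's distribution
reduces to when only one comparison is made).

## Synthetic constructs

The generator emulates the statistical structure the analysis assumes:
straight-line fibers with orientations drawn from an axial von Mises
distribution (sampled by the standard doubling construction: von Mises on
the full circle at 2µ, halved back; κ = 0 is isotropic, κ capped at 1e6),
rasterized as anti-aliased strokes of configurable width, blurred by a
Gaussian PSF and degraded with Gaussian or Poisson noise. Slices are
generated independently given their scheduled mean angle, matching the
per-slice nature of the analysis. Nuclei stacks place non-overlapping
Gaussian blobs (rejection sampling, centre separation ≥ 3 × radius, with
a placement-attempt guard) inside an occupancy band of slices.

Defaults describe a desk-scale construct consistent with the imaging
conditions the analysis targets: 256 × 256 px sections, 40 slices at
0.5 µm (a ~20 µm construct, the thickness scale of TGF-β-stimulated
constructs), ~1 fiber per kilopixel of 120 px length and 2 px width,
PSF σ = 1 px, additive Gaussian noise at 2% of the dynamic range, and
~30 nuclei of radius 4 px per slice. Determinism: identical spec + seed
yields bit-identical stacks (per-slice child RNG streams from a seed
sequence), which the suite asserts.

What the generator does *not* emulate: depth-dependent attenuation and
scattering, anisotropic PSFs, fibers curving or crossing slice boundaries
coherently, fluorophore photophysics, and non-fiber background structure.
Passing parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated image-formation model, not robustness to every
artifact of real confocal data.

## Fixture choices for the recovery experiments

- Orientation-recovery and equivariance fixtures use κ = 1e6 (effectively
  single-orientation fields) with noise off, isolating the spectral
  estimator's accuracy; recovery is within ±2° at every multiple of 15°.
- Rotation-rate recovery uses κ = 50 (strongly aligned lamellae — the
  regime in which a rotation profile is scientifically meaningful). At
  low concentration the per-slice angle noise, not the unwrapping or the
  slope fit, dominates the error at slow rates, which is a property of the
  input, not of the estimator under test.
- The paired-density counting experiment programs exact per-slice counts
  (20 vs 50) rather than Poisson draws, so the recovered 2.5× ratio
  measures counting fidelity instead of Poisson sampling noise.
- Rotation-equivariance tests crop images to the inscribed circle before
  and after rotation, removing corner regions that rotation would move in
  or out of the frame.

## Numerical notes and limitations

- All angles are reported in degrees; arcs and medians are exact in bin
  arithmetic with a single linear interpolation inside the boundary bin.
- Mass comparisons in the arc search use a 1e-12 relative slack so that
  floating-point rounding cannot change the selected arc length.
- The spectral estimator reports one global orientation distribution per
  slice; it does not produce local (patchwise) orientation maps, and no
  volumetric 3D orientation tensor is computed.
- Proprietary microscope formats (LIF, CZI) are out of scope; inputs are
  multi-page TIFF stacks. `pixel_size_um` is carried as metadata only —
  all spectral radii are in pixel units.
- For very small images the clipped integration radius lowers the angular
  resolution of the profile; images ≥ 128 px across are recommended.
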