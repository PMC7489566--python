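# Methods

## Coordinate and intensity conventions

All coordinates are 0-based `(row, col)` with row 0 at the top; "proximal"
is down the image (a PA wrist view with the hand up). Pixel spacing is
isotropic in mm/pixel; DICOM headers with two spacing values are accepted
only when they agree within 1%, `PixelSpacing` (calibrated) preferred over
`ImagerPixelSpacing`. MONOCHROME1 payloads are re-inverted on read so bone
is always bright. Intensities are used linearly; no exposure normalisation
is applied, and all intensity thresholds in the pipeline are relative
(fractions of local medians, peaks or dynamic range), so the measurements
do not depend on the absolute exposure scale.

## Pre-processing

**Orientation.** The central third of the image (rows `[R/3, 2R/3)`, cols
`[C/3, 2C/3)`; floor start, ceil length so the thirds tile) is where the
radius and ulna dominate. Canny edges are computed with Gaussian σ = 2 px
and hysteresis thresholds derived from the gradient histogram (high = Otsu
threshold of the Sobel magnitude, low = 0.55 × high) — the edge images this
produces are stable across the exposure range without per-image tuning. A
straight-line Hough transform at 0.5° angular resolution follows; up to 5
accumulator peaks are kept (minimum separation 5° / 20 px in (θ, ρ); vote
ties broken toward the smaller |angle|), and the **median** of their angles
from vertical is the forearm inclination. The median is what makes the
estimate robust to one spurious line (a cast edge, an annotation). If no
peak exists (featureless image) the angle falls back to 0° with a warning
so the measurement stages still run. Rotation is bilinear about the image
centre onto an enlarged canvas (fill 0); landmarks given on the original
image are mapped through the identical affine transform.

**Collimator removal.** On digital radiographs the pixels outside the
collimated field are exactly zero while the exposed field, however dark,
is strictly positive. The mask is therefore the union of exactly-zero
connected components (8-connectivity) that touch the image border, dilated
by a disc of radius 5 px to also swallow the bright collimation lines at
the field edge. Interior zero blobs (burnt-in annotations) are deliberately
left alone. Downstream, edge pixels adjacent to exact zeros are ignored by
the boundary tracer, so the mask and the rotation fill can never be
mistaken for anatomy.

## Forearm widths (10 ratios)

Below the lunate row, the outermost left/right Canny edge columns per row
are the soft-tissue boundary (a plaster cast, when present, *is* the outer
boundary — swelling under a cast is part of what the family measures).
Rows with no edge pair are linearly interpolated (error if > 30% missing),
then both boundaries are median-smoothed over 11 rows. Eight horizontal
width lines are placed: line 1 at 5 mm below the lunate row (the figure
geometry puts line 1 just proximal to the wrist; the offset is
configurable), lines 2–8 each 10 mm further, i.e. `round(10 mm / spacing)`
px apart. W1 is the most distal line. The ten reported quantities are the
ratios `Wi/W4` (i ≠ 4), `min/max`, `(W1+W8)/(W4+W5)` and
`(W1+W2)/(W7+W8)`; being ratios they are unit-free and scale-invariant.
Widths are horizontal because pre-processing has made the forearm vertical;
no local-normal estimate is attempted.

## Finger radiogrammetry (2 measurements)

A square ROI of side 30 mm is cut around the metacarpal landmark and
rotated so the finger axis (strongest Hough line in the ROI) is vertical —
the global rotation aligns the forearm, not the fingers. Column means
(ignoring rotation-fill zeros) give a 1-D profile with the two-peak
signature of a long bone: bright cortical shells flanking a dimmer
trabecular core. Segmentation on the profile:

* background = median of the outer 10% of columns;
* cortical peaks = the two tallest maxima with prominence ≥ 5% of the
  profile's dynamic range (the prominence floor suppresses trabecular
  texture);
* bone edges = outermost sub-pixel crossings of (background + peak)/2;
* trabecular interval = between the sub-pixel points where the profile
  falls to the midpoint of each cortical peak and the central minimum.

`Trabecular Area / Total Area` is the interval-length ratio (both regions
share the ROI height, so the 2-D area ratio reduces to 1-D exactly), and
`Width Finger` the edge distance in px. The exact delimitation rule for
the cortical/trabecular border is a declared choice of this package: the
midpoint-crossing rule is deterministic, sub-pixel, and invariant to
affine intensity rescaling, which the tests enforce.

## LBP texture (10 coefficients)

The texture ROI is placed without user input: from the styloid, 10 mm
along the unit vector toward the lunate plus 10 mm proximally (down),
a 15 mm square — on the phantom this is verified to land entirely on the
distal radius. The descriptor is the rotation-invariant uniform LBP
(P = 8, R = 1): each of the 8 neighbours of a 3×3 neighbourhood is compared
to the centre (≥ counts as 1 — the tie rule must be fixed for determinism;
a constant region therefore codes as the all-ones pattern), the circular
8-bit pattern maps to 10 classes (uniform patterns → their popcount, bins
0–8; all others → bin 9), and the class histogram is normalised to sum 1.
This is the only standard LBP formulation with exactly 10 output values.
The neighbour order (east first, counterclockwise) does not affect the
riu2 classes but is fixed so an independent per-pixel oracle can compare
bit-for-bit. Because the coding uses only intensity order, the histogram
is invariant under any strictly increasing intensity transform.

## Intensity profiles (10 statistics)

The baseline runs styloid → lunate. Each profile line is the baseline
rotated ±30° or ±45°; the sense is auto-resolved by sampling the first
10 px of both candidates and keeping the brighter one (the line should run
*into* the radius). Samples are taken at 1 px steps with bilinear
interpolation up to the image border; the trace terminates at the first
sample below 0.5 × the median of the first quarter of the border-limited
ray — the sharp drop where the ray exits the radius into the dark
inter-bone gap. Two guards: a trace shorter than 5 samples is an error,
and so is a styloid whose first samples are not brighter than the image's
median positive intensity (the landmark is off the bone). Per line:
least-squares slope over the whole trace and over the leading 50% of
samples ("short segment" — the fraction is configurable since no standard
definition exists), the raw sample standard deviation, the standard
deviation after removing the least-squares line (never larger than raw,
by the projection property of least squares), and the length in px.
The slopes and standard deviations are invariant to adding a constant to
the trace; the *termination point* is not, because the threshold is
relative — translation invariance is therefore a property of the
statistics, not of the tracing.

## Group statistics

Seven contrasts per measurement: control v patient (union of the four
fracture groups), pre v post, successful v unsuccessful, and the four
elementary pairs. The groups are independent samples of unequal size with
no case pairing, so the default test is Welch's two-sample *t*-test
(two-sided); Student and paired variants are selectable for designs that
support them. Zero-variance degenerate inputs give p = 1 when means agree.
Non-finite measurements (a failed family on one case) are dropped pairwise
with a logged count; a contrast left with fewer than 2 cases per side is
reported as NaN, not an error. Raw p-values are reported with a
significance flag at α = 0.05; Benjamini–Hochberg columns are available
behind a flag but off by default, matching the raw-p-value reporting
convention of the measurement table this mirrors.

## Phantom generator

The phantom renders, at true physical scale (default 180 × 140 mm at
0.2 mm/px): an exactly-zero collimator frame (40 px) around a strictly
positive field; a vertical forearm soft-tissue band (intensity 60 over
background 20) whose width follows a prescribed 8-point profile
interpolated per row (default 320…300 px, mild distal swelling); radius
(22 mm wide) and ulna (14 mm) as bone bands (intensity 200) separated by a
10 mm soft gap, the radius reaching 8 mm further distally and carrying the
styloid landmark; a lunate blob distal to the radius; and a finger
metacarpal (50 px bone width: 17 px trabecular half-width at 140, 8 px
cortical shells at 220) that can be tilted independently. Trabecular
regions carry Gaussian-smoothed noise (σ_corr = 2 px, SD 8 after
smoothing, seeded `default_rng`). The scene is rendered vertical, then
rotated by the true angle with the *same* bilinear operator the
pre-processing uses, so recovery error isolates detection accuracy.
Ground truth includes the transformed landmarks, the true widths, the
analytic finger ratio, anatomy masks, and profile gap distances obtained
by ray-marching the radius mask.

What the phantom does **not** emulate: x-ray physics (scatter, beam
hardening, heel effect), overlapping carpal anatomy, casts and metalwork,
exposure variation, and anatomical shape variability. Passing the phantom
suite therefore demonstrates the correctness and calibration of the
geometry and texture machinery under known truth — not clinical accuracy
on real radiographs.

`generate_cohort` synthesises measurement *tables* directly (no images)
for fast statistical testing: per-measurement baseline means/SDs of
realistic magnitude (ratios ≈ 1 ± 0.05, LBP bins at a plausible histogram
± 0.01, profile statistics at phantom magnitudes) with optional planted
group shifts in SD units.

## Problem sizes and numerical choices

The default test subject is one 900 × 700 phantom (≈ 1 s end to end);
orientation calibration uses 20 phantoms with angles U(−25°, 25°); the
type-I-error check runs 1000 null simulations at n = 20 per arm; the
study-level round trip uses 10 phantoms across the 5 groups. Tolerances:
orientation MAE ≤ 1° (Hough quantisation alone contributes ≤ 0.25°),
widths within 5%, finger ratio within 10%, profile distance within 3 px,
LBP oracle equality to machine precision. Ties and degenerate inputs are
resolved as documented above (LBP ≥ rule, Hough smaller-|angle| rule,
orientation fallback 0°, p = 1 for identical constant samples).

## Known limitations

* Landmark placement is manual by design; the three points are consumed
  from files, and their inter-observer variability is outside the scope of
  the automated stages.
* The width family measures the outer soft-tissue (or cast) boundary; it
  cannot separate oedema from cast padding.
* The finger segmentation assumes a clean two-peak profile; severely
  osteoporotic or overlapped fingers raise its error.
* The profile termination rule assumes the styloid-side bone is brighter
  than the inter-bone gap by at least a factor of two locally; unusual
  exposures can terminate early or late.
* The Canny/Hough parameter defaults are declared (and configurable), not
  claimed identical to any other implementation of this pipeline.
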