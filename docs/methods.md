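# Methods

This note documents the models, conventions and design choices behind
girthvision: what each stage computes, what the synthetic scene does and
does not emulate, and the numerical decisions a user may want to revisit.

## Measurement model

The subject is treated as a stack of body segments; each girth is the
circumference of one cross-section.  A calibrated stereo rig (pinhole
cameras, no lens distortion) views the segment from four turntable angles.
All 3-D quantities are metres; girths are reported in centimetres; pixel
coordinates are 0-based and continuous with the origin at the top-left
pixel centre, x rightward, y downward; camera frames are right-handed with
+z forward and +y down, so image axes coincide with camera axes.

**Triangulation** returns the midpoint of the common perpendicular between
the two back-projected rays, in the left-camera frame.  This symmetric
construction needs no rectification and degrades gracefully under sub-pixel
detection noise; rays closer than 1e-6 rad to parallel are rejected as
degenerate.

**Turntable de-rotation** rotates each view's reconstructed points by the
negative turntable angle about the axis, expressed in the same frame as the
points.  In practice the axis comes from the scene configuration (it is
known exactly in simulation); estimating it from data is out of scope.

**Closed-curve girth fitting.**  The named curve-fitting method of the
measurement literature (PIVCF) is defined outside the sources this package
is built from, so the implemented fit is a documented surrogate behind a
small interface: points are projected onto the plane normal to the body
axis, sorted by azimuth about their centroid, deduplicated, and
interpolated by a periodic cubic spline parameterised by cumulative chord
length (the intermediate variable); the reported girth is the spline's arc
length, integrated by the trapezoid rule on 4096 samples.  On 36 exact
points of an ellipse with 80–100 cm perimeter the fit agrees with adaptive
quadrature of the arc-length integral to better than 0.01%; halving or
doubling the point density moves the result by well under 0.1%.  The fit is
invariant to point ordering and to rigid motions of the point set together
with the axis.

**Selection rules.**  Three adjacent lines are measured one checkerboard
step apart; bust, hip and thigh report the maximum, the waist the minimum
(garment-measurement convention), and under-bust/mid-thigh are read from a
dedicated line shifted two steps below the bust/thigh baseline.

## Pixel-step model

One 2.5 cm checkerboard interval spans
`N_step = round(7.02 D² − 45.18 D + 93.43)` pixels at shooting distance D
metres (25 px at D = 2.4 m).  The quadratic is an empirical fit for a
specific rig; its validity range is taken as 1.5–3.0 m — outside it a
warning is logged and the value still returned, since the parabola turns
upward near 3.2 m where the model stops being physical.  The multi-line
shift uses N_step directly; the marker rectangle's half-cell margins absorb
the small difference between the fitted step and the true projected pitch.

## Colour classification

Markers are classified in HSV with hue in [0, 180] and saturation/value in
[0, 255].  Precedence: black (value below 46) first, then white, then red
(two hue intervals, 0–10 and 156–180), then cyan (hue 78–99).  Intervals
are half-open [min, max), closed at the full-scale top so pure white
(V = 255) and hue 180 (≡ 0) stay representable.  The reference table's
white value ceiling of 225 is read as a misprint for 255; the red
saturation minimum follows the table (45) rather than the accompanying
prose (43).  Every bound is configurable.  Marker pixel sets keep only the
largest connected blob per colour, guarding against stray pixels; centroids
are plain coordinate means.

## Corner detection

Shi–Tomasi response: min-eigenvalue of the structure tensor of central-
difference gradients after Gaussian pre-smoothing (σ = 1.0 px), averaged
over a 5×5 window.  Detection keeps local maxima above 0.05 of the peak
response, greedily suppressing neighbours within 12 px (about half the
checkerboard pixel pitch at the default rig, so at most one detection per
physical corner).  Responses within a border margin (half window + 3σ) are
artefacts of edge padding and are zeroed; a segmentation mask, eroded by
3 px to exclude silhouette-edge responses, restricts the search.

Sub-pixel refinement iterates the gradient-orthogonality normal equations
with bilinearly sampled gradients and a Gaussian window weighting, moving
at most half a window from the start, until the shift falls below 1e-3 px
or 40 iterations.  The default window is 7×7: on the default render a 5×5
window leaves ~0.3 px RMS error while 7×7 reaches ~0.17 px RMS (max
< 0.5 px), and larger windows gain little while risking contamination from
neighbouring cell edges at oblique viewing angles.

## Stereo matching

The regional constraint keeps corners strictly inside the axis-aligned
rectangle between the red and cyan centroids (min/max bounds, so swapping
the markers changes nothing; boundary corners are excluded).  Surviving
corners are ordered by ascending x, ties broken by ascending y — ties
cannot occur on a single corner row, the tie-break only keeps the order
total.  Equal left/right counts are a hard precondition; a mismatch raises
with per-view diagnostics rather than truncating, because no recovery rule
is defined for the physical setup.

## The synthetic scene

The simulator emulates the study conditions: an elliptic-cylinder body
segment (default circular, radius 0.13 m → girth 81.68 cm, in the 80–110 cm
regime of real torso measurements), checkerboard texture laid out by
surface arc length with exactly 2.5 cm vertical spacing, four marker cells,
and a verged stereo rig (focal 2400 px, 640×480 images, baseline 0.16 m) at
D = 2.4 m on a turntable whose axis is the body axis.

Circumferentially the perimeter is divided into the nearest **even** number
of cells (even so the wrapped pattern alternates seamlessly); the cells
stretch slightly like a garment, e.g. 32 cells of 2.55 cm on the default
body.  The four markers sit at near-quarter spacings — the classic
(8, 7, 8, 7)-interval pattern on a 30-cell garment — at rows ±0.5 so every
red/cyan pair straddles the same baseline corner row, and each marker fills
one whole cell, so its edges coincide with the grid and create no spurious
corner locations.  The default turntable angles are the pair-facing angles
(exactly 0/90/180/270° for the default layout); together the four
constrained rectangles tile the full circumference.

Rendering is analytic ray/ellipse-cylinder intersection per pixel with 3×3
supersampling (box-filter anti-aliasing), flat colours chosen to fall
inside the intended HSV windows, optional additive Gaussian pixel noise
(σ in 8-bit units, default 0), and a single integer seed driving all
randomness.  Ground truth — corner and marker 3-D positions, outward
normals (for visibility reasoning), and the exact cross-section perimeter
from dense arc-length quadrature — comes from the same closed-form geometry
the renderer uses.

Deliberately not modelled: cloth wrinkles and stretch inhomogeneity,
lighting/shading, lens distortion, calibration error, body asymmetry and
segmentation failures.  Passing tests therefore demonstrate the pipeline's
correctness and its noise behaviour under ideal optics, not robustness to
garment or calibration artefacts.

The procedural segmentation fixtures (soft-edged elliptical silhouettes
with intensity noise and colour casts) exercise the training loop only;
they are far easier than real human-body segmentation.

## Network accounting

The backbone is the standard deep residual topology (7×7/64 stride-2 stem,
3×3/2 max pool, bottleneck stages of 3/4/23/3 blocks, 256→2048 channels),
optionally with every bottleneck's 3×3 convolution grouped and an attention
block (shared bias-free two-layer perceptron at reduction ratio 16 for the
channel gate, one bias-free 7×7 kernel for the spatial gate) after each
stage.  The published totals are reproduced with g = 2 everywhere and
r = 16; the grouped-bottleneck illustration with g = 4 on a 64-channel
block is supported but inconsistent with the printed totals, so g is
configurable with default 2.  No classification head is counted (the
standard backbone's 42.50 M equals the full classifier minus its 1000-way
head), and no auxiliary segmentation loss is modelled.

Parameter counts are exact sums over trainable arrays.  FLOP counts use a
stated convention chosen to match the published totals at two decimals:
one multiply-accumulate of a convolution or linear layer = 1 FLOP,
normalisation/activation/residual-addition/attention-gating = 1 FLOP per
output element, pooling = 1 FLOP per input element read.  Convolutions
alone give 7.80 B for the standard backbone; the published 7.84 B implies
the elementwise ops were included, and the same convention then yields the
improved backbone's 5.94 B with no further freedom.

The networks run on an in-repo numpy layer library with reverse-mode
autodiff (im2col convolutions, fused batch normalisation, adaptive pooling,
bilinear resizing).  After the short smoke-training runs, batch-norm
running statistics are replaced by exact dataset statistics in one frozen
forward pass — with only tens of optimisation steps the running averages
otherwise lag the weights badly enough to break inference-mode predictions.

## Problem sizes used

Desk-scale sizes keep the full suite within a small CPU budget: 640×480
renders with 3× supersampling; sessions of 4 stereo pairs; 10 noisy
elliptic sessions and 20 randomised sessions in the recovery/matching
acceptance runs; 64 procedural fixtures at 64×64 and 60 Adam steps (batch
8, lr 3e-3) for the learnability smoke test, using a reduced backbone
(8 base channels, one block per stage, 1/4 output stride).  Full-scale
training and evaluation on real imagery are out of scope.

## Known limitations

- The girth fit interpolates the corners; with very few points per view or
  heavy noise a smoothing rather than interpolating closed curve would be
  preferable.  The fitting interface accepts a replacement.
- Marker centroids assume an unoccluded, well-segmented marker; partial
  occlusion shifts the rectangle and can drop or admit a corner column.
- The pixel-step polynomial is rig-specific; on a different rig the
  multi-line shift should use the projected pitch from calibration instead.
- The matcher requires equal corner counts per view by design; recovery
  from unequal counts (e.g. one occluded corner) is intentionally not
  attempted.
- Elliptic cross-sections are a first-order body model; real torsos are
  neither elliptic nor constant over height, so simulator girth errors
  underestimate real-world errors.
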