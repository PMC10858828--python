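# Methods

This note documents the models, numerical choices and limitations of
`carpodyn`: what the synthetic wrist phantom does and does not emulate,
how the geometric measurements are defined and stabilized, and how the
group statistics are computed.

## The synthetic wrist phantom

### What it emulates

The phantom reproduces the *statistical and geometric structure* of a
dynamic coronal wrist acquisition during continuous radioulnar abduction,
not wrist anatomy or MR physics:

- **Field geometry.** 168×168 px at 1.0 mm/px (acquired grid), one frame
  per 95 ms, 300 frames ≈ 28.5 s ≈ 1.9 motion cycles of 15 s each.
- **Bones.** Nine convex polygons (distal radius, distal ulna; proximal
  row scaphoid/lunate/triquetrum; distal row hamate/capitate/trapezium/
  trapezoid) with correct neighbour adjacencies and gap axes. Shapes are
  slightly irregular ellipse-like blobs; anatomical silhouettes are not
  attempted because the measurement pipeline is shape-agnostic.
- **Motion.** θ(t) is a sinusoid between the trajectory extremes
  (default −20°…+20°; the simulated motion device would allow ±60°, but
  measured data concentrate in the narrower range, so the default
  trajectory covers it with margin). The distal carpal row rotates by the
  full wrist angle about the pivot, the proximal row by a fixed fraction
  (default 0.5); no published intra-carpal kinematic model is implied —
  the fraction exists to make angle estimation non-trivial (proximal and
  distal structures move differently).
- **Joint gaps.** Preset gap-versus-angle curves with per-subject jitter:

  | preset | SL mean (−10…+20°) | SL peak | LT |
  |---|---|---|---|
  | healthy | 1.9 mm, flat | — | 1.3 mm, flat |
  | partial tear | 3.12 mm | 3.35 mm at 0° | 1.3 mm, flat |
  | complete tear | 3.39 mm | 3.91 mm at +7.5° | 1.25 mm + 0.02 mm/° (monotone) |

  SL curves are cosine bumps `base + amp·½(1+cos(π(θ−c)/w))` (half-width
  w = 25–30°) parameterized by (mean over the measured range, peak
  location, peak value); the complete-tear LT curve is linear and
  monotone increasing toward ulnar abduction. The healthy value of
  1.9 mm sits between the "≈ 2 mm" textbook figure and typical measured
  control means. Per-subject jitter multiplies the mean and the peak
  amplitude by clipped Gaussians (SD 15% of the mean) and bone sizes by
  3%-SD factors — group tables report only means ± SD, so the jitter SD
  is a modelling choice, chosen to make subject-level overlap between
  groups realistic rather than negligible.
- **Gap enforcement is exact.** Per frame, the scaphoid and the
  triquetrum are translated along their centroid-to-lunate axes so that
  the distance between the facing cortices *on that axis* equals the gap
  function at the current angle, in continuous coordinates, before the
  row rotation (which preserves it). Ground truth is therefore exact by
  construction; rasterization to the 1 mm grid is the only degradation
  (≤ 1 px by the pixel-pair bound).
- **Contrast and noise.** Each bone class maps to a distinct grayscale
  intensity, blurred by a Gaussian point spread (σ 0.7 mm) with additive
  Gaussian noise (σ 0.03 ≈ 5% of mean bone intensity). This makes the
  optional segmentation task well posed in a single coronal slice.

### What it does not emulate

No 3D anatomy or out-of-plane motion (pro/supination), no MR physics
(k-space, radial undersampling, reconstruction artifacts, Rician noise),
no realistic bone silhouettes or inter-subject anatomical variability, no
motion blur or through-plane bone entry/exit. Passing tests therefore
demonstrate that the *measurement pipeline* is faithful to its inputs —
not that the pipeline would reach the same accuracy on patient images.

### The pivot and the angle reference

The phantom's rotation pivot is placed at the centre of the forearm's
minimal bounding box, and the distal row is positioned so its box centre
lies on the forearm box's long axis at the neutral pose. With this
construction the bounding-box angle measurement (below) recovers the
device angle *exactly* in continuous coordinates, which is what makes a
±2° recovery requirement on the rasterized grid meaningful. With a pivot
inside the carpus the same construction would measure a geometry-dependent
fraction of the device angle — a legitimate instrument calibration issue
that the phantom deliberately avoids.

The forearm bones are drawn long and narrow (combined box ≈ 62×36 mm):
the minimal-area rectangle of a near-square hull can snap between
orientations ~3–4° apart under pixel-level contour noise, which was the
dominant angle-error mode in early experiments; an elongated hull pins
the orientation.

## Geometric measurements

### Outline extraction and smoothing

Bone outlines are traced with marching squares at iso-level 0.5 on the
binary image of each bone's largest connected component (components under
8 px are invalid), then converted to mm. The raw contour carries ±½ px
quantization zigzag. It is smoothed by **uniform-arclength resampling
(0.5 px step) followed by a periodic second-order Savitzky–Golay filter
spanning 14 px of arclength**. Order 2 reproduces locally quadratic
boundaries exactly, so convex outlines are not shrunk — a plain moving
average of the same span biases each boundary inward by ~0.12 px and
joint widths outward by ~0.25 px, which is a third of the error budget at
these gap sizes. The smoothing span is defined in *pixels* (the scale of
the noise it suppresses), making all geometry exactly scale covariant in
the pixel spacing. Measured on noiseless phantoms, widths recover ground
truth with ≈ +0.05 mm bias, 0.36 mm 95th-percentile error, <1% of frames
beyond 0.5 mm; angles recover within 1.1° worst-case.

### Widths, centreline, bounding boxes

The centreline is the two-segment polyline through the scaphoid, lunate
and triquetrum centroids (ordered by bone, so argument order is
irrelevant). A joint width is the distance between the two intersections
of the corresponding centroid segment with the facing cortices, choosing
on each outline the boundary crossing nearest the other bone's centroid.
Overlapping outlines (possible after segmentation errors) clamp the width
to 0 and flag the frame rather than produce negative values. Minimal
bounding boxes are exact minimal-area rotated rectangles (hull-edge
aligned; verified in tests against a 0.1° brute-force orientation sweep).
The wrist angle is signed positive toward the ulna, with the ulnar
direction inferred per frame from the ulna-vs-radius centroid offset —
left and right wrists therefore mirror without configuration; a side flag
in the series metadata can override it.

### Binning and tables

Wrist angles are assigned to the bin whose centre (a multiple of the 5°
bin width) is nearest; ties go right, i.e. bin c covers [c−2.5°, c+2.5°).
The "Entire" column pools frames, not bin means, so unevenly populated
bins (the sinusoidal trajectory dwells at the extremes) do not distort
the overall mean. Sweep direction (radial→ulnar vs ulnar→radial) is
tagged on every frame from the smoothed angle increment; both directions
pool into the same bins by default, leaving hysteresis analyses to the
user. Per-bin SD is reported as undefined (NaN) for bins with a single
frame. A wrist is flagged dynamically unstable when any bin's mean SL
width reaches 3.0 mm (inclusive), the conventional instability threshold.

## Group statistics

The group-wise comparison is a split-plot design: ligament condition
(between subjects), angle bin (within subjects), subject as a blocking
factor nested in group. `two_way_anova` computes the classical
sums-of-squares decomposition on subject-by-bin cell means; the group
effect is tested against the subject-within-group stratum and the bin and
interaction effects against the residual (bin × subject) stratum. For
balanced designs this is exact (it matches `pingouin.mixed_anova` to
floating-point accuracy in tests, and its α = 0.01 type-I error
calibrates to [0.005, 0.018] over 2000 null simulations); unbalanced
group sizes are handled by unweighted cell means with the harmonic mean
group size. Full REML mixed models are out of scope: on the balanced
phantom designs the blocked decomposition is the exact likelihood answer,
and nothing in the pipeline estimates covariance structures beyond the
random intercept.

Tukey posthoc contrasts take group means, an error mean square and its
df (from the blocked ANOVA, or per-bin from subject means) and compute
studentized-range adjusted p values (Tukey–Kramer standard errors for
unequal n). For two groups this reduces exactly to the pooled t test
(q = t√2). Per-bin posthocs run all pairwise group contrasts within each
bin at the same α = 0.01.

Sample size for the paired design inverts the noncentral-t power of the
paired t test (df = n−1, noncentrality d√n) by upward search; the
returned n satisfies power(n) ≥ target > power(n−1).

## The optional segmenter

No convolutional-network framework is part of this package's dependency
set; the trainable segmenter is a **per-pixel multilayer perceptron over
multi-scale image features**: raw intensity, Gaussian-smoothed intensity
at σ ∈ {0.5, 1, 2, 4} px, gradient magnitude at σ = 1 px, and normalized
(row, column) coordinates — two hidden layers (64, 48), ≈ 4700 weights.
Training samples pixels stratified by class, half uniformly and half from
a ±3 px band along bone boundaries: the narrow joint gaps contribute few
pixels but dominate the downstream geometry, and without boundary
emphasis the predicted lunate–triquetral gap (≈ 2.6 px on the
interpolated grid) collapses in a sizeable fraction of frames. Trained on
60 interpolated-grid phantom frames (40 epochs, ~4 min CPU) it reaches
mean Dice ≈ 0.97 on held-out frames with downstream width errors within
1 mm on ≥ 95% of them. Segmentation runs on the interpolated 336² grid,
matching the processing order of the measurement pipeline; masks travel
with nearest-neighbour upsampling only. This segmenter is a pixel
classifier: it has no learned spatial decoder, and on images whose
classes are not separable from local intensity + position (realistic MRI
contrast) it would need replacing — the pipeline accepts any mask source.

## Problem sizes and determinism

Default problem sizes are the simulated study conditions: 10 patients
(6 partial, 4 complete tears), paired healthy controls, 300 frames per
wrist. The end-to-end tests run exactly these sizes; unit tests use
shorter series (20–80 frames) of the same phantoms. All randomness flows
from explicit integer seeds through `numpy.random.Generator`; a cohort
spawns per-patient child seeds, so any wrist's series is reproducible
bit-for-bit from (cohort seed, patient index) alone, and a pipeline run
is reproducible byte-for-byte from its manifest.

## Known limitations

- The phantom's angle ground truth is defined by the same bounding-box
  construction the pipeline measures (by design, see "pivot" above); the
  angle tests therefore validate *recovery under rasterization and
  noise*, not the construction's agreement with an external goniometer.
- Joint widths are measured along the centroid axis only; radiology
  practice sometimes reports minimal or mid-portion widths, which differ
  on strongly tilted joints.
- Width accuracy is quantization-limited: ±0.5 mm guarantees hold at the
  1 mm acquired grid for the phantom's gap range (1–4 mm); much narrower
  joints would need finer acquisition.
- The ANOVA assumes normally distributed cell means and a common
  within-subject covariance (no sphericity correction is applied); with
  9 bins and 300 frames per wrist the cell means are stable, but small
  frame counts per bin would violate this silently.
- `analyze` mode trusts the class map of its input masks; no plausibility
  checking of anatomy is attempted beyond presence/size of each bone.
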