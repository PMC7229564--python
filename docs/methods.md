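# Methods

This note documents the model behind `guanloc`, the parameters that matter,
the numerical choices, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Problem and coordinate conventions

The target is a pixel position (and optionally a millimetre position) of
GUAN, the radial-artery segment above the radial styloid process, in a
single-channel thermal image of a wrist resting on a tilted bracket.
Pixel coordinates are 0-based `(column, row)`; rows increase downward. The
default image orientation is landscape with the arm along the columns and
the hand toward the right (`landmark.hand_side` mirrors this); the radial
side of the wrist is the upper contour (`contour.side`). The pipeline is
invariant to affine intensity shifts — all thresholds are derived from the
data — so raw counts, 8-bit, or 16-bit units behave identically.

## Edge detection

The edge response is the gradient magnitude of derivative-of-Gaussian
filtering at scale `edge.sigma` (default 2 px, reflective boundaries). For
each of `edge.n_angles` (default 8) equally spaced angles in [0°, 45°], the
grid is partitioned into digital pixel lines at that angle — `compact`
(Bresenham rounding) or `sparse` (floor) construction, both exact
partitions — and the response is non-maximum suppressed along each line.
Four grid symmetries (identity, transposition, 90° rotation, horizontal
flip) extend the sweep so every undirected direction in [0°, 180°) is
scanned exactly once; per-angle maps are OR-ed.

Numerical choices:

* **Plateau rule.** A pixel survives suppression when its response is at
  least its previous line neighbour and strictly exceeds the next. An
  intensity step falling between two pixel rows yields an exactly tied
  response pair; a fully strict rule marks neither and erases straight
  contours, while the asymmetric rule marks exactly one. Endpoints are
  never marked. Using one scan orientation per direction (hence four
  symmetries rather than all eight) keeps tied pairs single-marked.
* **Directional gate.** A scan direction only marks pixels whose local
  gradient lies within 45° of the scan line. Suppression must act along
  the gradient; scans running along an edge would otherwise mark every
  noise ripple across the several-pixel-wide response band, thickening and
  bridging edges.
* **Threshold.** `max(quantile(positive responses, 0.70),
  8 × median(all responses))`. On clean images most responses are exactly
  zero: the median floor is inert and the 0.70 quantile of the positive
  values falls below the weakest real boundary (on a quantized image,
  higher quantiles land mid-structure and erase low-contrast edges such as
  the artery boundary). Under broadband sensor noise every response is
  positive and the quantile collapses to the noise level; the floor —
  several times the typical (median) noise response — takes over. Both
  knobs are config-exposed (`edge.threshold_quantile`,
  `edge.noise_floor_mult`).

## Contour extraction

The largest 8-connected edge component is taken as the wrist edge
(ties: widest bounding box, then topmost). If it does not reach both
lateral borders, edge fragments are searched from the current leftmost
pixel at Chebyshev distance 1–2 in five directions (up, left-up, left,
left-down, down; mirrored on the right side), bridged by straight-line
pixel interpolation, and merged until both borders are reached. Side
branches traced from free endpoints to a junction are deleted when shorter
than `contour.max_spur_len` (default 15 px; the junction is detected as
the first pixel with two or more neighbours outside the traced chain).
The surviving pixel set is collapsed to one row per column (minimum row
for the upper side), with gaps of up to two columns filled linearly.

## Locating x: smoothing, curvature, recess rule

The outline is smoothed by a minimum-order Butterworth low-pass designed
for a pseudo sampling rate of 70 Hz with passband corner 2 Hz, stopband
corner 3 Hz, 3 dB passband ripple and 30 dB stopband attenuation (one
pixel column = one sample, so the passband corner is 2/70 cycles/px; the
design lands at order 9). The filter removes the one-pixel staircase of
the rasterized contour while passing anatomical features (σ ≳ 6 px). It
is applied zero-phase — forward–backward passes, averaged with the
reversed-input result so that the smoother is exactly symmetric under
outline reversal — because a causal pass would shift every landmark.

The signed curvature κ = s″/(1+s′²)^{3/2} is computed by central
differences, oriented so that protrusions of the wrist outline are
positive regardless of `side` and `hand_side`. The styloid salient is the
global positive-curvature maximum. Scanning from the salient toward the
elbow over an open finger-width window (`landmark.window_px`, 100 px), x0
is the nearest strict curvature maximum whose outline slope rises toward
the salient. Two numerical guards:

* **Slope floor** (`landmark.slope_min`, 0.02 px/px). Residual staircase
  ripple after smoothing produces spurious curvature maxima on flat
  stretches whose slopes are two orders of magnitude below any real recess
  shoulder; "positive slope" therefore means "above the floor".
* **Resolution limit.** The mandated filter cannot resolve a recess whose
  dip lies ≲ 45 px from the salient: its curvature shoulder merges into
  the bump's monotone curvature ramp and no qualifying maximum exists, for
  any anatomy. The pipeline then raises the documented no-landmark error
  rather than returning an arbitrary column; the phantom truth is likewise
  undefined there.

`landmark.scan` selects the tie-breaking order (`nearest` to the salient,
the default, or `farthest`); both readings of "first local maximum" are
thus available.

## Locating y: region statistics and the artery line

A 10×10 region is anchored at every interior edge point (an even window
spans `[r−5, r+4]`); its mean and population standard deviation are
computed via integral images. Thresholds come from the histograms of
these statistics (`artery.method`):

* `otsu` (default): the lower mean bound and the upper std bound are Otsu
  splits of the respective histograms, re-centred in the empty gap between
  the classes. Region means are bimodal — silhouette boundaries average
  skin and background, artery boundaries sit at or above skin temperature —
  and region stds likewise: the silhouette carries the largest thermal
  contrast, the artery boundary the smallest among true edges. Otsu splits
  are invariant to how many edge points each structure contributes, which
  fixed percentile windows are not. The lower std bound is a quarter of
  the upper, excluding near-flat regions (stray noise marks on response
  tails); there is no upper mean cut because saturated interiors are not
  edge points.
* `percentile`: config-exposed windows (`artery.mean_pct`,
  `artery.std_pct`) for data whose composition is known.

Selection applies two geometric gates: region centres must lie below the
extracted wrist outline plus `artery.outline_margin_px` (15 px — the
artery is interior to the wrist, and low-contrast silhouette regions are
otherwise statistically indistinguishable from artery boundaries), and the
fit is restricted to `artery.band_px` (60 px) around x0, which moves the
fit centroid to the evaluation point and cancels the lever arm that would
amplify slope noise into y errors. Per-column mean rows of the selected
pixels are fitted by ordinary least squares; columns covered by only a
sliver of a region are dropped (coverage below half the median), and one
re-fit pass removes columns with residuals above 5 px (a marker or
silhouette region that slipped through the gates would otherwise leverage
the line). y0 is the line at x0, rounded half-away-from-zero; the
unrounded value is kept in the diagnostics.

## Pixel-to-millimetre mapping

The camera looks straight down from height `h` above the reference point O
of the bracket plane, which is tilted by α. A signed pixel offset X along
the tilt axis subtends Δθ = X/(extent/2)·θ, the proportional reading that
makes Δθ = θ at the frame edge. By the sine theorem the horizontal
coordinate of the intersection with the plane is HP = sin Δθ·h·cos α /
cos(Δθ − α) on the raised (near) side and cos(Δθ + α) on the lowered
(far) side, with the sign chosen so x_P is strictly increasing in X and
reduces to h·tan Δθ at α = 0. The slant range AP = h·cos α/cos(Δθ ∓ α)
carries the cross coordinate y_P = AP·tan Δβ·sign(Y). In the default
landscape orientation the columns feed the tilt mapping (`tilt_axis`),
so the crease-to-GUAN distance is a difference of along-bracket
coordinates evaluated at the GUAN row. An independent pinhole
ray/tilted-plane intersection oracle agrees with the closed forms to
below 1e-6 mm over the frame.

## The phantom generator

A phantom emulates the platform's view: a warm forearm (150 intensity
units) on a cool background (80) spanning the full width and extending
below the frame (the arm rests on the support; only the radial-side
contour is visible), an upper contour of a flat baseline at row 70 with a
Gaussian styloid bump (amplitude 12 px, σ 9 px, jittered per subject) and
a recess dip (depth 8 px, σ 6 px) 60 px on the elbow side; a radial-artery
stripe (peak 190, Gaussian cross-section of half-width 4 px, slope 0.05)
visible over columns 150–290; a 4×4 px cold square (apparent temperature
40 — low-emissivity aluminium reads far colder than skin) at the crease
column 290; Gaussian sensor noise (σ = 1 intensity unit ≈ sub-0.1 K for a
multi-K scene contrast) and integer quantization.

Ground truth for x0 is the landmark of the *smoothed* analytic contour:
the defining low-pass applied to exact sub-pixel contour samples, salient
and recess-shoulder maxima located with quadratic sub-pixel refinement, by
code that shares nothing with the pipeline's edge detection, contour
tracing or landmark scan. The smoothing is part of the landmark's
definition — the unsmoothed analytic curvature maximum sits several pixels
away because the filter reshapes features of comparable width. The y truth
is the analytic artery line. Where the recess is below the filter's
resolution limit the truth is undefined (see above).

Acquisition jitter emulates a subject re-gripping the handle: translation
±3 px along the arm, ±1 px across (the wrist is strapped to the bracket,
so residual motion is predominantly longitudinal; the longitudinal
component cancels in the crease-referenced distance exactly as the
physical marker intends), rotation ±1° (applied by resampling with edge
extension — the scene continues beyond the frame), and ±10% bump-amplitude
variation. In the repeatability experiment the recess depth covaries with
bump amplitude (a more prominent styloid has a more pronounced adjacent
recess); a fixed depth cannot keep the styloid curvature dominant at small
amplitudes while keeping the shoulder resolvable at large ones.

What the phantom does not emulate: perfusion and thermal diffusion
(contours are hard or Gaussian, not physical temperature fields), textured
backgrounds, occluding clothing, vignetting, or fixed-pattern sensor
noise. Passing the synthetic suite therefore demonstrates correctness of
the algorithmic chain under the stated image model, not clinical
performance on human subjects.

## Repeatability experiment and problem sizes

The validation experiment uses 8 synthetic subjects × 10 jittered
acquisitions (80 images of 240×320 px, about 10 s on one CPU), runs the
full pipeline per image, maps to millimetres through the phantom's world
model (θ = 20°, β = 25°, h = 300 mm, α = 10°), and tabulates per-subject
mean, sample standard deviation and relative standard deviation (SD/mean)
of the crease-to-GUAN distance and the GUAN y coordinate. The landmark
recovery sweep covers 50 anatomies (bump amplitudes 5–20 px × recess
offsets 40–90 px, noiseless). Both are reproducible bit-for-bit from the
seed.

## Known limitations

* The finger-width window and the filter's pseudo-sampling interpretation
  assume a pixel scale comparable to the reference platform (~0.5–1 mm/px
  at 240×320); grossly different optics require rescaling
  `landmark.window_px` and the filter corners.
* The recess rule needs a resolvable recess: anatomies with the dip closer
  than ~45 px to the styloid yield a no-landmark error by design.
* The artery gate assumes the artery is the warmest linear structure below
  the outline; strong superficial veins or reflections would compete.
* The crease reference in synthetic runs comes from the generator; the
  cold-spot detector for real images (`pipeline.detect_cold_spot`) is
  best-effort plumbing and is not exercised by the acceptance path.
* Lens distortion and full extrinsic calibration are out of scope; the
  mapping assumes the paraxial tilted-plane model.
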