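# Methods

## Problem and model

A driver wears goggles carrying a forward-looking *view camera* and an eye
camera. A pupil tracker reports the eye-in-head rotation f1(t) in degrees.
Four printed markers — upward triangle (1), circle (2), downward triangle
(3), star (4) — sit on the windshield in a fixed left-to-right order. The
package estimates the head-in-world rotation f2(t) from the markers' image
positions, fuses the two streams into the gaze signal

    E(t) = f1(t) + f2(t)        (componentwise, x and y, in degrees)

and summarises a session by the gaze-range statistic X x Y described below.
The additive fusion rests on the eye–head coordination assumption: when a
person redirects gaze, eye and head rotations combine linearly, so the
world-referenced gaze direction is their sum per axis.

### Head angles from marker displacement

While the driver faces forward, each marker's *reference position* is
recorded. When the head rotates by yaw (about the vertical axis) or pitch
(about the lateral axis), the markers translate in the image; the linear
camera model converts pixel displacement to angle:

    angle = displacement_px x (fov / resolution)     per axis,

so a displacement spanning the full image equals the full viewing angle.
The printed layout of this conversion formula is typographically ambiguous
in places it has been described; the package fixes the reading by the
physical requirement above (degrees-per-pixel = fov/resolution).

Head roll (about the optical axis) tilts the whole marker constellation in
the image plane without a change of gaze direction, and would corrupt the
axis read-out. Roll is therefore estimated first from a visible marker
pair,

    theta = atan((y2 - y1) / (x2 - x1)),   x2 > x1,

valid because the markers are mounted on a horizontal line, and the
detected marker centers are rotated by -theta about the image center before
yaw/pitch are read off. The pivot choice is the package's own: any fixed
pivot yields the same *displacement differences*, and the image center is
the symmetric choice. References are recorded at zero roll and are **not**
derotated — derotating an already-roll-free point would move it; with this
convention a pure-roll pose recovers yaw = pitch = 0 exactly under the
package's forward model.

Yaw is read from the marker whose (roll-corrected) x lies nearest the image
x-center, pitch from the one nearest the y-center: the linear model is most
faithful near the optical axis. Ties break toward the lower marker id. When
more than two markers are visible, the roll pair is the two highest-scoring
detections. Single-marker frames carry the last valid roll forward (0 until
one exists): roll is unobservable from one point, and in a video stream
roll varies slowly. Frames with no accepted marker yield an invalid pose;
no interpolation is performed, because interpolated poses would fabricate
gaze samples in the downstream statistics.

Sign conventions, fixed package-wide: gaze/head x positive = subject's
right, y positive = up. Pixel coordinates are 0-based, origin top-left,
y downward; regions are half-open; a detection's anchor is the template's
top-left corner.

### Marker detection

Markers are located by normalized cross-correlation (NCC) template
matching (scikit-image backend), score clipped to [0, 1]; a detection is
accepted when its score reaches `similarity_threshold` (default 0.70,
configurable — high enough to reject background, low enough to tolerate
mild glyph rotation and noise). Three search-space reductions are applied:

1. **Ordering constraints.** Markers are searched in id order 1→2→3→4;
   each later marker's region is clipped to the right of the earlier ones'
   last seen positions, and marker 4 is skipped entirely in frames where
   marker 1 or 2 was just seen — the camera field of view is narrower than
   the constellation, so the two ends can never be co-framed.
2. **Three-section division.** Each region is split into three horizontal
   bands searched center → upper → bottom (drivers rarely pitch far), each
   band padded vertically by (template height − 1) px so a marker
   straddling a band cut is wholly contained in one band. The first band
   whose peak clears the threshold wins. Because the padded bands jointly
   cover every placement, a marker missed by all three would also be missed
   by a whole-region search; no fallback pass exists.
3. **Motion extension.** A region tracked from frame t−1 is a window of
   `search_margin` template-sizes around the last position, enlarged along
   the t−2→t−1 displacement vector by `extension_gain` x |displacement|
   (default 1.5: covers constant-velocity motion with 50 % margin), so fast
   head turns do not outrun the window. Unseen markers fall back to the
   constrained frame portion.

### Calibration and the extrapolated reference

The forward-facing window (nominally five seconds) is searched full-frame
for markers 1–3; each reference is the per-axis **median** of the accepted
positions, robust to isolated mismatches. Marker 4 extends the measurable
yaw range but is outside the view while facing forward, so its reference x
is extrapolated from the known spacing ratio alpha:beta of the physical
layout: with A, B the reference x of markers 2 and 3,

    C = -(1/alpha) * ( beta*(A - B) - alpha*B ),

equivalently B = (beta*A + alpha*C)/(alpha + beta) — B is the alpha:beta
ratio point of A and C. The formula is orientation-agnostic; the marker y
reference copies marker 3 (same mounting line). The bundled layouts place
markers left→right in id order, matching the search-planner constraints;
the published description of the layout is internally mirror-ambiguous, and
either orientation works because the geometry is symmetric.

### Zone classification

Each valid gaze sample is labeled with one of nine areas: front, rearview
mirror, meter, right mirror, right, right back, left mirror, left, left
back. The label vocabulary is fixed; the angular boundaries are not
published, so the default partition is the package's convention: |x| and
|y| ≤ 20° is "front"; beyond ±20° in x are the side zones, beyond ±90° the
"back" zones; the meter cluster is below the front box, the rearview
mirror above it, and the side mirrors are rectangles at typical glance
positions (x in ±[25, 55], y in [−30, −10]). Rules are evaluated in order,
first match wins, so boundary points resolve to the more central zone; the
rule list is fully user-overridable in the session config. This default
reproduces the left/right/front judgment family of every correctly-judged
sample in the bundled outdoor evaluation table.

### Gaze-range statistic

Valid gaze samples are binned on a 2-D grid aligned to multiples of
`bin_width` (default 5°; half-open bins, boundary samples go up). Counts
are marginalised per axis; bins reaching `range_threshold` (default 5 %)
of the **peak marginal count** survive, and the outer edges of the
surviving bins give Xmin/Xmax and Ymin/Ymax. The spans X = Xmax − Xmin and
Y = Ymax − Ymin multiply into the area X x Y (deg²). The threshold is
peak-relative because an absolute 5 % cut has no scale; the marginal
(per-axis) reading is chosen because X and Y are defined axis-wise, and
both the joint-threshold alternative and the Gaussian-interval alternative
remain available (`fit_gaussian` reports per-axis mean, sigma and the 95 %
interval mu ± 1.96 sigma).

For Gaussian gaze the marginal falls to 5 % of its peak at
sqrt(2 ln 20) ≈ 2.448 sigma, so X converges to 4.90 sigma_x — the closed
form the tests verify against. Cross-subject comparison reports per-subject
X, Y, area and the ratio to a designated reference subject (e.g. an
instructor), flagging areas below a configurable fraction (default 0.5).

## Synthetic scene generator

The generator renders frames under a known (yaw, pitch, roll) trajectory:
each marker is drawn at its forward-facing anchor displaced by
(−yaw/dpx, +pitch/dpy) pixels and rotated by roll about the image center,
clipped at the frame edge. The default layout (640x480 px, 60°x45° field
of view, markers at x = 80/300/520/740 px on the mid-height line, equal
220 px spacing so alpha:beta = 1:1) reproduces the real system's key
property: markers 1–3 visible facing forward, marker 4 entering only past
~10° of rightward yaw after markers 1–2 have left the frame. Glyphs are
filled shapes (triangle/circle/star on a white card) pasted at the nearest
integer pixel; backgrounds are uniform gray or seeded Gaussian noise
(sigma 12 gray levels). The forward model deliberately mirrors the
estimator's linear geometry — no perspective, no lens distortion, no
illumination change — so round trips test the estimator against its own
assumptions, not against photometric realism.

Eye streams are generated backwards from a target gaze distribution: gaze
targets are drawn from a 2-D Gaussian (defaults mu = (0, 0), sigma =
(15°, 8°) — a plausible driving scan pattern, wider horizontally),
re-drawn at Poisson saccade times (2 s⁻¹) and held between saccades, and
the eye angle is target minus ground-truth head angle. Fusing the simulated
eye stream with the true head trajectory therefore reproduces the sampled
gaze exactly, giving an exact oracle for the fusion and range stages.
Everything is reproducible bit-for-bit from one integer seed.

What the generator does **not** emulate — and what passing tests therefore
do not show about real recordings: perspective and lens distortion, motion
blur, illumination and shadow changes, glyph scale change with viewing
distance, occlusions (wipers, hands), eye-tracker noise and blinks, and
imperfect time alignment between the eye stream and the video.

## Numerical and testing choices

* NCC scores below 0 are clipped to 0: anti-correlated patches are as
  useless as uncorrelated ones for acceptance.
* Rotated glyphs degrade NCC against upright templates: the circle is
  rotation-invariant, but triangles and the star fall below the 0.70
  threshold beyond roughly ±20° of roll — the known shape-change failure
  mode of appearance templates. End-to-end render→match→pose recovery is
  therefore exercised at |roll| ≤ 15°, while the roll-correction
  *geometry* is verified to <1° up to |roll| = 30° on ground-truth marker
  positions; trajectories keep |roll| < 45 by construction.
* The bundled outdoor judgment table prints all angles to one decimal, so
  the sum of two rounded addends may legitimately differ from the rounded
  true sum by up to 0.1° per axis (0.15° worst case including the output
  rounding); the fusion regression asserts ≤ 0.1°, the observed maximum.
  The two samples logged as judgment errors (template-matching failure,
  eye-measurement failure) carry gaze values inconsistent with their own
  eye/head columns and are excluded from exact-sum checks.
* Problem sizes used by the test suite: pose-recovery grid of 20 poses
  (noiseless and noisy), 50 matching-oracle fixtures, 100 roll-invariance
  poses, 5 000 samples for the gaze-range closed-form check, 40–200-frame
  tracking sweeps. These sizes give sampling error well inside the asserted
  tolerances while keeping the suite fast.

## Known limitations

* The linear pixel↔angle model ignores perspective; accuracy degrades for
  markers far from the optical axis and for large viewing angles.
* Scale and appearance changes of the markers (distance, blur, lighting)
  are not modeled by plain NCC; the recognition rates of a real recording
  will be below the synthetic ones.
* Yaw hand-off between markers is not smoothed; small discontinuities can
  appear when the nearest-center marker changes and the references are
  imperfect.
* The gaze-range statistic depends on bin width near the threshold; report
  it together with `bin_width` and `range_threshold`.
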