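# Methods

This note documents the models, conventions and numerical choices behind
behavekin, and what the synthetic closed-loop tests do and do not show.

## Camera model and calibration

The camera is a pinhole with optional two-term radial distortion:
world → camera `X = R p + t`; normalized coordinates `(x, y) = (X1/X3, X2/X3)`;
radial factor `rho = 1 + k1 r² + k2 r⁴` with `r² = x² + y²`;
pixels `u = fx·rho·x + skew·y + cx`, `v = fy·rho·y + cy`. The pixel origin
is the center of the top-left pixel, u rightward, v downward. Distortion
and skew estimation are **off by default** — the short-baseline
machine-vision lenses this targets vary, and a model term that is not
constrained by the data degrades the fit — and can be switched on per run.

Calibration is Zhang's planar method. Each full interior-corner grid of a
checkerboard view gives a plane-to-pixel homography (Hartley-normalized
DLT); the homography columns constrain the image of the absolute conic,
whose SVD null vector yields closed-form intrinsics; per-view poses follow
from `K⁻¹H` with SVD orthonormalization. The closed form seeds a joint
Levenberg–Marquardt refinement of `{fx, fy, cx, cy}` (plus `skew`, `k1`,
`k2` when enabled) and all per-view poses over total squared reprojection
error (`scipy.optimize.least_squares`, `xtol = ftol = 1e-12`). Because the
refinement starts at the closed form, its cost can never exceed the
initialization; this is asserted.

Board sizes follow the two rigs the package targets: a 4×6-corner board
with 4.5 mm squares for the paw rig and a 63-corner (9×7) board with
115 mm squares for the human rig. Corner detection in images is out of
scope — calibration consumes corner coordinates from any corner finder or
from the simulator.

**Stereo frame.** Two cameras observing shared board views are placed in
one world frame anchored to the *first* shared view: board origin = world
origin, board plane = z = 0, units = board square units (mm everywhere).
With several shared views the relative pose is averaged — rotations by the
chordal (quaternion) mean via `scipy Rotation.mean`, translations
arithmetically — and the spread is reported in `rig.meta` so users can
judge consistency.

**Triangulation** undistorts both observations (fixed-point inversion of
the radial model, ≤ 20 iterations, tol 1e-10 in normalized coordinates,
with an explicit re-distortion check so a non-invertible configuration
raises rather than returning garbage), then solves the stacked two-view
projection equations by SVD. No per-point bundle refinement: with two
cameras the linear solution is already the algebraic optimum up to noise
weighting, and the returned mean reprojection residual (px) lets callers
filter. A homogeneous solution at infinity (near-parallel rays) raises a
geometry error.

## Reach kinematics

Detections from the two cameras are paired per frame; a 3D sample exists
only where both cameras saw the part with confidence ≥ `conf_min`
(default 0.5) and the triangulation residual is ≤ `residual_max`. Box
detections are reduced to centers — kinematics needs a point, and the box
center is the detector's best estimate of it. Everything else is a gap
(NaN), kept explicitly so downstream steps make deliberate choices:

* `interpolate_gaps` fills interior runs ≤ `max_gap_frames` (default 5)
  linearly and marks filled samples with confidence 0; boundary gaps are
  never extrapolated.
* `smooth` is a centered moving average (default window 5 frames, odd
  windows only) that excludes gaps from each window and preserves them.
* `speed_series` is the central difference
  `‖p(i+1) − p(i−1)‖·fps/2` on interior non-gap triples, one-sided at the
  ends. "Velocity" in reports means this scalar speed; the vector
  derivative is available via `velocity_vectors`.

Reach segmentation is hysteresis thresholding: onset when the speed rises
above `v_on`, offset when it falls below `v_off`, bouts closer than
`merge_gap_s` merged, bouts shorter than `min_duration_s` dropped —
merging before dropping, so a brief dip inside one movement does not split
it into two sub-threshold fragments. Defaults: `v_on = 20 mm/s`,
`v_off = 10 mm/s` (v_on = 2·v_off), `min_duration_s = 0.1`,
`merge_gap_s = 0.05`. These are configuration keys, logged on every run;
they suit the default simulated reach (40 mm, 0.25 s per stroke, peak
300 mm/s) and should be rescaled for preparations with different speed
scales.

Per-reach summaries: distance = sum of consecutive non-gap segment
lengths; duration = (offset − onset)/fps; path-length ratio =
distance / net displacement, reported as NaN (not ∞) when the displacement
is under 1e-9 — an out-and-back movement legitimately has a near-zero
displacement; velocity peaks = local maxima of the lightly smoothed speed
above `v_off`, with plateau runs counted once (a symmetric profile sampled
symmetrically produces exact ties at the top).

## Joint angles

Three-point angles use `atan2(‖u×v‖, u·v)`, stable near 0° and 180°;
degenerate limbs (segment < 1e-9) yield NaN with a warning, never an
exception, because a single bad frame should not abort a session. The
body axis is mid_hip → neck (the most stable trunk landmarks in standard
25-keypoint layouts); the shoulder-vs-body angle compares it with the
upper-arm vector as free vectors in [0, 180].

The supination angle required an operationalization, since "rotation about
the forearm axis" does not name its defining keypoints. We use the
palm-breadth vector `h = index_mcp − pinky_mcp` projected off the forearm
axis `f = wrist − elbow`; the angle is signed (right-hand rule about `f`)
relative to the same construction at a reference frame (default: first
valid frame; configurable), parallel-transported into the current palm
plane by the minimal rotation carrying the reference forearm axis onto the
current one. The series is unwrapped over time so consecutive valid frames
differ by < 180°; unwrapped values may therefore leave (−180, 180] during
sustained rotation, which is intended — continuity matters more than
principal values for cycle counting. These choices use only robust hand
keypoints and make the angle exactly equivariant: adding a constant twist
δ about the forearm shifts the whole series by δ (tested to 1e-6).

## Social assays

Both assays are 2D top-view in centimeters. Identity comes from the
detector's classes (the two animals are distinguishable classes), so no
tracker or identity-swap resolution exists — by design.

Close contacts are maximal runs of body-center distance below
`contact_threshold_cm` (default 10 cm); NaN frames break runs unless
bridged by `merge_gap_s` (0.3 s); runs shorter than `min_duration_s`
(0.5 s) are dropped. Within an epoch, each frame is labeled by the
*closest* of five pairings — nose–nose, noseA–tailB, noseB–tailA,
noseA–bodyB, noseB–bodyA — when that distance is below `nose_contact_cm`
(3 cm), else `proximity_only`; ties break in the listed priority order.
A single argmin label per frame (rather than independent per-pair
thresholds) produces a clean one-symbol-per-frame ethogram. All proximity
thresholds are configuration keys and logged: the underlying assays are
described only qualitatively ("a certain threshold"), so pinned,
documented defaults are what make the analysis reproducible.

The three-chamber report counts a frame as cup interaction when the head
is within `cup_radius + interact_margin` of the cup center (default
5 + 2 cm; an edge-distance variant is the same test with the margin
absorbed). It reports per-cup interaction time, the percentage split of
total interaction time *and* of session time (both are useful; the split
of interaction time is what a 120 s/60 s dwell script pins to
66.7%/33.3%), chamber occupancy by x-interval membership, transition
counts, and interaction bouts with timestamps.

## Movement clustering

DTW: Euclidean local cost, symmetric step set {(1,0), (0,1), (1,1)},
backtracking prefers diagonal, then (i−1,j), then (i,j−1) — a fixed rule
so paths are deterministic. The dissimilarity is the accumulated cost
divided by the alignment path length, making bouts of different durations
comparable; no warping window by default (bouts are short), one is
available as a parameter.

DTAK: Gaussian local similarity `k = exp(−‖xᵢ−yⱼ‖²/2σ²)`, max-rule
recursion with diagonal weight 2 starting from `K(0,0) = 2k(0,0)`,
normalized by `n + m`, then self-normalized
`K̂(x,y) = K/√(K(x,x)K(y,y))` so `K̂(x,x) = 1` exactly. With all local
similarities at 1 every monotone path accumulates exactly `n + m`, which
gives the σ → ∞ limit `K̂ → 1`. σ defaults to the median pairwise sample
distance (median heuristic), logged. The distance between bouts is the
kernel-induced distance `√(2 − 2K̂)` — the reading of "Euclidean distance
between kernels" that yields a valid dissimilarity directly from kernel
values; the alternative (distances between kernel-matrix rows) can be
assembled from the returned matrix.

Multidimensional bouts (3D reach trajectories) are compared after
subtracting each bout's first sample by default, so clusters reflect
movement shape, not where in the arena it happened; `center="none"`
compares raw values (the default for 1-D angle series).

Agglomerative clustering (single/complete/average, Lance–Williams) is
delegated to `scipy.cluster.hierarchy`; ties are resolved by scipy's
deterministic merge order. Dendrograms export as a merge table and a
Newick-style nested string; flat assignments cut at k clusters or at a
height.

## The synthetic-scene generators

The simulators *are* the study conditions the tests assume:

* **Rigs.** The mouse preset: 448×460 px cameras ~180 mm from the paw
  workspace with near-orthogonal optical axes; the human preset:
  1280×1024 px cameras with a 1574.8 mm (62 in) baseline placed so their
  axes meet near-orthogonally at the subject ~1.1 m away. Seeds jitter
  positions (~2%) and focals (~1%) deterministically.
* **Reaches** follow the minimum-jerk profile
  `x(τ) = x₀ + (x_f−x₀)(10τ³−15τ⁴+6τ⁵)` — smooth, standard for
  point-to-point limb movement, and with the closed-form peak speed
  `1.875·L/T` that serves as the kinematics oracle. The default session is
  10 out-and-back reaches of L = 40 mm, T = 0.25 s per stroke at 124 fps,
  one per second — a realistic brisk rodent reach whose speed rises
  through the segmentation threshold within ~2 frames, so onset timing is
  a meaningful test.
* **Mice** are rigid 4-point templates (nose +4 cm, head +2 cm, tail
  −4 cm from the body center along the heading). Contact events pull the
  pair into mode-specific two-body configurations (the named pair ~1 cm
  apart, every other pair > 3 cm, centers within the 10 cm contact
  threshold) with smoothstep approaches and a small bounded wander;
  back-to-back events morph across their shared boundary, which is how
  the rear-sniff-turning-into-nose-to-nose scenario is scripted. Sessions
  emit 8-class normalized-box detections at 30 fps in a 45×45 cm arena
  at 20 px/cm.
* **Three-chamber** head paths enter each cup's interaction zone exactly
  at the scripted visit start (transit stays just outside the zone), so
  scripted dwell frames equal in-zone frames exactly and percentage
  arithmetic is testable without tolerance.
* **Human pose** sessions animate a fixed upper-body skeleton; rotation
  events twist a rigid hand about the forearm axis sinusoidally
  (ground-truth angle = the scripted sinusoid), reach events move the
  wrist along minimum-jerk paths with two-link inverse kinematics and a
  downward elbow-swivel preference. Output is per-frame keypoint JSON for
  both cameras.

Detector imperfection is modeled as i.i.d. Gaussian pixel noise on the
emitted geometry plus per-frame per-camera Bernoulli dropout, with
confidences uniform in [0.6, 1.0] independent of dropout. The generators
do **not** model correlated detector failure (identity swaps, sustained
occlusion, confidence–error correlation, motion blur) or lens distortion
in the emitted scenes; passing the closed loop therefore demonstrates the
*post-processing* is correct under the stated noise model, not that any
particular detector is accurate on real video.

## Numerical choices and limitations

* Frames are 0-based; time = frame/fps; all lengths mm (cm in the 2D
  social assays); all angles degrees.
* Duplicate detections of one class in a frame: highest confidence wins
  (all assay classes are single-instance). Missing confidences default to
  1.0 (manual-label files carry none).
* Trajectory CSV uses `%.9g` formatting; reader round-trips are exact to
  1e-9, and corner CSVs are read with pandas' `round_trip` float parser
  for bit-exactness.
* Calibration needs ≥ 3 views with varied tilts; coplanar-pose sets make
  the conic system degenerate and raise with a diagnostic rather than
  returning an ill-conditioned solution.
* The hysteresis segmenter's absolute thresholds assume the speed scale of
  the configured preparation; there is no auto-scaling.
* The DTAK recursion is one standard variant of the time-alignment kernel
  family; other weightings exist, and σ, like the linkage (default:
  average), materially affects clusters — both are logged per run.
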