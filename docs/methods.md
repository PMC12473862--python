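# Methods

## Motion model and conventions

Inter-frame motion is a planar similarity with parameters (s, θ, Δx, Δy):
uniform scale, rotation and translation — adequate for a rigid probe over a
locally planar mucosal surface, and deliberately excluding shear
(a 6-DOF affine is a plausible extension, not implemented). Coordinates
are x = column, y = row, 0-based, origin at the top-left pixel centre; the
2×3 matrix acts on column vectors [x, y, 1]ᵀ. `compose(a, b)` applies `b`
first (matrix convention); θ is stored in (−π, π] and recovered with
`atan2`, so the parameterisation is unique. `from_matrix` rejects matrices
whose linear part has shear, anisotropic scale or reflection beyond a 1e-6
relative tolerance rather than silently projecting them.

Rotation and scale in the *simulator* pivot at the image centre
(`about_center`): a tremor pivoting at the corner would mostly translate
the field of view, which is not what probe tremor looks like. The
*estimator* fits a general origin-pivot similarity and is pivot-agnostic;
before ground-truth comparison both are conjugated to the centre pivot
(`params_about_center`), which makes the RMS parameter errors well defined.

## Tremor model

Each frame i ≥ 1 of a stable sequence is independently warped (no random
walk) by a transform with Δx ~ width·N(0, σt²), Δy ~ height·N(0, σt²),
θ ~ N(0, σr²) radians, s ~ N(1, σs²); draws consume the generator in the
fixed order (dx, dy, theta, s), so logs are bit-reproducible from the seed.
A scale draw ≤ 0.5 would be a degenerate warp and is redrawn; at the
realistic sigma range the event has negligible probability. The quoted
intensity range [0.005, 0.01] is interpreted as the standard-deviation
range applied to all three channels simultaneously; the benchmark default
grid is σ ∈ {0.005, 0.0075, 0.01}. Frame 0 is the unperturbed reference
and also the stabilization reference.

## Synthetic scene

The renderer emulates the gross statistics of 640×480 8-bit oral
capillaroscopy footage: a bright background (default 200/255) with a
single low-frequency sinusoidal illumination field (amplitude 12 grey
levels), `n_vessels` smooth cubic-spline curves drawn as dark ridges with
Gaussian cross-section (σ = 2.5 px, depth 60–100 grey levels), darker
circular RBC blobs advected along the curves at `rbc_speed_px` per frame,
and fresh per-frame Gaussian sensor noise (σ = 4). Everything is a pure
function of (spec, phase): the static layers are keyed by the spec seed,
the noise by (seed, phase).

What it does *not* emulate: non-rigid tissue deformation, illumination
flicker, motion blur, lens distortion (the target instrument is calibrated
for close-range imaging, so no distortion correction is modelled),
defocus, and the stroke-like intermittency of RBC flow in the finest
vessels. Passing tests therefore demonstrate correctness of the geometry,
estimation and metrics under realistic texture and noise — not robustness
to every clinical artefact.

## Detection, tracking, estimation

* **Detectors.** SIFT, ORB and GFTT (Shi–Tomasi) are delegated to
  scikit-image and plug into an identical pipeline surface; at most
  `max_keypoints` (default 200 — ample redundancy for a 4-DOF fit) are
  kept, strongest first, and keypoints are re-detected on every frame
  rather than propagated, which avoids track death and drift. The raw
  frame is used as-is (no contrast enhancement or denoising). SIFT runs
  without initial 2× upsampling: capillary structures are several pixels
  wide, so the sub-pixel octave adds cost (~15×) without detections that
  matter here. scikit-image's SIFT exposes no per-keypoint response, so
  SIFT detections are ranked by the Shi–Tomasi measure at their positions;
  this affects only truncation order. All three detectors feed the same
  flow tracker — descriptor matching is not used; flow tracking seeded at
  detected points is the single motion-estimation route.
* **Tracker.** A vectorised sparse pyramidal Lucas–Kanade implementation:
  21×21 window, 3 pyramid levels (downscale 2, Gaussian σ = 1 smoothing),
  per-level Gauss–Newton iterations terminated at 30 iterations or an
  update below 0.01 px; points with a flat normalised gradient matrix
  (min eigenvalue < 1e-4) or tracks leaving the frame are failed. A
  forward–backward re-track with a 1.0 px round-trip gate prunes
  unreliable correspondences.
* **Estimator.** RANSAC over 2-point minimal samples (the similarity has a
  closed form in complex arithmetic), inlier gate 3 px, confidence 0.99,
  ≤2000 seeded iterations with the standard adaptive stopping rule, then
  least-squares refinement on the consensus set. Two further refit rounds
  on a tightened gate (threshold/3) follow: transient objects that move
  coherently a pixel or two per frame — drifting RBCs, exactly the
  structures stabilization must ignore — survive a 3 px gate and otherwise
  bias the fit into slow cumulative drift. Fewer than `min_pairs` (3)
  validated pairs yields an identity link plus a per-frame failure flag;
  the chain never shortens and the run never aborts.
* **Alignment.** Cumulative inverse chaining aligns every frame to frame 0;
  no trajectory smoothing or drift correction is applied on top (fidelity
  to the raw chained model is the point; smoothing is a non-goal). Warping
  uses inverse-mapped bilinear interpolation with mirror reflection
  padding (edge pixel not duplicated), which preserves edge continuity.

## Metrics

* **SSIM** follows the canonical windowed form: 11×11 Gaussian window
  (σ = 1.5), c1 = (0.01·255)², c2 = (0.03·255)², local map mean-pooled over
  the interior (the 5-px border where the window hangs off the frame is
  excluded). It is validated against scikit-image's implementation to
  1e-6. Video SSIM compares each stabilized frame with the corresponding
  stable reference frame; frame 0 is excluded since it is untouched in
  both sequences and would inflate the mean.
* **Jitter Index** is the population standard deviation of inter-frame
  displacement magnitudes √(Δx²+Δy²). For an evaluated video the
  displacements come from transforms re-estimated between consecutive
  output frames, so the metric needs no ground truth; re-estimation always
  uses GFTT, keeping the metric identical across stabilization detectors
  and cheap.
* **Path Smoothness** is the mean Euclidean norm of the second difference
  of the cumulative translation path, normalised by the image diagonal;
  zero for static or constant-velocity paths.
* **RMS errors** compare the per-frame perturbation implied by the
  estimated cumulative chain (C_i⁻¹, centre-normalised) with the logged
  ground truth, as RMS over frames of Δx, Δy (px) and θ (degrees; the
  angular difference is wrapped before squaring).
* **Execution time** is wall-clock around the stabilize call only (no
  I/O). Because it is inherently non-reproducible, the reproducibility
  contract covers every persisted artifact — ground-truth logs, motion
  paths, frame checksums, and all report columns except `exec_time_s`.

## Benchmark sizing

The standard synthetic benchmark used by the acceptance tests runs the
default 640×480 scene at σ = 0.01 with seeds {1, 2, 3} and all three
detectors, 30 frames per sequence; parameter-recovery checks use the
noiseless scene at σ = 0.005, seed 1, 30 frames. These sizes keep a full
suite run to minutes on a single CPU while leaving every directional and
quantitative property (SSIM ordering, jitter reduction, ≤1 px / ≤0.5°
recovery, detector agreement) independent of the sequence length chosen.

## Known limitations

* Cumulative chaining accumulates estimation error; long sequences will
  drift. This is inherent to the raw chained model (no smoothing stage).
* The jitter/smoothness of an evaluated sequence depends on re-estimated
  residual motion and therefore inherits estimator noise near zero motion.
* The stabilizer assumes global rigid-similarity motion; localized tissue
  deformation is compensated only on average.
* Video container I/O requires an imageio plugin with a suitable codec
  backend; the canonical interchange format is a lossless PNG directory.
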