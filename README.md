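# capstab

Keypoint-based video stabilization for oral capillaroscopy sequences.

Capillaroscopy films the microcirculation of the oral mucosa at high
magnification. Hand-held probe contact and involuntary patient motion shake
the field of view, which degrades both visual reading and any downstream
automated capillary segmentation. `capstab` implements a classical,
fully-inspectable stabilization pipeline for such footage, together with a
synthetic tremor simulator (with logged ground truth) and a quantitative
evaluation suite, so stabilization quality can be measured rather than
eyeballed. It is aimed at researchers working on biomedical video
enhancement who need a reproducible baseline pipeline and benchmark.

## Method

Inter-frame motion is modelled as a 4-DOF similarity transform

```
T = [ s·cosθ  −s·sinθ  Δx ]
    [ s·sinθ   s·cosθ  Δy ]
```

with scale *s*, rotation *θ* (radians) and translation (Δx, Δy) in pixels.
For each consecutive frame pair the pipeline:

1. detects keypoints on the earlier frame (pluggable detector: SIFT, ORB or
   GFTT/Shi–Tomasi; no pre-processing is applied before detection);
2. tracks them into the later frame with sparse pyramidal Lucas–Kanade
   optical flow (brightness constancy `Ix·u + Iy·v + It = 0`; 21×21 window,
   3 pyramid levels, ≤30 iterations or update < 0.01 px), pruning tracks
   that fail a 1 px forward–backward check;
3. fits the similarity `T_i` mapping frame *i* to frame *i+1* by RANSAC
   (2-point minimal samples, 3 px inlier gate) followed by least-squares
   refinement on the inliers;
4. aligns every frame to frame 0 by chaining inverse transforms cumulatively,
   `C_{i+1} = T_1⁻¹·T_2⁻¹·…·T_i⁻¹`, and warping with bilinear interpolation
   and reflection padding. Frames where estimation fails contribute an
   identity link and are flagged, never dropped.

The tremor simulator perturbs a stable sequence with independent per-frame
similarities whose parameters are Gaussian: Δx ~ width·N(0, σt²),
Δy ~ height·N(0, σt²), θ ~ N(0, σr²), s ~ N(1, σs²), pivoting at the image
centre. Evaluation reports mean SSIM against the stable reference, a Jitter
Index (std of inter-frame displacement magnitudes), a Path Smoothness Index
(mean second difference of the cumulative trajectory, normalised by the
image diagonal), and RMS recovery errors of the motion parameters against
the logged ground truth.

## Worked example

Render a small synthetic capillary scene, shake it at tremor level
σ = 0.01, stabilize with each detector and compare:

```python
import capstab as cs

cfg = cs.RunConfig(
    scene=cs.SceneSpec(width=320, height=240, n_vessels=8, n_rbc=6, seed=1),
    n_frames=12, sigmas=(0.01,), replicates=1,
    methods=("gftt", "orb", "sift"), seed=1,
)
per_run, aggregate = cs.run_benchmark(cfg)
print(per_run[["method", "mean_ssim", "jitter_index", "rms_dx", "rms_dy",
               "rms_rotation_deg"]].round(4).to_string(index=False))
```

prints

```
method  mean_ssim  jitter_index  rms_dx  rms_dy  rms_rotation_deg
  gftt     0.9521        0.0195  0.0485  0.0232            0.0575
   orb     0.9537        0.0193  0.0383  0.0228            0.0216
  sift     0.9524        0.0311  0.0396  0.0541            0.0440
```

The same perturbed input scores mean SSIM 0.6967 against the stable
reference and a Jitter Index of 2.2467, so stabilization raises structural
similarity from ≈0.70 to ≈0.95 and cuts jitter by two orders of magnitude;
motion parameters are recovered to well under a tenth of a pixel and of a
degree (RMS). The three detectors agree to the second decimal in SSIM —
they are interchangeable front-ends to the same motion model.

The same workflow is available from the shell:

```bash
capstab render   --out ref --frames 30 --seed 1
capstab simulate --input ref --sigma 0.01 --seed 42 --out shaky
capstab stabilize --input shaky --method gftt --out stable
capstab evaluate --reference ref --test stable \
    --truth shaky/ground_truth.csv --estimated stable/motion_inter.csv
capstab benchmark --out bench   # full sigma × detector grid
```

Sequences are exchanged as lossless PNG directories with JSON manifests;
transform logs and reports are CSV.

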