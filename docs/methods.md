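# Methods

## Pipeline model

The package refines per-frame 2D keypoint detections produced by running an
arbitrary detector on rotated copies of a video.  The rotation schedule is
{0°, 10°, …, 350°} by default (any step dividing 360 is accepted).  Frames
are rotated about their centre onto a canvas expanded to the tight bounding
box of the rotated frame, so no content is cropped at any angle; detections
made in a rotated canvas are mapped back to original-frame pixels by the
exact inverse affine map.  Coordinates are 0-based, x right, y down,
sub-pixel continuous; angles are degrees everywhere and converted to
radians only inside trigonometric calls.

For each keypoint independently, the back-projected candidates form a
trellis: one layer per frame, one node per candidate, plus a virtual source
and sink.  The edge linking candidate *i* in frame *n* to candidate *j* in
frame *n+1* costs

    C = c·C_C + d·C_D + r·C_R,
    C_C = 1 / max(conf_j, ε),
    C_D = Euclidean distance between the two candidates (px),
    C_R = |sin(Δr/2)|, Δr the rotation-angle difference in radians.

The refined track is the minimum-cost source→sink path, computed with a
hand-rolled Dijkstra (binary heap, lazy deletion).  On a layered DAG with
non-negative costs this is exact; the test suite cross-checks it against
brute-force path enumeration and against networkx.

### Conventions the cost definition leaves open

* **Whose confidence C_C charges.**  C_C uses the *destination* candidate's
  confidence (`1/conf_j`).  Source edges charge each first-layer
  candidate's own confidence, so every selected node's confidence is
  counted exactly once along any path; sink edges cost zero.
* **Confidence floor.**  ε = 1e-6 keeps costs finite for confidence-0
  candidates while preserving their ordering.
* **Empty frames.**  Frames without candidates are bridged: the flanking
  non-empty layers are linked directly with the same three-term cost
  measured between the flanking candidates.  No per-frame gap penalty is
  added.  Bridged frames are reported as such and stay missing in the
  output pose — the selector never interpolates.
* **Ties.**  The heap orders by (cost, layer, candidate insertion order),
  making selection deterministic for equal-cost paths.
* **Rotation term range.**  With the degree difference converted to
  radians before halving, C_R is 360°-periodic, 0 at Δr = 0 and maximal
  (= 1) at the 180° flip, penalising fast rotation changes.

### Coefficients

Shipped defaults are c = 0.01, d = 1, r = 0.01 (`CostParams()`), the
combination found by exponential grid search during the method's original
validation.  `grid_search` re-runs that search: exhaustive evaluation of a
{10⁻³, 10⁻², 10⁻¹, 1, 10}³ grid (configurable) against mean MPJPE over
labelled validation scenes, deterministic with ties going to the first
combination in grid order.  Degenerate settings have exact interpretations:
d = r = 0 reduces to per-frame argmax confidence; c = r = 0 to the
shortest Euclidean polyline through the candidate layers.

## Metrics

All metrics exclude ground-truth keypoints marked invisible (the −1
sentinel on disk).

* **MPJPE** (px): mean Euclidean error over pairs where the prediction is
  present.  Missing predictions are excluded from the mean — MPJPE stays a
  pure localisation error — and reported separately (`n_missing_pred`).
* **PCK@0.2**: fraction of gt-visible keypoints with error at most
  0.2 × torso diameter; missing predictions count as incorrect.  The torso
  diameter is the per-frame distance between a configurable keypoint pair
  (default right shoulder ↔ left hip); frames where either endpoint is
  invisible fall back to the sequence-median diameter.  In the stratified
  report the fallback median is computed within each category subset.
* **AP**: detection-style average precision.  Per keypoint, every
  gt-visible frame is one positive; predictions present at those frames
  are ranked by confidence (frame order on ties) and are true positives
  within the same torso-fraction threshold as PCK.  AP is the mean
  precision at each true positive divided by the number of positives,
  averaged over keypoints.  This penalises both confident mistakes and
  missed detections.  The threshold rule is serialized into every report.

Reports stratify by per-frame situation label (regular, out-of-balance,
fall) alongside the overall column; a category with no frames is reported
as absent, not zero.

## Synthetic detector

The simulator supplies ground truth and detector output so the pipeline is
testable without GPUs, trained detectors or video data.  It emulates the
four candidate-distribution phenomenologies observed on real injury
footage — narrow unimodal (regular), diffuse with outliers
(out-of-balance), bimodal mirror swaps and sparse dropout (falls).

**Trajectories** are sums of linear drift and low-frequency sinusoids
around a 14-joint (or 24-point) skeleton: per-axis drift speed U(2, 5)
px/frame, two body-centre harmonics with amplitude U(5, 25) px and
frequency U(0.005, 0.02) cycles/frame, plus one per-keypoint harmonic with
amplitude U(1, 4) px and frequency U(0.02, 0.06).  An analytic bound keeps
the per-frame displacement of every keypoint at or below 15 px; parameter
draws exceeding the bound are scaled down.  Everything is drawn from one
seeded generator, so scenes regenerate bit-identically.

**Detections**, per (keypoint, frame, angle): dropout with probability
`dropout_rate`; otherwise the true position (or, with probability
`swap_rate` and only for paired body joints, the mirror joint's position)
plus isotropic Gaussian noise with sd `base_noise_sd` × profile(angle),
plus N(0, `outlier_sd`) with probability `outlier_rate`.  The per-angle
quality profile defaults to 1 + (1 − cos θ)/2 — noise multiplier 1 upright
rising smoothly to 2 at 180° — emulating detectors trained on upright
poses.  Confidence is `clip(1 − slope·err + N(0, 0.02), 0, 1)` where `err`
is the distance to the joint the simulated detector *latched onto*: the
keypoint's own truth normally, the mirror joint for swaps.  Swapped
candidates are therefore confidently wrong, which is what makes the
bimodal fall regime a genuine failure mode rather than a trivially
low-confidence one.

Regime defaults (chosen once as the study conditions):

| regime          | noise sd | outlier rate / sd | swap | dropout | conf. slope |
|-----------------|----------|-------------------|------|---------|-------------|
| regular         | 2 px     | 0.02 / 40 px      | 0    | 0.10    | 0.02 /px    |
| out_of_balance  | 6 px     | 0.10 / 80 px      | 0.05 | 0.25    | 0.01 /px    |
| fall            | 10 px    | 0.25 / 120 px     | 0.10 | 0.55    | 0.008 /px   |

**What the simulator does not model:** detector internals, rendering,
camera motion, snow-spray occlusion structure (dropout is i.i.d. per
rotation and frame rather than correlated across neighbouring angles),
multi-person scenes, and annotation error in the ground truth.  Passing
benchmarks on these scenes therefore demonstrates that the selector
recovers smooth tracks from the modelled corruption regimes — not detector
performance on real footage.

## Benchmark problem sizes

The acceptance script and the recovery tests use 20 scenes per regime of
120 frames × 14 body keypoints × 36 rotations, scoring median per-scene
metrics — large enough for stable medians, small enough to run on one CPU
in minutes.  On these conditions graph refinement cuts the fall-regime
median MPJPE by roughly 80% versus the unrotated baseline and stays within
5% of it in the regular regime, where candidate clouds are already narrow
and there is little to recover; the α-β-γ reference selector lands between
the two.  The sign of these effects (large fall gains, regular performance
maintained, graph more robust than the kinematic filter) is the property
asserted by the tests; exact magnitudes depend on the regime parameters.

## Reference selectors

* **Unrotated baseline** keeps only 0°-rotation candidates (highest
  confidence when several), reproducing standard detection.
* **α-β-γ selector** is a simplified kinematic alternative: a fixed-gain
  position/velocity/acceleration filter, initialised from the first
  non-empty frame's maximum-confidence candidate with zero velocity and
  acceleration, selecting per frame — among candidates within
  `gate_radius` (50 px default) of its prediction — the minimiser of
  distance/confidence, then updating on the residual and coasting through
  empty or gated-out frames.  Gains default to (0.85, 0.005, 0.0001).
  Earlier rotation-augmented pipelines used a filter of this family, but
  their gains, gating and initialisation are not published; these defaults
  are illustrative, and the implementation is a documented approximation,
  not a reproduction.

## Known limitations

* Keypoints are optimised independently; no skeletal consistency between
  joints is enforced.
* Single-subject footage is assumed; there is no multi-person association.
* Detector confidences are passed through unchanged across rotations; no
  recalibration is attempted.
* The shortest path optimises smoothness and confidence, not proximity to
  truth; in regimes where the unrotated detector is already near-perfect
  the refinement can trade a fraction of a pixel of MPJPE for robustness.
* AP has no universally agreed formula for keypoints without per-keypoint
  tolerance constants; the detection-style definition above is one
  consistent choice and is recorded in every report it produces.
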