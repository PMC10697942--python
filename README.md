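# skirefine

Graph-based refinement of 2D keypoint detections from rotated video.

## The problem

Keypoint detectors are trained almost exclusively on upright people, so they
fail precisely where biomechanists need them most: twisted, inverted or
occluded poses, such as a ski racer mid-fall in crash footage used for
injury analysis.  Running the *same* detector on incrementally rotated
copies of every frame (0° to 350° in 10° steps) recovers many of those
misdetections — some rotation usually presents the skier upright enough for
the detector to succeed — but it replaces one problem with another: each
keypoint now has up to 36 candidate locations per frame, and the right one
must be picked.

## The method

Per keypoint, candidates are arranged in a trellis (one layer per frame,
one node per candidate, virtual source and sink) and the selection is posed
as a shortest-path problem.  The edge from candidate *i* in frame *n* to
candidate *j* in frame *n+1* costs

```
C = c · C_C + d · C_D + r · C_R

C_C = 1 / c_{j,n+1}                             confidence of the destination
C_D = ‖(x,y)_{i,n} − (x,y)_{j,n+1}‖₂            spatial jump
C_R = |sin((r_{i,n} − r_{j,n+1}) / 2)|          rotation-angle change
```

with shipped coefficients `c = 0.01, d = 1, r = 0.01` (tunable by
exponential grid search).  Dijkstra's algorithm extracts the minimum-cost
path, i.e. one candidate per frame that is confident, smooth in space and
smooth in source-rotation angle.  Keypoints are optimised independently;
frames without candidates are bridged, never interpolated.

Results are scored with MPJPE (px), PCK@0.2 (threshold: 20% of the torso
diameter) and confidence-ranked AP, stratified by skiing situation
(regular / out-of-balance / fall) — the axis along which detector failures
concentrate.

Because the real injury footage and GPU detectors are external to this
package, it ships a synthetic multi-rotation detector
(`skirefine.synthetic`) that reproduces the observed failure regimes:
narrow unimodal clouds (regular skiing), diffuse clouds with outliers
(out-of-balance), and bimodal left/right swaps plus sparse dropout (falls),
with confidence correlated with localisation quality.

## Worked example

```python
from skirefine import (CostParams, evaluate, make_scene, mpjpe,
                       refine_sequence, tracks_to_pose, unrotated_baseline)

scene = make_scene("fall", seed=11, n_frames=60)      # synthetic fall footage
refined = refine_sequence(scene.trellises, CostParams(), schema="body14")
baseline = tracks_to_pose(
    {k: unrotated_baseline(t) for k, t in scene.trellises.items()},
    60, schema="body14")

print(f"unrotated MPJPE: {mpjpe(baseline, scene.ground_truth):.2f} px")
print(f"refined   MPJPE: {mpjpe(refined, scene.ground_truth):.2f} px")
report = evaluate(refined, scene.ground_truth, scene.labels)
print(report.to_frame().loc[["mpjpe", "pck", "ap"], ["all", "fall"]].round(3))
```

prints

```
unrotated MPJPE: 48.00 px
refined   MPJPE: 9.45 px
         all   fall
mpjpe  9.448  9.448
pck    0.638  0.638
ap     0.612  0.612
```

The unrotated detector loses 55% of its detections in this fall scene and
scatters the rest (48 px mean error); selecting across all 36 rotations
with the shortest path recovers every frame at a 9.4 px mean error, with
64% of keypoints within the PCK@0.2 threshold.

## Command line

```sh
skirefine simulate --out scenes --regime fall --n-seeds 3   # benchmark scenes
skirefine refine scenes/fall_00000/candidates.json \
    --out pose.json --report paths.csv                       # graph selection
skirefine evaluate pose.json scenes/fall_00000/ground_truth.csv \
    --labels scenes/fall_00000/labels.csv --out report       # stratified metrics
skirefine gridsearch scenes/fall_00000 --out grid.csv        # tune c, d, r
skirefine rotate-video frames.npy --out rotated              # for real detectors
```

Candidates travel as COCO-style keypoint JSON extended with a
`rotation_deg` field per annotation; ground truth and labels are plain CSV
with the `-1` sentinel marking invisible keypoints.

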