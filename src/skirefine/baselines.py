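"""Reference candidate selectors the graph refinement is compared against.

``unrotated_baseline`` reproduces standard keypoint detection: only the
0°-rotation candidates are kept, exactly what a detector run on the
original, unrotated video would return.

``abg_select`` is a simplified kinematic selector in the spirit of earlier
rotation-augmented pipelines that chose candidates with an α-β-γ filter.
The original method's gains, gating and initialisation are not published in
detail, so this is a documented approximation, not a reimplementation: a
standard fixed-gain position/velocity/acceleration recursion that gates
candidates around its prediction and picks the best by confidence-weighted
proximity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trellis import (
    FLAG_SELECTED,
    CandidateTrellis,
    RefinedTrack,
    _empty_track,
)


@dataclass(frozen=True)
class AbgParams:
    """Fixed filter gains and the candidate acceptance window.

    With ``gamma=0`` the recursion reduces to an α-β filter; with
    ``alpha=1, beta=gamma=0`` it passes the selected measurements through
    unsmoothed.  Defaults are illustrative, not tuned to any prior method.
    """

    alpha: float = 0.85
    beta: float = 0.005
    gamma: float = 0.0001
    gate_radius: float = 50.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be > 0")


def unrotated_baseline(trellis: CandidateTrellis) -> RefinedTrack:
    """Per frame, the 0°-rotation candidate (highest confidence if several).

    Frames without a 0° candidate are missing.  Equivalent to running the
    detector without any rotation augmentation.
    """
    track = _empty_track(trellis.keypoint_id, trellis.n_frames)
    for f in range(trellis.n_frames):
        xy, conf, rot = trellis.frame_arrays(f)
        at_zero = np.nonzero(rot == 0.0)[0]
        if at_zero.size == 0:
            continue
        best = at_zero[int(np.argmax(conf[at_zero]))]
        track.candidates[f] = trellis.candidate(f, int(best))
        track.flags[f] = FLAG_SELECTED
    return track


def abg_select(trellis: CandidateTrellis,
               params: AbgParams = AbgParams()) -> RefinedTrack:
    """α-β-γ filtered candidate selection (documented approximation).

    The filter state (position, velocity, acceleration; unit frame step) is
    initialised from the first non-empty frame's maximum-confidence
    candidate with zero velocity and acceleration.  Each following frame it
    predicts, selects -- among candidates within ``gate_radius`` of the
    prediction -- the one minimising ``distance / max(confidence, 1e-6)``,
    and updates on the residual; it coasts on the prediction through empty
    or fully gated-out frames, which stay missing in the output.
    """
    track = _empty_track(trellis.keypoint_id, trellis.n_frames)
    track.total_cost = math.nan
    non_empty = trellis.non_empty_frames()
    if not non_empty:
        return track
    first = non_empty[0]

    xy, conf, _ = trellis.frame_arrays(first)
    best = int(np.argmax(conf))
    pos = xy[best].astype(float)
    vel = np.zeros(2)
    acc = np.zeros(2)
    track.candidates[first] = trellis.candidate(first, best)
    track.flags[first] = FLAG_SELECTED

    for f in range(first + 1, trellis.n_frames):
        pred_pos = pos + vel + 0.5 * acc
        pred_vel = vel + acc

        xy, conf, _ = trellis.frame_arrays(f)
        chosen = None
        if xy.shape[0]:
            dist = np.linalg.norm(xy - pred_pos, axis=1)
            in_gate = np.nonzero(dist <= params.gate_radius)[0]
            if in_gate.size:
                score = dist[in_gate] / np.maximum(conf[in_gate], 1e-6)
                chosen = int(in_gate[int(np.argmin(score))])

        if chosen is None:
            pos, vel = pred_pos, pred_vel  # coast
            continue
        residual = xy[chosen] - pred_pos
        pos = pred_pos + params.alpha * residual
        vel = pred_vel + params.beta * residual
        acc = acc + 2.0 * params.gamma * residual
        track.candidates[f] = trellis.candidate(f, chosen)
        track.flags[f] = FLAG_SELECTED
    return track
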