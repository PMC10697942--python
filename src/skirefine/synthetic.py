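"""Synthetic multi-rotation detector: ground-truth trajectories observed
through a noisy, rotation-dependent keypoint detector.

Real detectors run on rotated copies of injury-skiing footage show four
distribution phenomenologies, one per situation regime:

* ``regular`` skiing -- narrow, unimodal candidate clouds around the truth;
* ``out_of_balance`` -- wider, diffuse clouds with occasional outliers;
* ``fall`` -- all of the above plus bimodal left/right mirror confusions and
  sparse distributions where most rotations detect nothing at all.

The simulator emulates exactly these regimes: smooth per-keypoint
trajectories (sum of low-frequency sinusoids plus linear drift) observed
per rotation angle with Gaussian localisation noise scaled by a per-angle
quality profile, plus independent dropout, large-deviation outliers and
mirror-joint swaps.  Confidence is tied to localisation quality through a
linear map, so high confidence correlates with small error -- except for
swaps, which latch onto the mirror joint and are confidently wrong.

Every scene is regenerated bit-identically from ``(params, seed)``, and an
event log records which candidates were dropped, outliers, or swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import RotationSchedule
from .pose import CategoryLabels, PoseSequence, SCHEMAS, mirror_map
from .trellis import CandidateTrellis

#: Canonical body-joint offsets (px) around the skier's centre, x right, y down.
_BODY14_OFFSETS: dict[str, tuple[float, float]] = {
    "head": (0, -70), "neck": (0, -50),
    "right_shoulder": (-18, -45), "right_elbow": (-28, -25), "right_wrist": (-34, -5),
    "left_shoulder": (18, -45), "left_elbow": (28, -25), "left_wrist": (34, -5),
    "right_hip": (-12, 0), "right_knee": (-15, 35), "right_ankle": (-18, 70),
    "left_hip": (12, 0), "left_knee": (15, 35), "left_ankle": (18, 70),
}
_SKI24_EXTRA: dict[str, tuple[float, float]] = {
    "right_ski_tip": (-60, 78), "right_ski_toe": (-25, 78),
    "right_ski_heel": (-10, 78), "right_ski_tail": (20, 78),
    "left_ski_tip": (60, 78), "left_ski_toe": (25, 78),
    "left_ski_heel": (10, 78), "left_ski_tail": (-20, 78),
    "right_pole_tip": (-45, 25), "left_pole_tip": (45, 25),
}


@dataclass(frozen=True)
class MotionModel:
    """Smooth skier motion: linear drift plus low-frequency sinusoids.

    Frequencies are cycles per frame; amplitudes and speeds are pixels.
    ``max_step`` bounds the per-frame displacement of any keypoint; drawn
    motions exceeding the analytic bound are scaled down to honour it.
    """

    schema: str | None = "body14"
    n_keypoints: int | None = None  # required when schema is None
    width: int = 1280
    height: int = 720
    speed_range: tuple[float, float] = (2.0, 5.0)
    center_amp_range: tuple[float, float] = (5.0, 25.0)
    center_freq_range: tuple[float, float] = (0.005, 0.02)
    n_center_harmonics: int = 2
    kp_amp_range: tuple[float, float] = (1.0, 4.0)
    kp_freq_range: tuple[float, float] = (0.02, 0.06)
    max_step: float = 15.0

    def resolved_n_keypoints(self) -> int:
        if self.schema is not None:
            return len(SCHEMAS[self.schema])
        if self.n_keypoints is None:
            raise ValueError("n_keypoints required when schema is None")
        return self.n_keypoints

    def skeleton_offsets(self) -> np.ndarray:
        k = self.resolved_n_keypoints()
        if self.schema == "body14":
            names = SCHEMAS["body14"]
            return np.array([_BODY14_OFFSETS[n] for n in names])
        if self.schema == "ski24":
            table = {**_BODY14_OFFSETS, **_SKI24_EXTRA}
            return np.array([table[n] for n in SCHEMAS["ski24"]])
        # anonymous schema: spread keypoints on a ring
        ang = 2 * np.pi * np.arange(k) / max(k, 1)
        return 40.0 * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class RegimeParams:
    """Detector-behaviour parameters for one situation regime.

    ``rotation_quality_profile`` multiplies the localisation noise per
    scheduled angle; ``None`` selects the default smooth profile rising
    from 1 at upright to 2 at the 180° flip, emulating detectors trained
    mostly on upright poses.
    """

    regime: str
    base_noise_sd: float
    outlier_rate: float
    outlier_sd: float
    swap_rate: float
    dropout_rate: float
    confidence_error_slope: float
    confidence_noise_sd: float = 0.02
    rotation_quality_profile: tuple[float, ...] | None = None

    def __post_init__(self):
        for name in ("outlier_rate", "swap_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("base_noise_sd", "outlier_sd", "confidence_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def profile_for(self, schedule: RotationSchedule) -> np.ndarray:
        if self.rotation_quality_profile is not None:
            prof = np.asarray(self.rotation_quality_profile, dtype=float)
            if prof.size != len(schedule):
                raise ValueError(
                    f"profile length {prof.size} != schedule length {len(schedule)}"
                )
            return prof
        return default_quality_profile(schedule)


def default_quality_profile(schedule: RotationSchedule) -> np.ndarray:
    """Noise multiplier 1 near upright, rising smoothly to 2 at 180°."""
    return 1.0 + 0.5 * (1.0 - np.cos(np.radians(schedule.angles)))


REGIME_DEFAULTS: dict[str, RegimeParams] = {
    "regular": RegimeParams(
        regime="regular", base_noise_sd=2.0, outlier_rate=0.02, outlier_sd=40.0,
        swap_rate=0.0, dropout_rate=0.10, confidence_error_slope=0.02,
    ),
    "out_of_balance": RegimeParams(
        regime="out_of_balance", base_noise_sd=6.0, outlier_rate=0.10,
        outlier_sd=80.0, swap_rate=0.05, dropout_rate=0.25,
        confidence_error_slope=0.01,
    ),
    "fall": RegimeParams(
        regime="fall", base_noise_sd=10.0, outlier_rate=0.25, outlier_sd=120.0,
        swap_rate=0.10, dropout_rate=0.55, confidence_error_slope=0.008,
    ),
}


@dataclass
class SyntheticScene:
    """One simulated recording: truth, candidates, labels and bookkeeping."""

    ground_truth: PoseSequence
    trellises: dict[int, CandidateTrellis]
    labels: CategoryLabels
    events: dict[int, dict]
    seed: int
    params: RegimeParams
    schedule: RotationSchedule
    width: int
    height: int

    def event_counts(self) -> dict[str, int]:
        out = {"emitted": 0, "dropped": 0, "outliers": 0, "swaps": 0}
        for ev in self.events.values():
            for key in out:
                out[key] += int(ev[key])
        return out


def simulate_trajectory(n_frames: int, model: MotionModel | None = None,
                        seed: int = 0) -> PoseSequence:
    """Smooth per-keypoint ground-truth trajectories, deterministic per seed."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    model = model or MotionModel()
    rng = np.random.default_rng(seed)
    k = model.resolved_n_keypoints()
    offsets = model.skeleton_offsets()

    center0 = np.array([model.width / 2.0, model.height / 2.0]) + \
        rng.uniform([-50, -30], [50, 30])
    speed = rng.uniform(*model.speed_range)
    heading = rng.uniform(0, 2 * np.pi)
    vel = speed * np.array([np.cos(heading), np.sin(heading)])

    nh = model.n_center_harmonics
    c_amp = rng.uniform(*model.center_amp_range, size=(nh, 2))
    c_freq = rng.uniform(*model.center_freq_range, size=(nh, 2))
    c_phase = rng.uniform(0, 2 * np.pi, size=(nh, 2))
    k_amp = rng.uniform(*model.kp_amp_range, size=(k, 2))
    k_freq = rng.uniform(*model.kp_freq_range, size=(k, 2))
    k_phase = rng.uniform(0, 2 * np.pi, size=(k, 2))

    # Analytic per-axis bound on the per-frame displacement; scale motion
    # terms down if the drawn parameters could exceed max_step.
    bound_axis = np.abs(vel) + (c_amp * 2 * np.pi * c_freq).sum(axis=0) + \
        (k_amp * 2 * np.pi * k_freq).max(axis=0)
    bound = float(np.hypot(*bound_axis))
    if bound > model.max_step > 0:
        scale = 0.999 * model.max_step / bound
        vel = vel * scale
        c_amp = c_amp * scale
        k_amp = k_amp * scale

    t = np.arange(n_frames)[:, None]
    center = center0[None, :] + vel[None, :] * t
    for h in range(nh):
        center = center + c_amp[h] * np.sin(2 * np.pi * c_freq[h] * t + c_phase[h])
    tt = np.arange(n_frames)[:, None, None]
    wobble = k_amp[None, :, :] * np.sin(
        2 * np.pi * k_freq[None, :, :] * tt + k_phase[None, :, :]
    )
    xy = center[:, None, :] + offsets[None, :, :] + wobble
    return PoseSequence(xy, schema=model.schema)


def simulate_detections(gt: PoseSequence, params: RegimeParams,
                        schedule: RotationSchedule | None = None,
                        seed: int = 0, width: int = 1280,
                        height: int = 720) -> SyntheticScene:
    """Observe a ground-truth sequence through the noisy rotation detector.

    Per (keypoint, frame, rotation): with probability ``dropout_rate``
    nothing is emitted; otherwise the candidate is the true location (or
    the mirror joint's, with probability ``swap_rate``) plus Gaussian noise
    scaled by the per-angle quality profile, plus a large-sd perturbation
    with probability ``outlier_rate``.  Confidence is
    ``clip(1 − slope·err + noise, 0, 1)`` with ``err`` measured against the
    joint the detector latched onto, so confidence tracks perceived quality.
    """
    schedule = schedule or RotationSchedule()
    rng = np.random.default_rng(seed)
    angles = schedule.angles
    n_ang = len(schedule)
    n_frames, n_kp = gt.n_frames, gt.n_keypoints
    profile = params.profile_for(schedule)
    mirrors = mirror_map(gt.schema, n_kp)

    trellises: dict[int, CandidateTrellis] = {}
    events: dict[int, dict] = {}
    for k in range(n_kp):
        u_drop = rng.random((n_frames, n_ang))
        u_swap = rng.random((n_frames, n_ang))
        u_out = rng.random((n_frames, n_ang))
        noise = rng.normal(size=(n_frames, n_ang, 2))
        out_extra = rng.normal(size=(n_frames, n_ang, 2))
        conf_noise = rng.normal(size=(n_frames, n_ang))

        emitted = u_drop >= params.dropout_rate
        swapped = (u_swap < params.swap_rate) & (k in mirrors)
        outlier = u_out < params.outlier_rate

        own = gt.xy[:, k, :][:, None, :]
        base = np.broadcast_to(own, (n_frames, n_ang, 2)).copy()
        if k in mirrors:
            mirror_xy = gt.xy[:, mirrors[k], :][:, None, :]
            base[swapped] = np.broadcast_to(
                mirror_xy, (n_frames, n_ang, 2))[swapped]

        sd = params.base_noise_sd * profile  # (n_ang,)
        pos = base + noise * sd[None, :, None]
        pos = pos + np.where(outlier[..., None], out_extra * params.outlier_sd, 0.0)

        err = np.linalg.norm(pos - base, axis=-1)
        conf = np.clip(
            1.0 - params.confidence_error_slope * err
            + params.confidence_noise_sd * conf_noise,
            0.0, 1.0,
        )

        tr = CandidateTrellis(keypoint_id=k, n_frames=n_frames)
        for f in range(n_frames):
            sel = emitted[f]
            if sel.any():
                tr.extend_frame(f, pos[f, sel], conf[f, sel], angles[sel])
        trellises[k] = tr
        events[k] = {
            "emitted": int(emitted.sum()),
            "dropped": int((~emitted).sum()),
            "outliers": int((emitted & outlier).sum()),
            "swaps": int((emitted & swapped).sum()),
            "emitted_mask": emitted,
            "outlier_mask": emitted & outlier,
            "swap_mask": emitted & swapped,
        }

    labels = CategoryLabels.constant(params.regime, n_frames)
    return SyntheticScene(
        ground_truth=gt, trellises=trellises, labels=labels, events=events,
        seed=seed, params=params, schedule=schedule, width=width, height=height,
    )


def make_scene(regime: str, seed: int, n_frames: int = 120,
               model: MotionModel | None = None,
               schedule: RotationSchedule | None = None,
               params: RegimeParams | None = None) -> SyntheticScene:
    """One scene of a regime: trajectory seed ``2·seed``, detector ``2·seed+1``."""
    model = model or MotionModel()
    params = params or REGIME_DEFAULTS[regime]
    if params.regime != regime:
        params = replace(params, regime=regime)
    gt = simulate_trajectory(n_frames, model, seed=2 * seed)
    return simulate_detections(gt, params, schedule, seed=2 * seed + 1,
                               width=model.width, height=model.height)


def make_benchmark_suite(
    seeds: Iterable[int],
    regimes: Sequence[str] = ("regular", "out_of_balance", "fall"),
    n_frames: int = 120,
    model: MotionModel | None = None,
    schedule: RotationSchedule | None = None,
    overrides: Mapping[str, RegimeParams] | None = None,
) -> list[SyntheticScene]:
    """Scenes across all regimes and seeds, reproducible bit-identically."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    overrides = dict(overrides or {})
    out = []
    for regime in regimes:
        params = overrides.get(regime, REGIME_DEFAULTS[regime])
        for seed in seeds:
            out.append(make_scene(regime, seed, n_frames=n_frames, model=model,
                                  schedule=schedule, params=params))
    return out
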