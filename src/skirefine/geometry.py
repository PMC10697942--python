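"""Rotation geometry: forward rotation and exact back-projection of keypoints.

The refinement pipeline runs a keypoint detector on incrementally rotated
copies of every video frame (0° to 360° in fixed steps, 10° by default).
Detections come back in the rotated canvas's pixel coordinates and must be
mapped exactly back into the original frame before candidates can be linked
across frames.  This module owns that coordinate algebra: the rotation
schedule, the rotate-and-expand canvas geometry, and the exact affine maps
in both directions.

Conventions: coordinates are 0-based, x to the right, y down, sub-pixel
continuous; keypoints are points, not pixels.  Rotation is about the image
center with the canvas expanded to the tight bounding box of the rotated
frame, so no image content is ever cropped.  Angles are degrees throughout;
radians appear only inside trigonometric calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np


class Detection(NamedTuple):
    """One raw detector output in rotated-canvas coordinates."""

    frame: int
    keypoint_id: int
    angle: float
    x: float
    y: float
    confidence: float


@dataclass(frozen=True)
class RotationSchedule:
    """The set of angles {0, step, 2·step, …, 360 − step} in degrees."""

    step: float = 10.0

    def __post_init__(self):
        if not 0 < self.step <= 360:
            raise ValueError(f"step must be in (0, 360], got {self.step}")
        k = 360.0 / self.step
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"step must divide 360 evenly, got {self.step}")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.step)

    def __len__(self) -> int:
        return int(round(360.0 / self.step))

    def __iter__(self):
        return iter(self.angles)

    def __contains__(self, angle: float) -> bool:
        q = (float(angle) % 360.0) / self.step
        return abs(q - round(q)) < 1e-9

    def index(self, angle: float) -> int:
        """1-based rotation index i ∈ 1…len(schedule)."""
        if angle not in self:
            raise ValueError(f"angle {angle} not in schedule (step {self.step})")
        return 1 + int(round((float(angle) % 360.0) / self.step))


@dataclass(frozen=True)
class ImageGeometry:
    """Original and rotated-canvas dimensions for one rotation angle.

    The rotated canvas is the tight integer bounding box of the original
    frame rotated by ``angle`` about its center.
    """

    width: int
    height: int
    angle: float
    rotated_width: int
    rotated_height: int

    @classmethod
    def create(cls, width: int, height: int, angle: float) -> "ImageGeometry":
        if width <= 0 or height <= 0:
            raise ValueError("image dimensions must be positive")
        a = float(angle) % 360.0
        t = math.radians(a)
        c, s = abs(math.cos(t)), abs(math.sin(t))
        # 1e-9 slack absorbs float dust (cos 90° ~ 6e-17) while ceil keeps
        # every original point inside the canvas.
        rw = math.ceil(width * c + height * s - 1e-9)
        rh = math.ceil(width * s + height * c - 1e-9)
        return cls(int(width), int(height), a, rw, rh)


def _rotation_terms(geom: ImageGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = math.radians(geom.angle)
    ct, st = math.cos(t), math.sin(t)
    rot = np.array([[ct, st], [-st, ct]])
    center = np.array([geom.width / 2.0, geom.height / 2.0])
    center_rot = np.array([geom.rotated_width / 2.0, geom.rotated_height / 2.0])
    return rot, center, center_rot


def _check_schedule(geom: ImageGeometry, schedule: RotationSchedule | None) -> None:
    if schedule is not None and geom.angle not in schedule:
        raise ValueError(
            f"angle {geom.angle} is not in the rotation schedule (step {schedule.step})"
        )


def rotate_point(p, geom: ImageGeometry, schedule: RotationSchedule | None = None):
    """Map original-frame coordinates into the rotated, expanded canvas.

    ``p`` may be a single (x, y) pair or an (N, 2) array; points outside
    the image bounds are mapped without clipping.  Pure exact affine map.
    """
    _check_schedule(geom, schedule)
    rot, center, center_rot = _rotation_terms(geom)
    p = np.asarray(p, dtype=float)
    return (p - center) @ rot.T + center_rot


def backproject_point(p_rot, geom: ImageGeometry, schedule: RotationSchedule | None = None):
    """Exact inverse of :func:`rotate_point` for the same geometry."""
    _check_schedule(geom, schedule)
    rot, center, center_rot = _rotation_terms(geom)
    p_rot = np.asarray(p_rot, dtype=float)
    return (p_rot - center_rot) @ rot + center


def forward_matrix(geom: ImageGeometry) -> np.ndarray:
    """The 2×3 affine matrix M with p_rot = M @ [x, y, 1]."""
    rot, center, center_rot = _rotation_terms(geom)
    offset = center_rot - rot @ center
    return np.hstack([rot, offset[:, None]])


def geometries_for(width: int, height: int,
                   schedule: RotationSchedule) -> dict[float, ImageGeometry]:
    """One :class:`ImageGeometry` per scheduled angle."""
    return {float(a): ImageGeometry.create(width, height, a) for a in schedule}


def backproject_detections(
    detections: Iterable[Detection],
    schedule: RotationSchedule,
    geoms: Mapping[float, ImageGeometry],
    n_frames: int | None = None,
):
    """Back-rotate per-rotation detections into original-frame candidates.

    Every detection carries its source angle and rotated-canvas coordinates;
    the result is one candidate trellis per keypoint id, with confidences
    passed through unchanged and the source rotation retained.  Missing
    detections are simply absent -- no placeholders are inserted.

    Returns
    -------
    dict mapping keypoint_id -> CandidateTrellis
    """
    from .trellis import CandidateTrellis, KeypointCandidate

    detections = list(detections)
    if n_frames is None:
        n_frames = 1 + max((d.frame for d in detections), default=-1)

    per_kp: dict[int, list[KeypointCandidate]] = {}
    for det in detections:
        a = float(det.angle) % 360.0
        if a not in schedule:
            raise ValueError(
                f"detection at frame {det.frame}, keypoint {det.keypoint_id} "
                f"references angle {det.angle} absent from the schedule"
            )
        try:
            geom = geoms[a]
        except KeyError:
            raise ValueError(f"no geometry supplied for angle {a}") from None
        x, y = backproject_point((det.x, det.y), geom)
        per_kp.setdefault(det.keypoint_id, []).append(
            KeypointCandidate(
                x=float(x),
                y=float(y),
                confidence=det.confidence,
                rotation=a,
                frame=det.frame,
                keypoint_id=det.keypoint_id,
                rotation_index=schedule.index(a),
            )
        )

    return {
        k: CandidateTrellis.from_candidates(cands, n_frames=n_frames, keypoint_id=k)
        for k, cands in sorted(per_kp.items())
    }


def rotate_frame(frame: np.ndarray, geom: ImageGeometry, order: int = 1) -> np.ndarray:
    """Resample one image onto the rotated, expanded canvas.

    Bilinear interpolation by default, black padding.  Integer inputs are
    rounded back to their own dtype.  Only the optional video utility uses
    this; the coordinate math above is resolution independent.
    """
    from scipy import ndimage

    rot, center, center_rot = _rotation_terms(geom)
    # affine_transform maps output (row, col) to input coords:
    #   p_in(xy) = R^T (p_out - c_rot) + c
    inv = rot.T
    offset_xy = center - inv @ center_rot
    # xy form p_in = A p_out + b becomes [y,x]_in = SAS [y,x]_out + Sb
    # with S the axis swap.  Pixel (row, col) samples the continuous plane
    # at (col+0.5, row+0.5), so shift into and out of cell centres.
    matrix_yx = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset_yx = np.array([offset_xy[1], offset_xy[0]])
    half = np.array([0.5, 0.5])
    offset_yx = matrix_yx @ half + offset_yx - half

    def _snap(a):
        # affine_transform treats -2e-16 as fully outside the image, so
        # round away trig dust at right angles
        r = np.rint(a)
        return np.where(np.abs(a - r) < 1e-12, r, a)

    matrix_yx = _snap(matrix_yx)
    offset_yx = _snap(offset_yx)
    out_shape = (geom.rotated_height, geom.rotated_width)

    def _one_channel(img2d):
        return ndimage.affine_transform(
            img2d.astype(float), matrix_yx, offset=offset_yx,
            output_shape=out_shape, order=order, mode="constant", cval=0.0,
        )

    if frame.ndim == 2:
        out = _one_channel(frame)
    elif frame.ndim == 3:
        out = np.stack([_one_channel(frame[..., c]) for c in range(frame.shape[2])], axis=-1)
    else:
        raise ValueError("frame must be 2D grayscale or 3D multichannel")
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(frame.dtype)
    return out


def rotate_video_frames(
    frames, schedule: RotationSchedule, order: int = 1
) -> tuple[dict[float, np.ndarray], dict[float, ImageGeometry]]:
    """Rotate an image stack by every scheduled angle.

    Parameters
    ----------
    frames : array (n, H, W) or (n, H, W, C)
        Frames sharing dimensions.

    Returns
    -------
    (stacks, geoms) : per-angle image stacks on expanded canvases and the
        lossless geometry metadata needed to back-project detections.
    """
    frames = np.asarray(frames)
    if frames.ndim not in (3, 4) or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, H, W[, C]) stack")
    h, w = frames.shape[1:3]
    geoms = geometries_for(w, h, schedule)
    stacks: dict[float, np.ndarray] = {}
    for a, geom in geoms.items():
        if a == 0.0:
            stacks[a] = frames.copy()
        else:
            stacks[a] = np.stack([rotate_frame(f, geom, order=order) for f in frames])
    return stacks, geoms
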