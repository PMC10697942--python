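"""Pose sequences, keypoint schemas and per-frame situation labels.

The annotation convention used for injury-skiing footage assigns 24
keypoints per frame: 14 body joints, 4 points per ski (tip, toe piece,
heel piece, tail) and one tip per pole.  Keypoints that are not visible
carry the ``(-1, -1)`` coordinate sentinel on disk and an explicit boolean
flag in memory.  Every frame additionally carries a situation label --
``regular`` skiing, ``out_of_balance`` (skier out of control but on skis)
or ``fall`` (skier on the ground or airborne) -- which is the axis along
which all evaluation is stratified.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

BODY14: tuple[str, ...] = (
    "head",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
)

SKI24: tuple[str, ...] = BODY14 + (
    "right_ski_tip",
    "right_ski_toe",
    "right_ski_heel",
    "right_ski_tail",
    "left_ski_tip",
    "left_ski_toe",
    "left_ski_heel",
    "left_ski_tail",
    "right_pole_tip",
    "left_pole_tip",
)

SCHEMAS: dict[str, tuple[str, ...]] = {"body14": BODY14, "ski24": SKI24}

#: Left/right joint pairs eligible for detector side confusion. Only paired
#: body joints can be mirror-swapped; head, neck and equipment points never are.
MIRROR_JOINTS: tuple[tuple[str, str], ...] = (
    ("right_shoulder", "left_shoulder"),
    ("right_elbow", "left_elbow"),
    ("right_wrist", "left_wrist"),
    ("right_hip", "left_hip"),
    ("right_knee", "left_knee"),
    ("right_ankle", "left_ankle"),
)

CATEGORIES: tuple[str, ...] = ("regular", "out_of_balance", "fall")

SENTINEL = -1.0


def schema_names(schema: str | None, n_keypoints: int) -> tuple[str, ...]:
    """Keypoint names for ``schema``, or generic ``kp<i>`` names if None."""
    if schema is None:
        return tuple(f"kp{i}" for i in range(n_keypoints))
    try:
        names = SCHEMAS[schema]
    except KeyError:
        raise ValueError(f"unknown keypoint schema {schema!r}") from None
    if len(names) != n_keypoints:
        raise ValueError(
            f"schema {schema!r} has {len(names)} keypoints, got {n_keypoints}"
        )
    return names


def mirror_map(schema: str | None, n_keypoints: int) -> dict[int, int]:
    """Index map of mirror-swappable joints (both directions)."""
    if schema is None:
        return {}
    names = schema_names(schema, n_keypoints)
    index = {name: i for i, name in enumerate(names)}
    out: dict[int, int] = {}
    for a, b in MIRROR_JOINTS:
        if a in index and b in index:
            out[index[a]] = index[b]
            out[index[b]] = index[a]
    return out


class PoseSequence:
    """Per-frame 2D keypoints with visibility flags and optional confidences.

    Parameters
    ----------
    xy : array (n_frames, K, 2)
        Pixel coordinates; NaN allowed where invisible.
    visible : bool array (n_frames, K), optional
        Defaults to finite-coordinate entries.
    confidence : array (n_frames, K), optional
        Detector scores in [0, 1]; NaN where unavailable.
    schema : str, optional
        Named schema (``body14``/``ski24``); ``None`` leaves keypoints
        anonymous.
    """

    __slots__ = ("xy", "visible", "confidence", "schema")

    def __init__(self, xy, visible=None, confidence=None, schema: str | None = None):
        xy = np.array(xy, dtype=float)
        if xy.ndim != 3 or xy.shape[2] != 2:
            raise ValueError(f"xy must have shape (n_frames, K, 2), got {xy.shape}")
        if visible is None:
            visible = np.all(np.isfinite(xy), axis=2)
        visible = np.array(visible, dtype=bool)
        if visible.shape != xy.shape[:2]:
            raise ValueError("visible shape must match (n_frames, K)")
        if confidence is not None:
            confidence = np.array(confidence, dtype=float)
            if confidence.shape != xy.shape[:2]:
                raise ValueError("confidence shape must match (n_frames, K)")
        if schema is not None:
            schema_names(schema, xy.shape[1])  # validates
        self.xy = xy
        self.visible = visible
        self.confidence = confidence
        self.schema = schema

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.xy.shape[1]

    @property
    def keypoint_names(self) -> tuple[str, ...]:
        return schema_names(self.schema, self.n_keypoints)

    def keypoint_index(self, name: str | int) -> int:
        if isinstance(name, (int, np.integer)):
            k = int(name)
            if not 0 <= k < self.n_keypoints:
                raise ValueError(f"keypoint index {k} out of range")
            return k
        try:
            return self.keypoint_names.index(name)
        except ValueError:
            raise ValueError(f"unknown keypoint {name!r}") from None

    def subset(self, frames: Iterable[int]) -> "PoseSequence":
        idx = np.asarray(list(frames), dtype=int)
        conf = None if self.confidence is None else self.confidence[idx]
        return PoseSequence(self.xy[idx], self.visible[idx], conf, self.schema)

    def to_sentinel(self) -> np.ndarray:
        """Serialized form: invisible keypoints as (-1, -1)."""
        out = self.xy.copy()
        out[~self.visible] = SENTINEL
        return out

    @classmethod
    def from_sentinel(cls, arr, confidence=None, schema: str | None = None) -> "PoseSequence":
        arr = np.array(arr, dtype=float)
        invisible = np.all(arr == SENTINEL, axis=2) | ~np.all(np.isfinite(arr), axis=2)
        xy = arr.copy()
        xy[invisible] = np.nan
        return cls(xy, ~invisible, confidence, schema)


class CategoryLabels:
    """One skiing-situation label per frame."""

    __slots__ = ("labels",)

    def __init__(self, labels: Sequence[str]):
        labels = np.asarray(labels, dtype=object)
        bad = [l for l in labels if l not in CATEGORIES]
        if bad:
            raise ValueError(f"unknown categories {sorted(set(map(str, bad)))}; "
                             f"expected one of {CATEGORIES}")
        self.labels = labels

    @classmethod
    def constant(cls, label: str, n_frames: int) -> "CategoryLabels":
        return cls([label] * n_frames)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def frames_for(self, category: str) -> np.ndarray:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return np.nonzero(self.labels == category)[0]
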