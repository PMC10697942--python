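"""Readers and writers for the pipeline's on-disk formats.

Candidates travel as COCO-style keypoint JSON extended with a per-annotation
``rotation_deg`` field; coordinates are stored in the rotated canvas exactly
as a detector would emit them, and are back-projected into the original
frame on read.  Poses are COCO keypoint triplets with the ``-1`` sentinel
for invisible points.  Ground truth and situation labels are plain CSV;
geometry sidecars and configuration are YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    Detection,
    ImageGeometry,
    RotationSchedule,
    backproject_detections,
    geometries_for,
    rotate_point,
)
from .pose import CategoryLabels, PoseSequence, SCHEMAS, schema_names
from .trellis import CandidateTrellis, RefinedTrack

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# candidate JSON (extended COCO keypoints)

def write_candidates_json(path, trellises: Mapping[int, CandidateTrellis],
                          schedule: RotationSchedule, width: int, height: int,
                          schema: str | None = None) -> None:
    """Serialize candidate trellises as per-rotation detections.

    Candidate coordinates are forward-rotated into each angle's canvas, so
    the file looks exactly like raw detector output on rotated video.
    """
    geoms = geometries_for(width, height, schedule)
    n_frames = max((t.n_frames for t in trellises.values()), default=0)
    n_keypoints = 1 + max(trellises.keys(), default=-1)

    images = []
    for a in schedule:
        g = geoms[float(a)]
        for f in range(n_frames):
            images.append({
                "id": (schedule.index(a) - 1) * n_frames + f,
                "frame_index": f,
                "rotation_deg": float(a),
                "width": g.rotated_width,
                "height": g.rotated_height,
            })

    annotations = []
    ann_id = 0
    for k in sorted(trellises):
        tr = trellises[k]
        for f in range(tr.n_frames):
            xy, conf, rot = tr.frame_arrays(f)
            for i in range(xy.shape[0]):
                a = float(rot[i])
                g = geoms[a]
                xr, yr = rotate_point(xy[i], g)
                annotations.append({
                    "id": ann_id,
                    "image_id": (schedule.index(a) - 1) * n_frames + f,
                    "category_id": 1,
                    "keypoint_id": k,
                    "keypoints": [float(xr), float(yr), float(conf[i])],
                    "rotation_deg": a,
                })
                ann_id += 1

    doc = {
        "info": {
            "description": "rotated keypoint candidates",
            "width": int(width),
            "height": int(height),
            "n_frames": int(n_frames),
            "schema": schema,
        },
        "rotation": {"step": schedule.step},
        "categories": [{
            "id": 1,
            "name": "skier",
            "keypoints": list(schema_names(schema, n_keypoints)),
        }],
        "images": images,
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc))


def read_candidates_json(path) -> dict:
    """Read per-rotation detections and back-project them.

    Returns a dict with ``trellises`` (keypoint_id -> CandidateTrellis in
    original-frame pixels), ``schedule``, ``width``, ``height``,
    ``n_frames`` and ``schema``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc

    try:
        info = doc["info"]
        width, height = int(info["width"]), int(info["height"])
        n_frames = int(info["n_frames"])
        schema = info.get("schema")
        schedule = RotationSchedule(step=float(doc["rotation"]["step"]))
        image_frame = {img["id"]: int(img["frame_index"]) for img in doc["images"]}
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed header field {exc}") from exc

    detections = []
    for ann in doc.get("annotations", []):
        try:
            x, y, score = ann["keypoints"][:3]
            detections.append(Detection(
                frame=image_frame[ann["image_id"]],
                keypoint_id=int(ann["keypoint_id"]),
                angle=float(ann["rotation_deg"]),
                x=float(x), y=float(y), confidence=float(score),
            ))
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise FormatError(
                f"{path}: malformed annotation id={ann.get('id')!r}: {exc}"
            ) from exc

    geoms = geometries_for(width, height, schedule)
    trellises = backproject_detections(detections, schedule, geoms,
                                       n_frames=n_frames)
    return {
        "trellises": trellises,
        "schedule": schedule,
        "width": width,
        "height": height,
        "n_frames": n_frames,
        "schema": schema,
    }


# ---------------------------------------------------------------------------
# pose JSON

def write_pose_json(path, pose: PoseSequence) -> None:
    """COCO-style keypoint triplets [x, y, v] with -1 sentinels."""
    sent = pose.to_sentinel()
    annotations = []
    for f in range(pose.n_frames):
        triplets = []
        for k in range(pose.n_keypoints):
            v = 1 if pose.visible[f, k] else 0
            triplets += [float(sent[f, k, 0]), float(sent[f, k, 1]), v]
        scores = None
        if pose.confidence is not None:
            scores = [
                float(c) if np.isfinite(c) else -1.0
                for c in pose.confidence[f]
            ]
        ann = {"frame_index": f, "keypoints": triplets}
        if scores is not None:
            ann["scores"] = scores
        annotations.append(ann)
    doc = {
        "info": {
            "schema": pose.schema,
            "n_frames": pose.n_frames,
            "n_keypoints": pose.n_keypoints,
        },
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc))


def read_pose_json(path) -> PoseSequence:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        info = doc["info"]
        n_frames, n_kp = int(info["n_frames"]), int(info["n_keypoints"])
        schema = info.get("schema")
        xy = np.full((n_frames, n_kp, 2), np.nan)
        visible = np.zeros((n_frames, n_kp), dtype=bool)
        conf = np.full((n_frames, n_kp), np.nan)
        has_scores = False
        for ann in doc["annotations"]:
            f = int(ann["frame_index"])
            trip = np.asarray(ann["keypoints"], dtype=float).reshape(n_kp, 3)
            visible[f] = trip[:, 2] > 0
            xy[f][visible[f]] = trip[visible[f], :2]
            if "scores" in ann:
                has_scores = True
                s = np.asarray(ann["scores"], dtype=float)
                conf[f] = np.where(s < 0, np.nan, s)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed pose record: {exc}") from exc
    return PoseSequence(xy, visible, conf if has_scores else None, schema)


# ---------------------------------------------------------------------------
# ground truth / labels CSV

def write_ground_truth_csv(path, pose: PoseSequence) -> None:
    """One row per frame; ``<name>_x, <name>_y`` columns, -1 sentinels."""
    sent = pose.to_sentinel()
    data = {"frame": np.arange(pose.n_frames)}
    for k, name in enumerate(pose.keypoint_names):
        data[f"{name}_x"] = sent[:, k, 0]
        data[f"{name}_y"] = sent[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_ground_truth_csv(path, schema: str | None = "auto") -> PoseSequence:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise FormatError(f"{path}: missing 'frame' column")
    df = df.sort_values("frame").reset_index(drop=True)
    names = [c[:-2] for c in df.columns if c.endswith("_x")]
    if schema == "auto":
        schema = next(
            (s for s, sn in SCHEMAS.items() if tuple(names) == sn), None
        )
    arr = np.stack(
        [df[[f"{n}_x", f"{n}_y"] ].to_numpy(dtype=float) for n in names], axis=1
    )
    return PoseSequence.from_sentinel(arr, schema=schema)


def write_labels_csv(path, labels: CategoryLabels) -> None:
    pd.DataFrame({"frame": np.arange(len(labels)),
                  "label": list(labels)}).to_csv(path, index=False)


def read_labels_csv(path) -> CategoryLabels:
    df = pd.read_csv(path)
    for col in ("frame", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing '{col}' column")
    df = df.sort_values("frame")
    if not np.array_equal(df["frame"].to_numpy(), np.arange(len(df))):
        raise FormatError(f"{path}: frames must be contiguous from 0")
    return CategoryLabels(df["label"].tolist())


# ---------------------------------------------------------------------------
# reports and sidecars

def write_path_report_csv(path, tracks: Mapping[int, RefinedTrack],
                          schema: str | None = None) -> None:
    """Per-keypoint, per-frame selection report (angle, confidence, cost)."""
    n_kp = 1 + max(tracks.keys(), default=-1)
    names = schema_names(schema, n_kp)
    rows = []
    for k in sorted(tracks):
        tr = tracks[k]
        for f in range(tr.n_frames):
            cand = tr.candidates[f]
            rows.append({
                "keypoint_id": k,
                "keypoint_name": names[k] if k < len(names) else f"kp{k}",
                "frame": f,
                "flag": tr.flags[f],
                "x": cand.x if cand else np.nan,
                "y": cand.y if cand else np.nan,
                "confidence": cand.confidence if cand else np.nan,
                "rotation_deg": cand.rotation if cand else np.nan,
                "total_cost": tr.total_cost,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_geometry_yaml(path, geoms: Mapping[float, ImageGeometry]) -> None:
    doc = {
        "angles": {
            float(a): {
                "width": g.width, "height": g.height,
                "rotated_width": g.rotated_width,
                "rotated_height": g.rotated_height,
            }
            for a, g in geoms.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(doc))


# ---------------------------------------------------------------------------
# scene directories (simulate output)

def write_scene_dir(directory, scene) -> None:
    """candidates.json + ground_truth.csv + labels.csv + scene.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_candidates_json(directory / "candidates.json", scene.trellises,
                          scene.schedule, scene.width, scene.height,
                          schema=scene.ground_truth.schema)
    write_ground_truth_csv(directory / "ground_truth.csv", scene.ground_truth)
    write_labels_csv(directory / "labels.csv", scene.labels)
    meta = {
        "seed": scene.seed,
        "regime": scene.params.regime,
        "width": scene.width,
        "height": scene.height,
        "rotation_step": scene.schedule.step,
        "schema": scene.ground_truth.schema,
        "event_counts": scene.event_counts(),
    }
    (directory / "scene.yaml").write_text(yaml.safe_dump(meta))


def read_scene_dir(directory) -> dict:
    """Inverse of :func:`write_scene_dir` (events are summary counts only)."""
    directory = Path(directory)
    cand = read_candidates_json(directory / "candidates.json")
    gt = read_ground_truth_csv(directory / "ground_truth.csv",
                               schema=cand["schema"] or "auto")
    labels = read_labels_csv(directory / "labels.csv")
    meta = yaml.safe_load((directory / "scene.yaml").read_text())
    return {**cand, "ground_truth": gt, "labels": labels, "meta": meta}
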