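"""Pose-estimation metrics: MPJPE, PCK@alpha and average precision,
stratified by skiing situation.

Conventions
-----------
* Ground-truth keypoints marked invisible (the ``-1`` sentinel on disk) are
  excluded from every metric.
* MPJPE averages Euclidean error over pairs where the prediction is present,
  keeping it a pure localisation error; the number of missing predictions is
  reported separately.
* PCK and AP count missing predictions as incorrect, so non-detection is
  penalised in the threshold metrics.
* The PCK distance threshold is a fraction (0.2 by default) of the torso
  diameter, measured per frame between a configurable keypoint pair
  (right shoulder to left hip by default); frames where either endpoint is
  invisible fall back to the sequence-median torso diameter.
* AP is detection-style: per keypoint, predictions at gt-visible frames are
  ranked by confidence, counted as true positives within the PCK-style
  distance threshold, and AP is the mean precision at each true positive
  over the number of gt-visible frames, averaged over keypoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose import CATEGORIES, CategoryLabels, PoseSequence

logger = logging.getLogger(__name__)

DEFAULT_TORSO_PAIR: tuple[str, str] = ("right_shoulder", "left_hip")


class UndefinedMetricError(ValueError):
    """Raised when a metric has no valid (frame, keypoint) pair to average."""


@dataclass(frozen=True)
class ThresholdRule:
    """Distance-threshold rule shared by PCK and AP.

    A prediction is correct when its error is at most ``alpha`` times the
    frame's torso diameter.
    """

    alpha: float = 0.2
    torso_pair: tuple[str | int, str | int] = DEFAULT_TORSO_PAIR

    def describe(self) -> dict:
        return {"kind": "torso_fraction", "alpha": self.alpha,
                "torso_pair": list(self.torso_pair)}


def _check_aligned(pred: PoseSequence, gt: PoseSequence) -> None:
    if pred.n_frames != gt.n_frames:
        raise ValueError(
            f"frame count mismatch: pred {pred.n_frames} vs gt {gt.n_frames}"
        )
    if pred.n_keypoints != gt.n_keypoints:
        raise ValueError(
            f"keypoint count mismatch: pred {pred.n_keypoints} vs gt {gt.n_keypoints}"
        )


def _keypoint_mask(gt: PoseSequence, mask) -> np.ndarray:
    keep = np.zeros(gt.n_keypoints, dtype=bool)
    if mask is None:
        keep[:] = True
    else:
        for m in mask:
            keep[gt.keypoint_index(m)] = True
    return keep


def _errors(pred: PoseSequence, gt: PoseSequence) -> np.ndarray:
    return np.linalg.norm(pred.xy - gt.xy, axis=2)


def mpjpe(pred: PoseSequence, gt: PoseSequence, mask=None) -> float:
    """Mean per joint position error in pixels.

    Averaged over (frame, keypoint) pairs where gt is visible and the
    prediction is present; pairs with a missing prediction are excluded.
    """
    _check_aligned(pred, gt)
    keep = _keypoint_mask(gt, mask)
    valid = gt.visible & pred.visible & keep[None, :]
    if not valid.any():
        raise UndefinedMetricError("MPJPE: no valid (frame, keypoint) pairs")
    return float(np.mean(_errors(pred, gt)[valid]))


def torso_diameters(gt: PoseSequence,
                    torso_pair: tuple[str | int, str | int] = DEFAULT_TORSO_PAIR
                    ) -> np.ndarray:
    """Per-frame torso diameter with sequence-median fallback.

    Frames where either endpoint is invisible get the median diameter of
    the frames where both are visible.
    """
    a = gt.keypoint_index(torso_pair[0])
    b = gt.keypoint_index(torso_pair[1])
    diam = np.linalg.norm(gt.xy[:, a] - gt.xy[:, b], axis=1)
    ok = gt.visible[:, a] & gt.visible[:, b]
    if not ok.any():
        raise UndefinedMetricError(
            "torso diameter undefined: endpoints never jointly visible"
        )
    out = np.where(ok, diam, np.median(diam[ok]))
    return out


def pck(pred: PoseSequence, gt: PoseSequence, alpha: float = 0.2,
        torso_pair: tuple[str | int, str | int] = DEFAULT_TORSO_PAIR,
        mask=None) -> float:
    """Fraction of gt-visible keypoints within ``alpha`` torso diameters.

    Missing predictions count as incorrect.
    """
    _check_aligned(pred, gt)
    keep = _keypoint_mask(gt, mask)
    gt_valid = gt.visible & keep[None, :]
    if not gt_valid.any():
        raise UndefinedMetricError("PCK: no gt-visible keypoints")
    thr = alpha * torso_diameters(gt, torso_pair)
    err = _errors(pred, gt)
    correct = gt_valid & pred.visible & (err <= thr[:, None])
    return float(correct.sum() / gt_valid.sum())


def average_precision(pred: PoseSequence, gt: PoseSequence,
                      rule: ThresholdRule = ThresholdRule(),
                      mask=None) -> float:
    """Confidence-ranked detection AP averaged over keypoints.

    Per keypoint: every gt-visible frame is one positive; predictions
    present at those frames are ranked by confidence (descending, frame
    order on ties) and are true positives within the distance threshold.
    AP is the mean precision at each true positive, divided by the number
    of positives; keypoints without gt-visible frames are skipped.
    Predictions without a stored confidence count as fully confident.
    """
    _check_aligned(pred, gt)
    keep = _keypoint_mask(gt, mask)
    thr = rule.alpha * torso_diameters(gt, rule.torso_pair)
    err = _errors(pred, gt)
    if pred.confidence is None:
        conf = np.ones((pred.n_frames, pred.n_keypoints))
    else:
        conf = np.where(np.isnan(pred.confidence), 1.0, pred.confidence)

    if not (gt.visible & keep[None, :]).any():
        raise UndefinedMetricError("AP: no gt-visible keypoints")

    aps = []
    any_pred = False
    for k in range(gt.n_keypoints):
        if not keep[k]:
            continue
        pos_frames = np.nonzero(gt.visible[:, k])[0]
        if pos_frames.size == 0:
            continue
        det_frames = pos_frames[pred.visible[pos_frames, k]]
        if det_frames.size == 0:
            aps.append(0.0)
            continue
        any_pred = True
        order = det_frames[np.lexsort((det_frames, -conf[det_frames, k]))]
        is_tp = err[order, k] <= thr[order]
        tp_cum = np.cumsum(is_tp)
        ranks = np.arange(1, order.size + 1)
        precision_at_tp = (tp_cum / ranks)[is_tp]
        aps.append(float(precision_at_tp.sum() / pos_frames.size))
    if not any_pred:
        logger.warning("AP: no confident predictions at gt-visible frames")
    return float(np.mean(aps))


@dataclass
class MetricConfig:
    """Evaluation configuration mirroring the report's columns."""

    pck_alpha: float = 0.2
    torso_pair: tuple[str | int, str | int] = DEFAULT_TORSO_PAIR

    @property
    def rule(self) -> ThresholdRule:
        return ThresholdRule(self.pck_alpha, tuple(self.torso_pair))


@dataclass
class EvalReport:
    """MPJPE / PCK / AP overall and per situation category.

    ``cells`` maps ``all`` plus each category name to a dict of metric
    values and counts, or to ``None`` for categories with no frames.
    """

    cells: dict[str, dict | None]
    rule: dict = field(default_factory=dict)

    COLUMNS = ("all",) + CATEGORIES

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for metric in ("mpjpe", "pck", "ap", "n_frames", "n_valid_keypoints",
                       "n_missing_pred"):
            rows[metric] = {
                col: (self.cells[col] or {}).get(metric) for col in self.COLUMNS
                if col in self.cells
            }
        return pd.DataFrame(rows).T[list(self.COLUMNS)]

    def to_json(self) -> str:
        return json.dumps({"rule": self.rule, "cells": self.cells}, indent=2)

    def write(self, prefix: str) -> None:
        self.to_frame().to_csv(f"{prefix}.csv")
        with open(f"{prefix}.json", "w") as fh:
            fh.write(self.to_json())


def _cell(pred: PoseSequence, gt: PoseSequence, config: MetricConfig) -> dict:
    gt_valid = int(gt.visible.sum())
    missing = int((gt.visible & ~pred.visible).sum())
    out = {
        "n_frames": gt.n_frames,
        "n_valid_keypoints": gt_valid,
        "n_missing_pred": missing,
    }
    try:
        out["mpjpe"] = mpjpe(pred, gt)
    except UndefinedMetricError:
        out["mpjpe"] = None
    try:
        out["pck"] = pck(pred, gt, config.pck_alpha, config.torso_pair)
        out["ap"] = average_precision(pred, gt, config.rule)
    except UndefinedMetricError:
        out["pck"] = None
        out["ap"] = None
    return out


def evaluate(pred: PoseSequence, gt: PoseSequence, labels: CategoryLabels,
             config: MetricConfig | None = None) -> EvalReport:
    """All three metrics, overall and per category.

    Categories with zero frames are reported as absent (``None``), not as
    zero.  Deterministic and serialisable to CSV/JSON.
    """
    _check_aligned(pred, gt)
    if len(labels) != gt.n_frames:
        raise ValueError(
            f"label count {len(labels)} != frame count {gt.n_frames}"
        )
    config = config or MetricConfig()
    cells: dict[str, dict | None] = {"all": _cell(pred, gt, config)}
    for cat in CATEGORIES:
        frames = labels.frames_for(cat)
        if frames.size == 0:
            cells[cat] = None
            continue
        cells[cat] = _cell(pred.subset(frames), gt.subset(frames), config)
    return EvalReport(cells=cells, rule=config.rule.describe())
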