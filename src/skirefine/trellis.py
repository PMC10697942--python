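"""Trellis construction and shortest-path keypoint selection.

Running a detector on 36 rotated copies of a video yields, per keypoint and
frame, up to 36 candidate locations with confidences.  Selecting one
candidate per frame is posed as a shortest-path problem on a layered graph
(one layer per frame, one node per candidate, virtual source and sink).
The edge cost linking candidate ``p_i`` in frame ``n`` to candidate ``p_j``
in frame ``n+1`` combines three terms::

    C = c * C_C + d * C_D + r * C_R

    C_C = 1 / conf_j            (penalise low-confidence destinations)
    C_D = ||xy_i - xy_j||_2     (penalise jumps; trajectories are smooth)
    C_R = |sin(Δr / 2)|         (penalise fast rotation-angle changes,
                                 Δr the angular difference in radians)

The minimum-cost source→sink path, found with Dijkstra's algorithm, picks
exactly one candidate per frame that has any; keypoints are optimised
independently of each other.  Default coefficients are c=0.01, d=1, r=0.01.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pose import PoseSequence

logger = logging.getLogger(__name__)

#: Default exponential grid for coefficient tuning.
EXPONENTIAL_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)

FLAG_SELECTED = "selected"
FLAG_BRIDGED = "bridged"
FLAG_MISSING = "missing"


class NoSolutionError(RuntimeError):
    """Raised when a trellis admits no source→sink path."""


@dataclass(frozen=True, slots=True)
class KeypointCandidate:
    """One detector hypothesis for one keypoint in one frame.

    ``rotation`` is the source rotation angle in degrees, ``rotation_index``
    its 1-based position in the schedule when known.
    """

    x: float
    y: float
    confidence: float
    rotation: float
    frame: int
    keypoint_id: int = 0
    rotation_index: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if not 0.0 <= self.rotation < 360.0:
            raise ValueError(f"rotation must be in [0, 360), got {self.rotation}")
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class CostParams:
    """Coefficients of the three-term edge cost.

    ``confidence_floor`` bounds the confidence away from zero so the
    confidence term stays finite while preserving candidate ordering.
    """

    c: float = 0.01
    d: float = 1.0
    r: float = 0.01
    confidence_floor: float = 1e-6

    def __post_init__(self):
        if min(self.c, self.d, self.r) < 0:
            raise ValueError("cost coefficients must be non-negative")
        if max(self.c, self.d, self.r) <= 0:
            raise ValueError("at least one of c, d, r must be strictly positive")
        if self.confidence_floor <= 0:
            raise ValueError("confidence_floor must be > 0")


class CandidateTrellis:
    """Per-frame candidate lists for a single keypoint.

    Zero-candidate frames are permitted and recorded; the graph builder
    bridges across them.  Internally stores per-frame coordinate /
    confidence / rotation arrays for vectorised cost evaluation.
    """

    __slots__ = ("keypoint_id", "n_frames", "_x", "_y", "_conf", "_rot", "_cache")

    def __init__(self, keypoint_id: int = 0, n_frames: int = 0):
        if n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        self.keypoint_id = keypoint_id
        self.n_frames = n_frames
        self._x = [[] for _ in range(n_frames)]
        self._y = [[] for _ in range(n_frames)]
        self._conf = [[] for _ in range(n_frames)]
        self._rot = [[] for _ in range(n_frames)]
        self._cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_candidates(
        cls,
        candidates: Iterable[KeypointCandidate],
        n_frames: int | None = None,
        keypoint_id: int | None = None,
    ) -> "CandidateTrellis":
        candidates = list(candidates)
        if keypoint_id is None:
            keypoint_id = candidates[0].keypoint_id if candidates else 0
        if n_frames is None:
            n_frames = 1 + max((c.frame for c in candidates), default=-1)
        tr = cls(keypoint_id, n_frames)
        for c in candidates:
            tr.add(c)
        return tr

    def add(self, cand: KeypointCandidate) -> None:
        if not 0 <= cand.frame < self.n_frames:
            raise ValueError(f"frame {cand.frame} outside [0, {self.n_frames})")
        if cand.keypoint_id != self.keypoint_id:
            raise ValueError(
                f"candidate keypoint {cand.keypoint_id} != trellis {self.keypoint_id}"
            )
        self._x[cand.frame].append(cand.x)
        self._y[cand.frame].append(cand.y)
        self._conf[cand.frame].append(cand.confidence)
        self._rot[cand.frame].append(cand.rotation)
        self._cache.pop(cand.frame, None)

    def extend_frame(self, frame: int, xy: np.ndarray, conf: np.ndarray,
                     rot: np.ndarray) -> None:
        """Bulk-append candidates for one frame (simulator fast path)."""
        if not 0 <= frame < self.n_frames:
            raise ValueError(f"frame {frame} outside [0, {self.n_frames})")
        self._x[frame].extend(np.asarray(xy)[:, 0].tolist())
        self._y[frame].extend(np.asarray(xy)[:, 1].tolist())
        self._conf[frame].extend(np.asarray(conf, dtype=float).tolist())
        self._rot[frame].extend(np.asarray(rot, dtype=float).tolist())
        self._cache.pop(frame, None)

    def n_candidates(self, frame: int | None = None) -> int:
        if frame is None:
            return sum(len(f) for f in self._x)
        return len(self._x[frame])

    def frame_arrays(self, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(xy (m,2), confidence (m,), rotation (m,)) for one frame."""
        got = self._cache.get(frame)
        if got is None:
            xy = np.column_stack([self._x[frame], self._y[frame]]) if self._x[frame] \
                else np.empty((0, 2))
            got = (xy, np.asarray(self._conf[frame], dtype=float),
                   np.asarray(self._rot[frame], dtype=float))
            self._cache[frame] = got
        return got

    def candidates(self, frame: int) -> tuple[KeypointCandidate, ...]:
        return tuple(
            KeypointCandidate(x=self._x[frame][i], y=self._y[frame][i],
                              confidence=self._conf[frame][i],
                              rotation=self._rot[frame][i],
                              frame=frame, keypoint_id=self.keypoint_id)
            for i in range(len(self._x[frame]))
        )

    def candidate(self, frame: int, idx: int) -> KeypointCandidate:
        return KeypointCandidate(
            x=self._x[frame][idx], y=self._y[frame][idx],
            confidence=self._conf[frame][idx], rotation=self._rot[frame][idx],
            frame=frame, keypoint_id=self.keypoint_id,
        )

    def non_empty_frames(self) -> list[int]:
        return [f for f in range(self.n_frames) if self._x[f]]

    def translated(self, dx: float, dy: float) -> "CandidateTrellis":
        out = CandidateTrellis(self.keypoint_id, self.n_frames)
        for f in range(self.n_frames):
            out._x[f] = [x + dx for x in self._x[f]]
            out._y[f] = [y + dy for y in self._y[f]]
            out._conf[f] = list(self._conf[f])
            out._rot[f] = list(self._rot[f])
        return out


def rotation_cost(delta_deg: float | np.ndarray):
    """|sin(Δr/2)| with the degree difference taken to radians; 360°-periodic,
    zero at Δr=0 and maximal (=1) at the 180° flip."""
    return np.abs(np.sin(np.radians(delta_deg) / 2.0))


def edge_cost(p_i: KeypointCandidate, p_j: KeypointCandidate,
              params: CostParams) -> float:
    """Three-term cost of the edge from ``p_i`` (frame n) to ``p_j`` (frame n+1).

    Symmetric in position but not in confidence: the confidence term uses the
    destination candidate's confidence.
    """
    if p_j.frame != p_i.frame + 1:
        raise ValueError(
            f"edge_cost requires consecutive frames, got {p_i.frame} -> {p_j.frame}"
        )
    if p_i.keypoint_id != p_j.keypoint_id:
        raise ValueError("edge_cost requires candidates of the same keypoint")
    c_c = 1.0 / max(p_j.confidence, params.confidence_floor)
    c_d = math.hypot(p_i.x - p_j.x, p_i.y - p_j.y)
    c_r = float(rotation_cost(p_i.rotation - p_j.rotation))
    return params.c * c_c + params.d * c_d + params.r * c_r


def edge_cost_matrix(xy_a, rot_a, xy_b, conf_b, rot_b,
                     params: CostParams) -> np.ndarray:
    """Vectorised edge costs between two candidate layers, shape (m_a, m_b)."""
    diff = np.asarray(xy_a)[:, None, :] - np.asarray(xy_b)[None, :, :]
    c_d = np.sqrt(np.sum(diff * diff, axis=-1))
    c_c = 1.0 / np.maximum(np.asarray(conf_b, dtype=float), params.confidence_floor)
    c_r = rotation_cost(np.asarray(rot_a)[:, None] - np.asarray(rot_b)[None, :])
    return params.c * c_c[None, :] + params.d * c_d + params.r * c_r


@dataclass
class TrellisGraph:
    """Layered graph over a candidate trellis with virtual source and sink.

    ``layers`` lists the non-empty frame indices in order; ``costs[l]`` is
    the (m_l, m_{l+1}) edge-cost matrix between consecutive layers (empty
    frames are bridged: flanking layers are linked directly with the same
    cost form).  ``source_cost[j]`` charges the first layer's own confidence
    term so every selected node's confidence is counted exactly once along
    any path; sink edges cost zero.
    """

    trellis: CandidateTrellis
    params: CostParams
    layers: list[int]
    costs: list[np.ndarray]
    source_cost: np.ndarray

    def layer_size(self, layer: int) -> int:
        return self.trellis.n_candidates(self.layers[layer])

    @property
    def n_nodes(self) -> int:
        return 2 + sum(self.layer_size(l) for l in range(len(self.layers)))

    @property
    def n_edges(self) -> int:
        inter = sum(c.size for c in self.costs)
        return self.layer_size(0) + inter + self.layer_size(len(self.layers) - 1)

    def to_networkx(self):
        """The same graph as a networkx DiGraph (tests, interop)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("source")
        g.add_node("sink")
        for j, w in enumerate(self.source_cost):
            g.add_edge("source", (self.layers[0], j), weight=float(w))
        for l, cost in enumerate(self.costs):
            fa, fb = self.layers[l], self.layers[l + 1]
            for i in range(cost.shape[0]):
                for j in range(cost.shape[1]):
                    g.add_edge((fa, i), (fb, j), weight=float(cost[i, j]))
        last = self.layers[-1]
        for i in range(self.layer_size(len(self.layers) - 1)):
            g.add_edge((last, i), "sink", weight=0.0)
        return g


def build_graph(trellis: CandidateTrellis, params: CostParams) -> TrellisGraph:
    """Assemble the layered candidate graph with three-term edge costs.

    Consecutive non-empty frames are linked completely (bipartite); empty
    frames are skipped, with the two flanking layers connected directly and
    the distance/rotation terms measured between the flanking candidates.
    """
    layers = trellis.non_empty_frames()
    if not layers:
        raise NoSolutionError(
            f"keypoint {trellis.keypoint_id}: no candidates in any frame"
        )
    _, conf0, _ = trellis.frame_arrays(layers[0])
    source_cost = params.c / np.maximum(conf0, params.confidence_floor)
    costs = []
    for fa, fb in zip(layers[:-1], layers[1:]):
        xy_a, _, rot_a = trellis.frame_arrays(fa)
        xy_b, conf_b, rot_b = trellis.frame_arrays(fb)
        costs.append(edge_cost_matrix(xy_a, rot_a, xy_b, conf_b, rot_b, params))
    return TrellisGraph(trellis, params, layers, costs, source_cost)


@dataclass
class RefinedTrack:
    """Per-frame selected candidates for one keypoint.

    ``flags[f]`` is ``selected`` where a candidate was chosen, ``bridged``
    for empty frames inside the covered span, and ``missing`` outside it
    (or everywhere if no path exists).  ``total_cost`` is the summed cost
    of the traversed edges (NaN for selectors without a path cost).
    """

    keypoint_id: int
    n_frames: int
    candidates: list[KeypointCandidate | None]
    flags: list[str]
    total_cost: float

    def selected_frames(self) -> list[int]:
        return [f for f, fl in enumerate(self.flags) if fl == FLAG_SELECTED]


def _empty_track(keypoint_id: int, n_frames: int) -> RefinedTrack:
    return RefinedTrack(keypoint_id, n_frames, [None] * n_frames,
                        [FLAG_MISSING] * n_frames, math.nan)


def shortest_path(graph: TrellisGraph) -> RefinedTrack:
    """Minimum-total-cost source→sink path via Dijkstra's algorithm.

    Uses a binary heap with lazy deletion; ties are broken deterministically
    by (cost, layer, candidate insertion order).  Valid because all edge
    costs are non-negative by construction.
    """
    layers = graph.layers
    n_layers = len(layers)
    dist = [np.full(graph.layer_size(l), np.inf) for l in range(n_layers)]
    pred = [np.full(graph.layer_size(l), -1, dtype=int) for l in range(n_layers)]

    heap: list[tuple[float, int, int]] = []
    dist[0][:] = graph.source_cost
    for j in range(dist[0].size):
        heapq.heappush(heap, (dist[0][j], 0, j))

    end: tuple[float, int] | None = None
    while heap:
        d, l, i = heapq.heappop(heap)
        if d != dist[l][i]:
            continue  # stale entry
        if l == n_layers - 1:
            end = (d, i)  # sink edges cost 0: first final-layer pop is optimal
            break
        nd = d + graph.costs[l][i]
        better = np.nonzero(nd < dist[l + 1])[0]
        for j in better:
            dist[l + 1][j] = nd[j]
            pred[l + 1][j] = i
            heapq.heappush(heap, (nd[j], l + 1, j))

    if end is None:
        raise NoSolutionError(
            f"keypoint {graph.trellis.keypoint_id}: sink unreachable"
        )

    total_cost, i = end
    chosen = np.empty(n_layers, dtype=int)
    for l in range(n_layers - 1, -1, -1):
        chosen[l] = i
        i = pred[l][i]

    tr = graph.trellis
    track = _empty_track(tr.keypoint_id, tr.n_frames)
    track.total_cost = float(total_cost)
    first, last = layers[0], layers[-1]
    for f in range(first, last + 1):
        if track.flags[f] == FLAG_MISSING:
            track.flags[f] = FLAG_BRIDGED
    for l, f in enumerate(layers):
        track.candidates[f] = tr.candidate(f, int(chosen[l]))
        track.flags[f] = FLAG_SELECTED
    return track


def tracks_to_pose(
    tracks: Mapping[int, RefinedTrack],
    n_frames: int,
    schema: str | None = None,
    n_keypoints: int | None = None,
) -> PoseSequence:
    """Compose per-keypoint tracks into a pose sequence.

    Keypoint ids index pose columns; frames without a selected candidate
    are marked invisible, never interpolated.
    """
    from .pose import schema_names, SCHEMAS

    if n_keypoints is None:
        if schema is not None:
            n_keypoints = len(SCHEMAS[schema])
        else:
            n_keypoints = 1 + max(tracks.keys(), default=-1)
    xy = np.full((n_frames, n_keypoints, 2), np.nan)
    visible = np.zeros((n_frames, n_keypoints), dtype=bool)
    conf = np.full((n_frames, n_keypoints), np.nan)
    for k, track in tracks.items():
        for f, cand in enumerate(track.candidates):
            if cand is not None:
                xy[f, k] = (cand.x, cand.y)
                conf[f, k] = cand.confidence
                visible[f, k] = True
    return PoseSequence(xy, visible, conf, schema)


def refine_sequence(
    trellises: Mapping[int, CandidateTrellis] | Sequence[CandidateTrellis],
    params: CostParams = CostParams(),
    schema: str | None = None,
    return_tracks: bool = False,
):
    """Refine all keypoints of a sequence independently.

    Each keypoint's trellis is solved with its own shortest path (keypoints
    carry no inter-keypoint constraint).  A keypoint whose trellis has no
    candidates at all is downgraded to all-missing with a logged warning.

    Returns the refined :class:`PoseSequence`, or ``(pose, tracks)`` when
    ``return_tracks`` is true.
    """
    if not isinstance(trellises, Mapping):
        trellises = {t.keypoint_id: t for t in trellises}
    if not trellises:
        raise ValueError("no trellises supplied")
    n_frames = {t.n_frames for t in trellises.values()}
    if len(n_frames) != 1:
        raise ValueError(f"trellises disagree on n_frames: {sorted(n_frames)}")
    n_frames = n_frames.pop()

    tracks: dict[int, RefinedTrack] = {}
    for k in sorted(trellises):
        try:
            tracks[k] = shortest_path(build_graph(trellises[k], params))
        except NoSolutionError as exc:
            logger.warning("keypoint %d: %s; marked all-missing", k, exc)
            tracks[k] = _empty_track(k, n_frames)
    pose = tracks_to_pose(tracks, n_frames, schema=schema)
    if return_tracks:
        return pose, tracks
    return pose


def grid_search(
    scenes: Sequence[tuple[Mapping[int, CandidateTrellis], PoseSequence]],
    grid: Mapping[str, Iterable[float]] | None = None,
    objective: Callable[[PoseSequence, PoseSequence], float] | None = None,
) -> tuple[CostParams, pd.DataFrame]:
    """Exhaustive (exponential) grid search of the cost coefficients.

    Evaluates every (c, d, r) combination on labelled validation scenes and
    returns the argmin of the objective (mean MPJPE over scenes by default)
    together with the full results table.  Deterministic: ties go to the
    first combination in grid order.
    """
    from .metrics import mpjpe

    if not scenes:
        raise ValueError("grid_search needs at least one validation scene")
    grid = dict(grid or {})
    cs = list(grid.get("c", EXPONENTIAL_GRID))
    ds = list(grid.get("d", EXPONENTIAL_GRID))
    rs = list(grid.get("r", EXPONENTIAL_GRID))
    if not (cs and ds and rs):
        raise ValueError("grid values must be non-empty for each coefficient")
    objective = objective or mpjpe

    rows = []
    for c, d, r in itertools.product(cs, ds, rs):
        params = CostParams(c=c, d=d, r=r)
        scores = []
        for trellises, gt in scenes:
            pred = refine_sequence(trellises, params, schema=gt.schema)
            scores.append(objective(pred, gt))
        rows.append({"c": c, "d": d, "r": r, "objective": float(np.mean(scores))})
    results = pd.DataFrame(rows)
    best = results.iloc[int(np.argmin(results["objective"].to_numpy()))]
    logger.info("grid search best: c=%g d=%g r=%g objective=%g",
                best["c"], best["d"], best["r"], best["objective"])
    return CostParams(c=best["c"], d=best["d"], r=best["r"]), results
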