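"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest

from skirefine.trellis import CandidateTrellis, KeypointCandidate

ANGLES = tuple(float(a) for a in range(0, 360, 10))


def make_random_trellis(rng, max_frames=6, max_cands=5, allow_empty=True,
                        keypoint_id=0):
    """A small random trellis; guaranteed at least one non-empty frame."""
    n_frames = int(rng.integers(1, max_frames + 1))
    while True:
        counts = rng.integers(0 if allow_empty else 1, max_cands + 1,
                              size=n_frames)
        if counts.sum() > 0:
            break
    tr = CandidateTrellis(keypoint_id=keypoint_id, n_frames=n_frames)
    for f in range(n_frames):
        for _ in range(counts[f]):
            tr.add(KeypointCandidate(
                x=float(rng.uniform(0, 100)),
                y=float(rng.uniform(0, 100)),
                confidence=float(rng.uniform(0.05, 1.0)),
                rotation=float(rng.choice(ANGLES)),
                frame=f,
                keypoint_id=keypoint_id,
            ))
    return tr


def path_cost_by_hand(trellis, params, layers, combo):
    """Total cost of one explicit path, recomputed term by term from the
    cost definition (independent of the graph builder)."""
    _, conf0, _ = trellis.frame_arrays(layers[0])
    cost = params.c / max(conf0[combo[0]], params.confidence_floor)
    for (fa, ia), (fb, ib) in zip(zip(layers, combo), zip(layers[1:], combo[1:])):
        xy_a, _, rot_a = trellis.frame_arrays(fa)
        xy_b, conf_b, rot_b = trellis.frame_arrays(fb)
        cost += params.c / max(conf_b[ib], params.confidence_floor)
        cost += params.d * math.hypot(xy_a[ia, 0] - xy_b[ib, 0],
                                      xy_a[ia, 1] - xy_b[ib, 1])
        cost += params.r * abs(math.sin(math.radians(rot_a[ia] - rot_b[ib]) / 2))
    return cost


def exhaustive_best_path(trellis, params):
    """Brute-force optimum over every source→sink path (oracle)."""
    layers = trellis.non_empty_frames()
    best_cost, best_combo = math.inf, None
    for combo in itertools.product(
            *[range(trellis.n_candidates(f)) for f in layers]):
        cost = path_cost_by_hand(trellis, params, layers, combo)
        if cost < best_cost:
            best_cost, best_combo = cost, combo
    return best_cost, dict(zip(layers, best_combo))


def min_distance_polyline_dp(trellis):
    """Independent dynamic program: per-frame selection minimising the summed
    Euclidean polyline length through the non-empty layers."""
    layers = trellis.non_empty_frames()
    xy = [trellis.frame_arrays(f)[0] for f in layers]
    dist = np.zeros(xy[0].shape[0])
    back = []
    for a, b in zip(xy, xy[1:]):
        step = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        total = dist[:, None] + step
        back.append(np.argmin(total, axis=0))
        dist = np.min(total, axis=0)
    combo = [int(np.argmin(dist))]
    for bk in reversed(back):
        combo.append(int(bk[combo[-1]]))
    combo.reverse()
    return float(np.min(dist)), dict(zip(layers, combo))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def fall_scene_small():
    """One moderate fall-regime scene reused by several tests."""
    from skirefine.synthetic import make_scene

    return make_scene("fall", seed=11, n_frames=40)
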