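"""Edge cost, graph construction and shortest-path selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skirefine.metrics import mpjpe
from skirefine.pose import PoseSequence
from skirefine.trellis import (
    CandidateTrellis,
    CostParams,
    KeypointCandidate,
    NoSolutionError,
    build_graph,
    edge_cost,
    edge_cost_matrix,
    refine_sequence,
    rotation_cost,
    shortest_path,
    tracks_to_pose,
)

from conftest import exhaustive_best_path, make_random_trellis

P = CostParams()  # shipped defaults


def cand(x, y, conf, rot, frame, k=0):
    return KeypointCandidate(x=x, y=y, confidence=conf, rotation=rot,
                             frame=frame, keypoint_id=k)


def chain_trellis(points, confs=None, rots=None):
    """One candidate per frame from a list of (x, y)."""
    tr = CandidateTrellis(0, len(points))
    for f, (x, y) in enumerate(points):
        tr.add(cand(x, y, 1.0 if confs is None else confs[f],
                    0.0 if rots is None else rots[f], f))
    return tr


class TestEdgeCost:
    def test_coincident_full_confidence_same_rotation_costs_exactly_c(self):
        a = cand(5, 5, 0.7, 40, 0)
        b = cand(5, 5, 1.0, 40, 1)
        assert edge_cost(a, b, P) == pytest.approx(0.01, abs=1e-15)

    def test_hand_evaluated_three_term_example(self):
        # c·(1/0.5) + d·hypot(3,4) + r·|sin(90°)| = 0.02 + 5 + 0.01
        a = cand(0, 0, 0.9, 0, 0)
        b = cand(3, 4, 0.5, 180, 1)
        assert edge_cost(a, b, P) == pytest.approx(5.03, abs=1e-12)

    def test_confidence_term_uses_destination_not_source(self):
        lo_hi = edge_cost(cand(0, 0, 0.1, 0, 0), cand(0, 0, 1.0, 0, 1), P)
        hi_lo = edge_cost(cand(0, 0, 1.0, 0, 0), cand(0, 0, 0.1, 0, 1), P)
        assert lo_hi == pytest.approx(0.01)
        assert hi_lo == pytest.approx(0.1)

    def test_rotation_term_extremes_and_periodicity(self):
        assert rotation_cost(0) == 0
        assert rotation_cost(180) == pytest.approx(1.0)
        assert rotation_cost(360) == pytest.approx(0.0, abs=1e-12)
        assert rotation_cost(-90) == rotation_cost(90)

    @settings(max_examples=60, derandomize=True)
    @given(d=st.floats(-720, 720))
    def test_rotation_term_symmetric_periodic_bounded(self, d):
        c = rotation_cost(d)
        assert 0 <= c <= 1
        assert c == pytest.approx(rotation_cost(-d), abs=1e-9)
        assert c == pytest.approx(rotation_cost(d + 360), abs=1e-9)

    def test_zero_confidence_is_floored_not_divided_by_zero(self):
        b = cand(0, 0, 0.0, 0, 1)
        cost = edge_cost(cand(0, 0, 1.0, 0, 0), b, P)
        assert math.isfinite(cost)
        assert cost == pytest.approx(P.c / P.confidence_floor)

    def test_non_consecutive_frames_rejected(self):
        with pytest.raises(ValueError):
            edge_cost(cand(0, 0, 1, 0, 0), cand(0, 0, 1, 0, 2), P)

    def test_mismatched_keypoints_rejected(self):
        with pytest.raises(ValueError):
            edge_cost(cand(0, 0, 1, 0, 0), cand(0, 0, 1, 0, 1, k=3), P)

    def test_negative_or_all_zero_params_rejected(self):
        with pytest.raises(ValueError):
            CostParams(c=-0.1)
        with pytest.raises(ValueError):
            CostParams(c=0, d=0, r=0)

    def test_matrix_form_matches_scalar_form(self, rng):
        tr = make_random_trellis(rng, max_frames=2, allow_empty=False)
        while tr.n_frames < 2:
            tr = make_random_trellis(rng, max_frames=2, allow_empty=False)
        xy_a, _, rot_a = tr.frame_arrays(0)
        xy_b, conf_b, rot_b = tr.frame_arrays(1)
        mat = edge_cost_matrix(xy_a, rot_a, xy_b, conf_b, rot_b, P)
        for i, pi in enumerate(tr.candidates(0)):
            for j, pj in enumerate(tr.candidates(1)):
                assert mat[i, j] == pytest.approx(edge_cost(pi, pj, P), rel=1e-12)


class TestBuildGraph:
    def test_node_and_edge_counts_for_full_trellis(self):
        F, M = 4, 3
        tr = CandidateTrellis(0, F)
        for f in range(F):
            for m in range(M):
                tr.add(cand(m, m, 0.5, 0, f))
        g = build_graph(tr, P)
        assert g.n_nodes == 2 + F * M
        assert g.n_edges == M + (F - 1) * M ** 2 + M

    def test_single_chain_total_cost_is_sum_of_edges(self):
        tr = chain_trellis([(0, 0), (3, 4), (6, 8)], confs=[0.5, 0.8, 1.0])
        track = shortest_path(build_graph(tr, P))
        expected = P.c / 0.5  # source edge charges first candidate
        expected += edge_cost(tr.candidate(0, 0), tr.candidate(1, 0), P)
        expected += edge_cost(tr.candidate(1, 0), tr.candidate(2, 0), P)
        assert track.total_cost == pytest.approx(expected, abs=1e-9)

    def test_empty_middle_frame_bridges_flanking_layers(self):
        tr = CandidateTrellis(0, 3)
        tr.add(cand(0, 0, 1.0, 0, 0))
        tr.add(cand(10, 0, 1.0, 0, 2))
        g = build_graph(tr, P)
        assert g.layers == [0, 2]
        track = shortest_path(g)
        assert track.flags == ["selected", "bridged", "selected"]
        # bridged edge uses the same three-term cost between flanking candidates
        assert track.total_cost == pytest.approx(P.c + (P.c + P.d * 10), abs=1e-12)

    def test_all_frames_empty_is_no_solution(self):
        with pytest.raises(NoSolutionError):
            build_graph(CandidateTrellis(0, 4), P)

    def test_networkx_export_agrees_with_internal_solver(self, rng):
        import networkx as nx

        for _ in range(5):
            tr = make_random_trellis(rng)
            g = build_graph(tr, P)
            track = shortest_path(g)
            nx_len = nx.dijkstra_path_length(g.to_networkx(), "source", "sink")
            assert track.total_cost == pytest.approx(nx_len, abs=1e-9)


class TestShortestPath:
    def test_matches_exhaustive_enumeration_on_random_trellises(self, rng):
        for _ in range(30):
            tr = make_random_trellis(rng)
            track = shortest_path(build_graph(tr, P))
            best_cost, best_combo = exhaustive_best_path(tr, P)
            assert track.total_cost == pytest.approx(best_cost, abs=1e-9)
            for f, idx in best_combo.items():
                assert track.candidates[f] == tr.candidate(f, idx)

    def test_forced_single_candidate_path(self):
        tr = chain_trellis([(0, 0), (50, 0), (0, 50)])
        track = shortest_path(build_graph(tr, P))
        assert track.flags == ["selected"] * 3
        assert [c.x for c in track.candidates] == [0, 50, 0]

    def test_confidence_only_cost_selects_per_frame_argmax(self, rng):
        params = CostParams(c=1.0, d=0.0, r=0.0)
        for _ in range(10):
            tr = make_random_trellis(rng, allow_empty=False)
            track = shortest_path(build_graph(tr, params))
            for f in range(tr.n_frames):
                _, conf, _ = tr.frame_arrays(f)
                assert track.candidates[f].confidence == conf.max()

    def test_monotonicity_raising_one_edge_never_lowers_optimum(self, rng):
        for _ in range(10):
            tr = make_random_trellis(rng, allow_empty=False)
            g = build_graph(tr, P)
            base = shortest_path(g).total_cost
            if not g.costs:
                continue
            l = int(rng.integers(len(g.costs)))
            i = int(rng.integers(g.costs[l].shape[0]))
            j = int(rng.integers(g.costs[l].shape[1]))
            g.costs[l][i, j] += float(rng.uniform(0.1, 5.0))
            assert shortest_path(g).total_cost >= base - 1e-12

    def test_total_cost_invariant_under_translation(self, rng):
        tr = make_random_trellis(rng, allow_empty=False)
        t1 = shortest_path(build_graph(tr, P))
        t2 = shortest_path(build_graph(tr.translated(57.3, -12.9), P))
        assert t2.total_cost == pytest.approx(t1.total_cost, abs=1e-9)
        assert t1.selected_frames() == t2.selected_frames()

    def test_distance_term_scales_linearly_with_coordinates(self, rng):
        params = CostParams(c=0.0, d=1.0, r=0.0)
        tr = make_random_trellis(rng, allow_empty=False)
        scaled = CandidateTrellis(0, tr.n_frames)
        for f in range(tr.n_frames):
            for c in tr.candidates(f):
                scaled.add(KeypointCandidate(
                    x=3.0 * c.x, y=3.0 * c.y, confidence=c.confidence,
                    rotation=c.rotation, frame=f))
        base = shortest_path(build_graph(tr, params)).total_cost
        assert shortest_path(build_graph(scaled, params)).total_cost == \
            pytest.approx(3.0 * base, rel=1e-9)


class TestRefineSequence:
    def test_single_keypoint_equals_plain_shortest_path(self, rng):
        tr = make_random_trellis(rng, allow_empty=False)
        pose, tracks = refine_sequence({0: tr}, P, return_tracks=True)
        direct = shortest_path(build_graph(tr, P))
        assert tracks[0].total_cost == pytest.approx(direct.total_cost)
        for f in range(tr.n_frames):
            if direct.candidates[f] is not None:
                assert pose.xy[f, 0, 0] == direct.candidates[f].x

    def test_candidates_equal_to_truth_refine_to_zero_error(self):
        gt_xy = np.cumsum(np.ones((6, 2, 2)), axis=0) * 5
        gt = PoseSequence(gt_xy)
        trellises = {}
        for k in range(2):
            tr = CandidateTrellis(k, 6)
            for f in range(6):
                tr.add(KeypointCandidate(x=gt_xy[f, k, 0], y=gt_xy[f, k, 1],
                                         confidence=1.0, rotation=0.0,
                                         frame=f, keypoint_id=k))
            trellises[k] = tr
        pose = refine_sequence(trellises, P)
        assert mpjpe(pose, gt) == 0.0

    def test_keypoint_without_candidates_downgrades_to_missing(self, caplog):
        trellises = {
            0: chain_trellis([(0, 0), (1, 1)]),
            1: CandidateTrellis(1, 2),
        }
        with caplog.at_level("WARNING"):
            pose = refine_sequence(trellises, P)
        assert not pose.visible[:, 1].any()
        assert pose.visible[:, 0].all()
        assert any("keypoint 1" in r.message for r in caplog.records)

    def test_mismatched_frame_counts_rejected(self):
        with pytest.raises(ValueError):
            refine_sequence({0: chain_trellis([(0, 0)]),
                             1: chain_trellis([(0, 0), (1, 1)])}, P)

    def test_missing_frames_are_never_interpolated(self):
        tr = CandidateTrellis(0, 4)
        tr.add(cand(0, 0, 1.0, 0, 0))
        tr.add(cand(9, 9, 1.0, 0, 3))
        pose = refine_sequence({0: tr}, P)
        assert pose.visible[:, 0].tolist() == [True, False, False, True]
        assert np.isnan(pose.xy[1, 0]).all()

    def test_tracks_to_pose_carries_confidence_and_position(self):
        tr = chain_trellis([(1, 2), (3, 4)], confs=[0.25, 0.75])
        _, tracks = refine_sequence({0: tr}, P, return_tracks=True)
        pose = tracks_to_pose(tracks, 2)
        assert pose.confidence[0, 0] == 0.25
        assert pose.xy[1, 0].tolist() == [3, 4]
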