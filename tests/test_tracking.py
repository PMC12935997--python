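"""Containment-constrained tracker: linking cost, Hungarian oracle, gap
interpolation, global refinement, CLEAR-MOT accounting."""

from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from lftiming import SimConfig, corrupt_detections, simulate_well
from lftiming.simulate import Detection
from lftiming.tracking import (MotaReport, Track, TrackingParams,
                               TrackPoint, compute_mota, estimate_velocity,
                               interpolate_gaps, link_frames, mask_iou,
                               pairwise_cost, refine_objective,
                               refine_tracks, track_well)
from lftiming.simulate import GroundTruthWell


def _track(points):
    return Track(cell_id=0, points=[
        TrackPoint(frame=t, centroid=np.array(p, float), source="detected")
        for t, p in points])


class TestVelocity:
    def test_single_point_zero(self):
        assert np.allclose(estimate_velocity(_track([(0, (0, 0))]), 3), 0)

    def test_two_equal_steps(self):
        tr = _track([(0, (0, 0)), (1, (3, 4)), (2, (6, 8))])
        assert np.allclose(estimate_velocity(tr, 2), (3, 4))

    def test_mean_of_two_unequal_steps(self):
        tr = _track([(0, (0, 0)), (1, (2, 0)), (2, (2, 2))])
        assert np.allclose(estimate_velocity(tr, 2), (1, 1))


class TestPairwiseCost:
    def test_identical_masks_and_position(self):
        p = TrackingParams()
        m = np.zeros((20, 20), bool)
        m[5:10, 5:10] = True
        c = pairwise_cost((7, 7), (7, 7), (0, 0), p, mask_i=m, mask_j=m)
        assert c == pytest.approx(-p.beta_iou)

    def test_distance_and_velocity_terms(self):
        p = TrackingParams(lambda_vel=1.0)
        c = pairwise_cost((0, 0), (3, 4), (0, 0), p)
        assert c == pytest.approx(50.0)     # 25 distance + 25 velocity

    def test_switch_penalty_is_100(self):
        p = TrackingParams()
        base = pairwise_cost((0, 0), (3, 4), (0, 0), p)
        flagged = pairwise_cost((0, 0), (3, 4), (0, 0), p, i_switch=True)
        assert flagged - base == pytest.approx(100.0)


class TestHungarianOracle:
    def test_matches_brute_force_on_1000_matrices(self):
        rng = np.random.default_rng(0)
        for k in range(1000):
            n = int(rng.integers(2, 6))
            cost = rng.normal(0, 10, (n, n))
            rows, cols = linear_sum_assignment(cost)
            total = cost[rows, cols].sum()
            best = min(sum(cost[i, p[i]] for i in range(n))
                       for p in permutations(range(n)))
            assert total == pytest.approx(best, abs=1e-9)

    def test_single_pair_links(self):
        tr = _track([(0, (10, 10))])
        det = Detection(frame=1, mask=np.zeros((20, 20), bool),
                        centroid=np.array([11.0, 10.0]))
        pairs, _prov = link_frames([tr], [det], TrackingParams())
        assert pairs == {0: 0}

    def test_empty_frames_empty_assignment(self):
        pairs, prov = link_frames([], [], TrackingParams())
        assert pairs == {} and prov == set()

    def test_velocity_preserves_crossing_identities(self):
        # two cells crossing with consistent prior velocities: the
        # velocity-aware cost keeps identities where nearest-centroid swaps
        a = _track([(0, (10, 10)), (1, (10, 20)), (2, (10, 30))])
        b = _track([(0, (10, 52)), (1, (10, 42)), (2, (10, 32))])
        a.cell_id, b.cell_id = 0, 1
        # at t=3 they have crossed; the det nearest a's last position
        # belongs to b and vice versa
        det_a = Detection(frame=3, mask=np.zeros((64, 64), bool),
                          centroid=np.array([10.0, 40.0]))
        det_b = Detection(frame=3, mask=np.zeros((64, 64), bool),
                          centroid=np.array([10.0, 22.0]))
        pairs, _ = link_frames([a, b], [det_a, det_b], TrackingParams())
        assert pairs == {0: 0, 1: 1}
        # nearest-centroid linking would swap
        d_a = [np.linalg.norm(np.array([10, 30.]) - d.centroid)
               for d in (det_a, det_b)]
        assert np.argmin(d_a) == 1


class TestInterpolation:
    def test_no_gaps_unchanged(self):
        tr = _track([(0, (0, 0)), (1, (1, 1)), (2, (2, 2))])
        out = interpolate_gaps([tr], frame_range=(0, 3))
        assert [p.source for p in out[0].points] == ["detected"] * 3

    def test_interior_gap_is_linear(self):
        tr = _track([(0, (0, 0)), (4, (4, 0))])
        out = interpolate_gaps([tr], frame_range=(0, 5))
        pts = out[0].points
        for t in (1, 2, 3):
            assert pts[t].source == "interpolated"
            assert np.allclose(pts[t].centroid, (t, 0), atol=1e-8)

    def test_leading_frames_constant_extension(self):
        tr = _track([(2, (5, 5)), (3, (6, 5))])
        out = interpolate_gaps([tr], frame_range=(0, 4))
        assert np.allclose(out[0].points[0].centroid, (5, 5))
        assert np.allclose(out[0].points[1].centroid, (5, 5))

    def test_qp_equals_closed_form_on_random_anchors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            T = int(rng.integers(5, 30))
            n_anchor = int(rng.integers(2, max(3, T // 2)))
            frames = np.sort(rng.choice(T, n_anchor, replace=False))
            pos = rng.normal(0, 20, (n_anchor, 2))
            tr = Track(cell_id=0, points=[
                TrackPoint(frame=int(f), centroid=pos[k],
                           source="detected")
                for k, f in enumerate(frames)])
            out = interpolate_gaps([tr], frame_range=(0, T))[0]
            got = out.centroids()
            # closed form: piecewise-linear between anchors, constant ends
            for dim in range(2):
                expect = np.interp(np.arange(T), frames, pos[:, dim])
                assert np.allclose(got[:, dim], expect, atol=1e-8)

    def test_interpolated_points_carry_translated_mask(self):
        m = np.zeros((30, 30), bool)
        m[4:9, 4:9] = True
        d0 = Detection(frame=0, mask=m, centroid=np.array([6.0, 6.0]))
        m2 = np.zeros((30, 30), bool)
        m2[4:9, 14:19] = True
        d2 = Detection(frame=2, mask=m2, centroid=np.array([6.0, 16.0]))
        tr = Track(cell_id=0, points=[
            TrackPoint(frame=0, centroid=d0.centroid, source="detected",
                       detection=d0),
            TrackPoint(frame=2, centroid=d2.centroid, source="detected",
                       detection=d2)])
        out = interpolate_gaps([tr], frame_range=(0, 3))[0]
        mid = out.points[1]
        assert mid.source == "interpolated"
        expect = np.zeros((30, 30), bool)
        expect[4:9, 9:14] = True        # the 5x5 square moved to col 11
        assert np.array_equal(mid.get_mask(), expect)

    def test_zero_detection_track_dropped(self):
        tr = Track(cell_id=0, points=[TrackPoint(
            frame=0, centroid=np.zeros(2), source="interpolated")])
        assert interpolate_gaps([tr], frame_range=(0, 3)) == []


class TestRefinement:
    def test_high_fidelity_returns_provisional(self):
        rng = np.random.default_rng(4)
        tr = _track([(t, p) for t, p in
                     enumerate(rng.normal(0, 10, (8, 2)))])
        p = TrackingParams(alpha_fid=1e6, lambda_smooth=1, alpha_acc=1)
        out = refine_tracks([tr], p)[0]
        assert np.abs(out.refined - tr.centroids()).max() < 1e-3

    def test_straight_line_unchanged(self):
        tr = _track([(t, (2.0 * t, -t)) for t in range(6)])
        out = refine_tracks([tr], TrackingParams())[0]
        assert np.allclose(out.refined, tr.centroids(), atol=1e-9)

    def test_solver_matches_dense_normal_equations(self):
        rng = np.random.default_rng(5)
        p = TrackingParams(lambda_smooth=1.3, alpha_acc=0.7, alpha_fid=4.0)
        for _ in range(20):
            T = int(rng.integers(5, 25))
            pbar = rng.normal(0, 15, (T, 2))
            tr = _track(list(enumerate(pbar)))
            got = refine_tracks([tr], p)[0].refined
            w = p.lambda_smooth + p.alpha_acc
            D = np.zeros((T - 2, T))
            for k in range(T - 2):
                D[k, k:k + 3] = (1, -2, 1)
            A = w * D.T @ D + p.alpha_fid * np.eye(T)
            expect = np.linalg.solve(A, p.alpha_fid * pbar)
            assert np.allclose(got, expect, atol=1e-6)

    def test_refined_objective_not_worse(self):
        rng = np.random.default_rng(6)
        p = TrackingParams()
        for _ in range(20):
            pbar = rng.normal(0, 10, (int(rng.integers(4, 20)), 2))
            tr = _track(list(enumerate(pbar)))
            refined = refine_tracks([tr], p)[0].refined
            assert refine_objective(refined, pbar, p) <= \
                refine_objective(pbar, pbar, p) + 1e-9


class TestTrackWell:
    def test_clean_two_cell_simulation(self):
        cfg = SimConfig(n_frames=40, render=False, seed=70)
        _v, gt = simulate_well(cfg)
        dets = [gt.detections(t) for t in range(gt.n_frames)]
        tracks = track_well(dets)
        assert len(tracks) == 2
        for tr in tracks:
            assert all(p.source == "detected" for p in tr.points)
            assert [p.frame for p in tr.points] == list(range(40))
        assert compute_mota(tracks, gt).mota == 1.0

    def test_dropped_frames_interpolated_exactly(self):
        cfg = SimConfig(n_frames=30, render=False, seed=71)
        _v, gt = simulate_well(cfg)
        dets = [gt.detections(t) for t in range(gt.n_frames)]
        dropped = {(7, 0), (15, 1), (22, 0)}     # (frame, cell index)
        for t, i in dropped:
            dets[t] = [d for k, d in enumerate(gt.detections(t)) if k != i]
        tracks = track_well(dets)
        assert len(tracks) == 2
        interp = {(p.frame, tr.cell_id) for tr in tracks
                  for p in tr.points if p.source == "interpolated"}
        assert {f for f, _ in interp} == {f for f, _ in dropped}

    def test_occlusion_merge_identities_recovered(self):
        ok = 0
        for s in range(5):
            cfg = SimConfig(n_frames=50, n_crossings=2,
                            crossing_occlusion_frames=2, render=False,
                            seed=80 + s)
            _v, gt = simulate_well(cfg)
            dets = corrupt_detections(gt, merge_rate=0.6, seed=s,
                                      merge_contact_only=True)
            rep = compute_mota(track_well(dets), gt)
            ok += rep.idsw.sum() == 0
        assert ok >= 4

    def test_containment_track_count(self):
        for s in range(4):
            cfg = SimConfig(n_effectors=2, n_targets=2, n_frames=25,
                            render=False, seed=90 + s)
            _v, gt = simulate_well(cfg)
            dets = [gt.detections(t) for t in range(gt.n_frames)]
            assert len(track_well(dets)) == 4

    def test_all_empty_frames(self):
        assert track_well([[], [], []]) == []


def _toy_gt(n_frames=10):
    """Two 4x4 cells gliding along fixed rows of a 30x60 grid."""
    masks, labels, centroids = [], [], []
    for t in range(n_frames):
        frame_masks = []
        lab = np.zeros((30, 60), np.uint16)
        cents = []
        for i, row in enumerate((6, 20)):
            c0 = 5 + 4 * t
            m = np.zeros((30, 60), bool)
            m[row:row + 4, c0:c0 + 4] = True
            frame_masks.append(m)
            lab[m] = i + 1
            cents.append([row + 1.5, c0 + 1.5])
        masks.append(frame_masks)
        labels.append(lab)
        centroids.append(cents)
    return GroundTruthWell(masks=masks, labels=np.stack(labels),
                           cell_types=["effector", "target"],
                           death_frames=[None, None],
                           centroids=np.array(centroids),
                           contacts={}, well_mask=np.ones((30, 60), bool))


def _tracks_from_gt(gt, skip=(), swap_from=None):
    tracks = [Track(cell_id=i) for i in range(2)]
    for t in range(gt.n_frames):
        for i in range(2):
            if (t, i) in skip:
                continue
            j = i
            if swap_from is not None and t >= swap_from:
                j = 1 - i
            d = Detection(frame=t, mask=gt.masks[t][i],
                          centroid=gt.centroids[t, i].copy())
            tracks[j].points.append(d and TrackPoint(
                frame=t, centroid=d.centroid, source="detected",
                detection=d))
    return tracks


class TestMota:
    def test_perfect_tracks_score_one(self):
        gt = _toy_gt()
        assert compute_mota(_tracks_from_gt(gt), gt).mota == 1.0

    def test_hand_count_fn_plus_idsw(self):
        # 2 cells x 10 frames = 20 object-frames; 1 missed detection on
        # cell 0, and cell 1 handed from one track to a new track at t=7
        # (1 identity switch) -> MOTA = 1 - 2/20 = 0.9
        gt = _toy_gt(10)
        t0, t1, t2 = Track(cell_id=0), Track(cell_id=1), Track(cell_id=2)
        for t in range(10):
            if t != 4:
                d = Detection(frame=t, mask=gt.masks[t][0],
                              centroid=gt.centroids[t, 0].copy())
                t0.points.append(TrackPoint(frame=t, centroid=d.centroid,
                                            source="detected", detection=d))
            d = Detection(frame=t, mask=gt.masks[t][1],
                          centroid=gt.centroids[t, 1].copy())
            target = t1 if t < 7 else t2
            target.points.append(TrackPoint(frame=t, centroid=d.centroid,
                                            source="detected", detection=d))
        rep = compute_mota([t0, t1, t2], gt)
        assert rep.fn.sum() == 1
        assert rep.idsw.sum() == 1
        assert rep.mota == pytest.approx(0.9)

    def test_empty_predictions_all_fn(self):
        gt = _toy_gt(10)
        rep = compute_mota([], gt)
        assert rep.mota == 0.0 and rep.fn.sum() == 20

    def test_empty_ground_truth_rejected(self):
        gt = _toy_gt(2)
        gt.cell_types = []
        gt.masks = [[] for _ in range(2)]
        with pytest.raises(ValueError):
            compute_mota([], gt)

    def test_monotone_in_injected_errors(self):
        gt = _toy_gt(10)
        last = 1.1
        for n_skip in (0, 1, 2, 3):
            skip = {(2 + k, k % 2) for k in range(n_skip)}
            mota = compute_mota(_tracks_from_gt(gt, skip=skip), gt).mota
            assert mota <= last + 1e-12
            last = mota
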