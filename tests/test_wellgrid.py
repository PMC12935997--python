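"""Well localization: rim detection, NMS, lattice fitting, drift-corrected
cropping."""

import numpy as np
import pytest

from lftiming import SimConfig, simulate_array
from lftiming.wellgrid import (GridModel, box_iou, detect_well_rims,
                               fit_lattice, nms, propagate_and_crop)


def brute_force_nms(candidates, iou_threshold):
    """Reference NMS: for each box, kept iff no higher-scoring kept box
    overlaps it beyond the threshold (greedy by score)."""
    ordered = sorted(candidates, key=lambda c: -c["score"])
    kept = []
    for c in ordered:
        if not any(box_iou(c["box"], k["box"]) > iou_threshold
                   for k in kept):
            kept.append(c)
    return kept


def boxes_equal(a, b):
    return sorted((c["box"], c["score"]) for c in a) == \
        sorted((c["box"], c["score"]) for c in b)


class TestNms:
    def test_identical_boxes_keep_best(self):
        cands = [{"box": (0, 0, 10, 10), "score": 0.9},
                 {"box": (0, 0, 10, 10), "score": 0.8}]
        kept = nms(cands, 0.5)
        assert len(kept) == 1 and kept[0]["score"] == 0.9

    def test_disjoint_all_kept(self):
        cands = [{"box": (0, 0, 10, 10), "score": 0.5},
                 {"box": (20, 20, 30, 30), "score": 0.4},
                 {"box": (50, 0, 60, 10), "score": 0.3}]
        assert len(nms(cands, 0.5)) == 3

    def test_matches_reference_on_random_overlaps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cands = []
            for _k in range(5):
                r0, c0 = rng.integers(0, 20, 2)
                s = int(rng.integers(8, 20))
                cands.append({"box": (int(r0), int(c0), int(r0) + s,
                                      int(c0) + s),
                              "score": float(rng.random())})
            thr = float(rng.uniform(0.2, 0.7))
            assert boxes_equal(nms(cands, thr),
                               brute_force_nms(cands, thr))

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(1)
        cands = [{"box": (int(r), int(c), int(r) + 12, int(c) + 12),
                  "score": float(rng.random())}
                 for r, c in rng.integers(0, 30, (8, 2))]
        kept = nms(cands, 0.4)
        ids = {id(c) for c in cands}
        assert all(id(c) in ids for c in kept)
        assert boxes_equal(nms(kept, 0.4), kept)


class TestDetect:
    def test_clean_array_all_wells_found(self):
        arr = simulate_array(SimConfig(n_frames=2, noise_sd=0.0, seed=3),
                             3, 3)
        cands = nms(detect_well_rims(arr.video[0], 80), 0.3)
        assert len(cands) == 9
        for tb in arr.boxes[0]:
            tc = ((tb[0] + tb[2]) / 2, (tb[1] + tb[3]) / 2)
            best = min(cands, key=lambda c: abs((c["box"][0] + c["box"][2])
                                                / 2 - tc[0])
                       + abs((c["box"][1] + c["box"][3]) / 2 - tc[1]))
            bc = ((best["box"][0] + best["box"][2]) / 2,
                  (best["box"][1] + best["box"][3]) / 2)
            assert abs(bc[0] - tc[0]) <= 2 and abs(bc[1] - tc[1]) <= 2

    def test_blank_frame_no_candidates(self):
        assert detect_well_rims(np.full((200, 200), 0.5), 80) == []

    def test_noisy_array_recall(self):
        arr = simulate_array(SimConfig(n_frames=2, noise_sd=0.05, seed=4),
                             3, 3)
        cands = nms(detect_well_rims(arr.video[0], 80), 0.3)
        hits = sum(any(box_iou(tb, c["box"]) >= 0.5 for c in cands)
                   for tb in arr.boxes[0])
        assert hits / 9 >= 0.9


class TestLattice:
    @staticmethod
    def _perfect(pitch=100, rows=3, cols=3, jitter=0.0, drop=(), seed=0):
        rng = np.random.default_rng(seed)
        cands = []
        for i in range(rows):
            for j in range(cols):
                if (i, j) in drop:
                    continue
                r = 50 + i * pitch + rng.normal(0, jitter)
                c = 60 + j * pitch + rng.normal(0, jitter)
                cands.append({"box": (r - 40, c - 40, r + 40, c + 40),
                              "score": 1.0})
        return cands

    def test_perfect_grid_exact_pitch(self):
        grid = fit_lattice(self._perfect(pitch=100), box_side=80)
        assert grid.row_pitch == pytest.approx(100.0, abs=1e-9)
        assert grid.col_pitch == pytest.approx(100.0, abs=1e-9)

    def test_jittered_grid_pitch_within_half_pixel(self):
        grid = fit_lattice(self._perfect(pitch=100, rows=4, cols=4,
                                         jitter=1.0, seed=2), box_side=80)
        assert abs(grid.row_pitch - 100) <= 0.5
        assert abs(grid.col_pitch - 100) <= 0.5

    def test_missing_sites_synthesized(self):
        grid = fit_lattice(self._perfect(rows=3, cols=3,
                                         drop={(1, 1)}), box_side=80)
        assert grid.n_rows * grid.n_cols == 9
        box = grid.site_box(1, 1)       # synthesized at the missing site
        assert box[2] - box[0] == 80
        assert (1, 1) not in grid.occupied

    def test_collinear_fails(self):
        cands = [{"box": (0, c, 80, c + 80), "score": 1.0}
                 for c in (0, 100, 200, 300)]
        with pytest.raises(ValueError):
            fit_lattice(cands, box_side=80)

    def test_translation_equivariance(self):
        base = self._perfect(pitch=95, rows=3, cols=4, jitter=0.5, seed=5)
        g1 = fit_lattice(base, box_side=80)
        shifted = [{"box": (b["box"][0] + 17, b["box"][1] - 23,
                            b["box"][2] + 17, b["box"][3] - 23),
                    "score": 1.0} for b in base]
        g2 = fit_lattice(shifted, box_side=80)
        assert g2.row_pitch == pytest.approx(g1.row_pitch, abs=1e-6)
        assert g2.col_pitch == pytest.approx(g1.col_pitch, abs=1e-6)
        assert g2.origin[0] - g1.origin[0] == pytest.approx(17, abs=1e-6)
        assert g2.origin[1] - g1.origin[1] == pytest.approx(-23, abs=1e-6)


class TestCrop:
    def test_zero_drift_crops_equal_standalone(self):
        cfg = SimConfig(n_frames=4, seed=7)
        arr = simulate_array(cfg, 2, 2)
        cands = nms(detect_well_rims(arr.video[0], 80), 0.3)
        grid = fit_lattice(cands, box_side=80)
        wells = propagate_and_crop(arr.video, grid)
        assert len(wells) == 4
        for w in wells:
            assert all(b[2] - b[0] == 80 and b[3] - b[1] == 80
                       for b in w["boxes"])
        by_site = {w["site"]: w for w in wells}
        for k, (vid, _gt) in enumerate(arr.well_sims):
            i, j = divmod(k, 2)
            assert np.allclose(by_site[(i, j)]["video"].frames, vid.frames)

    def test_drift_estimated_within_half_pixel(self):
        cfg = SimConfig(n_frames=5, seed=8)
        drift = np.array([[0, 0], [1, 1], [2, 2], [2, 3], [3, 4]])
        arr = simulate_array(cfg, 2, 2, drift=drift)
        cands = nms(detect_well_rims(arr.video[0], 80), 0.3)
        grid = fit_lattice(cands, box_side=80)
        propagate_and_crop(arr.video, grid)
        est = np.array(grid.shifts)
        assert np.all(np.abs(est - drift) <= 0.5)

    def test_overhanging_well_excluded(self):
        cfg = SimConfig(n_frames=2, seed=9)
        arr = simulate_array(cfg, 2, 2)
        cands = nms(detect_well_rims(arr.video[0], 80), 0.3)
        grid = fit_lattice(cands, box_side=80)
        # chop the array so the right column of wells overhangs
        cut = arr.video[:, :, :grid.site_box(0, 1)[3] - 10]
        wells = propagate_and_crop(cut, grid)
        sites = {w["site"] for w in wells}
        assert sites == {(0, 0), (1, 0)}
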