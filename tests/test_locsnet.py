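"""Occlusion-aware segmentation: mask decomposition, loss arithmetic,
training behavior and mIoU evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lftiming.locsnet import (HeadOutputs, LossWeights, MaskTriplet,
                              bce_grid, composite_mask_loss,
                              decompose_mask, evaluate_miou,
                              locsnet_forward, mask_head_losses,
                              total_loss)

LN2 = float(np.log(2.0))


class TestDecompose:
    def test_isolated_cell(self):
        e = np.zeros((10, 10), bool)
        e[2:6, 2:6] = True
        trip = decompose_mask(e, [])
        assert not trip.overlap.any()
        assert np.array_equal(trip.complement, e)
        assert np.array_equal(trip.whole, e)

    def test_coincident_masks(self):
        e = np.zeros((8, 8), bool)
        e[1:5, 1:5] = True
        trip = decompose_mask(e, [e.copy()])
        assert np.array_equal(trip.overlap, e)
        assert not trip.complement.any()

    def test_three_pixel_strip(self):
        # two 3x3 squares overlapping in a 3x1 strip
        a = np.zeros((6, 8), bool)
        a[1:4, 1:4] = True
        b = np.zeros((6, 8), bool)
        b[1:4, 3:6] = True
        trip = decompose_mask(a, [b])
        assert trip.overlap.sum() == 3
        assert trip.complement.sum() == 6

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_reconstruction_property(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.random((12, 12)) < 0.3
        others = [rng.random((12, 12)) < 0.3 for _ in range(3)]
        trip = decompose_mask(e, others)
        assert np.array_equal(trip.overlap | trip.complement, e)
        assert not (trip.overlap & trip.complement).any()
        union = np.zeros_like(e)
        for m in others:
            union |= m
        assert not (trip.overlap & ~union).any()


class TestLosses:
    def test_confident_correct_prediction_near_zero(self):
        t = np.zeros((8, 8), bool)
        t[2:5, 2:5] = True
        p = np.where(t, 1 - 1e-9, 1e-9)
        out = HeadOutputs(p, p * 0 + 1e-9, p)
        trip = MaskTriplet(t, np.zeros_like(t), t)
        l_w, l_o, l_c = mask_head_losses(out, trip)
        assert max(l_w, l_o, l_c) < 1e-6

    def test_uniform_half_gives_ln2(self):
        t = np.zeros((6, 6), bool)
        t[1:3, 1:3] = True
        half = np.full((6, 6), 0.5)
        out = HeadOutputs(half, half, half)
        trip = MaskTriplet(t, np.zeros_like(t), t)
        for loss in mask_head_losses(out, trip):
            assert loss == pytest.approx(LN2, rel=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.99, (8, 8))
        t = rng.random((8, 8)) < 0.4
        expect = -np.mean(np.where(t, np.log(p), np.log(1 - p)))
        assert bce_grid(p, t) == pytest.approx(expect, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_grid(np.full((4, 4), 0.5), np.zeros((5, 5), bool))

    def test_composite_single_instance(self):
        t = np.zeros((6, 6), bool)
        t[2:4, 2:4] = True
        half = np.full((6, 6), 0.5)
        out = HeadOutputs(half, half, half)
        trip = MaskTriplet(t, np.zeros_like(t), t)
        assert composite_mask_loss([(out, trip)]) == \
            pytest.approx(sum(mask_head_losses(out, trip)))

    def test_composite_is_mean_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(6):
            t = rng.random((6, 6)) < 0.4
            trip = decompose_mask(t, [rng.random((6, 6)) < 0.3])
            out = HeadOutputs(rng.uniform(0.01, 0.99, (6, 6)),
                              rng.uniform(0.01, 0.99, (6, 6)),
                              rng.uniform(0.01, 0.99, (6, 6)))
            pairs.append((out, trip))
        expect = np.mean([sum(mask_head_losses(o, t)) for o, t in pairs])
        assert composite_mask_loss(pairs) == pytest.approx(expect)
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        assert composite_mask_loss(perm) == \
            pytest.approx(composite_mask_loss(pairs))

    def test_no_overlap_batch_degenerates_to_whole_plus_complement(self):
        # with no overlaps anywhere, complement == whole and L_o is the
        # loss against an all-empty target
        t = np.zeros((6, 6), bool)
        t[1:4, 1:4] = True
        trip = decompose_mask(t, [np.zeros_like(t)])
        assert np.array_equal(trip.complement, trip.whole)
        p = np.full((6, 6), 0.2)
        out = HeadOutputs(p, p, p)
        l_w, l_o, l_c = mask_head_losses(out, trip)
        assert l_w == pytest.approx(l_c)
        assert l_o == pytest.approx(bce_grid(p, np.zeros_like(t)))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            composite_mask_loss([])

    def test_total_loss_arithmetic(self):
        assert total_loss(0.2, 0.3, 0.5) == pytest.approx(1.0)
        assert total_loss(7.0, 9.0, 0.4, LossWeights(0, 0, 1)) == \
            pytest.approx(0.4)
        assert total_loss(1, 1, 2, LossWeights(2, 1, 0.5)) == \
            pytest.approx(4.0)
        with pytest.raises(ValueError):
            total_loss(np.inf, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(-1, 0, 0)


class TestMiou:
    def _square(self, r0, c0, side=10, shape=(40, 40)):
        m = np.zeros(shape, bool)
        m[r0:r0 + side, c0:c0 + side] = True
        return m

    def test_identical_predictions(self):
        gt = [[self._square(5, 5), self._square(20, 20)]]
        _per, mean, _sd = evaluate_miou(gt, gt)
        assert mean == 1.0

    def test_shifted_square_third(self):
        gt = [[self._square(10, 10)]]
        pred = [[self._square(10, 15)]]
        _per, mean, _sd = evaluate_miou(pred, gt)
        assert mean == pytest.approx(1 / 3)

    def test_missed_cell_contributes_zero(self):
        gt = [[self._square(5, 5), self._square(25, 25)]]
        pred = [[self._square(5, 5)]]
        _per, mean, _sd = evaluate_miou(pred, gt)
        assert mean == pytest.approx(0.5)

    def test_erosion_monotonically_degrades(self):
        from scipy import ndimage
        gt = [[self._square(8, 8, 14), self._square(24, 24, 12)]]
        last = 1.1
        for k in range(4):
            pred = [[ndimage.binary_erosion(m, iterations=k) if k else m
                     for m in gt[0]]]
            _p, mean, _s = evaluate_miou(pred, gt)
            assert mean < last
            last = mean

    def test_frame_count_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_miou([[]], [[], []])


class TestTraining:
    def test_loss_decreases(self, seg_fixture):
        for (mode, seed), hist in seg_fixture["histories"].items():
            assert np.isfinite(hist["train"][-1])
            assert hist["train"][-1] < hist["train"][0]
            assert hist["holdout"][-1] < hist["holdout"][0]

    def test_heldout_miou_on_separated_cells(self, seg_fixture):
        assert seg_fixture["separated_miou"] > 0.5

    def test_triplet_heads_not_worse_than_baseline(self, seg_fixture):
        mious = seg_fixture["mious"]
        assert np.mean(mious["locsnet"]) >= np.mean(mious["baseline"])

    def test_inference_deterministic(self, seg_fixture):
        frame = seg_fixture["test"][0][0]
        model = seg_fixture["model"]
        d1 = locsnet_forward(model, frame)
        d2 = locsnet_forward(model, frame)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert np.array_equal(a.mask, b.mask)
            assert a.score == b.score

    def test_blank_frame_no_detections(self, seg_fixture):
        blank = np.full((80, 80), 0.5)
        assert locsnet_forward(seg_fixture["model"], blank) == []

    def test_consistency_diagnostic_reported(self, seg_fixture):
        frame = seg_fixture["test"][0][0]
        dets = locsnet_forward(seg_fixture["model"], frame)
        assert dets, "expected at least one detection"
        for d in dets:
            assert 0.0 <= d.consistency_iou <= 1.0

    def test_untrained_model_refuses_inference(self):
        from lftiming.locsnet import LOCSNet
        with pytest.raises(RuntimeError):
            locsnet_forward(LOCSNet(), np.zeros((80, 80)))

    def test_empty_dataset_rejected(self):
        from lftiming.locsnet import train_locsnet
        with pytest.raises(ValueError):
            train_locsnet([])
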