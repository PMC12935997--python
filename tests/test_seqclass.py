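"""Sequence classification: motion descriptors, patch assembly, metric
suite, DeLong test, and toy training."""

import numpy as np
import pytest

from lftiming.seqclass import (EFFECTOR_LABEL, TARGET_LABEL, auroc,
                               build_patch_sequence, classification_metrics,
                               classify_track, delong_test,
                               label_smoothed_ce, motion_descriptors)

LN2 = float(np.log(2.0))


class TestMotionDescriptors:
    def test_stationary_track(self):
        md = motion_descriptors(np.tile([5.0, 5.0], (8, 1)))
        assert np.all(md.values[:, 0] == 0)
        assert np.all(md.values[:, 3] == 0)

    def test_constant_step(self):
        p = np.cumsum(np.tile([3.0, 4.0], (6, 1)), axis=0)
        md = motion_descriptors(p)
        assert np.allclose(md.values[1:, 0], 5.0)
        assert np.allclose(md.values[2:, 3], 0.0)
        assert np.allclose(md.values[2:, 4], 0.0)

    def test_right_angle_turn(self):
        p = np.array([[0, 0], [1, 0], [1, 1]], float)
        md = motion_descriptors(p)
        assert md.values[2, 4] == pytest.approx(np.pi / 2)
        assert md.values[2, 3] == pytest.approx(np.sqrt(2))

    def test_translation_invariant_rotation_equivariant(self):
        rng = np.random.default_rng(0)
        p = np.cumsum(rng.normal(0, 3, (10, 2)), axis=0)
        base = motion_descriptors(p).values
        shifted = motion_descriptors(p + [47.0, -12.0]).values
        assert np.allclose(base, shifted)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = motion_descriptors(p @ R.T).values
        assert np.allclose(rot[:, 0], base[:, 0])        # speed unchanged
        assert np.allclose(rot[:, 3], base[:, 3])        # |acceleration|
        assert np.allclose(rot[:, 4], base[:, 4])        # turning angle
        # direction unit vector rotates with the track
        assert np.allclose(rot[1:, 1] ** 2 + rot[1:, 2] ** 2, 1.0)

    def test_length_one_track_all_zero(self):
        md = motion_descriptors(np.array([[3.0, 4.0]]))
        assert md.values.shape == (1, 5)
        assert md.values[0, 0] == 0


class TestPatchSequence:
    def _video(self, T=10, side=40):
        rng = np.random.default_rng(1)
        return rng.random((T, side, side)).astype(np.float32)

    def test_centered_patch_equals_subimage(self):
        video = self._video()
        cents = np.tile([20.0, 20.0], (10, 1))
        masks = [np.ones((40, 40), bool)] * 10
        s = build_patch_sequence(video, cents, masks, patch_side=16,
                                 seq_len=10, crop_side=16)
        r0 = 20 - 8
        assert np.allclose(s.patches[0, 0], video[0, r0:r0 + 16,
                                                  r0:r0 + 16])
        assert np.array_equal(s.patches[0, 0], s.patches[0, 2])

    def test_corner_cell_zero_filled_mask_binary(self):
        video = self._video()
        cents = np.tile([1.0, 1.0], (10, 1))
        masks = [np.ones((40, 40), bool)] * 10
        s = build_patch_sequence(video, cents, masks, patch_side=16,
                                 seq_len=10, crop_side=16)
        assert np.all(s.patches[0, 0, :6, :] == 0)       # off-frame region
        assert set(np.unique(s.patches[0, 3])) <= {0.0, 1.0}

    def test_padding_flags(self):
        video = self._video(T=10)
        cents = np.tile([20.0, 20.0], (10, 1))
        masks = [np.ones((40, 40), bool)] * 10
        s = build_patch_sequence(video, cents, masks, patch_side=16,
                                 seq_len=64, crop_side=16)
        assert s.valid.sum() == 10
        assert not s.valid[10:].any()
        assert np.array_equal(s.patches[10], s.patches[9])  # repeat-last

    def test_empty_video_rejected(self):
        with pytest.raises(ValueError):
            build_patch_sequence(np.zeros((0, 4, 4)), np.zeros((0, 2)), [])


class TestSmoothedCrossEntropy:
    def test_uniform_prediction_ln2(self):
        assert label_smoothed_ce([0.5, 0.5], 0, eps=0.1) == \
            pytest.approx(LN2)

    def test_confident_prediction_value(self):
        # -0.95 ln 0.95 - 0.05 ln 0.05
        got = label_smoothed_ce([0.05, 0.95], 1, eps=0.1)
        assert got == pytest.approx(0.19852, abs=1e-4)


class TestMetrics:
    def test_perfect_separation(self):
        m = classification_metrics([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv,
                m.auroc) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_null_scores_auroc_near_half(self):
        rng = np.random.default_rng(2)
        n = 10_000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        a = auroc(scores, labels)
        n1 = labels.sum()
        n0 = n - n1
        se = np.sqrt((n + 1) / (12 * n1 * n0))
        assert abs(a - 0.5) <= 3 * se

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 200)
        labels = (rng.random(200) < 0.4).astype(int)
        base = auroc(scores, labels)
        for f in (np.exp, np.tanh, lambda x: 3 * x - 7):
            assert auroc(f(scores), labels) == pytest.approx(base)

    def test_single_class_flags(self):
        m = classification_metrics([0.9, 0.8], [1, 1])
        assert m.auroc is None
        assert m.npv is None        # no negative predictions/labels

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            classification_metrics([0.5], [1, 0])


class TestDeLong:
    def test_identical_scores(self):
        d, p = delong_test([0.1, 0.9, 0.4], [0.1, 0.9, 0.4], [0, 1, 0])
        assert d == 0.0 and p == 1.0

    def test_auc_matches_metric_suite(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(40) < 0.5).astype(int)
        a = rng.normal(labels, 1.0)
        b = rng.normal(labels, 2.0)
        delta, _p = delong_test(a, b, labels)
        assert delta == pytest.approx(auroc(a, labels) - auroc(b, labels))

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 20
        labels = np.array([1] * 10 + [0] * 10)
        a = rng.normal(labels * 1.2, 1.0)
        b = rng.normal(labels * 0.8, 1.0)
        delta, p = delong_test(a, b, labels)
        from scipy import stats
        z = stats.norm.isf(p / 2)
        var_delong = (delta / z) ** 2 if z > 0 else np.nan
        boots = []
        for _ in range(4000):
            idx = np.concatenate([rng.integers(0, 10, 10),
                                  10 + rng.integers(0, 10, 10)])
            boots.append((auroc(a[idx], labels[idx]) or 0)
                         - (auroc(b[idx], labels[idx]) or 0))
        var_boot = np.var(boots)
        assert abs(var_delong - var_boot) <= 0.2 * var_boot


class TestToyTraining:
    def test_fold_auroc_above_chance(self, classifier_fixture):
        aurocs = [m.auroc for m in classifier_fixture["folds"]]
        assert np.mean(aurocs) > 0.8

    def test_heldout_effectors_mostly_recognized(self, classifier_fixture):
        model = classifier_fixture["model"]
        eff = [s for s in classifier_fixture["holdout"]
               if s.label == EFFECTOR_LABEL]
        hits = sum(classify_track(model, s)[0] > 0.5 for s in eff)
        assert hits / len(eff) >= 0.8

    def test_classification_deterministic(self, classifier_fixture):
        model = classifier_fixture["model"]
        s = classifier_fixture["holdout"][0]
        p1, l1 = classify_track(model, s)
        p2, l2 = classify_track(model, s)
        assert p1 == p2 and l1 == l2

    def test_all_padding_sample_returns_probability(self,
                                                    classifier_fixture):
        import copy
        s = copy.deepcopy(classifier_fixture["holdout"][0])
        s.valid[:] = False
        p, lab = classify_track(classifier_fixture["model"], s)
        assert 0.0 <= p <= 1.0
        assert lab in (EFFECTOR_LABEL, TARGET_LABEL)

    def test_untrained_model_refuses(self):
        from lftiming.seqclass import ClassifierConfig, CnnLstmClassifier
        from tests.conftest import classification_samples

        model = CnnLstmClassifier(ClassifierConfig(patch_side=32,
                                                   seq_len=36))
        s = classification_samples(1, 999)[0]
        with pytest.raises(RuntimeError):
            classify_track(model, s)

    def test_single_class_training_rejected(self):
        from lftiming.seqclass import ClassifierConfig, train_classifier
        from tests.conftest import classification_samples

        samples = [s for s in classification_samples(2, 998)
                   if s.label == EFFECTOR_LABEL]
        with pytest.raises(ValueError):
            train_classifier(samples, ClassifierConfig())
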