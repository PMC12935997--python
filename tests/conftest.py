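"""Shared fixtures.  Expensive model trainings are session-scoped and
reused by several tests."""

import numpy as np
import pytest

from lftiming import SimConfig, simulate_well
from lftiming.seqclass import (EFFECTOR_LABEL, TARGET_LABEL,
                               ClassifierConfig, build_patch_sequence)


def classification_samples(n_wells, seed0, seq_len=36, n_frames=36,
                           patch=32, separated=True):
    """Per-cell patch/motion samples from simulated 1E:1T wells."""
    out = []
    for s in range(n_wells):
        kw = {}
        if not separated:
            # identical morphology and motility for both classes
            kw = dict(effector_speed_um_min=(0.4, 0.8),
                      target_speed_um_min=(0.4, 0.8),
                      effector_radius_px=(7.5, 0.8),
                      target_radius_px=(7.5, 0.8),
                      effector_persistence=0.5, target_persistence=0.5)
        cfg = SimConfig(n_effectors=1, n_targets=1, n_frames=n_frames,
                        seed=seed0 + s, **kw)
        vid, gt = simulate_well(cfg)
        for i, kind in enumerate(gt.cell_types):
            masks = [gt.masks[t][i] for t in range(gt.n_frames)]
            out.append(build_patch_sequence(
                vid.frames, gt.centroids[:, i], masks,
                patch_side=patch, seq_len=seq_len, crop_side=40,
                label=EFFECTOR_LABEL if kind == "effector" else TARGET_LABEL,
                well_id=f"w{s}", cell_id=i))
    return out


def apoptosis_samples(n_wells, seed0, n_frames=60, seq_len=48, patch=32):
    """Target-cell tracks, every other well carrying a death event with a
    strong morphology change."""
    from lftiming.apoptosis import label_frames

    out = []
    for s in range(n_wells):
        dying = s % 2 == 0
        cfg = SimConfig(n_effectors=1, n_targets=1, n_frames=n_frames,
                        apoptosis_prob=1.0 if dying else 0.0,
                        apoptosis_onset_window=(18, 45),
                        apoptosis_area_factor=0.6,
                        apoptosis_intensity_shift=0.12,
                        seed=seed0 + s)
        vid, gt = simulate_well(cfg)
        i = gt.cell_types.index("target")
        onset = gt.death_frames[i]
        masks = [gt.masks[t][i] for t in range(n_frames)]
        smp = build_patch_sequence(
            vid.frames, gt.centroids[:, i], masks,
            patch_side=patch, seq_len=seq_len, crop_side=40,
            well_id=f"w{s}", cell_id=i,
            frame_labels=label_frames(n_frames, onset))
        smp.true_onset = onset
        smp.n_frames = n_frames
        out.append(smp)
    return out


@pytest.fixture(scope="session")
def seg_fixture():
    """LOCSNet vs whole-head-only baseline, trained twice each on an
    overlap-rich fixture, plus one held-out test set."""
    from lftiming.locsnet import (SegTrainConfig, evaluate_miou,
                                  locsnet_forward, train_locsnet)

    def make(n_wells, seed0, n_frames=4):
        data = []
        for s in range(n_wells):
            cfg = SimConfig(n_effectors=2, n_targets=2, n_frames=n_frames,
                            n_crossings=2, crossing_occlusion_frames=2,
                            seed=seed0 + s)
            vid, gt = simulate_well(cfg)
            for t in range(n_frames):
                data.append((vid.frames[t].astype(float), gt.masks[t]))
        return data

    train = make(12, 100)
    test = make(3, 900)
    separated = []
    for s in range(3):
        cfg = SimConfig(n_effectors=1, n_targets=1, n_frames=3,
                        seed=700 + s)
        vid, gt = simulate_well(cfg)
        for t in range(3):
            separated.append((vid.frames[t].astype(float), gt.masks[t]))

    out = {"mious": {"locsnet": [], "baseline": []}, "histories": {}}
    for seed in (1, 2):
        for mode in ("locsnet", "baseline"):
            cfg = SegTrainConfig(epochs=12, lr=2e-3, seed=seed,
                                 baseline=(mode == "baseline"))
            model, hist = train_locsnet(train, cfg)
            preds = [locsnet_forward(model, f) for f, _m in test]
            _, miou, _ = evaluate_miou(preds, [m for _f, m in test])
            out["mious"][mode].append(miou)
            out["histories"][(mode, seed)] = hist
            if mode == "locsnet" and seed == 1:
                out["model"] = model
                sep_preds = [locsnet_forward(model, f)
                             for f, _m in separated]
                _, sep_miou, _ = evaluate_miou(sep_preds,
                                               [m for _f, m in separated])
                out["separated_miou"] = sep_miou
                out["test"] = test
    return out


@pytest.fixture(scope="session")
def classifier_fixture():
    """Toy-trained cell-type classifier with grouped stratified folds."""
    from lftiming.seqclass import train_classifier

    samples = classification_samples(28, 7000)
    cfg = ClassifierConfig(patch_side=32, seq_len=36, lr=3e-3, epochs=6,
                           folds=3, seed=0, dropout=0.3)
    model, fold_metrics = train_classifier(samples, cfg)
    # a held-out batch from fresh wells
    holdout = classification_samples(10, 7600)
    return {"model": model, "folds": fold_metrics, "samples": samples,
            "holdout": holdout, "config": cfg}


@pytest.fixture(scope="session")
def apoptosis_fixture():
    """Toy-trained frame-wise apoptosis detector (strong morphology
    change), with history and samples."""
    from lftiming.apoptosis import train_apoptosis

    samples = apoptosis_samples(120, 31000)
    cfg = ClassifierConfig(per_frame=True, patch_side=32, seq_len=48,
                           lr=2e-3, epochs=6, seed=0, dropout=0.3)
    model, history = train_apoptosis(samples, cfg, lambda_mono=1.0,
                                     holdout_frac=0.3)
    # ablation partner: same data and schedule, regularizer off
    model_nomono, _hist = train_apoptosis(samples, cfg, lambda_mono=0.0,
                                          holdout_frac=0.3)
    return {"model": model, "model_nomono": model_nomono,
            "history": history, "samples": samples, "config": cfg}
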