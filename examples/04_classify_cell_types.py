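"""Label-free effector-vs-target classification of tracked cells.

Each tracked cell becomes a sequence of 4-channel patches (phase contrast
replicated plus the cell's mask) and five motion descriptors; a CNN-LSTM
issues one label per track.  Training uses label smoothing 0.1, AdamW
with cosine annealing, dropout, and folds grouped by well so no well
leaks between training and validation.  A few minutes on CPU.
"""

import numpy as np

from lftiming import SimConfig, simulate_well
from lftiming.seqclass import (EFFECTOR_LABEL, TARGET_LABEL,
                               ClassifierConfig, build_patch_sequence,
                               classify_track, train_classifier)

samples = []
for s in range(24):
    cfg = SimConfig(n_effectors=1, n_targets=1, n_frames=36, seed=7000 + s)
    video, gt = simulate_well(cfg)
    for i, kind in enumerate(gt.cell_types):
        masks = [gt.masks[t][i] for t in range(gt.n_frames)]
        samples.append(build_patch_sequence(
            video.frames, gt.centroids[:, i], masks, patch_side=32,
            seq_len=36, crop_side=40,
            label=EFFECTOR_LABEL if kind == "effector" else TARGET_LABEL,
            well_id=f"w{s}", cell_id=i))

cfg = ClassifierConfig(patch_side=32, seq_len=36, lr=3e-3, epochs=6,
                       folds=3, seed=0, dropout=0.3)
model, folds = train_classifier(samples, cfg)
for k, m in enumerate(folds):
    print(f"fold {k}: accuracy {m.accuracy:.2f}, AUROC {m.auroc:.2f}")

prob, label = classify_track(model, samples[0])
print(f"track 0 ({'effector' if samples[0].label else 'target'}): "
      f"P(effector) = {prob:.2f} -> "
      f"{'effector' if label == EFFECTOR_LABEL else 'target'}")
# Small fast effectors vs large sluggish targets separate cleanly
# (fold AUROC ~1.0 at this difficulty).
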