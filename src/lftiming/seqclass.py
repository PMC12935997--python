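"""Sequence-level label-free cell-type classification.

Effector (e.g. CAR T) and target (e.g. NALM6) cells differ subtly in
phase contrast: effectors are smaller, rounder and markedly more motile.
Frame-level classification is unreliable, so classification operates on
the whole tracked sequence: a small CNN encodes each 4-channel patch
(phase contrast replicated into three channels plus the cell's binary
mask), the embedding is concatenated with five per-frame motion
descriptors (speed, direction cosine and sine, acceleration magnitude,
signed turning angle), an LSTM integrates the sequence, and a fully
connected head maps the final hidden state to a single label for the
track.

Training follows the sequence-classification recipe: cross-entropy with
label smoothing 0.1, AdamW with cosine annealing, dropout in the LSTM
head, optional freezing of the early CNN stage, and k-fold
cross-validation stratified by label and grouped by well (no same-well
leakage).  The metric suite covers accuracy, sensitivity, specificity,
PPV, NPV and AUROC (Mann-Whitney rank form), plus DeLong's paired test
for comparing AUROCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from skimage.transform import resize

from .nn import (AdamW, Conv2d, Dropout, Linear, LSTM, Tensor, conv2d,
                 cosine_lr, log_softmax, maxpool2d)
from .nn.layers import Module

__all__ = [
    "MotionDescriptors",
    "TrackSequenceSample",
    "ClassifierMetrics",
    "ClassifierConfig",
    "CnnLstmClassifier",
    "motion_descriptors",
    "build_patch_sequence",
    "classify_track",
    "train_classifier",
    "classification_metrics",
    "label_smoothed_ce",
    "auroc",
    "delong_test",
    "EFFECTOR_LABEL",
    "TARGET_LABEL",
]

EFFECTOR_LABEL = 1
TARGET_LABEL = 0


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class MotionDescriptors:
    """Per-frame 5-vector: speed, direction cosine, direction sine,
    acceleration magnitude, signed turning angle.

    The direction convention at zero speed is (1, 0); the first frame(s)
    are zero-filled (zero speed and acceleration)."""

    values: np.ndarray      # (T, 5)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def speed(self):
        return self.values[:, 0]


def motion_descriptors(centroids: np.ndarray) -> MotionDescriptors:
    """Kinematic descriptors of a gap-free centroid series (T, 2)."""
    p = np.asarray(centroids, dtype=float)
    T = len(p)
    out = np.zeros((T, 5))
    out[:, 1] = 1.0                           # (cos, sin) = (1, 0) at rest
    if T < 2:
        return MotionDescriptors(out)
    d = np.diff(p, axis=0)                    # displacement at frames 1..T-1
    speed = np.linalg.norm(d, axis=1)
    for t in range(1, T):
        s = speed[t - 1]
        out[t, 0] = s
        if s > 1e-12:
            out[t, 1] = d[t - 1, 0] / s
            out[t, 2] = d[t - 1, 1] / s
        if t >= 2:
            acc = d[t - 1] - d[t - 2]
            out[t, 3] = np.linalg.norm(acc)
            if speed[t - 1] > 1e-12 and speed[t - 2] > 1e-12:
                a0 = np.arctan2(d[t - 2, 1], d[t - 2, 0])
                a1 = np.arctan2(d[t - 1, 1], d[t - 1, 0])
                ang = a1 - a0
                out[t, 4] = np.arctan2(np.sin(ang), np.cos(ang))
    return MotionDescriptors(out)


@dataclass
class TrackSequenceSample:
    """Model input for one track.

    ``patches``: (L, 4, S, S) -- phase replicated into channels 0-2, the
    cell's binary mask in channel 3.  ``motion``: (L, 5).  ``valid``: per
    position, whether it holds a real frame (False = repeat-last
    padding).  ``frame_labels`` (optional) are per-frame binary states for
    frame-wise tasks such as apoptosis."""

    patches: np.ndarray
    motion: np.ndarray
    valid: np.ndarray
    label: Optional[int] = None
    well_id: str = ""
    cell_id: int = -1
    frame_labels: Optional[np.ndarray] = None


def build_patch_sequence(video_frames: np.ndarray, centroids: np.ndarray,
                         masks, patch_side: int = 64, seq_len: int = 64,
                         crop_side: Optional[int] = None,
                         label: Optional[int] = None, well_id: str = "",
                         cell_id: int = -1,
                         frame_labels=None) -> TrackSequenceSample:
    """Assemble the 4-channel patch sequence for one tracked cell.

    Per frame, a ``crop_side`` square centered on the centroid is cut out
    (zero-padded at borders) and resized to ``patch_side``; channel 3 is
    the cell's own mask cropped the same way.  Tracks shorter than
    ``seq_len`` are padded by repeating the last frame (flagged invalid);
    longer tracks are subsampled evenly.
    """
    if video_frames.size == 0:
        raise ValueError("empty video")
    T = len(centroids)
    crop = crop_side or patch_side
    md = motion_descriptors(centroids).values
    if frame_labels is not None:
        frame_labels = np.asarray(frame_labels)

    if T > seq_len:
        pick = np.linspace(0, T - 1, seq_len).round().astype(int)
    else:
        pick = np.arange(T)
    patches = np.zeros((seq_len, 4, patch_side, patch_side), dtype=float)
    motion = np.zeros((seq_len, 5))
    valid = np.zeros(seq_len, dtype=bool)
    flabels = np.zeros(seq_len) if frame_labels is not None else None
    H, W = video_frames.shape[1:]
    for k, t in enumerate(pick):
        r, c = centroids[t]
        r0 = int(round(r - crop / 2))
        c0 = int(round(c - crop / 2))
        img = _pad_crop(video_frames[t], r0, c0, crop)
        m = masks[t]
        mm = _pad_crop(m.astype(float), r0, c0, crop) if m is not None \
            else np.zeros((crop, crop))
        if crop != patch_side:
            img = resize(img, (patch_side, patch_side), order=1,
                         anti_aliasing=False, preserve_range=True)
            mm = resize(mm, (patch_side, patch_side), order=0,
                        anti_aliasing=False, preserve_range=True)
        patches[k, 0] = patches[k, 1] = patches[k, 2] = img
        patches[k, 3] = mm > 0.5
        motion[k] = md[t]
        valid[k] = True
        if flabels is not None:
            flabels[k] = frame_labels[t]
    # repeat-last padding
    n = len(pick)
    for k in range(n, seq_len):
        patches[k] = patches[n - 1]
        motion[k] = motion[n - 1]
        if flabels is not None:
            flabels[k] = flabels[n - 1]
    return TrackSequenceSample(patches=patches, motion=motion, valid=valid,
                               label=label, well_id=well_id, cell_id=cell_id,
                               frame_labels=flabels)


def _pad_crop(img, r0, c0, side):
    H, W = img.shape
    out = np.zeros((side, side), dtype=float)
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + side, H), min(c0 + side, W)
    if rr1 > rr0 and cc1 > cc0:
        out[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = img[rr0:rr1, cc0:cc1]
    return out


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    patch_side: int = 64          # 224 in production-scale use
    seq_len: int = 64
    channels: int = 8
    embed: int = 16
    hidden: int = 32
    lr: float = 3e-5              # production default; desk tests raise it
    epochs: int = 10
    label_smoothing: float = 0.1
    dropout: float = 0.5
    freeze_early: bool = False    # freeze the first CNN stage
    folds: int = 5
    seed: int = 0
    weight_decay: float = 1e-4
    per_frame: bool = False       # per-frame outputs (apoptosis head)


class CnnLstmClassifier(Module):
    """Per-frame CNN encoder -> motion concat -> LSTM -> linear head.

    With ``per_frame`` False the head maps the last valid hidden state to
    two class logits (sequence label); with True it maps every hidden
    state to one logit (frame-wise probability sequence).
    """

    def __init__(self, config: Optional[ClassifierConfig] = None):
        self.config = config or ClassifierConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        self.c1 = Conv2d(4, ch, 3, rng=rng)
        self.c2 = Conv2d(ch, 2 * ch, 3, rng=rng)
        self.c3 = Conv2d(2 * ch, 2 * ch, 3, rng=rng)
        self.proj = Linear(2 * ch, cfg.embed, rng=rng)
        self.lstm = LSTM(cfg.embed + 5, cfg.hidden, rng=rng)
        self.drop = Dropout(cfg.dropout, rng=np.random.default_rng(
            cfg.seed + 1))
        self.head = Linear(cfg.hidden, 1 if cfg.per_frame else 2, rng=rng)
        self.trained = False
        if cfg.freeze_early:
            self.c1.freeze()

    def encode(self, patches: np.ndarray) -> Tensor:
        """(L, 4, S, S) -> (L, embed) frame embeddings."""
        x = Tensor(patches)
        h = maxpool2d(self.c1(x).relu(), 2)
        h = maxpool2d(self.c2(h).relu(), 2)
        h = maxpool2d(self.c3(h).relu(), 2)
        L = h.data.shape[0]
        pooled = h.mean(axis=3).mean(axis=2)      # global average pool
        return self.proj(pooled.reshape(L, -1)).relu()

    def forward(self, sample: TrackSequenceSample):
        emb = self.encode(sample.patches)
        from .nn import concat
        seq = concat([emb, Tensor(sample.motion)], axis=1)
        hs, _last = self.lstm(seq)
        hs = self.drop(hs)
        if self.config.per_frame:
            return self.head(hs)                  # (L, 1) logits
        last_valid = int(np.flatnonzero(sample.valid)[-1]) \
            if sample.valid.any() else sample.patches.shape[0] - 1
        return self.head(hs[last_valid:last_valid + 1])   # (1, 2) logits


def classify_track(model: CnnLstmClassifier, sample: TrackSequenceSample):
    """(probability of effector, predicted label) for one track."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model is untrained; call train_classifier first")
    model.set_training(False)
    logits = model.forward(sample)
    p = np.exp(log_softmax(logits).data)[0]
    prob_eff = float(p[EFFECTOR_LABEL])
    return prob_eff, EFFECTOR_LABEL if prob_eff >= 0.5 else TARGET_LABEL


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def label_smoothed_ce(probs, true_idx: int, eps: float = 0.1) -> float:
    """Label-smoothed cross-entropy of a 2-class probability vector."""
    p = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0)
    q = np.full(2, eps / 2)
    q[true_idx] += 1 - eps
    return float(-(q * np.log(p)).sum())


def _train_on(model, samples, cfg, rng):
    opt = AdamW(model.parameters(), lr=cfg.lr,
                weight_decay=cfg.weight_decay)
    total_steps = cfg.epochs * len(samples)
    step = 0
    model.set_training(True)
    eps = cfg.label_smoothing
    for _epoch in range(cfg.epochs):
        for i in rng.permutation(len(samples)):
            s = samples[i]
            logits = model.forward(s)
            ls = log_softmax(logits)
            q = np.full((1, 2), eps / 2)
            q[0, s.label] += 1 - eps
            loss = -(Tensor(q) * ls).sum()
            model.zero_grad()
            loss.backward()
            opt.lr = cosine_lr(cfg.lr, step, total_steps)
            opt.step()
            step += 1
    model.set_training(False)
    model.trained = True


def train_classifier(samples, config: Optional[ClassifierConfig] = None):
    """Grouped, stratified k-fold training.

    Folds are grouped by well (no same-well leakage) and stratified by
    label.  Returns ``(model, fold_metrics)``: the model trained on all
    data, and per-fold validation metrics (accuracy and AUROC).  With
    ``folds`` <= 1 a single 75/25 grouped split is used.
    """
    from sklearn.model_selection import StratifiedGroupKFold

    cfg = config or ClassifierConfig()
    samples = list(samples)
    labels = np.array([s.label for s in samples])
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to train")
    if min(np.bincount(labels)) < 2:
        raise ValueError("need at least 2 samples per class")
    groups = np.array([s.well_id for s in samples])
    rng = np.random.default_rng(cfg.seed)

    fold_metrics = []
    n_folds = max(cfg.folds, 2) if cfg.folds > 1 else 2
    splitter = StratifiedGroupKFold(n_splits=min(n_folds,
                                                 len(np.unique(groups))),
                                    shuffle=True, random_state=cfg.seed)
    splits = list(splitter.split(np.zeros(len(samples)), labels, groups))
    if cfg.folds <= 1:
        splits = splits[:1]
    for fold, (tr_idx, va_idx) in enumerate(splits):
        fm = CnnLstmClassifier(cfg)
        _train_on(fm, [samples[i] for i in tr_idx], cfg,
                  np.random.default_rng(cfg.seed + 100 + fold))
        scores, truth = [], []
        for i in va_idx:
            p, _lab = classify_track(fm, samples[i])
            scores.append(p)
            truth.append(samples[i].label)
        m = classification_metrics(np.array(scores), np.array(truth))
        fold_metrics.append(m)
    model = CnnLstmClassifier(cfg)
    _train_on(model, samples, cfg, rng)
    return model, fold_metrics


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    auroc: Optional[float]
    counts: dict = field(default_factory=dict)


def auroc(scores, labels) -> Optional[float]:
    """Area under the ROC curve via the Mann-Whitney rank statistic
    (ties share average rank).  None when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_metrics(scores, labels,
                           threshold: float = 0.5) -> ClassifierMetrics:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    total = tp + tn + fp + fn

    def safe(num, den):
        return num / den if den > 0 else None

    return ClassifierMetrics(
        accuracy=(tp + tn) / total if total else 0.0,
        sensitivity=safe(tp, tp + fn) if (tp + fn) else 0.0,
        specificity=safe(tn, tn + fp) if (tn + fp) else 0.0,
        ppv=safe(tp, tp + fp),
        npv=safe(tn, tn + fn),
        auroc=auroc(scores, labels),
        counts={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def delong_test(scores_a, scores_b, labels):
    """DeLong's paired test for the difference of two AUROCs measured on
    the same samples.  Returns (delta_auc, two-sided p-value); identical
    score vectors give (0, 1) by convention."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.array_equal(scores_a, scores_b):
        return 0.0, 1.0
    pos_a, neg_a = scores_a[labels == 1], scores_a[labels == 0]
    pos_b, neg_b = scores_b[labels == 1], scores_b[labels == 0]
    m, n = len(pos_a), len(neg_a)
    if m == 0 or n == 0:
        raise ValueError("both classes required")

    def structural(pos, neg):
        # V10[i] = P(score_pos_i > score_neg), V01[j] = P(score_pos > neg_j)
        cmp = (pos[:, None] > neg[None, :]).astype(float) \
            + 0.5 * (pos[:, None] == neg[None, :])
        return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()

    v10_a, v01_a, auc_a = structural(pos_a, neg_a)
    v10_b, v01_b, auc_b = structural(pos_b, neg_b)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 1.0
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return delta, float(p)
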