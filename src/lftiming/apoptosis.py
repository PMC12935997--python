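"""Temporally consistent label-free apoptosis detection.

Apoptosis is irreversible: once a cell dies it stays dead.  Ground-truth
labels follow the fluorescence-marker convention -- a cell is alive until
its first marker-positive frame and apoptotic from then on.  The detector
is the CNN-LSTM sequence model with per-frame outputs: one apoptosis
probability per time point, trained with class-weighted binary
cross-entropy plus a monotonicity regularizer that penalizes downward
fluctuations of the predicted probability,

    R = lambda_mono * sum_t max(0, p_t - p_{t+1})^2 ,

which is zero exactly when the predicted sequence is non-decreasing.
Death frames are called with hysteresis (threshold + persistence) to
suppress single-frame blips, and onset accuracy is scored against the
ground-truth death frame with a +/-4-frame tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import AdamW, Tensor, bce_with_logits, cosine_lr
from .seqclass import (ClassifierConfig, CnnLstmClassifier,
                       TrackSequenceSample, auroc)

__all__ = [
    "ApoptosisTrace",
    "label_frames",
    "monotonicity_penalty",
    "train_apoptosis",
    "predict_trace",
    "call_death_frame",
    "evaluate_onset",
    "frame_metrics",
]


@dataclass
class ApoptosisTrace:
    """Per-frame apoptosis probabilities for one track."""

    probs: np.ndarray                   # (T,) in [0, 1]
    death_frame: Optional[int] = None
    cell_id: int = -1
    well_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)


def label_frames(track_length: int, onset_frame: Optional[int]) -> np.ndarray:
    """0 before the onset frame, 1 from it onward; all-0 when no onset."""
    if onset_frame is None:
        return np.zeros(track_length, dtype=int)
    if not (0 <= onset_frame < track_length):
        raise ValueError(f"onset {onset_frame} outside [0, {track_length})")
    out = np.zeros(track_length, dtype=int)
    out[onset_frame:] = 1
    return out


def monotonicity_penalty(probs, lambda_mono: float = 1.0) -> float:
    """Squared-hinge penalty on downward steps of a probability sequence;
    zero iff the sequence is non-decreasing."""
    p = np.asarray(probs, dtype=float)
    if len(p) < 2:
        return 0.0
    drops = np.maximum(0.0, p[:-1] - p[1:])
    return float(lambda_mono * np.sum(drops ** 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sequence_loss(model, sample, pos_weight, neg_weight, lambda_mono):
    logits = model.forward(sample)                  # (L, 1)
    t = sample.frame_labels.reshape(-1, 1)
    v = sample.valid.reshape(-1, 1).astype(float)
    w = np.where(t > 0.5, pos_weight, neg_weight) * v
    bce = bce_with_logits(logits, t, weights=w).sum() / max(v.sum(), 1.0)
    probs = logits.sigmoid()
    drops = (probs[:-1] - probs[1:]).relu()
    mono = (drops * drops).sum() * lambda_mono
    return bce + mono


def train_apoptosis(samples, config: Optional[ClassifierConfig] = None,
                    lambda_mono: float = 1.0, holdout_frac: float = 0.3):
    """Train the per-frame apoptosis detector.

    ``samples`` are ``TrackSequenceSample`` with ``frame_labels`` set
    (from :func:`label_frames`).  Class weights are the inverse label
    frequencies over the training set.  Returns ``(model, history)`` with
    per-epoch training loss and held-out frame-level AUROC.
    """
    cfg = config or ClassifierConfig(per_frame=True)
    if not cfg.per_frame:
        raise ValueError("apoptosis detector needs per_frame=True")
    samples = [s for s in samples if s.frame_labels is not None]
    if not samples:
        raise ValueError("no samples with frame labels")
    if not any(s.frame_labels.max() > 0 for s in samples):
        raise ValueError("no apoptotic tracks in the training set")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(samples))
    n_hold = int(len(samples) * holdout_frac)
    hold = [samples[i] for i in order[:n_hold]]
    train = [samples[i] for i in order[n_hold:]]

    all_labels = np.concatenate([s.frame_labels[s.valid] for s in train])
    pos_frac = max(all_labels.mean(), 1e-6)
    pos_weight = 0.5 / pos_frac
    neg_weight = 0.5 / max(1 - pos_frac, 1e-6)

    model = CnnLstmClassifier(cfg)
    model.set_training(True)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    total_steps = cfg.epochs * len(train)
    history = {"train_loss": [], "holdout_auroc": []}
    step = 0
    for _epoch in range(cfg.epochs):
        losses = []
        for i in rng.permutation(len(train)):
            loss = _sequence_loss(model, train[i], pos_weight, neg_weight,
                                  lambda_mono)
            model.zero_grad()
            loss.backward()
            opt.lr = cosine_lr(cfg.lr, step, total_steps)
            opt.step()
            step += 1
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if hold:
            scores, labels = _frame_scores(model, hold)
            history["holdout_auroc"].append(auroc(scores, labels))
    model.set_training(False)
    model.trained = True
    return model, history


def _frame_scores(model, samples):
    model.set_training(False)
    scores, labels = [], []
    for s in samples:
        tr = predict_trace(model, s)
        scores.append(tr.probs[s.valid])
        labels.append(s.frame_labels[s.valid])
    return np.concatenate(scores), np.concatenate(labels)


def predict_trace(model: CnnLstmClassifier,
                  sample: TrackSequenceSample) -> ApoptosisTrace:
    """Frame-wise apoptosis probabilities for one track."""
    if not getattr(model, "trained", False) and not model.config.per_frame:
        raise RuntimeError("model is untrained")
    model.set_training(False)
    logits = model.forward(sample)
    probs = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
    return ApoptosisTrace(probs=probs, cell_id=sample.cell_id,
                          well_id=sample.well_id)


# ---------------------------------------------------------------------------
# calling and evaluation
# ---------------------------------------------------------------------------

def call_death_frame(trace, threshold: float = 0.5,
                     persistence_k: int = 2) -> Optional[int]:
    """First frame t with p >= threshold sustained for ``persistence_k``
    consecutive frames (hysteresis suppresses single-frame blips)."""
    p = trace.probs if isinstance(trace, ApoptosisTrace) \
        else np.asarray(trace, dtype=float)
    k = max(1, int(persistence_k))
    above = p >= threshold
    for t in range(len(p) - k + 1):
        if above[t:t + k].all():
            return t
    return None


def evaluate_onset(pred_frames, true_frames, tol: int = 4):
    """Fraction of cells whose called death frame lies within ``tol``
    frames of the reference, plus per-cell signed errors (None where the
    call or the reference is missing)."""
    if len(pred_frames) != len(true_frames):
        raise ValueError("cell lists must align")
    errors = []
    within = 0
    n_scored = 0
    for pred, true in zip(pred_frames, true_frames):
        if true is None:
            errors.append(None)
            continue
        n_scored += 1
        if pred is None:
            errors.append(None)        # missed call counts against
            continue
        err = int(pred) - int(true)
        errors.append(err)
        if abs(err) <= tol:
            within += 1
    frac = within / n_scored if n_scored else float("nan")
    return frac, errors


def frame_metrics(traces, label_seqs, threshold: float = 0.5):
    """Frame-level confusion counts, accuracy, sensitivity, specificity,
    PPV and AUROC over a set of traces."""
    from .seqclass import classification_metrics

    scores, labels = [], []
    for tr, lab in zip(traces, label_seqs):
        p = tr.probs if isinstance(tr, ApoptosisTrace) else np.asarray(tr)
        lab = np.asarray(lab)
        if len(p) != len(lab):
            raise ValueError("trace and labels must align")
        scores.append(p)
        labels.append(lab)
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    return classification_metrics(scores, labels, threshold=threshold)
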