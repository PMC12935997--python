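"""Occlusion-aware instance segmentation for label-free nanowell frames.

Touching and overlapping cells are the dominant failure mode of
single-mask instance segmentation in phase contrast.  The model here
supervises three mask representations per instance: the *whole* mask, its
*overlap* part (pixels shared with other instances) and its *complement*
(the visible remainder).  The overlap and complement heads consume the ROI
feature map; the feature maps of their third convolution layer are summed
elementwise with the ROI features to form the input of the whole-mask
head, so the whole head sees where its neighbours are.  Training minimizes

    total = lambda1 * L_reg + lambda2 * L_cls + lambda3 * L_mask,

with ``L_mask`` the mean over instances of the three per-pixel binary
cross-entropies; with the extra heads disabled (baseline mode) this
reduces to the standard single-mask-head two-stage loss.

Desk scale: proposals come from darkness components split at
distance-transform peaks (region-proposal stand-in), per-ROI features
from a small trainable convolutional backbone on 28 x 28 crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.transform import resize

from .nn import (AdamW, Conv2d, Linear, Tensor, bce_with_logits, conv2d,
                 cosine_lr, log_softmax, maxpool2d, smooth_l1)
from .nn.layers import Module
from .simulate import Detection
from .wellgrid import nms as box_nms

__all__ = [
    "MaskTriplet",
    "HeadOutputs",
    "LossWeights",
    "SegLossReport",
    "SegTrainConfig",
    "LOCSNet",
    "decompose_mask",
    "bce_grid",
    "mask_head_losses",
    "composite_mask_loss",
    "total_loss",
    "propose_boxes",
    "train_locsnet",
    "locsnet_forward",
    "evaluate_miou",
]


# ---------------------------------------------------------------------------
# mask decomposition and loss arithmetic
# ---------------------------------------------------------------------------

@dataclass
class MaskTriplet:
    """Whole / overlap / complement decomposition of one instance mask."""

    whole: np.ndarray
    overlap: np.ndarray
    complement: np.ndarray

    def __post_init__(self):
        self.whole = np.asarray(self.whole, dtype=bool)
        self.overlap = np.asarray(self.overlap, dtype=bool)
        self.complement = np.asarray(self.complement, dtype=bool)


@dataclass
class HeadOutputs:
    """Per-instance probability grids emitted by the three mask heads."""

    prob_whole: np.ndarray
    prob_overlap: np.ndarray
    prob_complement: np.ndarray


@dataclass
class LossWeights:
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class SegLossReport:
    l_reg: float
    l_cls: float
    l_mask: float
    l_w: float
    l_o: float
    l_c: float
    total: float


def decompose_mask(instance_mask: np.ndarray, other_masks) -> MaskTriplet:
    """Split a mask into overlap (pixels shared with any other instance)
    and complement (the rest)."""
    e = np.asarray(instance_mask, dtype=bool)
    union = np.zeros_like(e)
    for m in other_masks:
        union |= np.asarray(m, dtype=bool)
    overlap = e & union
    return MaskTriplet(whole=e, overlap=overlap, complement=e & ~overlap)


def bce_grid(prob: np.ndarray, target: np.ndarray, eps: float = 1e-12) -> float:
    """Mean per-pixel binary cross-entropy between a probability grid and a
    binary target."""
    p = np.clip(np.asarray(prob, dtype=float), eps, 1 - eps)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def mask_head_losses(out: HeadOutputs, target: MaskTriplet):
    """(L_w, L_o, L_c): per-head mean pixel cross-entropies."""
    return (bce_grid(out.prob_whole, target.whole),
            bce_grid(out.prob_overlap, target.overlap),
            bce_grid(out.prob_complement, target.complement))


def composite_mask_loss(pairs) -> float:
    """Mean over instance-frames of (L_w + L_c + L_o)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty batch")
    totals = []
    for out, target in pairs:
        l_w, l_o, l_c = mask_head_losses(out, target)
        totals.append(l_w + l_c + l_o)
    return float(np.mean(totals))


def total_loss(l_reg: float, l_cls: float, l_mask: float,
               weights: Optional[LossWeights] = None) -> float:
    w = weights or LossWeights()
    for v in (l_reg, l_cls, l_mask):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return w.lambda1 * l_reg + w.lambda2 * l_cls + w.lambda3 * l_mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    epochs: int = 14
    lr: float = 2e-3
    seed: int = 0
    head_res: int = 28
    channels: int = 8
    baseline: bool = False          # whole head only (single-mask comparator)
    weights: LossWeights = field(default_factory=LossWeights)
    score_threshold: float = 0.5
    nms_iou: float = 0.3
    expected_radius_px: float = 7.0
    neg_per_pos: float = 2.0
    holdout_frac: float = 0.2


class _MaskHead(Module):
    """Three 3x3 conv layers plus a logit layer at head resolution."""

    def __init__(self, channels, rng):
        self.c1 = Conv2d(channels, channels, 3, rng=rng)
        self.c2 = Conv2d(channels, channels, 3, rng=rng)
        self.c3 = Conv2d(channels, channels, 3, rng=rng)
        self.out = Conv2d(channels, 1, 3, rng=rng)

    def features(self, f_roi: Tensor) -> Tensor:
        """Post-activation feature map of the third convolution layer."""
        h = self.c1(f_roi).relu()
        h = self.c2(h).relu()
        return self.c3(h).relu()

    def logits(self, feat: Tensor) -> Tensor:
        return self.out(feat)


class LOCSNet(Module):
    """Two-stage occlusion-aware instance segmentation at desk scale."""

    def __init__(self, config: Optional[SegTrainConfig] = None):
        self.config = config or SegTrainConfig()
        rng = np.random.default_rng(self.config.seed)
        ch = self.config.channels
        # per-ROI backbone on the resized crop
        self.b1 = Conv2d(1, ch, 3, rng=rng)
        self.b2 = Conv2d(ch, ch, 3, rng=rng)
        # mask heads
        self.head_whole = _MaskHead(ch, rng)
        if not self.config.baseline:
            self.head_overlap = _MaskHead(ch, rng)
            self.head_complement = _MaskHead(ch, rng)
        # proposal classification / box regression from pooled ROI features
        res = self.config.head_res
        pooled = ch * (res // 2) * (res // 2)
        self.fc = Linear(pooled, 64, rng=rng)
        self.cls = Linear(64, 2, rng=rng)
        self.reg = Linear(64, 4, rng=rng)
        self.trained = False

    # -- stages ------------------------------------------------------------

    def roi_features(self, crops: np.ndarray) -> Tensor:
        """(P, res, res) image crops -> (P, C, res, res) ROI features."""
        x = Tensor(crops[:, None, :, :])
        h = self.b1(x).relu()
        return self.b2(h).relu()

    def forward_heads(self, f_roi: Tensor):
        """Mask logits; the whole head consumes f_roi summed with the
        layer-3 feature maps of the overlap and complement heads."""
        if self.config.baseline:
            f_added = f_roi
            z_o = z_c = None
        else:
            feat_o = self.head_overlap.features(f_roi)
            feat_c = self.head_complement.features(f_roi)
            z_o = self.head_overlap.logits(feat_o)
            z_c = self.head_complement.logits(feat_c)
            f_added = f_roi + feat_o + feat_c
        z_w = self.head_whole.logits(self.head_whole.features(f_added))
        return z_w, z_o, z_c

    def forward_cls_reg(self, f_roi: Tensor):
        pooled = maxpool2d(f_roi, 2)
        P = pooled.data.shape[0]
        h = self.fc(pooled.reshape(P, -1)).relu()
        return self.cls(h), self.reg(h)


# ---------------------------------------------------------------------------
# proposals, targets
# ---------------------------------------------------------------------------

def propose_boxes(frame: np.ndarray, expected_radius_px: float = 7.0,
                  max_proposals: int = 24) -> list:
    """Region proposals for one nanowell frame.

    Cells are darker than the background with a bright halo.  Darkness
    components inside the well interior (the rim itself is dark and is
    excluded) are split at distance-transform peaks, and each peak emits
    square boxes at three scales around the expected cell radius; the
    classification head and NMS sort out scale and duplicates.
    """
    img = np.asarray(frame, dtype=float)
    H, W = img.shape
    rr, cc = np.mgrid[0:H, 0:W]
    interior = np.hypot(rr - (H - 1) / 2, cc - (W - 1) / 2) \
        <= min(H, W) / 2 - 4
    if not interior.any():
        interior = np.ones_like(img, dtype=bool)
    bg = np.median(img[interior])
    dark = ndimage.gaussian_filter(bg - img, 1.2)
    peak = dark[interior].max() if interior.any() else 0.0
    if peak <= 0.02:
        return []
    blobmask = (dark > max(0.03, 0.3 * peak)) & interior
    blobmask = ndimage.binary_opening(blobmask, iterations=1)
    labels, n = ndimage.label(blobmask)
    boxes = []
    min_area = 0.25 * np.pi * expected_radius_px ** 2
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_area * 0.3:
            continue
        dist = ndimage.distance_transform_edt(comp)
        from skimage.feature import peak_local_max as _plm
        peaks = _plm(dist, min_distance=max(3,
                                            int(expected_radius_px * 0.8)),
                     labels=comp.astype(int), num_peaks=4)
        if len(peaks) == 0:
            peaks = [np.unravel_index(np.argmax(dist), dist.shape)]
        for (pr, pc) in peaks:
            for scale in (0.7, 1.0, 1.4):
                side = int(round(2.4 * expected_radius_px * scale))
                r0 = int(round(pr - side / 2))
                c0 = int(round(pc - side / 2))
                boxes.append((r0, c0, r0 + side, c0 + side))
    return boxes[:max_proposals]


def _crop_resized(img: np.ndarray, box, res: int, order: int = 1):
    r0, c0, r1, c1 = box
    H, W = img.shape
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, H), min(c1, W)
    out = np.zeros((r1 - r0, c1 - c0), dtype=float)
    if rr1 > rr0 and cc1 > cc0:
        out[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = img[rr0:rr1, cc0:cc1]
    return resize(out, (res, res), order=order, anti_aliasing=False,
                  preserve_range=True)


def _tight_box(mask: np.ndarray):
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return (int(r0), int(c0), int(r1) + 1, int(c1) + 1)


def _box_iou(a, b):
    from .wellgrid import box_iou
    return box_iou(a, b)


def _reg_target(prop, gt_box):
    ph = prop[2] - prop[0]
    pw = prop[3] - prop[1]
    pcy = (prop[0] + prop[2]) / 2.0
    pcx = (prop[1] + prop[3]) / 2.0
    gh = gt_box[2] - gt_box[0]
    gw = gt_box[3] - gt_box[1]
    gcy = (gt_box[0] + gt_box[2]) / 2.0
    gcx = (gt_box[1] + gt_box[3]) / 2.0
    return np.array([(gcy - pcy) / ph, (gcx - pcx) / pw,
                     np.log(gh / ph), np.log(gw / pw)])


def _apply_reg(prop, deltas):
    ph = prop[2] - prop[0]
    pw = prop[3] - prop[1]
    pcy = (prop[0] + prop[2]) / 2.0
    pcx = (prop[1] + prop[3]) / 2.0
    cy = pcy + deltas[0] * ph
    cx = pcx + deltas[1] * pw
    h = ph * np.exp(np.clip(deltas[2], -1.0, 1.0))
    w = pw * np.exp(np.clip(deltas[3], -1.0, 1.0))
    return (int(round(cy - h / 2)), int(round(cx - w / 2)),
            int(round(cy + h / 2)), int(round(cx + w / 2)))


def _frame_samples(frame, gt_masks, cfg, rng):
    """Proposals with matched targets for one training frame."""
    props = propose_boxes(frame, cfg.expected_radius_px)
    gt_boxes = [_tight_box(m) for m in gt_masks if m.any()]
    gt_kept = [m for m in gt_masks if m.any()]
    # augment with jittered ground-truth boxes (positive sampling)
    for b in gt_boxes:
        side = max(b[2] - b[0], b[3] - b[1]) + int(rng.integers(2, 7))
        cy = (b[0] + b[2]) / 2 + rng.integers(-2, 3)
        cx = (b[1] + b[3]) / 2 + rng.integers(-2, 3)
        r0, c0 = int(cy - side // 2), int(cx - side // 2)
        props.append((r0, c0, r0 + side, c0 + side))
    samples = []
    for p in props:
        ious = [_box_iou(p, gb) for gb in gt_boxes]
        best = int(np.argmax(ious)) if ious else -1
        if best >= 0 and ious[best] >= 0.5:
            gi = best
            triplet = decompose_mask(
                gt_kept[gi], [m for k, m in enumerate(gt_kept) if k != gi])
            res = cfg.head_res
            tw = _crop_resized(triplet.whole.astype(float), p, res,
                               order=0) > 0.5
            to = _crop_resized(triplet.overlap.astype(float), p, res,
                               order=0) > 0.5
            tc = _crop_resized(triplet.complement.astype(float), p, res,
                               order=0) > 0.5
            samples.append((p, 1, _reg_target(p, gt_boxes[gi]),
                            MaskTriplet(tw, to, tc)))
        elif best < 0 or ious[best] < 0.3:
            samples.append((p, 0, None, None))
    return samples


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_locsnet(dataset, config: Optional[SegTrainConfig] = None):
    """Train on (frame, instance-mask-list) pairs.

    Returns ``(model, history)`` where history records the epoch losses on
    the training portion and the held-out portion; the final held-out loss
    is asserted lower than the initial one by the training sanity tests.
    """
    cfg = config or SegTrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model = LOCSNet(cfg)
    n_hold = max(1, int(len(dataset) * cfg.holdout_frac)) \
        if len(dataset) > 2 else 0
    order = rng.permutation(len(dataset))
    hold_idx = set(order[:n_hold].tolist())
    train_set = [dataset[i] for i in range(len(dataset)) if i not in hold_idx]
    hold_set = [dataset[i] for i in sorted(hold_idx)]

    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=1e-4)
    total_steps = cfg.epochs * max(len(train_set), 1)
    history = {"train": [], "holdout": []}
    step = 0
    for epoch in range(cfg.epochs):
        losses = []
        for i in rng.permutation(len(train_set)):
            frame, masks = train_set[i]
            loss_t, report = _frame_loss(model, frame, masks, cfg, rng)
            if loss_t is None:
                continue
            model.zero_grad()
            loss_t.backward()
            opt.lr = cosine_lr(cfg.lr, step, total_steps)
            opt.step()
            step += 1
            losses.append(report.total)
        history["train"].append(float(np.mean(losses)) if losses else np.nan)
        history["holdout"].append(evaluate_loss(model, hold_set, cfg)
                                  if hold_set else np.nan)
    model.trained = True
    return model, history


def _frame_loss(model, frame, gt_masks, cfg, rng):
    samples = _frame_samples(frame, gt_masks, cfg, rng)
    pos = [s for s in samples if s[1] == 1]
    neg = [s for s in samples if s[1] == 0]
    if not pos and not neg:
        return None, None
    k = int(np.ceil(len(pos) * cfg.neg_per_pos)) or 2
    if len(neg) > k:
        neg = [neg[i] for i in rng.choice(len(neg), k, replace=False)]
    chosen = pos + neg
    crops = np.stack([_crop_resized(frame, s[0], cfg.head_res)
                      for s in chosen])
    f_roi = model.roi_features(crops)
    cls_logits, reg_out = model.forward_cls_reg(f_roi)
    labels = np.array([s[1] for s in chosen])
    ls = log_softmax(cls_logits)
    l_cls_t = -(ls[np.arange(len(chosen)), labels]).mean()
    loss_t = Tensor(0.0)
    l_reg = 0.0
    l_mask = 0.0
    l_w = l_o = l_c = 0.0
    w = cfg.weights
    if pos:
        pos_idx = np.arange(len(pos))
        reg_targets = np.stack([s[2] for s in pos])
        l_reg_t = smooth_l1(reg_out[pos_idx], reg_targets).mean()
        f_pos = f_roi[pos_idx]
        z_w, z_o, z_c = model.forward_heads(f_pos)
        tw = np.stack([s[3].whole for s in pos])[:, None].astype(float)
        l_w_t = bce_with_logits(z_w, tw).mean()
        heads_t = l_w_t
        l_w = l_w_t.item()
        if z_o is not None:
            to = np.stack([s[3].overlap for s in pos])[:, None].astype(float)
            tc = np.stack([s[3].complement
                           for s in pos])[:, None].astype(float)
            l_o_t = bce_with_logits(z_o, to).mean()
            l_c_t = bce_with_logits(z_c, tc).mean()
            heads_t = heads_t + l_o_t + l_c_t
            l_o, l_c = l_o_t.item(), l_c_t.item()
        loss_t = loss_t + w.lambda1 * l_reg_t + w.lambda3 * heads_t
        l_reg = l_reg_t.item()
        l_mask = heads_t.item()
    loss_t = loss_t + w.lambda2 * l_cls_t
    report = SegLossReport(l_reg=l_reg, l_cls=l_cls_t.item(), l_mask=l_mask,
                           l_w=l_w, l_o=l_o, l_c=l_c,
                           total=total_loss(l_reg, l_cls_t.item(), l_mask, w))
    return loss_t, report


def evaluate_loss(model, dataset, cfg) -> float:
    rng = np.random.default_rng(12345)
    vals = []
    for frame, masks in dataset:
        _t, report = _frame_loss(model, frame, masks, cfg, rng)
        if report is not None:
            vals.append(report.total)
    return float(np.mean(vals)) if vals else np.nan


def locsnet_forward(model: LOCSNet, frame: np.ndarray,
                    frame_index: int = 0) -> list:
    """Segment one frame with a trained model.

    Returns identity-free ``Detection`` objects; each carries a
    ``consistency_iou`` diagnostic, the IoU between the thresholded
    (overlap OR complement) reconstruction and the whole-head mask.
    """
    if not getattr(model, "trained", False):
        raise RuntimeError("model is untrained; call train_locsnet first")
    cfg = model.config
    props = propose_boxes(frame, cfg.expected_radius_px)
    if not props:
        return []
    crops = np.stack([_crop_resized(frame, p, cfg.head_res) for p in props])
    f_roi = model.roi_features(crops)
    cls_logits, reg_out = model.forward_cls_reg(f_roi)
    probs = np.exp(log_softmax(cls_logits).data)[:, 1]
    keep = [i for i, s in enumerate(probs) if s >= cfg.score_threshold]
    if not keep:
        return []
    cands = [{"box": props[i], "score": float(probs[i]), "idx": i}
             for i in keep]
    cands = box_nms(cands, cfg.nms_iou)
    idx = np.array([c["idx"] for c in cands])
    z_w, z_o, z_c = model.forward_heads(f_roi[idx])
    H, W = frame.shape
    out = []
    for k, cand in enumerate(cands):
        box = _apply_reg(cand["box"], reg_out.data[cand["idx"]])
        prob_w = 1.0 / (1.0 + np.exp(-z_w.data[k, 0]))
        side_r = max(box[2] - box[0], 1)
        side_c = max(box[3] - box[1], 1)
        pw = resize(prob_w, (side_r, side_c), order=1,
                    anti_aliasing=False, preserve_range=True)
        mask = np.zeros((H, W), dtype=bool)
        r0, c0, r1, c1 = box
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, H), min(c1, W)
        if rr1 <= rr0 or cc1 <= cc0:
            continue
        mask[rr0:rr1, cc0:cc1] = \
            pw[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] >= 0.5
        if not mask.any():
            continue
        com = ndimage.center_of_mass(mask)
        det = Detection(frame=frame_index, mask=mask,
                        centroid=np.array(com), score=cand["score"])
        if z_o is not None:
            po = 1.0 / (1.0 + np.exp(-z_o.data[k, 0]))
            pc = 1.0 / (1.0 + np.exp(-z_c.data[k, 0]))
            recon = (po >= 0.5) | (pc >= 0.5)
            whole28 = prob_w >= 0.5
            inter = np.count_nonzero(recon & whole28)
            union = np.count_nonzero(recon | whole28)
            det.consistency_iou = inter / union if union else 1.0
        out.append(det)
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_miou(pred_frames, gt_mask_frames):
    """Mean instance IoU against ground truth.

    ``pred_frames``: per frame, a list of ``Detection`` (or boolean
    masks).  ``gt_mask_frames``: per frame, a list of boolean ground-truth
    instance masks.  Per frame, predictions are matched to ground-truth
    instances by optimal assignment on IoU; unmatched ground-truth
    instances contribute 0.  Returns (per_frame_scores, mean, sd).
    """
    from scipy.optimize import linear_sum_assignment

    if len(pred_frames) != len(gt_mask_frames):
        raise ValueError("frame count mismatch")
    scores = []
    for preds, gts in zip(pred_frames, gt_mask_frames):
        gts = [np.asarray(g, dtype=bool) for g in gts if np.any(g)]
        if not gts:
            continue
        masks = [p.mask if isinstance(p, Detection) else np.asarray(p, bool)
                 for p in preds]
        iou = np.zeros((len(gts), max(len(masks), 1)))
        for i, g in enumerate(gts):
            for j, m in enumerate(masks):
                inter = np.count_nonzero(g & m)
                if inter:
                    iou[i, j] = inter / np.count_nonzero(g | m)
        if masks:
            rows, cols = linear_sum_assignment(-iou)
            matched = {r: iou[r, c] for r, c in zip(rows, cols)}
        else:
            matched = {}
        scores.append(float(np.mean([matched.get(i, 0.0)
                                     for i in range(len(gts))])))
    arr = np.asarray(scores)
    return arr, float(arr.mean()) if len(arr) else 0.0, \
        float(arr.std()) if len(arr) else 0.0
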