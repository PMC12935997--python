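"""Contact analysis and end-to-end per-well orchestration.

An effector-target contact (immunological synapse candidate) is declared
when the two masks overlap or their boundaries come within ``gap_px``
(default 1 px) -- the same rule the simulator uses for its ground-truth
contact intervals, so contact evaluation is self-consistent.  The
orchestrator runs crop -> segment -> track -> classify -> apoptosis ->
contacts per well, never letting one failed well abort a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .simulate import Detection, GroundTruthWell, WellVideo
from .tracking import TrackingParams, Track, compute_mota, track_well

logger = logging.getLogger("lftiming")

__all__ = [
    "ContactRecord",
    "WellSummary",
    "detect_contact",
    "contact_records",
    "contact_confusion",
    "gt_contact_records",
    "run_pipeline",
]


@dataclass
class ContactRecord:
    well_id: str
    effector_id: int
    target_id: int
    frame: int
    in_contact: bool

    @property
    def key(self):
        return (self.well_id, self.effector_id, self.target_id, self.frame)


@dataclass
class WellSummary:
    well_id: str
    n_effectors: int
    n_targets: int
    cell_types: dict                      # cell_id -> "effector"|"target"
    death_frames: dict = field(default_factory=dict)
    contact_intervals: list = field(default_factory=list)  # (e,t,start,end)
    n_frames: int = 0
    track_quality: str = "ok"


def detect_contact(mask_a: np.ndarray, mask_b: np.ndarray,
                   gap_px: int = 1) -> bool:
    """Contact iff the masks overlap or their minimum boundary distance is
    at most ``gap_px`` (tested by dilating one mask and intersecting).
    Symmetric; empty masks are never in contact."""
    if mask_a is None or mask_b is None:
        return False
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if not a.any() or not b.any():
        return False
    if (a & b).any():
        return True
    if gap_px <= 0:
        return False
    struct = ndimage.generate_binary_structure(2, 2)
    dil = ndimage.binary_dilation(a, structure=struct, iterations=int(gap_px))
    return bool((dil & b).any())


def contact_records(tracks, cell_types: dict, well_id: str = "well",
                    gap_px: int = 1, temporal_close: bool = False) -> list:
    """Frame-wise contact calls for every effector-target track pair.

    ``cell_types`` maps track cell_id to "effector" or "target".  With
    ``temporal_close`` single-frame gaps inside a contact run are closed
    (off by default)."""
    effectors = [tr for tr in tracks
                 if cell_types.get(tr.cell_id) == "effector"]
    targets = [tr for tr in tracks
               if cell_types.get(tr.cell_id) == "target"]
    records = []
    for e in effectors:
        e_by_frame = {p.frame: p for p in e.points}
        for g in targets:
            g_by_frame = {p.frame: p for p in g.points}
            frames = sorted(set(e_by_frame) & set(g_by_frame))
            flags = []
            for t in frames:
                flags.append(detect_contact(e_by_frame[t].get_mask(),
                                            g_by_frame[t].get_mask(),
                                            gap_px=gap_px))
            flags = np.array(flags, dtype=bool)
            if temporal_close and len(flags) > 2:
                interior = flags[:-2] & ~flags[1:-1] & flags[2:]
                flags[1:-1] |= interior
            for t, v in zip(frames, flags):
                records.append(ContactRecord(well_id=well_id,
                                             effector_id=e.cell_id,
                                             target_id=g.cell_id,
                                             frame=t, in_contact=bool(v)))
    return records


def gt_contact_records(gt: GroundTruthWell, well_id: str = "well") -> list:
    records = []
    for (i, j), series in gt.contacts.items():
        for t, v in enumerate(series):
            records.append(ContactRecord(well_id=well_id, effector_id=i,
                                         target_id=j, frame=t,
                                         in_contact=bool(v)))
    return records


def contact_confusion(pred_records, gt_records):
    """Row-normalized confusion of frame-wise contact calls.

    Records are aligned on (well, effector, target, frame); a key mismatch
    is an error.  Returns a dict with TN/FP/FN/TP percentages (rows
    normalized within true-negative and true-positive frames) and the
    frame-weighted overall accuracy.
    """
    pred = {r.key: r.in_contact for r in pred_records}
    gt = {r.key: r.in_contact for r in gt_records}
    common = set(pred) & set(gt)
    if len(common) != len(pred) or len(common) != len(gt):
        raise ValueError("prediction and ground-truth records do not align")
    tp = tn = fp = fn = 0
    for k in common:
        p, g = pred[k], gt[k]
        if g and p:
            tp += 1
        elif g and not p:
            fn += 1
        elif not g and p:
            fp += 1
        else:
            tn += 1
    neg = tn + fp
    pos = tp + fn
    return {
        "tn_pct": 100.0 * tn / neg if neg else float("nan"),
        "fp_pct": 100.0 * fp / neg if neg else float("nan"),
        "fn_pct": 100.0 * fn / pos if pos else float("nan"),
        "tp_pct": 100.0 * tp / pos if pos else float("nan"),
        "accuracy": (tp + tn) / len(common) if common else float("nan"),
        "counts": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def _contact_intervals(records):
    """Collapse frame-wise records into (effector, target, start, end)."""
    by_pair = {}
    for r in records:
        by_pair.setdefault((r.effector_id, r.target_id), []).append(r)
    intervals = []
    for (e, g), rs in sorted(by_pair.items()):
        rs.sort(key=lambda r: r.frame)
        start = None
        prev = None
        for r in rs:
            if r.in_contact and start is None:
                start = r.frame
            elif not r.in_contact and start is not None:
                intervals.append((e, g, start, prev))
                start = None
            prev = r.frame
        if start is not None:
            intervals.append((e, g, start, prev))
    return intervals


@dataclass
class PipelineConfig:
    mode: str = "bypass"                 # "bypass" | "model"
    gap_px: int = 1
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seg_model: object = None             # trained LOCSNet (model mode)
    type_model: object = None            # trained CnnLstmClassifier
    apoptosis_model: object = None
    patch_side: int = 32
    seq_len: int = 64
    crop_side: int = 40
    corrupt: Optional[dict] = None       # corruption kwargs in bypass mode


def run_pipeline(wells, config: Optional[PipelineConfig] = None):
    """Analyze a batch of wells end to end.

    ``wells`` is a list of ``(WellVideo, GroundTruthWell | None)`` pairs.
    In bypass mode the ground-truth masks are fed to the tracker (with
    optional detection corruption); in model mode the segmentation model
    produces detections and the classifier/apoptosis models annotate the
    tracks.  Per-well failures are logged and skipped; the batch never
    aborts.  Returns a dict with summaries, per-well tracks, contact
    records and (where ground truth is available) MOTA and contact
    metrics.
    """
    cfg = config or PipelineConfig()
    if cfg.mode == "model" and cfg.seg_model is None:
        raise ValueError("model mode requires a trained segmentation model")
    summaries, all_tracks, all_contacts, metrics, failures = \
        [], {}, [], {}, []
    for idx, (video, gt) in enumerate(wells):
        well_id = video.well_id if video is not None else f"well_{idx}"
        try:
            result = _run_one(video, gt, cfg, well_id)
        except Exception as exc:                      # noqa: BLE001
            logger.warning("well %s failed: %s", well_id, exc)
            failures.append({"well_id": well_id, "error": str(exc)})
            continue
        summaries.append(result["summary"])
        all_tracks[well_id] = result["tracks"]
        all_contacts.extend(result["contacts"])
        if result.get("mota") is not None:
            metrics.setdefault("mota", {})[well_id] = result["mota"]
        logger.info("well %s: ok (%d tracks)", well_id,
                    len(result["tracks"]))
    return {"summaries": summaries, "tracks": all_tracks,
            "contacts": all_contacts, "metrics": metrics,
            "failures": failures}


def _run_one(video, gt, cfg, well_id):
    from .locsnet import locsnet_forward
    from .seqclass import build_patch_sequence, classify_track
    from .apoptosis import call_death_frame, predict_trace

    if cfg.mode == "bypass":
        if gt is None:
            raise ValueError("bypass mode needs ground truth")
        if cfg.corrupt:
            from .simulate import corrupt_detections
            dets = corrupt_detections(gt, **cfg.corrupt)
        else:
            dets = [gt.detections(t) for t in range(gt.n_frames)]
        n_frames = gt.n_frames
    else:
        dets = [locsnet_forward(cfg.seg_model, video.frames[t].astype(float),
                                frame_index=t)
                for t in range(video.n_frames)]
        n_frames = video.n_frames

    tracks = track_well(dets, cfg.tracking)
    if not tracks:
        raise ValueError("no cells tracked")

    # per-cell type
    cell_types = {}
    if cfg.mode == "bypass":
        # identity-free detections; recover the type by majority mask vote
        for tr in tracks:
            votes = np.zeros(gt.n_cells)
            for p in tr.points:
                m = p.get_mask()
                if p.source != "detected" or m is None:
                    continue
                for i in range(gt.n_cells):
                    inter = np.count_nonzero(gt.masks[p.frame][i] & m)
                    votes[i] += inter
            cell_types[tr.cell_id] = gt.cell_types[int(votes.argmax())] \
                if votes.sum() else "target"
    elif cfg.type_model is not None and video is not None:
        for tr in tracks:
            smp = _track_sample(video, tr, cfg)
            prob, _ = classify_track(cfg.type_model, smp)
            cell_types[tr.cell_id] = "effector" if prob >= 0.5 else "target"
    else:
        cell_types = {tr.cell_id: "target" for tr in tracks}

    # apoptosis
    death_frames = {}
    if cfg.apoptosis_model is not None and video is not None:
        for tr in tracks:
            smp = _track_sample(video, tr, cfg)
            trace = predict_trace(cfg.apoptosis_model, smp)
            death_frames[tr.cell_id] = call_death_frame(trace)
    elif cfg.mode == "bypass" and gt is not None:
        pass    # ground-truth death frames live in gt; not re-derived here

    contacts = contact_records(tracks, cell_types, well_id=well_id,
                               gap_px=cfg.gap_px)
    n_eff = sum(1 for v in cell_types.values() if v == "effector")
    summary = WellSummary(
        well_id=well_id,
        n_effectors=n_eff,
        n_targets=len(cell_types) - n_eff,
        cell_types=dict(cell_types),
        death_frames=death_frames,
        contact_intervals=_contact_intervals(contacts),
        n_frames=n_frames,
    )
    mota = None
    if gt is not None:
        mota = compute_mota(tracks, gt, cfg.tracking).mota
    return {"summary": summary, "tracks": tracks, "contacts": contacts,
            "mota": mota}


def _track_sample(video, track: Track, cfg):
    from .seqclass import build_patch_sequence

    centroids = track.centroids()
    masks = [p.get_mask() for p in track.points]
    return build_patch_sequence(video.frames, centroids, masks,
                                patch_side=cfg.patch_side,
                                seq_len=cfg.seq_len,
                                crop_side=cfg.crop_side,
                                cell_id=track.cell_id)
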