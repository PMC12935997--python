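"""Standard-format I/O: multi-page TIFF stacks, CSV tables, YAML configs,
JSON metrics."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruthWell, SimConfig, WellVideo

__all__ = [
    "save_well_video", "load_well_video",
    "save_label_stack", "load_label_stack",
    "save_ground_truth", "save_sim_config", "load_sim_config",
    "tracks_to_dataframe", "save_tracks_csv", "load_tracks_csv",
    "contacts_to_dataframe", "save_metrics_json",
]


def save_well_video(path, video: WellVideo):
    tifffile.imwrite(str(path), video.frames.astype(np.float32),
                     metadata={"axes": "TYX",
                               "frame_interval_min": video.frame_interval_min,
                               "pixel_size_um": video.pixel_size_um,
                               "well_id": video.well_id})


def load_well_video(path, frame_interval_min: float = 5.0,
                    pixel_size_um: float = 0.65) -> WellVideo:
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    return WellVideo(frames=frames.astype(np.float32),
                     frame_interval_min=float(meta.get("frame_interval_min",
                                                       frame_interval_min)),
                     pixel_size_um=float(meta.get("pixel_size_um",
                                                  pixel_size_um)),
                     well_id=str(meta.get("well_id", Path(path).stem)))


def save_label_stack(path, labels: np.ndarray):
    tifffile.imwrite(str(path), labels.astype(np.uint16),
                     metadata={"axes": "TYX"})


def load_label_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.uint16)


def save_ground_truth(outdir, gt: GroundTruthWell, well_id: str = "well"):
    """Label stack + per-cell metadata CSV + per-frame contact CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_label_stack(outdir / f"{well_id}_labels.tif", gt.labels)
    cells = pd.DataFrame({
        "cell_id": np.arange(gt.n_cells),
        "cell_type": gt.cell_types,
        "death_frame": [(-1 if d is None else d) for d in gt.death_frames],
    })
    cells.to_csv(outdir / f"{well_id}_cells.csv", index=False)
    rows = []
    for (i, j), series in gt.contacts.items():
        for t, v in enumerate(series):
            rows.append({"effector_id": i, "target_id": j, "frame": t,
                         "in_contact": int(v)})
    pd.DataFrame(rows).to_csv(outdir / f"{well_id}_contacts.csv", index=False)


def save_sim_config(path, config: SimConfig):
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    clean = {}
    for k, v in raw.items():
        if k not in fields:
            raise ValueError(f"unknown simulation parameter {k!r}")
        clean[k] = tuple(v) if isinstance(v, list) else v
    return SimConfig(**clean)


def tracks_to_dataframe(tracks, well_id: str = "well") -> pd.DataFrame:
    rows = []
    for tr in tracks:
        refined = tr.refined
        for k, p in enumerate(tr.points):
            mask = p.get_mask()
            rows.append({
                "well_id": well_id,
                "cell_id": tr.cell_id,
                "frame": p.frame,
                "row": float(p.centroid[0]),
                "col": float(p.centroid[1]),
                "row_refined": float(refined[k][0]) if refined is not None
                else float(p.centroid[0]),
                "col_refined": float(refined[k][1]) if refined is not None
                else float(p.centroid[1]),
                "source": p.source,
                "area": int(mask.sum()) if mask is not None else 0,
            })
    return pd.DataFrame(rows)


def save_tracks_csv(path, tracks, well_id: str = "well"):
    tracks_to_dataframe(tracks, well_id).to_csv(path, index=False)


def load_tracks_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def contacts_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def save_metrics_json(path, metrics: dict):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, default=default)
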