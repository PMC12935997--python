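"""Array-to-well conversion: locate nanowells in array-level frame stacks
and extract per-well movies.

Raw fields of view contain many wells; downstream analysis operates on one
well at a time.  The pipeline is: rim detection on the first frame (here a
normalized cross-correlation ring-template detector; the interface admits
a learned detector), non-maximum suppression, robust lattice fitting with
synthesis of boxes at sites that lost their candidate, per-frame rigid
shift estimation against frame 0, and centered square crops with a
persistent well identifier.  Crops that would fall partially outside the
frame (partial-rim wells) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from skimage.registration import phase_cross_correlation

from .simulate import WellVideo

__all__ = [
    "GridModel",
    "detect_well_rims",
    "nms",
    "fit_lattice",
    "propagate_and_crop",
    "box_iou",
]


@dataclass
class GridModel:
    """A fitted rectangular well lattice.

    Boxes are half-open ``[r0, r1) x [c0, c1)`` in 0-based (row, col)
    coordinates.  ``shifts`` holds the per-frame global rigid shift
    relative to frame 0 once ``propagate_and_crop`` has estimated it.
    """

    row_pitch: float
    col_pitch: float
    origin: tuple                       # (row, col) of site (0, 0) center
    rotation_rad: float
    box_side: int
    n_rows: int
    n_cols: int
    occupied: list = field(default_factory=list)   # (i, j) site indices
    shifts: list = field(default_factory=list)     # per-frame (dr, dc)

    def site_center(self, i: int, j: int):
        ca, sa = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        dr = i * self.row_pitch
        dc = j * self.col_pitch
        return (self.origin[0] + ca * dr - sa * dc,
                self.origin[1] + sa * dr + ca * dc)

    def site_box(self, i: int, j: int):
        r, c = self.site_center(i, j)
        h = self.box_side / 2.0
        r0 = int(round(r - h))
        c0 = int(round(c - h))
        return (r0, c0, r0 + self.box_side, c0 + self.box_side)


def box_iou(a, b) -> float:
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[2], b[2])
    c1 = min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def _ring_template(well_side: int, shape: str = "circle") -> np.ndarray:
    """Dark-rim template matching the rendered well boundary."""
    s = well_side + 6
    c = (s - 1) / 2.0
    radius = well_side / 2.0 - 1.5
    rr, cc = np.mgrid[0:s, 0:s]
    if shape == "circle":
        d = np.hypot(rr - c, cc - c) - radius
    else:
        d = np.maximum(np.abs(rr - c), np.abs(cc - c)) - radius
    t = np.zeros((s, s))
    t[(d > 0) & (d <= 1.8)] = -1.0       # dark rim
    t[(d > -1.2) & (d <= 0)] = 0.4       # bright inner edge
    return t - t.mean()


def detect_well_rims(frame: np.ndarray, well_side: int = 80,
                     shape: str = "circle", score_threshold: float = 0.5,
                     max_wells: int = 10_000) -> list:
    """Candidate well boxes from one array frame.

    Normalized cross-correlation against a rim template; peaks above
    ``score_threshold`` become boxes with scores in [0, 1].  An empty or
    constant frame yields no candidates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or np.ptp(frame) < 1e-12:
        return []
    templ = _ring_template(well_side, shape)
    if frame.shape[0] < templ.shape[0] or frame.shape[1] < templ.shape[1]:
        return []
    resp = match_template(frame, templ, pad_input=True)
    peaks = peak_local_max(resp, min_distance=max(3, well_side // 3),
                           threshold_abs=score_threshold,
                           num_peaks=max_wells)
    out = []
    h = well_side / 2.0
    for (pr, pc) in peaks:
        score = float(np.clip(resp[pr, pc], 0.0, 1.0))
        r0 = int(round(pr - h))
        c0 = int(round(pc - h))
        out.append({"box": (r0, c0, r0 + well_side, c0 + well_side),
                    "score": score})
    return out


def nms(candidates: list, iou_threshold: float = 0.5) -> list:
    """Greedy score-descending non-maximum suppression."""
    ordered = sorted(candidates, key=lambda c: -c["score"])
    kept = []
    for cand in ordered:
        if all(box_iou(cand["box"], k["box"]) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept


def fit_lattice(candidates: list, box_side: int = None) -> GridModel:
    """Robust least-squares fit of a rectangular lattice to candidate boxes.

    Requires candidates spanning at least 2 rows and 2 columns; collinear
    candidate sets are rejected.  Sites missing a candidate get synthesized
    boxes; sites with no candidate nearby are flagged unoccupied
    (``GridModel.occupied`` lists sites that had a supporting candidate).
    """
    if len(candidates) < 4:
        raise ValueError("need at least 4 candidates to fit a lattice")
    centers = np.array([[(b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0]
                        for b in (c["box"] for c in candidates)])
    if box_side is None:
        b = candidates[0]["box"]
        box_side = int(round(b[2] - b[0]))

    # initial pitch estimates from sorted coordinate gaps
    def pitch_1d(vals):
        v = np.sort(vals)
        gaps = np.diff(v)
        gaps = gaps[gaps > box_side * 0.4]
        if len(gaps) == 0:
            return None
        return float(np.median(gaps))

    row_pitch = pitch_1d(centers[:, 0])
    col_pitch = pitch_1d(centers[:, 1])
    if row_pitch is None or col_pitch is None:
        raise ValueError("degenerate (collinear) candidate set")

    # two rounds of index assignment + linear least squares
    origin = centers.min(axis=0)
    rotation = 0.0
    for _ in range(2):
        ca, sa = np.cos(rotation), np.sin(rotation)
        rel = centers - origin
        # rotate back into lattice frame
        rr = ca * rel[:, 0] + sa * rel[:, 1]
        cc = -sa * rel[:, 0] + ca * rel[:, 1]
        ii = np.round(rr / row_pitch).astype(int)
        jj = np.round(cc / col_pitch).astype(int)
        ii -= ii.min()
        jj -= jj.min()
        if ii.max() == 0 or jj.max() == 0:
            raise ValueError("degenerate (collinear) candidate set")
        # model: center = origin + R(theta) @ (i*pr, j*pc); linearize with
        # small-angle theta around 0: unknowns origin_r, origin_c, pr, pc, th
        A = np.zeros((2 * len(centers), 5))
        y = np.zeros(2 * len(centers))
        for k in range(len(centers)):
            A[2 * k] = [1, 0, ii[k], 0, -jj[k] * col_pitch]
            A[2 * k + 1] = [0, 1, 0, jj[k], ii[k] * row_pitch]
            y[2 * k] = centers[k, 0]
            y[2 * k + 1] = centers[k, 1]
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        origin = np.array([sol[0], sol[1]])
        row_pitch, col_pitch = float(sol[2]), float(sol[3])
        rotation = float(sol[4])
        if abs(rotation) > 0.1:
            raise ValueError(f"implausible lattice rotation {rotation:.3f} rad")

    n_rows = int(ii.max()) + 1
    n_cols = int(jj.max()) + 1
    grid = GridModel(row_pitch=row_pitch, col_pitch=col_pitch,
                     origin=(float(origin[0]), float(origin[1])),
                     rotation_rad=rotation, box_side=box_side,
                     n_rows=n_rows, n_cols=n_cols)
    grid.occupied = sorted({(int(i), int(j)) for i, j in zip(ii, jj)})
    return grid


def _crop(frame, box):
    r0, c0, r1, c1 = box
    return frame[r0:r1, c0:c1]


def _has_cell_blob(crop: np.ndarray, min_area: int = 30) -> bool:
    """Occupied-well proxy: a size-plausible dark-or-bright blob inside."""
    inner = crop[4:-4, 4:-4]
    if inner.size == 0:
        return False
    med = np.median(inner)
    mad = np.median(np.abs(inner - med)) + 1e-6
    mask = np.abs(inner - med) > 6 * mad
    mask = ndimage.binary_opening(mask, iterations=1)
    labels, n = ndimage.label(mask)
    if n == 0:
        return False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=range(1, n + 1))
    return bool(np.max(sizes) >= min_area)


def propagate_and_crop(array_video: np.ndarray, grid: GridModel,
                       frame_interval_min: float = 5.0,
                       pixel_size_um: float = 0.65,
                       occupancy_filter: bool = False) -> list:
    """Cut per-well movies out of an array stack.

    The global rigid shift of every frame is estimated against frame 0 by
    phase cross-correlation and applied to all boxes; wells whose shifted
    box leaves the frame at any time are discarded (partial-rim wells), and
    each kept well receives a persistent identifier ``well_r{i}c{j}``.
    With ``occupancy_filter`` wells without a size-plausible blob in frame
    0 are skipped.
    """
    T = array_video.shape[0]
    ref = array_video[0]
    shifts = [(0.0, 0.0)]
    for t in range(1, T):
        shift, _err, _phase = phase_cross_correlation(ref, array_video[t],
                                                      upsample_factor=4,
                                                      normalization=None)
        # shift maps frame t onto ref; boxes move by the negative
        dr, dc = -float(shift[0]), -float(shift[1])
        if abs(dr) > grid.row_pitch / 2 or abs(dc) > grid.col_pitch / 2:
            raise RuntimeError(
                f"registration failure at frame {t}: shift ({dr:.1f},{dc:.1f})"
                f" exceeds half a pitch")
        shifts.append((dr, dc))
    grid.shifts = shifts

    H, W = array_video.shape[1:]
    wells = []
    for (i, j) in (grid.occupied or
                   [(a, b) for a in range(grid.n_rows)
                    for b in range(grid.n_cols)]):
        base = grid.site_box(i, j)
        boxes = []
        ok = True
        for t in range(T):
            dr, dc = shifts[t]
            r0 = int(round(base[0] + dr))
            c0 = int(round(base[1] + dc))
            box = (r0, c0, r0 + grid.box_side, c0 + grid.box_side)
            if box[0] < 0 or box[1] < 0 or box[2] > H or box[3] > W:
                ok = False          # partial-rim well: discard
                break
            boxes.append(box)
        if not ok:
            continue
        if occupancy_filter and not _has_cell_blob(_crop(array_video[0],
                                                         boxes[0])):
            continue
        frames = np.stack([_crop(array_video[t], boxes[t])
                           for t in range(T)])
        wells.append({
            "well_id": f"well_r{i}c{j}",
            "site": (i, j),
            "boxes": boxes,
            "video": WellVideo(frames=frames.astype(np.float32),
                               frame_interval_min=frame_interval_min,
                               pixel_size_um=pixel_size_um,
                               well_id=f"well_r{i}c{j}"),
        })
    return wells
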