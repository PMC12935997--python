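"""Containment-constrained multi-object cell tracking for nanowell videos.

Three-step tracker exploiting the nanowell containment prior (cell count is
constant over a video barring mitosis/apoptosis):

1. frame-to-frame linking by the Hungarian algorithm on a four-term cost —
   squared centroid displacement, squared deviation from a short-horizon
   velocity estimate, a mask-IoU reward, and a fixed identity-switch
   penalty applied to post-contact links inconsistent with extrapolation;
   links are computed in the forward and reverse time directions and
   disagreements flagged provisional;
2. recovery of missed detections by minimizing the sum of squared
   velocities subject to equality anchors at detected centroids (a convex
   quadratic whose solution is piecewise-linear interpolation with
   constant end extension), solved by a banded linear system;
3. per-track global refinement balancing velocity-change smoothness,
   acceleration and fidelity to the provisional trajectory, another
   unconstrained convex quadratic solved in closed form; provisional
   (forward/reverse-inconsistent) links are reconciled by comparing the
   refined objective of the two link hypotheses.

Evaluation follows the CLEAR-MOT protocol: MOTA = 1 - (FP+FN+IDSW)/GT.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.linalg import solveh_banded
from scipy.optimize import linear_sum_assignment

from .simulate import Detection, GroundTruthWell

__all__ = [
    "TrackingParams",
    "TrackPoint",
    "Track",
    "MotaReport",
    "estimate_velocity",
    "pairwise_cost",
    "link_frames",
    "interpolate_gaps",
    "refine_tracks",
    "refine_objective",
    "track_well",
    "compute_mota",
]


@dataclass
class TrackingParams:
    """Weights and thresholds of the three-step tracker.

    ``lambda_switch`` defaults to the empirically fixed penalty of ~100
    used in production nanowell tracking.
    """

    lambda_vel: float = 1.0       # weight on velocity-consistency term
    beta_iou: float = 300.0       # px^2 reward for centroid-aligned mask IoU
    lambda_switch: float = 100.0  # post-contact inconsistency penalty
    velocity_horizon: int = 3     # frames for the short-horizon estimate
    lambda_smooth: float = 1.0    # Step-3 velocity-change weight
    alpha_acc: float = 1.0        # Step-3 acceleration weight
    alpha_fid: float = 10.0       # Step-3 fidelity weight
    contact_gap_px: int = 1       # boundary distance defining "in contact"
    mota_match_iou: float = 0.5
    mota_match_dist_px: float = 10.0
    gate_px: float = 60.0         # max distance of a link from extrapolation
    gate_growth_px: float = 10.0  # gate widening per frame of track gap
    switch_margin_px: float = 4.0 # slack before a link counts as inconsistent
    beta_continuity: float = 150.0  # in-contact raw-overlap continuity reward
    ambiguity_margin: float = 30.0  # cost gap under which a link is provisional
    recon_window: int = 5         # reconciliation evidence window (frames)
    recon_bend_weight: float = 0.002  # bend weight in reconciliation score

    def __post_init__(self):
        for name in ("lambda_vel", "beta_iou", "lambda_switch",
                     "lambda_smooth", "alpha_acc", "alpha_fid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.velocity_horizon < 1:
            raise ValueError("velocity_horizon must be >= 1")


@dataclass
class TrackPoint:
    frame: int
    centroid: np.ndarray                 # (row, col)
    source: str                          # "detected" | "interpolated"
    detection: Optional[Detection] = None
    mask: Optional[np.ndarray] = None    # synthetic mask for interpolated pts
    isolated: bool = True                # detection not touching another one

    def get_mask(self):
        if self.detection is not None:
            return self.detection.mask
        return self.mask


@dataclass
class Track:
    """One cell's trajectory; frames strictly increasing."""

    cell_id: int
    points: list = field(default_factory=list)
    refined: Optional[np.ndarray] = None   # (len(points), 2) smoothed centroids

    @property
    def frames(self):
        return [p.frame for p in self.points]

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.points], dtype=float)

    def point_at(self, frame):
        for p in self.points:
            if p.frame == frame:
                return p
        return None


@dataclass
class MotaReport:
    fp: np.ndarray        # per-frame counts
    fn: np.ndarray
    idsw: np.ndarray
    n_gt: int             # total ground-truth object-frames
    mota: float


def mask_iou(a: Optional[np.ndarray], b: Optional[np.ndarray]) -> float:
    if a is None or b is None:
        return 0.0
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    union = np.count_nonzero(a | b)
    return inter / union


def shape_iou(a: Optional[np.ndarray], b: Optional[np.ndarray],
              centroid_a=None, centroid_b=None) -> float:
    """IoU of two masks after aligning their centroids (pure shape
    similarity, independent of displacement).

    This is the shape term of the linking cost: centroid displacement is
    already charged by the distance terms, so the mask term should compare
    morphology.  A large sluggish target and a small effector then remain
    distinguishable even when a cell moves farther than its own diameter
    between frames.
    """
    if a is None or b is None:
        return 0.0
    if centroid_a is None:
        centroid_a = np.array(ndimage.center_of_mass(a)) if a.any() else None
    if centroid_b is None:
        centroid_b = np.array(ndimage.center_of_mass(b)) if b.any() else None
    if centroid_a is None or centroid_b is None:
        return 0.0
    delta = np.asarray(centroid_a, float) - np.asarray(centroid_b, float)
    dr, dc = int(round(delta[0])), int(round(delta[1]))
    H, W = b.shape
    shifted = np.zeros_like(b)
    rs, re = max(0, dr), min(H, H + dr)
    cs, ce = max(0, dc), min(W, W + dc)
    if rs < re and cs < ce:
        shifted[rs:re, cs:ce] = b[rs - dr:re - dr, cs - dc:ce - dc]
    return mask_iou(a, shifted)


def masks_in_contact(a, b, gap_px=1) -> bool:
    if a is None or b is None or not a.any() or not b.any():
        return False
    if (a & b).any():
        return True
    if gap_px <= 0:
        return False
    struct = ndimage.generate_binary_structure(2, 2)
    dil = ndimage.binary_dilation(a, structure=struct, iterations=int(gap_px))
    return bool((dil & b).any())


# ---------------------------------------------------------------------------
# Step 1: pairwise costs + Hungarian linking
# ---------------------------------------------------------------------------

def estimate_velocity(track: Track, horizon: int) -> np.ndarray:
    """Mean displacement (px/frame) over the last ``horizon`` links."""
    pts = track.points
    if len(pts) < 2:
        return np.zeros(2)
    n_links = min(horizon, len(pts) - 1)
    a = pts[-1 - n_links]
    b = pts[-1]
    span = b.frame - a.frame
    if span <= 0:
        return np.zeros(2)
    return (np.asarray(b.centroid, float) - np.asarray(a.centroid, float)) / span


def pairwise_cost(p_i, p_j, v_hat, params: TrackingParams,
                  mask_i=None, mask_j=None, i_switch: bool = False,
                  gap: int = 1, mask_i_centroid=None) -> float:
    """Four-term linking cost between detection i at t and j at t+gap.

    ``mask_i``/``mask_i_centroid`` may refer to an earlier (pre-contact)
    detection of the same cell when its current mask is entangled with a
    neighbour; by default the shape term compares the masks at hand.
    """
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    v_hat = np.asarray(v_hat, float)
    disp = p_j - p_i
    v_ij = disp / max(gap, 1)
    cost = float(disp @ disp)
    cost += params.lambda_vel * float((v_hat - v_ij) @ (v_hat - v_ij))
    ca = p_i if mask_i_centroid is None else mask_i_centroid
    cost -= params.beta_iou * shape_iou(mask_i, mask_j, ca, p_j)
    if i_switch:
        cost += params.lambda_switch
    return cost


def _assignment_margin(cost: np.ndarray, pairs: dict) -> float:
    """Gap between the optimal assignment total and the best alternative
    assignment (exhaustive; N < 5 per the containment setting)."""
    from itertools import permutations
    n, m = cost.shape
    best = sum(cost[i, j] for i, j in pairs.items())
    second = np.inf
    if n <= m:
        for perm in permutations(range(m), n):
            total = sum(cost[i, perm[i]] for i in range(n))
            if any(pairs.get(i) != perm[i] for i in range(n)):
                second = min(second, total)
    else:
        for perm in permutations(range(n), m):
            total = sum(cost[perm[j], j] for j in range(m))
            if any(pairs.get(perm[j]) != j for j in range(m)):
                second = min(second, total)
    return float(second - best)


def _shape_reference(track: Track) -> TrackPoint:
    """Last detection made while the cell was isolated (masks of touching
    cells are entangled, so the pre-contact appearance is the reliable
    shape anchor); falls back to the last point."""
    for p in reversed(track.points):
        if p.source == "detected" and p.isolated:
            return p
    return track.points[-1]


def _frame_isolation(dets, gap_px):
    """Per-detection flag: not touching (within gap_px of) any other one."""
    n = len(dets)
    iso = [True] * n
    for i in range(n):
        for j in range(i + 1, n):
            if masks_in_contact(dets[i].mask, dets[j].mask, gap_px):
                iso[i] = iso[j] = False
    return iso


def _switch_flags(tracks, dets_next, params):
    """I_switch(i, j): the identity-swap penalty fires on the links most at
    risk after a contact event -- track i is currently in contact with
    another track, candidate j has *separated* (is isolated again), and j
    lies farther from track i's velocity-extrapolated position than the
    nearest candidate by more than ``switch_margin_px``.  During sustained
    conjugation (candidate still entangled) extrapolation is unreliable
    and no penalty is applied."""
    n, m = len(tracks), len(dets_next)
    flags = np.zeros((n, m), dtype=bool)
    if m == 0 or n == 0:
        return flags
    last_masks = [tr.points[-1].get_mask() for tr in tracks]
    in_contact = np.zeros(n, dtype=bool)
    for i in range(n):
        for k in range(n):
            if k != i and masks_in_contact(last_masks[i], last_masks[k],
                                           params.contact_gap_px):
                in_contact[i] = True
                break
    iso_next = _frame_isolation(dets_next, params.contact_gap_px)
    det_pos = np.array([d.centroid for d in dets_next], float)
    for i, tr in enumerate(tracks):
        if not in_contact[i]:
            continue
        v_hat = estimate_velocity(tr, params.velocity_horizon)
        last = tr.points[-1]
        gap = dets_next[0].frame - last.frame if m else 1
        pred = np.asarray(last.centroid, float) + v_hat * max(gap, 1)
        dist = np.linalg.norm(det_pos - pred, axis=1)
        far = dist > dist.min() + params.switch_margin_px
        flags[i, :] = far & np.asarray(iso_next)
    return flags


def link_frames(tracks, dets_next, params: TrackingParams):
    """Optimal one-to-one assignment of active tracks to next-frame
    detections; returns (pairs, provisional) where ``pairs`` maps track
    index -> detection index and ``provisional`` flags links on which the
    velocity-informed (forward) and proximity-only (reverse-role) matchings
    disagree."""
    n, m = len(tracks), len(dets_next)
    if n == 0 or m == 0:
        return {}, set()
    cost = np.zeros((n, m))
    prox = np.zeros((n, m))
    switch = _switch_flags(tracks, dets_next, params)
    last_masks = [tr.points[-1].get_mask() for tr in tracks]
    in_contact = [any(k != i and masks_in_contact(last_masks[i],
                                                  last_masks[k],
                                                  params.contact_gap_px)
                      for k in range(n))
                  for i in range(n)]
    for i, tr in enumerate(tracks):
        last = tr.points[-1]
        v_hat = estimate_velocity(tr, params.velocity_horizon)
        gap = dets_next[0].frame - last.frame
        ref = _shape_reference(tr)
        mi, ci = ref.get_mask(), ref.centroid
        for j, d in enumerate(dets_next):
            cost[i, j] = pairwise_cost(last.centroid, d.centroid, v_hat,
                                       params, mask_i=mi, mask_j=d.mask,
                                       i_switch=switch[i, j], gap=gap,
                                       mask_i_centroid=ci)
            if in_contact[i]:
                # inside a conjugation, follow the same segmented blob:
                # raw overlap with the track's current mask is the only
                # stable per-frame cue there
                cost[i, j] -= params.beta_continuity * mask_iou(
                    last_masks[i], d.mask)
            prox[i, j] = pairwise_cost(last.centroid, d.centroid,
                                       np.zeros(2),
                                       replace(params, lambda_vel=0.0,
                                               lambda_switch=0.0),
                                       mask_i=mi, mask_j=d.mask, gap=gap,
                                       mask_i_centroid=ci)
    rows, cols = linear_sum_assignment(cost)
    pairs = dict(zip(rows.tolist(), cols.tolist()))
    # reverse-role matching (roles swapped: assign detections to tracks on
    # the velocity-free cost); disagreements are flagged provisional
    r2, c2 = linear_sum_assignment(prox.T)
    rev = {int(c): int(r) for r, c in zip(r2.tolist(), c2.tolist())}
    provisional = {i for i, j in pairs.items() if rev.get(i) != j}
    # near-ties between the optimal and the runner-up assignment are also
    # provisional: the sequence-level reconciliation decides those
    if min(n, m) >= 2 and _assignment_margin(cost, pairs) < \
            params.ambiguity_margin:
        provisional |= set(pairs)
    # gate: drop links far from the velocity-extrapolated position
    for i in list(pairs):
        tr = tracks[i]
        last = tr.points[-1]
        v_hat = estimate_velocity(tr, params.velocity_horizon)
        gap = dets_next[pairs[i]].frame - last.frame
        pred = np.asarray(last.centroid, float) + v_hat * max(gap, 1)
        gate = params.gate_px + params.gate_growth_px * (max(gap, 1) - 1)
        if np.linalg.norm(dets_next[pairs[i]].centroid - pred) > gate:
            del pairs[i]
            provisional.discard(i)
    return pairs, provisional


# ---------------------------------------------------------------------------
# Step 2: convex minimum-velocity gap interpolation
# ---------------------------------------------------------------------------

def _min_velocity_fill(frames_all, anchor_frames, anchor_pos):
    """Minimize sum ||p_{t+1}-p_t||^2 with equality anchors; banded solve."""
    T = len(frames_all)
    idx = {f: k for k, f in enumerate(frames_all)}
    anchored = np.zeros(T, bool)
    vals = np.zeros((T, 2))
    for f, p in zip(anchor_frames, anchor_pos):
        anchored[idx[f]] = True
        vals[idx[f]] = p
    free = np.where(~anchored)[0]
    if len(free) == 0:
        return vals
    # normal equations of the chain Laplacian restricted to free nodes
    nfree = len(free)
    pos_of = {t: k for k, t in enumerate(free)}
    diag = np.zeros(nfree)
    off = np.zeros(nfree)           # upper off-diagonal (k, k+1)
    rhs = np.zeros((nfree, 2))
    for k, t in enumerate(free):
        deg = (1 if t > 0 else 0) + (1 if t < T - 1 else 0)
        diag[k] = deg
        for nb in (t - 1, t + 1):
            if 0 <= nb < T:
                if anchored[nb]:
                    rhs[k] += vals[nb]
                elif nb == t + 1:
                    off[k] = -1.0
    if nfree < 3:
        A = np.diag(diag)
        for k in range(nfree - 1):
            A[k, k + 1] = A[k + 1, k] = off[k]
        sol = np.linalg.solve(A, rhs)
    else:
        ab = np.zeros((2, nfree))
        ab[0, 1:] = off[:-1]
        ab[1] = diag
        sol = solveh_banded(ab, rhs)
    vals[free] = sol
    return vals


def _shift_mask(mask: np.ndarray, delta) -> np.ndarray:
    dr, dc = int(round(delta[0])), int(round(delta[1]))
    out = np.zeros_like(mask)
    H, W = mask.shape
    rs, re = max(0, dr), min(H, H + dr)
    cs, ce = max(0, dc), min(W, W + dc)
    out[rs:re, cs:ce] = mask[rs - dr:re - dr, cs - dc:ce - dc]
    return out


def interpolate_gaps(tracks, frame_range=None):
    """Make each track gap-free over the full frame range (Step 2).

    Interior gaps become the minimum-velocity (piecewise linear)
    interpolation between flanking anchors; leading/trailing missing frames
    extend the nearest anchor.  Inserted points are flagged
    ``interpolated`` and carry a synthetic mask: the nearest detected mask
    translated to the interpolated centroid.  Tracks with zero detections
    are dropped.
    """
    out = []
    if frame_range is None:
        lo = min((tr.points[0].frame for tr in tracks if tr.points),
                 default=0)
        hi = max((tr.points[-1].frame for tr in tracks if tr.points),
                 default=0)
        frame_range = (lo, hi + 1)
    frames_all = list(range(frame_range[0], frame_range[1]))
    for tr in tracks:
        det_pts = [p for p in tr.points if p.source == "detected"]
        if not det_pts:
            continue
        anchor_frames = [p.frame for p in det_pts]
        anchor_pos = [np.asarray(p.centroid, float) for p in det_pts]
        filled = _min_velocity_fill(frames_all, anchor_frames, anchor_pos)
        by_frame = {p.frame: p for p in det_pts}
        med_area = float(np.median([np.count_nonzero(p.get_mask())
                                    for p in det_pts
                                    if p.get_mask() is not None] or [0]))
        new_points = []
        for k, f in enumerate(frames_all):
            if f in by_frame:
                new_points.append(by_frame[f])
            else:
                # source mask: among the nearest anchors, prefer the one
                # whose area is closest to the track's median (avoids
                # propagating a badly eroded/dilated segmentation)
                near = sorted(det_pts, key=lambda p: abs(p.frame - f))[:2]
                nearest = min(
                    near,
                    key=lambda p: (abs(p.frame - f) > min(
                        abs(q.frame - f) for q in near) + 1,
                        abs(np.count_nonzero(p.get_mask()) - med_area)
                        if p.get_mask() is not None else 1e9))
                nmask = nearest.get_mask()
                smask = None
                if nmask is not None:
                    smask = _shift_mask(nmask,
                                        filled[k] - np.asarray(nearest.centroid))
                new_points.append(TrackPoint(frame=f, centroid=filled[k],
                                             source="interpolated",
                                             mask=smask))
        out.append(Track(cell_id=tr.cell_id, points=new_points))
    return out


# ---------------------------------------------------------------------------
# Step 3: global quadratic trajectory refinement
# ---------------------------------------------------------------------------

def _second_difference(T):
    if T < 3:
        return np.zeros((0, T))
    D = np.zeros((T - 2, T))
    for k in range(T - 2):
        D[k, k:k + 3] = (1.0, -2.0, 1.0)
    return D


def refine_objective(p: np.ndarray, p_bar: np.ndarray,
                     params: TrackingParams) -> float:
    """Smoothness + fidelity objective of the Step-3 quadratic."""
    p = np.asarray(p, float)
    p_bar = np.asarray(p_bar, float)
    w = params.lambda_smooth + params.alpha_acc
    obj = params.alpha_fid * float(np.sum((p - p_bar) ** 2))
    if len(p) >= 3:
        d2 = p[:-2] - 2 * p[1:-1] + p[2:]
        obj += w * float(np.sum(d2 ** 2))
    return obj


def _refine_positions(p_bar: np.ndarray, params: TrackingParams) -> np.ndarray:
    """Closed-form minimizer of the Step-3 quadratic (pentadiagonal solve)."""
    T = len(p_bar)
    w = params.lambda_smooth + params.alpha_acc
    if T < 3 or w == 0:
        return p_bar.copy()
    if params.alpha_fid == 0:
        raise ValueError("alpha_fid must be > 0 for a unique refinement")
    # A = w D2^T D2 + alpha_fid I, SPD banded with bandwidth 2
    D = _second_difference(T)
    A = w * (D.T @ D) + params.alpha_fid * np.eye(T)
    ab = np.zeros((3, T))
    for k in range(3):
        ab[2 - k, k:] = np.diagonal(A, offset=k)
    return solveh_banded(ab, params.alpha_fid * p_bar, lower=False)


def refine_tracks(tracks, params: TrackingParams):
    """Step 3: per-track refinement; stores smoothed centroids in
    ``track.refined`` (measured centroids and masks are kept)."""
    out = []
    for tr in tracks:
        p_bar = tr.centroids()
        refined = _refine_positions(p_bar, params)
        out.append(Track(cell_id=tr.cell_id, points=tr.points,
                         refined=refined))
    return out


# ---------------------------------------------------------------------------
# full tracker
# ---------------------------------------------------------------------------

def _sweep(dets_per_frame, order, params):
    """One directional Step-1 sweep over ``order`` (any frame visit order).

    Linking runs in virtual time (the position within ``order``), so
    forward and reverse sweeps are exactly symmetric -- velocity estimates
    and extrapolation work identically in both directions.  Returns
    (tracks with real frame indices, per-transition links keyed by real
    (t_from, t_to), provisional transition set).
    """
    from dataclasses import replace as _dc_replace

    vdets = []
    for k, t in enumerate(order):
        vdets.append([_dc_replace(d, frame=k) for d in dets_per_frame[t]])
    iso_by_k = [_frame_isolation(dets_per_frame[t], params.contact_gap_px)
                for t in order]
    tracks = [Track(cell_id=k, points=[TrackPoint(frame=0,
                                                  centroid=d.centroid,
                                                  source="detected",
                                                  detection=d,
                                                  isolated=iso_by_k[0][k])])
              for k, d in enumerate(vdets[0])]
    links = {}          # (t_from, t_to) -> {det_idx_from: det_idx_to}
    provisional = set()
    last_det_index = {id(tr): i for i, tr in enumerate(tracks)}
    last_det_frame = {id(tr): 0 for tr in tracks}
    for kprev in range(len(order) - 1):
        kcur = kprev + 1
        dets = vdets[kcur]
        active = [tr for tr in tracks if tr.points]
        pairs, prov = link_frames(active, dets, params)
        tr_links = {}
        for i, j in pairs.items():
            tr = active[i]
            tr.points.append(TrackPoint(frame=kcur,
                                        centroid=dets[j].centroid,
                                        source="detected",
                                        detection=dets[j],
                                        isolated=iso_by_k[kcur][j]))
            if last_det_frame[id(tr)] == kprev:
                tr_links[last_det_index[id(tr)]] = j
            last_det_index[id(tr)] = j
            last_det_frame[id(tr)] = kcur
        links[(order[kprev], order[kcur])] = tr_links
        if prov:
            provisional.add((order[kprev], order[kcur]))
    # map virtual time back to real frames and original detections
    for tr in tracks:
        for p in tr.points:
            k = p.frame
            t = order[k]
            p.frame = t
            if p.detection is not None:
                p.detection = dets_per_frame[t][
                    next(jj for jj, d in enumerate(vdets[k])
                         if d is p.detection)]
        tr.points.sort(key=lambda p: p.frame)
    return tracks, links, provisional


def track_well(dets_per_frame, params: Optional[TrackingParams] = None):
    """Track one well's detections through Steps 1-3.

    ``dets_per_frame`` is a list (length T) of lists of ``Detection``.  The
    expected cell count N is the mode of per-frame detection counts
    (containment constraint); frames with fewer detections leave gaps that
    Step 2 interpolates, surplus detections are left unlinked.  Returns a
    list of gap-free ``Track`` spanning the full frame range, with
    persistent ids and refined centroids.
    """
    if params is None:
        params = TrackingParams()
    T = len(dets_per_frame)
    if T < 2:
        raise ValueError("need at least 2 frames")
    counts = [len(d) for d in dets_per_frame]
    if max(counts, default=0) == 0:
        return []
    n_expected = Counter(c for c in counts if c > 0).most_common(1)[0][0]
    # start at the first frame with the modal count
    t0 = next(t for t in range(T) if counts[t] == n_expected)

    fwd_order = list(range(t0, T)) + []
    tracks, fwd_links, fwd_prov = _sweep(dets_per_frame, fwd_order, params)

    # head of the video before t0: a backward sweep, stitched on by the
    # shared detections at t0
    if t0 > 0:
        head_tracks, _, _ = _sweep(dets_per_frame, list(range(t0, -1, -1)),
                                   params)
        det_to_main = {}
        for tr in tracks:
            p0 = next((p for p in tr.points if p.frame == t0), None)
            if p0 is not None and p0.detection is not None:
                det_to_main[id(p0.detection)] = tr
        for htr in head_tracks:
            pt0 = next((p for p in htr.points if p.frame == t0), None)
            if pt0 is None or pt0.detection is None:
                continue
            main = det_to_main.get(id(pt0.detection))
            if main is None:
                continue
            head_pts = [p for p in htr.points if p.frame < t0]
            main.points = sorted(head_pts + main.points,
                                 key=lambda p: p.frame)

    # reverse sweep over the main range to expose inconsistencies
    rev_order = list(range(T - 1, t0 - 1, -1))
    t_last = next(t for t in rev_order if counts[t] == n_expected)
    rev_order = [t for t in rev_order if t <= t_last]
    rev_prov_transitions = set()
    rev_links = {}
    if len(rev_order) >= 2:
        _, rlinks, _ = _sweep(dets_per_frame, rev_order, params)
        for (a, b), mp in rlinks.items():       # a > b in time
            rev_links[(b, a)] = {v: k for k, v in mp.items()}
        for key, fmap in fwd_links.items():
            rmap = rev_links.get(key)
            if rmap is None:
                continue
            common = set(fmap) & set(rmap)
            if any(fmap[k] != rmap[k] for k in common):
                rev_prov_transitions.add(key)

    disputed = sorted(fwd_prov | rev_prov_transitions)

    tracks = [tr for tr in tracks if tr.points]
    full = interpolate_gaps(tracks, frame_range=(0, T))

    # Step-3 reconciliation: for each disputed transition, compare the kept
    # links against the tail-swap hypothesis by local trajectory-bend
    # energy around the transition; swap only on a clear margin.
    for (ta, tb) in disputed:
        frame_of = {tr.cell_id: {p.frame: k for k, p in enumerate(tr.points)}
                    for tr in full}
        involved = [tr for tr in full
                    if tb in frame_of[tr.cell_id] and ta in frame_of[tr.cell_id]]
        if len(involved) < 2:
            continue
        for a in range(len(involved)):
            for b in range(a + 1, len(involved)):
                t1, t2 = involved[a], involved[b]
                k1 = frame_of[t1.cell_id][tb]
                k2 = frame_of[t2.cell_id][tb]
                p1 = t1.points[:k1] + t2.points[k2:]
                p2 = t2.points[:k2] + t1.points[k1:]
                w = params.recon_window
                kb = params.recon_bend_weight
                base = (_hypothesis_score(t1.points, k1, w, kb)
                        + _hypothesis_score(t2.points, k2, w, kb))
                swapped = (_hypothesis_score(p1, k1, w, kb)
                           + _hypothesis_score(p2, k2, w, kb))
                if swapped < base - 0.05:
                    t1.points, t2.points = p1, p2
                    frame_of = {tr.cell_id:
                                {p.frame: k for k, p in enumerate(tr.points)}
                                for tr in full}
    return refine_tracks(full, params)


def _hypothesis_score(points, k, w, bend_weight=0.002):
    """Reconciliation evidence for a link hypothesis in a window of +/- w
    points around index k: shape discontinuity (1 - aligned mask IoU per
    consecutive pair) plus a small trajectory-bend tie-breaker for wells
    whose cells are morphologically alike."""
    lo = max(0, k - w)
    hi = min(len(points), k + w + 1)
    seg = points[lo:hi]
    score = 0.0
    for p_prev, p_next in zip(seg[:-1], seg[1:]):
        score += 1.0 - shape_iou(p_prev.get_mask(), p_next.get_mask(),
                                 p_prev.centroid, p_next.centroid)
    pos = np.array([p.centroid for p in seg], float)
    if len(pos) >= 3:
        d2 = pos[:-2] - 2 * pos[1:-1] + pos[2:]
        score += bend_weight * float(np.sum(d2 ** 2))
    return score


# ---------------------------------------------------------------------------
# CLEAR-MOT evaluation
# ---------------------------------------------------------------------------

def compute_mota(tracks, gt: GroundTruthWell,
                 params: Optional[TrackingParams] = None) -> MotaReport:
    """CLEAR-MOT accounting of FP, FN and identity switches against the
    simulator ground truth.  Correspondence per frame by mask IoU >=
    ``mota_match_iou`` (centroid distance <= ``mota_match_dist_px`` when
    either mask is absent); established correspondences persist while they
    remain valid."""
    if params is None:
        params = TrackingParams()
    T = gt.n_frames
    n_gt_cells = gt.n_cells
    if n_gt_cells == 0:
        raise ValueError("empty ground truth")
    fp = np.zeros(T, int)
    fn = np.zeros(T, int)
    idsw = np.zeros(T, int)
    last_match = {}          # gt cell -> track id of last correspondence
    track_pts = [{p.frame: p for p in tr.points} for tr in tracks]

    for t in range(T):
        preds = [(tr.cell_id, track_pts[k].get(t))
                 for k, tr in enumerate(tracks)]
        preds = [(cid, p) for cid, p in preds if p is not None]
        n_pred = len(preds)
        # affinity matrix: valid pairs only
        aff = np.full((n_gt_cells, n_pred), -1.0)
        for gi in range(n_gt_cells):
            gmask = gt.masks[t][gi]
            gpos = gt.centroids[t, gi]
            for pj, (cid, pt) in enumerate(preds):
                # measured (detected) masks are compared by IoU; recovered
                # points carry only a synthetic stand-in mask and are
                # assessed positionally, like point predictions in MOT
                pmask = pt.get_mask() if pt.detection is not None else None
                if pmask is not None and gmask.any():
                    iou = mask_iou(gmask, pmask)
                    if iou >= params.mota_match_iou:
                        aff[gi, pj] = iou
                else:
                    dist = np.linalg.norm(gpos - np.asarray(pt.centroid))
                    if dist <= params.mota_match_dist_px:
                        aff[gi, pj] = 1.0 / (1.0 + dist)
        matched_g, matched_p = set(), set()
        matches = {}
        # persist previous correspondences when still valid
        for gi in range(n_gt_cells):
            cid_prev = last_match.get(gi)
            if cid_prev is None:
                continue
            for pj, (cid, _pt) in enumerate(preds):
                if cid == cid_prev and aff[gi, pj] > 0 and pj not in matched_p:
                    matches[gi] = pj
                    matched_g.add(gi)
                    matched_p.add(pj)
                    break
        # optimal assignment on the remainder
        rem_g = [g for g in range(n_gt_cells) if g not in matched_g]
        rem_p = [p for p in range(n_pred) if p not in matched_p]
        if rem_g and rem_p:
            sub = aff[np.ix_(rem_g, rem_p)]
            cost = np.where(sub > 0, -sub, 1e6)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if sub[r, c] > 0:
                    matches[rem_g[r]] = rem_p[c]
                    matched_g.add(rem_g[r])
                    matched_p.add(rem_p[c])
        for gi, pj in matches.items():
            cid = preds[pj][0]
            if gi in last_match and last_match[gi] != cid:
                idsw[t] += 1
            last_match[gi] = cid
        fn[t] = n_gt_cells - len(matches)
        fp[t] = n_pred - len(matches)
    n_gt_total = n_gt_cells * T
    mota = 1.0 - (fp.sum() + fn.sum() + idsw.sum()) / n_gt_total
    return MotaReport(fp=fp, fn=fn, idsw=idsw, n_gt=n_gt_total,
                      mota=float(mota))
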