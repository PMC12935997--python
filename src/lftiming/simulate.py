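"""Synthetic nanowell video generator with full ground truth.

Emulates the imaging regime of time-lapse imaging microscopy in nanowell
grids (TIMING): small cohorts of effector and target cells confined in a
nanoliter well, imaged in phase contrast every few minutes for hours.
Every downstream stage (well cropping, segmentation, tracking,
classification, apoptosis calling, contact analysis) is testable against
the generator's exact ground truth: per-frame instance masks with
persistent identities, cell types, death frames and contact intervals.

Motion is a persistent (Ornstein-Uhlenbeck) random walk reflected at the
well boundary.  The ``*_speed_um_min`` parameters set the *effective
frame-scale* speed: the mean net centroid displacement per frame equals
``speed * frame_interval_min / pixel_size_um`` pixels.  Confined
lymphocytes turn on sub-frame time scales, so their net displacement per
multi-minute frame is far below the instantaneous path speed; the
generator parameterizes the quantity the tracker actually sees.

Rendering is deliberately phase-contrast-like rather than optics-accurate:
dark deformed-ellipse interiors, a bright halo ring, a low-order
illumination gradient, additive Gaussian noise, and a visible well rim.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SimConfig",
    "Detection",
    "WellVideo",
    "GroundTruthWell",
    "ArraySim",
    "simulate_well",
    "simulate_array",
    "corrupt_detections",
]

EFFECTOR = "effector"
TARGET = "target"


@dataclass
class SimConfig:
    """Parameters of one simulated nanowell video.

    All randomness is drawn from ``seed``; identical configs produce
    bit-identical outputs.
    """

    well_shape: str = "circle"          # "circle" | "square"
    well_size_px: int = 80              # crop side length
    n_effectors: int = 1
    n_targets: int = 1
    n_frames: int = 72                  # 6 h at 5-min intervals
    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.65
    # effective frame-scale speeds (um/min); net step = speed*interval/pixel
    effector_speed_um_min: tuple = (0.6, 1.2)
    target_speed_um_min: tuple = (0.2, 0.5)
    effector_persistence: float = 0.7   # OU mean-reversion in [0, 1)
    target_persistence: float = 0.3
    effector_radius_px: tuple = (6.0, 0.6)   # (mean, sd); ~8 um diameter
    target_radius_px: tuple = (9.0, 0.9)     # ~12 um diameter
    apoptosis_prob: float = 0.0         # per-target probability of death
    apoptosis_onset_window: tuple = (20, 50)
    apoptosis_area_factor: float = 0.7
    apoptosis_roughness_factor: float = 3.0
    apoptosis_speed_factor: float = 0.15
    apoptosis_intensity_shift: float = 0.10
    halo_width_px: float = 2.0
    noise_sd: float = 0.03
    illum_gradient_amp: float = 0.05
    boundary_pert_amp: float = 0.08     # Fourier boundary roughness
    n_crossings: int = 0                # scripted effector-through-target passes
    crossing_occlusion_frames: int = 1  # frames of strong mask overlap per pass
    render: bool = True                 # False skips pixel rendering of the video
    seed: int = 0

    def validate(self) -> None:
        if self.n_effectors < 0 or self.n_targets < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for rng in (self.effector_speed_um_min, self.target_speed_um_min):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"speed range must be positive and ordered: {rng}")
        for p in (self.effector_persistence, self.target_persistence):
            if not (0.0 <= p < 1.0):
                raise ValueError("persistence must lie in [0, 1)")
        if self.well_shape not in ("circle", "square"):
            raise ValueError(f"unknown well_shape {self.well_shape!r}")
        # unresolvable crowding: reject if total cell area > 60% of well area
        mean_area = (self.n_effectors * np.pi * self.effector_radius_px[0] ** 2
                     + self.n_targets * np.pi * self.target_radius_px[0] ** 2)
        if self.well_shape == "circle":
            well_area = np.pi * (self.well_size_px / 2.0) ** 2
        else:
            well_area = float(self.well_size_px) ** 2
        if mean_area > 0.6 * well_area:
            raise ValueError(
                f"total cell area {mean_area:.0f} px^2 exceeds 60% of well area "
                f"{well_area:.0f} px^2"
            )


@dataclass(eq=False)
class Detection:
    """One segmented instance in one frame (no identity)."""

    frame: int
    mask: np.ndarray          # bool (H, W)
    centroid: np.ndarray      # (row, col), float
    area: int = 0
    score: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.area == 0:
            self.area = int(self.mask.sum())


@dataclass
class WellVideo:
    """One nanowell's phase-contrast frame stack with calibration."""

    frames: np.ndarray        # float32 (T, H, W) in [0, 1]
    frame_interval_min: float
    pixel_size_um: float
    well_id: str = "well_0"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruthWell:
    """Simulator-emitted ground truth for one well.

    ``masks[t][i]`` is the full-extent boolean mask of cell ``i`` at frame
    ``t`` (occluded parts included; masks of different cells may overlap).
    ``labels`` is the z-ordered 16-bit label stack (smaller cells drawn on
    top); instance ids are ``i + 1``.
    """

    masks: list                       # [T][n_cells] bool arrays
    labels: np.ndarray                # uint16 (T, H, W)
    cell_types: list                  # n_cells strings
    death_frames: list                # n_cells Optional[int]
    centroids: np.ndarray             # float (T, n_cells, 2) (row, col)
    contacts: dict                    # {(i_eff, j_tgt): bool array (T,)}
    well_mask: np.ndarray             # bool (H, W) interior of the well

    @property
    def n_cells(self) -> int:
        return len(self.cell_types)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def detections(self, frame: int) -> list:
        """Ground-truth masks of one frame as identity-free detections."""
        out = []
        for i in range(self.n_cells):
            m = self.masks[frame][i]
            out.append(Detection(frame=frame, mask=m,
                                 centroid=self.centroids[frame, i].copy()))
        return out


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

@dataclass
class _Cell:
    kind: str
    base_radius: float
    aspect: float            # minor/major axis ratio
    step_len: float          # mean net displacement per frame (px)
    persistence: float
    death_frame: Optional[int]
    pert_phases: np.ndarray  # Fourier boundary phases (k = 2..5)
    pert_amps: np.ndarray
    orient0: float
    orient_rate: float

    def radius_at(self, t: int, cfg: SimConfig) -> float:
        r = self.base_radius
        if self.death_frame is not None and t >= self.death_frame:
            r *= np.sqrt(cfg.apoptosis_area_factor)
        return r

    def roughness_at(self, t: int, cfg: SimConfig) -> np.ndarray:
        a = self.pert_amps
        if self.death_frame is not None and t >= self.death_frame:
            a = a * cfg.apoptosis_roughness_factor
        return a


def _well_geometry(cfg: SimConfig):
    s = cfg.well_size_px
    c = (s - 1) / 2.0
    if cfg.well_shape == "circle":
        radius = s / 2.0 - 1.5
    else:
        radius = s / 2.0 - 1.5
    return np.array([c, c]), radius


def _well_mask(cfg: SimConfig) -> np.ndarray:
    s = cfg.well_size_px
    center, radius = _well_geometry(cfg)
    rr, cc = np.mgrid[0:s, 0:s]
    if cfg.well_shape == "circle":
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    return (np.abs(rr - center[0]) <= radius) & (np.abs(cc - center[1]) <= radius)


def _reflect(pos, vel, center, bound, shape):
    """Reflect a position (and its velocity) back inside the well."""
    if shape == "circle":
        d = pos - center
        r = np.hypot(*d)
        if r > bound:
            u = d / r
            pos = center + u * (2 * bound - r)
            vel = vel - 2 * np.dot(vel, u) * u
            d2 = pos - center
            r2 = np.hypot(*d2)
            if r2 > bound:          # pathological overshoot: clamp
                pos = center + d2 / r2 * bound
    else:
        for ax in range(2):
            lo, hi = center[ax] - bound, center[ax] + bound
            if pos[ax] < lo:
                pos[ax] = 2 * lo - pos[ax]
                vel[ax] = -vel[ax]
            elif pos[ax] > hi:
                pos[ax] = 2 * hi - pos[ax]
                vel[ax] = -vel[ax]
            pos[ax] = min(max(pos[ax], lo), hi)
    return pos, vel


def _make_cells(cfg: SimConfig, rng: np.random.Generator) -> list:
    cells = []
    scale = cfg.frame_interval_min / cfg.pixel_size_um
    for kind, n in ((EFFECTOR, cfg.n_effectors), (TARGET, cfg.n_targets)):
        if kind == EFFECTOR:
            rmean, rsd = cfg.effector_radius_px
            smin, smax = cfg.effector_speed_um_min
            pers = cfg.effector_persistence
        else:
            rmean, rsd = cfg.target_radius_px
            smin, smax = cfg.target_speed_um_min
            pers = cfg.target_persistence
        for _ in range(n):
            death = None
            if kind == TARGET and rng.random() < cfg.apoptosis_prob:
                lo, hi = cfg.apoptosis_onset_window
                hi = min(hi, cfg.n_frames - 1)
                lo = min(lo, hi)
                death = int(rng.integers(lo, hi + 1))
            cells.append(_Cell(
                kind=kind,
                base_radius=max(2.5, rng.normal(rmean, rsd)),
                aspect=rng.uniform(0.75, 0.95),
                step_len=rng.uniform(smin, smax) * scale,
                persistence=pers,
                death_frame=death,
                pert_phases=rng.uniform(0, 2 * np.pi, 4),
                pert_amps=cfg.boundary_pert_amp * rng.uniform(0.5, 1.0, 4)
                / np.arange(2, 6),
                orient0=rng.uniform(0, np.pi),
                orient_rate=rng.normal(0, 0.05),
            ))
    return cells


def _visibility_floor(a: _Cell, b: _Cell, t: int, cfg: SimConfig) -> float:
    # centers apart enough that the smaller cell always shows a sliver in
    # the z-ordered label image (count conservation by construction)
    ra, rb = a.radius_at(t, cfg), b.radius_at(t, cfg)
    return abs(ra - rb) * (1.0 + cfg.boundary_pert_amp) + 3.0


def _min_separation(a: _Cell, b: _Cell, t: int, cfg: SimConfig) -> float:
    # conjugating cells abut and deform rather than interpenetrate: cap
    # sustained overlap at ~30% of the radius sum.  Scripted crossings
    # relax this to the visibility floor to produce genuine occlusions.
    ra, rb = a.radius_at(t, cfg), b.radius_at(t, cfg)
    return max(_visibility_floor(a, b, t, cfg), 0.72 * (ra + rb))


def _push_apart(positions, cells, t, cfg, center, bound, relaxed=()):
    """Resolve pairwise center collisions, weighted by cell size so that
    a small effector yields to a large target rather than displacing it.
    Pairs in ``relaxed`` (scripted occlusions) only keep the visibility
    floor and may overlap deeply."""
    n = len(cells)
    for _ in range(4):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in relaxed or (j, i) in relaxed:
                    dmin = _visibility_floor(cells[i], cells[j], t, cfg)
                else:
                    dmin = _min_separation(cells[i], cells[j], t, cfg)
                d = positions[j] - positions[i]
                dist = np.hypot(*d)
                if dist < dmin:
                    moved = True
                    if dist < 1e-9:
                        ang = 2.399963 * (i * n + j)   # deterministic direction
                        d = np.array([np.cos(ang), np.sin(ang)])
                        dist = 1.0
                    ri2 = cells[i].base_radius ** 2
                    rj2 = cells[j].base_radius ** 2
                    wi = rj2 / (ri2 + rj2)             # lighter cell yields more
                    gap = (dmin - dist) * d / dist
                    positions[i] -= wi * gap
                    positions[j] += (1.0 - wi) * gap
                    for k in (i, j):
                        positions[k], _ = _reflect(
                            positions[k], np.zeros(2), center, bound, cfg.well_shape)
        if not moved:
            break
    return positions


@dataclass
class _Crossing:
    eff: int
    tgt: int
    anchor: np.ndarray        # target position at window start
    u: np.ndarray             # crossing direction
    u_perp: np.ndarray
    offsets: np.ndarray       # along-u offsets from the anchor, per frame
    impact: float             # perpendicular impact parameter (px)
    k: int = 0
    age: int = 0

    @property
    def done(self):
        # stall guard: a pass that cannot complete (wall, blocking cell)
        # is abandoned rather than pinning the pair indefinitely
        return self.k >= len(self.offsets) or self.age > len(self.offsets) + 6


def _plan_crossing(cfg, cells, e, g, p_in, tgt_pos):
    sep = _visibility_floor(cells[e], cells[g], 0, cfg)
    d_vec = tgt_pos - p_in
    dist = np.hypot(*d_vec)
    if dist < sep + 4:
        return None
    u = d_vec / dist
    occl = max(1, cfg.crossing_occlusion_frames)
    n_app = max(1, int(np.ceil((dist - sep) / 10.0)))
    approach = np.linspace(-dist, -sep, n_app + 1)[1:]
    dwell = np.linspace(-0.5 * sep, 0.5 * sep, occl)
    leave = sep + np.arange(1, 3) * 9.0
    offsets = np.concatenate([approach, dwell, leave])
    return _Crossing(eff=e, tgt=g, anchor=tgt_pos.copy(), u=u,
                     u_perp=np.array([-u[1], u[0]]),
                     offsets=offsets, impact=0.45 * sep)


def _simulate_trajectories(cfg: SimConfig, rng: np.random.Generator):
    """OU trajectories with optional in-loop scripted effector-through-
    target crossings; returns cells, centroids (T, n, 2).

    Scripted crossings steer an effector through a target along a line
    with a small impact parameter (so centers never coincide), with the
    target sluggish during conjugation.  All motion is integrated frame by
    frame -- scripting changes the effector's velocity, never teleports it,
    and ordinary OU motion resumes from the exit state.
    """
    cells = _make_cells(cfg, rng)
    n = len(cells)
    T = cfg.n_frames
    center, well_radius = _well_geometry(cfg)
    pos = np.zeros((T, n, 2))
    if n == 0:
        return cells, pos

    margin = np.array([c.base_radius * (1 + cfg.boundary_pert_amp) + 1.0
                       for c in cells])
    bounds = well_radius - margin

    # initial positions: uniform in the allowed disk/square, pushed apart
    cur = np.zeros((n, 2))
    for i in range(n):
        while True:
            p = center + (rng.uniform(-1, 1, 2)) * bounds[i]
            if cfg.well_shape == "square" or np.hypot(*(p - center)) <= bounds[i]:
                cur[i] = p
                break
    cur = _push_apart(cur, cells, 0, cfg, center, float(bounds.min()))
    pos[0] = cur

    # crossing schedule: start times only; geometry resolved at trigger time
    eff_idx = [i for i, c in enumerate(cells) if c.kind == EFFECTOR]
    tgt_idx = [i for i, c in enumerate(cells) if c.kind == TARGET]
    schedule = {}
    if cfg.n_crossings > 0 and eff_idx and tgt_idx:
        t_next = 6
        for _ in range(cfg.n_crossings):
            if t_next + 10 >= T:
                break
            schedule[t_next] = (int(rng.choice(eff_idx)),
                                int(rng.choice(tgt_idx)))
            t_next += max(1, cfg.crossing_occlusion_frames) + 12 \
                + int(rng.integers(0, 6))

    # OU velocity: v_t = rho v_{t-1} + sqrt(1-rho^2) sigma eta,
    # stationary E||v|| = sigma*sqrt(pi/2) = step_len
    sigma = np.array([c.step_len / np.sqrt(np.pi / 2.0) for c in cells])
    rho = np.array([c.persistence for c in cells])
    cap = 2.2 * np.array([c.step_len for c in cells])
    vel = rng.normal(0, 1, (n, 2)) * sigma[:, None]

    crossing = None
    dead_factor = np.ones(n)
    for t in range(1, T):
        for i, c in enumerate(cells):
            if c.death_frame is not None and t >= c.death_frame:
                dead_factor[i] = cfg.apoptosis_speed_factor
        eta = rng.normal(0, 1, (n, 2))
        vel = rho[:, None] * vel \
            + np.sqrt(1 - rho[:, None] ** 2) * sigma[:, None] * eta
        # biophysical cap: net frame displacement cannot greatly exceed the
        # cell's typical step (truncates the OU Rayleigh tail)
        speed = np.hypot(vel[:, 0], vel[:, 1])
        over = speed > cap
        if over.any():
            vel[over] *= (cap[over] / speed[over])[:, None]

        if crossing is None and t in schedule:
            e, g = schedule[t]
            crossing = _plan_crossing(cfg, cells, e, g, cur[e], cur[g])
        if crossing is not None:
            e, g = crossing.eff, crossing.tgt
            crossing.age += 1
            # home on the target's current position, projected inside the
            # effector's allowed region so the pass can always complete
            desired = (cur[g]
                       + crossing.offsets[crossing.k] * crossing.u
                       + crossing.impact * crossing.u_perp)
            dc = desired - center
            rdc = np.hypot(*dc)
            if cfg.well_shape == "circle" and rdc > bounds[e]:
                desired = center + dc * (bounds[e] / rdc)
            else:
                desired = np.clip(desired, center - bounds[e],
                                  center + bounds[e])
            step_e = desired - cur[e]
            d = np.hypot(*step_e)
            if d > 14.0:                       # keep the approach physical
                step_e *= 14.0 / d
            else:
                crossing.k += 1
            vel[e] = step_e
            vel[g] *= 0.3                      # conjugated target is sluggish
            if crossing.done:
                crossing = None

        step = vel * dead_factor[:, None]
        for i in range(n):
            p, v = _reflect(cur[i] + step[i], vel[i], center, bounds[i],
                            cfg.well_shape)
            cur[i], vel[i] = p, v
        relaxed = ()
        if crossing is not None:
            relaxed = ((crossing.eff, crossing.tgt),)
        cur = _push_apart(cur.copy(), cells, t, cfg, center,
                          float(bounds.min()), relaxed=relaxed)
        pos[t] = cur
    return cells, pos


# ---------------------------------------------------------------------------
# mask + image rendering
# ---------------------------------------------------------------------------

def _cell_mask_and_dist(cell: _Cell, pos, t, cfg, shape):
    """Boolean mask of one cell and the signed radial excess (for halo)."""
    r0 = cell.radius_at(t, cfg)
    amps = cell.roughness_at(t, cfg)
    orient = cell.orient0 + cell.orient_rate * t
    rmax = r0 * (1 + amps.sum()) / min(cell.aspect, 1.0) + cfg.halo_width_px + 1
    r_lo = max(int(np.floor(pos[0] - rmax)), 0)
    r_hi = min(int(np.ceil(pos[0] + rmax)) + 1, shape[0])
    c_lo = max(int(np.floor(pos[1] - rmax)), 0)
    c_hi = min(int(np.ceil(pos[1] + rmax)) + 1, shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        z = np.zeros(shape, bool)
        return z, None, (slice(0, 0), slice(0, 0))
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dy = rr - pos[0]
    dx = cc - pos[1]
    ca, sa = np.cos(orient), np.sin(orient)
    # rotate into the ellipse frame, scale the minor axis
    y = (ca * dy + sa * dx)
    x = (-sa * dy + ca * dx) / cell.aspect
    dist = np.hypot(y, x)
    theta = np.arctan2(x, y)
    radius = r0 * (1.0 + sum(a * np.cos(k * theta + ph)
                             for k, a, ph in zip(range(2, 6), amps,
                                                 cell.pert_phases + 0.13 * t)))
    box = (slice(r_lo, r_hi), slice(c_lo, c_hi))
    inside = dist <= radius
    excess = dist - radius           # >0 outside boundary (halo band)
    return inside, excess, box


def _render_frame(cfg, cells, pos_t, t, well_mask, illum, rng):
    s = cfg.well_size_px
    img = np.full((s, s), 0.42, dtype=np.float64)     # outside-well material
    img[well_mask] = 0.55
    # well rim: dark ring just outside the interior
    center, radius = _well_geometry(cfg)
    rr, cc = np.mgrid[0:s, 0:s]
    if cfg.well_shape == "circle":
        d = np.hypot(rr - center[0], cc - center[1]) - radius
    else:
        d = np.maximum(np.abs(rr - center[0]), np.abs(cc - center[1])) - radius
    img[(d > 0) & (d <= 1.8)] = 0.30
    img[(d > -1.2) & (d <= 0)] += 0.10                # bright inner rim edge

    order = np.argsort([-c.base_radius for c in cells])   # big first, small on top
    for i in order:
        cell = cells[i]
        inside, excess, box = _cell_mask_and_dist(cell, pos_t[i], t, cfg,
                                                  (s, s))
        if excess is None:
            continue
        sub = img[box]
        shade = 0.16
        if cell.death_frame is not None and t >= cell.death_frame:
            shade = max(0.02, 0.16 - cfg.apoptosis_intensity_shift)
        interior = sub[inside]
        sub[inside] = 0.55 - shade + 0.06 * np.cos(
            np.pi * np.clip(excess[inside] / -max(cell.base_radius, 1), -1, 0))
        halo = (excess > 0) & (excess <= cfg.halo_width_px)
        sub[halo] = np.maximum(sub[halo],
                               0.55 + 0.22 * (1 - excess[halo] / cfg.halo_width_px))
        img[box] = sub
    img += illum
    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _masks_for_frame(cfg, cells, pos_t, t, well_mask):
    s = cfg.well_size_px
    masks = []
    for i, cell in enumerate(cells):
        inside, _, box = _cell_mask_and_dist(cell, pos_t[i], t, cfg, (s, s))
        m = np.zeros((s, s), bool)
        if box[0].stop > box[0].start:
            m[box] = inside
        m &= well_mask
        masks.append(m)
    return masks


def _contact_pair(mask_a, mask_b, gap_px=1):
    """Overlap, or boundary distance <= gap_px (dilation-intersection)."""
    if not mask_a.any() or not mask_b.any():
        return False
    if (mask_a & mask_b).any():
        return True
    if gap_px <= 0:
        return False
    from scipy import ndimage
    struct = ndimage.generate_binary_structure(2, 2)
    dil = ndimage.binary_dilation(mask_a, structure=struct, iterations=int(gap_px))
    return bool((dil & mask_b).any())


def simulate_well(config: SimConfig):
    """Simulate one nanowell video.

    Returns ``(WellVideo, GroundTruthWell)``.  With ``config.render`` False
    the video frames are an all-zero stack (trajectory/mask ground truth
    only), which is much faster for tracking studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells, pos = _simulate_trajectories(config, rng)
    T, n = config.n_frames, len(cells)
    s = config.well_size_px
    well_mask = _well_mask(config)

    # low-order illumination gradient, fixed over the video
    gx, gy = rng.uniform(-1, 1, 2)
    rr, cc = np.mgrid[0:s, 0:s]
    illum = config.illum_gradient_amp * (
        gx * (cc - s / 2) / s + gy * (rr - s / 2) / s)

    labels = np.zeros((T, s, s), dtype=np.uint16)
    all_masks = []
    frames = np.zeros((T, s, s), dtype=np.float32)
    eff_ids = [i for i, c in enumerate(cells) if c.kind == EFFECTOR]
    tgt_ids = [i for i, c in enumerate(cells) if c.kind == TARGET]
    contacts = {(i, j): np.zeros(T, bool) for i in eff_ids for j in tgt_ids}

    for t in range(T):
        masks = _masks_for_frame(config, cells, pos[t], t, well_mask)
        all_masks.append(masks)
        order = np.argsort([-c.base_radius for c in cells])  # small cells on top
        lab = labels[t]
        for i in order:
            lab[masks[i]] = i + 1
        for (i, j) in contacts:
            contacts[(i, j)][t] = _contact_pair(masks[i], masks[j], gap_px=1)
        if config.render:
            frames[t] = _render_frame(config, cells, pos[t], t, well_mask,
                                      illum, rng)

    video = WellVideo(frames=frames,
                      frame_interval_min=config.frame_interval_min,
                      pixel_size_um=config.pixel_size_um,
                      well_id=f"well_seed{config.seed}")
    gt = GroundTruthWell(
        masks=all_masks,
        labels=labels,
        cell_types=[c.kind for c in cells],
        death_frames=[c.death_frame for c in cells],
        centroids=pos,
        contacts=contacts,
        well_mask=well_mask,
    )
    return video, gt


# ---------------------------------------------------------------------------
# arrays of wells
# ---------------------------------------------------------------------------

@dataclass
class ArraySim:
    """A tiled array of independently simulated wells."""

    video: np.ndarray                 # float32 (T, H, W)
    boxes: list                       # [T][n_wells] (r0, c0, r1, c1) half-open
    pitch: tuple                      # (row_pitch, col_pitch) px
    well_configs: list                # row-major per-well SimConfig
    well_sims: list                   # row-major (WellVideo, GroundTruthWell)
    grid: tuple                       # (rows, cols)
    drift: np.ndarray                 # int (T, 2) cumulative rigid shift


def simulate_array(config: SimConfig, grid_rows: int, grid_cols: int,
                   gutter_px: int = 14, drift=None,
                   occupied=None) -> ArraySim:
    """Tile ``grid_rows x grid_cols`` independently simulated wells.

    ``drift`` is an optional per-frame sequence of cumulative integer rigid
    shifts (row, col), each entry of magnitude <= 2 px relative to its
    predecessor.  ``occupied`` is an optional boolean row-major list; empty
    sites are rendered as cell-free wells.  Per-well seeds are derived from
    ``config.seed``, and the per-well configs are returned so each true box
    crop of an undrifted array equals the standalone ``simulate_well``
    output bit for bit.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dims must be >= 1")
    T = config.n_frames
    s = config.well_size_px
    pitch = s + gutter_px
    if drift is None:
        drift_arr = np.zeros((T, 2), dtype=int)
    else:
        drift_arr = np.asarray(drift, dtype=int)
        if drift_arr.shape != (T, 2):
            raise ValueError("drift must have shape (n_frames, 2)")
    pad = int(np.abs(drift_arr).max()) + gutter_px // 2
    H = grid_rows * pitch + 2 * pad
    W = grid_cols * pitch + 2 * pad

    n_sites = grid_rows * grid_cols
    if occupied is None:
        occupied = [True] * n_sites
    seeds = np.random.SeedSequence(config.seed).generate_state(n_sites) % (2 ** 31)

    well_configs, well_sims = [], []
    for k in range(n_sites):
        cfg_k = replace(config, seed=int(seeds[k]))
        if not occupied[k]:
            cfg_k = replace(cfg_k, n_effectors=0, n_targets=0)
        well_configs.append(cfg_k)
        well_sims.append(simulate_well(cfg_k))

    canvas = np.full((T, H, W), 0.42, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
    canvas += rng.normal(0, config.noise_sd, canvas.shape).astype(np.float32)
    base_boxes = []
    for i in range(grid_rows):
        for j in range(grid_cols):
            r0 = pad + i * pitch + gutter_px // 2
            c0 = pad + j * pitch + gutter_px // 2
            base_boxes.append((r0, c0, r0 + s, c0 + s))
    for k, (vid, _gt) in enumerate(well_sims):
        r0, c0, r1, c1 = base_boxes[k]
        canvas[:, r0:r1, c0:c1] = vid.frames

    video = np.empty_like(canvas)
    boxes = []
    for t in range(T):
        dr, dc = drift_arr[t]
        video[t] = np.roll(canvas[t], (dr, dc), axis=(0, 1))
        boxes.append([(r0 + dr, c0 + dc, r1 + dr, c1 + dc)
                      for (r0, c0, r1, c1) in base_boxes])
    return ArraySim(video=video, boxes=boxes, pitch=(pitch, pitch),
                    well_configs=well_configs, well_sims=well_sims,
                    grid=(grid_rows, grid_cols), drift=drift_arr)


# ---------------------------------------------------------------------------
# detection corruption
# ---------------------------------------------------------------------------

def corrupt_detections(gt: GroundTruthWell, fn_rate: float = 0.0,
                       fp_rate: float = 0.0, merge_rate: float = 0.0,
                       boundary_jitter_px: int = 0, seed: int = 0,
                       merge_contact_only: bool = False) -> list:
    """Degrade ground-truth masks into identity-free per-frame detections.

    Per instance-frame: touching pairs are merged with probability
    ``merge_rate`` (union replaces the pair); survivors are dropped with
    probability ``fn_rate`` and their boundaries eroded/dilated by up to
    ``boundary_jitter_px``; spurious blobs are added at ``fp_rate`` per
    frame.  With all rates zero the output equals the ground truth with
    identities stripped.  ``merge_contact_only`` restricts merges to frames
    where the pair is in ground-truth contact (occlusion-merge stress).
    """
    for r in (fn_rate, fp_rate, merge_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    if boundary_jitter_px < 0:
        raise ValueError("jitter must be >= 0")
    from scipy import ndimage
    struct = ndimage.generate_binary_structure(2, 2)
    rng = np.random.default_rng(seed)
    frames_out = []
    H, W = gt.labels.shape[1:]
    for t in range(gt.n_frames):
        masks = [m.copy() for m in gt.masks[t] if m.any()]
        # merges: union of a touching pair becomes a single detection
        merged = []
        used = set()
        for i in range(len(masks)):
            if i in used:
                continue
            mi = masks[i]
            partner = None
            for j in range(i + 1, len(masks)):
                if j in used:
                    continue
                if _contact_pair(mi, masks[j], gap_px=1):
                    if merge_contact_only and not (mi & masks[j]).any():
                        continue
                    partner = j
                    break
            if partner is not None and rng.random() < merge_rate:
                merged.append(mi | masks[partner])
                used.update((i, partner))
            else:
                merged.append(mi)
                used.add(i)
        dets = []
        for m in merged:
            if rng.random() < fn_rate:
                continue
            if boundary_jitter_px > 0:
                k = int(rng.integers(0, boundary_jitter_px + 1))
                if k > 0:
                    # unit-radius diamond: a faithful 1-px boundary move
                    diamond = ndimage.generate_binary_structure(2, 1)
                    if rng.random() < 0.5:
                        m2 = ndimage.binary_erosion(m, structure=diamond,
                                                    iterations=k)
                        if m2.any():
                            m = m2
                    else:
                        m = ndimage.binary_dilation(m, structure=diamond,
                                                    iterations=k)
            com = ndimage.center_of_mass(m)
            dets.append(Detection(frame=t, mask=m, centroid=np.array(com)))
        n_fp = rng.poisson(fp_rate)
        for _ in range(n_fp):
            r0 = rng.uniform(6, H - 6)
            c0 = rng.uniform(6, W - 6)
            rad = rng.uniform(2.5, 4.5)
            rr, cc = np.mgrid[0:H, 0:W]
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
            blob &= gt.well_mask
            if blob.any():
                dets.append(Detection(frame=t, mask=blob,
                                      centroid=np.array([r0, c0])))
        rng.shuffle(dets)
        frames_out.append(dets)
    return frames_out
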