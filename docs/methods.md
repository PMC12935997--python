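# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and the limits of what the tests demonstrate.

## The synthetic nanowell generator

The generator (`lftiming.simulate`) emulates the data regime of nanowell
cytotoxicity imaging: an 80 px (52 µm at 0.65 µm/px) circular well
imaged every 5 minutes for 72 frames (6 h), holding a configurable
cohort of effectors and targets. It is first-class, tested code: every
downstream stage is validated against its exact ground truth.

**Motion.** Cells follow an Ornstein–Uhlenbeck velocity process
`v_t = ρ v_{t−1} + √(1−ρ²) σ η` reflected at the well wall, with
per-type persistence ρ (effector 0.7, target 0.3). The speed parameters
are *effective frame-scale speeds*: σ is set so the stationary mean step
length equals `speed · frame_interval / pixel_size`. This matters:
lymphocytes move at 5–10 µm/min instantaneous path speed, but their
direction decorrelates on sub-frame time scales, so the net displacement
per 5-minute frame is far below `speed × 5 min` — if it were not,
confined cells would be position-randomized between frames and no
tracker (or human) could maintain identities, contrary to what real
nanowell tracking achieves. Defaults are effector 0.6–1.2 µm/min and
target 0.2–0.5 µm/min effective (≈5–9 and ≈1.5–4 px/frame); the step
length is capped at 2.2× the cell's typical step, truncating the OU
Rayleigh tail at a biophysically plausible bound.

**Geometry and collisions.** Cells are deformed ellipses (low-order
Fourier boundary perturbation, amplitude 8%) with radii drawn from
N(6, 0.6) px for effectors (≈8 µm diameter) and N(9, 0.9) px for
targets (≈12 µm). Conjugating cells abut and deform rather than
interpenetrate: sustained center distance is floored at
0.72·(r_a + r_b) (≈30% maximal overlap), resolved with size-weighted
pushes so a small effector yields to a large target. A second, smaller
floor (|r_a − r_b| + 3 px) guarantees the smaller cell always shows a
sliver in the z-ordered label image, so instance counts are conserved by
construction. Scripted *crossing* events steer an effector through a
target along a line with a small impact parameter, relaxing the overlap
floor to produce genuine occlusions of a configured duration (1–2
frames); scripting is integrated frame by frame (it changes velocities,
never teleports positions) and aborts cleanly at walls.

**Appearance.** Dark cell interior, bright halo ring of configurable
width, visible well rim, low-order illumination gradient, additive
Gaussian noise. Apoptosis (targets only, onset uniform in a configured
window) shrinks the area by ×0.7 (×0.6 in the "strong" setting used for
detector training), triples boundary roughness, darkens the interior
and slows the cell to 15% — a stylized version of blebbing and arrest.
Rendering is deliberately not optics-accurate (no phase PSF); the
fluorescence death marker exists only as a ground-truth onset frame.

**Corruption model.** `corrupt_detections` degrades ground-truth masks
into identity-free detections: independent per-instance drops
(`fn_rate`), union-merges of touching pairs (`merge_rate`, optionally
restricted to contact frames), spurious blobs (`fp_rate`), and boundary
erosion/dilation by up to `boundary_jitter_px`, implemented with a
unit-radius diamond structuring element (a faithful 1-px boundary
move; the 8-connected square would move boundaries by √2 px).

**What this does not show.** Passing tests on this generator demonstrate
algorithmic correctness and robustness to the modelled failure modes;
they do not demonstrate performance on real phase-contrast data, whose
halos, focus drift, debris and texture are richer than the renderer.
Real-data accuracy claims require real annotated corpora, which are out
of scope here.

## Occlusion-aware segmentation

The segmentation model supervises a whole/overlap/complement mask
triplet per instance with three parallel mask heads. The overlap and
complement heads consume the per-ROI feature map `f_ROI`; the
post-activation feature maps of their third convolution layer are summed
elementwise with `f_ROI` to give `f_added`, the whole head's input
(which choice of pre- vs post-activation maps was open; post-activation
is used). Loss weights λ₁=λ₂=λ₃=1 by default. Proposal–truth matching
uses IoU ≥ 0.5 positives and < 0.3 negatives; head resolution is 28×28;
inference thresholds the whole-head probabilities at 0.5 and reports,
per instance, the IoU between the thresholded (overlap ∪ complement)
reconstruction and the whole mask as a consistency diagnostic.

At desk scale the two-stage pipeline is small: region proposals come
from darkness components split at distance-transform peaks (three box
scales per peak; the classification head and NMS prune duplicates), and
per-ROI features from a two-layer trainable CNN on the resized 28×28
crop. This preserves the architecture's substance — triplet
supervision, feature fusion, composite loss — at CPU-trainable size;
the backbone depth is configuration, not architecture. mIoU evaluation
matches predictions to ground-truth instances by optimal assignment,
with unmatched ground truth contributing zero, penalizing both misses
and merges.

## Tracking

Expected count N is the mode of per-frame detection counts (the
containment prior). Step 1 links active tracks to next-frame detections
with the four-term cost; two deliberate interpretations:

- the mask term is **centroid-aligned** IoU (pure shape similarity,
  β_IoU = 300). Raw-overlap IoU is identically zero once a cell moves
  beyond its own diameter in one frame and therefore cannot anchor a
  large, sluggish, shape-stable target against a fast effector's
  breakaway — the exact situation the term exists for. The shape
  reference is the track's last *isolated* detection, because masks of
  touching cells are entangled (this also makes a mis-assignment during
  a conjugation self-correcting). During contact, a raw-overlap
  continuity reward (β = 150) additionally prefers following the same
  segmented blob, the only stable per-frame cue there.
- the switch penalty (λ_switch = 100) fires on *separation* links that
  disagree with velocity extrapolation by more than a 4-px margin.
  Applying it during sustained conjugation, where extrapolation is
  noise, destabilizes the assignment instead of protecting it.

Links where the forward and the reverse-time sweeps disagree, where the
velocity-free proximity matching disagrees, or where the runner-up
assignment is within 30 cost units, are provisional; Step 3 reconciles
them by comparing tail-swap hypotheses on shape continuity plus a small
local trajectory-bend term over a ±5-frame window.

Step 2 (missed-detection recovery) solves min Σ‖p_{t+1} − p_t‖² with
equality anchors at detections — its exact solution is piecewise-linear
interpolation with constant end extension, computed by a banded
(tridiagonal) solve and verified against the closed form to 1e-8.
Step 3 minimizes the smoothness+fidelity quadratic; since the
velocity-change and acceleration terms coincide as second differences,
their weights add, and the minimizer solves a pentadiagonal
symmetric-positive-definite system (verified against dense normal
equations to 1e-6). Defaults: λ_vel = 1, velocity_horizon = 3,
λ_smooth = α_acc = 1, α_fid = 10.

MOTA follows CLEAR-MOT: per-frame correspondence by IoU ≥ 0.5 for
measured masks, with established correspondences persisting while
valid. Interpolated points are assessed positionally (centroid within
10 px): their synthetic translated masks are stand-ins for downstream
patch extraction, not measured segmentations, and scoring them by IoU
would perversely reward trackers that output less.

## Sequence classification and apoptosis

Both tasks share the CNN-LSTM: 3-stage CNN on 4-channel patches →
16-d embedding ⊕ 5 motion descriptors (speed, direction cosine/sine,
acceleration magnitude, signed turning angle; (1, 0) direction
convention at rest, zero-filled first frames) → LSTM (hidden 32).
Cell-type classification maps the last valid hidden state to two logits
and trains with label smoothing 0.1, AdamW + cosine annealing, dropout
0.5 (production default; desk runs use 0.3), optional early-stage
freezing, and k-fold cross-validation stratified by label and *grouped
by well* so no well appears on both sides of a split. Sequences are 64
patches by default (desk tests use the track length), padded by
repeating the last frame with validity flags, subsampled evenly when
longer. Patch side 224 in production geometry; 32–64 at desk scale.
The production learning rate 3e-5 suits large pretrained backbones;
desk-scale runs on the small randomly initialized CNN use 2–3e-3.

Apoptosis uses per-frame heads, class-weighted (inverse-frequency)
binary cross-entropy over valid frames, and the monotonicity penalty
λ Σ max(0, p_t − p_{t+1})² with λ = 1 (squared hinge; zero exactly on
non-decreasing sequences). Death frames are called at threshold 0.5
sustained for k = 2 frames; single-frame blips are not calls. Onset
accuracy is the fraction of cells called within ±4 frames (≈20 min) of
the true onset, with missed calls counting against.

AUROC is the Mann–Whitney rank statistic with tied ranks averaged;
DeLong's test uses structural components with a two-sided normal
p-value, returning (0, 1) for identical score vectors.

## Contact analysis

Effector–target contact at a frame iff masks overlap or their boundary
distance is ≤ 1 px (dilation–intersection test, 8-connected), the same
rule the generator uses for its ground truth — the confusion-matrix
evaluation is therefore self-consistent by design, and the interesting
questions are robustness under boundary jitter (tested at up to ±2 px)
and behavior of model-produced masks. An optional 1-frame temporal
closing is off by default.

## Problem sizes

Study conditions used by the test suite and `scripts/acceptance.py`
(the script's sizes in parentheses where they differ): clean-tracking
accuracy over 100 wells of 72 frames; corrupted-cohort accuracy over 30
(50) wells per E:T configuration; occlusion-merge accuracy over 50
wells; apoptosis training on 120 (200) single-target tracks of 60
frames at 32-px patches with a 30% held-out split; contact accuracy
over 100 wells × 40 frames; segmentation trainings on 48 frames from
crowded 2E:2T wells. Every randomized quantity is seeded; the
acceptance script derives all seeds from its `--seed` argument.

## Known limitations

- The generator's phase-contrast rendering is stylized; models trained
  on it will not transfer to real microscopes.
- Appearance-based re-identification across occlusions longer than two
  frames is out of scope; extended occlusions can still switch
  identities.
- Two same-type cells in prolonged contact are distinguished only by
  kinematic continuity; under heavy segmentation noise some identity
  switches there are irreducible.
- Mitosis is not modelled (counts are constant barring apoptosis).
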