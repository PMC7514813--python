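"""Synthetic 2D articulated walker with exact toe-off ground truth.

Renders a side-view pedestrian — torso, head, and two three-segment
legs (thigh, shank, foot) — walking across a 320x240 frame at 25 fps
with ~1 s gait cycles, as binary silhouettes.  Joint motion is driven
by closed-form periodic trajectories: each leg alternates a stance
phase (foot planted on the ground while the hip advances) and a swing
phase (the ankle follows a smooth forward arc), with the two legs
offset by half a cycle.  Because the foot-contact interval of each leg
is known in continuous time, the instant ``t*`` at which a stance foot
leaves the ground is exact, and the toe-off *frame* is the first frame
after lift-off: ``ceil(t* * frame_rate)``.

Ground contact is defined at the resolution of the rendered video: the
ground line is one pixel thick, and a foot within ``contact_clearance_px``
(default 1) of it counts as touching — a sub-pixel gap does not exist
in a binary silhouette, and labels on real footage are likewise made
from what the video shows.  The lift-off instant is therefore the
closed-form time the swing-height bump crosses that clearance.

A horizontal compression factor emulates oblique viewing angles
(1.0 = lateral view); silhouette degradation (boundary pixel flips,
one-step dilation/erosion) is applied after labeling, from an RNG
stream independent of the kinematics, so toggling noise never moves an
event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import polygon as _draw_polygon

from .csd import stream_csd
from .silhouettes import BinarySilhouette, SilhouetteSequence

__all__ = [
    "WalkerConfig",
    "ToeOffGroundTruth",
    "LabeledDataset",
    "simulate_walker",
    "make_dataset",
]


@dataclass(frozen=True)
class WalkerConfig:
    """Study conditions for one synthetic walking sequence.

    Defaults emulate the capture setup the detector targets: 320x240
    binary silhouettes at 25 fps with a 1 s gait cycle, viewed
    laterally.  ``view_compression`` scales the walker horizontally to
    stand in for oblique camera angles; ``stance_fraction`` is the
    fraction of each leg's cycle spent on the ground (~0.6 in normal
    human gait).  Noise parameters degrade the rendered masks only —
    ground-truth events are computed before degradation.
    """

    image_w: int = 320
    image_h: int = 240
    frame_rate_hz: float = 25.0
    cycle_duration_s: float = 1.0
    n_cycles: int = 3
    thigh_len: float = 32.0
    shank_len: float = 30.0
    foot_len: float = 14.0
    torso_w: float = 22.0
    torso_h: float = 52.0
    head_radius: float = 9.0
    limb_width: float = 7.0
    hip_sway_amplitude: float = 2.0
    step_height: float = 10.0
    contact_clearance_px: float = 1.0
    stance_fraction: float = 0.6
    base_phase: float = 0.27
    phase_jitter: float = 0.1
    size_jitter: float = 0.08
    view_compression: float = 1.0
    boundary_flip_prob: float = 0.02
    dilation_erosion_radius: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz * self.cycle_duration_s < 8:
            raise ValueError(
                "need frame_rate_hz * cycle_duration_s >= 8 frames per cycle "
                f"(got {self.frame_rate_hz * self.cycle_duration_s:.1f})"
            )
        if not 0 < self.view_compression <= 1:
            raise ValueError("view_compression must lie in (0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.2 <= self.stance_fraction <= 0.8:
            raise ValueError("stance_fraction must lie in [0.2, 0.8]")


@dataclass
class ToeOffGroundTruth:
    """Sorted toe-off frame indices with optional left/right labels."""

    toe_off_indices: np.ndarray
    side_labels: list[str] | None = None
    lift_off_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.toe_off_indices = np.asarray(self.toe_off_indices, dtype=np.int64)
        if self.toe_off_indices.size > 1:
            gaps = np.diff(self.toe_off_indices)
            if not np.all(gaps > 0):
                raise ValueError("toe-off indices must be strictly increasing")
            if np.any(gaps < 2):
                raise ValueError(
                    "alternating-feet toe-offs must be >= 2 frames apart"
                )

    def __len__(self) -> int:
        return int(self.toe_off_indices.size)


# -- continuous-time kinematics -------------------------------------------


def _leg_rel_trajectory(s: np.ndarray, f: float, half_stride: float, step_h: float):
    """Ankle position relative to the hip at leg-cycle phase ``s`` in [0,1).

    Stance (s < f): ankle fixed on the ground in world coordinates while
    the hip advances, so the relative x falls linearly +half_stride ->
    -half_stride and the height is 0.  Swing (s >= f): relative x eases
    back with a raised-cosine and the ankle height follows a sine bump
    peaking at ``step_h``.  The height leaves 0 exactly at s = f — the
    lift-off instant — with *nonzero* vertical velocity, as a real foot
    does at toe-off, so the separation is visible from the very first
    airborne frame.
    """
    s = np.asarray(s)
    stance = s < f
    u = np.where(
        stance,
        half_stride * (1.0 - 2.0 * s / f),
        -half_stride + 2.0 * half_stride * 0.5 * (1 - np.cos(np.pi * (s - f) / (1 - f))),
    )
    h = np.where(stance, 0.0, step_h * np.sin(np.pi * (s - f) / (1 - f)))
    return u, h


def _lift_off_times(cfg: WalkerConfig, phase: float, duration: float) -> np.ndarray:
    """All lift-off instants of one leg within [0, duration).

    The ground line has the thickness of one rendered pixel: a foot
    within ``contact_clearance_px`` of it is in contact (a sub-pixel gap
    is not resolvable in a binary silhouette), so the lift-off instant
    is when the sine swing bump first exceeds that clearance —
    ``tau* = asin(clearance / step_height) / pi`` into the swing phase.
    """
    T, f = cfg.cycle_duration_s, cfg.stance_fraction
    frac = min(1.0, cfg.contact_clearance_px / cfg.step_height)
    tau_star = math.asin(frac) / math.pi  # fraction of the swing phase
    offset = f + (1.0 - f) * tau_star
    times = []
    k_min = math.floor(phase - offset) - 1
    for k in range(k_min, cfg.n_cycles + 2):
        t = T * (k + offset - phase)
        if 0 <= t < duration:
            times.append(t)
    return np.array(sorted(times))


def _two_link_ik(
    hip: tuple[float, float], ankle: tuple[float, float], l1: float, l2: float
) -> tuple[float, float]:
    """Knee position for a thigh+shank chain; knee points forward (+x)."""
    dx, dy = ankle[0] - hip[0], ankle[1] - hip[1]
    dist = math.hypot(dx, dy)
    reach = l1 + l2
    if dist > reach - 1e-6:  # clamp: fully extended leg
        scale = (reach - 1e-6) / dist
        dx, dy = dx * scale, dy * scale
        dist = reach - 1e-6
    dist = max(dist, abs(l1 - l2) + 1e-6)
    a = (l1 * l1 - l2 * l2 + dist * dist) / (2 * dist)
    h = math.sqrt(max(l1 * l1 - a * a, 0.0))
    mx, my = hip[0] + a * dx / dist, hip[1] + a * dy / dist
    # two mirror solutions; pick the knee ahead of the hip-ankle line
    k1 = (mx + h * dy / dist, my - h * dx / dist)
    k2 = (mx - h * dy / dist, my + h * dx / dist)
    return k1 if k1[0] >= k2[0] else k2


# -- rasterization ---------------------------------------------------------


def _thick_segment(mask, p0, p1, width, compress, cx):
    """Draw a line segment of the given width as a filled quadrilateral."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    if norm < 1e-9:
        _compressed_disk(mask, p0, width / 2, compress, cx)
        return
    ox, oy = -dy / norm * width / 2, dx / norm * width / 2
    xs = np.array([x0 + ox, x1 + ox, x1 - ox, x0 - ox])
    ys = np.array([y0 + oy, y1 + oy, y1 - oy, y0 - oy])
    xs = cx + (xs - cx) * compress
    rr, cc = _draw_polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = 1
    for p in (p0, p1):  # round caps keep joints connected
        _compressed_disk(mask, p, width / 2, compress, cx)


def _compressed_disk(mask, center, radius, compress, cx):
    x, y = center
    x = cx + (x - cx) * compress
    n = 24
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xs = x + radius * compress * np.cos(ang)
    ys = y + radius * np.sin(ang)
    rr, cc = _draw_polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = 1


def _render_frame(cfg: WalkerConfig, geo: dict, t: float) -> np.ndarray:
    """Rasterize the walker at continuous time ``t`` to a binary mask."""
    T = cfg.cycle_duration_s
    ground_y = geo["ground_y"]
    hip_x = geo["x_start"] + geo["speed"] * t
    hip_x += cfg.hip_sway_amplitude * math.sin(4 * math.pi * t / T)
    hip_y = ground_y - geo["hip_height"]
    mask = np.zeros((cfg.image_h, cfg.image_w), dtype=np.uint8)
    cx = hip_x  # compression pivot: the walker's own axis
    vc = cfg.view_compression
    ankle_rest = geo["ankle_rest"]
    for phase in (geo["phase_a"], geo["phase_b"]):
        s = (t / T + phase) % 1.0
        u, h = _leg_rel_trajectory(
            np.array([s]), cfg.stance_fraction, geo["half_stride"], cfg.step_height
        )
        ankle = (hip_x + float(u[0]), ground_y - ankle_rest - float(h[0]))
        knee = _two_link_ik((hip_x, hip_y), ankle, geo["thigh"], geo["shank"])
        lw = cfg.limb_width
        _thick_segment(mask, (hip_x, hip_y), knee, lw, vc, cx)
        _thick_segment(mask, knee, ankle, lw, vc, cx)
        toe = (ankle[0] + geo["foot"], ankle[1])
        _thick_segment(mask, ankle, toe, lw * 0.8, vc, cx)
    # torso: rectangle from the hip up, overlapping the hip joint
    tw, th = geo["torso_w"], geo["torso_h"]
    xs = np.array([hip_x - tw / 2, hip_x + tw / 2, hip_x + tw / 2, hip_x - tw / 2])
    ys = np.array([hip_y + 6, hip_y + 6, hip_y - th, hip_y - th])
    xs = cx + (xs - cx) * vc
    rr, cc = _draw_polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = 1
    _compressed_disk(
        mask, (hip_x, hip_y - th - geo["head_r"] + 2), geo["head_r"], vc, cx
    )
    return mask


def _degrade(mask: np.ndarray, cfg: WalkerConfig, rng: np.random.Generator) -> np.ndarray:
    out = mask.astype(bool)
    r = cfg.dilation_erosion_radius
    if r > 0:
        structure = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        if rng.random() < 0.5:
            out = binary_dilation(out, structure=structure)
        else:
            eroded = binary_erosion(out, structure=structure)
            if eroded.any():  # never erase the walker entirely
                out = eroded
    p = cfg.boundary_flip_prob
    if p > 0:
        inner = out & ~binary_erosion(out)
        outer = binary_dilation(out) & ~out
        boundary = inner | outer
        flips = boundary & (rng.random(out.shape) < p)
        out = out ^ flips
    return out.astype(np.uint8)


def _geometry(cfg: WalkerConfig, rng: np.random.Generator) -> dict:
    """Resolve per-sequence geometry (with seeded size/phase jitter)."""
    scale = 1.0 + cfg.size_jitter * float(rng.uniform(-1, 1))
    thigh, shank, foot = cfg.thigh_len * scale, cfg.shank_len * scale, cfg.foot_len * scale
    torso_w, torso_h = cfg.torso_w * scale, cfg.torso_h * scale
    head_r = cfg.head_radius * scale
    duration = cfg.n_cycles * cfg.cycle_duration_s
    margin = 0.18 * cfg.image_w
    speed = (cfg.image_w - 2 * margin) / duration
    half_stride = speed * cfg.stance_fraction * cfg.cycle_duration_s / 2
    ankle_rest = max(3.0, cfg.limb_width / 2)
    reach = thigh + shank
    # hip must stay reachable at the extreme stance offset
    max_h = math.sqrt(max(reach**2 - (1.02 * half_stride) ** 2, 0.0))
    hip_height = min(0.93 * reach, 0.995 * max_h) + ankle_rest
    if hip_height <= ankle_rest + 0.3 * reach:
        raise ValueError(
            "walker stride too long for its legs; reduce image width or "
            "increase limb lengths"
        )
    total_height = hip_height + torso_h + 2 * head_r + 4
    if total_height > cfg.image_h - 4 or torso_w > cfg.image_w / 2:
        raise ValueError(
            f"walker larger than image: needs {total_height:.0f} px of "
            f"{cfg.image_h} px height"
        )
    phase_a = cfg.base_phase + cfg.phase_jitter * float(rng.uniform(-1, 1))
    return {
        "thigh": thigh,
        "shank": shank,
        "foot": foot,
        "torso_w": torso_w,
        "torso_h": torso_h,
        "head_r": head_r,
        "ground_y": cfg.image_h - 12,
        "hip_height": hip_height,
        "ankle_rest": ankle_rest,
        "speed": speed,
        "half_stride": half_stride,
        "x_start": margin,
        "phase_a": phase_a,
        "phase_b": phase_a + 0.5,
        "duration": duration,
    }


def simulate_walker(cfg: WalkerConfig) -> tuple[SilhouetteSequence, ToeOffGroundTruth]:
    """Render one walking sequence and its exact toe-off ground truth.

    Deterministic given ``cfg.seed``: the kinematic jitter and the pixel
    noise draw from independent derived RNG streams, so changing the
    noise parameters never changes the labels.
    """
    rng_kin = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    geo = _geometry(cfg, rng_kin)
    theta = cfg.frame_rate_hz
    n_frames = int(round(geo["duration"] * theta))
    # ground truth from the continuous-time contact schedule
    events = []
    for phase, side in ((geo["phase_a"], "right"), (geo["phase_b"], "left")):
        for t_star in _lift_off_times(cfg, phase, geo["duration"]):
            frame = math.ceil(t_star * theta)
            if 0 <= frame < n_frames:
                events.append((frame, side, t_star))
    if not events:
        raise ValueError("configuration yields zero toe-off events; add cycles")
    events.sort()
    truth = ToeOffGroundTruth(
        toe_off_indices=np.array([e[0] for e in events]),
        side_labels=[e[1] for e in events],
        lift_off_times_s=np.array([e[2] for e in events]),
    )
    frames = []
    for i in range(n_frames):
        mask = _render_frame(cfg, geo, i / theta)
        mask = _degrade(mask, cfg, rng_noise)
        frames.append(BinarySilhouette(mask=mask, frame_index=i))
    seq = SilhouetteSequence(
        frames=frames,
        frame_rate_hz=theta,
        view_tag=f"compress{cfg.view_compression:.2f}",
        subject_id=f"walker{cfg.seed}",
    )
    return seq, truth


@dataclass
class LabeledDataset:
    """CSD-map examples with per-anchor toe-off labels and provenance."""

    X: np.ndarray  # (n_examples, target_h, target_w) float32
    y: np.ndarray  # (n_examples,) int, 1 = toe-off anchor
    anchor_indices: np.ndarray
    sequence_index: np.ndarray  # which input walker each example came from
    truths: list[ToeOffGroundTruth]
    configs: list[WalkerConfig]
    frame_rate_hz: float
    n: int

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def __len__(self) -> int:
        return len(self.y)


def make_dataset(
    cfgs: Sequence[WalkerConfig],
    n: int = 2,
    target_w: int = 32,
    target_h: int = 48,
) -> LabeledDataset:
    """Simulate walkers and pair each CSD-map with a toe-off label.

    An example is positive iff its anchor frame index is a ground-truth
    toe-off frame.  An empty config list yields an empty dataset.
    """
    X_list, y_list, anchors, seq_idx = [], [], [], []
    truths: list[ToeOffGroundTruth] = []
    frame_rate = None
    for si, cfg in enumerate(cfgs):
        seq, truth = simulate_walker(cfg)
        frame_rate = seq.frame_rate_hz
        truths.append(truth)
        positives = set(truth.toe_off_indices.tolist())
        for m in stream_csd(seq, n=n, target_w=target_w, target_h=target_h):
            X_list.append(m.values)
            y_list.append(1 if m.anchor_frame_index in positives else 0)
            anchors.append(m.anchor_frame_index)
            seq_idx.append(si)
    if X_list:
        X = np.stack(X_list)
    else:
        X = np.empty((0, target_h, target_w), dtype=np.float32)
    return LabeledDataset(
        X=X,
        y=np.array(y_list, dtype=np.int64),
        anchor_indices=np.array(anchors, dtype=np.int64),
        sequence_index=np.array(seq_idx, dtype=np.int64),
        truths=truths,
        configs=list(cfgs),
        frame_rate_hz=frame_rate if frame_rate is not None else 25.0,
        n=n,
    )
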