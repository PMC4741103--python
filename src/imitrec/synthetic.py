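"""Parametric humanoid-avatar image sequences for imitation-learning runs.

The generator emulates a mutual-imitation recording: a set of visually similar
humanoid silhouettes ("avatars") that differ only in parametric morphology
(arm length/width, head radius, torso size) each imitate the robot's five
postures over a stream of frames with small per-frame jitter and pixel noise.
Partner blocks are contiguous, as in a session where participants take turns.

Everything is a pure function of its seeds, so sessions are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, polygon

N_POSTURES = 5

# Arm angles per posture, degrees from the downward vertical, outward positive:
# 0 arms down, 1 both raised, 2 left raised, 3 right raised, 4 T-pose.
POSTURE_ARM_ANGLES: dict[int, tuple[float, float]] = {
    0: (15.0, 15.0),
    1: (150.0, 150.0),
    2: (150.0, 15.0),
    3: (15.0, 150.0),
    4: (90.0, 90.0),
}

_LEG_LENGTH = 26
_LEG_WIDTH = 6
_NECK_GAP = 2
_BACKGROUND = 0.15
_FIT_MARGIN = 4  # head-room for the +/-2 px jitter plus anti-clipping slack
_MAX_ARM_RAISE_COS = math.cos(math.radians(180.0 - 150.0))  # vertical reach of a raised arm


@dataclass(frozen=True)
class AvatarSpec:
    """Morphology of one avatar; all lengths in pixels."""

    avatar_id: int
    arm_length: float
    arm_width: float
    head_radius: float
    torso_width: float
    torso_height: float
    gray_level: float = 0.85
    texture_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arm_length", "arm_width", "head_radius", "torso_width", "torso_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.gray_level <= 1.0:
            raise ValueError("gray_level must be in [0, 1]")


@dataclass(frozen=True)
class Frame:
    image: np.ndarray
    posture: int
    partner_id: int
    frame_index: int


@dataclass
class Session:
    """Ordered labelled frames plus the contiguous partner schedule."""

    frames: list[Frame]
    schedule: list[tuple[int, int, int]]  # (partner_id, start_frame, end_frame) inclusive
    seed: int

    def __len__(self) -> int:
        return len(self.frames)

    def partner_frames(self, partner_id: int) -> list[Frame]:
        return [f for f in self.frames if f.partner_id == partner_id]


def default_avatar_specs() -> list[AvatarSpec]:
    """Twelve avatars spanning arm length x torso width x head radius.

    The three factors are crossed on a coarse grid and each avatar then gets
    a small seeded perturbation of every trait plus its own torso height and
    arm width, so that -- like real bodies -- no two avatars share an exact
    measurement even when they sit on the same grid cell. All avatars share
    the same gray level, so only morphology (and imitation style) can
    distinguish them.
    """
    grid = product((28.0, 36.0, 44.0), (18.0, 26.0), (8.0, 12.0))
    specs = []
    for i, (al, tw, hr) in enumerate(grid):
        rng = np.random.default_rng(2000 + i)
        specs.append(AvatarSpec(
            avatar_id=i,
            arm_length=round(al + rng.uniform(-2.0, 1.0), 2),
            arm_width=round(4.0 + 0.35 * i + rng.uniform(-0.2, 0.2), 2),
            head_radius=round(hr + rng.uniform(-1.0, 1.0), 2),
            torso_width=round(tw + rng.uniform(-1.5, 1.5), 2),
            torso_height=round(32.0 + 0.7 * i + rng.uniform(-0.3, 0.3), 2),
            gray_level=0.85,
            texture_seed=1000 + i,
        ))
    return specs


def _check_fits(spec: AvatarSpec, image_size: int) -> None:
    half = image_size / 2.0
    # horizontal: shoulder + fully extended arm
    if spec.torso_width / 2.0 + spec.arm_length + _FIT_MARGIN >= half:
        offender = "arm_length" if spec.arm_length >= spec.torso_width / 2.0 else "torso_width"
        raise ValueError(f"figure exceeds frame horizontally: reduce {offender}")
    # vertical, above the shoulder line: head or a raised arm
    head_top = spec.torso_height / 2.0 + _NECK_GAP + 2.0 * spec.head_radius
    if head_top + _FIT_MARGIN >= half:
        offender = "head_radius" if 2.0 * spec.head_radius >= spec.torso_height / 2.0 else "torso_height"
        raise ValueError(f"figure exceeds frame vertically: reduce {offender}")
    if spec.torso_height / 2.0 + spec.arm_length * _MAX_ARM_RAISE_COS + _FIT_MARGIN >= half:
        raise ValueError("figure exceeds frame vertically: reduce arm_length")
    # vertical, below: torso + legs
    if spec.torso_height / 2.0 + _LEG_LENGTH + _FIT_MARGIN >= half:
        raise ValueError("figure exceeds frame vertically: reduce torso_height")


def _limb_polygon(origin_rc: tuple[float, float], angle_deg: float, length: float,
                  width: float, outward: float) -> tuple[np.ndarray, np.ndarray]:
    """Corner coordinates of a limb rectangle hinged at ``origin_rc``.

    ``angle_deg`` is measured from the downward vertical; ``outward`` is +1 for
    the figure's right side (increasing column) and -1 for the left.
    """
    th = math.radians(angle_deg)
    d = np.array([math.cos(th), outward * math.sin(th)])  # (drow, dcol), rows grow downward
    n = np.array([-d[1], d[0]])  # unit normal
    o = np.asarray(origin_rc, dtype=float)
    c = [o + n * width / 2, o - n * width / 2, o + d * length - n * width / 2, o + d * length + n * width / 2]
    corners = np.array([c[0], c[1], c[2], c[3]])
    return corners[:, 0], corners[:, 1]


def render_avatar(spec: AvatarSpec, posture: int, jitter_seed: int,
                  image_size: int = 128, noise_level: float = 0.02) -> np.ndarray:
    """Render one avatar frame as a float image in [0, 1].

    Deterministic for fixed ``(spec, posture, jitter_seed)``: the RNG is seeded
    from the avatar's texture seed, the posture and the frame jitter seed.
    Jitter is a +/-2 px body translation and +/-3 degrees of per-arm angle
    noise; ``noise_level`` is the sigma of additive Gaussian pixel noise.
    """
    if posture not in POSTURE_ARM_ANGLES:
        raise ValueError(f"posture must be in 0..{N_POSTURES - 1}")
    if image_size < 64:
        raise ValueError("image_size must be at least 64")
    _check_fits(spec, image_size)

    rng = np.random.default_rng([spec.texture_seed & 0x7FFFFFFF, posture, jitter_seed & 0x7FFFFFFF])
    dy, dx = rng.uniform(-2.0, 2.0, size=2)
    ang_noise = rng.uniform(-3.0, 3.0, size=2)
    # idiosyncratic imitation style: each avatar holds its arms with a fixed
    # personal offset (up to +/-8 degrees per arm), the way human partners
    # imitate the same posture in subtly different ways; derived from the
    # avatar's own seed so it is constant across frames and sessions
    style = np.random.default_rng(spec.texture_seed & 0x7FFFFFFF).uniform(-8.0, 8.0, size=2)
    ang_noise = ang_noise + style

    cy = image_size / 2.0 + dy
    cx = image_size / 2.0 + dx
    shoulder_row = cy - spec.torso_height / 2.0
    hip_row = cy + spec.torso_height / 2.0

    img = np.full((image_size, image_size), _BACKGROUND, dtype=np.float64)
    shape = img.shape

    def fill(rr: np.ndarray, cc: np.ndarray) -> None:
        img[rr, cc] = spec.gray_level

    # torso
    rr, cc = polygon(
        np.array([shoulder_row, shoulder_row, hip_row, hip_row]),
        np.array([cx - spec.torso_width / 2, cx + spec.torso_width / 2,
                  cx + spec.torso_width / 2, cx - spec.torso_width / 2]),
        shape,
    )
    fill(rr, cc)
    # head
    head_center = (shoulder_row - _NECK_GAP - spec.head_radius, cx)
    rr, cc = disk(head_center, spec.head_radius, shape=shape)
    fill(rr, cc)
    # arms, hinged slightly below the shoulder corners
    left_deg, right_deg = POSTURE_ARM_ANGLES[posture]
    for side, (deg, noise) in zip((-1.0, 1.0), ((left_deg, ang_noise[0]), (right_deg, ang_noise[1]))):
        origin = (shoulder_row + spec.arm_width / 2.0, cx + side * spec.torso_width / 2.0)
        rr, cc = _limb_polygon(origin, deg + noise, spec.arm_length, spec.arm_width, side)
        rr, cc = polygon(rr, cc, shape)
        fill(rr, cc)
    # legs: fixed, slightly splayed
    for side in (-1.0, 1.0):
        origin = (hip_row, cx + side * (spec.torso_width / 2.0 - _LEG_WIDTH / 2.0 - 1.0))
        rr, cc = _limb_polygon(origin, 5.0, _LEG_LENGTH, _LEG_WIDTH, side)
        rr, cc = polygon(rr, cc, shape)
        fill(rr, cc)

    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, size=shape)
    return np.clip(img, 0.0, 1.0)


def _posture_run_lengths(rng: np.random.Generator, n_frames: int) -> list[tuple[int, int]]:
    """Posture schedule for one partner block: (posture, run length) pairs.

    Runs cycle through shuffled permutations of the five postures (no
    immediate repeats across cycle boundaries), so every block covers the
    full repertoire and commanded postures stay roughly balanced, as they
    are when the robot draws each posture about equally often. Run lengths
    are uniform on {5..15} frames.
    """
    runs: list[tuple[int, int]] = []
    order: list[int] = []
    total = 0
    prev = -1
    while total < n_frames:
        if not order:
            order = list(rng.permutation(N_POSTURES))
            if order[0] == prev:  # avoid merging two runs of the same posture
                order.append(order.pop(0))
        p = int(order.pop(0))
        k = int(rng.integers(5, 16))
        runs.append((p, min(k, n_frames - total)))
        total += k
        prev = p
    return runs


def generate_session(specs: Sequence[AvatarSpec], frames_per_partner: int,
                     posture_schedule_seed: int, noise_level: float = 0.02,
                     image_size: int = 128) -> Session:
    """Generate a full learning session: one contiguous block per avatar.

    Within a block the commanded posture is held for seeded short runs
    (5-15 frames) covering all five postures, mimicking the robot announcing a
    posture and the partner imitating it for a few seconds.
    """
    if not specs:
        raise ValueError("need at least one avatar spec")
    if frames_per_partner < 10:
        raise ValueError("frames_per_partner must be >= 10")

    rng = np.random.default_rng(posture_schedule_seed & 0x7FFFFFFF)
    frames: list[Frame] = []
    schedule: list[tuple[int, int, int]] = []
    idx = 0
    for spec in specs:
        start = idx
        for posture, run in _posture_run_lengths(rng, frames_per_partner):
            for _ in range(run):
                jitter_seed = int(rng.integers(0, 2**31 - 1))
                img = render_avatar(spec, posture, jitter_seed,
                                    image_size=image_size, noise_level=noise_level)
                frames.append(Frame(img, posture, spec.avatar_id, idx))
                idx += 1
        schedule.append((spec.avatar_id, start, idx - 1))
    return Session(frames=frames, schedule=schedule, seed=posture_schedule_seed)


def subsample_session(session: Session, stride: int) -> Session:
    """Keep frames whose original index is a multiple of ``stride``.

    Original frame indices and labels are preserved; the schedule is
    recomputed over the retained frames. Composes: subsampling by 10 then by 3
    equals subsampling by 30 on the original indices.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kept = [f for f in session.frames if f.frame_index % stride == 0]
    schedule: list[tuple[int, int, int]] = []
    for f in kept:
        if schedule and schedule[-1][0] == f.partner_id:
            pid, start, _ = schedule[-1]
            schedule[-1] = (pid, start, f.frame_index)
        else:
            schedule.append((f.partner_id, f.frame_index, f.frame_index))
    return Session(frames=kept, schedule=schedule, seed=session.seed)


# --- disk layout: PNG frames + CSV manifest + JSON schedule ----------------

def save_session(session: Session, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in session.frames:
        fname = f"frame_{f.frame_index:06d}.png"
        iio.imwrite(directory / fname, np.round(f.image * 255).astype(np.uint8))
        rows.append({"frame_index": f.frame_index, "filename": fname,
                     "posture": f.posture, "partner_id": f.partner_id})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    (directory / "schedule.json").write_text(json.dumps(
        {"seed": session.seed,
         "schedule": [list(b) for b in session.schedule]}, indent=2))


def load_session(directory: str | Path) -> Session:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    meta = json.loads((directory / "schedule.json").read_text())
    frames = []
    for row in manifest.itertuples(index=False):
        img = iio.imread(directory / row.filename).astype(np.float64) / 255.0
        frames.append(Frame(img, int(row.posture), int(row.partner_id), int(row.frame_index)))
    schedule = [tuple(b) for b in meta["schedule"]]
    return Session(frames=frames, schedule=schedule, seed=int(meta["seed"]))
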