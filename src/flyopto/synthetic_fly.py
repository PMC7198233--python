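"""Synthetic walking-fly pose tracks with tripod gait and injectable
stimulus-locked behavioral effects.

The generator produces what the limb tracker of a real rig would output:
per-frame centroid position, heading, and six limb-tip positions, at a fixed
camera frame rate.  Forward speed follows a mean-reverting
(Ornstein-Uhlenbeck) process clipped at zero, heading drifts with a slower
mean-reverting yaw-rate process, and limbs step with fixed tripod phasing
(L1/R2/L3 anti-phase to R1/L2/R3): during stance a tip stays planted at
its touchdown point in the ground frame, during swing it returns smoothly
to its touchdown target ahead of the body-frame rest position.

`inject_response` adds ground-truth stimulus-locked effects to a track —
multiplicative forward-speed fold-change, signed yaw, and signed lateral
velocity, each rising after a latency and decaying exponentially — so that
the full analysis chain can be validated against known effect sizes.

Coordinates are mm in a right-handed plane (heading measured CCW from +x,
the fly's left at heading + 90 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LIMB_LABELS",
    "TRIPOD_A",
    "TRIPOD_B",
    "FlyBodyModel",
    "WalkParams",
    "PoseTrack",
    "EffectSpec",
    "simulate_walk",
    "inject_response",
    "expected_fold_change",
]

#: limb order used throughout: 1 = fore, 2 = mid, 3 = hind
LIMB_LABELS = ("L1", "L2", "L3", "R1", "R2", "R3")
TRIPOD_A = (0, 4, 2)  # L1, R2, L3
TRIPOD_B = (3, 1, 5)  # R1, L2, R3

_DEFAULT_REST = (
    (0.70, 0.95),   # L1
    (0.00, 1.10),   # L2
    (-0.80, 0.95),  # L3
    (0.70, -0.95),  # R1
    (0.00, -1.10),  # R2
    (-0.80, -0.95), # R3
)


@dataclass(frozen=True)
class FlyBodyModel:
    """Stereotyped fly geometry and gait parameters.

    The body axis is partitioned head/thorax/abdomen by fractions of the
    body length measured from the front; limb rest offsets are body-frame
    (mm, +x forward, +y left).
    """

    body_length_mm: float = 2.5
    body_width_mm: float = 1.0
    head_fraction: float = 0.25
    thorax_fraction: float = 0.35
    abdomen_fraction: float = 0.40
    limb_rest_offsets: tuple = _DEFAULT_REST
    limb_amplitude_mm: float = 0.75
    step_period_s: float = 0.125
    duty_factor: float = 0.6

    def __post_init__(self):
        fr = (self.head_fraction, self.thorax_fraction, self.abdomen_fraction)
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"body fractions must be positive and sum to 1, got {fr}")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if len(self.limb_rest_offsets) != 6:
            raise ValueError("six limb rest offsets required (L1,L2,L3,R1,R2,R3)")

    @property
    def rest_offsets(self) -> np.ndarray:
        return np.asarray(self.limb_rest_offsets, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "FlyBodyModel":
        d = yaml.safe_load(Path(path).read_text())
        if "limb_rest_offsets" in d:
            d["limb_rest_offsets"] = tuple(tuple(p) for p in d["limb_rest_offsets"])
        return cls(**d)


@dataclass(frozen=True)
class WalkParams:
    """Stochastic locomotion parameters.

    Forward speed: OU process with mean `mean_speed_mm_s`, stationary s.d.
    `speed_sd_mm_s`, relaxation time `speed_tau_s`, clipped at zero.  Yaw
    rate: OU with zero mean and s.d. `turn_sd_rad_s`.  When `arena_mm` is
    set, a smooth steering torque turns the fly toward the arena center
    within `wall_margin_mm` of a wall, keeping tracks inside the imaged
    region.
    """

    mean_speed_mm_s: float = 10.0
    speed_sd_mm_s: float = 3.0
    speed_tau_s: float = 1.0
    turn_sd_rad_s: float = 0.5
    turn_tau_s: float = 0.5
    arena_mm: tuple | None = None  # (x_min, y_min, x_max, y_max)
    wall_margin_mm: float = 3.0
    wall_turn_rad_s: float = 6.0
    start_xy: tuple | None = None
    start_heading_rad: float | None = None


@dataclass
class PoseTrack:
    """Tracked fly state at a fixed frame rate.

    centroid_xy : (n, 2) mm; heading_rad : (n,) unwrapped radians;
    limb_xy : (n, 6, 2) mm in the ground (camera) frame, limb order
    L1, L2, L3, R1, R2, R3.
    """

    fps: float
    centroid_xy: np.ndarray
    heading_rad: np.ndarray
    limb_xy: np.ndarray
    fly_id: str = "fly0"

    def __post_init__(self):
        self.centroid_xy = np.asarray(self.centroid_xy, dtype=float)
        self.heading_rad = np.asarray(self.heading_rad, dtype=float)
        self.limb_xy = np.asarray(self.limb_xy, dtype=float)
        n = len(self.heading_rad)
        if self.centroid_xy.shape != (n, 2) or self.limb_xy.shape != (n, 6, 2):
            raise ValueError("centroid_xy, heading_rad, limb_xy lengths disagree")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.heading_rad)

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def pose_at(self, frame: int):
        """(centroid (2,), heading, limb_xy (6,2)) at one frame."""
        return self.centroid_xy[frame], self.heading_rad[frame], self.limb_xy[frame]

    # ---------------------------------------------------------------- IO
    def to_frame(self) -> pd.DataFrame:
        cols = {"frame": np.arange(self.n_frames), "t_s": self.t_s,
                "x_mm": self.centroid_xy[:, 0], "y_mm": self.centroid_xy[:, 1],
                "heading_rad": self.heading_rad}
        for i, lab in enumerate(LIMB_LABELS):
            cols[f"{lab}x"] = self.limb_xy[:, i, 0]
            cols[f"{lab}y"] = self.limb_xy[:, i, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float | None = None, fly_id: str = "fly0") -> "PoseTrack":
        df = pd.read_csv(path)
        if fps is None:
            dt = np.diff(df["t_s"].to_numpy())
            fps = 1.0 / float(np.median(dt))
        limb = np.stack(
            [df[[f"{lab}x", f"{lab}y"]].to_numpy() for lab in LIMB_LABELS], axis=1
        )
        return cls(fps=fps, centroid_xy=df[["x_mm", "y_mm"]].to_numpy(),
                   heading_rad=df["heading_rad"].to_numpy(), limb_xy=limb,
                   fly_id=fly_id)

    def to_hdf5(self, path, group: str | None = None) -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group or self.fly_id)
            for key in ("fps",):
                g.attrs["fps"] = self.fps
            g.attrs["fly_id"] = self.fly_id
            for name, arr in (("t_s", self.t_s), ("centroid_xy", self.centroid_xy),
                              ("heading_rad", self.heading_rad), ("limb_xy", self.limb_xy)):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=arr)

    @classmethod
    def from_hdf5(cls, path, group: str) -> "PoseTrack":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(fps=float(g.attrs["fps"]),
                       centroid_xy=g["centroid_xy"][...],
                       heading_rad=g["heading_rad"][...],
                       limb_xy=g["limb_xy"][...],
                       fly_id=str(g.attrs.get("fly_id", group)))


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth stimulus-locked effect injected at activation events.

    After `latency_s`, forward speed is multiplied by
    ``1 + (slow_gain - 1) * exp(-t'/decay_s)`` (so it relaxes from the full
    gain back to baseline), yaw rate gains ``turn_gain_rad_s`` signed toward
    (+) or away from (-) the activated side, and lateral velocity gains
    ``lateral_gain_mm_s`` with the same sign convention.  Each gain may be a
    scalar (all target classes) or a dict keyed by target class; classes
    absent from a dict take the neutral value.  Overlapping effect windows
    superpose additively.
    """

    latency_s: float = 0.02
    slow_gain: float | dict = 1.0
    turn_gain_rad_s: float | dict = 0.0
    lateral_gain_mm_s: float | dict = 0.0
    decay_s: float = 0.1

    def __post_init__(self):
        if self.decay_s <= 0:
            raise ValueError("decay_s must be positive")

    def gains_for(self, target_class: str) -> tuple:
        return (
            _gain(self.slow_gain, target_class, 1.0),
            _gain(self.turn_gain_rad_s, target_class, 0.0),
            _gain(self.lateral_gain_mm_s, target_class, 0.0),
        )


def _gain(g, target_class: str, neutral: float) -> float:
    if isinstance(g, dict):
        return float(g.get(target_class, neutral))
    return float(g)


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _limb_ground_track(t: np.ndarray, centroid: np.ndarray, heading: np.ndarray,
                       model: FlyBodyModel, phase_offset: float,
                       rest_xy: np.ndarray) -> np.ndarray:
    """Ground-frame tip trajectory for one limb.

    Stance: the tip stays planted at its touchdown point in the ground
    frame (so it is exactly stationary however the body translates or
    turns).  Swing: the tip moves in the body frame from its liftoff
    position to the touchdown target ``rest + amplitude/2`` ahead of the
    rest offset, following a smoothstep profile.
    """
    n = len(t)
    half = model.limb_amplitude_mm / 2.0
    d = model.duty_factor
    phase = (t / model.step_period_s + phase_offset) % 1.0
    stance = phase < d
    target_bf = np.array([rest_xy[0] + half, rest_xy[1]])

    def _to_ground(i, bf):
        c, s = math.cos(heading[i]), math.sin(heading[i])
        return np.array([centroid[i, 0] + c * bf[0] - s * bf[1],
                         centroid[i, 1] + s * bf[0] + c * bf[1]])

    # run boundaries of the stance/swing labels
    change = np.flatnonzero(np.diff(stance.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])

    out = np.empty((n, 2))
    for start, end in zip(starts, ends):
        if stance[start]:
            if start == 0:  # steady-state mid-stance initialization
                bf0 = np.array(
                    [rest_xy[0] + half - (phase[0] / d) * model.limb_amplitude_mm,
                     rest_xy[1]])
                plant = _to_ground(0, bf0)
            else:
                plant = out[start - 1]  # where the swing completed
            out[start:end] = plant
        else:
            if start == 0:
                lift = _to_ground(0, np.array([rest_xy[0] - half, rest_xy[1]]))
            else:
                lift = out[start - 1]
            # the swing completes AT its last frame, so the following
            # touchdown frame copies a planted point (zero ground speed)
            k = end - start if end < n else max(end - start, 1) + 1
            target = _to_ground(min(end, n) - 1, target_bf)
            s = _smoothstep(np.arange(1, end - start + 1) / k)
            out[start:end] = lift + (target - lift) * s[:, None]
    return out


def _limbs_to_ground(centroid: np.ndarray, heading: np.ndarray,
                     limb_bf: np.ndarray) -> np.ndarray:
    """(n,6,2) body-frame tips -> ground frame given centroid/heading."""
    c, s = np.cos(heading), np.sin(heading)
    gx = centroid[:, None, 0] + c[:, None] * limb_bf[..., 0] - s[:, None] * limb_bf[..., 1]
    gy = centroid[:, None, 1] + s[:, None] * limb_bf[..., 0] + c[:, None] * limb_bf[..., 1]
    return np.stack([gx, gy], axis=-1)


def _ou_series(n: int, dt: float, mean: float, sd: float, tau: float,
               rng: np.random.Generator, x0: float | None = None) -> np.ndarray:
    """Euler-discretized Ornstein-Uhlenbeck path with stationary s.d. `sd`."""
    x = np.empty(n)
    x[0] = mean if x0 is None else x0
    if sd == 0.0 or n == 1:
        x[:] = x[0]
        return x
    alpha = dt / tau
    noise = sd * math.sqrt(2.0 * alpha) * rng.standard_normal(n - 1)
    for i in range(n - 1):
        x[i + 1] = x[i] + (mean - x[i]) * alpha + noise[i]
    return x


def simulate_walk(model: FlyBodyModel, duration_s: float, fps: float,
                  rng: np.random.Generator | int | None = None,
                  walk: WalkParams | None = None,
                  fly_id: str = "fly0") -> PoseTrack:
    """Simulate a freely walking fly.

    Returns a PoseTrack of ``round(duration_s * fps)`` frames.  With
    zero-noise WalkParams (``speed_sd_mm_s=0, turn_sd_rad_s=0``, no arena)
    the path is a straight line at constant heading.
    """
    walk = walk or WalkParams()
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * fps))
    if n < 2:
        raise ValueError("duration_s * fps must give at least 2 frames")
    dt = 1.0 / fps
    t = np.arange(n) * dt

    speed = np.clip(
        _ou_series(n, dt, walk.mean_speed_mm_s, walk.speed_sd_mm_s,
                   walk.speed_tau_s, rng),
        0.0, None,
    )
    yaw = _ou_series(n, dt, 0.0, walk.turn_sd_rad_s, walk.turn_tau_s, rng)

    if walk.start_heading_rad is None:
        heading0 = rng.uniform(-math.pi, math.pi) if walk.turn_sd_rad_s > 0 else 0.0
    else:
        heading0 = walk.start_heading_rad

    centroid = np.empty((n, 2))
    heading = np.empty(n)
    if walk.start_xy is not None:
        centroid[0] = walk.start_xy
    elif walk.arena_mm is not None:
        x0, y0, x1, y1 = walk.arena_mm
        m = walk.wall_margin_mm
        centroid[0] = (rng.uniform(x0 + m, x1 - m), rng.uniform(y0 + m, y1 - m))
    else:
        centroid[0] = (0.0, 0.0)
    heading[0] = heading0

    for i in range(n - 1):
        w = yaw[i]
        if walk.arena_mm is not None:
            w += _wall_steer(centroid[i], heading[i], walk)
        heading[i + 1] = heading[i] + w * dt
        centroid[i + 1, 0] = centroid[i, 0] + speed[i] * math.cos(heading[i]) * dt
        centroid[i + 1, 1] = centroid[i, 1] + speed[i] * math.sin(heading[i]) * dt

    rest = model.rest_offsets
    limb_xy = np.empty((n, 6, 2))
    for l in range(6):
        off = 0.0 if l in TRIPOD_A else 0.5
        limb_xy[:, l, :] = _limb_ground_track(t, centroid, heading, model,
                                              off, rest[l])

    return PoseTrack(fps=fps, centroid_xy=centroid, heading_rad=heading,
                     limb_xy=limb_xy, fly_id=fly_id)


def _wall_steer(pos, heading: float, walk: WalkParams) -> float:
    """Smooth steering toward the arena center near walls."""
    x0, y0, x1, y1 = walk.arena_mm
    m = walk.wall_margin_mm
    dists = (pos[0] - x0, pos[1] - y0, x1 - pos[0], y1 - pos[1])
    d = min(dists)
    if d >= m:
        return 0.0
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    to_center = math.atan2(cy - pos[1], cx - pos[0])
    err = math.atan2(math.sin(to_center - heading), math.cos(to_center - heading))
    # grows without bound past the wall so excursions turn back quickly
    strength = (m - d) / m
    return walk.wall_turn_rad_s * strength * math.copysign(
        1.0 if abs(err) > 0.5 else abs(err) / 0.5, err
    )


def _event_sign(side: str) -> float:
    """+1 for left-side events (positive yaw = leftward = toward the side)."""
    return {"left": 1.0, "right": -1.0, "midline": 0.0}[side]


def inject_response(track: PoseTrack, events, spec: EffectSpec,
                    rng: np.random.Generator | None = None) -> PoseTrack:
    """Return a copy of `track` with stimulus-locked effects added.

    `events` is an iterable with attributes ``onset_frame`` (camera frame),
    ``target_class`` and ``side`` (duck-typed; hitdetect.ActivationEvent
    works).  The track's velocities are decomposed into forward/lateral
    components, the effect envelopes are applied, and the trajectory is
    re-integrated; body-frame limb coordinates are preserved and mapped back
    through the new poses.  With neutral gains the track is reproduced
    exactly (up to float round-off).
    """
    n = track.n_frames
    dt = 1.0 / track.fps
    t = track.t_s

    # per-frame envelopes, summed additively over events
    slow = np.zeros(n)      # sum of (gain-1)*e(t)
    yaw_add = np.zeros(n)   # rad/s
    lat_add = np.zeros(n)   # mm/s
    for ev in events:
        g_slow, g_turn, g_lat = spec.gains_for(ev.target_class)
        t0 = ev.onset_frame / track.fps + spec.latency_s
        env = np.zeros(n)
        after = t >= t0
        env[after] = np.exp(-(t[after] - t0) / spec.decay_s)
        sgn = _event_sign(ev.side)
        slow += (g_slow - 1.0) * env
        yaw_add += sgn * g_turn * env
        lat_add += sgn * g_lat * env

    heading = track.heading_rad
    pos = track.centroid_xy
    c, s = np.cos(heading[:-1]), np.sin(heading[:-1])
    disp = np.diff(pos, axis=0)
    v_fwd = (disp[:, 0] * c + disp[:, 1] * s) / dt
    v_lat = (-disp[:, 0] * s + disp[:, 1] * c) / dt
    w = np.diff(heading) / dt

    new_heading = np.empty(n)
    new_heading[0] = heading[0]
    new_heading[1:] = heading[0] + np.cumsum((w + yaw_add[:-1]) * dt)

    v_fwd_new = v_fwd * (1.0 + slow[:-1])
    v_lat_new = v_lat + lat_add[:-1]
    cn, sn = np.cos(new_heading[:-1]), np.sin(new_heading[:-1])
    dx = (v_fwd_new * cn - v_lat_new * sn) * dt
    dy = (v_fwd_new * sn + v_lat_new * cn) * dt
    new_pos = np.empty((n, 2))
    new_pos[0] = pos[0]
    new_pos[1:, 0] = pos[0, 0] + np.cumsum(dx)
    new_pos[1:, 1] = pos[0, 1] + np.cumsum(dy)

    # carry body-frame limb coordinates over to the new poses
    ch, sh = np.cos(heading), np.sin(heading)
    rel = track.limb_xy - pos[:, None, :]
    bf_x = ch[:, None] * rel[..., 0] + sh[:, None] * rel[..., 1]
    bf_y = -sh[:, None] * rel[..., 0] + ch[:, None] * rel[..., 1]
    limb_bf = np.stack([bf_x, bf_y], axis=-1)
    new_limbs = _limbs_to_ground(new_pos, new_heading, limb_bf)

    return PoseTrack(fps=track.fps, centroid_xy=new_pos,
                     heading_rad=new_heading, limb_xy=new_limbs,
                     fly_id=track.fly_id)


def expected_fold_change(spec: EffectSpec, target_class: str,
                         window_s: float = 0.1) -> float:
    """Closed-form expectation of the post-onset window-mean fold-change.

    The injected forward-speed multiplier is
    ``m(t) = 1 + (g-1) exp(-(t-L)/tau)`` for ``t >= L`` (latency L, decay
    tau); its mean over ``[0, W]`` is
    ``1 + (g-1) (tau/W) (1 - exp(-(W-L)/tau))`` when ``L < W``.
    """
    g, _, _ = spec.gains_for(target_class)
    L, tau, W = spec.latency_s, spec.decay_s, window_s
    if L >= W:
        return 1.0
    return 1.0 + (g - 1.0) * (tau / W) * (1.0 - math.exp(-(W - L) / tau))
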