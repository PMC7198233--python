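"""Body-frame walking kinematics from pose tracks.

Velocity components follow the standard insect-locomotion conventions:
forward velocity v_par (centroid velocity projected onto the heading),
lateral velocity v_perp (+ toward the fly's left), and yaw velocity v_rot
(+ leftward/CCW turn, rad/s).  Derivatives are central differences with
one-sided differences at the track boundaries.

Swing/stance labels come from limb-tip speed in the ground frame: a tip in
stance is planted and nearly stationary regardless of how fast the body
translates, while a swinging tip moves faster than the body.  A short
hysteresis suppresses single-frame label chatter.

Forward-velocity responses are reported as fold-changes relative to the
mean speed in a pre-stimulus window, which normalizes out slow drifts in
baseline walking speed across flies and time; events in which the fly was
nearly stopped before stimulation (pre-window mean below a minimum speed)
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flyopto.synthetic_fly import LIMB_LABELS, PoseTrack

__all__ = [
    "SWING", "STANCE", "UNKNOWN",
    "ResponseWindowConfig",
    "KinematicSeries",
    "FoldChange",
    "compute_velocities",
    "classify_phase",
    "fold_change_trace",
    "contralateral_distance",
    "contralateral_change_trace",
]

SWING, STANCE, UNKNOWN = 0, 1, -1
_PHASE_NAME = {SWING: "swing", STANCE: "stance", UNKNOWN: "unknown"}

CONTRA_PAIRS = {"fore": (0, 3), "mid": (1, 4), "hind": (2, 5)}


@dataclass(frozen=True)
class ResponseWindowConfig:
    """Event-analysis windows (seconds) and the pre-stimulus speed filter."""

    pre_window_s: float = 0.25
    post_window_s: float = 0.1
    min_prestim_speed_mm_s: float = 3.0
    horizon_s: float = 0.5

    def __post_init__(self):
        if min(self.pre_window_s, self.post_window_s, self.horizon_s) <= 0:
            raise ValueError("windows must be positive")


@dataclass
class KinematicSeries:
    """Per-frame kinematics aligned with a PoseTrack."""

    fps: float
    v_par: np.ndarray       # mm/s, + forward
    v_perp: np.ndarray      # mm/s, + toward fly's left
    v_rot: np.ndarray       # rad/s, + leftward (CCW)
    limb_body_xy: np.ndarray  # (n, 6, 2) body-frame limb tips, mm
    phases: np.ndarray | None = None  # (n, 6) int8: SWING/STANCE/UNKNOWN

    @property
    def n_frames(self) -> int:
        return len(self.v_par)

    def to_frame(self, fly_id: str = "fly0") -> pd.DataFrame:
        cols = {"fly_id": fly_id, "frame": np.arange(self.n_frames),
                "v_par": self.v_par, "v_perp": self.v_perp, "v_rot": self.v_rot}
        for i, lab in enumerate(LIMB_LABELS):
            cols[f"{lab}_bx"] = self.limb_body_xy[:, i, 0]
            cols[f"{lab}_by"] = self.limb_body_xy[:, i, 1]
            if self.phases is not None:
                cols[f"{lab}_phase"] = [_PHASE_NAME[p] for p in self.phases[:, i]]
        return pd.DataFrame(cols)


def compute_velocities(track: PoseTrack) -> KinematicSeries:
    """Forward/lateral/yaw velocity and body-frame limb positions.

    Uses `np.gradient` (central differences, one-sided at the ends) on the
    centroid and the unwrapped heading.
    """
    if track.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / track.fps
    heading = np.unwrap(track.heading_rad)
    vel = np.gradient(track.centroid_xy, dt, axis=0)
    ch, sh = np.cos(heading), np.sin(heading)
    v_par = vel[:, 0] * ch + vel[:, 1] * sh
    v_perp = -vel[:, 0] * sh + vel[:, 1] * ch
    v_rot = np.gradient(heading, dt)

    rel = track.limb_xy - track.centroid_xy[:, None, :]
    bx = ch[:, None] * rel[..., 0] + sh[:, None] * rel[..., 1]
    by = -sh[:, None] * rel[..., 0] + ch[:, None] * rel[..., 1]
    return KinematicSeries(fps=track.fps, v_par=v_par, v_perp=v_perp,
                           v_rot=v_rot, limb_body_xy=np.stack([bx, by], axis=-1))


def _suppress_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Merge runs shorter than `min_run` into the preceding run (hysteresis)."""
    if min_run <= 1 or len(labels) == 0:
        return labels
    out = labels.copy()
    change = np.flatnonzero(np.diff(out)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(out)]])
    for s, e in zip(starts[1:], ends[1:]):  # first run always kept
        if e - s < min_run:
            out[s:e] = out[s - 1]
    return out


def classify_phase(track: PoseTrack, speed_fraction: float = 0.25,
                   floor_mm_s: float = 1.0, hysteresis_frames: int = 2
                   ) -> np.ndarray:
    """Per-frame, per-limb swing/stance labels, shape (n, 6), int8.

    A limb is in stance when its tip's ground-frame speed is below
    ``max(floor_mm_s, speed_fraction * body_speed)``; runs shorter than
    `hysteresis_frames` are merged into their predecessor.  Tracks shorter
    than 3 frames return all-UNKNOWN.

    Speeds here are displacements over the *preceding* inter-frame
    interval (backward differences, first frame copying the second):
    central differences would blend the fast swing motion into the frames
    bordering each touchdown and liftoff and bias the stance fraction low.
    """
    n = track.n_frames
    if n < 3:
        return np.full((n, 6), UNKNOWN, dtype=np.int8)
    dt = 1.0 / track.fps

    def _back_speed(arr):
        d = np.linalg.norm(np.diff(arr, axis=0), axis=-1) / dt
        return np.concatenate([d[:1], d], axis=0)

    body_speed = _back_speed(track.centroid_xy)
    thresh = np.maximum(floor_mm_s, speed_fraction * body_speed)
    tip_speed = _back_speed(track.limb_xy)  # (n, 6)
    phases = np.where(tip_speed < thresh[:, None], STANCE, SWING).astype(np.int8)
    for l in range(6):
        phases[:, l] = _suppress_short_runs(phases[:, l], hysteresis_frames)
    return phases


@dataclass
class FoldChange:
    """Fold-change trace around one event (or the reason it was dropped)."""

    t_rel: np.ndarray | None
    trace: np.ndarray | None
    pre_mean: float
    excluded: bool
    reason: str  # none | slow_prestim | edge


def _window_frames(config: ResponseWindowConfig, fps: float) -> tuple[int, int]:
    pre = int(round(config.pre_window_s * fps))
    post = int(round(config.horizon_s * fps))
    return pre, post


def fold_change_trace(series: KinematicSeries, onset_frame: int,
                      config: ResponseWindowConfig = ResponseWindowConfig()
                      ) -> FoldChange:
    """v_par normalized by its pre-stimulus-window mean, around one onset.

    The trace spans ``[-pre_window_s, +horizon_s]``.  Events whose pre
    window extends past the track start (or horizon past its end) are
    dropped with reason ``edge``; events with pre-window mean forward speed
    below the minimum are flagged ``slow_prestim``.
    """
    pre, post = _window_frames(config, series.fps)
    if onset_frame - pre < 0 or onset_frame + post >= series.n_frames:
        return FoldChange(None, None, np.nan, True, "edge")
    pre_mean = float(series.v_par[onset_frame - pre: onset_frame].mean())
    if pre_mean < config.min_prestim_speed_mm_s:
        return FoldChange(None, None, pre_mean, True, "slow_prestim")
    sl = slice(onset_frame - pre, onset_frame + post + 1)
    t_rel = (np.arange(-pre, post + 1)) / series.fps
    return FoldChange(t_rel, series.v_par[sl] / pre_mean, pre_mean, False, "none")


def contralateral_distance(track: PoseTrack, pair: str) -> np.ndarray:
    """Per-frame Euclidean distance (mm) between left/right tips of a
    segment pair, ``pair`` in {"fore", "mid", "hind"}."""
    try:
        i, j = CONTRA_PAIRS[pair]
    except KeyError:
        raise ValueError(f"pair must be one of {sorted(CONTRA_PAIRS)}, got {pair!r}")
    diff = track.limb_xy[:, i, :] - track.limb_xy[:, j, :]
    return np.linalg.norm(diff, axis=1)


def contralateral_change_trace(track: PoseTrack, pair: str, onset_frame: int,
                               config: ResponseWindowConfig = ResponseWindowConfig()
                               ) -> tuple[np.ndarray, np.ndarray] | None:
    """Distance-change trace (distance minus its pre-window mean) around an
    onset; None when the window falls off the track."""
    dist = contralateral_distance(track, pair)
    pre, post = _window_frames(config, track.fps)
    if onset_frame - pre < 0 or onset_frame + post >= len(dist):
        return None
    base = dist[onset_frame - pre: onset_frame].mean()
    t_rel = np.arange(-pre, post + 1) / track.fps
    return t_rel, dist[onset_frame - pre: onset_frame + post + 1] - base
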