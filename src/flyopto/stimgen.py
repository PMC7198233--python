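"""Random-patch stimulus design: Poisson patch counts, uniform placement,
frame-quantized pulse timing.

Each stimulus pulse is a set of circular activation patches whose count is
Poisson(lambda) and whose centers are i.i.d. uniform over the arena
rectangle, presented for a brief duration and followed by a dark interleave.
The projector runs much faster than the camera (1440 Hz here), and pulse
durations are rounded DOWN to an integer number of projector frames.

Defaults follow the experimental conditions this package models:
lambda = 35 patches per pulse, patch radius 5 camera pixels at
0.043 mm/pixel (= 0.215 mm), 30 ms pulses separated by 500 ms interleaves,
1440 Hz projector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "StimParams",
    "Pulse",
    "StimulusSchedule",
    "sample_pulse",
    "quantize_duration",
    "build_schedule",
    "rasterize_pulse",
]


@dataclass(frozen=True)
class StimParams:
    """Stimulus design parameters.

    arena_bounds is (x_min, y_min, x_max, y_max) in camera pixels; the
    default covers a 2.75 x 2.2 cm field of view at 0.043 mm/pixel.
    """

    lam: float = 35.0
    radius_px: float = 5.0
    resolution_mm_per_px: float = 0.043
    radius_mm: float | None = None
    duration_ms: float = 30.0
    interleave_ms: float = 500.0
    projector_hz: float = 1440.0
    arena_bounds: tuple = (0.0, 0.0, 640.0, 512.0)
    seed: int | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.duration_ms <= 0 or self.interleave_ms < 0:
            raise ValueError("duration_ms must be positive, interleave_ms non-negative")
        if self.projector_hz <= 0:
            raise ValueError("projector_hz must be positive")
        expected_mm = self.radius_px * self.resolution_mm_per_px
        if self.radius_mm is None:
            object.__setattr__(self, "radius_mm", expected_mm)
        elif abs(self.radius_mm - expected_mm) > 1e-9:
            raise ValueError(
                f"radius_mm={self.radius_mm} inconsistent with "
                f"radius_px*resolution={expected_mm}"
            )
        x0, y0, x1, y1 = self.arena_bounds
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"empty arena_bounds {self.arena_bounds}")

    @property
    def n_frames(self) -> int:
        return quantize_duration(self.duration_ms, self.projector_hz)

    @classmethod
    def from_yaml(cls, path) -> "StimParams":
        d = yaml.safe_load(Path(path).read_text())
        if "arena_bounds" in d:
            d["arena_bounds"] = tuple(d["arena_bounds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["arena_bounds"] = list(d["arena_bounds"])
        Path(path).write_text(yaml.safe_dump(d))


@dataclass(frozen=True)
class Pulse:
    """One stimulus presentation: onset time, frame count, patch centers."""

    onset_s: float
    onset_frame: int  # projector frame index
    n_frames: int
    centers: np.ndarray  # (k, 2) camera px

    def __post_init__(self):
        object.__setattr__(
            self, "centers", np.asarray(self.centers, dtype=float).reshape(-1, 2)
        )


@dataclass
class StimulusSchedule:
    pulses: list
    params: StimParams

    def __len__(self):
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.pulses:
                fh.write(
                    json.dumps(
                        {
                            "onset_s": p.onset_s,
                            "onset_frame": p.onset_frame,
                            "n_frames": p.n_frames,
                            "centers": p.centers.tolist(),
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path, params: StimParams) -> "StimulusSchedule":
        pulses = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                pulses.append(
                    Pulse(
                        onset_s=d["onset_s"],
                        onset_frame=d["onset_frame"],
                        n_frames=d["n_frames"],
                        centers=np.array(d["centers"], dtype=float).reshape(-1, 2),
                    )
                )
        return cls(pulses=pulses, params=params)


def quantize_duration(duration_ms: float, projector_hz: float) -> int:
    """Number of projector frames for a nominal pulse duration.

    Durations round down to the nearest integer frame count, with a floor of
    one frame (e.g. 10 ms at 1440 Hz -> 14 frames, 30 ms -> 43 frames).
    A small epsilon guards exact multiples against float rounding.
    """
    if duration_ms <= 0 or projector_hz <= 0:
        raise ValueError("duration_ms and projector_hz must be positive")
    frames = math.floor(duration_ms * projector_hz / 1000.0 + 1e-9)
    return max(1, frames)


def sample_pulse(params: StimParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one pulse's patch centers: Poisson(lam) count, uniform placement.

    Returns a (k, 2) array of centers in camera pixels, k ~ Poisson(lam).
    """
    k = int(rng.poisson(params.lam))
    x0, y0, x1, y1 = params.arena_bounds
    centers = np.empty((k, 2))
    centers[:, 0] = rng.uniform(x0, x1, size=k)
    centers[:, 1] = rng.uniform(y0, y1, size=k)
    return centers


def build_schedule(
    params: StimParams, session_s: float, rng: np.random.Generator | int | None = None
) -> StimulusSchedule:
    """Tile a session with pulses at the stated duration and interleave.

    Pulse onsets sit on the projector frame grid; patch sets are resampled
    independently per pulse and held constant for the pulse's frames.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    period_s = (params.duration_ms + params.interleave_ms) / 1000.0
    if session_s <= period_s:
        raise ValueError(
            f"session_s={session_s} must exceed duration+interleave={period_s}"
        )
    n_frames = params.n_frames
    interleave_frames = math.ceil(params.interleave_ms * params.projector_hz / 1000.0 - 1e-9)
    period_frames = n_frames + interleave_frames
    total_frames = math.floor(session_s * params.projector_hz)

    pulses = []
    for onset_frame in range(0, total_frames - n_frames + 1, period_frames):
        pulses.append(
            Pulse(
                onset_s=onset_frame / params.projector_hz,
                onset_frame=onset_frame,
                n_frames=n_frames,
                centers=sample_pulse(params, rng),
            )
        )
    return StimulusSchedule(pulses=pulses, params=params)


def rasterize_pulse(
    centers, radius: float, canvas_shape: tuple
) -> np.ndarray:
    """Binary mask of a pulse: pixel (row=y, col=x) set iff its center lies
    within `radius` of any patch center.

    Pixel centers are at integer coordinates (0-based, origin top-left).
    This is the pixel-level ground truth used as an oracle for the geometric
    hit tests and for mask export.
    """
    h, w = canvas_shape
    mask = np.zeros((h, w), dtype=bool)
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    r2 = float(radius) ** 2
    for cx, cy in centers:
        x_lo = max(0, math.ceil(cx - radius))
        x_hi = min(w - 1, math.floor(cx + radius))
        y_lo = max(0, math.ceil(cy - radius))
        y_hi = min(h - 1, math.floor(cy + radius))
        if x_hi < x_lo or y_hi < y_lo:
            continue
        xs = np.arange(x_lo, x_hi + 1)
        ys = np.arange(y_lo, y_hi + 1)
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        mask[y_lo : y_hi + 1, x_lo : x_hi + 1] |= dy2[:, None] + dx2[None, :] <= r2
    return mask
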