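"""Post hoc matching of activation patches to fly body parts.

Because patches are placed at random rather than targeted, which body part
each one struck is reconstructed after the fact from the tracked pose at
pulse onset:

* **Limb hits** — a patch hits a limb when its disc intersects the line
  segment from the fly's centroid to that limb's tip, restricted to the
  portion of the segment outside an elliptical body exclusion zone.  The
  test is exact disc-segment geometry (closest-point projection with
  endpoint clamping), not rasterization.
* **Body hits** — a patch whose center falls inside the body ellipse is
  assigned head / thorax / abdomen by its position along the body axis, and
  left / right / midline by its lateral body-frame coordinate.

Pulses that stimulate more than one limb, or a limb together with the body,
are excluded from analysis (the stimulated parts are ambiguous); excluded
events are retained with their exclusion reason for bookkeeping.  Wings are
not modelled, so wing/limb and wing/body co-stimulation is not excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from flyopto.synthetic_fly import FlyBodyModel, LIMB_LABELS

__all__ = [
    "TARGET_CLASSES",
    "BodyPartition",
    "ActivationEvent",
    "to_body_frame",
    "from_body_frame",
    "detect_limb_hits",
    "detect_body_hit",
    "classify_patches",
    "classify_pulse",
    "symmetrize",
    "events_to_frame",
    "events_to_csv",
    "events_to_jsonl",
]

TARGET_CLASSES = ("head", "thorax", "abdomen", "forelimb", "midlimb", "hindlimb")
_LIMB_CLASS = {0: "forelimb", 1: "midlimb", 2: "hindlimb",
               3: "forelimb", 4: "midlimb", 5: "hindlimb"}


@dataclass(frozen=True)
class BodyPartition:
    """Elliptical body exclusion zone and head/thorax/abdomen boundaries.

    The ellipse is centered on the centroid with its major axis along the
    heading.  Boundaries are body-axis coordinates (mm, +x toward the head)
    separating head|thorax and thorax|abdomen.  `midline_eps_mm` is the
    half-width of the midline band for side assignment.
    """

    semi_major_mm: float = 1.25
    semi_minor_mm: float = 0.5
    head_boundary_mm: float = 0.625
    abdomen_boundary_mm: float = -0.25
    midline_eps_mm: float = 0.05

    def __post_init__(self):
        if self.semi_major_mm <= 0 or self.semi_minor_mm <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (-self.semi_major_mm < self.abdomen_boundary_mm
                < self.head_boundary_mm < self.semi_major_mm):
            raise ValueError("partition boundaries must be ordered within the body")

    @classmethod
    def from_body_model(cls, model: FlyBodyModel, midline_eps_mm: float = 0.05
                        ) -> "BodyPartition":
        a = model.body_length_mm / 2.0
        return cls(
            semi_major_mm=a,
            semi_minor_mm=model.body_width_mm / 2.0,
            head_boundary_mm=a - model.head_fraction * model.body_length_mm,
            abdomen_boundary_mm=-a + model.abdomen_fraction * model.body_length_mm,
            midline_eps_mm=midline_eps_mm,
        )

    def region_of(self, body_x: float) -> str:
        if body_x > self.head_boundary_mm:
            return "head"
        if body_x > self.abdomen_boundary_mm:
            return "thorax"
        return "abdomen"

    def side_of(self, body_y: float) -> str:
        if abs(body_y) <= self.midline_eps_mm:
            return "midline"
        return "left" if body_y > 0 else "right"

    def contains(self, body_xy) -> bool:
        x, y = body_xy
        return (x / self.semi_major_mm) ** 2 + (y / self.semi_minor_mm) ** 2 <= 1.0


@dataclass
class ActivationEvent:
    """One detected patch-fly contact at a pulse onset."""

    fly_id: str
    onset_frame: int
    onset_s: float
    patch_center_xy: tuple          # ground/camera frame, mm
    target_class: str               # head|thorax|abdomen|fore|mid|hindlimb
    side: str                       # left|right|midline
    limb_index: int | None = None   # 0..5 when a limb was hit
    limb_phase: str = "unknown"     # swing|stance|unknown
    excluded: bool = False
    exclusion_reason: str = "none"  # multi_limb|limb_and_body|slow_prestim|none
    patch_center_body_xy: tuple | None = None

    def __post_init__(self):
        if self.excluded and self.exclusion_reason == "none":
            raise ValueError("excluded events must carry an exclusion reason")
        if not self.excluded and self.exclusion_reason != "none":
            raise ValueError(f"non-excluded event has reason {self.exclusion_reason}")
        if self.limb_index is not None and self.side == "midline":
            raise ValueError("limb hits cannot be midline")

    @property
    def limb_label(self) -> str | None:
        return LIMB_LABELS[self.limb_index] if self.limb_index is not None else None


# ------------------------------------------------------------ geometry

def to_body_frame(point_xy, centroid_xy, heading_rad):
    """Ground -> body frame: +x along heading, +y toward the fly's left.

    Accepts a single point or an (n, 2) array; shape is preserved.
    """
    p = np.asarray(point_xy, dtype=float)
    c = np.asarray(centroid_xy, dtype=float)
    rel = p - c
    ch, sh = np.cos(heading_rad), np.sin(heading_rad)
    bx = ch * rel[..., 0] + sh * rel[..., 1]
    by = -sh * rel[..., 0] + ch * rel[..., 1]
    return np.stack([bx, by], axis=-1)


def from_body_frame(body_xy, centroid_xy, heading_rad):
    """Inverse of `to_body_frame`."""
    b = np.asarray(body_xy, dtype=float)
    ch, sh = np.cos(heading_rad), np.sin(heading_rad)
    gx = ch * b[..., 0] - sh * b[..., 1]
    gy = sh * b[..., 0] + ch * b[..., 1]
    return np.stack([gx, gy], axis=-1) + np.asarray(centroid_xy, dtype=float)


def _segment_exit_fraction(tip_bf, partition: BodyPartition) -> float | None:
    """Fraction s along centroid->tip where the segment leaves the body
    ellipse; None when the tip itself is inside the ellipse."""
    q = ((tip_bf[0] / partition.semi_major_mm) ** 2
         + (tip_bf[1] / partition.semi_minor_mm) ** 2)
    if q <= 1.0:
        return None
    return 1.0 / np.sqrt(q)


def _point_segment_distance(p, a, b) -> float:
    """Distance from point p to segment ab (exact, endpoint-clamped)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    s = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    closest = a + s * ab
    return float(np.hypot(*(p - closest)))


def detect_limb_hits(patch_center, radius, pose, partition: BodyPartition) -> list:
    """Indices of limbs whose exposed centroid->tip segment passes within
    `radius` of the patch center.

    `pose` is ``(centroid_xy, heading_rad, limb_xy (6, 2))`` in ground
    coordinates (mm); the patch center is in the same frame.  The segment is
    clipped to its portion outside the body ellipse before the disc-segment
    test, so patches over the body do not register as limb hits.
    """
    centroid, heading, limbs = pose
    patch_bf = to_body_frame(patch_center, centroid, heading)
    hits = []
    for l in range(6):
        tip_bf = to_body_frame(limbs[l], centroid, heading)
        s_exit = _segment_exit_fraction(tip_bf, partition)
        if s_exit is None or s_exit >= 1.0:
            continue  # tip inside the exclusion zone: no exposed segment
        a = s_exit * tip_bf  # ellipse exit point along the segment
        if _point_segment_distance(patch_bf, a, tip_bf) <= radius:
            hits.append(l)
    return hits


def detect_body_hit(patch_center, radius, pose, partition: BodyPartition):
    """(region, side) when the patch center lies inside the body ellipse,
    else None.  Region from the body-axis coordinate against the partition
    boundaries; side from the sign of the lateral coordinate, with a
    +-`midline_eps_mm` midline band."""
    centroid, heading, _ = pose
    bf = to_body_frame(patch_center, centroid, heading)
    if not partition.contains(bf):
        return None
    return partition.region_of(float(bf[0])), partition.side_of(float(bf[1]))


# ------------------------------------------------------- classification

def classify_patches(centers_mm, radius_mm, pose, partition: BodyPartition,
                     fly_id: str, onset_frame: int, onset_s: float,
                     limb_phases=None) -> ActivationEvent | None:
    """Aggregate all patches of one pulse against one fly's pose.

    Returns a single ActivationEvent (possibly excluded) or None when no
    patch touched the fly.  Rules:

    * exactly one limb hit (any number of patches on that limb), no body
      hit -> limb event;
    * more than one distinct limb -> excluded ``multi_limb`` (a patch
      equidistant within radius of two limbs counts as both);
    * limb(s) plus body -> excluded ``limb_and_body``;
    * body only -> body-region event; with several on-body patches, the one
      nearest the centroid defines region and side.
    """
    centers_mm = np.asarray(centers_mm, dtype=float).reshape(-1, 2)
    centroid, heading, limbs = pose
    # cheap reject: nothing beyond the fly's reach (+ patch radius) can hit
    reach = max(partition.semi_major_mm,
                float(np.linalg.norm(limbs - centroid, axis=1).max())) + radius_mm
    near = np.linalg.norm(centers_mm - centroid, axis=1) <= reach
    centers_mm = centers_mm[near]
    limb_set: set[int] = set()
    limb_patch: dict[int, np.ndarray] = {}
    body_hits = []  # (dist_to_centroid, region, side, center)
    for center in centers_mm:
        for l in detect_limb_hits(center, radius_mm, pose, partition):
            limb_set.add(l)
            limb_patch.setdefault(l, center)
        bh = detect_body_hit(center, radius_mm, pose, partition)
        if bh is not None:
            dist = float(np.hypot(*(center - centroid)))
            body_hits.append((dist, bh[0], bh[1], center))

    if not limb_set and not body_hits:
        return None

    def _bf(center):
        return tuple(to_body_frame(center, centroid, heading))

    if limb_set and body_hits:
        l = min(limb_set)
        center = limb_patch[l]
        return ActivationEvent(
            fly_id=fly_id, onset_frame=onset_frame, onset_s=onset_s,
            patch_center_xy=tuple(center), target_class=_LIMB_CLASS[l % 3],
            side="left" if l < 3 else "right", limb_index=l,
            excluded=True, exclusion_reason="limb_and_body",
            patch_center_body_xy=_bf(center),
        )
    if len(limb_set) > 1:
        l = min(limb_set)
        center = limb_patch[l]
        return ActivationEvent(
            fly_id=fly_id, onset_frame=onset_frame, onset_s=onset_s,
            patch_center_xy=tuple(center), target_class=_LIMB_CLASS[l % 3],
            side="left" if l < 3 else "right", limb_index=l,
            excluded=True, exclusion_reason="multi_limb",
            patch_center_body_xy=_bf(center),
        )
    if limb_set:
        l = limb_set.pop()
        center = limb_patch[l]
        phase = "unknown"
        if limb_phases is not None:
            phase = limb_phases[l]
        return ActivationEvent(
            fly_id=fly_id, onset_frame=onset_frame, onset_s=onset_s,
            patch_center_xy=tuple(center), target_class=_LIMB_CLASS[l % 3],
            side="left" if l < 3 else "right", limb_index=l, limb_phase=phase,
            patch_center_body_xy=_bf(center),
        )
    body_hits.sort(key=lambda h: h[0])
    _, region, side, center = body_hits[0]
    return ActivationEvent(
        fly_id=fly_id, onset_frame=onset_frame, onset_s=onset_s,
        patch_center_xy=tuple(center), target_class=region, side=side,
        patch_center_body_xy=_bf(center),
    )


def classify_pulse(pulse, poses: dict, partition: BodyPartition,
                   radius_mm: float, fps: float,
                   limb_phases: dict | None = None) -> list:
    """Classify one stimulus pulse against every fly present.

    `poses` maps fly_id -> pose tuple at the pulse onset frame (patch
    centers and poses in the same mm frame); flies without any hit
    contribute no event.  `limb_phases` optionally maps fly_id -> per-limb
    swing/stance labels at that frame.
    """
    onset_frame = int(round(pulse.onset_s * fps))
    events = []
    for fly_id, pose in poses.items():
        ev = classify_patches(
            pulse.centers, radius_mm, pose, partition,
            fly_id=fly_id, onset_frame=onset_frame, onset_s=pulse.onset_s,
            limb_phases=None if limb_phases is None else limb_phases.get(fly_id),
        )
        if ev is not None:
            events.append(ev)
    return events


def symmetrize(side: str, traces: dict) -> tuple[str, dict]:
    """Mirror sided events onto a common side so that positive yaw
    (`v_rot`) and lateral (`v_perp`) values mean "toward the activation
    side".

    Internally both signals are signed + = toward the fly's LEFT (CCW), so
    left-side events already satisfy the convention and pass through, while
    right-side events have their signs flipped; forward-velocity and
    distance traces are untouched, and midline events pass through
    unchanged.  Sided events are relabeled to the common mirrored side.
    """
    if side == "midline":
        return side, dict(traces)
    out = {}
    for key, val in traces.items():
        if key in ("v_rot", "v_perp") and side == "right":
            out[key] = -np.asarray(val)
        else:
            out[key] = val
    return "mirrored", out


# ------------------------------------------------------------------ IO

_EVENT_COLUMNS = [
    "fly_id", "onset_frame", "onset_s", "patch_x_mm", "patch_y_mm",
    "target_class", "side", "limb_index", "limb_phase",
    "excluded", "exclusion_reason", "body_x_mm", "body_y_mm",
]


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        bx, by = ev.patch_center_body_xy or (np.nan, np.nan)
        rows.append({
            "fly_id": ev.fly_id, "onset_frame": ev.onset_frame,
            "onset_s": ev.onset_s,
            "patch_x_mm": ev.patch_center_xy[0],
            "patch_y_mm": ev.patch_center_xy[1],
            "target_class": ev.target_class, "side": ev.side,
            "limb_index": -1 if ev.limb_index is None else ev.limb_index,
            "limb_phase": ev.limb_phase, "excluded": ev.excluded,
            "exclusion_reason": ev.exclusion_reason,
            "body_x_mm": bx, "body_y_mm": by,
        })
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def events_to_csv(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def events_to_jsonl(events, path) -> None:
    df = events_to_frame(events)
    with open(path, "w") as fh:
        for rec in df.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")
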