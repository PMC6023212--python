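"""Frame-to-frame linking of detected wells and population-level statistics.

Linking is greedy mutual-nearest-neighbour: with a well pitch of ~225 px and
per-frame drift far below it, assignment ambiguity cannot arise, so a global
optimal matcher is unnecessary.  A well that leaves the field of view and
re-enters later starts a new track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .features import FeatureRecord
from .well_detect import WellDetection


@dataclass
class TrackPoint:
    frame_index: int
    time_min: float
    center: tuple[float, float]
    features: FeatureRecord | None = None


@dataclass
class Track:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)
    status: str = "active"  # active | lost

    @property
    def last_center(self) -> tuple[float, float]:
        return self.points[-1].center

    def __len__(self) -> int:
        return len(self.points)


def link_frames(
    prev_tracks: list[Track],
    detections: list[WellDetection],
    frame_index: int,
    time_min: float = 0.0,
    max_shift: float = 112.0,
    features: list[FeatureRecord] | None = None,
    next_id: int | None = None,
) -> list[Track]:
    """Link one frame's detections onto the existing tracks.

    Pairs (active track, detection) closer than ``max_shift`` are matched by
    greedy mutual-nearest-neighbour assignment; unmatched detections start new
    tracks and unmatched active tracks are marked lost.  Track ids are never
    reused.  Returns the updated track list (tracks are mutated in place).
    """
    if max_shift <= 0:
        raise ConfigurationError("max_shift must be positive")
    if features is not None and len(features) != len(detections):
        raise ValueError("features must align with detections")

    # deterministic detection order for ties, including exact duplicates
    order = sorted(range(len(detections)), key=lambda i: (detections[i].cx, detections[i].cy))
    active = [t for t in prev_tracks if t.status == "active"]
    active.sort(key=lambda t: t.track_id)

    pairs: list[tuple[float, int, int]] = []
    for ti, t in enumerate(active):
        tx, ty = t.last_center
        for rank, di in enumerate(order):
            d = detections[di]
            dist = math.hypot(d.cx - tx, d.cy - ty)
            if dist <= max_shift:
                pairs.append((dist, ti, rank))
    pairs.sort()  # greedy global-min == iterated mutual nearest neighbours

    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for dist, ti, rank in pairs:
        if ti in matched_t or rank in matched_d:
            continue
        matched_t.add(ti)
        matched_d.add(rank)
        di = order[rank]
        d = detections[di]
        feat = features[di] if features is not None else None
        active[ti].points.append(TrackPoint(frame_index, time_min, d.center, feat))

    for ti, t in enumerate(active):
        if ti not in matched_t:
            t.status = "lost"

    if next_id is None:
        next_id = max((t.track_id for t in prev_tracks), default=-1) + 1
    out = list(prev_tracks)
    for rank, di in enumerate(order):
        if rank in matched_d:
            continue
        d = detections[di]
        feat = features[di] if features is not None else None
        out.append(
            Track(
                track_id=next_id,
                points=[TrackPoint(frame_index, time_min, d.center, feat)],
            )
        )
        next_id += 1
    return out


class Tracker:
    """Stateful convenience wrapper around :func:`link_frames`."""

    def __init__(self, max_shift: float = 112.0) -> None:
        self.max_shift = max_shift
        self.tracks: list[Track] = []

    def update(
        self,
        frame_index: int,
        time_min: float,
        detections: list[WellDetection],
        features: list[FeatureRecord] | None = None,
    ) -> list[Track]:
        self.tracks = link_frames(
            self.tracks,
            detections,
            frame_index,
            time_min,
            self.max_shift,
            features,
        )
        return self.tracks


_FEATURE_FIELDS = {
    "area_px",
    "area_um2",
    "perimeter_px",
    "perimeter_um",
    "minor_px",
    "major_px",
    "roundness",
    "circularity",
    "eq_diam_px",
    "eccentricity",
    "solidity",
}


def population_average(
    tracks: list[Track],
    feature_name: str,
    condition_label: str | None = None,
) -> pd.DataFrame:
    """Per-frame mean, sample SD (n-1) and n of one feature over all tracks.

    Missing values (empty masks, gaps) are excluded from the statistics, not
    zero-filled.  The SD is NaN where fewer than two values are present.
    """
    if feature_name not in _FEATURE_FIELDS:
        raise ConfigurationError(f"unknown feature: {feature_name!r}")
    if not tracks:
        raise ConfigurationError("population_average requires at least one track")
    per_frame: dict[int, tuple[float, list[float]]] = {}
    for t in tracks:
        for p in t.points:
            if p.features is None or p.features.empty_flag:
                continue
            val = p.features.as_dict()[feature_name]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            per_frame.setdefault(p.frame_index, (p.time_min, []))[1].append(float(val))
    rows = []
    for fi in sorted(per_frame):
        time_min, vals = per_frame[fi]
        arr = np.asarray(vals)
        rows.append(
            {
                "frame": fi,
                "time_min": time_min,
                "feature": feature_name,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else math.nan,
                "n": len(arr),
            }
        )
    df = pd.DataFrame(rows)
    if condition_label is not None:
        df.insert(0, "condition", condition_label)
    return df


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table: one row per (track_id, frame) with all features."""
    rows = []
    for t in sorted(tracks, key=lambda t: t.track_id):
        for p in t.points:
            row = {
                "track_id": t.track_id,
                "status": t.status,
                "frame": p.frame_index,
                "time_min": p.time_min,
                "well_cx": p.center[0],
                "well_cy": p.center[1],
            }
            if p.features is not None:
                row.update(p.features.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
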