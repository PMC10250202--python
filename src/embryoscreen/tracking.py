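"""Link per-frame detections into per-embryo tracks.

Embryos in a well barely translate between frames, so appearance features
are unnecessary: tracking is motion-gated assignment only.  Each live track
predicts its next position with a constant-velocity model; predictions are
matched to the frame's detections by minimum-cost (Hungarian) assignment on
a (1 - IoU) cost over the circles' bounding squares, gated by IoU >= iou_gate
or center distance <= max_center_dist.  Unmatched detections seed new
tracks; a track unmatched for more than ``max_age`` consecutive frames is
terminated and never resurrected (no re-identification).  Tracks shorter
than ``min_track_length`` detections are discarded.

Determinism: tracks are processed in track_id order and detections in their
input order, and assignment cost ties resolve to the lower track_id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection

__all__ = ["TrackingConfig", "EmbryoTrack", "link_tracks"]

_INF = 1e9


@dataclass(frozen=True)
class TrackingConfig:
    """Gates and lifetimes for the assignment tracker."""

    iou_gate: float = 0.1
    max_center_dist: float | None = None  # defaults to smallest radius seen
    max_age: int = 5
    min_track_length: int = 10

    @classmethod
    def from_config(cls, section: dict | None) -> "TrackingConfig":
        section = section or {}
        return cls(
            iou_gate=float(section.get("iou_gate", 0.1)),
            max_center_dist=section.get("max_center_dist"),
            max_age=int(section.get("max_age", 5)),
            min_track_length=int(section.get("min_track_length", 10)),
        )


@dataclass
class EmbryoTrack:
    """An identity-linked sequence of detections (gaps up to max_age allowed)."""

    track_id: int
    detections: list[tuple[int, Detection]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.detections]

    def __len__(self) -> int:
        return len(self.detections)


def _circle_box(d: Detection) -> tuple[float, float, float, float]:
    # half-open bounding square [cx-r, cx+r) x [cy-r, cy+r)
    return (d.center_x_px - d.radius_px, d.center_y_px - d.radius_px,
            d.center_x_px + d.radius_px, d.center_y_px + d.radius_px)


def _iou(a: tuple, b: tuple) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


class _Live:
    __slots__ = ("track", "pos", "vel", "radius", "misses")

    def __init__(self, track: EmbryoTrack, det: Detection):
        self.track = track
        self.pos = np.array([det.center_x_px, det.center_y_px])
        self.vel = np.zeros(2)
        self.radius = det.radius_px
        self.misses = 0

    def predicted(self, frame_index: int) -> Detection:
        p = self.pos + self.vel  # constant-velocity, one-frame lookahead
        return Detection(frame_index, float(p[0]), float(p[1]), self.radius, 1.0)

    def update(self, frame_index: int, det: Detection) -> None:
        new = np.array([det.center_x_px, det.center_y_px])
        self.vel = new - self.pos
        self.pos = new
        self.radius = det.radius_px
        self.misses = 0
        self.track.detections.append((frame_index, det))


def link_tracks(per_frame_detections: Mapping[int, Sequence[Detection]] | Sequence[Sequence[Detection]],
                config: TrackingConfig | None = None) -> list[EmbryoTrack]:
    """Associate detections across frames into EmbryoTracks.

    ``per_frame_detections`` maps frame_index -> detections (or is a list
    indexed by frame).  Returns tracks sorted by track_id; ids are assigned
    in order of first appearance.
    """
    config = config or TrackingConfig()
    if isinstance(per_frame_detections, Mapping):
        if not per_frame_detections:
            return []
        lo, hi = min(per_frame_detections), max(per_frame_detections)
        # absent frames still age the live tracks
        items = [(t, per_frame_detections.get(t, ())) for t in range(lo, hi + 1)]
    else:
        items = list(enumerate(per_frame_detections))
    if not items:
        return []

    live: list[_Live] = []
    finished: list[EmbryoTrack] = []
    next_id = 0

    for frame_index, dets in items:
        dets = list(dets)
        live.sort(key=lambda lv: lv.track.track_id)
        if live and dets:
            cost = np.full((len(live), len(dets)), _INF)
            gate_dist = config.max_center_dist
            if gate_dist is None:
                gate_dist = min(lv.radius for lv in live)
            for i, lv in enumerate(live):
                pred = lv.predicted(frame_index)
                pbox = _circle_box(pred)
                for j, det in enumerate(dets):
                    iou = _iou(pbox, _circle_box(det))
                    dist = float(np.hypot(det.center_x_px - pred.center_x_px,
                                          det.center_y_px - pred.center_y_px))
                    if iou >= config.iou_gate or dist <= gate_dist:
                        # tiny id-ordered epsilon makes cost ties deterministic
                        cost[i, j] = (1.0 - iou) + 1e-9 * i
            rows, cols = linear_sum_assignment(cost)
            matched_live, matched_det = set(), set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _INF:
                    live[i].update(frame_index, dets[j])
                    matched_live.add(i)
                    matched_det.add(j)
        else:
            matched_live, matched_det = set(), set()

        still_live: list[_Live] = []
        for i, lv in enumerate(live):
            if i in matched_live:
                still_live.append(lv)
            else:
                lv.misses += 1
                lv.pos = lv.pos + lv.vel  # coast through the gap
                if lv.misses > config.max_age:
                    finished.append(lv.track)
                else:
                    still_live.append(lv)
        live = still_live

        for j, det in enumerate(dets):
            if j not in matched_det:
                tr = EmbryoTrack(next_id)
                next_id += 1
                lv = _Live(tr, det)
                tr.detections.append((frame_index, det))
                live.append(lv)

    finished.extend(lv.track for lv in live)
    tracks = [t for t in finished if len(t) >= config.min_track_length]
    tracks.sort(key=lambda t: t.track_id)
    return tracks
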