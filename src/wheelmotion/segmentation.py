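"""Movement segmentation and ground-truth labeling.

A segment is a maximal run of samples whose absolute chair speed exceeds a
threshold (default 0.1 m/s) lasting at least a minimum duration (default
2 s).  Absolute speed is used so that reverse driving still counts as
movement.  Labels come from the manual annotation track by majority time
overlap; ties and uncovered segments are labeled "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationTrack
from .kinematics import KinematicSeries

__all__ = ["SegmentationConfig", "Segment", "detect_segments", "label_segments"]


@dataclass(frozen=True)
class SegmentationConfig:
    speed_threshold: float = 0.1  # m/s, strict >
    min_duration: float = 2.0  # seconds

    def __post_init__(self) -> None:
        if self.speed_threshold < 0:
            raise ValueError("speed_threshold must be >= 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")


@dataclass
class Segment:
    """A contiguous movement bout: time span, sample span and label."""

    start: float
    end: float
    sample_span: tuple[int, int]  # half-open index range into the source series
    label: str = "unknown"
    participant_id: str = ""
    diagnosis: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_segments(
    kin: KinematicSeries, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Segment]:
    """Maximal runs of |v| > threshold, discarding runs shorter than min_duration.

    Duration is measured between the first and last qualifying sample's
    timestamps.  An empty series yields an empty list.
    """
    t = np.asarray(kin.timestamps, dtype=float)
    if len(t) == 0:
        return []
    moving = np.abs(np.asarray(kin.forward_speed, dtype=float)) > cfg.speed_threshold
    edges = np.flatnonzero(np.diff(moving.astype(np.int8)))
    starts = list(edges[~moving[edges]] + 1)
    ends = list(edges[moving[edges]] + 1)
    if moving[0]:
        starts = [0] + starts
    if moving[-1]:
        ends = ends + [len(t)]
    segments = []
    for i, j in zip(starts, ends):
        if t[j - 1] - t[i] >= cfg.min_duration:
            segments.append(Segment(start=float(t[i]), end=float(t[j - 1]), sample_span=(i, j)))
    return segments


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_segments(segments: list[Segment], track: AnnotationTrack) -> list[Segment]:
    """Assign each segment the label covering the largest share of its span.

    A tie between active and passive coverage, or zero coverage, yields
    "unknown".  Participant metadata is copied from the track.  Returns new
    Segment objects; the input list is not modified.
    """
    out = []
    for seg in segments:
        cover = {"active": 0.0, "passive": 0.0}
        for s, e, lab in track.intervals:
            cover[lab] += _overlap(seg.start, seg.end, s, e)
        if cover["active"] > cover["passive"]:
            label = "active"
        elif cover["passive"] > cover["active"]:
            label = "passive"
        else:
            label = "unknown"
        out.append(
            Segment(
                start=seg.start,
                end=seg.end,
                sample_span=seg.sample_span,
                label=label,
                participant_id=track.participant_id,
                diagnosis=track.diagnosis,
            )
        )
    return out
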