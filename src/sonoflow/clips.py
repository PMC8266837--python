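"""Event-anchored clip extraction and anatomy labelling.

Important scan events — the sonographer freezing the image or saving a
still/cine loop — mark the moments an acquisition was judged satisfactory.
Each such event anchors a 5-second clip ending at the event (the approach
context precedes the event), clamped at the scan start.  Events fired in
quick succession (freeze immediately followed by save) describe the same
acquisition, so clips overlapping an earlier kept clip by at least half
their length are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session import LabelSegment, MachineEvent

#: Event kinds that anchor a clip.
CLIP_ANCHOR_KINDS = ("freeze_on", "image_save", "clip_save")
DEFAULT_CLIP_LEN_S = 5.0
DEDUP_OVERLAP_FRACTION = 0.5


@dataclass
class Clip:
    """A short video excerpt anchored at an important machine event."""

    clip_id: str
    scan_id: str
    t_start: float
    t_end: float
    anchor_event: str
    label: Optional[str] = None
    features: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def extract_clips(
    events: Sequence[MachineEvent],
    scan_duration: float,
    clip_len: float = DEFAULT_CLIP_LEN_S,
    scan_id: str = "",
    dedup_overlap: float = DEDUP_OVERLAP_FRACTION,
) -> list[Clip]:
    """One clip per qualifying event, with near-duplicate windows dropped.

    Each qualifying event at time ``t`` yields the window
    ``[max(0, t - clip_len), t]``.  A window overlapping any earlier *kept*
    window by at least ``dedup_overlap`` of the shorter of the two windows
    is discarded.  The dedup is idempotent: re-extracting from the surviving
    anchors reproduces the same clip set.
    """
    if scan_duration <= 0:
        raise ValueError("scan_duration must be positive")
    kept: list[Clip] = []
    n = 0
    for ev in sorted(events, key=lambda e: e.t):
        if ev.kind not in CLIP_ANCHOR_KINDS:
            continue
        t0, t1 = max(0.0, ev.t - clip_len), ev.t
        if t1 <= t0:
            continue  # event at t=0 has no preceding context
        duplicate = False
        for c in kept:
            ov = _overlap(t0, t1, c.t_start, c.t_end)
            if ov >= dedup_overlap * min(t1 - t0, c.duration):
                duplicate = True
                break
        if duplicate:
            continue
        kept.append(Clip(f"{scan_id}_clip{n:04d}" if scan_id else f"clip{n:04d}",
                         scan_id, t0, t1, ev.kind))
        n += 1
    return kept


def assign_truth_label(clip: Clip, timeline: Sequence[LabelSegment]) -> str:
    """Label of the timeline segment set with the largest overlap with the clip.

    Overlap is accumulated per label across segments; ties go to the label
    whose contributing segment ends later (the content on screen at the
    anchor moment).
    """
    overlap: dict[str, float] = {}
    last_end: dict[str, float] = {}
    for seg in timeline:
        ov = _overlap(clip.t_start, clip.t_end, seg.start, seg.end)
        if ov > 0:
            overlap[seg.label] = overlap.get(seg.label, 0.0) + ov
            last_end[seg.label] = seg.end
    if not overlap:
        raise ValueError(
            f"clip [{clip.t_start}, {clip.t_end}] does not intersect the timeline"
        )
    return max(overlap, key=lambda lab: (overlap[lab], last_end[lab]))


def label_clips(clips: Sequence[Clip], timeline: Sequence[LabelSegment]) -> list[Clip]:
    """Assign ground-truth labels to every clip (in place) and return them."""
    for c in clips:
        c.label = assign_truth_label(c, timeline)
    return list(clips)


def clip_prevalence(clips_or_labels: Sequence) -> dict[str, float]:
    """Per-label fraction of clips, summing to 1 over the observed labels."""
    if len(clips_or_labels) == 0:
        raise ValueError("no clips to summarize")
    labels = [c.label if isinstance(c, Clip) else c for c in clips_or_labels]
    if any(lab is None for lab in labels):
        raise ValueError("every clip must be labelled before computing prevalence")
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0
    total = len(labels)
    return {lab: n / total for lab, n in sorted(out.items())}
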