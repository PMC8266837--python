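"""Gaze fixation-episode detection and the safety / biometry gaze audits.

A *fixation* here is an uninterrupted run of gaze samples inside an area of
interest (AOI) whose first-to-last timestamp span is at least 100 ms.  Runs
shorter than that are discarded.  Consecutive fixations separated by an
interruption of 400 ms or less merge into a single *fixation episode*;
longer interruptions start a new episode.  Both thresholds are inclusive
(>= 100 ms counts; a gap of exactly 400 ms merges).  Run length is measured
in time, not sample count, so the rule is independent of the tracker's
sampling rate.  Invalid or missing samples conservatively break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .screen import AOIRegion, MEASUREMENT_BOX
from .session import ScanSession
from .ui_extraction import extract_event_timeline

MIN_FIXATION_S = 0.100
MERGE_GAP_S = 0.400
#: A measurement-display event counts as "looked at" if a measurement-box
#: episode overlaps this window (seconds) around the event.
BIOMETRY_WINDOW_S = 2.0


@dataclass(frozen=True)
class FixationEpisode:
    """A merged interval of sustained gaze toward one AOI."""

    aoi: str
    t_start: float
    t_end: float
    n_fixations: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j] (inclusive) of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_fixation_episodes(
    gaze: pd.DataFrame,
    aoi: AOIRegion,
    min_fix: float = MIN_FIXATION_S,
    merge_gap: float = MERGE_GAP_S,
) -> list[FixationEpisode]:
    """Detect AOI fixation episodes in a gaze stream.

    Parameters
    ----------
    gaze
        DataFrame with columns ``t`` (strictly increasing seconds), ``x``,
        ``y`` (screen pixels) and ``valid``.
    aoi
        The screen rectangle to attribute gaze to.
    min_fix
        Minimum first-to-last span of an in-AOI run (seconds, inclusive).
    merge_gap
        Maximum interruption merged into one episode (seconds, inclusive).
    """
    if len(gaze) == 0:
        return []
    t = gaze["t"].to_numpy(dtype=float)
    inside = (
        gaze["valid"].to_numpy(dtype=bool)
        & np.asarray(aoi.contains(gaze["x"].to_numpy(), gaze["y"].to_numpy()))
    )
    # Maximal in-AOI runs lasting >= min_fix become fixations.
    fixations = [
        (t[i], t[j]) for i, j in _runs(inside) if t[j] - t[i] >= min_fix
    ]
    episodes: list[FixationEpisode] = []
    for start, end in fixations:
        if episodes and start - episodes[-1].t_end <= merge_gap:
            prev = episodes[-1]
            episodes[-1] = FixationEpisode(aoi.name, prev.t_start, end, prev.n_fixations + 1)
        else:
            episodes.append(FixationEpisode(aoi.name, start, end, 1))
    return episodes


def scan_aoi_flag(gaze: pd.DataFrame, aoi: AOIRegion, **kwargs) -> bool:
    """True iff the scan contains at least one fixation episode on the AOI."""
    return len(detect_fixation_episodes(gaze, aoi, **kwargs)) > 0


def align_gaze_to_frames(
    gaze: pd.DataFrame, frame_times: Sequence[float], max_gap: float = 0.050
) -> pd.DataFrame:
    """Nearest-timestamp gaze point per video frame.

    A frame is marked ``missing`` when the nearest gaze sample is more than
    ``max_gap`` seconds away or invalid.  Returns a DataFrame with columns
    ``t_frame, x, y, missing``.
    """
    if len(gaze) == 0 or len(frame_times) == 0:
        raise ValueError("gaze stream and frame timestamps must be non-empty")
    t = gaze["t"].to_numpy(dtype=float)
    ft = np.asarray(frame_times, dtype=float)
    right = np.searchsorted(t, ft)
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    pick_right = np.abs(t[right] - ft) < np.abs(t[left] - ft)
    idx = np.where(pick_right, right, left)
    gap = np.abs(t[idx] - ft)
    valid = gaze["valid"].to_numpy(dtype=bool)[idx]
    missing = (gap > max_gap) | ~valid
    return pd.DataFrame(
        {
            "t_frame": ft,
            "x": gaze["x"].to_numpy(dtype=float)[idx],
            "y": gaze["y"].to_numpy(dtype=float)[idx],
            "missing": missing,
        }
    )


def measurement_gaze_rate(
    sessions: Sequence[ScanSession],
    window: float = BIOMETRY_WINDOW_S,
    aoi: AOIRegion = MEASUREMENT_BOX,
    min_fix: float = MIN_FIXATION_S,
    merge_gap: float = MERGE_GAP_S,
) -> dict:
    """Fraction of biometric measurement displays that received gaze.

    For every ``measurement_display`` event, the event counts as *looked at*
    when a measurement-box fixation episode overlaps ``[t - window,
    t + window]``.  Returns the overall fraction plus a per-type breakdown::

        {"rate": 0.93, "n_events": 120, "by_type": {"HC": ..., ...}}
    """
    looked: dict[str, list[bool]] = {}
    for s in sessions:
        if s.ui is None or s.gaze is None:
            raise ValueError(f"session {s.scan_id}: UI and gaze streams required")
        events = [
            e
            for e in extract_event_timeline(s.ui, s.frame_rate)
            if e.kind == "measurement_display"
        ]
        episodes = detect_fixation_episodes(s.gaze, aoi, min_fix, merge_gap)
        for e in events:
            hit = any(
                ep.t_start <= e.t + window and ep.t_end >= e.t - window
                for ep in episodes
            )
            looked.setdefault(e.payload["type"], []).append(hit)
    n_events = sum(len(v) for v in looked.values())
    if n_events == 0:
        raise ValueError("no measurement events in the provided sessions")
    all_hits = [h for v in looked.values() for h in v]
    return {
        "rate": float(np.mean(all_hits)),
        "n_events": n_events,
        "by_type": {k: float(np.mean(v)) for k, v in sorted(looked.items())},
    }
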