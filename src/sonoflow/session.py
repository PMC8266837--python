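"""Core record types for one multimodal scan session, plus directory I/O.

A :class:`ScanSession` bundles everything the acquisition rig records during
one obstetric examination — per-frame machine UI state, the gaze point
stream, the transducer IMU stream — together with the synthetic ground truth
(anatomy timeline, true orientation, true machine events) that only the
generator knows.  Streams are stored as pandas DataFrames with one row per
sample; small ordered structures (segments, events) are lists of dataclasses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Machine event kinds recognized by the extraction stage.
EVENT_KINDS = ("freeze_on", "freeze_off", "image_save", "clip_save", "measurement_display")
SAVE_KINDS = ("image_save", "clip_save")
MEASUREMENT_TYPES = ("HC", "AC", "FL")


@dataclass(frozen=True)
class LabelSegment:
    """One contiguous stretch of scan time spent on a single anatomy label."""

    label: str
    start: float  # seconds from scan start
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class MachineEvent:
    """A timestamped machine interaction event recovered from the UI stream.

    ``payload`` carries event-specific detail: for ``measurement_display``,
    ``{"type": "AC", "value_mm": 152.3}``.
    """

    kind: str
    t: float
    frame_index: int
    payload: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class UIState:
    """Machine UI state visible on a single video frame."""

    frame_index: int
    frozen: bool
    save_kind: Optional[str] = None          # None, "image_save" or "clip_save"
    measurement: Optional[tuple[str, float]] = None  # (type, value in mm)
    thermal_index: float = 0.0


@dataclass
class ScanSession:
    """One synthetic scan with all modality streams and ground truth.

    Attributes
    ----------
    timeline
        Ground-truth anatomy segments; contiguous and covering [0, duration].
    gaze
        DataFrame ``t, x, y, valid`` (pixels, origin top-left).
    imu
        DataFrame ``t, gx, gy, gz, ax, ay, az, mx, my, mz`` (rad/s, m/s^2,
        unit magnetometer, all sensor frame).
    imu_truth
        DataFrame ``t, qw, qx, qy, qz, lax, lay, laz`` — true sensor-to-world
        attitude quaternion and world-frame linear acceleration.
    ui
        DataFrame ``frame_index, frozen, save_kind, meas_type, meas_value,
        thermal_index`` (one row per video frame; empty strings mean absent).
    ui_events
        Ground-truth machine events as planted by the generator.
    transcript
        Sonographer utterances, one list of lowercase words per sentence.
    clips_truth
        DataFrame ``clip_id, t_start, t_end, anchor, label`` of the event
        clips implied by the planted events.
    clip_features
        Array (n_clips, n_labels): label-dependent centroid plus noise,
        standing in for video content for the baseline classifier.
    """

    scan_id: str
    seed: int
    duration: float
    frame_rate: float
    timeline: list[LabelSegment]
    gaze: Optional[pd.DataFrame] = None
    imu: Optional[pd.DataFrame] = None
    imu_truth: Optional[pd.DataFrame] = None
    ui: Optional[pd.DataFrame] = None
    ui_events: list[MachineEvent] = field(default_factory=list)
    transcript: list[list[str]] = field(default_factory=list)
    clips_truth: Optional[pd.DataFrame] = None
    clip_features: Optional[np.ndarray] = None

    def ui_states(self) -> list[UIState]:
        """Materialize the UI stream as per-frame :class:`UIState` records."""
        if self.ui is None:
            return []
        out = []
        for row in self.ui.itertuples(index=False):
            meas = None
            if row.meas_type:
                meas = (row.meas_type, float(row.meas_value))
            out.append(
                UIState(
                    frame_index=int(row.frame_index),
                    frozen=bool(row.frozen),
                    save_kind=row.save_kind or None,
                    measurement=meas,
                    thermal_index=float(row.thermal_index),
                )
            )
        return out


def validate_timeline(timeline: list[LabelSegment], duration: float, tol: float = 1e-6) -> None:
    """Check contiguity, ordering and exact coverage of [0, duration]."""
    if not timeline:
        raise ValueError("empty timeline")
    if abs(timeline[0].start) > tol:
        raise ValueError("timeline does not start at 0")
    for a, b in zip(timeline, timeline[1:]):
        if abs(b.start - a.end) > tol:
            raise ValueError(f"gap/overlap between segments at t={a.end}")
    if abs(timeline[-1].end - duration) > tol:
        raise ValueError("timeline does not end at scan duration")


# ---------------------------------------------------------------------------
# Session directory serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def _events_to_records(events: list[MachineEvent]) -> list[dict]:
    return [
        {"kind": e.kind, "t": e.t, "frame_index": e.frame_index, "payload": e.payload}
        for e in events
    ]


def _events_from_records(records: list[dict]) -> list[MachineEvent]:
    return [
        MachineEvent(r["kind"], float(r["t"]), int(r["frame_index"]), r.get("payload"))
        for r in records
    ]


def save_session(session: ScanSession, out_dir: str | Path) -> Path:
    """Write a session to a directory of plain-text interchange files.

    Layout: ``timeline.csv``, ``gaze.csv``, ``imu.csv``, ``imu_truth.csv``,
    ``ui.jsonl``, ``transcript.txt``, ``clips_truth.csv`` and ``truth.json``
    (scan metadata, seed and ground-truth events).  Serialization is
    deterministic: the same session always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tl = pd.DataFrame(
        {"label": [s.label for s in session.timeline],
         "start": [s.start for s in session.timeline],
         "end": [s.end for s in session.timeline]}
    )
    tl.to_csv(out / "timeline.csv", index=False, float_format=_FLOAT_FMT)

    if session.gaze is not None:
        session.gaze.to_csv(out / "gaze.csv", index=False, float_format=_FLOAT_FMT)
    if session.imu is not None:
        session.imu.to_csv(out / "imu.csv", index=False, float_format=_FLOAT_FMT)
    if session.imu_truth is not None:
        session.imu_truth.to_csv(out / "imu_truth.csv", index=False, float_format=_FLOAT_FMT)
    if session.ui is not None:
        with open(out / "ui.jsonl", "w") as fh:
            for row in session.ui.itertuples(index=False):
                rec = {
                    "frame_index": int(row.frame_index),
                    "frozen": bool(row.frozen),
                    "save_kind": row.save_kind,
                    "meas_type": row.meas_type,
                    "meas_value": None if np.isnan(row.meas_value) else float(row.meas_value),
                    "thermal_index": round(float(row.thermal_index), 6),
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if session.transcript:
        with open(out / "transcript.txt", "w") as fh:
            for sentence in session.transcript:
                fh.write(" ".join(sentence) + "\n")
    if session.clips_truth is not None:
        session.clips_truth.to_csv(out / "clips_truth.csv", index=False, float_format=_FLOAT_FMT)
    if session.clip_features is not None:
        np.savetxt(out / "clip_features.csv", session.clip_features, delimiter=",", fmt=_FLOAT_FMT)

    truth = {
        "scan_id": session.scan_id,
        "seed": session.seed,
        "duration": session.duration,
        "frame_rate": session.frame_rate,
        "ui_events": _events_to_records(session.ui_events),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return out


def load_session(in_dir: str | Path) -> ScanSession:
    """Read a session directory written by :func:`save_session`."""
    p = Path(in_dir)
    with open(p / "truth.json") as fh:
        truth = json.load(fh)
    tl = pd.read_csv(p / "timeline.csv")
    timeline = [LabelSegment(r.label, float(r.start), float(r.end)) for r in tl.itertuples()]

    def _maybe_csv(name: str) -> Optional[pd.DataFrame]:
        f = p / name
        return pd.read_csv(f) if f.exists() else None

    ui = None
    if (p / "ui.jsonl").exists():
        recs = [json.loads(line) for line in open(p / "ui.jsonl")]
        ui = pd.DataFrame(
            {
                "frame_index": [r["frame_index"] for r in recs],
                "frozen": [r["frozen"] for r in recs],
                "save_kind": [r["save_kind"] or "" for r in recs],
                "meas_type": [r["meas_type"] or "" for r in recs],
                "meas_value": [np.nan if r["meas_value"] is None else r["meas_value"] for r in recs],
                "thermal_index": [r["thermal_index"] for r in recs],
            }
        )

    transcript: list[list[str]] = []
    if (p / "transcript.txt").exists():
        transcript = [line.split() for line in open(p / "transcript.txt") if line.strip()]

    features = None
    if (p / "clip_features.csv").exists():
        features = np.loadtxt(p / "clip_features.csv", delimiter=",", ndmin=2)

    return ScanSession(
        scan_id=truth["scan_id"],
        seed=int(truth["seed"]),
        duration=float(truth["duration"]),
        frame_rate=float(truth["frame_rate"]),
        timeline=timeline,
        gaze=_maybe_csv("gaze.csv"),
        imu=_maybe_csv("imu.csv"),
        imu_truth=_maybe_csv("imu_truth.csv"),
        ui=ui,
        ui_events=_events_from_records(truth["ui_events"]),
        transcript=transcript,
        clips_truth=_maybe_csv("clips_truth.csv"),
        clip_features=features,
    )
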