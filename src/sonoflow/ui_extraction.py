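"""Recover machine events and displayed values from per-frame UI data.

Two input channels are supported.  The *structured* channel is the
generator's per-frame UI table and is lossless by construction.  The
*raster* channel reads rendered UI frames by exact template matching of the
glyph font (the machine's own glyphs, so a normalized match score below
threshold means corrupted content and the reader refuses rather than
guesses a value).  On clean renders both channels yield identical event
timelines.

Event kinds: ``freeze_on`` / ``freeze_off`` (transitions of the freeze
indicator), ``image_save`` / ``clip_save`` (save icons, which by machine
convention only appear while frozen), and ``measurement_display`` (a
biometric measurement box becoming readable with a new value).  Timestamps
are ``frame_index / frame_rate`` with 0-based frames.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from . import glyphs as _glyphs
from .screen import UI_REGIONS
from .session import MEASUREMENT_TYPES, MachineEvent, UIState

log = logging.getLogger(__name__)

#: Minimum normalized match score for a glyph cell to count as recognized.
MATCH_THRESHOLD = 0.99
#: A measurement display interrupted for less than this many seconds and
#: resuming with the same value is treated as one continuous display.
MEASUREMENT_DEBOUNCE_S = 0.5

_TYPE_BY_LETTER = {t[0]: t for t in MEASUREMENT_TYPES}


@dataclass(frozen=True)
class ExtractedValue:
    """Outcome of reading one numeric display box."""

    value: Optional[float]
    confidence: float
    readable: bool

    def __post_init__(self) -> None:
        if not self.readable and self.value is not None:
            raise ValueError("unreadable extraction must not carry a value")


def _match_cell(cell: np.ndarray, glyphs: dict[str, np.ndarray]) -> tuple[str, float]:
    """Best-matching character for one glyph cell.

    Score is the fraction of pixels agreeing with the template after
    binarization; an exact render scores 1.0.
    """
    binary = cell > 127
    best_char, best_score = " ", -1.0
    for char, template in glyphs.items():
        if template.shape != cell.shape:
            continue
        score = float(np.mean(binary == (template > 127)))
        if score > best_score:
            best_char, best_score = char, score
    return best_char, best_score


def read_numeric_box(
    raster: np.ndarray,
    region: tuple[int, int, int, int],
    glyphs: dict[str, np.ndarray] | None = None,
    threshold: float = MATCH_THRESHOLD,
) -> ExtractedValue:
    """Read a fixed-pitch numeric display from a raster region.

    The region is split into glyph cells which are matched individually
    against the template set; the value is parsed left to right.  If any
    cell's best score falls below ``threshold``, or the recognized text is
    not a number, the box is reported unreadable with no value.
    """
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty region {region}")
    if y1 > raster.shape[0] or x1 > raster.shape[1] or x0 < 0 or y0 < 0:
        raise ValueError(f"region {region} outside raster bounds {raster.shape}")
    glyphs = glyphs or _glyphs.DEFAULT_GLYPHS

    patch = raster[y0:y1, x0:x1]
    n_cells = patch.shape[1] // _glyphs.CELL_W
    if n_cells == 0 or patch.shape[0] != _glyphs.CELL_H:
        raise ValueError(f"region {region} does not hold an integral glyph row")

    chars, scores = [], []
    for i in range(n_cells):
        cell = patch[:, i * _glyphs.CELL_W : (i + 1) * _glyphs.CELL_W]
        char, score = _match_cell(cell, glyphs)
        chars.append(char)
        scores.append(score)
    confidence = float(min(scores))
    if confidence < threshold:
        return ExtractedValue(None, confidence, False)
    text = "".join(chars).strip()
    if not re.fullmatch(r"\d+(\.\d+)?", text or ""):
        return ExtractedValue(None, confidence, False)
    return ExtractedValue(float(text), confidence, True)


def _read_indicator(raster: np.ndarray, region: tuple[int, int, int, int]) -> bool:
    x0, y0, x1, y1 = region
    return bool(np.mean(raster[y0:y1, x0:x1]) > 127)


def _read_save_icon(raster: np.ndarray) -> Optional[str]:
    x0, y0, x1, y1 = UI_REGIONS["save_indicator"]
    patch = raster[y0:y1, x0:x1] > 127
    if not patch.any():
        return None
    for kind, icon in _glyphs.SAVE_ICONS.items():
        if np.array_equal(patch, icon > 127):
            return kind
    log.warning("unrecognized save icon pattern; skipping")
    return None


def read_ui_state(
    raster: np.ndarray,
    frame_index: int,
    glyphs: dict[str, np.ndarray] | None = None,
) -> UIState:
    """Reconstruct the structured UI state of one rendered frame."""
    glyphs = glyphs or _glyphs.DEFAULT_GLYPHS
    frozen = _read_indicator(raster, UI_REGIONS["freeze_indicator"])
    save_kind = _read_save_icon(raster)

    measurement = None
    tx0, ty0, tx1, ty1 = UI_REGIONS["meas_type"]
    type_cell = raster[ty0:ty1, tx0:tx1]
    if type_cell.any():
        letter, score = _match_cell(type_cell, glyphs)
        value = read_numeric_box(raster, UI_REGIONS["meas_value"], glyphs)
        if score >= MATCH_THRESHOLD and letter in _TYPE_BY_LETTER and value.readable:
            measurement = (_TYPE_BY_LETTER[letter], value.value)
        else:
            log.warning("frame %d: unreadable measurement box, skipped", frame_index)

    thermal = read_numeric_box(raster, UI_REGIONS["thermal_value"], glyphs)
    return UIState(
        frame_index=frame_index,
        frozen=frozen,
        save_kind=save_kind,
        measurement=measurement,
        thermal_index=thermal.value if thermal.readable else float("nan"),
    )


# ---------------------------------------------------------------------------
# Event timeline extraction
# ---------------------------------------------------------------------------


def detect_freeze_transitions(ui: pd.DataFrame, frame_rate: float) -> list[MachineEvent]:
    """Freeze indicator transitions: one ``freeze_on`` per false->true flip,
    one ``freeze_off`` per true->false flip, timestamped at the flip frame."""
    if len(ui) == 0:
        return []
    frozen = ui["frozen"].to_numpy(dtype=bool)
    frames = ui["frame_index"].to_numpy(dtype=np.int64)
    flips = np.flatnonzero(np.diff(frozen.astype(np.int8)))
    events = []
    for i in flips:
        kind = "freeze_on" if frozen[i + 1] else "freeze_off"
        f = int(frames[i + 1])
        events.append(MachineEvent(kind, f / frame_rate, f))
    return events


def _detect_save_events(ui: pd.DataFrame, frame_rate: float) -> list[MachineEvent]:
    events = []
    kinds = ui["save_kind"].to_numpy(dtype=object)
    frames = ui["frame_index"].to_numpy(dtype=np.int64)
    for i in np.flatnonzero(kinds != ""):
        f = int(frames[i])
        events.append(MachineEvent(str(kinds[i]), f / frame_rate, f))
    return events


def _detect_measurement_events(
    ui: pd.DataFrame, frame_rate: float, debounce: float = MEASUREMENT_DEBOUNCE_S
) -> list[MachineEvent]:
    """Emit one event each time the measurement box shows a *new* reading.

    A reading is new when the type or value differs from the previous
    readable frame, or when the box has been absent/unreadable for longer
    than the debounce window (so the same value redisplayed later in the
    scan counts as a distinct measurement).
    """
    events = []
    mtypes = ui["meas_type"].to_numpy(dtype=object)
    values = ui["meas_value"].to_numpy(dtype=float)
    frames = ui["frame_index"].to_numpy(dtype=np.int64)
    last_key: Optional[tuple[str, float]] = None
    last_seen_t = -np.inf
    for i in np.flatnonzero(mtypes != ""):
        t = frames[i] / frame_rate
        key = (str(mtypes[i]), float(values[i]))
        if key != last_key or (t - last_seen_t) > debounce:
            events.append(
                MachineEvent(
                    "measurement_display",
                    t,
                    int(frames[i]),
                    {"type": key[0], "value_mm": key[1]},
                )
            )
        last_key = key
        last_seen_t = t
    return events


def _iter_rasters(
    frames: Iterable[tuple[int, np.ndarray]] | str | Path,
) -> Iterator[tuple[int, np.ndarray]]:
    if isinstance(frames, (str, Path)):
        from PIL import Image

        for path in sorted(Path(frames).glob("*.png")):
            idx = int(re.search(r"(\d+)", path.stem).group(1))
            yield idx, np.asarray(Image.open(path).convert("L"))
    else:
        yield from frames


def ui_table_from_rasters(
    frames: Iterable[tuple[int, np.ndarray]] | str | Path,
    glyphs: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run per-frame recognition over rendered frames -> structured UI table.

    ``frames`` is either a directory of ``*.png`` files (frame index parsed
    from the file name) or an iterable of ``(frame_index, raster)`` pairs.
    """
    rows = []
    for idx, raster in _iter_rasters(frames):
        s = read_ui_state(raster, idx, glyphs)
        rows.append(
            {
                "frame_index": s.frame_index,
                "frozen": s.frozen,
                "save_kind": s.save_kind or "",
                "meas_type": s.measurement[0] if s.measurement else "",
                "meas_value": s.measurement[1] if s.measurement else np.nan,
                "thermal_index": s.thermal_index,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("frame_index", ignore_index=True) if len(df) else df


def extract_event_timeline(
    ui: pd.DataFrame | Iterable[tuple[int, np.ndarray]] | str | Path,
    frame_rate: float,
    glyphs: dict[str, np.ndarray] | None = None,
) -> list[MachineEvent]:
    """Full machine-event timeline from a UI stream (structured or raster).

    Returns the union of freeze transitions, save events and measurement
    displays, sorted by time (stable for simultaneous events).
    """
    if not isinstance(ui, pd.DataFrame):
        ui = ui_table_from_rasters(ui, glyphs)
    if len(ui) == 0:
        return []
    events = (
        detect_freeze_transitions(ui, frame_rate)
        + _detect_save_events(ui, frame_rate)
        + _detect_measurement_events(ui, frame_rate)
    )
    return sorted(events, key=lambda e: (e.t, e.frame_index))


def count_biometric_measurements(events: list[MachineEvent]) -> dict[str, int]:
    """Count ``measurement_display`` events by biometric type.

    Returns ``{"HC": ..., "AC": ..., "FL": ..., "total": ...}``.
    """
    counts = {t: 0 for t in MEASUREMENT_TYPES}
    for e in events:
        if e.kind == "measurement_display":
            counts[e.payload["type"]] += 1
    counts["total"] = sum(counts[t] for t in MEASUREMENT_TYPES)
    return counts
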