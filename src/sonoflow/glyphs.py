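"""Bitmap glyph font and UI frame rendering.

The synthetic machine interface renders numeric displays with a fixed-pitch
5x7 bitmap font scaled 4x (glyph cells of 24x28 px), and status indicators
as solid/striped icons.  Because the extraction stage matches against these
exact templates, rendering is a deterministic pixel function of the UI
state, which makes the render -> read round trip exact on clean frames and
lets corruption tests verify that unreadable content is refused rather than
guessed.
"""

from __future__ import annotations

import numpy as np

from .reference import SCREEN_HEIGHT, SCREEN_WIDTH
from .screen import (
    FREEZE_INDICATOR_BOX,
    MEAS_TYPE_BOX,
    MEAS_VALUE_BOX,
    SAVE_INDICATOR_BOX,
    THERMAL_VALUE_BOX,
)
from .session import UIState

_SCALE = 4
GLYPH_W = 5 * _SCALE          # 20
GLYPH_H = 7 * _SCALE          # 28
CELL_W = GLYPH_W + _SCALE     # 24, one scaled column of spacing
CELL_H = GLYPH_H
N_VALUE_CELLS = 6
#: Fixed-width numeric display format used by every value box.
VALUE_FORMAT = "{:>6.1f}"

_RAW_GLYPHS: dict[str, tuple[str, ...]] = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    ".": ("00000", "00000", "00000", "00000", "00000", "00110", "00110"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
    "A": ("01110", "10001", "10001", "11111", "10001", "10001", "10001"),
    "F": ("11111", "10000", "10000", "11110", "10000", "10000", "10000"),
    " ": ("00000", "00000", "00000", "00000", "00000", "00000", "00000"),
}


def _scale_glyph(rows: tuple[str, ...]) -> np.ndarray:
    g = np.array([[int(c) for c in row] for row in rows], dtype=np.uint8) * 255
    g = np.kron(g, np.ones((_SCALE, _SCALE), dtype=np.uint8))
    cell = np.zeros((CELL_H, CELL_W), dtype=np.uint8)
    cell[:, :GLYPH_W] = g
    return cell


#: Character -> rendered cell template (CELL_H x CELL_W uint8, values 0/255).
DEFAULT_GLYPHS: dict[str, np.ndarray] = {c: _scale_glyph(r) for c, r in _RAW_GLYPHS.items()}


def _save_icon(kind: str) -> np.ndarray:
    x0, y0, x1, y1 = SAVE_INDICATOR_BOX
    h, w = y1 - y0, x1 - x0
    icon = np.zeros((h, w), dtype=np.uint8)
    if kind == "image_save":
        icon[4:-4, 4:-4] = 255
    elif kind == "clip_save":
        for r0 in range(4, h - 8, 16):
            icon[r0 : r0 + 8, 4:-4] = 255
    else:
        raise ValueError(f"unknown save kind {kind!r}")
    return icon


SAVE_ICONS: dict[str, np.ndarray] = {k: _save_icon(k) for k in ("image_save", "clip_save")}


class RenderError(ValueError):
    """A UI value cannot be drawn with the available glyph set."""


def render_text(text: str, glyphs: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Render a string into a horizontal strip of glyph cells."""
    glyphs = glyphs or DEFAULT_GLYPHS
    cells = []
    for ch in text:
        if ch not in glyphs:
            raise RenderError(f"character {ch!r} not in glyph set")
        cells.append(glyphs[ch])
    return np.hstack(cells) if cells else np.zeros((CELL_H, 0), dtype=np.uint8)


def format_value(value: float) -> str:
    """Fixed six-character numeric display text (one decimal place)."""
    text = VALUE_FORMAT.format(float(value))
    if len(text) != N_VALUE_CELLS:
        raise RenderError(f"value {value!r} does not fit the six-cell display")
    return text


def render_numeric_box(value: float, glyphs: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Render one numeric display box (six cells) for a value in display units."""
    return render_text(format_value(value), glyphs)


def _blit(raster: np.ndarray, x0: int, y0: int, patch: np.ndarray) -> None:
    raster[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]] = patch


def render_ui_frame(
    state: UIState, glyphs: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    """Render the full-screen UI raster for one frame.

    The raster is a 1080x1920 uint8 image containing only interface glyphs
    (no echo content): freeze indicator, save icon, measurement type/value
    and the thermal-index display, each at its fixed documented rectangle.
    """
    glyphs = glyphs or DEFAULT_GLYPHS
    raster = np.zeros((SCREEN_HEIGHT, SCREEN_WIDTH), dtype=np.uint8)

    if state.frozen:
        x0, y0, x1, y1 = FREEZE_INDICATOR_BOX
        raster[y0:y1, x0:x1] = 255
    if state.save_kind:
        if state.save_kind not in SAVE_ICONS:
            raise RenderError(f"unknown save kind {state.save_kind!r}")
        _blit(raster, SAVE_INDICATOR_BOX[0], SAVE_INDICATOR_BOX[1], SAVE_ICONS[state.save_kind])
    if state.measurement is not None:
        mtype, mvalue = state.measurement
        if mvalue <= 0:
            raise RenderError(f"measurement value must be positive, got {mvalue}")
        # One-cell type slot: H / A / F (first letter uniquely identifies
        # head circumference, abdominal circumference, femur length).
        _blit(raster, MEAS_TYPE_BOX[0], MEAS_TYPE_BOX[1], render_text(mtype[0], glyphs))
        _blit(raster, MEAS_VALUE_BOX[0], MEAS_VALUE_BOX[1], render_numeric_box(mvalue, glyphs))
    _blit(
        raster,
        THERMAL_VALUE_BOX[0],
        THERMAL_VALUE_BOX[1],
        render_numeric_box(state.thermal_index, glyphs),
    )
    return raster
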