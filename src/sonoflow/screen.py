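"""Screen geometry: areas of interest (AOIs) and UI widget rectangles.

Coordinates are pixels on the 1920x1080 ultrasound display, origin at the
top-left corner, x rightward, y downward.  Rectangles are half-open:
``x0 <= x < x1`` and ``y0 <= y < y1``.

The layout is the artifact's own fixed convention (a stand-in for a real
machine's interface): the live image occupies the central area, the
measurement box and the bioeffect (thermal index) box sit in the right-hand
column, and the freeze/save indicators sit at the bottom-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import SCREEN_HEIGHT, SCREEN_WIDTH


@dataclass(frozen=True)
class AOIRegion:
    """Named half-open screen rectangle used to attribute gaze samples."""

    name: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 <= SCREEN_WIDTH):
            raise ValueError(f"AOI {self.name!r}: x bounds {self.x0},{self.x1} invalid")
        if not (0 <= self.y0 < self.y1 <= SCREEN_HEIGHT):
            raise ValueError(f"AOI {self.name!r}: y bounds {self.y0},{self.y1} invalid")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains(self, x, y):
        """Vectorized membership test (half-open on both axes)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


#: Gaze areas of interest.
IMAGE_AREA = AOIRegion("image_area", 420, 60, 1500, 940)
MEASUREMENT_BOX = AOIRegion("measurement_box", 1530, 110, 1880, 230)
BIOEFFECT_BOX = AOIRegion("bioeffect_box", 1530, 10, 1880, 100)

DEFAULT_AOIS: dict[str, AOIRegion] = {
    a.name: a for a in (IMAGE_AREA, MEASUREMENT_BOX, BIOEFFECT_BOX)
}

# UI widget rectangles read by the extraction stage.  Numeric boxes hold six
# fixed-pitch glyph cells (24x28 px each); indicator boxes hold icons.
MEAS_TYPE_BOX = (1540, 150, 1564, 178)       # one glyph cell: H / A / F
MEAS_VALUE_BOX = (1580, 150, 1724, 178)      # six glyph cells, value in mm
THERMAL_VALUE_BOX = (1700, 40, 1844, 68)     # six glyph cells, thermal index
FREEZE_INDICATOR_BOX = (40, 980, 120, 1040)
SAVE_INDICATOR_BOX = (140, 980, 220, 1040)

UI_REGIONS: dict[str, tuple[int, int, int, int]] = {
    "meas_type": MEAS_TYPE_BOX,
    "meas_value": MEAS_VALUE_BOX,
    "thermal_value": THERMAL_VALUE_BOX,
    "freeze_indicator": FREEZE_INDICATOR_BOX,
    "save_indicator": SAVE_INDICATOR_BOX,
}
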