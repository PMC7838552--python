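"""Screen geometry and pixel/degree conversion.

All analysis runs in degrees of visual angle in a screen-centered frame
(x rightward, y upward).  Stimuli are specified in pixels of a concrete
display, so each experiment ships a named screen preset; conversion uses
the small-angle expression

    deg = pix * (screen_width_cm / horizontal_resolution) / distance_cm * 180/pi

which is accurate to <0.1% for the sub-degree displacements involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used to convert pixels to degrees."""

    width_cm: float
    height_cm: float
    width_px: int
    height_px: int
    distance_cm: float
    refresh_hz: float = 75.0

    @property
    def deg_per_px(self) -> float:
        return (self.width_cm / self.width_px) / self.distance_cm * (180.0 / math.pi)

    def px_to_deg(self, px):
        return px * self.deg_per_px

    def deg_to_px(self, deg):
        return deg / self.deg_per_px


#: 20-in CRT, 1024x768 @ 75 Hz, 57 cm viewing distance (ambiguous-cube study).
NECKER_SCREEN = ScreenGeometry(
    width_cm=40.0, height_cm=30.0, width_px=1024, height_px=768, distance_cm=57.0
)

#: 19-in CRT, 1280x1024 @ 75 Hz, 57 cm viewing distance (luminance-report studies).
REPLICATION_SCREEN = ScreenGeometry(
    width_cm=36.0, height_cm=27.5, width_px=1280, height_px=1024, distance_cm=57.0
)

SCREEN_PRESETS = {
    "necker": NECKER_SCREEN,
    "replication": REPLICATION_SCREEN,
}


def get_screen(name_or_geometry) -> ScreenGeometry:
    """Resolve a preset name or pass through a :class:`ScreenGeometry`."""
    if isinstance(name_or_geometry, ScreenGeometry):
        return name_or_geometry
    try:
        return SCREEN_PRESETS[str(name_or_geometry)]
    except KeyError:
        raise KeyError(
            f"unknown screen preset {name_or_geometry!r}; "
            f"available: {sorted(SCREEN_PRESETS)}"
        ) from None
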