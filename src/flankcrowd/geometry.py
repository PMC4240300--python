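"""Visual-angle geometry for a fixed-distance psychophysics display.

Stimulus sizes are specified physically (mm on the screen) but all task
parameters are in degrees of visual angle; the two are linked through the
viewing distance by ``angle = 2 * atan(size / (2 * distance))``.  At the
canonical 500 mm viewing distance a 10.5 mm letter subtends 1.20 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import GeometryError

#: Canonical viewing distance (mm).
DEFAULT_DISTANCE_MM = 500.0
#: Default pixel pitch of the simulated display (mm per pixel).
DEFAULT_PIXEL_PITCH_MM = 0.25


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing distance and display resolution.

    Parameters
    ----------
    distance_mm : float
        Eye-to-screen distance in mm; must be positive.
    pixel_pitch_mm : float
        Physical size of one display pixel in mm; must be positive.
    """

    distance_mm: float = DEFAULT_DISTANCE_MM
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        if not (self.distance_mm > 0):
            raise GeometryError(f"viewing distance must be > 0, got {self.distance_mm}")
        if not (self.pixel_pitch_mm > 0):
            raise GeometryError(f"pixel pitch must be > 0, got {self.pixel_pitch_mm}")

    def deg_to_px(self, angle_deg: float) -> int:
        """Nearest pixel count subtending ``angle_deg`` at this geometry."""
        return int(round(deg_to_mm(angle_deg, self.distance_mm) / self.pixel_pitch_mm))


def mm_to_deg(size_mm: float, distance_mm: float = DEFAULT_DISTANCE_MM) -> float:
    """Convert a physical extent on the screen to degrees of visual angle.

    Uses the exact (non-small-angle) relation ``2 * atan(s / (2 d))``.
    """
    if not (distance_mm > 0):
        raise GeometryError(f"viewing distance must be > 0, got {distance_mm}")
    if size_mm < 0:
        raise GeometryError(f"size must be >= 0, got {size_mm}")
    return math.degrees(2.0 * math.atan2(size_mm, 2.0 * distance_mm))


def deg_to_mm(angle_deg: float, distance_mm: float = DEFAULT_DISTANCE_MM) -> float:
    """Physical extent on the screen subtending ``angle_deg``; inverse of mm_to_deg."""
    if not (distance_mm > 0):
        raise GeometryError(f"viewing distance must be > 0, got {distance_mm}")
    if angle_deg < 0:
        raise GeometryError(f"angle must be >= 0, got {angle_deg}")
    if angle_deg >= 180.0:
        raise GeometryError(f"angle must be < 180 deg, got {angle_deg}")
    return 2.0 * distance_mm * math.tan(math.radians(angle_deg) / 2.0)
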