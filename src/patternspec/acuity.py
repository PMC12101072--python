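"""Physical-unit frequency bounds from camera geometry and viewing distance.

Two closed forms: the maximum spatial frequency retained by the analysis
given the sensor geometry, and the finest spatial frequency a viewer with a
given inter-receptor angle can resolve at a given distance.  Both are in
cycles per millimetre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AcuityParams",
    "max_analyzed_frequency",
    "spatial_resolution_limit",
]

#: Default sensor width (px) and horizontal field of view (mm) of the
#: shortest-extension camera configuration used for calibration.
DEFAULT_SENSOR_WIDTH_PX = 1392
DEFAULT_FOV_MM = 5.7
#: Default inter-receptor angle (degrees) of the salticid principal eye.
DEFAULT_INTER_RECEPTOR_DEG = 0.04
#: Default courtship viewing distance (mm).
DEFAULT_DISTANCE_MM = 27.0


@dataclass(frozen=True)
class AcuityParams:
    """Parameters for the two acuity bounds."""

    sensor_width_px: int = DEFAULT_SENSOR_WIDTH_PX
    fov_mm: float = DEFAULT_FOV_MM
    distance_mm: float = DEFAULT_DISTANCE_MM
    inter_receptor_deg: float = DEFAULT_INTER_RECEPTOR_DEG

    def __post_init__(self) -> None:
        for name in ("sensor_width_px", "fov_mm", "distance_mm", "inter_receptor_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def max_analyzed_frequency(
    sensor_width_px: float = DEFAULT_SENSOR_WIDTH_PX,
    fov_mm: float = DEFAULT_FOV_MM,
) -> float:
    """Maximum analysed spatial frequency in cycles/mm.

    The analysis keeps frequencies up to one tenth of the crop dimension in
    pixels, so in physical units the ceiling is ``sensor_width_px / fov_mm / 10``.

    >>> round(max_analyzed_frequency(1392, 5.7), 1)
    24.4
    """
    if sensor_width_px <= 0 or fov_mm <= 0:
        raise ValueError("sensor_width_px and fov_mm must be positive")
    return sensor_width_px / fov_mm / 10.0


def spatial_resolution_limit(
    distance_mm: float = DEFAULT_DISTANCE_MM,
    inter_receptor_deg: float = DEFAULT_INTER_RECEPTOR_DEG,
) -> float:
    """Finest resolvable spatial frequency (cycles/mm) at a viewing distance.

    One cycle needs two receptor rows, so the limit is
    ``1 / (4 * d * tan(angle / 2))`` with the inter-receptor angle in degrees.

    >>> round(spatial_resolution_limit(27, 0.04), 1)
    26.5
    """
    if distance_mm <= 0 or inter_receptor_deg <= 0:
        raise ValueError("distance_mm and inter_receptor_deg must be positive")
    half_angle_rad = math.radians(inter_receptor_deg) / 2.0
    return 1.0 / (4.0 * distance_mm * math.tan(half_angle_rad))
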