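"""Shared primitives: spatial calibration and zone labels.

Pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left
of the image, so smaller row values are physically *higher* in a vertically
mounted vial. Metric positions are expressed in millimetres, distances moved
in centimetres (the convention of the tracking software the pipeline mirrors).
"""

from __future__ import annotations

from dataclasses import dataclass

ZONE_UPPER = "upper"
ZONE_LOWER = "lower"
ZONE_UNDETECTED = "undetected"


@dataclass(frozen=True)
class CalibrationScale:
    """Linear pixel-to-millimetre calibration.

    Areas convert with the square of the scale: ``mm² = px² / pixels_per_mm²``.
    """

    pixels_per_mm: float

    def __post_init__(self) -> None:
        if not self.pixels_per_mm > 0:
            raise ValueError("pixels_per_mm must be positive")

    def px_to_mm(self, px: float) -> float:
        return px / self.pixels_per_mm

    def mm_to_px(self, mm: float) -> float:
        return mm * self.pixels_per_mm

    def area_px2_to_mm2(self, area_px2: float) -> float:
        return area_px2 / self.pixels_per_mm**2
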