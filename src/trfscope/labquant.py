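"""Closed-form laboratory quantification formulas.

Implemented verbatim as printed in the source protocols: the tumour/spheroid
volume proxy is (length x width)^2 x 0.526 — note this differs from the common
(width^2 x length)/2 ellipsoid proxy; the printed form is kept for fidelity —
and the DAB immunostaining optical density is log10(max intensity / mean
intensity) with an 8-bit maximum of 255.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Measurement2D", "tumour_volume", "dab_od"]

VOLUME_CONSTANT = 0.526


@dataclass(frozen=True)
class Measurement2D:
    """Calliper length/width measurement in mm (strictly positive)."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be strictly positive")


def tumour_volume(m: Measurement2D) -> float:
    """Volume proxy = (length x width)^2 x 0.526 (symmetric in length/width)."""
    return (m.length * m.width) ** 2 * VOLUME_CONSTANT


def dab_od(mean_intensity: float, max_intensity: float = 255.0) -> float:
    """DAB optical density = log10(max_intensity / mean_intensity).

    ``mean_intensity`` must be in (0, max_intensity]; a zero mean (saturated or
    empty field) is an error.
    """
    if mean_intensity <= 0:
        raise ValueError("mean intensity must be > 0 (saturated/empty field)")
    if mean_intensity > max_intensity:
        raise ValueError("mean intensity exceeds the maximum intensity")
    return math.log10(max_intensity / mean_intensity)
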