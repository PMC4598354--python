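"""Physical description of the tubular vein phantom.

The phantom is a straight PTFE tube of circular cross-section, inclined at a
fixed angle, imaged side-on by a camera with a known spatial calibration.
All unit conversions (px -> mm, linear rate -> volumetric rate) are grounded
in this object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry and calibration of one vein-phantom recording.

    Parameters
    ----------
    inner_diameter_mm
        Tube inner diameter in mm. The study design uses 4 mm (small
        varicosity) and 10 mm (large varicosity), but any positive value is
        accepted.
    inclination_deg
        Inclination angle of the tube above horizontal, degrees in [0, 90).
        Metadata only: it conditions the physics of the experiment, not the
        image analysis.
    mm_per_pixel
        Spatial calibration of the camera along the tube axis.
    injection_end
        Which image side the injection port is on; plug length is measured
        from this end. ``"left"`` or ``"right"``.
    """

    inner_diameter_mm: float = 4.0
    inclination_deg: float = 25.0
    mm_per_pixel: float = 0.25
    injection_end: str = "left"

    def __post_init__(self) -> None:
        if not (self.inner_diameter_mm > 0 and math.isfinite(self.inner_diameter_mm)):
            raise InvalidParameterError(
                f"inner_diameter_mm must be positive, got {self.inner_diameter_mm}"
            )
        if not (0 <= self.inclination_deg < 90):
            raise InvalidParameterError(
                f"inclination_deg must be in [0, 90), got {self.inclination_deg}"
            )
        if not (self.mm_per_pixel > 0 and math.isfinite(self.mm_per_pixel)):
            raise InvalidParameterError(
                f"mm_per_pixel must be positive, got {self.mm_per_pixel}"
            )
        if self.injection_end not in ("left", "right"):
            raise InvalidParameterError(
                f"injection_end must be 'left' or 'right', got {self.injection_end!r}"
            )

    @property
    def cross_section_mm2(self) -> float:
        """Lumen cross-sectional area in mm^2."""
        return math.pi * (self.inner_diameter_mm / 2.0) ** 2
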