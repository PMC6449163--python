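"""Dorsoventral slice-position regression and longitudinal zone binning.

Slice position along the septotemporal (dorsoventral) axis is predicted
from three anatomical shape ratios measured in the transverse plane — the
transverse/radial length ratios of CA1, CA3, and the dentate gyrus — via a
published linear regression:

    position (mm) = -7.23 + 0.43 * CA1 + 0.50 * CA3 + 0.34 * DG

with dorsal positive.  The regression's calibration data belong to the
prior study that fitted it, so the model is evaluated, never re-fitted;
its stated precision (+/-0.59 mm at 90% confidence) is carried as metadata.

The longitudinal axis is divided into four contiguous 1.5-mm zones.  The
source publications print zone midpoints (dorsal 2 mm, ventral -2.5 mm)
rather than edges, so the edges here are reconstructed from those midpoints:
dorsal [1.25, 2.75], dorsal-intermediate [-0.25, 1.25), ventral-intermediate
[-1.75, -0.25), ventral [-3.25, -1.75).  Positions elsewhere on the ~8-mm
axis are labelled "outside".  Bins are closed at their dorsal edge for
deterministic boundary behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AnatomicalRatios",
    "PositionEstimate",
    "longitudinal_position",
    "classify_zone",
    "estimate_position",
    "INTERCEPT",
    "COEF_CA1",
    "COEF_CA3",
    "COEF_DG",
    "POSITION_UNCERTAINTY_MM",
    "ZONE_BINS",
]

INTERCEPT = -7.23
COEF_CA1 = 0.43
COEF_CA3 = 0.50
COEF_DG = 0.34

#: stated predictive precision of the source regression (mm, 90% confidence)
POSITION_UNCERTAINTY_MM = 0.59

#: (label, ventral edge, dorsal edge); dorsal-most bin closed at both edges
ZONE_BINS = (
    ("dorsal", 1.25, 2.75),
    ("dorsal-intermediate", -0.25, 1.25),
    ("ventral-intermediate", -1.75, -0.25),
    ("ventral", -3.25, -1.75),
)


@dataclass(frozen=True)
class AnatomicalRatios:
    """Transverse/radial shape ratios for CA1, CA3, and the dentate gyrus."""

    ca1: float
    ca3: float
    dg: float

    def __post_init__(self):
        for name in ("ca1", "ca3", "dg"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} ratio must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class PositionEstimate:
    position: float  # mm, dorsal positive
    zone: str
    uncertainty: float = POSITION_UNCERTAINTY_MM  # mm, 90% confidence


def longitudinal_position(ratios: AnatomicalRatios) -> float:
    """Evaluate the printed position regression, in mm (dorsal positive)."""
    return (
        INTERCEPT
        + COEF_CA1 * ratios.ca1
        + COEF_CA3 * ratios.ca3
        + COEF_DG * ratios.dg
    )


def classify_zone(position: float) -> str:
    """Longitudinal zone label for a position in mm."""
    dorsal_label, lo, hi = ZONE_BINS[0]
    if lo <= position <= hi:
        return dorsal_label
    for label, lo, hi in ZONE_BINS[1:]:
        if lo <= position < hi:
            return label
    return "outside"


def estimate_position(ratios: AnatomicalRatios) -> PositionEstimate:
    """Position regression plus zone classification in one call."""
    pos = longitudinal_position(ratios)
    return PositionEstimate(position=pos, zone=classify_zone(pos))
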