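"""Two-point Hounsfield-unit standardization from water/air references.

Raw reconstructed gray values depend on exposure settings, so scans
acquired with different parameters are not directly comparable. Anchoring
an affine map HU(g) = slope·g + intercept at the mean gray values of an air
and a distilled-water reference (the water cell scanned immediately after
the specimen, without switching off the beam) puts every scan on a common
density scale.

Two anchor conventions are supported:

* ``"air0"`` (default): air → 0 HU, water → 1000 HU — the convention used
  in the protocol-comparison workflow this package implements;
* ``"clinical"``: air → −1000 HU, water → 0 HU — the standard clinical CT
  definition.

Outputs are full precision (no rounding to integer HU). Note that a
contrast ratio computed on HU values differs from one computed on raw gray
values whenever the intercept is nonzero, and that with the default
convention an air background sits near 0 HU, where the ratio's denominator
is ill-conditioned — hence the explicit ε guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CONVENTIONS",
    "EPS_HU",
    "CalibrationModel",
    "fit_calibration",
    "to_hu",
    "hu_contrast_ratio",
]

#: Anchor HU values per convention as (HU at air, HU at water).
CONVENTIONS = {"air0": (0.0, 1000.0), "clinical": (-1000.0, 0.0)}

#: Smallest background |HU| considered non-degenerate.
EPS_HU = 10.0

_ANCHOR_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationModel:
    """Affine gray→HU map anchored at air and water reference means."""

    air_gray: float
    water_gray: float
    slope: float
    intercept: float
    convention: str = "air0"

    def __post_init__(self) -> None:
        if self.water_gray <= self.air_gray:
            raise ValueError("water_gray must exceed air_gray")
        hu_air, hu_water = CONVENTIONS[self.convention]
        for gray, anchor in ((self.air_gray, hu_air), (self.water_gray, hu_water)):
            got = self.slope * gray + self.intercept
            if abs(got - anchor) > _ANCHOR_TOL:
                raise ValueError(
                    f"model maps gray {gray} to {got} HU, expected anchor {anchor}"
                )


def fit_calibration(
    air_mean: float, water_mean: float, convention: str = "air0"
) -> CalibrationModel:
    """Fit the affine map through the two reference anchors.

    With the default convention: slope = 1000 / (water − air) and
    intercept = −slope·air, so HU(air) = 0 and HU(water) = 1000 exactly.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {sorted(CONVENTIONS)}")
    if not (math.isfinite(air_mean) and math.isfinite(water_mean)):
        raise ValueError("reference means must be finite")
    if water_mean <= air_mean:
        raise ValueError(
            f"water mean ({water_mean}) must exceed air mean ({air_mean}); "
            f"check for a phantom mix-up"
        )
    hu_air, hu_water = CONVENTIONS[convention]
    slope = (hu_water - hu_air) / (water_mean - air_mean)
    intercept = hu_air - slope * air_mean
    return CalibrationModel(
        air_gray=air_mean,
        water_gray=water_mean,
        slope=slope,
        intercept=intercept,
        convention=convention,
    )


def to_hu(g, model: CalibrationModel):
    """Map gray values (scalar or array) to HU; shape-preserving, unclipped."""
    if np.isscalar(g):
        return model.slope * float(g) + model.intercept
    return model.slope * np.asarray(g, dtype=np.float64) + model.intercept


def hu_contrast_ratio(organ_hu: float, background_hu: float, eps_hu: float = EPS_HU) -> float:
    """Contrast ratio computed on HU means: (organ − background) / background."""
    if abs(background_hu) <= eps_hu:
        raise ValueError(
            f"background of {background_hu:.3g} HU is within {eps_hu} HU of zero: "
            f"with an air-anchored calibration the background maps near 0 HU and "
            f"the ratio's denominator is ill-conditioned; compare raw-gray ratios "
            f"or HU differences instead"
        )
    return (organ_hu - background_hu) / background_hu
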