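"""The nine calcaneal morphological parameters and their containers.

Seven parameters derive from surface landmarks A–F (plus the constructed
points G and H): five lengths (mm), Gissane's angle and Böhler's angle
(degrees). The remaining two are articular-facet areas (cm²) measured on
the bone surface mesh: the posterior subtalar facet (APF) and the middle
facet (AMF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterator, Optional

#: Canonical reporting order for all nine parameters.
PARAMETERS: tuple[str, ...] = (
    "LCA", "HPF", "LPF", "LAP", "HAP", "GA", "BA", "APF", "AMF",
)

#: Subsets by kind: lengths in mm, angles in degrees, facet areas in cm².
LENGTH_PARAMETERS: tuple[str, ...] = ("LCA", "HPF", "LPF", "LAP", "HAP")
ANGLE_PARAMETERS: tuple[str, ...] = ("GA", "BA")
AREA_PARAMETERS: tuple[str, ...] = ("APF", "AMF")

#: The seven parameters fully determined by the landmark configuration.
LANDMARK_PARAMETERS: tuple[str, ...] = LENGTH_PARAMETERS + ANGLE_PARAMETERS

UNITS: dict[str, str] = {
    **{p: "mm" for p in LENGTH_PARAMETERS},
    **{p: "deg" for p in ANGLE_PARAMETERS},
    **{p: "cm^2" for p in AREA_PARAMETERS},
}

LONG_NAMES: dict[str, str] = {
    "LCA": "length of calcaneal axis",
    "HPF": "height of posterior facet",
    "LPF": "length of posterior facet",
    "LAP": "length of anterior process",
    "HAP": "height of anterior process",
    "GA": "Gissane's angle",
    "BA": "Böhler's angle",
    "APF": "area of posterior facet",
    "AMF": "area of middle facet",
}


@dataclass(frozen=True)
class ParameterVector:
    """A prescribed set of the nine parameters, used to drive simulation.

    Invariants are those of a plausible normal calcaneus: positive lengths
    and areas, Gissane's angle in (0, 180)°, Böhler's angle in (0, 90)°.
    Realizability of the landmark construction (e.g. HPF smaller than the
    realized |A−G| distance) is checked at realization time, not here.
    """

    LCA: float
    HPF: float
    LPF: float
    LAP: float
    HAP: float
    GA: float
    BA: float
    APF: float
    AMF: float

    def __post_init__(self) -> None:
        for name in LENGTH_PARAMETERS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive length, got {v!r}")
        if not 0.0 < self.GA < 180.0:
            raise ValueError(f"GA must lie in (0, 180) degrees, got {self.GA!r}")
        if not 0.0 < self.BA < 90.0:
            raise ValueError(f"BA must lie in (0, 90) degrees, got {self.BA!r}")
        for name in AREA_PARAMETERS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive area, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __iter__(self) -> Iterator[float]:
        return iter(getattr(self, p) for p in PARAMETERS)


@dataclass(frozen=True)
class MorphometricRecord:
    """Measured values of the nine parameters for one calcaneus.

    APF/AMF are ``None`` when no mesh + facet boundaries were supplied;
    the seven landmark parameters are always present. Böhler's angle is
    allowed up to 180° here (a measurement may fall outside the normal
    anatomical range; the record only enforces geometric validity).
    """

    LCA: float
    HPF: float
    LPF: float
    LAP: float
    HAP: float
    GA: float
    BA: float
    APF: Optional[float] = None
    AMF: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("LCA", "LPF", "LAP", "HAP"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive length, got {v!r}")
        if not (math.isfinite(self.HPF) and self.HPF >= 0):
            raise ValueError(f"HPF must be non-negative, got {self.HPF!r}")
        if not 0.0 < self.GA <= 180.0:
            raise ValueError(f"GA must lie in (0, 180] degrees, got {self.GA!r}")
        if not 0.0 <= self.BA < 180.0:
            raise ValueError(f"BA must lie in [0, 180) degrees, got {self.BA!r}")
        for name in AREA_PARAMETERS:
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a non-negative area, got {v!r}")

    def as_dict(self, include_missing: bool = True) -> dict[str, float]:
        d = {p: getattr(self, p) for p in PARAMETERS}
        if not include_missing:
            d = {k: v for k, v in d.items() if v is not None}
        return d
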