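"""TEER-to-conductivity conversions for the capillary wall and tight junction.

Transendothelial electrical resistance (TEER) is the areal resistance of the
vessel wall, conventionally reported in Ohm cm^2.  Two conversions are
provided, matching the two scales at which the wall is modelled:

* wall scale — the wall is a uniform slab of thickness ``l_wall``, so
  ``sigma_wall = l_wall / TEER``;
* tight-junction scale — all of the wall resistance is attributed to the TJ
  constriction (length ``l_TJ``, opening ``2h``, junction length per unit
  vessel area ``L_TJ``), so ``sigma_TJ = l_TJ / (TEER * 2h * L_TJ)``.

The per-compartment conductivity table used across all three model scales is
shipped as package data (``data/conductivities.yaml``) so users can override
individual compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .electroosmosis import InvalidParameterError

__all__ = [
    "TEERSpec",
    "TJGeometry",
    "teer_to_ohm_m2",
    "ohm_m2_to_ohm_cm2",
    "wall_conductivity_from_teer",
    "tj_conductivity_from_teer",
    "default_conductivities",
]

OHM_CM2_PER_OHM_M2 = 1e4  # 1 Ohm m^2 = 1e4 Ohm cm^2


def teer_to_ohm_m2(value: float, unit: str = "ohm_cm2") -> float:
    """Convert a TEER value to Ohm m^2 from an explicitly tagged unit."""
    if unit == "ohm_cm2":
        return value / OHM_CM2_PER_OHM_M2
    if unit == "ohm_m2":
        return value
    raise InvalidParameterError(f"unknown TEER unit {unit!r}; use ohm_cm2 or ohm_m2")


def ohm_m2_to_ohm_cm2(value: float) -> float:
    return value * OHM_CM2_PER_OHM_M2


@dataclass(frozen=True)
class TEERSpec:
    """A TEER value with an explicit unit tag plus the wall thickness.

    The default unit is Ohm cm^2, the unit in which BBB TEER is reported
    experimentally (1000 Ohm cm^2 for a tight in vivo barrier, 5000 for an
    upper-bound barrier).
    """

    teer: float
    unit: str = "ohm_cm2"
    wall_thickness: float = 1e-6  # m

    def __post_init__(self) -> None:
        if self.teer <= 0:
            raise InvalidParameterError("teer must be positive")
        if self.wall_thickness <= 0:
            raise InvalidParameterError("wall_thickness must be positive")
        teer_to_ohm_m2(1.0, self.unit)  # validate the tag

    @property
    def teer_ohm_m2(self) -> float:
        return teer_to_ohm_m2(self.teer, self.unit)

    @property
    def teer_ohm_cm2(self) -> float:
        return ohm_m2_to_ohm_cm2(self.teer_ohm_m2)


@dataclass(frozen=True)
class TJGeometry:
    """Tight-junction and interendothelial-cleft geometry.

    Defaults describe a single 11 nm long, 2 nm wide TJ sitting 105 nm down a
    700 nm long, 20 nm wide cleft, with 150 000 m of junction per m^2 of
    vessel wall.
    """

    tj_length: float = 11e-9                  # m, l_TJ
    opening_2h: float = 2e-9                  # m, TJ opening
    junction_length_per_area: float = 150000.0  # m per m^2 of wall, L_TJ
    tj_position_from_glycocalyx: float = 105e-9  # m, depth of TJ in the cleft
    cleft_length: float = 700e-9              # m
    cleft_width: float = 20e-9                # m

    def __post_init__(self) -> None:
        for name in (
            "tj_length",
            "opening_2h",
            "junction_length_per_area",
            "tj_position_from_glycocalyx",
            "cleft_length",
            "cleft_width",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.tj_position_from_glycocalyx >= self.cleft_length:
            raise InvalidParameterError(
                "tj_position_from_glycocalyx must be inside the cleft"
            )


def wall_conductivity_from_teer(spec: TEERSpec) -> float:
    """Uniform-slab wall conductivity, S/m: wall thickness divided by TEER.

    1000 Ohm cm^2 with a 1 um wall gives 1e-5 S/m; 5000 gives 2e-6 S/m.
    """
    return spec.wall_thickness / spec.teer_ohm_m2


def tj_conductivity_from_teer(teer, tj: TJGeometry) -> float:
    """TJ conductivity, S/m, attributing all wall resistance to the TJ.

    ``sigma_TJ = l_TJ / (TEER * 2h * L_TJ)``.  ``teer`` may be a
    :class:`TEERSpec` or a bare number interpreted as Ohm cm^2.

    1000 Ohm cm^2 with the default geometry gives 3.67e-4 S/m; 5000 gives
    7.34e-5 S/m.
    """
    if not isinstance(teer, TEERSpec):
        teer = TEERSpec(teer=float(teer))
    return tj.tj_length / (
        teer.teer_ohm_m2 * tj.opening_2h * tj.junction_length_per_area
    )


def default_conductivities() -> dict[str, float]:
    """Per-compartment electrical conductivities (S/m) across all scales."""
    text = resources.files("tdcsflow.data").joinpath("conductivities.yaml").read_text()
    return yaml.safe_load(text)["conductivities"]
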