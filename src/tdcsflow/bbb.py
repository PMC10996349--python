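"""Coupling between capillary-wall current density and the tight-junction field.

A current density ``J_vi`` crossing the capillary wall is funnelled through
the BBB ultrastructure — glycocalyx, interendothelial cleft, the TJ
constriction, basement membrane and astrocytic channel — and concentrates an
electric field ``E_TJ`` inside the 11 nm TJ.  The relation is linear,

    E_TJ = C * J_vi,

with a coupling constant C (V m / A) that depends on the wall TEER and on
the number of TJs in the cleft.

Two ways to obtain C are provided:

* ``lookup`` (default) — the constants from the full 3D ultrastructure field
  solution: 2.73e6 V m/A at 1000 Ohm cm^2 TEER and 3.83e6 at 5000, for a
  single TJ.
* ``model`` — a reduced-order series-parallel conductance network.  The
  paracellular branch is the series chain glycocalyx -> cleft (luminal side)
  -> TJ -> cleft (abluminal side) -> basement membrane -> astrocytic
  channel, each with per-vessel-area conductance sigma * open_fraction /
  length; the transcellular branch is the insulating endothelial membrane,
  sigma_insulating / wall_thickness.  The fraction f of wall current taking
  the paracellular route sets C = f * TEER / (l_TJ * area_correction), where
  the area correction (default 2.04) maps the parenchyma-side current
  density onto the smaller astro-endothelial surface.  This exposes the
  physics of the coupling for sensitivity work; it reproduces the lookup
  constants to within ~30%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .electroosmosis import InvalidParameterError
from .membranes import TEERSpec, TJGeometry

__all__ = [
    "UltrastructureModel",
    "CouplingConstant",
    "COUPLING_LOOKUP_VM_PER_A",
    "coupling_constant",
    "tj_field_from_wall_current",
]

# Coupling constants from the full 3D BBB ultrastructure solution, single TJ,
# keyed by TEER in Ohm cm^2.
COUPLING_LOOKUP_VM_PER_A: dict[float, float] = {1000.0: 2.73e6, 5000.0: 3.83e6}


@dataclass(frozen=True)
class UltrastructureModel:
    """Geometry and conductivities of the reduced-order BBB conductance network.

    Channel conductivities are in S/m; the glycocalyx thickness, basement
    membrane thickness and astrocytic channel length are not tightly
    constrained but sit far above the TJ resistance, so C is insensitive to
    them.
    """

    tj: TJGeometry = field(default_factory=TJGeometry)
    wall_thickness: float = 1e-6          # m, endothelial wall
    sigma_cleft: float = 1.5              # S/m, interendothelial cleft channel
    sigma_glycocalyx: float = 0.3         # S/m
    sigma_basement: float = 0.3           # S/m
    sigma_astro_channel: float = 1.5      # S/m
    sigma_transcellular: float = 1e-5     # S/m, insulating membranes
    glycocalyx_thickness: float = 100e-9  # m
    basement_thickness: float = 100e-9    # m
    astro_channel_length: float = 1e-6    # m
    area_correction: float = 2.04         # parenchyma / astro-endothelial area
    n_tight_junctions: int = 1

    def __post_init__(self) -> None:
        if self.area_correction < 1:
            raise InvalidParameterError("area_correction must be >= 1")
        if self.n_tight_junctions < 1:
            raise InvalidParameterError("n_tight_junctions must be >= 1")

    # -- per-unit-vessel-area branch conductances (S/m^2) ------------------

    def paracellular_conductance(self, teer: TEERSpec) -> float:
        """Series chain through glycocalyx, cleft, TJ, basement membrane, astrocyte."""
        tj = self.tj
        cleft_frac = tj.cleft_width * tj.junction_length_per_area
        pre_len = tj.tj_position_from_glycocalyx
        post_len = tj.cleft_length - tj.tj_position_from_glycocalyx - tj.tj_length
        # TJ conductance per vessel area follows from attributing the full
        # TEER to the constriction: sigma_TJ * 2h * L_TJ / l_TJ = 1/TEER.
        resistances = [
            self.glycocalyx_thickness / self.sigma_glycocalyx,  # full coverage
            pre_len / (self.sigma_cleft * cleft_frac),
            teer.teer_ohm_m2,
            post_len / (self.sigma_cleft * cleft_frac),
            self.basement_thickness / self.sigma_basement,      # full coverage
            self.astro_channel_length / (self.sigma_astro_channel * cleft_frac),
        ]
        return self.n_tight_junctions / sum(resistances)

    def transcellular_conductance(self) -> float:
        return self.sigma_transcellular / self.wall_thickness


@dataclass(frozen=True)
class CouplingConstant:
    """E_TJ per unit wall current density, with its provenance."""

    C: float               # V m / A
    teer_ohm_cm2: float
    mode: str              # "lookup" | "model"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidParameterError("coupling constant must be positive")


def coupling_constant(
    model: UltrastructureModel | None = None,
    teer: float | TEERSpec = 1000.0,
    mode: str = "lookup",
) -> CouplingConstant:
    """Coupling constant C mapping wall current density to TJ field.

    Parameters
    ----------
    model
        Reduced-order network parameters (required for ``mode="model"``;
        defaults are the standard ultrastructure).
    teer
        TEER, Ohm cm^2 if bare number.  Lookup mode supports only the
        tabulated values (1000, 5000); model mode accepts any positive TEER.
    mode
        ``"lookup"`` for the tabulated 3D-solution constants (default),
        ``"model"`` for the series-parallel network.
    """
    spec = teer if isinstance(teer, TEERSpec) else TEERSpec(teer=float(teer))
    if mode == "lookup":
        key = spec.teer_ohm_cm2
        for tabulated, c in COUPLING_LOOKUP_VM_PER_A.items():
            if abs(key - tabulated) < 1e-6 * tabulated:
                return CouplingConstant(C=c, teer_ohm_cm2=tabulated, mode="lookup")
        available = sorted(COUPLING_LOOKUP_VM_PER_A)
        raise InvalidParameterError(
            f"no tabulated coupling constant for TEER {key:g} Ohm cm^2; "
            f"available: {available}; use mode='model' for other values"
        )
    if mode == "model":
        if model is None:
            model = UltrastructureModel()
        g_para = model.paracellular_conductance(spec)
        g_trans = model.transcellular_conductance()
        f = g_para / (g_para + g_trans)
        c = f * spec.teer_ohm_m2 / (model.tj.tj_length * model.area_correction)
        return CouplingConstant(C=c, teer_ohm_cm2=spec.teer_ohm_cm2, mode="model")
    raise InvalidParameterError(f"unknown mode {mode!r}; use 'lookup' or 'model'")


def tj_field_from_wall_current(J_vi: float, constant: CouplingConstant) -> float:
    """TJ field E_TJ = C * J_vi (V/m); the sign of J_vi is preserved."""
    return constant.C * J_vi
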