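"""Run configuration and the staged pipeline driver.

A :class:`RunConfig` collects every tunable of the chain — double-layer
constants, TJ geometry, TEER, network generation targets, solver grid and
boundary mode, exchange convention and tDCS dose — with defaults equal to
the standard parameterization of each stage.  :func:`run_pipeline` executes
the stages in order, feeding each stage's peak output into the next:

  head-scale peak current density (per mA)
    -> capillary voxel solve (signed wall current densities)
    -> TJ coupling (E_TJ = C * J) and electroosmotic flux (QA)
    -> net interstitial exchange and the scaling factor k
    -> brain-wide exchange map (k * current-density map)

and writes per-stage tables plus a provenance record of every constant used.
Outputs are deterministic (byte-identical) for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from .bbb import UltrastructureModel, coupling_constant
from .capillary import (
    DEFAULT_VOXEL_DIMS,
    generate_network,
    network_stats,
    solve_voxel_current,
)
from .electroosmosis import (
    DoubleLayerParams,
    InvalidParameterError,
    fit_coefficients,
    flux_coefficient,
)
from .membranes import (
    TEERSpec,
    TJGeometry,
    tj_conductivity_from_teer,
    wall_conductivity_from_teer,
)
from .pipeline import (
    PEAK_CURRENT_DENSITY_PER_MA,
    BrainField,
    couple_solution,
    scale_brain_map,
    synthetic_brain_field,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline settings; defaults are the standard parameterization."""

    electroosmosis: DoubleLayerParams = field(default_factory=DoubleLayerParams)
    tj: TJGeometry = field(default_factory=TJGeometry)
    teer_ohm_cm2: float = 1000.0
    wall_thickness: float = 1e-6
    coupling_mode: str = "lookup"            # lookup | model
    boundary_mode: str = "closed"            # closed | open
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    target_length_density: float = 557.0     # mm / mm^3
    diameter_range: tuple[float, float] = (8e-6, 10e-6)
    network_seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    n_grounded_segments: int = 4
    exchange_convention: str = "both"        # both | half
    applied_current_mA: float = 1.0
    montage: str = "bifrontal"
    brain_shape: tuple[int, int, int] = (40, 48, 40)
    brain_voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_seed: int = 0

    @property
    def teer(self) -> TEERSpec:
        return TEERSpec(
            teer=self.teer_ohm_cm2, unit="ohm_cm2", wall_thickness=self.wall_thickness
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "electroosmosis" in kwargs and isinstance(kwargs["electroosmosis"], dict):
            kwargs["electroosmosis"] = DoubleLayerParams(**kwargs["electroosmosis"])
        if "tj" in kwargs and isinstance(kwargs["tj"], dict):
            kwargs["tj"] = TJGeometry(**kwargs["tj"])
        for key in ("voxel_dims", "diameter_range", "grid_shape", "brain_shape",
                    "brain_voxel_size_mm"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _write_tsv(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the staged pipeline and write per-stage artifacts.

    Returns the provenance record (constants, seeds, per-stage peaks) that
    is also written to ``provenance.json`` in the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: electroosmotic coefficients (velocity and flux per unit field)
    coeffs = fit_coefficients(config.electroosmosis)
    q_coeff = flux_coefficient(coeffs, config.tj)
    _write_tsv(
        out / "eo_coefficients.tsv",
        [
            {
                "avg_velocity_coeff_m_s_per_V_m": coeffs.avg_velocity_coeff,
                "max_velocity_coeff_m_s_per_V_m": coeffs.max_velocity_coeff,
                "flux_coeff_m3_s_m2_per_V_m": q_coeff,
            }
        ],
    )

    # stage: membrane conductivities from TEER
    spec = config.teer
    sigma_wall = wall_conductivity_from_teer(spec)
    sigma_tj = tj_conductivity_from_teer(spec, config.tj)
    _write_tsv(
        out / "membrane_conductivities.tsv",
        [
            {
                "teer_ohm_cm2": spec.teer_ohm_cm2,
                "sigma_wall_S_per_m": sigma_wall,
                "sigma_tj_S_per_m": sigma_tj,
            }
        ],
    )

    # stage: wall-current -> TJ-field coupling constant
    model = UltrastructureModel(tj=config.tj, wall_thickness=config.wall_thickness)
    constant = coupling_constant(model, spec, mode=config.coupling_mode)

    # stage: capillary network in the peak-current-density voxel
    graph = generate_network(
        voxel_dims=config.voxel_dims,
        target_length_density=config.target_length_density,
        diameter_range=config.diameter_range,
        seed=config.network_seed,
        wall_thickness=config.wall_thickness,
    )
    stats = network_stats(graph)
    tio.save_vessel_graph_json(graph, out / "network.json")

    # stage: voxel current solve driven by the head-scale peak density
    j_in = PEAK_CURRENT_DENSITY_PER_MA * config.applied_current_mA
    solution = solve_voxel_current(
        graph,
        boundary_mode=config.boundary_mode,
        teer=spec,
        inward_current_density=j_in,
        grid_shape=config.grid_shape,
        n_grounded_segments=config.n_grounded_segments,
    )
    tio.solution_table(solution).to_csv(
        out / "wall_elements.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # stage: electroosmotic coupling and net exchange
    result = couple_solution(
        solution,
        q_coeff,
        constant,
        float(config.voxel_dims[0] * config.voxel_dims[1] * config.voxel_dims[2]),
        convention=config.exchange_convention,
    )
    _write_tsv(
        out / "exchange.tsv",
        [
            {
                "boundary_mode": result.boundary_mode,
                "teer_ohm_cm2": result.teer_ohm_cm2,
                "peak_j_norm_A_per_m2": solution.peak_j_norm,
                "peak_qa_m3_s_m2": result.peak_qa,
                "net_exchange_per_min": result.net_exchange,
                "scaling_factor_m2_per_A_min": result.scaling_factor_k,
            }
        ],
    )

    # stage: brain-wide exchange map for the dose
    if config.applied_current_mA > 0:
        brain = synthetic_brain_field(
            shape=config.brain_shape,
            applied_current_mA=config.applied_current_mA,
            seed=config.brain_seed,
            voxel_size_mm=config.brain_voxel_size_mm,
        )
    else:
        import numpy as np

        brain = BrainField(
            values=np.zeros(config.brain_shape),
            voxel_size_mm=config.brain_voxel_size_mm,
            applied_current_mA=0.0,
        )
    exchange_map = scale_brain_map(brain, result.scaling_factor_k)
    tio.save_brain_field(brain, out / "current_density_map.npy")
    tio.save_brain_field(exchange_map, out / "exchange_map.npy")

    provenance = {
        "montage": config.montage,
        "applied_current_mA": config.applied_current_mA,
        "peak_current_density_A_per_m2": j_in,
        "teer_ohm_cm2": spec.teer_ohm_cm2,
        "boundary_mode": config.boundary_mode,
        "coupling_mode": constant.mode,
        "coupling_constant_Vm_per_A": constant.C,
        "avg_velocity_coeff": coeffs.avg_velocity_coeff,
        "flux_coefficient": q_coeff,
        "sigma_wall_S_per_m": sigma_wall,
        "sigma_tj_S_per_m": sigma_tj,
        "network_seed": config.network_seed,
        "brain_seed": config.brain_seed,
        "network_stats": dataclasses.asdict(stats),
        "grid_shape": list(solution.grid_shape),
        "peak_j_norm_A_per_m2": solution.peak_j_norm,
        "peak_qa_m3_s_m2": result.peak_qa,
        "net_exchange_per_min": result.net_exchange,
        "scaling_factor_m2_per_A_min": result.scaling_factor_k,
        "exchange_convention": config.exchange_convention,
        "conservation_residual": solution.conservation_residual,
        "boundary_balance": solution.boundary_balance,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return provenance
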