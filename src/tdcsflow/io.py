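"""Readers and writers: vessel graphs, brain fields, result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .capillary import VesselGraph, VoxelCurrentSolution
from .pipeline import BrainField

__all__ = [
    "save_vessel_graph_json",
    "load_vessel_graph_json",
    "save_vessel_graph_csv",
    "load_vessel_graph_csv",
    "save_brain_field",
    "load_brain_field",
    "solution_table",
]


def save_vessel_graph_json(graph: VesselGraph, path) -> None:
    payload = {
        "voxel_dims_m": list(graph.voxel_dims),
        "seed": graph.seed,
        "nodes_m": graph.nodes.tolist(),
        "segments": [
            {
                "nodes": [int(a), int(b)],
                "outer_diameter_m": float(d),
                "wall_thickness_m": float(w),
            }
            for (a, b), d, w in zip(
                graph.segments, graph.outer_diameters, graph.wall_thicknesses
            )
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_vessel_graph_json(path) -> VesselGraph:
    payload = json.loads(Path(path).read_text())
    segs = payload["segments"]
    return VesselGraph(
        nodes=np.asarray(payload["nodes_m"], dtype=float).reshape(-1, 3),
        segments=np.asarray([s["nodes"] for s in segs], dtype=int).reshape(-1, 2),
        outer_diameters=np.asarray([s["outer_diameter_m"] for s in segs]),
        wall_thicknesses=np.asarray([s["wall_thickness_m"] for s in segs]),
        voxel_dims=tuple(payload["voxel_dims_m"]),
        seed=payload.get("seed"),
    )


def save_vessel_graph_csv(graph: VesselGraph, path) -> None:
    """Edge list with inline endpoint coordinates (self-contained CSV)."""
    a = graph.nodes[graph.segments[:, 0]] if len(graph.segments) else np.zeros((0, 3))
    b = graph.nodes[graph.segments[:, 1]] if len(graph.segments) else np.zeros((0, 3))
    df = pd.DataFrame(
        {
            "x0_m": a[:, 0], "y0_m": a[:, 1], "z0_m": a[:, 2],
            "x1_m": b[:, 0], "y1_m": b[:, 1], "z1_m": b[:, 2],
            "outer_diameter_m": graph.outer_diameters,
            "wall_thickness_m": graph.wall_thicknesses,
        }
    )
    df.to_csv(path, index=False)


def load_vessel_graph_csv(path, voxel_dims=None) -> VesselGraph:
    df = pd.read_csv(path)
    pts = {}
    segments = []
    for _, row in df.iterrows():
        key_a = (row.x0_m, row.y0_m, row.z0_m)
        key_b = (row.x1_m, row.y1_m, row.z1_m)
        for key in (key_a, key_b):
            if key not in pts:
                pts[key] = len(pts)
        segments.append((pts[key_a], pts[key_b]))
    nodes = np.asarray(list(pts.keys()), dtype=float).reshape(-1, 3)
    if voxel_dims is None:
        from .capillary import DEFAULT_VOXEL_DIMS

        voxel_dims = DEFAULT_VOXEL_DIMS
    return VesselGraph(
        nodes=nodes,
        segments=np.asarray(segments, dtype=int).reshape(-1, 2),
        outer_diameters=df["outer_diameter_m"].to_numpy(),
        wall_thicknesses=df["wall_thickness_m"].to_numpy(),
        voxel_dims=tuple(voxel_dims),
    )


def save_brain_field(field: BrainField, path) -> None:
    """Write a brain field as NIfTI (.nii/.nii.gz) or .npy with a JSON sidecar."""
    path = Path(path)
    meta = {
        "voxel_size_mm": list(field.voxel_size_mm),
        "applied_current_mA": field.applied_current_mA,
        "units": field.units,
    }
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(field.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(field.values.astype(np.float32), affine), str(path))
        sidecar = path.with_name(path.name.split(".")[0] + ".json")
    else:
        np.save(path, field.values)
        sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def load_brain_field(path) -> BrainField:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        sidecar = path.with_name(path.name.split(".")[0] + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        voxel = meta.get("voxel_size_mm", list(img.header.get_zooms()[:3]))
    else:
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        values = np.load(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        voxel = meta["voxel_size_mm"]
    return BrainField(
        values=values,
        voxel_size_mm=tuple(voxel),
        applied_current_mA=meta.get("applied_current_mA", 1.0),
        units=meta.get("units", "A m^-2"),
    )


def solution_table(solution: VoxelCurrentSolution) -> pd.DataFrame:
    """Per-wall-element table of position, area and signed current density."""
    return pd.DataFrame(
        {
            "x_m": solution.element_positions[:, 0]
            if len(solution.element_positions)
            else [],
            "y_m": solution.element_positions[:, 1]
            if len(solution.element_positions)
            else [],
            "z_m": solution.element_positions[:, 2]
            if len(solution.element_positions)
            else [],
            "segment": solution.element_segment,
            "area_m2": solution.element_areas,
            "j_norm_A_per_m2": solution.element_j_norm,
        }
    )
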