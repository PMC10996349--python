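"""Synthetic capillary networks and steady-state current flow in a brain voxel.

A tissue voxel (default 0.15 x 0.16 x 0.43 mm) containing a capillary
network is driven by a uniform inward current density on its top face, as in
the brain region receiving peak parenchymal current during tDCS.  Steady
current flow obeys the Laplace equation div(sigma grad V) = 0 with the
parenchyma, the vessel lumen and the high-resistance capillary wall as the
three conductors.

The vasculature is represented by :class:`VesselGraph` — a node/segment
graph of cylindrical capillaries (8-10 um outer diameter, 1 um wall) grown
by a seeded branching random walk with anastomosis until a target length
density is reached.  The solver embeds the network in a regular
finite-difference grid: each segment contributes a 1D axial lumen conductor,
coupled to nearby grid cells through a membrane conductance per unit area of
1/TEER (the thin-wall approximation sigma_wall / l_wall).  Two boundary
conditions mirror the two physiological limits:

* ``closed`` — all current crossing into the blood returns to the
  interstitium elsewhere in the same network (grounded voxel bottom only);
* ``open`` — part of the current is collected by larger vessels, modelled by
  additionally grounding the lumen of the few largest-diameter segments.

The signed wall-normal current density per wall element (positive = into
the lumen) is the quantity handed to the electroosmotic flux pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .electroosmosis import InvalidParameterError
from .membranes import TEERSpec

__all__ = [
    "VesselGraph",
    "NetworkStats",
    "VoxelCurrentSolution",
    "DEFAULT_VOXEL_DIMS",
    "generate_network",
    "network_stats",
    "solve_voxel_current",
]

DEFAULT_VOXEL_DIMS = (0.15e-3, 0.16e-3, 0.43e-3)  # m
#: Default finite-difference grid for the default voxel (~3.1 um spacing).
DEFAULT_GRID_SHAPE = (48, 52, 140)

MM_PER_M_DENSITY = 1e-6  # (m / m^3) -> (mm / mm^3)


class SolverError(RuntimeError):
    """Raised when the voxel linear solve fails or does not converge."""


@dataclass
class VesselGraph:
    """Node/segment representation of a capillary network inside a voxel.

    ``nodes`` is an (N, 3) array of positions in metres; ``segments`` an
    (M, 2) integer array of node indices; per-segment outer diameters and
    wall thicknesses are in metres.
    """

    nodes: np.ndarray
    segments: np.ndarray
    outer_diameters: np.ndarray
    wall_thicknesses: np.ndarray
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    seed: int | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.segments = np.asarray(self.segments, dtype=int).reshape(-1, 2)
        self.outer_diameters = np.asarray(self.outer_diameters, dtype=float)
        self.wall_thicknesses = np.asarray(self.wall_thicknesses, dtype=float)
        lumen = self.outer_diameters - 2.0 * self.wall_thicknesses
        if len(self.segments) and np.any(lumen <= 0):
            raise InvalidParameterError("lumen diameter must be positive")
        dims = np.asarray(self.voxel_dims)
        if len(self.nodes) and (
            np.any(self.nodes < -1e-12) or np.any(self.nodes > dims + 1e-12)
        ):
            raise InvalidParameterError("all nodes must lie inside the voxel")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lumen_diameters(self) -> np.ndarray:
        return self.outer_diameters - 2.0 * self.wall_thicknesses

    def segment_lengths(self) -> np.ndarray:
        if not len(self.segments):
            return np.zeros(0)
        a = self.nodes[self.segments[:, 0]]
        b = self.nodes[self.segments[:, 1]]
        return np.linalg.norm(b - a, axis=1)

    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))

    def is_connected(self) -> bool:
        if not len(self.segments):
            return len(self.nodes) <= 1
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(map(tuple, self.segments))
        return nx.is_connected(g)


@dataclass(frozen=True)
class NetworkStats:
    """Morphometric densities of a network, in the units of the literature."""

    length_density: float   # mm / mm^3
    surface_density: float  # mm^2 / mm^3 (outer surface)
    volume_fraction: float  # lumen volume / voxel volume


@dataclass
class VoxelCurrentSolution:
    """Grid potentials and signed wall-normal current densities.

    Wall elements are the per-piece membrane couplings between a lumen node
    and a grid cell; ``element_j_norm`` is positive for current flowing from
    interstitium into the lumen.
    """

    grid_potentials: np.ndarray        # (nx, ny, nz) volts
    lumen_potentials: np.ndarray       # per lumen DOF, volts
    element_positions: np.ndarray      # (K, 3) m
    element_areas: np.ndarray          # (K,) m^2
    element_j_norm: np.ndarray         # (K,) A/m^2, signed (+ into lumen)
    element_segment: np.ndarray        # (K,) index into graph.segments
    applied_inward_current_density: float
    boundary_mode: str
    teer_ohm_cm2: float
    grid_shape: tuple[int, int, int]
    conservation_residual: float       # max interior Kirchhoff residual / I_in
    boundary_balance: float            # |I_in - I_out| / I_in
    wall_balance: float                # closed: |net lumen current| / gross

    @property
    def peak_j_norm(self) -> float:
        return float(np.max(np.abs(self.element_j_norm))) if len(
            self.element_j_norm
        ) else 0.0


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def generate_network(
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS,
    target_length_density: float = 557.0,
    diameter_range: tuple[float, float] = (8e-6, 10e-6),
    seed: int = 0,
    wall_thickness: float = 1e-6,
    step: float | None = None,
    branch_probability: float = 0.18,
    capture_radius: float | None = None,
    direction_noise: float = 0.55,
) -> VesselGraph:
    """Grow a seeded random capillary network to a target length density.

    A single tip starts at a random interior point and performs a
    persistent random walk; tips branch stochastically, terminate at the
    voxel boundary (sealing the vessel end at the face, as real capillaries
    do at the voxel cut), and anastomose when they pass close to an existing
    node.  When all tips have died and length is still short, a new tip
    sprouts from a random existing node, keeping the graph connected.
    Growth stops once the summed segment length reaches the target (within
    one step, i.e. well inside 10%).  Deterministic for a fixed seed.

    Parameters
    ----------
    target_length_density
        mm of vessel per mm^3 of tissue (in vivo cortex: ~557).
    diameter_range
        Outer diameters sampled uniformly per segment, m.
    """
    if target_length_density < 0:
        raise InvalidParameterError("target_length_density must be >= 0")
    dims = np.asarray(voxel_dims, dtype=float)
    volume = float(np.prod(dims))
    if target_length_density == 0:
        return VesselGraph(
            nodes=np.zeros((0, 3)),
            segments=np.zeros((0, 2), dtype=int),
            outer_diameters=np.zeros(0),
            wall_thicknesses=np.zeros(0),
            voxel_dims=tuple(dims),
            seed=seed,
        )
    target_length = target_length_density / MM_PER_M_DENSITY * volume  # m
    d_max = max(diameter_range)
    if target_length * math.pi / 4.0 * d_max**2 > 0.5 * volume:
        raise InvalidParameterError(
            "voxel too small: target length density at these diameters would "
            "fill more than half the voxel volume"
        )
    if step is None:
        step = min(12e-6, float(dims.min()) / 6.0)
    if capture_radius is None:
        capture_radius = 0.45 * step

    rng = np.random.default_rng(seed)

    def rand_dir() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    nodes: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    adjacency: dict[int, set[int]] = {}

    def add_node(p: np.ndarray) -> int:
        nodes.append(p)
        adjacency[len(nodes) - 1] = set()
        return len(nodes) - 1

    def add_edge(i: int, j: int) -> None:
        edges.append((i, j))
        adjacency[i].add(j)
        adjacency[j].add(i)

    start = add_node(dims * (0.25 + 0.5 * rng.random(3)))
    tips: list[tuple[int, np.ndarray]] = [(start, rand_dir())]
    total_length = 0.0
    max_iter = 200000
    for _ in range(max_iter):
        if total_length >= target_length:
            break
        if not tips:
            src = int(rng.integers(len(nodes)))
            tips.append((src, rand_dir()))
            continue
        node_idx, direction = tips.pop(0)
        new_dir = direction + direction_noise * rng.normal(size=3)
        new_dir /= np.linalg.norm(new_dir)
        p0 = nodes[node_idx]
        p1 = p0 + step * new_dir
        # terminate at the boundary, sealing the vessel end on the face
        if np.any(p1 < 0) or np.any(p1 > dims):
            with np.errstate(divide="ignore", invalid="ignore"):
                t_low = np.where(new_dir < 0, -p0 / (step * new_dir), np.inf)
                t_high = np.where(new_dir > 0, (dims - p0) / (step * new_dir), np.inf)
            t = float(min(np.min(t_low), np.min(t_high)))
            if t * step > 0.25 * step:
                j = add_node(p0 + t * step * new_dir)
                add_edge(node_idx, j)
                total_length += t * step
            continue
        # anastomosis: fuse with a nearby non-adjacent node and retire the tip
        if len(nodes) > 2:
            pts = np.asarray(nodes)
            dist = np.linalg.norm(pts - p1, axis=1)
            dist[node_idx] = np.inf
            for nb in adjacency[node_idx]:
                dist[nb] = np.inf
            near = int(np.argmin(dist))
            if dist[near] < capture_radius:
                add_edge(node_idx, near)
                total_length += float(np.linalg.norm(pts[near] - p0))
                continue
        j = add_node(p1)
        add_edge(node_idx, j)
        total_length += step
        tips.append((j, new_dir))
        if rng.random() < branch_probability:
            tips.append((j, rand_dir()))
    else:  # pragma: no cover - generous iteration cap
        raise SolverError("network generation did not reach the target length")

    m = len(edges)
    d_lo, d_hi = min(diameter_range), max(diameter_range)
    return VesselGraph(
        nodes=np.asarray(nodes),
        segments=np.asarray(edges, dtype=int),
        outer_diameters=rng.uniform(d_lo, d_hi, size=m),
        wall_thicknesses=np.full(m, wall_thickness),
        voxel_dims=tuple(dims),
        seed=seed,
    )


def network_stats(graph: VesselGraph) -> NetworkStats:
    """Length, outer-surface and lumen-volume densities of a network."""
    volume = graph.voxel_volume()
    lengths = graph.segment_lengths()
    if not len(lengths):
        return NetworkStats(0.0, 0.0, 0.0)
    length_density = lengths.sum() / volume * MM_PER_M_DENSITY
    surface = float(np.sum(math.pi * graph.outer_diameters * lengths))
    volume_lumen = float(
        np.sum(math.pi / 4.0 * graph.lumen_diameters**2 * lengths)
    )
    return NetworkStats(
        length_density=float(length_density),
        surface_density=surface / volume * 1e-3,  # m^2/m^3 -> mm^2/mm^3
        volume_fraction=volume_lumen / volume,
    )


# ---------------------------------------------------------------------------
# Voxel current solve
# ---------------------------------------------------------------------------

def _default_grid_shape(voxel_dims) -> tuple[int, int, int]:
    ref = np.asarray(DEFAULT_VOXEL_DIMS)
    dims = np.asarray(voxel_dims)
    shape = np.maximum(4, np.round(np.asarray(DEFAULT_GRID_SHAPE) * dims / ref))
    return tuple(int(n) for n in shape)


def solve_voxel_current(
    graph: VesselGraph,
    boundary_mode: str = "closed",
    teer: float | TEERSpec = 1000.0,
    inward_current_density: float = 0.082,
    grid_shape: tuple[int, int, int] | None = None,
    sigma_parenchyma: float = 0.276,
    sigma_lumen: float = 0.7,
    n_grounded_segments: int = 4,
    rtol: float = 1e-10,
) -> VoxelCurrentSolution:
    """Solve div(sigma grad V) = 0 in the voxel with an embedded vessel network.

    A uniform inward (downward) current density enters the top face; the
    bottom face is grounded; the four sides are insulated.  In ``open`` mode
    the lumen of the ``n_grounded_segments`` largest-diameter segments is
    additionally grounded, standing in for collection by larger vessels.

    The capillary wall enters as a membrane conductance per unit area of
    1/TEER between lumen nodes and the grid cells within one grid spacing of
    the vessel axis (lateral area split equally among them).

    Returns the grid potential, the signed wall-normal current density per
    wall element (positive into the lumen), and conservation diagnostics.
    """
    if boundary_mode not in ("closed", "open"):
        raise InvalidParameterError("boundary_mode must be 'closed' or 'open'")
    if inward_current_density < 0:
        raise InvalidParameterError("inward_current_density must be >= 0")
    spec = teer if isinstance(teer, TEERSpec) else TEERSpec(teer=float(teer))
    g_wall_per_area = 1.0 / spec.teer_ohm_m2  # S/m^2, thin-wall membrane

    dims = np.asarray(graph.voxel_dims, dtype=float)
    if grid_shape is None:
        grid_shape = _default_grid_shape(dims)
    nx_, ny_, nz_ = grid_shape
    hx, hy, hz = dims / np.asarray(grid_shape)
    n_grid = nx_ * ny_ * nz_

    def cell_index(i, j, k):
        return (i * ny_ + j) * nz_ + k

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add_pairs(a: np.ndarray, b: np.ndarray, g: np.ndarray) -> None:
        rows.extend((a, b, a, b))
        cols.extend((a, b, b, a))
        vals.extend((g, g, -g, -g))

    ii, jj, kk = np.meshgrid(
        np.arange(nx_), np.arange(ny_), np.arange(nz_), indexing="ij"
    )
    idx = cell_index(ii, jj, kk)
    gx = sigma_parenchyma * hy * hz / hx
    gy = sigma_parenchyma * hx * hz / hy
    gz = sigma_parenchyma * hx * hy / hz
    a = idx[:-1, :, :].ravel()
    add_pairs(a, idx[1:, :, :].ravel(), np.full(a.size, gx))
    a = idx[:, :-1, :].ravel()
    add_pairs(a, idx[:, 1:, :].ravel(), np.full(a.size, gy))
    a = idx[:, :, :-1].ravel()
    add_pairs(a, idx[:, :, 1:].ravel(), np.full(a.size, gz))

    diag_extra = np.zeros(n_grid)
    b = np.zeros(n_grid)
    # top face: uniform Neumann influx; bottom face: Dirichlet 0 via the
    # half-cell conductance from the cell centre to the grounded face
    top = idx[:, :, nz_ - 1].ravel()
    b[top] += inward_current_density * hx * hy
    bottom = idx[:, :, 0].ravel()
    g_ground = sigma_parenchyma * hx * hy / (hz / 2.0)
    diag_extra[bottom] += g_ground

    # --- embed the vessel network -----------------------------------------
    h_min = float(min(hx, hy, hz))
    h_cap = float(max(hx, hy, hz))
    lumen_of_graph_node: dict[int, int] = {}
    n_lumen = 0

    def lumen_junction(gn: int) -> int:
        nonlocal n_lumen
        if gn not in lumen_of_graph_node:
            lumen_of_graph_node[gn] = n_lumen
            n_lumen += 1
        return lumen_of_graph_node[gn]

    piece_rows = []  # (lumen_dof, segment, midpoint, lateral_area)
    axial_links = []  # (dof_a, dof_b, conductance)
    lengths = graph.segment_lengths()
    for s in range(graph.n_segments):
        na, nb = graph.segments[s]
        pa, pb = graph.nodes[na], graph.nodes[nb]
        L = lengths[s]
        if L <= 0:
            continue
        d_lum = graph.lumen_diameters[s]
        a_lum = math.pi / 4.0 * d_lum**2
        n_sub = max(1, int(math.ceil(L / h_min)))
        dl = L / n_sub
        g_ax = sigma_lumen * a_lum / dl
        ja, jb = lumen_junction(na), lumen_junction(nb)
        mids = []
        for q in range(n_sub):
            t = (q + 0.5) / n_sub
            dof = n_lumen
            n_lumen += 1
            mids.append(dof)
            piece_rows.append(
                (dof, s, pa + t * (pb - pa), math.pi * graph.outer_diameters[s] * dl)
            )
        axial_links.append((ja, mids[0], 2.0 * g_ax))
        for q in range(n_sub - 1):
            axial_links.append((mids[q], mids[q + 1], g_ax))
        axial_links.append((mids[-1], jb, 2.0 * g_ax))

    n_dof = n_grid + n_lumen
    # membrane couplings: equal split of each piece's lateral area among the
    # grid cells whose centres lie within one grid spacing of the piece
    elem_cell: list[int] = []
    elem_lumen: list[int] = []
    elem_area: list[float] = []
    elem_seg: list[int] = []
    elem_pos: list[np.ndarray] = []
    for dof, s, mid, area in piece_rows:
        ci = np.floor(mid / np.array([hx, hy, hz])).astype(int)
        cands = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    i, j, k = ci[0] + di, ci[1] + dj, ci[2] + dk
                    if 0 <= i < nx_ and 0 <= j < ny_ and 0 <= k < nz_:
                        center = (np.array([i, j, k]) + 0.5) * np.array([hx, hy, hz])
                        if np.linalg.norm(center - mid) <= h_cap:
                            cands.append(cell_index(i, j, k))
        if not cands:
            ci = np.clip(ci, 0, np.array([nx_, ny_, nz_]) - 1)
            cands = [cell_index(*ci)]
        share = area / len(cands)
        for c in cands:
            elem_cell.append(int(c))
            elem_lumen.append(n_grid + dof)
            elem_area.append(share)
            elem_seg.append(s)
            elem_pos.append(mid)

    if elem_cell:
        ec = np.asarray(elem_cell)
        el = np.asarray(elem_lumen)
        ea = np.asarray(elem_area)
        add_pairs(ec, el, g_wall_per_area * ea)
    for da, db, g in axial_links:
        add_pairs(
            np.array([n_grid + da]), np.array([n_grid + db]), np.array([g])
        )

    rows_c = np.concatenate(rows)
    cols_c = np.concatenate(cols)
    vals_c = np.concatenate(vals)
    A = sparse.coo_matrix((vals_c, (rows_c, cols_c)), shape=(n_dof, n_dof)).tocsr()
    A = A + sparse.diags(np.concatenate([diag_extra, np.zeros(n_lumen)]))
    b_full = np.concatenate([b, np.zeros(n_lumen)])

    # open mode: ground the lumen DOFs of the largest-diameter segments
    dirichlet = np.zeros(n_dof, dtype=bool)
    if boundary_mode == "open" and graph.n_segments:
        k = min(n_grounded_segments, graph.n_segments)
        order = np.argsort(-graph.outer_diameters, kind="stable")[:k]
        grounded_segments = set(int(s) for s in order)
        for dof, s, _mid, _area in piece_rows:
            if s in grounded_segments:
                dirichlet[n_grid + dof] = True
        for s in grounded_segments:
            for gn in graph.segments[s]:
                dirichlet[n_grid + lumen_of_graph_node[int(gn)]] = True

    keep = ~dirichlet
    A_red = A[keep][:, keep]
    b_red = b_full[keep]
    if A_red.shape[0] == 0 or b_red.size == 0:
        raise SolverError("no free degrees of freedom")

    V = np.zeros(n_dof)
    n_red = A_red.shape[0]
    if n_red <= 6000:
        V[keep] = splu(A_red.tocsc()).solve(b_red)
    else:
        inv_diag = 1.0 / A_red.diagonal()
        M = sparse.diags(inv_diag)
        x, info = cg(A_red, b_red, rtol=rtol, atol=0.0, maxiter=50000, M=M)
        if info != 0:
            res = np.linalg.norm(A_red @ x - b_red) / np.linalg.norm(b_red)
            raise SolverError(f"CG did not converge (info={info}, rel res={res:.2e})")
        V[keep] = x

    total_in = inward_current_density * dims[0] * dims[1]
    residual = A @ V - b_full
    interior = keep.copy()
    interior[top] = False
    interior[bottom] = False
    cons = (
        float(np.max(np.abs(residual[interior]))) / total_in if total_in > 0 else 0.0
    )
    out_bottom = float(np.sum(g_ground * V[bottom]))
    out_lumen = -float(residual[dirichlet].sum()) if dirichlet.any() else 0.0
    balance = abs(total_in - out_bottom - out_lumen) / total_in if total_in else 0.0

    if elem_cell:
        j_norm = g_wall_per_area * (V[ec] - V[el])  # + = into lumen
        gross = float(np.sum(np.abs(j_norm) * ea))
        net = float(np.sum(j_norm * ea))
        wall_balance = abs(net) / gross if gross > 0 else 0.0
        positions = np.asarray(elem_pos)
        seg_arr = np.asarray(elem_seg)
    else:
        j_norm = np.zeros(0)
        ea = np.zeros(0)
        wall_balance = 0.0
        positions = np.zeros((0, 3))
        seg_arr = np.zeros(0, dtype=int)

    return VoxelCurrentSolution(
        grid_potentials=V[:n_grid].reshape(grid_shape),
        lumen_potentials=V[n_grid:],
        element_positions=positions,
        element_areas=np.asarray(ea, dtype=float),
        element_j_norm=j_norm,
        element_segment=seg_arr,
        applied_inward_current_density=inward_current_density,
        boundary_mode=boundary_mode,
        teer_ohm_cm2=spec.teer_ohm_cm2,
        grid_shape=tuple(grid_shape),
        conservation_residual=cons,
        boundary_balance=balance,
        wall_balance=wall_balance,
    )
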