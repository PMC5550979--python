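"""Geometric state of the simulation: arena, cells, links, constraints.

Each cell is an eight-node ring (its discretized membrane) plus a centroid
(the mean of the node positions). One node is the *leader* and sets the
migration direction. The membrane is deformable — nodes move individually —
but ideal bond lengths between adjacent nodes and a preferred node-centroid
radius maintain the cell shape. Cells can neither overlap with each other
nor escape the circular simulation arena; both are enforced by iterative
position projection.

For speed the population state is stored struct-of-arrays
(``SimulationState``); per-cell object views (``Cell``) are provided for
inspection and serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "N_NODES",
    "OPPOSITE_OFFSET",
    "Arena",
    "Cell",
    "SimulationState",
    "make_cell",
    "octagon_nodes",
    "enforce_constraints",
    "hex_pack",
    "state_to_table",
    "state_from_table",
]

#: Number of membrane nodes per cell.
N_NODES = 8
#: Ring offset of the node opposite a given node.
OPPOSITE_OFFSET = N_NODES // 2

#: Free slot marker in the link partner arrays.
NO_LINK = -1


@dataclass(frozen=True)
class Arena:
    """Circular simulation area centered at the origin."""

    diameter: float = 500.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("arena diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Cell:
    """Read-only per-cell view of the simulation state."""

    id: int
    population: str
    nodes: np.ndarray  # (8, 2) node positions, um
    leader: int
    radius: float
    ideal_bond: float

    @property
    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from the centroid to the leader node."""
        v = self.nodes[self.leader] - self.centroid
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.zeros(2)


def octagon_nodes(center: np.ndarray, radius: float) -> np.ndarray:
    """Vertices of a regular octagon of circumradius ``radius``."""
    ang = 2.0 * np.pi * np.arange(N_NODES) / N_NODES
    return np.asarray(center, float) + radius * np.column_stack(
        [np.cos(ang), np.sin(ang)]
    )


def ideal_bond_length(radius: float) -> float:
    """Edge length of the regular octagon: 2 r sin(pi/8)."""
    return 2.0 * radius * math.sin(math.pi / N_NODES)


class SimulationState:
    """Positions, labels, leaders and adhesion links of all cells.

    Attributes
    ----------
    pos : (n_cells, 8, 2) float array of node positions, um.
    populations : tuple of population names; ``pop`` holds the index of
        each cell's population in this tuple.
    leader : (n_cells,) int array, ring index of each cell's leader node.
    link_cell, link_node : (n_cells, 8) int arrays; for node ``(i, k)``
        that is linked, ``link_cell[i, k]`` / ``link_node[i, k]`` identify
        the partner node, and are ``-1`` when the node is free. A node
        holds at most one link and links are symmetric.
    """

    def __init__(
        self,
        arena: Arena,
        pos: np.ndarray,
        pop: np.ndarray,
        populations: tuple[str, ...],
        leader: np.ndarray,
        radius: float = 7.5,
        step_duration_s: float = 0.5,
    ) -> None:
        self.arena = arena
        self.pos = np.asarray(pos, dtype=float)
        if self.pos.ndim != 3 or self.pos.shape[1:] != (N_NODES, 2):
            raise ValueError("pos must have shape (n_cells, 8, 2)")
        self.pop = np.asarray(pop, dtype=np.int64)
        self.populations = tuple(populations)
        self.leader = np.asarray(leader, dtype=np.int64)
        self.radius = float(radius)
        self.ideal_bond = ideal_bond_length(self.radius)
        self.step_duration_s = float(step_duration_s)
        n = self.n_cells
        self.link_cell = np.full((n, N_NODES), NO_LINK, dtype=np.int64)
        self.link_node = np.full((n, N_NODES), NO_LINK, dtype=np.int64)
        self.step_count = 0

    # -- basic views -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @property
    def dt_min(self) -> float:
        """Duration of one step in minutes."""
        return self.step_duration_s / 60.0

    @property
    def time_min(self) -> float:
        return self.step_count * self.dt_min

    @property
    def centroids(self) -> np.ndarray:
        return self.pos.mean(axis=1)

    def directions(self) -> np.ndarray:
        """(n_cells, 2) unit migration directions (centroid -> leader)."""
        c = self.centroids
        v = self.pos[np.arange(self.n_cells), self.leader] - c
        n = np.linalg.norm(v, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return v / n

    def cell(self, i: int) -> Cell:
        return Cell(
            id=i,
            population=self.populations[self.pop[i]],
            nodes=self.pos[i].copy(),
            leader=int(self.leader[i]),
            radius=self.radius,
            ideal_bond=self.ideal_bond,
        )

    @property
    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n_cells)]

    # -- links -------------------------------------------------------------

    def n_links(self) -> int:
        return int(np.count_nonzero(self.link_cell >= 0)) // 2

    def linked_pairs(self) -> np.ndarray:
        """(n_links, 4) array of (cell_a, node_a, cell_b, node_b) with
        each unordered link listed once (cell_a < cell_b)."""
        ci, ni = np.nonzero(self.link_cell >= 0)
        cj = self.link_cell[ci, ni]
        nj = self.link_node[ci, ni]
        keep = ci < cj
        return np.column_stack([ci[keep], ni[keep], cj[keep], nj[keep]])

    def add_link(self, ca: int, na: int, cb: int, nb: int) -> None:
        if ca == cb:
            raise ValueError("links may only join nodes of distinct cells")
        if self.link_cell[ca, na] != NO_LINK or self.link_cell[cb, nb] != NO_LINK:
            raise ValueError("node already holds a link")
        self.link_cell[ca, na], self.link_node[ca, na] = cb, nb
        self.link_cell[cb, nb], self.link_node[cb, nb] = ca, na

    def remove_link(self, ca: int, na: int) -> None:
        cb, nb = self.link_cell[ca, na], self.link_node[ca, na]
        self.link_cell[ca, na] = self.link_node[ca, na] = NO_LINK
        if cb != NO_LINK:
            self.link_cell[cb, nb] = self.link_node[cb, nb] = NO_LINK

    def copy(self) -> "SimulationState":
        out = SimulationState(
            self.arena,
            self.pos.copy(),
            self.pop.copy(),
            self.populations,
            self.leader.copy(),
            self.radius,
            self.step_duration_s,
        )
        out.link_cell = self.link_cell.copy()
        out.link_node = self.link_node.copy()
        out.step_count = self.step_count
        return out


def make_cell(
    center,
    population: str = "A",
    radius: float = 7.5,
    arena: Arena | None = None,
    rng: np.random.Generator | None = None,
) -> Cell:
    """Create a cell as a regular octagon with a randomly chosen leader.

    Raises ``ValueError`` for non-positive radius or a center too close to
    the arena wall for the cell to fit.
    """
    if not radius > 0:
        raise ValueError(f"cell radius must be > 0, got {radius}")
    center = np.asarray(center, dtype=float)
    if arena is not None:
        if np.linalg.norm(center) > arena.radius - radius:
            raise ValueError(
                f"cell center {center} does not fit inside arena of "
                f"radius {arena.radius} (cell radius {radius})"
            )
    rng = np.random.default_rng() if rng is None else rng
    return Cell(
        id=0,
        population=population,
        nodes=octagon_nodes(center, radius),
        leader=int(rng.integers(N_NODES)),
        radius=radius,
        ideal_bond=ideal_bond_length(radius),
    )


def hex_pack(
    n: int,
    arena: Arena,
    cell_radius: float,
    rng: np.random.Generator,
    jitter: float = 0.5,
) -> np.ndarray:
    """Place ``n`` non-overlapping cell centers in the arena.

    Centers are laid on a triangular lattice whose spacing distributes the
    available area evenly over the requested cells (confluent packings up
    to ~0.8 area fraction), then jittered. Raises ``ValueError`` if the
    arena cannot hold ``n`` cells at the implied spacing.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    usable_r = arena.radius - cell_radius
    if usable_r <= 0:
        raise ValueError("arena too small for even one cell")
    # lattice spacing from equal-area partition, but never tighter than the
    # cell diameter minus the jitter allowance
    area = math.pi * usable_r**2
    s = math.sqrt(2.0 * area / (math.sqrt(3.0) * n))
    pts: list[tuple[float, float]] = []
    # boundary loss can leave the equal-area spacing a few sites short;
    # tighten until the disc holds n sites, down to a sanity floor
    for _ in range(30):
        pts = []
        ny = int(math.ceil(2 * usable_r / (s * math.sqrt(3) / 2))) + 2
        nx = int(math.ceil(2 * usable_r / s)) + 2
        for iy in range(-ny, ny + 1):
            y = iy * s * math.sqrt(3) / 2
            off = (iy % 2) * s / 2
            for ix in range(-nx, nx + 1):
                x = ix * s + off
                if x * x + y * y <= usable_r**2:
                    pts.append((x, y))
        if len(pts) >= n:
            break
        s *= 0.98
        if s < cell_radius:
            break
    if len(pts) < n:
        raise ValueError(
            f"arena of diameter {arena.diameter} holds only {len(pts)} lattice "
            f"sites for {n} requested cells; lower the density"
        )
    pts = np.asarray(pts)
    idx = rng.choice(len(pts), size=n, replace=False)
    centers = pts[idx]
    centers = centers + rng.uniform(-jitter, jitter, size=centers.shape)
    # keep jittered centers inside the usable disc
    r = np.linalg.norm(centers, axis=1)
    over = r > usable_r
    if over.any():
        centers[over] *= (usable_r / r[over])[:, None]
    return centers


# ---------------------------------------------------------------------------
# Constraint enforcement
# ---------------------------------------------------------------------------

def enforce_constraints(
    state: SimulationState,
    contact_distance: float = 2.0,
    max_sweeps: int = 10,
    tol: float = 0.02,
    bond_stiffness: float = 0.5,
    radial_stiffness: float = 0.05,
    area_stiffness: float = 0.0,
    separation_distance: float | None = None,
    separation_stiffness: float = 0.5,
    eject_stiffness: float = 0.0,
    use_segment_exclusion: bool = False,
    tether_rest: float | None = None,
    tether_stiffness: float = 0.3,
    pair_index: tuple[np.ndarray, np.ndarray] | None = None,
    linked_index: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimulationState:
    """Project node positions back onto the model's structural constraints.

    Iteratively (at most ``max_sweeps`` sweeps, stopping when the largest
    correction falls below ``tol`` um):

    1. node-centroid distances relax toward the cell radius (hard-capped
       at twice the radius) and membrane bonds relax toward the ideal
       bond length;
    2. linked nodes stretched beyond ``tether_rest`` (default twice the
       contact distance) are pulled back together, a fraction
       ``tether_stiffness`` of the excess per sweep — adhesion is a loose
       leash that holds contacts without rigidifying the tissue;
    3. nodes of distinct cells closer than ``separation_distance``
       (default half the contact distance) are pushed apart symmetrically
       (no overlap);
    4. nodes outside the arena are projected back to its boundary.

    In a crowded arena the separation constraints are under global
    compression and cannot all be met exactly; the sweep budget then acts
    as a soft pressure response, which is the intended behaviour.

    ``pair_index`` / ``linked_index`` may supply precomputed flat node
    index pairs (candidate separation pairs, linked pairs); when omitted
    they are derived with a KD tree / from the link table.
    """
    from ._kernels import constraint_sweep

    if separation_distance is None:
        separation_distance = contact_distance
    if tether_rest is None:
        tether_rest = contact_distance

    n_flat = state.n_cells * N_NODES
    flat = state.pos.reshape(n_flat, 2)

    if pair_index is None:
        tree = cKDTree(flat)
        # candidate radius covers node-to-segment contacts up to half a
        # bond away from the nearest segment endpoint
        reach = max(
            contact_distance * 1.5,
            separation_distance + 0.5 * state.ideal_bond + 0.5,
        )
        pairs = tree.query_pairs(reach, output_type="ndarray")
        if pairs.size:
            i_f, j_f = pairs[:, 0], pairs[:, 1]
            same = (i_f // N_NODES) == (j_f // N_NODES)
            i_f, j_f = i_f[~same], j_f[~same]
        else:
            i_f = j_f = np.empty(0, np.int64)
    else:
        i_f, j_f = pair_index

    if linked_index is None:
        lp = state.linked_pairs()
        li = lp[:, 0] * N_NODES + lp[:, 1]
        lj = lp[:, 2] * N_NODES + lp[:, 3]
    else:
        li, lj = linked_index

    # resting enclosed area of the regular octagon of the cell radius
    area_target = N_NODES * 0.5 * state.radius**2 * math.sin(2 * math.pi / N_NODES)
    for _ in range(max_sweeps):
        worst = constraint_sweep(
            flat,
            state.n_cells,
            state.ideal_bond,
            state.radius,
            bond_stiffness,
            radial_stiffness,
            np.ascontiguousarray(li),
            np.ascontiguousarray(lj),
            np.ascontiguousarray(i_f),
            np.ascontiguousarray(j_f),
            separation_distance,
            tether_rest,
            tether_stiffness,
            area_target,
            area_stiffness,
            separation_stiffness,
            eject_stiffness,
            1 if use_segment_exclusion else 0,
            state.arena.radius,
        )
        if worst < tol:
            break
    return state


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_NODE_COLS = [f"node{k}_{ax}" for k in range(N_NODES) for ax in ("x", "y")]


def state_to_table(state: SimulationState) -> pd.DataFrame:
    """Flat per-cell snapshot table (one row per cell)."""
    n = state.n_cells
    c = state.centroids
    data = {
        "step": np.full(n, state.step_count),
        "time_min": np.full(n, state.time_min),
        "cell_id": np.arange(n),
        "population": [state.populations[p] for p in state.pop],
        "centroid_x": c[:, 0],
        "centroid_y": c[:, 1],
        "leader_index": state.leader,
    }
    flat_nodes = state.pos.reshape(n, N_NODES * 2)
    for k, col in enumerate(_NODE_COLS):
        data[col] = flat_nodes[:, k]
    return pd.DataFrame(data)


def state_from_table(
    df: pd.DataFrame,
    arena: Arena,
    radius: float = 7.5,
    step_duration_s: float = 0.5,
) -> SimulationState:
    """Rebuild a state from a snapshot table (links are not stored)."""
    populations = tuple(dict.fromkeys(df["population"]))
    pop = np.array([populations.index(p) for p in df["population"]])
    pos = df[_NODE_COLS].to_numpy(float).reshape(len(df), N_NODES, 2)
    state = SimulationState(
        arena, pos, pop, populations, df["leader_index"].to_numpy(),
        radius=radius, step_duration_s=step_duration_s,
    )
    state.step_count = int(df["step"].iloc[0]) if len(df) else 0
    return state


def save_state_csv(state: SimulationState, path) -> None:
    """Write a checkpoint CSV that round-trips node positions bit-exactly."""
    state_to_table(state).to_csv(path, index=False, float_format="%.17g")


def load_state_csv(
    path, arena: Arena, radius: float = 7.5, step_duration_s: float = 0.5
) -> SimulationState:
    df = pd.read_csv(path, float_precision="round_trip")
    return state_from_table(df, arena, radius=radius, step_duration_s=step_duration_s)
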