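"""One stochastic update step of the cell model.

Each step (default 0.5 s), in a fixed phase order:

1. *link formation* — free membrane nodes of distinct cells within the
   contact distance become linked (adhesion);
2. *link breaking* — every link independently breaks with a per-step
   hazard derived from the pair-class break rate (the inverse mean contact
   duration); links sheared beyond a detach distance are removed passively;
3. *repulsion* — for each cell whose link just broke, a Bernoulli draw
   with that cell's p(repulsion) against the partner's population decides
   whether the membrane node opposite the broken link becomes the leader
   (contact inhibition of locomotion); in adhesion-only mode (directed
   off) the leader is instead re-chosen uniformly at random;
4. *spontaneous direction change* — once per decision tick each cell
   re-chooses its leader uniformly with probability p(change of direction);
5. *displacement* — every cell translates toward its leader node by
   speed x step duration;
6. *cohesion* — a repelled cell pulls on linked neighbours, rotating their
   migration direction toward its own by the pull weight;
7. *constraints* — bond lengths, cell shape, non-overlap and the arena
   wall are re-enforced by position projection.

All randomness is drawn from a single ``numpy.random.Generator``; equal
seed and configuration give bit-identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .behaviour import CohesionParams, InteractionMatrix, MotilityParams, Preset
from .geometry import (
    N_NODES,
    NO_LINK,
    OPPOSITE_OFFSET,
    SimulationState,
    enforce_constraints,
)

__all__ = [
    "Simulation",
    "form_links",
    "break_links",
    "trigger_repulsion",
    "cohesion_pull",
    "DEFAULT_CONTACT_DISTANCE",
]

#: Default node-to-node distance (um) at which adhesion links form; also the
#: minimum separation enforced between nodes of distinct cells.
DEFAULT_CONTACT_DISTANCE = 2.0

_EPS = 1e-9


def _cross_cell_pairs(state: SimulationState, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Flat node-index pairs of distinct cells within ``radius``."""
    flat = state.pos.reshape(-1, 2)
    pairs = cKDTree(flat).query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    i_f, j_f = pairs[:, 0], pairs[:, 1]
    keep = (i_f // N_NODES) != (j_f // N_NODES)
    return i_f[keep], j_f[keep]


def form_links(
    state: SimulationState,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    rng: np.random.Generator | None = None,
    candidates: tuple[np.ndarray, np.ndarray] | None = None,
    blocked_pairs: dict[tuple[int, int], int] | None = None,
    events: list | None = None,
) -> SimulationState:
    """Link every eligible free node pair within the contact distance.

    A node holds at most one link; when several partners are in range the
    nearest eligible one wins (ties broken by lowest cell id through the
    stable distance sort). ``blocked_pairs`` maps unordered cell-id pairs
    to an expiry step before which they may not re-link (refractory period
    after a stochastic break, giving a repelled cell time to disengage).
    """
    if candidates is None:
        candidates = _cross_cell_pairs(state, contact_distance * (1 + _EPS))
    i_f, j_f = candidates
    if i_f.size == 0:
        return state
    flat = state.pos.reshape(-1, 2)
    d = np.linalg.norm(flat[i_f] - flat[j_f], axis=1)
    within = d <= contact_distance * (1 + _EPS)
    free = (state.link_cell.reshape(-1)[i_f] == NO_LINK) & (
        state.link_cell.reshape(-1)[j_f] == NO_LINK
    )
    mask = within & free
    if not mask.any():
        return state
    i_c, j_c, d_c = i_f[mask], j_f[mask], d[mask]
    order = np.argsort(d_c, kind="stable")
    link_cell = state.link_cell.reshape(-1)
    for idx in order:
        a, b = int(i_c[idx]), int(j_c[idx])
        if link_cell[a] != NO_LINK or link_cell[b] != NO_LINK:
            continue
        ca, na = divmod(a, N_NODES)
        cb, nb = divmod(b, N_NODES)
        if blocked_pairs:
            key = (ca, cb) if ca < cb else (cb, ca)
            expiry = blocked_pairs.get(key)
            if expiry is not None:
                if state.step_count < expiry:
                    continue
                del blocked_pairs[key]
        state.add_link(ca, na, cb, nb)
        if events is not None:
            events.append((state.step_count, state.time_min, "link_form", ca, na, cb, nb))
    return state


def _per_step_break_probs(
    state: SimulationState, matrix: InteractionMatrix
) -> np.ndarray:
    """(n_pop, n_pop) per-step break probability table.

    The per-minute break rate of a pair class is converted to a per-step
    hazard ``1 - exp(-rate * dt)`` so the expected link lifetime equals the
    measured mean contact duration regardless of the step size.
    """
    pops = state.populations
    n = len(pops)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            rate = matrix.link_break_rate(pops[a], pops[b])
            out[a, b] = 1.0 - math.exp(-rate * state.dt_min)
    return out


def _break_links_impl(
    state: SimulationState,
    p_step: np.ndarray,
    rng: np.random.Generator,
    lp: np.ndarray,
    events: list | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-link break events; returns (broken, surviving) rows."""
    if lp.shape[0] == 0:
        return lp, lp
    p = p_step[state.pop[lp[:, 0]], state.pop[lp[:, 2]]]
    broke = rng.random(lp.shape[0]) < p
    broken = lp[broke]
    for ca, na, cb, nb in broken:
        state.remove_link(int(ca), int(na))
        if events is not None:
            events.append(
                (state.step_count, state.time_min, "link_break", int(ca), int(na), int(cb), int(nb))
            )
    return broken, lp[~broke]


def break_links(
    state: SimulationState,
    matrix: InteractionMatrix | np.ndarray,
    rng: np.random.Generator,
    events: list | None = None,
) -> tuple[SimulationState, np.ndarray]:
    """Break each link independently with its pair-class per-step hazard.

    ``matrix`` is either an :class:`InteractionMatrix` (whose populations
    must cover the state's populations) or a precomputed per-step
    probability table indexed by population. Returns the state and an
    ``(n_broken, 4)`` array of ``(cell_a, node_a, cell_b, node_b)`` rows.
    """
    if isinstance(matrix, InteractionMatrix):
        p_step = _per_step_break_probs(state, matrix)
    else:
        p_step = matrix
    broken, _ = _break_links_impl(state, p_step, rng, state.linked_pairs(), events)
    return state, broken


def trigger_repulsion(
    state: SimulationState,
    cell_index: int,
    broken_node_index: int,
    p_repulsion: float,
    directed: bool,
    rng: np.random.Generator,
) -> bool:
    """Possibly reassign the leader of one cell after a link break.

    With directed repulsion, a Bernoulli(p_repulsion) success makes the
    node opposite the broken link (four ring positions away) the leader —
    the collapse/repulsion response — and ``True`` is returned. Without
    directed repulsion the leader is re-chosen uniformly at random
    (random migration after contact) and ``False`` is returned.
    """
    if not 0 <= broken_node_index < N_NODES:
        raise ValueError(f"broken_node_index must be in 0..{N_NODES - 1}")
    if directed:
        if rng.random() < p_repulsion:
            state.leader[cell_index] = (broken_node_index + OPPOSITE_OFFSET) % N_NODES
            return True
        return False
    state.leader[cell_index] = int(rng.integers(N_NODES))
    return False


def cohesion_pull(
    state: SimulationState,
    repelled_cells,
    pull_weight: float,
) -> SimulationState:
    """Rotate linked neighbours of repelled cells toward their direction.

    Each cell holding at least one adhesion link to a repelled cell has
    its migration direction blended toward the repelled cell's new
    direction by fraction ``pull_weight`` (0 = no effect, 1 = adopt it),
    then its leader snaps to the membrane node best aligned with the
    blended direction. Only direct link neighbours are affected within a
    single step; influence propagates further only over subsequent steps.
    """
    repelled = np.asarray(list(repelled_cells), dtype=np.int64)
    if repelled.size == 0 or pull_weight == 0.0:
        return state
    dirs = state.directions()
    # neighbours linked to each repelled cell
    pull_vec: dict[int, list[np.ndarray]] = {}
    rep_set = set(int(r) for r in repelled)
    for r in rep_set:
        partners = state.link_cell[r]
        for cb in partners[partners != NO_LINK]:
            cb = int(cb)
            if cb in rep_set:
                continue
            pull_vec.setdefault(cb, []).append(dirs[r])
    if not pull_vec:
        return state
    c = state.centroids
    for nb, vecs in pull_vec.items():
        target = np.mean(vecs, axis=0)
        blended = (1.0 - pull_weight) * dirs[nb] + pull_weight * target
        norm = np.linalg.norm(blended)
        if norm < 1e-12:
            continue
        blended /= norm
        node_vecs = state.pos[nb] - c[nb]
        nv = np.linalg.norm(node_vecs, axis=1)
        nv[nv == 0] = 1.0
        align = (node_vecs / nv[:, None]) @ blended
        state.leader[nb] = int(np.argmax(align))
    return state


@dataclass
class _EventCounts:
    link_form: int = 0
    link_break: int = 0
    link_detach: int = 0
    repulsion: int = 0
    dir_change: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "link_form": self.link_form,
            "link_break": self.link_break,
            "link_detach": self.link_detach,
            "repulsion": self.repulsion,
            "dir_change": self.dir_change,
        }


class Simulation:
    """Drives a :class:`SimulationState` under a behaviour preset.

    Parameters
    ----------
    state
        Initial geometric state (see ``cilsim.experiments`` initializers).
    preset
        Behaviour preset: interaction matrix, motility, cohesion.
    contact_distance
        Node separation (um) at and below which links form; also the
        enforced minimum separation between cells.
    relink_refractory_min
        After a stochastic link break, the two cells may not form a new
        link for this many minutes, giving a repelled cell time to
        disengage before adhesion can re-capture it.
    record_events
        Keep a full per-event log (step, time, kind, ids); event counts
        are always kept.
    """

    def __init__(
        self,
        state: SimulationState,
        preset: Preset,
        rng: np.random.Generator | int | None = None,
        contact_distance: float = DEFAULT_CONTACT_DISTANCE,
        separation_distance: float | None = None,
        tether_rest: float | None = None,
        tether_stiffness: float = 0.3,
        detach_factor: float = 3.0,
        relink_refractory_min: float = 3.0,
        skin: float = 1.0,
        record_events: bool = False,
    ) -> None:
        if set(state.populations) - set(preset.populations):
            raise ValueError(
                f"state populations {state.populations} not covered by "
                f"preset populations {preset.populations}"
            )
        self.state = state
        self.preset = preset
        self.rng = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        self.contact_distance = float(contact_distance)
        self.separation_distance = (
            self.contact_distance
            if separation_distance is None
            else float(separation_distance)
        )
        self.tether_rest = (
            self.contact_distance if tether_rest is None else float(tether_rest)
        )
        self.tether_stiffness = float(tether_stiffness)
        self.detach_distance = detach_factor * self.contact_distance
        self.skin = float(skin)
        self.refractory_steps = int(round(relink_refractory_min / state.dt_min))
        self.record_events = record_events
        self.events: list = [] if record_events else None
        self.counts = _EventCounts()
        self._blocked: dict[tuple[int, int], int] = {}

        # per-step tables indexed by population
        self._p_step_break = _per_step_break_probs(state, preset.matrix)
        npop = len(state.populations)
        self._p_rep = np.zeros((npop, npop))
        self._directed = np.zeros((npop, npop), dtype=bool)
        for a, pa in enumerate(state.populations):
            for b, pb in enumerate(state.populations):
                e = preset.matrix.get(pa, pb)
                self._p_rep[a, b] = e.p_repulsion
                self._directed[a, b] = e.directed

        m = preset.motility
        self._step_disp = m.speed * state.dt_min
        self._tick_steps = max(1, int(round(m.decision_tick_min / state.dt_min)))
        self._p_change_dir = m.p_change_dir
        self._pull_weight = preset.cohesion.pull_weight

        # Verlet neighbour list
        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._pos_at_build: np.ndarray | None = None

    # -- neighbour bookkeeping --------------------------------------------

    def _ensure_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.state
        if self._pairs is not None and self._pos_at_build is not None:
            drift = np.abs(s.pos - self._pos_at_build).max()
            if drift < self.skin / 2.0:
                return self._pairs
        reach = (
            max(
                self.contact_distance,
                self.separation_distance + 0.5 * s.ideal_bond,
            )
            + self.skin
        )
        self._pairs = _cross_cell_pairs(s, reach)
        self._pos_at_build = s.pos.copy()
        return self._pairs

    # -- one step ----------------------------------------------------------

    def step(self) -> None:
        s = self.state
        rng = self.rng
        pairs = self._ensure_pairs()

        # 1. adhesion link formation
        n_before = s.n_links()
        form_links(
            s,
            self.contact_distance,
            rng,
            candidates=pairs,
            blocked_pairs=self._blocked,
            events=self.events,
        )
        self.counts.link_form += s.n_links() - n_before

        # passive detachment of overstretched links (sheared apart by the
        # crowd); no repulsion and no refractory period
        lp = s.linked_pairs()
        if lp.shape[0]:
            flat = s.pos.reshape(-1, 2)
            ia = lp[:, 0] * N_NODES + lp[:, 1]
            ib = lp[:, 2] * N_NODES + lp[:, 3]
            too_far = (
                np.linalg.norm(flat[ia] - flat[ib], axis=1) > self.detach_distance
            )
            if too_far.any():
                for ca, na, cb, nb in lp[too_far]:
                    s.remove_link(int(ca), int(na))
                    self.counts.link_detach += 1
                    if self.events is not None:
                        self.events.append(
                            (s.step_count, s.time_min, "link_detach", int(ca), int(na), int(cb), int(nb))
                        )
                lp = lp[~too_far]

        # 2. stochastic link breaking
        broken, lp = _break_links_impl(s, self._p_step_break, rng, lp, self.events)
        self.counts.link_break += broken.shape[0]

        # 3. repulsion responses, evaluated independently on both sides.
        # The contact point is re-derived at break time (the node currently
        # facing the partner): cells slide around each other during long
        # contacts, so the node that carried the link no longer marks where
        # the partner is, and the repulsed leader must point away from the
        # partner as it is now.
        repelled: list[int] = []
        if broken.shape[0]:
            cent = s.centroids
        for ca, na, cb, nb in broken:
            ca, na, cb, nb = int(ca), int(na), int(cb), int(nb)
            if self.refractory_steps:
                key = (ca, cb) if ca < cb else (cb, ca)
                self._blocked[key] = s.step_count + self.refractory_steps
            for cell, other in ((ca, cb), (cb, ca)):
                pa, pb = s.pop[cell], s.pop[other]
                facing = int(
                    np.argmin(
                        ((s.pos[cell] - cent[other]) ** 2).sum(axis=1)
                    )
                )
                if trigger_repulsion(
                    s, cell, facing, self._p_rep[pa, pb], bool(self._directed[pa, pb]), rng
                ):
                    repelled.append(cell)
                    self.counts.repulsion += 1
                    if self.events is not None:
                        self.events.append(
                            (s.step_count, s.time_min, "repulsion", cell, facing, other, -1)
                        )

        # 4. spontaneous direction change, once per decision tick
        if s.step_count % self._tick_steps == 0:
            change = rng.random(s.n_cells) < self._p_change_dir
            n_change = int(change.sum())
            if n_change:
                s.leader[change] = rng.integers(N_NODES, size=n_change)
                self.counts.dir_change += n_change

        # 5. displacement toward the leader node
        if self._step_disp:
            s.pos += (self._step_disp * s.directions())[:, None, :]

        # 6. cohesive pull of linked neighbours of repelled cells
        if repelled and self._pull_weight:
            cohesion_pull(s, repelled, self._pull_weight)

        # 7. structural constraints (linked pairs unchanged since phase 3)
        enforce_constraints(
            s,
            contact_distance=self.contact_distance,
            separation_distance=self.separation_distance,
            tether_rest=self.tether_rest,
            tether_stiffness=self.tether_stiffness,
            pair_index=self._pairs,
            linked_index=(
                lp[:, 0] * N_NODES + lp[:, 1],
                lp[:, 2] * N_NODES + lp[:, 3],
            ),
        )
        s.step_count += 1
        # drop expired refractory entries occasionally
        if self._blocked and s.step_count % 1200 == 0:
            self._blocked = {
                k: v for k, v in self._blocked.items() if v > s.step_count
            }

    def run(self, n_steps: int) -> SimulationState:
        for _ in range(n_steps):
            self.step()
        return self.state

    def events_dataframe(self) -> pd.DataFrame:
        """Event log as a table (requires ``record_events=True``)."""
        if self.events is None:
            raise ValueError("event recording was not enabled")
        return pd.DataFrame(
            self.events,
            columns=["step", "time_min", "event", "cell_a", "node_a", "cell_b", "node_b"],
        )
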