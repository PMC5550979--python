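"""Quantitation of segregation, border sharpness and cell behaviour.

Operates on labelled point sets (cell centroids with population labels),
on binary rasters, or on track tables (per-frame positions), so the same
algorithms apply to simulation output and to externally supplied tracks.

* ``border_length`` — the interface between two populations, measured by
  linking each cell to its nearest heterotypic neighbour, taking the
  midpoint of each such segment, and chaining the midpoints into a
  polyline whose total length is the border length. Sharpening shows as a
  decrease of this length over time.
* ``cluster_particle_analysis`` — connected-component analysis of a
  binary raster of one population; clusters below a minimum area are
  discarded and areas are converted to cell counts with a mean cell area.
* ``extract_contact_events`` / ``migrates_away`` /
  ``displacement_after_repulsion`` — contact-event statistics from track
  tables: duration, collapse flag, the angle theta between the contact
  axis and the post-contact direction, and the displacement time course
  after repulsion.
* ``segregation_index`` — mean fraction of k nearest neighbours sharing a
  cell's label; 0.5 for a random 50:50 mixture, approaching 1 for fully
  sorted populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import N_NODES, SimulationState

__all__ = [
    "BorderTrace",
    "ClusterReport",
    "ContactEvent",
    "border_length",
    "relative_border_length",
    "cluster_particle_analysis",
    "rasterize_population",
    "extract_contact_events",
    "migrates_away",
    "displacement_after_repulsion",
    "segregation_index",
    "labelled_points_from_state",
]

TRACK_COLUMNS = ["frame", "time_min", "cell_id", "population", "x_um", "y_um"]


def labelled_points_from_state(state: SimulationState) -> pd.DataFrame:
    """Centroid table (cell_id, population, x_um, y_um) from a state."""
    c = state.centroids
    return pd.DataFrame(
        {
            "cell_id": np.arange(state.n_cells),
            "population": [state.populations[p] for p in state.pop],
            "x_um": c[:, 0],
            "y_um": c[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Border length
# ---------------------------------------------------------------------------

@dataclass
class BorderTrace:
    """Ordered border midpoints and their polyline length."""

    midpoints: np.ndarray  # (m, 2), chained order
    length: float
    frame: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.midpoints, columns=["x_um", "y_um"])


def _nearest_heterotypic_midpoints(xy: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Midpoints of the short segments joining neighbouring cells of the
    two populations.

    Each cell is paired with its nearest heterotypic neighbour and the
    *mutual* pairs (each cell is the other's nearest) are kept: these are
    the segments between cells that actually abut across the interface,
    whereas a cell deep inside its own territory chooses a distant
    partner that does not choose it back, and contributes no segment.
    """
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(
            f"border is defined for exactly two populations, got {list(uniq)}"
        )
    a_idx = np.flatnonzero(labels == uniq[0])
    b_idx = np.flatnonzero(labels == uniq[1])
    tree_a, tree_b = cKDTree(xy[a_idx]), cKDTree(xy[b_idx])
    _, nb = tree_b.query(xy[a_idx])  # for each a-cell, nearest b position
    _, na = tree_a.query(xy[b_idx])  # for each b-cell, nearest a position
    mutual = na[nb] == np.arange(len(a_idx))
    pairs = np.column_stack([a_idx[mutual], b_idx[nb[mutual]]])
    if pairs.shape[0] == 0:
        raise ValueError("no abutting heterotypic cell pairs; border undefined")
    return 0.5 * (xy[pairs[:, 0]] + xy[pairs[:, 1]])


def _chain_length(midpoints: np.ndarray, start_from: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy nearest-neighbour chaining of midpoints starting at the
    point farthest along ``start_from`` (an arena-edge anchor)."""
    m = len(midpoints)
    if m < 2:
        return midpoints, 0.0
    remaining = list(range(m))
    # start from the midpoint nearest the field edge (extreme projection)
    proj = midpoints @ start_from
    cur = int(np.argmax(proj))
    order = [cur]
    remaining.remove(cur)
    pts = midpoints
    length = 0.0
    while remaining:
        d = np.linalg.norm(pts[remaining] - pts[cur], axis=1)
        k = int(np.argmin(d))
        length += float(d[k])
        cur = remaining.pop(k)
        order.append(cur)
    return pts[order], length


def border_length(
    points: pd.DataFrame,
    frame: int | None = None,
) -> BorderTrace:
    """Border between two populations of labelled points.

    ``points`` needs columns ``x_um``, ``y_um``, ``population`` (a frame
    column is ignored unless ``frame`` selects one). Each cell is paired
    with its nearest heterotypic neighbour; the midpoints of the
    deduplicated segments are chained greedily (starting from the
    midpoint nearest the field edge along the border's minor axis) and
    the polyline length is returned.
    """
    df = points
    if frame is not None:
        df = df[df["frame"] == frame]
    xy = df[["x_um", "y_um"]].to_numpy(float)
    labels = df["population"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("both populations must be present to define a border")
    mid = _nearest_heterotypic_midpoints(xy, labels)
    # chain along the border's own principal axis so the start anchor sits
    # at one end of the interface
    centred = mid - mid.mean(axis=0)
    if len(mid) > 1:
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
    else:
        axis = np.array([0.0, 1.0])
    ordered, length = _chain_length(mid, axis)
    return BorderTrace(midpoints=ordered, length=length, frame=frame)


def relative_border_length(trace: BorderTrace, reference_width: float) -> float:
    """Border length normalized to the straight-interface width, so runs
    in different geometries are comparable (1.0 = perfectly straight)."""
    if reference_width <= 0:
        raise ValueError("reference_width must be > 0")
    return trace.length / reference_width


# ---------------------------------------------------------------------------
# Cluster particle analysis
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """Connected-cluster areas of one population and their cell counts."""

    areas_um2: np.ndarray
    cell_counts: np.ndarray
    min_area_um2: float
    cell_area_um2: float

    @property
    def n_clusters(self) -> int:
        return len(self.areas_um2)

    @property
    def total_cells(self) -> int:
        return int(self.cell_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_um2": self.areas_um2, "cells": self.cell_counts}
        )


def rasterize_population(
    state: SimulationState,
    population: str,
    um_per_px: float = 1.0,
) -> np.ndarray:
    """Binary raster of one population, cells drawn as filled node rings."""
    from skimage.draw import polygon

    r = state.arena.radius
    size = int(math.ceil(2 * r / um_per_px)) + 1
    mask = np.zeros((size, size), dtype=bool)
    pidx = state.populations.index(population)
    for i in np.flatnonzero(state.pop == pidx):
        ring = state.pos[i]
        rr, cc = polygon(
            (ring[:, 1] + r) / um_per_px, (ring[:, 0] + r) / um_per_px, shape=mask.shape
        )
        mask[rr, cc] = True
    return mask


def cluster_particle_analysis(
    mask: np.ndarray,
    um_per_px: float = 1.0,
    min_area: float = 500.0,
    cell_area: float = 200.0,
) -> ClusterReport:
    """Particle analysis of a binary mask.

    Connected components (8-connectivity) with area >= ``min_area`` um^2
    are reported; each cluster's area is converted to a cell count with
    the mean single-cell area ``cell_area`` um^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D binary raster")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return ClusterReport(
            np.empty(0), np.empty(0, int), min_area, cell_area
        )
    px_area = um_per_px**2
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)) * px_area
    keep = sizes >= min_area
    areas = np.sort(sizes[keep])[::-1]
    cells = np.rint(areas / cell_area).astype(int)
    return ClusterReport(areas, cells, min_area, cell_area)


# ---------------------------------------------------------------------------
# Contact events
# ---------------------------------------------------------------------------

@dataclass
class ContactEvent:
    """One episode of sustained proximity between two tracked cells."""

    cell_id: int
    partner_id: int
    pair_class: str  # "homotypic" or "heterotypic"
    t_start: float
    t_end: float
    duration: float
    axis_at_start: np.ndarray | None
    post_direction: np.ndarray | None
    theta: float | None
    collapse: bool
    censored: bool

    @property
    def theta_defined(self) -> bool:
        return self.theta is not None


def _check_regular(times: np.ndarray) -> float:
    diffs = np.diff(np.unique(times))
    if len(diffs) == 0:
        return 0.0
    if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise ValueError("tracks must be regularly sampled in time")
    return float(diffs[0])


def extract_contact_events(
    tracks: pd.DataFrame,
    contact_radius: float = 17.0,
    frame_interval: float = 3.0,
    theta_dt_frames: int = 3,
    censor_window_min: float = 20.0,
    collapse_events: pd.DataFrame | None = None,
) -> list[ContactEvent]:
    """Contact events from a regularly sampled track table.

    A contact spans consecutive frames in which the inter-centroid
    distance of a cell pair is <= ``contact_radius``; its duration is the
    number of in-contact frames times ``frame_interval``. For each event
    and each of the two cells:

    * the contact axis at the start is the unit vector from the cell to
      its partner;
    * the post-contact direction is the displacement over
      ``theta_dt_frames`` frames following the end of contact;
    * ``theta`` is the angle between the two (undefined, and flagged, for
      a stationary cell or when the track ends first);
    * the event is censored if the cell enters another contact within
      ``censor_window_min`` after the contact ends.

    ``collapse_events`` optionally annotates collapses: a table with
    columns ``cell_id``, ``partner_id``, ``time_min`` (e.g. the repulsion
    rows of a simulation event log, or a manual annotation for external
    tracks); an event is a collapse if such a row falls within the
    contact interval (inclusive of its end frame).

    Events are reported once per (cell, partner) ordered pair, so each
    physical contact yields two events, one from each cell's perspective.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    dt = _check_regular(tracks["time_min"].to_numpy(float))
    if dt and not math.isclose(dt, frame_interval, rel_tol=1e-6):
        frame_interval = dt

    frames = np.sort(tracks["frame"].unique())
    # positions indexed [cell][frame]
    piv_x = tracks.pivot_table(index="cell_id", columns="frame", values="x_um")
    piv_y = tracks.pivot_table(index="cell_id", columns="frame", values="y_um")
    piv_x = piv_x.reindex(columns=frames)
    piv_y = piv_y.reindex(columns=frames)
    ids = piv_x.index.to_numpy()
    pop = tracks.groupby("cell_id")["population"].first().reindex(ids)
    X = piv_x.to_numpy(float)
    Y = piv_y.to_numpy(float)
    t0 = float(tracks["time_min"].min())

    # per-frame contact adjacency
    n = len(ids)
    in_contact = {}
    for fi in range(len(frames)):
        xy = np.column_stack([X[:, fi], Y[:, fi]])
        ok = ~np.isnan(xy).any(axis=1)
        idx = np.flatnonzero(ok)
        if len(idx) < 2:
            in_contact[fi] = set()
            continue
        pairs = cKDTree(xy[idx]).query_pairs(contact_radius)
        in_contact[fi] = {(int(idx[a]), int(idx[b])) for a, b in pairs}

    # contiguous runs per pair
    runs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    active: dict[tuple[int, int], int] = {}
    for fi in range(len(frames)):
        now = in_contact[fi]
        for p in now:
            if p not in active:
                active[p] = fi
        ended = [p for p in active if p not in now]
        for p in ended:
            runs.setdefault(p, []).append((active.pop(p), fi - 1))
    for p, start in active.items():
        runs.setdefault(p, []).append((start, len(frames) - 1))

    # contact frame sets per cell, for censoring
    contact_frames: dict[int, list[tuple[int, int]]] = {}
    for (a, b), intervals in runs.items():
        for iv in intervals:
            contact_frames.setdefault(a, []).append(iv)
            contact_frames.setdefault(b, []).append(iv)

    if collapse_events is not None:
        ce = collapse_events[["cell_id", "partner_id", "time_min"]]
    else:
        ce = None

    events: list[ContactEvent] = []
    censor_frames = int(round(censor_window_min / frame_interval))
    for (a, b), intervals in sorted(runs.items()):
        for fs, fe in intervals:
            duration = (fe - fs + 1) * frame_interval
            t_start = t0 + fs * frame_interval
            t_end = t0 + fe * frame_interval
            for me, other in ((a, b), (b, a)):
                ax = np.array(
                    [X[other, fs] - X[me, fs], Y[other, fs] - Y[me, fs]]
                )
                nax = np.linalg.norm(ax)
                axis = ax / nax if nax > 0 else None
                fpost = fe + theta_dt_frames
                post = theta = None
                if fpost < len(frames):
                    v = np.array([X[me, fpost] - X[me, fe], Y[me, fpost] - Y[me, fe]])
                    nv = np.linalg.norm(v)
                    if nv > 1e-12 and axis is not None:
                        post = v / nv
                        theta = float(np.arccos(np.clip(post @ axis, -1.0, 1.0)))
                censored = False
                for fs2, fe2 in contact_frames.get(me, []):
                    if fs2 > fe and fs2 <= fe + censor_frames:
                        censored = True
                        break
                collapse = False
                if ce is not None:
                    sel = (
                        (ce["cell_id"] == ids[me])
                        & (ce["partner_id"] == ids[other])
                        & (ce["time_min"] >= t_start - frame_interval / 2)
                        & (ce["time_min"] <= t_end + frame_interval)
                    )
                    collapse = bool(sel.any())
                events.append(
                    ContactEvent(
                        cell_id=int(ids[me]),
                        partner_id=int(ids[other]),
                        pair_class=(
                            "homotypic" if pop.iloc[me] == pop.iloc[other] else "heterotypic"
                        ),
                        t_start=t_start,
                        t_end=t_end,
                        duration=duration,
                        axis_at_start=axis,
                        post_direction=post,
                        theta=theta,
                        collapse=collapse,
                        censored=censored,
                    )
                )
    return events


def migrates_away(
    event: ContactEvent,
    lower: float = math.pi / 2,
    upper: float = 3 * math.pi / 4,
) -> bool:
    """Whether a cell migrated away from its partner after contact.

    True iff theta lies within [lower, upper]; the default band is
    pi/2 .. 3*pi/4. Pass ``upper=math.pi`` to treat every direction with
    a component away from the partner as migrating away.
    Raises ``ValueError`` when theta is undefined for the event.
    """
    if event.theta is None:
        raise ValueError("theta undefined for this event (stationary cell)")
    return lower <= event.theta <= upper


def displacement_after_repulsion(
    events: list[ContactEvent],
    tracks: pd.DataFrame,
    frame_interval: float = 3.0,
    window_min: float = 20.0,
) -> pd.Series:
    """Mean per-interval displacement after uncensored collapse events.

    For every collapse event without a further collision within the
    window, the cell's displacement is measured over each
    ``frame_interval`` bin after the end of contact, and averaged over
    events. Returns a series indexed by bin start time (min after
    disengagement); empty (with a warning) when no usable events exist.
    """
    usable = [e for e in events if e.collapse and not e.censored]
    if not usable:
        warnings.warn("no uncensored collapse events; empty displacement profile")
        return pd.Series(dtype=float, name="displacement_um")
    piv_x = tracks.pivot_table(index="cell_id", columns="time_min", values="x_um")
    piv_y = tracks.pivot_table(index="cell_id", columns="time_min", values="y_um")
    n_bins = int(window_min // frame_interval)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    times = piv_x.columns.to_numpy(float)
    for e in usable:
        for k in range(n_bins):
            ta = e.t_end + k * frame_interval
            tb = ta + frame_interval
            ia = np.argmin(np.abs(times - ta))
            ib = np.argmin(np.abs(times - tb))
            if not (
                math.isclose(times[ia], ta, abs_tol=frame_interval / 4)
                and math.isclose(times[ib], tb, abs_tol=frame_interval / 4)
            ):
                continue
            x0, y0 = piv_x.at[e.cell_id, piv_x.columns[ia]], piv_y.at[e.cell_id, piv_y.columns[ia]]
            x1, y1 = piv_x.at[e.cell_id, piv_x.columns[ib]], piv_y.at[e.cell_id, piv_y.columns[ib]]
            if np.isnan([x0, y0, x1, y1]).any():
                continue
            sums[k] += math.hypot(x1 - x0, y1 - y0)
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    idx = pd.Index(
        np.arange(n_bins) * frame_interval, name="min_after_disengagement"
    )
    return pd.Series(prof, index=idx, name="displacement_um")


# ---------------------------------------------------------------------------
# Segregation index
# ---------------------------------------------------------------------------

def segregation_index(points: pd.DataFrame, k: int = 6) -> float:
    """Mean fraction of k nearest neighbours sharing each cell's label.

    0.5 for a random 50:50 mixture; -> 1 as the populations sort; below
    0.5 for anti-correlated (checkerboard) arrangements.
    """
    xy = points[["x_um", "y_um"]].to_numpy(float)
    labels = points["population"].to_numpy()
    n = len(xy)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    tree = cKDTree(xy)
    _, nbr = tree.query(xy, k=k + 1)
    same = labels[nbr[:, 1:]] == labels[:, None]
    return float(same.mean())
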