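"""Deterministic synthetic inputs with known ground truth for the metrics.

Three fixture kinds are provided (all synthetic, generated by code):

* ``labelled_points`` — labelled centroid sets with a known border
  geometry (straight split, checkerboard, random mixture);
* ``scripted_tracks`` — track tables with scripted contacts of known
  durations, optional collapses and a post-repulsion speed burst;
* ``boundary_masks`` — binary rasters containing blobs of specified
  areas for the cluster particle analysis.

Each generator returns in-memory objects plus a ground-truth dict; the
``generate_fixture`` entry point optionally writes them to disk as
CSV/JSON (text formats only).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "labelled_points_fixture",
    "scripted_tracks_fixture",
    "boundary_masks_fixture",
    "generate_fixture",
]


def labelled_points_fixture(
    kind: str = "straight",
    width: float = 100.0,
    spacing_x: float = 10.0,
    spacing_y: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Grid of labelled points in a square of side ``width``.

    ``kind``:
      * ``straight`` — left half population A, right half population B;
        the true border is the vertical midline of length ``width``;
      * ``checkerboard`` — labels alternate per grid site;
      * ``random`` — labels assigned 50:50 at random.

    A fine ``spacing_y`` makes the chained straight border converge to
    the interface width.
    """
    xs = np.arange(-width / 2 + spacing_x / 2, width / 2, spacing_x)
    ys = np.arange(-width / 2 + spacing_y / 2, width / 2, spacing_y)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    x = gx.ravel()
    y = gy.ravel()
    n = len(x)
    if kind == "straight":
        labels = np.where(x < 0, "A", "B")
    elif kind == "checkerboard":
        ix = np.rint((x - xs[0]) / spacing_x).astype(int)
        iy = np.rint((y - ys[0]) / spacing_y).astype(int)
        labels = np.where((ix + iy) % 2 == 0, "A", "B")
    elif kind == "random":
        rng = np.random.default_rng(seed)
        labels = np.full(n, "A", dtype=object)
        labels[rng.permutation(n)[: n // 2]] = "B"
    else:
        raise ValueError(f"unknown labelled_points kind {kind!r}")
    df = pd.DataFrame(
        {"cell_id": np.arange(n), "population": labels, "x_um": x, "y_um": y}
    )
    truth = {
        "kind": kind,
        "interface_width": width,
        "straight_border_length": width * (len(ys) - 1) / len(ys),
    }
    return df, truth


def scripted_tracks_fixture(
    n_contacts: int = 4,
    contact_frames: int = 4,
    frame_interval: float = 3.0,
    contact_radius: float = 17.0,
    speed: float = 0.75,
    burst_factor: float = 1.0,
    burst_min: float = 6.0,
    collapse: bool = True,
    gap_frames: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-cell approach/touch/retreat episodes with known durations.

    A mover (cell 0, population A) repeatedly approaches a stationary
    partner (cell 1, population B), stays within ``contact_radius`` for
    exactly ``contact_frames`` frames, then retreats along the same axis
    (theta = pi). ``burst_factor`` > 1 elevates the retreat speed for the
    first ``burst_min`` minutes after disengagement. Returns the track
    table, a collapse-annotation table (empty when ``collapse`` is
    False), and the ground truth.

    ``gap_frames`` must exceed the 20-min censoring window for the events
    to be uncensored (default 12 frames = 36 min).
    """
    rows = []
    collapses = []
    d_in = contact_radius - 2.0  # separation while "in contact"
    d_out = contact_radius + 30.0  # separation while apart
    frame = 0
    t = 0.0
    partner_xy = (0.0, 0.0)
    events = []
    for k in range(n_contacts):
        # approach: a few frames clearly out of contact
        for j in range(3):
            x = d_out - j * (d_out - d_in) / 3
            rows.append((frame, t, 0, "A", x, 0.0))
            rows.append((frame, t, 1, "B", *partner_xy))
            frame += 1
            t += frame_interval
        start_frame = frame
        for j in range(contact_frames):
            rows.append((frame, t, 0, "A", d_in, 0.0))
            rows.append((frame, t, 1, "B", *partner_xy))
            frame += 1
            t += frame_interval
        end_t = t - frame_interval
        events.append(
            {
                "duration": contact_frames * frame_interval,
                "t_end": end_t,
            }
        )
        if collapse:
            collapses.append((0, 1, end_t))
        # retreat straight away from partner (theta = pi), with optional burst
        x = d_in
        for j in range(gap_frames):
            within_burst = j * frame_interval < burst_min
            v = speed * (burst_factor if within_burst else 1.0)
            x += v * frame_interval
            rows.append((frame, t, 0, "A", x, 0.0))
            rows.append((frame, t, 1, "B", *partner_xy))
            frame += 1
            t += frame_interval
        # jump back out for next episode handled by approach loop
    tracks = pd.DataFrame(
        rows, columns=["frame", "time_min", "cell_id", "population", "x_um", "y_um"]
    )
    ann = pd.DataFrame(collapses, columns=["cell_id", "partner_id", "time_min"])
    truth = {
        "n_contacts": n_contacts,
        "duration_min": contact_frames * frame_interval,
        "theta": math.pi,
        "base_speed": speed,
        "burst_factor": burst_factor,
        "burst_min": burst_min,
        "event_ends": [e["t_end"] for e in events],
    }
    return tracks, ann, truth


def boundary_masks_fixture(
    blob_areas: tuple[float, ...] = (600.0, 600.0),
    um_per_px: float = 1.0,
    size: int = 200,
    min_gap_px: int = 10,
) -> tuple[np.ndarray, dict]:
    """Binary raster with square blobs of the requested areas.

    Blobs are axis-aligned squares (area exact in pixels at integer side
    lengths) separated by more than one pixel, so connected-component
    counting recovers them exactly.
    """
    mask = np.zeros((size, size), dtype=bool)
    x0 = 5
    placed = []
    for area in blob_areas:
        side = int(round(math.sqrt(area / um_per_px**2)))
        if x0 + side >= size:
            raise ValueError("fixture mask too small for requested blobs")
        mask[5 : 5 + side, x0 : x0 + side] = True
        placed.append(side * side * um_per_px**2)
        x0 += side + min_gap_px
    truth = {
        "areas_um2": placed,
        "cell_counts": [int(round(a / 200.0)) for a in placed],
    }
    return mask, truth


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0, outdir=None):
    """Generate a named fixture, optionally writing it to ``outdir``.

    ``kind`` is one of ``labelled_points``, ``scripted_tracks``,
    ``boundary_masks``. Ground truth is returned alongside the data and
    written as a JSON sidecar when ``outdir`` is given.
    """
    params = dict(params or {})
    if kind == "labelled_points":
        df, truth = labelled_points_fixture(seed=seed, **params)
        payload = {"points.csv": df}
    elif kind == "scripted_tracks":
        tracks, ann, truth = scripted_tracks_fixture(**params)
        payload = {"tracks.csv": tracks, "collapses.csv": ann}
    elif kind == "boundary_masks":
        mask, truth = boundary_masks_fixture(**params)
        payload = {"mask.csv": pd.DataFrame(mask.astype(int))}
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected labelled_points, "
            "scripted_tracks or boundary_masks"
        )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in payload.items():
            df.to_csv(out / name, index=False)
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    if kind == "labelled_points":
        return df, truth
    if kind == "scripted_tracks":
        return tracks, ann, truth
    return mask, truth
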