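"""Numba kernels for the constraint-projection inner loop.

The constraint sweep touches every node several times per step, so it is
implemented as a single fused Gauss-Seidel pass over flat position arrays:
membrane bonds, node-centroid radius, link tethering, pairwise separation
and the arena wall, returning the largest correction applied so the caller
can stop sweeping once the state has relaxed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_NODES = 8


@njit(cache=True)
def constraint_sweep(
    pos,            # (n_cells * 8, 2) node positions, modified in place
    n_cells,        # int
    ideal_bond,     # float
    radius,         # float, resting node-centroid distance
    bond_stiffness,  # float
    radial_stiffness,  # float
    li, lj,         # flat node indices of linked pairs (tether)
    pair_i, pair_j,  # flat node indices of candidate separation pairs
    separation,     # float, min separation between foreign nodes
    tether_rest,    # float, link length beyond which the tether pulls
    tether_stiffness,  # float, fraction of the excess recovered per sweep
    area_target,    # float, resting enclosed area of the node ring
    area_stiffness,  # float, fraction of the area deficit recovered per sweep
    separation_stiffness,  # float, fraction of shell violation recovered per sweep
    eject_stiffness,  # float, fraction of a containment violation recovered per sweep
    use_segments,   # int flag: 1 = node-to-segment membrane exclusion,
                    # 0 = node-to-node exclusion (cells may partially
                    # interpenetrate, standing in for 3D squeezing)
    arena_r,        # float
):
    worst = 0.0
    centroids = np.empty((n_cells, 2))

    # membrane bonds and shape radius, cell by cell
    for c in range(n_cells):
        base = c * N_NODES
        cx = 0.0
        cy = 0.0
        for k in range(N_NODES):
            cx += pos[base + k, 0]
            cy += pos[base + k, 1]
        cx /= N_NODES
        cy /= N_NODES
        centroids[c, 0] = cx
        centroids[c, 1] = cy
        for k in range(N_NODES):
            i = base + k
            # radial relaxation toward the resting radius, hard-capped at 2r
            vx = pos[i, 0] - cx
            vy = pos[i, 1] - cy
            dist = np.sqrt(vx * vx + vy * vy)
            if dist > 1e-12:
                target = dist + radial_stiffness * (radius - dist)
                if target > 2.0 * radius:
                    target = 2.0 * radius
                corr = abs(target - dist)
                if corr > worst:
                    worst = corr
                f = target / dist
                pos[i, 0] = cx + vx * f
                pos[i, 1] = cy + vy * f
        if area_stiffness > 0.0:
            # area maintenance: inflate/deflate the ring along the radial
            # directions toward the resting enclosed area, leaving the
            # perimeter free to elongate (floppy, deformable membrane)
            area = 0.0
            for k in range(N_NODES):
                i = base + k
                j = base + (k + 1) % N_NODES
                area += pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1]
            area = 0.5 * area
            if area < 0.0:
                area = -area
            # radial scale factor for the deficit, bounded per sweep
            if area > 1e-9:
                g = area_stiffness * (area_target - area) / area
                if g > 0.2:
                    g = 0.2
                elif g < -0.2:
                    g = -0.2
                for k in range(N_NODES):
                    i = base + k
                    pos[i, 0] += g * (pos[i, 0] - cx)
                    pos[i, 1] += g * (pos[i, 1] - cy)
        for k in range(N_NODES):
            i = base + k
            j = base + (k + 1) % N_NODES
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist > 1e-12:
                corr = 0.5 * bond_stiffness * (dist - ideal_bond) / dist
                cxy = abs(corr * dist)
                if cxy > worst:
                    worst = cxy
                pos[i, 0] += corr * dx
                pos[i, 1] += corr * dy
                pos[j, 0] -= corr * dx
                pos[j, 1] -= corr * dy

    # adhesion links pull stretched contacts back together
    for p in range(li.shape[0]):
        i = li[p]
        j = lj[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        if dist > tether_rest:
            corr = tether_stiffness * (dist - tether_rest) / dist
            cxy = corr * dist
            if cxy > worst:
                worst = cxy
            pos[i, 0] += corr * dx
            pos[i, 1] += corr * dy
            pos[j, 0] -= corr * dx
            pos[j, 1] -= corr * dy

    # node-to-node exclusion (default): foreign nodes closer than the
    # separation distance are pushed apart symmetrically. The push acts
    # along the cell-centroid axis, which keeps its sign meaningful even
    # when membranes have transiently interpenetrated (a node-difference
    # direction would then push the rings deeper into each other).
    if use_segments == 0:
        for p in range(pair_i.shape[0]):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist < separation:
                ci = i // N_NODES
                cj = j // N_NODES
                ax = centroids[cj, 0] - centroids[ci, 0]
                ay = centroids[cj, 1] - centroids[ci, 1]
                an = np.sqrt(ax * ax + ay * ay)
                if an < 1e-12:
                    continue
                ax /= an
                ay /= an
                push = separation_stiffness * (separation - dist)
                if push > worst:
                    worst = push
                pos[i, 0] -= push * ax
                pos[i, 1] -= push * ay
                pos[j, 0] += push * ax
                pos[j, 1] += push * ay

    # deep-overlap ejection: a node that has penetrated inside another
    # cell's membrane polygon feels no shell force, so detect containment
    # (ray crossing) and eject the node through the nearest membrane
    # point; tested once per candidate pair, node i against cell of j
    for p in range(0 if (use_segments == 0 or eject_stiffness <= 0.0) else pair_i.shape[0]):
        for direction in range(2):
            if direction == 0:
                i = pair_i[p]
                cell_j = pair_j[p] // N_NODES
            else:
                i = pair_j[p]
                cell_j = pair_i[p] // N_NODES
            base = cell_j * N_NODES
            px = pos[i, 0]
            py = pos[i, 1]
            inside = False
            for k in range(N_NODES):
                ax = pos[base + k, 0]
                ay = pos[base + k, 1]
                bx = pos[base + (k + 1) % N_NODES, 0]
                by = pos[base + (k + 1) % N_NODES, 1]
                if (ay > py) != (by > py):
                    xint = ax + (py - ay) * (bx - ax) / (by - ay)
                    if px < xint:
                        inside = not inside
            if not inside:
                continue
            # nearest point on the polygon boundary
            best_d2 = 1e30
            best_qx = px
            best_qy = py
            for k in range(N_NODES):
                ax = pos[base + k, 0]
                ay = pos[base + k, 1]
                bx = pos[base + (k + 1) % N_NODES, 0]
                by = pos[base + (k + 1) % N_NODES, 1]
                ex = bx - ax
                ey = by - ay
                seg2 = ex * ex + ey * ey
                if seg2 < 1e-12:
                    continue
                t = ((px - ax) * ex + (py - ay) * ey) / seg2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
                qx = ax + t * ex
                qy = ay + t * ey
                d2 = (px - qx) ** 2 + (py - qy) ** 2
                if d2 < best_d2:
                    best_d2 = d2
                    best_qx = qx
                    best_qy = qy
            d = np.sqrt(best_d2)
            if d > 1e-12:
                # move the node back toward just outside the membrane
                scale = eject_stiffness * (d + 0.5 * separation) / d
                mx = (best_qx - px) * scale
                my = (best_qy - py) * scale
                pos[i, 0] = px + mx
                pos[i, 1] = py + my
                if d > worst:
                    worst = d

    # membrane-segment exclusion (optional): each candidate node is kept
    # at least `separation` away from the partner node's adjacent
    # membrane segment (node-to-segment, so rings cannot interpenetrate
    # between nodes), with the push shared between the node and the
    # segment endpoints
    for p in range(0 if use_segments == 0 else pair_i.shape[0]):
        for direction in range(2):
            if direction == 0:
                i = pair_i[p]
                j = pair_j[p]
            else:
                i = pair_j[p]
                j = pair_i[p]
            cell_j = j // N_NODES
            k_j = j - cell_j * N_NODES
            jn = cell_j * N_NODES + (k_j + 1) % N_NODES
            ax = pos[j, 0]
            ay = pos[j, 1]
            bx = pos[jn, 0]
            by = pos[jn, 1]
            ex = bx - ax
            ey = by - ay
            seg2 = ex * ex + ey * ey
            if seg2 < 1e-12:
                continue
            t = ((pos[i, 0] - ax) * ex + (pos[i, 1] - ay) * ey) / seg2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            qx = ax + t * ex
            qy = ay + t * ey
            dx = pos[i, 0] - qx
            dy = pos[i, 1] - qy
            dist = np.sqrt(dx * dx + dy * dy)
            if 1e-12 < dist < separation:
                push = separation_stiffness * (separation - dist)
                if push > worst:
                    worst = push
                ux = dx / dist
                uy = dy / dist
                pos[i, 0] += push * ux
                pos[i, 1] += push * uy
                pos[j, 0] -= push * (1.0 - t) * ux
                pos[j, 1] -= push * (1.0 - t) * uy
                pos[jn, 0] -= push * t * ux
                pos[jn, 1] -= push * t * uy

    # hard circular arena wall
    for i in range(pos.shape[0]):
        r2 = pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
        if r2 > arena_r * arena_r:
            r = np.sqrt(r2)
            f = arena_r / r
            pos[i, 0] *= f
            pos[i, 1] *= f
            if r - arena_r > worst:
                worst = r - arena_r

    return worst
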