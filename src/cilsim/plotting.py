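"""Static snapshots of simulation states."""

from __future__ import annotations

import numpy as np

from .geometry import SimulationState

_POP_COLORS = ("tab:green", "tab:red", "tab:blue", "tab:orange")


def plot_state(state: SimulationState, path=None, ax=None, border=None):
    """Draw every cell as its filled membrane ring, coloured by
    population; optionally overlay a border polyline and save to
    ``path`` (PNG)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for i in range(state.n_cells):
        ring = np.vstack([state.pos[i], state.pos[i][:1]])
        ax.fill(
            ring[:, 0],
            ring[:, 1],
            color=_POP_COLORS[state.pop[i] % len(_POP_COLORS)],
            alpha=0.6,
            lw=0.4,
            ec="k",
        )
    if border is not None:
        ax.plot(border.midpoints[:, 0], border.midpoints[:, 1], "k-", lw=1.0)
    r = state.arena.radius
    ax.add_patch(plt.Circle((0, 0), r, fill=False, color="0.4", lw=1.0))
    ax.set_xlim(-1.05 * r, 1.05 * r)
    ax.set_ylim(-1.05 * r, 1.05 * r)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {state.time_min:.0f} min, {state.n_cells} cells")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
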