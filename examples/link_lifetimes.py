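"""Adhesion-link lifetimes reproduce the measured contact durations.

Links break with a constant per-step hazard derived from the mean contact
duration of their pair class (heterotypic EphB2/ephrinB1 contacts last
~24-26 min, homotypic EphB2 contacts ~72 min). Simulating a large batch
of links and averaging their lifetimes recovers those durations.
"""

import numpy as np

from cilsim import Arena, SimulationState, break_links, build_preset
from cilsim.geometry import octagon_nodes

preset = build_preset("control_EphB2_ephrinB1")
rng = np.random.default_rng(0)

for pops, label in [((0, 1), "heterotypic EphB2-ephrinB1"), ((0, 0), "homotypic EphB2")]:
    n_links = 2000
    # a row of linked cell pairs, far apart so only the hazard matters
    arena = Arena(100000.0)
    centers = np.arange(2 * n_links)[:, None] * np.array([40.0, 0.0])
    pos = np.stack([octagon_nodes(c, 7.5) for c in centers])
    pop = np.tile(pops, n_links).astype(np.int64)
    state = SimulationState(arena, pos, pop, preset.populations, np.zeros(2 * n_links, np.int64))
    for k in range(n_links):
        state.add_link(2 * k, 0, 2 * k + 1, 4)
    lifetimes = np.zeros(n_links)
    alive = state.n_links()
    while alive:
        _, broken = break_links(state, preset.matrix, rng)
        for ca, na, cb, nb in broken:
            lifetimes[ca // 2] = state.time_min + state.dt_min
        state.step_count += 1
        alive -= len(broken)
    expect = 1.0 / preset.matrix.link_break_rate(*[preset.populations[p] for p in pops])
    print(f"{label}: mean lifetime {lifetimes.mean():6.1f} min (hazard predicts {expect:.1f})")
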