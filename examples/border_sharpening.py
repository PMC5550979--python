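"""A small boundary assay: two populations meet at a fuzzy interface.

Runs the control condition (directed heterotypic repulsion) on a reduced
arena and prints the relative border length (1.0 = perfectly straight
interface) and segregation index over time. Expect the border metric to
stay near its initial value or drift down as mixed cells are resorbed;
the run is short, so changes are modest.
"""

import numpy as np

from cilsim.behaviour import build_preset
from cilsim.dynamics import Simulation
from cilsim.experiments import desk_scale_config, init_boundary
from cilsim.metrics import border_length, labelled_points_from_state, segregation_index

cfg = desk_scale_config(preset="control_EphB2_ephrinB1", assay="boundary", n_steps=5000)
preset = build_preset(cfg.preset)
rng = np.random.default_rng(42)
state = init_boundary(cfg, rng, preset)
sim = Simulation(state, preset, rng=rng)

print("time_min  relative_border_length  segregation_index")
for _ in range(6):
    pts = labelled_points_from_state(state)
    rel = border_length(pts).length / cfg.arena_diameter
    print(f"{state.time_min:8.1f}  {rel:22.3f}  {segregation_index(pts):17.3f}")
    sim.run(1000)
print(f"\nevents: {sim.counts.as_dict()}")
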