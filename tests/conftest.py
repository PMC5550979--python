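import numpy as np
import pytest

from cilsim.behaviour import build_preset
from cilsim.geometry import Arena, SimulationState, octagon_nodes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control_preset():
    return build_preset("control_EphB2_ephrinB1")


def make_state(centers, pops=None, arena=None, radius=7.5, leaders=None):
    """State with octagonal cells at the given centers."""
    centers = np.atleast_2d(np.asarray(centers, float))
    n = len(centers)
    arena = arena or Arena(500.0)
    pos = np.stack([octagon_nodes(c, radius) for c in centers])
    pops = np.zeros(n, dtype=np.int64) if pops is None else np.asarray(pops, np.int64)
    leaders = (
        np.zeros(n, dtype=np.int64) if leaders is None else np.asarray(leaders, np.int64)
    )
    return SimulationState(arena, pos, pops, ("EphB2", "ephrinB1"), leaders, radius=radius)


@pytest.fixture
def two_cell_state():
    """Two cells whose nearest nodes just touch the 2 um contact distance."""
    # octagon node 0 at +7.5 along x; facing node 4 of the partner at -7.5:
    # center separation 17 gives a 2 um node gap
    return make_state([(0.0, 0.0), (17.0, 0.0)], pops=[0, 1])


def linked_pair_batch(n_pairs, pops=(0, 1), pair_gap=17.0, spacing=60.0):
    """Isolated touching cell pairs, one link each, for calibration tests.

    Pair members sit 17 um apart (2 um node gap, the contact distance);
    distinct pairs are 60 um apart so they never interact."""
    arena = Arena(max(1000.0, spacing * n_pairs * 2.2))
    base = (np.arange(n_pairs) - n_pairs / 2) * spacing
    xs = np.empty(2 * n_pairs)
    xs[0::2] = base
    xs[1::2] = base + pair_gap
    centers = np.column_stack([xs, np.zeros_like(xs)])
    pop = np.tile(pops, n_pairs)
    state = make_state(centers, pops=pop, arena=arena)
    for k in range(n_pairs):
        state.add_link(2 * k, 0, 2 * k + 1, 4)
    return state
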