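"""Stochastic update step: migration, links, repulsion, cohesion."""

import numpy as np
import pytest
from scipy import stats

from cilsim.behaviour import build_preset
from cilsim.dynamics import (
    Simulation,
    break_links,
    cohesion_pull,
    form_links,
    trigger_repulsion,
)
from cilsim.geometry import Arena, N_NODES
from conftest import linked_pair_batch, make_state


class TestFreeMigration:
    def test_one_minute_net_displacement_bounded_by_speed(self, control_preset, rng):
        state = make_state([(0.0, 0.0)], arena=Arena(500.0), leaders=[3])
        sim = Simulation(state, control_preset, rng=rng)
        c0 = state.centroids[0].copy()
        sim.run(120)  # one simulated minute
        net = np.linalg.norm(state.centroids[0] - c0)
        assert net <= 0.75 + 1e-6
        if sim.counts.dir_change == 0:
            assert net == pytest.approx(0.75, rel=1e-6)

    def test_mean_path_speed_matches_configuration(self, control_preset):
        """Free-cell path speed equals 0.75 um/min within 2% over 1e4 steps.

        Sampling every 120 steps (the decision tick) makes each sampled
        chord a straight segment, so the summed chords measure the true
        path length."""
        state = make_state([(0.0, 0.0)], arena=Arena(100000.0), leaders=[1])
        sim = Simulation(state, control_preset, rng=np.random.default_rng(7))
        path = [state.centroids[0].copy()]
        for _ in range(100):
            sim.run(120)
            path.append(state.centroids[0].copy())
        path = np.array(path)
        per_min = np.linalg.norm(np.diff(path, axis=0), axis=1).sum() / state.time_min
        assert per_min == pytest.approx(0.75, rel=0.02)

    def test_time_step_mapping(self, control_preset, rng):
        """50 000 steps of 0.5 s correspond to ~7 hours of simulated time."""
        state = make_state([(0.0, 0.0)])
        state.step_count = 50_000
        assert state.time_min / 60 == pytest.approx(6.94, abs=0.01)


class TestFormLinks:
    def test_distant_cells_do_not_link(self, rng):
        state = make_state([(0, 0), (100, 0)], pops=[0, 1])
        form_links(state, 2.0, rng)
        assert state.n_links() == 0

    def test_touching_cells_link_once(self, two_cell_state, rng):
        form_links(two_cell_state, 2.0, rng)
        assert two_cell_state.n_links() == 1
        lp = two_cell_state.linked_pairs()
        assert lp[0].tolist() == [0, 0, 1, 4]

    def test_multi_cell_links_match_enumeration_oracle(self, rng):
        """Links in a touching cluster equal a brute-force enumeration:
        all cross-cell node pairs within the contact distance, assigned
        nearest-first, one link per node."""
        h = 16.8 * np.sqrt(3) / 2
        state = make_state(
            [(0, 0), (16.8, 0), (8.4, h), (33.6, 0)], pops=[0, 1, 0, 1]
        )
        # rotate cell 2 so nodes face its inclined interfaces
        c = state.pos[2].mean(axis=0)
        ang = np.deg2rad(15)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        state.pos[2] = (state.pos[2] - c) @ R.T + c

        # independent oracle: greedy nearest-first matching
        flat = state.pos.reshape(-1, 2)
        cand = []
        for a in range(len(flat)):
            for b in range(a + 1, len(flat)):
                if a // 8 != b // 8:
                    d = np.linalg.norm(flat[a] - flat[b])
                    if d <= 2.0 * (1 + 1e-9):
                        cand.append((d, a, b))
        used, expected = set(), set()
        for d, a, b in sorted(cand):
            if a not in used and b not in used:
                used |= {a, b}
                expected.add((a, b))

        form_links(state, 2.0, rng)
        lp = state.linked_pairs()
        got = {
            (int(r[0]) * 8 + int(r[1]), int(r[2]) * 8 + int(r[3])) for r in lp
        }
        got = {tuple(sorted(p)) for p in got}
        assert got == expected
        assert len(expected) >= 2  # several interfaces actually touch

    def test_node_holds_at_most_one_link(self, rng):
        # three collinear cells: the middle cell's facing nodes each link once
        state = make_state([(-17, 0), (0, 0), (17, 0)], pops=[0, 1, 0])
        form_links(state, 2.0, rng)
        assert np.all(np.bincount(np.flatnonzero(state.link_cell >= 0)) <= 1)


class TestBreakLinks:
    def test_zero_hazard_never_breaks(self, control_preset, rng):
        state = linked_pair_batch(50)
        p_step = np.zeros((2, 2))
        for _ in range(500):
            _, broken = break_links(state, p_step, rng)
            assert broken.shape[0] == 0
        assert state.n_links() == 50

    def test_unknown_population_rejected(self, rng):
        state = linked_pair_batch(2)
        matrix = build_preset("kiEphB2_ephrinB1").matrix  # lacks "EphB2"
        with pytest.raises(KeyError, match="EphB2"):
            break_links(state, matrix, rng)

    @pytest.mark.parametrize("pops, expected", [((0, 1), 24.96), ((0, 0), 72.0)])
    def test_mean_lifetime_matches_hazard(self, control_preset, pops, expected):
        """Monte-Carlo lifetimes recover 1/eta_adh for the pair class."""
        rng = np.random.default_rng(99)
        state = linked_pair_batch(1500, pops=pops)
        lifetimes = np.zeros(1500)
        alive = state.n_links()
        while alive:
            _, broken = break_links(state, control_preset.matrix, rng)
            state.step_count += 1
            for ca, *_ in broken:
                lifetimes[int(ca) // 2] = state.time_min
            alive -= broken.shape[0]
        assert lifetimes.mean() == pytest.approx(expected, rel=0.05)

    def test_lifetimes_exponential(self, control_preset):
        """Link lifetimes follow the memoryless (exponential) law."""
        rng = np.random.default_rng(5)
        state = linked_pair_batch(1000, pops=(0, 1))
        lifetimes = np.zeros(1000)
        alive = state.n_links()
        while alive:
            _, broken = break_links(state, control_preset.matrix, rng)
            state.step_count += 1
            for ca, *_ in broken:
                lifetimes[int(ca) // 2] = state.time_min
            alive -= broken.shape[0]
        res = stats.kstest(lifetimes, "expon", args=(0, lifetimes.mean()))
        assert res.pvalue > 0.01


class TestTriggerRepulsion:
    def test_certain_repulsion_picks_opposite_node(self, two_cell_state, rng):
        repelled = trigger_repulsion(two_cell_state, 0, 0, 1.0, True, rng)
        assert repelled and two_cell_state.leader[0] == 4
        repelled = trigger_repulsion(two_cell_state, 1, 6, 1.0, True, rng)
        assert repelled and two_cell_state.leader[1] == 2

    def test_zero_repulsion_leaves_leader(self, two_cell_state, rng):
        before = int(two_cell_state.leader[0])
        assert not trigger_repulsion(two_cell_state, 0, 2, 0.0, True, rng)
        assert two_cell_state.leader[0] == before

    def test_undirected_choice_is_uniform(self, two_cell_state):
        """Random migration after contact: post-break leaders uniform."""
        rng = np.random.default_rng(3)
        counts = np.zeros(N_NODES, int)
        for _ in range(1600):
            trigger_repulsion(two_cell_state, 0, 0, 0.84, False, rng)
            counts[two_cell_state.leader[0]] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_invalid_node_index_rejected(self, two_cell_state, rng):
        with pytest.raises(ValueError):
            trigger_repulsion(two_cell_state, 0, 8, 1.0, True, rng)


class TestCohesionPull:
    def test_zero_weight_is_identity(self, two_cell_state):
        two_cell_state.add_link(0, 0, 1, 4)
        before = two_cell_state.leader.copy()
        cohesion_pull(two_cell_state, [0], 0.0)
        assert np.array_equal(two_cell_state.leader, before)

    def test_full_weight_aligns_neighbour(self, two_cell_state):
        two_cell_state.add_link(0, 0, 1, 4)
        two_cell_state.leader[0] = 2  # repelled cell heads +y
        two_cell_state.leader[1] = 0  # neighbour heads +x
        cohesion_pull(two_cell_state, [0], 1.0)
        # neighbour's new leader is the node best aligned with +y
        assert two_cell_state.leader[1] == 2

    def test_single_step_locality(self, rng):
        """A pull reaches only direct link neighbours in one call."""
        state = make_state([(0, 0), (17, 0), (34, 0)], pops=[0, 0, 0])
        state.add_link(0, 0, 1, 4)
        state.add_link(1, 0, 2, 4)
        state.leader[:] = [2, 0, 0]
        far_before = int(state.leader[2])
        cohesion_pull(state, [0], 1.0)
        assert state.leader[1] == 2  # direct neighbour rotated
        assert state.leader[2] == far_before  # second-order untouched


class TestStepIntegration:
    def test_repulsion_fraction_matches_configured_probability(self, control_preset):
        """Across many broken heterotypic links, the fraction of sides
        answering with a collapse approximates each side's p(repulsion)."""
        rng = np.random.default_rng(11)
        state = linked_pair_batch(800, pops=(0, 1))
        sim = Simulation(state, control_preset, rng=rng, record_events=True)
        sim.run(1200)
        ev = sim.events_dataframe()
        breaks = (ev.event == "link_break").sum()
        reps = ev[ev.event == "repulsion"]
        assert breaks >= 200
        p0 = (state.pop[reps.cell_a.to_numpy()] == 0).sum() / breaks
        p1 = (state.pop[reps.cell_a.to_numpy()] == 1).sum() / breaks
        # binomial 99% envelopes around 0.84 and 0.92
        for phat, p in ((p0, 0.84), (p1, 0.92)):
            se = np.sqrt(p * (1 - p) / breaks)
            assert abs(phat - p) < 3.5 * se + 0.01

    def test_bit_reproducible_with_equal_seed(self, control_preset):
        results = []
        for _ in range(2):
            state = make_state(
                [(0, 0), (17, 0), (0, 17), (17, 17)], pops=[0, 1, 0, 1]
            )
            sim = Simulation(state, control_preset, rng=np.random.default_rng(21))
            sim.run(500)
            results.append((state.pos.copy(), state.leader.copy(), sim.counts.as_dict()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])
        assert results[0][2] == results[1][2]

    def test_event_log_schema(self, control_preset, rng):
        state = make_state([(0, 0), (17, 0)], pops=[0, 1])
        sim = Simulation(state, control_preset, rng=rng, record_events=True)
        sim.run(300)
        ev = sim.events_dataframe()
        assert list(ev.columns) == [
            "step", "time_min", "event", "cell_a", "node_a", "cell_b", "node_b",
        ]
        assert set(ev.event) <= {"link_form", "link_break", "link_detach", "repulsion"}
        assert (ev.event == "link_form").sum() >= 1
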