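"""Quantitation algorithms: border length, particle analysis, contact
events, migrate-away rule, displacement profile, segregation index."""

import math

import numpy as np
import pandas as pd
import pytest

from cilsim.fixtures import (
    boundary_masks_fixture,
    labelled_points_fixture,
    scripted_tracks_fixture,
)
from cilsim.metrics import (
    ContactEvent,
    border_length,
    cluster_particle_analysis,
    displacement_after_repulsion,
    extract_contact_events,
    migrates_away,
    relative_border_length,
    segregation_index,
)


class TestBorderLength:
    def test_straight_split_recovers_interface_width(self):
        pts, truth = labelled_points_fixture("straight", width=100.0)
        trace = border_length(pts)
        assert trace.length == pytest.approx(100.0, rel=0.05)
        assert np.allclose(trace.midpoints[:, 0], 0.0, atol=1e-9)

    def test_checkerboard_longer_than_straight(self):
        straight, _ = labelled_points_fixture("straight", width=100.0, spacing_y=10.0)
        checker, _ = labelled_points_fixture("checkerboard", width=100.0, spacing_y=10.0)
        assert border_length(checker).length > border_length(straight).length

    def test_random_mixture_longer_than_straight(self):
        """Randomly mixed labels give a longer border than the straight
        split of the same points in at least 95% of seeded draws."""
        straight, _ = labelled_points_fixture("straight", width=100.0, spacing_y=10.0)
        ref = border_length(straight).length
        wins = 0
        n_draws = 100
        for seed in range(n_draws):
            mixed, _ = labelled_points_fixture(
                "random", width=100.0, spacing_y=10.0, seed=seed
            )
            if border_length(mixed).length > ref:
                wins += 1
        assert wins >= 0.95 * n_draws

    def test_rigid_motion_invariance(self):
        # jittered points: a regular grid has distance ties whose
        # resolution is not rotation-stable
        rng = np.random.default_rng(3)
        xy = rng.uniform(-50, 50, size=(120, 2))
        labels = np.where(rng.random(120) < 0.5, "A", "B")
        pts = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "population": labels})
        base = border_length(pts).length
        ang = 0.83
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        xy = pts[["x_um", "y_um"]].to_numpy() @ R.T + np.array([13.0, -41.0])
        moved = pts.assign(x_um=xy[:, 0], y_um=xy[:, 1])
        assert border_length(moved).length == pytest.approx(base, rel=1e-9)

    def test_single_population_rejected(self):
        pts, _ = labelled_points_fixture("straight")
        only_a = pts[pts.population == "A"]
        with pytest.raises(ValueError):
            border_length(only_a)

    def test_relative_length_normalization(self):
        pts, _ = labelled_points_fixture("straight", width=100.0)
        trace = border_length(pts)
        assert relative_border_length(trace, 100.0) == pytest.approx(1.0, rel=0.05)
        with pytest.raises(ValueError):
            relative_border_length(trace, 0.0)


class TestClusterParticleAnalysis:
    def test_disc_area_to_cell_count(self):
        # one ~1000 um^2 blob -> one cluster of 5 cells at 200 um^2 each
        mask, _ = boundary_masks_fixture(blob_areas=(1000.0,))
        rep = cluster_particle_analysis(mask)
        assert rep.n_clusters == 1
        assert rep.cell_counts.tolist() == [5]

    def test_blob_below_minimum_size_dropped(self):
        mask, _ = boundary_masks_fixture(blob_areas=(400.0,))
        rep = cluster_particle_analysis(mask)
        assert rep.n_clusters == 0

    def test_separated_blobs_counted_separately(self):
        mask, truth = boundary_masks_fixture(blob_areas=(600.0, 600.0))
        rep = cluster_particle_analysis(mask)
        assert rep.n_clusters == 2
        assert rep.cell_counts.tolist() == truth["cell_counts"]

    def test_empty_mask_empty_report(self):
        rep = cluster_particle_analysis(np.zeros((50, 50), dtype=bool))
        assert rep.n_clusters == 0 and rep.total_cells == 0

    def test_pixel_scale_applied(self):
        # 2 um/px: a 15x15 px blob is 900 um^2 -> 4-5 cells
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:25, 10:25] = True
        rep = cluster_particle_analysis(mask, um_per_px=2.0)
        assert rep.areas_um2[0] == pytest.approx(900.0)

    def test_total_cells_bounded_by_population(self):
        """Rasterized simulated cells yield a total count no larger than
        the population size."""
        from cilsim.behaviour import build_preset
        from cilsim.experiments import desk_scale_config, init_segregation
        from cilsim.metrics import rasterize_population

        cfg = desk_scale_config()
        preset = build_preset(cfg.preset)
        state = init_segregation(cfg, np.random.default_rng(0), preset)
        mask = rasterize_population(state, "EphB2")
        rep = cluster_particle_analysis(mask)
        n_pop = int((state.pop == 0).sum())
        assert 0 < rep.total_cells <= n_pop


class TestContactEvents:
    def test_scripted_durations_recovered_exactly(self):
        tracks, ann, truth = scripted_tracks_fixture(n_contacts=4, contact_frames=4)
        events = extract_contact_events(tracks, collapse_events=ann)
        mover = [e for e in events if e.cell_id == 0]
        assert len(mover) == truth["n_contacts"]
        assert all(e.duration == truth["duration_min"] for e in mover)
        assert all(e.collapse for e in mover)

    def test_five_frame_contact_is_fifteen_minutes(self):
        tracks, _, _ = scripted_tracks_fixture(n_contacts=1, contact_frames=5)
        events = extract_contact_events(tracks)
        assert events[0].duration == 15.0

    def test_theta_measures_retreat_angle(self):
        tracks, ann, truth = scripted_tracks_fixture(n_contacts=2)
        events = [e for e in extract_contact_events(tracks, collapse_events=ann)
                  if e.cell_id == 0 and e.theta is not None]
        assert events and all(e.theta == pytest.approx(math.pi) for e in events)

    def test_stationary_cell_theta_undefined(self):
        frames = np.arange(8)
        rows = []
        for f in frames:
            rows.append((f, 3.0 * f, 0, "A", 10.0 if f in (3, 4) else 40.0, 0.0))
            rows.append((f, 3.0 * f, 1, "B", 0.0, 0.0))
        tracks = pd.DataFrame(
            rows, columns=["frame", "time_min", "cell_id", "population", "x_um", "y_um"]
        )
        events = extract_contact_events(tracks, contact_radius=17.0)
        stationary = [e for e in events if e.cell_id == 1]
        assert stationary and all(e.theta is None for e in stationary)
        with pytest.raises(ValueError):
            migrates_away(stationary[0])

    def test_duration_invariant_to_frame_renumbering(self):
        tracks, ann, _ = scripted_tracks_fixture(n_contacts=2)
        shifted = tracks.assign(frame=tracks.frame + 1000)
        a = extract_contact_events(tracks, collapse_events=ann)
        b = extract_contact_events(shifted, collapse_events=ann)
        assert [e.duration for e in a] == [e.duration for e in b]

    def test_irregular_sampling_rejected(self):
        tracks, _, _ = scripted_tracks_fixture(n_contacts=1)
        bad = tracks.copy()
        bad.loc[bad.index[-2:], "time_min"] += 1.7
        with pytest.raises(ValueError, match="regular"):
            extract_contact_events(bad)

    def test_censoring_flags_recollision_within_window(self):
        # next contact starts (gap+4) frames after t_end; gap=2 gives
        # 18 min < 20 min window -> first event censored
        tracks, ann, _ = scripted_tracks_fixture(n_contacts=2, gap_frames=2)
        events = [e for e in extract_contact_events(tracks, collapse_events=ann)
                  if e.cell_id == 0]
        assert events[0].censored
        # 12-frame gap (36 min) > window -> uncensored
        tracks2, ann2, _ = scripted_tracks_fixture(n_contacts=2, gap_frames=12)
        events2 = [e for e in extract_contact_events(tracks2, collapse_events=ann2)
                   if e.cell_id == 0]
        assert not events2[0].censored


class TestMigratesAway:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.6 * math.pi, True),
            (0.0, False),
            (0.9 * math.pi, False),  # literal rule excludes near-pi
            (math.pi / 2, True),
            (3 * math.pi / 4, True),
        ],
    )
    def test_literal_band(self, theta, expected):
        e = ContactEvent(0, 1, "heterotypic", 0, 9, 9, None, None, theta, True, False)
        assert migrates_away(e) is expected

    def test_configurable_upper_bound(self):
        e = ContactEvent(0, 1, "heterotypic", 0, 9, 9, None, None, 0.9 * math.pi, True, False)
        assert migrates_away(e, upper=math.pi)


class TestDisplacementProfile:
    def test_constant_velocity_flat_profile(self):
        tracks, ann, truth = scripted_tracks_fixture(
            n_contacts=3, burst_factor=1.0, gap_frames=12
        )
        events = [e for e in extract_contact_events(tracks, collapse_events=ann)
                  if e.cell_id == 0]
        prof = displacement_after_repulsion(events, tracks)
        expected = truth["base_speed"] * 3.0
        assert np.nanmax(np.abs(prof.to_numpy() - expected)) < 1e-9

    def test_speed_burst_elevates_first_bins_only(self):
        tracks, ann, truth = scripted_tracks_fixture(
            n_contacts=3, burst_factor=2.0, burst_min=6.0, gap_frames=12
        )
        events = [e for e in extract_contact_events(tracks, collapse_events=ann)
                  if e.cell_id == 0]
        prof = displacement_after_repulsion(events, tracks).to_numpy()
        base = truth["base_speed"] * 3.0
        assert prof[0] == pytest.approx(2 * base) and prof[1] == pytest.approx(2 * base)
        assert np.allclose(prof[2:], base)

    def test_censored_only_gives_empty_profile(self):
        tracks, ann, _ = scripted_tracks_fixture(n_contacts=3, gap_frames=2)
        events = [e for e in extract_contact_events(tracks, collapse_events=ann)
                  if e.cell_id == 0][:-1]  # all censored
        assert all(e.censored for e in events)
        with pytest.warns(UserWarning):
            prof = displacement_after_repulsion(events, tracks)
        assert prof.empty


class TestSegregationIndex:
    def test_split_halves_near_one(self):
        pts, _ = labelled_points_fixture("straight", width=100.0, spacing_y=10.0)
        assert segregation_index(pts) > 0.85

    def test_random_labels_near_half(self):
        vals = [
            segregation_index(labelled_points_fixture("random", width=200.0,
                                                      spacing_x=10.0, spacing_y=10.0,
                                                      seed=s)[0])
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_checkerboard_below_half(self):
        pts, _ = labelled_points_fixture("checkerboard", width=100.0,
                                         spacing_x=10.0, spacing_y=10.0)
        assert segregation_index(pts) < 0.5

    def test_too_few_cells_rejected(self):
        pts = pd.DataFrame(
            {"x_um": [0, 1, 2], "y_um": [0, 1, 2], "population": ["A", "B", "A"]}
        )
        with pytest.raises(ValueError):
            segregation_index(pts, k=6)
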