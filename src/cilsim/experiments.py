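"""In-silico segregation and boundary assays.

Two assay geometries are provided:

* *segregation* — the two populations (400 cells each at full scale)
  start intermingled at random positions in a circular arena of diameter
  500 um, and sort into clusters;
* *boundary* — each population occupies one half of the arena with a
  fuzzy initial interface (labels swapped within a mixing band around the
  midline with a probability that decays with distance), and the border
  length is tracked as it sharpens, or fails to.

``run_experiment`` runs a preset over independent seeded replicates,
records metric time courses, and aggregates them as mean +/- s.e.;
``compare_conditions`` performs an exact two-sided Mann-Whitney U test on
the final border lengths of two conditions.

A *desk-scale* configuration (200 cells, 250 um arena, 10 000 steps)
keeps replicate batteries tractable on one CPU while preserving the
packing density and time step of the full-scale setup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import Preset, build_preset
from .dynamics import Simulation
from .geometry import Arena, SimulationState, enforce_constraints, hex_pack, octagon_nodes, state_to_table
from .metrics import (
    border_length,
    cluster_particle_analysis,
    labelled_points_from_state,
    rasterize_population,
    relative_border_length,
    segregation_index,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "init_segregation",
    "init_boundary",
    "run_experiment",
    "compare_conditions",
    "desk_scale_config",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one simulated assay condition."""

    preset: str = "control_EphB2_ephrinB1"
    assay: str = "segregation"  # or "boundary"
    n_cells_per_population: int = 400
    arena_diameter: float = 500.0
    cell_radius: float = 7.5
    n_steps: int = 50_000
    step_duration_s: float = 0.5
    record_every: int = 500
    n_replicates: int = 10
    base_seed: int = 0
    seeds: tuple[int, ...] | None = None
    mixing_band: float = 50.0  # um, boundary assay initial fuzziness

    def __post_init__(self) -> None:
        if self.assay not in ("segregation", "boundary"):
            raise ValueError("assay must be 'segregation' or 'boundary'")
        if self.seeds is not None:
            if len(self.seeds) != self.n_replicates:
                raise ValueError("len(seeds) must equal n_replicates")
            if len(set(self.seeds)) != len(self.seeds):
                raise ValueError("replicate seeds must be unique")

    def replicate_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        ss = np.random.SeedSequence(self.base_seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(self.n_replicates)]


def desk_scale_config(**overrides) -> ExperimentConfig:
    """Scaled-down configuration: 100 cells per population in a 250 um
    arena for 10 000 steps (same packing density and time step as the
    full-scale assay)."""
    base = dict(
        n_cells_per_population=100,
        arena_diameter=250.0,
        n_steps=10_000,
        record_every=500,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def _packed_state(
    config: ExperimentConfig, preset: Preset, rng: np.random.Generator
) -> tuple[SimulationState, np.ndarray]:
    arena = Arena(config.arena_diameter)
    n = 2 * config.n_cells_per_population
    centers = hex_pack(n, arena, config.cell_radius, rng)
    pos = np.stack([octagon_nodes(c, config.cell_radius) for c in centers])
    state = SimulationState(
        arena,
        pos,
        np.zeros(n, dtype=np.int64),
        preset.populations,
        rng.integers(8, size=n),
        radius=config.cell_radius,
        step_duration_s=config.step_duration_s,
    )
    return state, centers


def init_segregation(
    config: ExperimentConfig,
    rng: np.random.Generator,
    preset: Preset | None = None,
) -> SimulationState:
    """Intermingled start: random non-overlapping packing, labels
    assigned by random permutation, half to each population."""
    preset = build_preset(config.preset) if preset is None else preset
    state, _ = _packed_state(config, preset, rng)
    n = state.n_cells
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[: n // 2]] = 1
    state.pop = labels
    enforce_constraints(state, max_sweeps=30)
    return state


def init_boundary(
    config: ExperimentConfig,
    rng: np.random.Generator,
    preset: Preset | None = None,
) -> SimulationState:
    """Half-field start with a fuzzy interface.

    Labels are assigned by the side of the x = 0 midline; cells within
    the mixing band are then label-swapped in left/right pairs with a
    probability that decays exponentially with distance from the midline,
    producing a ragged initial border while conserving the population
    counts exactly.
    """
    preset = build_preset(config.preset) if preset is None else preset
    state, centers = _packed_state(config, preset, rng)
    x = centers[:, 0]
    labels = (x > 0).astype(np.int64)
    # midline ties and imbalance from packing asymmetry: rebalance by
    # flipping the cells nearest the midline
    n_half = state.n_cells // 2
    imbalance = int(labels.sum()) - n_half
    if imbalance != 0:
        side = 1 if imbalance > 0 else 0
        cand = np.flatnonzero(labels == side)
        cand = cand[np.argsort(np.abs(x[cand]))]
        labels[cand[: abs(imbalance)]] = 1 - side
    if config.mixing_band > 0:
        half_band = config.mixing_band / 2.0
        decay = config.mixing_band / 4.0
        p_swap = 0.5 * np.exp(-np.abs(x) / decay)
        in_band = np.abs(x) <= half_band
        pick = in_band & (rng.random(state.n_cells) < p_swap)
        left = np.flatnonzero(pick & (labels == 0))
        right = np.flatnonzero(pick & (labels == 1))
        k = min(len(left), len(right))
        if k:
            swap_l = rng.permutation(left)[:k]
            swap_r = rng.permutation(right)[:k]
            labels[swap_l], labels[swap_r] = 1, 0
    state.pop = labels
    enforce_constraints(state, max_sweeps=30)
    return state


@dataclass
class ReplicateResult:
    seed: int
    timecourse: pd.DataFrame
    final_state_table: pd.DataFrame
    cluster_report: pd.DataFrame
    event_counts: dict[str, int]


@dataclass
class ExperimentResult:
    """Per-replicate metric time courses plus their aggregate."""

    config: ExperimentConfig
    replicates: list[ReplicateResult]

    @property
    def preset_name(self) -> str:
        return self.config.preset

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard error of each metric across replicates."""
        frames = [r.timecourse for r in self.replicates]
        cat = pd.concat(frames)
        g = cat.groupby("step")
        cols = [c for c in cat.columns if c not in ("step", "time_min")]
        out = g[["time_min"]].first()
        for c in cols:
            out[f"{c}_mean"] = g[c].mean()
            out[f"{c}_se"] = g[c].sem()
        return out.reset_index()

    def final_values(self, metric: str = "relative_border_length") -> np.ndarray:
        return np.array(
            [r.timecourse[metric].iloc[-1] for r in self.replicates], float
        )

    def initial_values(self, metric: str = "relative_border_length") -> np.ndarray:
        return np.array(
            [r.timecourse[metric].iloc[0] for r in self.replicates], float
        )

    def save(self, outdir) -> None:
        """Write per-replicate time courses, final snapshots, cluster
        reports, the aggregate table and run metadata as CSV/JSON."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, r in enumerate(self.replicates):
            r.timecourse.to_csv(out / f"replicate_{i:02d}_timecourse.csv", index=False)
            r.final_state_table.to_csv(
                out / f"replicate_{i:02d}_final_state.csv", index=False,
                float_format="%.17g",
            )
            r.cluster_report.to_csv(
                out / f"replicate_{i:02d}_clusters.csv", index=False
            )
        self.aggregate().to_csv(out / "aggregate_timecourse.csv", index=False)
        meta = {
            "preset": self.config.preset,
            "assay": self.config.assay,
            "n_cells_per_population": self.config.n_cells_per_population,
            "arena_diameter": self.config.arena_diameter,
            "n_steps": self.config.n_steps,
            "step_duration_s": self.config.step_duration_s,
            "record_every": self.config.record_every,
            "seeds": [r.seed for r in self.replicates],
            "event_counts": [r.event_counts for r in self.replicates],
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))


def _record_metrics(state: SimulationState, reference_width: float) -> dict:
    pts = labelled_points_from_state(state)
    trace = border_length(pts)
    return {
        "step": state.step_count,
        "time_min": state.time_min,
        "border_length": trace.length,
        "relative_border_length": trace.length / reference_width,
        "segregation_index": segregation_index(pts),
    }


def run_replicate(
    config: ExperimentConfig, preset: Preset, seed: int
) -> ReplicateResult:
    rng = np.random.default_rng(seed)
    init = init_boundary if config.assay == "boundary" else init_segregation
    state = init(config, rng, preset)
    sim = Simulation(state, preset, rng=rng)
    reference_width = config.arena_diameter
    records = [_record_metrics(state, reference_width)]
    steps_done = 0
    while steps_done < config.n_steps:
        chunk = min(config.record_every, config.n_steps - steps_done)
        sim.run(chunk)
        steps_done += chunk
        records.append(_record_metrics(state, reference_width))
    mask = rasterize_population(state, preset.populations[0], um_per_px=1.0)
    report = cluster_particle_analysis(mask, um_per_px=1.0)
    return ReplicateResult(
        seed=seed,
        timecourse=pd.DataFrame(records),
        final_state_table=state_to_table(state),
        cluster_report=report.to_frame(),
        event_counts=sim.counts.as_dict(),
    )


def run_experiment(
    config: ExperimentConfig,
    output_dir=None,
    progress: bool = False,
) -> ExperimentResult:
    """Run every replicate of a condition with independent seeds.

    Replicates are fully independent (fresh state and generator per
    seed); results are returned in memory and optionally written to
    ``output_dir``.
    """
    preset = build_preset(config.preset)
    seeds = config.replicate_seeds()
    replicates = []
    iterator = seeds
    if progress:
        from tqdm import tqdm

        iterator = tqdm(seeds, desc=config.preset)
    for seed in iterator:
        try:
            replicates.append(run_replicate(config, preset, seed))
        except Exception as err:  # pragma: no cover - context for debugging
            raise RuntimeError(
                f"replicate with seed {seed} of preset {config.preset!r} failed"
            ) from err
    result = ExperimentResult(config=config, replicates=replicates)
    if output_dir is not None:
        result.save(output_dir)
    return result


def compare_conditions(
    result_a: ExperimentResult,
    result_b: ExperimentResult,
    metric: str = "relative_border_length",
) -> dict:
    """Exact two-sided Mann-Whitney U test on final metric values.

    Returns a dict with the U statistic, the p-value and per-condition
    medians. Requires at least 3 replicates per condition and the same
    assay/metric on both sides.
    """
    if result_a.config.assay != result_b.config.assay:
        raise ValueError("conditions use different assays; metrics not comparable")
    a = result_a.final_values(metric)
    b = result_b.final_values(metric)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 replicates per condition")
    method = "exact" if (len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "metric": metric,
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": len(a),
        "n_b": len(b),
        "condition_a": result_a.preset_name,
        "condition_b": result_b.preset_name,
    }
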