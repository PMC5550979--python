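"""Convert measured cell behaviour into simulation probabilities.

Tracked contact durations and per-contact collapse frequencies determine
the adhesion-link break probabilities p(break) and the repulsion
frequencies per minute; their heterotypic/homotypic ratio summarizes how
much more strongly a cell is repelled by the other population than by its
own. Ratios well above 1 predict segregation and border sharpening.
"""

from cilsim import build_preset, p_break_from_duration, preset_names

for name in ("control_EphB2_ephrinB1", "ncad_kd"):
    preset = build_preset(name)
    print(f"\n{name}")
    for (pop, other), entry in sorted(preset.matrix.entries.items()):
        kind = "homotypic " if pop == other else "heterotypic"
        print(
            f"  {kind} {pop:9s}: duration {entry.duration_min:5.1f} min -> "
            f"p(break) {p_break_from_duration(entry.duration_min):.3f}/min, "
            f"p(repulsion) {entry.p_repulsion:.2f}"
        )
    for pop, ratio in preset.repulsion_ratios().items():
        print(f"  repulsion ratio {pop}: {ratio:.2f}")

print("\navailable presets:", ", ".join(preset_names()))
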