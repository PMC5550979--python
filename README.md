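# cilsim

An off-lattice agent-based simulator of cell segregation and tissue
border sharpening driven by **contact inhibition of locomotion (CIL)**,
with the quantitation toolkit used to analyse it. It is written for
researchers in computational developmental biology who want to test
whether measured cell-contact behaviour — how long two cells stay in
contact, and how often a contact ends in a collapse/repulsion response —
is sufficient to explain the sorting of two cell populations (e.g.
EphB2- and ephrinB1-expressing HEK293 cells) and the sharpening of the
interface between them.

## Model in brief

Each cell is a deformable ring of eight membrane nodes plus a centroid.
A *leader* node sets the migration direction; cells move at
v = 0.75 um/min and re-choose their leader with probability 0.2 per
minute. Nodes of different cells within 2 um form adhesion links. A link
breaks with constant hazard

    eta_adh = 1 / (mean contact duration),      p(break) = 1 - exp(-eta_adh)

and on breaking, each cell mounts a repulsion response with probability
p(repulsion) (the measured collapse frequency per contact): the node
opposite the contact becomes the leader, so the cell migrates away.
A repelled cell pulls linked neighbours' directions toward its own
(cohesive migration). The summary statistic for a condition is the
repulsion ratio

    repulsion frequency per minute = collapse frequency / contact duration
    repulsion ratio = heterotypic frequency / homotypic frequency

Measured behaviour for EphB2, kinase-dead EphB2 and ephrinB1 cells, with
and without N-cadherin knockdown, ships as presets along with the
in-silico manipulations of those values. See `docs/methods.md` for the
full model description, numerical choices and limitations.

## Worked example

```bash
python examples/repulsion_ratios.py
```

```
control_EphB2_ephrinB1
  homotypic  EphB2    : duration  72.0 min -> p(break) 0.014/min, p(repulsion) 0.47
  heterotypic EphB2    : duration  24.0 min -> p(break) 0.041/min, p(repulsion) 0.84
  heterotypic ephrinB1 : duration  26.0 min -> p(break) 0.038/min, p(repulsion) 0.92
  homotypic  ephrinB1 : duration  57.0 min -> p(break) 0.017/min, p(repulsion) 0.62
  repulsion ratio EphB2: 5.36
  repulsion ratio ephrinB1: 3.25

ncad_kd
  ...
  repulsion ratio EphB2: 1.79
  repulsion ratio ephrinB1: 1.47
```

Control EphB2 cells are repelled 5.36x more often (per minute of
contact) by ephrinB1 cells than by their own kind; N-cadherin knockdown
collapses that differential to 1.79, which is why segregation and border
sharpening degrade under knockdown.

Other example scripts, one per capability:

* `examples/single_cell_migration.py` — persistent random walk of a free
  cell (path speed prints 0.750 um/min).
* `examples/link_lifetimes.py` — Monte-Carlo link lifetimes recover the
  measured contact durations (prints ~25 and ~72-73 min).
* `examples/border_sharpening.py` — a small boundary assay with the
  relative border length and segregation index over time.
* `examples/track_metrics.py` — contact events, theta/migrates-away
  scoring and the post-repulsion displacement profile on scripted tracks.

A CLI covers the same ground from a shell:

```bash
cilsim presets list
cilsim presets show control_EphB2_ephrinB1
cilsim simulate --preset ncad_kd --assay boundary --scale desk --out runs/ncad
cilsim compare runs/control runs/ncad
cilsim analyze tracks.csv --out metrics/
cilsim reproduce --scale desk --out battery/
```

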