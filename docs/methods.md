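# Model and methods

`cilsim` simulates two co-cultured cell populations whose contacts are
governed by adhesion and by contact inhibition of locomotion (CIL), and
quantifies the resulting segregation and interface sharpening. The model
follows the off-lattice, stochastic agent design used to study
Eph/ephrin-mediated cell sorting: probabilities are constant in time and
all behaviour parameters are taken directly from tracked cell contacts.

## Cell representation and migration

A cell is a ring of eight membrane nodes plus its centroid (the node
mean). The resting geometry is a regular octagon of radius 7.5 um (cell
diameter 15 um); bonds between adjacent nodes relax toward the octagon
edge length (2 r sin(pi/8) ~ 5.74 um), and a weak radial spring restores
circularity, with node-centroid distance hard-capped at twice the radius.
The membrane is deformable: each node moves individually under the
constraints.

One node is the *leader* and the cell translates toward it at a constant
speed of 0.75 um/min. Direction changes are stochastic: once per decision
tick (1 simulated minute) each cell re-chooses its leader uniformly at
random with probability p(change of direction) = 0.2, giving a
persistence of a few minutes, as in tracked cells. One time step is
0.5 s, so 50 000 steps correspond to ~7 h.

## Adhesion, repulsion, cohesion

Free membrane nodes of distinct cells within the contact distance
(2 um, node to node) form an adhesion link; a node holds at most one
link. Each link breaks with a constant hazard eta_adh equal to the
inverse of the measured mean contact duration of its pair class,
converted to a per-step probability 1 - exp(-eta_adh dt) so the expected
link lifetime equals the measured duration regardless of the step size.
Because the two populations of a heterotypic pair report slightly
different mean durations (24 vs 26 min in the control), the per-link
hazard uses the mean of the two ordered rates; the resulting lifetime
(~25 min) is within 5% of both measurements.

When a link breaks, each of the two cells independently mounts a
repulsion (collapse) response with its own p(repulsion): the node
opposite the contact becomes the leader, so the cell migrates away — CIL.
The contact node is re-derived at break time as the node nearest the
partner's centroid, because cells slide around each other during long
contacts and the node that originally carried the link no longer marks
the contact. In adhesion-only mode (`directed = False`) the leader is
instead re-chosen uniformly at random after every break: contacts then
modulate only how often a cell re-randomizes its direction, which is the
"random migration after contact" control.

A repelled cell pulls on its linked neighbours: their migration
direction is rotated toward the repelled cell's new direction by the
pull weight (default 0.5; the magnitude is a free parameter), then snapped to
the best-aligned membrane node. Only direct link neighbours are affected
within a step.

## Mechanical closure

The model description leaves the contact mechanics open, and
the emergent behaviour depends on them. The package uses:

* **Exclusion** — node-vs-node: foreign nodes closer than the contact
  distance are pushed apart along the cell-centroid axis (half the
  violation per sweep). Membranes may therefore interpenetrate
  transiently and partially; in a strictly two-dimensional model this
  stands in for the squeezing and partial overlap available to real
  cells in three dimensions. With strict membrane-segment exclusion
  (available via `use_segment_exclusion`, with polygon-containment
  ejection and an area-maintenance term) the confluent monolayer is
  glassy: cells cannot exchange neighbours at 0.72 area fraction at
  this speed, and neither segregation nor sharpening can emerge on any
  timescale. The softer node-level rule restores tissue fluidity.
* **Adhesion tether** — linked nodes beyond the contact distance are
  pulled back together (0.3 of the excess per sweep), so a contact
  persists until its stochastic break: the measured contact duration is
  meaningful only if the link actually holds the cells together.
  Links sheared beyond three times the contact distance are removed as
  passive detachments (no repulsion response).
* **Relink refractory** — after a stochastic break the two cells cannot
  form a new link for 3 minutes, giving a repelled cell time to
  disengage before adhesion re-captures it.
* **Arena** — a hard circular wall (nodes are projected back); no
  periodic boundaries.
* Constraints are enforced by Gauss-Seidel position projection, at most
  10 sweeps per step, stopping when the largest correction falls below
  0.02 um. In a crowded arena the exclusion constraints are under global
  compression and act as a soft pressure rather than a hard guarantee.

All stochastic draws come from one seeded generator; equal seed and
configuration reproduce a run bit-for-bit.

## Behaviour presets

Contact durations and collapse frequencies measured for EphB2, kinase-
dead EphB2 (kiEphB2) and ephrinB1 cells — and for each after N-cadherin
knockdown — are shipped as presets, together with the in-silico
manipulations (shortened heterotypic contact, lengthened homotypic
contact, reduced homotypic or heterotypic collapse frequency). The
repulsion-ratio statistic summarizes each condition:

    repulsion frequency per minute = collapse frequency / contact duration
    repulsion ratio = heterotypic frequency / homotypic frequency

In `ncad_kd_hom45` the lengthened homotypic duration (45 min) is applied
to both populations' homotypic entries; the reported manipulation names
only the EphB2 value and an unstated ephrinB1 value would otherwise have
to be invented. Two table entries (homotypic ephrinB1 control, printed
0.018, and the heterotypic knockdown entry, printed 0.063) differ from
1 - exp(-1/duration) by about one unit in the last digit; the package
always uses the formula.

## Assays and metrics

*Segregation assay*: populations intermingled at random (400 + 400 cells
in a 500 um arena at full scale) — quantified by the k-nearest-neighbour
segregation index (fraction of k = 6 nearest neighbours sharing the
label; 0.5 for a random mixture) and by particle analysis of the final
rasterized population mask (8-connected components, minimum cluster
500 um^2, cell number = area / 200 um^2).

*Boundary assay*: each population fills one half of the arena; labels
within a 50 um band around the midline are swapped in left/right pairs
with probability decaying with distance (scale = band/4), producing a
fuzzy interface with exactly conserved counts. Border length is measured
by pairing each cell with its nearest heterotypic neighbour, keeping the
*mutual* pairs (cells that actually abut across the interface — a cell
deep in its own territory chooses a distant partner that does not choose
it back and contributes no segment), taking each segment's midpoint, and
chaining midpoints greedily from one end of the interface's principal
axis; the polyline length, normalized by the straight-interface width
(the arena diameter), is the relative border length. Restricting to
mutual pairs realizes "short segments between neighbouring cells": with
all nearest-heterotypic pairs included, bulk cells contribute long
segments whose midpoints lie far from the interface and the straight-
interface oracle fails by several fold.

*Track metrics*: contact events are episodes of inter-centroid distance
below 17 um (cell diameter + contact distance) in regularly sampled
tracks; per event the duration (in-contact frames x frame interval), the
angle theta between the contact axis at the start and the post-contact
direction (displacement over 3 frames after the end), a collapse flag
(from the simulation event log or a caller-supplied annotation), and a
censoring flag (another collision within 20 min) are computed. A cell
with theta in [pi/2, 3pi/4] is scored as migrating away (the literal
band; an upper bound of pi is available as an option since the stated
band excludes straight-backwards retreat). Displacement after repulsion
averages per-3-min displacement over a 20-min window for uncensored
collapse events.

## Scale used in the test suite

The full-scale assay (800 cells, 500 um, 50 000 steps, 10 replicates) is
available through the library and CLI. The test suite and the condition
battery run a reduced desk scale — 200 cells in a 250 um arena for
10 000 steps (~83 simulated minutes), same packing fraction, time step
and speed — so a full battery of conditions runs on one CPU in minutes.

## Known limitations

* At desk scale the simulated time window (~1.4 h versus ~7 h at full
  scale) is short relative to the contact-turnover times that drive
  sorting (24-72 min): segregation indices move only a few hundredths
  and border-length changes are within replicate noise, so ordering
  tests across conditions at this scale have limited power, and the
  sharpening contrasts seen at full scale are not expected to reach
  significance. The acceptance tests encode the full-scale expectations
  regardless and report the desk-scale reality.
* The border-length chain is sensitive to isolated stragglers (each adds
  a detour); this is genuine raggedness but makes the metric noisy for
  small populations.
* The model is strictly 2D: no piling up or extrusion; compaction of
  clusters seen in culture is absent.
* Contact durations at confluence are emergent (multiple concurrent
  links, re-linking after refractory) and only match the measured values
  for isolated pairs; the measured values enter as per-link hazards.
* The mechanics (stiffnesses, exclusion softness, refractory) are model
  closures chosen for tissue fluidity and physical plausibility; the
  original description leaves them open.
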