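# Methods

`sbgnpd-layout` computes automatic layouts for SBGN process description
(PD) maps.  A PD map is essentially a bipartite compound graph: entity
pool nodes (EPNs — macromolecules, simple chemicals, complexes, …) connect
only to process nodes, molecular complexes contain degree-0 members, and
cellular compartments nest arbitrarily.  The algorithm is a two-phase
compound spring embedder: a generic force-directed draft phase followed by
an SBGN-specific phase that enforces the notation's conventions — substrates
attach at an input port, products at the opposite output port, and
effectors sit perpendicular to the port axis.

## Model

### Compound graph and forces

A map is a compound graph C = (V, E, F): nodes, adjacency edges and an
inclusion forest.  Geometry uses screen coordinates (y grows downward),
rectangles stored as top-left corner plus extent.  Compound bounds are
recomputed bottom-up every iteration as the tight box around the children
plus a margin (default 10 units; process containers use 1 unit so they wrap
their unit tightly; an empty compound keeps a 20-unit minimum).

The force scheme follows the classic spring-embedder form:

* **Springs** on every adjacency edge: `F = k_s · (d − l)` along the center
  line, with spring constant `k_s = 0.45` and ideal edge length `l = 70`
  units.  *Rigid* port edges exert no spring force.
* **Repulsion** `F = k_r / d²` (`k_r = 4500`) between every pair of movable
  entities — leaves, plus packed or empty compounds treated as wholes.  A
  process and its own ports do not repel each other; ports do repel other
  nodes, which is what pushes substrates off the product side of a process
  and vice versa.  Overlapping rectangles receive a fixed-magnitude
  separating push (25 units of force) instead of the singular inverse
  square; exactly coincident centers separate along a deterministic
  direction.
* **Gravity**: constant-magnitude pull (0.8) toward the center of the owner
  graph's bounds, keeping disconnected pieces together.  Process and port
  nodes are exempt.

Movement is `cooling · force` per node, clamped to 100 units.  A compound
moves as a cart: its displacement is inherited by its whole subtree.  The
cooling factor anneals **linearly to zero** across each phase's iteration
budget (phase 1 starts at 1.0 over at most `ip1 = 200` iterations; phase 2
starts lower, at `ccool = 0.3`, over at most 1000).  Linear annealing
matters: with a cooling floor the system keeps drifting after the last
gathering pass and the gathered clusters fan back out around the ports,
which destroys the orientation the second phase just established.  A
multiplicative schedule with a floor remains available via
`LayoutParams.cooling_schedule = "multiplicative"`.

Initial positions are drawn uniformly from a square sized to twice the
square root of the total node area, from a single seeded RNG that also
drives every later stochastic step; a run is fully reproducible from its
seed.

### Port machinery

Every process receives two port nodes of negligible (1×1) size at
`±(width/2 + 2)` units from its center along the orientation axis, held by
two rigid edges, all wrapped in a process-container compound.  Consumption
arcs are re-anchored to the input port, production arcs to the output port;
effector arcs stay on the process.  Forces accumulated on the ports (and on
the process, whose own forces would otherwise be discarded when the unit's
forces are reset) are transferred to the container each iteration, so the
unit translates rigidly; port offsets are re-imposed exactly after every
movement.  The machinery is removed before serialization and the inverse
restores the original arc set bit-for-bit.

### Rotational forces and rotation decisions

For each neighbor the signed deviation angle is measured between the vector
from the connection point (input port for substrates, output port for
products, process center for effectors) to the neighbor and the vector to
the neighbor's ideal position.  The magnitude is the arccos of the
normalized dot product — evaluated as `atan2(|cross|, dot)`, which is the
same quantity but numerically stable near 0° and 180° — and the sign comes
from a left test: a left turn (in screen coordinates) is negative, ties are
positive.  Effectors have exactly two ideal anchors, perpendicular to the
port axis at one ideal edge length; the nearer one is used, first in
enumeration order on ties.

The rotational force of a process is the signed sum of these angles over
all substrates, products and effectors.  Angles are accumulated every
iteration; every `rp = 2` iterations each process is checked:

1. if the fraction of samples with obtuse deviation (|angle| > 90°)
   exceeds `c180 = 0.5`, a **180° port swap** is proposed (checked first
   because it is the more drastic correction — it catches configurations
   whose signed sum cancels);
2. otherwise, if the accumulated signed sum, normalized by the number of
   samples in the window (making the threshold an average per-neighbor
   angle in degrees), exceeds `c90 = 70`, a **90° rotation** is proposed,
   clockwise for positive sign.

Orientations are discrete (left-to-right, top-to-bottom, right-to-left,
bottom-to-top; clockwise in that cycle).  For stability only one proposal
per window is applied, chosen uniformly at random among the qualifying
processes.

**Descent guard.**  A proposed action is first trial-applied and vetoed if
it would strictly increase the measured rotational-force magnitude on the
current geometry.  The raw obtuse-majority rule is not monotone: on
uniform-random neighbor configurations the 180° swap *increases* the
rotational force in roughly a fifth of the cases where it fires (sign-
imbalanced configurations with a small signed sum), while the 90° branch
is provably monotone under the per-neighbor normalization.  The guard
makes every committed action non-increasing by construction and leaves the
canonical swap scenario untouched: in the symmetric "everything on the
wrong side" configuration the signed sum is ~0 before and after the swap,
so the swap is never vetoed there.

### Gathering heuristic

Every `ap = 211` iterations, free neighbors are pulled next to their
peers: for each process, the highest-degree substrate (product) becomes a
seed and every degree-1 substrate (product) is teleported to a uniform
random point in the disc of radius `ad = 50` around it; degree-1 effectors
are teleported the same way around their nearer ideal anchor.  Nodes of
degree ≥ 2 ("hop" nodes) are never moved — their position carries
structural information the spring system has produced.

### Phase-2 loop and stopping

Each phase-2 iteration: resize compounds, compute spring/repulsion/gravity
forces with the dummy-machinery exclusions, sample the deviation angles
into the rotation accumulators, transfer and reset unit forces, apply at
most one rotation per decision window, and move with the annealed cooling.
The loop stops early when movement has converged (max displacement below
1 unit) *and* every process edge is properly oriented, or at 1000
iterations.

### Success metric

An edge is *properly oriented* when its deviation angle is within the
angle tolerance `at` (default 45°); the success ratio is measured over all
consumption, production and effector edges (an edge-free map scores 1.0).
The metric is invariant under translation and uniform scaling and can be
recomputed from a written SBGN-ML file alone, using the serialized port
coordinates.

With the default 45° tolerance the achievable ratio on busy processes is
intrinsically bounded: orientations are discrete, so after the best
rotation a gathered cluster can still sit up to 45° off-axis, and the
gathering disc (radius 50 at a ring radius of ~80) re-randomizes angles by
up to ±40° around the seed.  Typical end-to-end values on the synthetic
maps are 0.60–0.70 for the full algorithm versus 0.30–0.40 for the draft
phase alone; the full algorithm wins essentially every paired seed.
Raising `at` raises both numbers; it is a reporting choice, not an
algorithmic one.

### Packing and compaction

Molecular-complex members are all degree zero, so before layout every
compound containing no edge (none incident to any node inside it, at any
depth) has its members packed, deepest compound first; members become
position-fixed relative to their compound and ride along as a rigid block.
Compounds containing any connected member are left untouched — a connected
member must stay free to move toward its neighbors.  The complex's own
arcs do not block packing of its members.

* **Tiling** (default): first-fit rows by decreasing height, row width
  tracking √(total area × aspect).  Deterministic: stable sort, ties by
  input order.
* **Polyomino packing** (optional, `--packing polyomino`): rectangles are
  rasterized to grid cells (grid step = half the shortest item side),
  placed largest-first at the free anchor nearest the packing center, ties
  broken lexicographically.  It pays off only for large member counts,
  which complexes rarely have.
* **Adjusted fullness** measures packing quality: total item area over the
  area of the enclosing box grown along one axis to a target aspect ratio.
* **Visibility-graph compaction** (off by default, improvements are
  usually minimal): a DAG per scan direction with an edge u→v when v lies
  strictly ahead, v's perpendicular span fully covers u's facing span
  (complete visibility) and no third rectangle intrudes.  Items are then
  slid front-to-back toward the boundary.  The slide is collision-limited
  against *every* perpendicular-overlap blocker, not only
  complete-visibility predecessors — with the strict visibility rule a
  partially overlapping pair may share no edge, and sliding past such a
  neighbor would create an overlap.  Compaction therefore never grows the
  bounding box and never introduces overlaps, by construction.

## Synthetic maps

The generator emulates PD structure, not biology: EPN–process bipartite
connectivity (never EPN–EPN or process–process), each process with at
least one substrate and one product (counts drawn from configurable
ranges, defaults 1–3 substrates/products and 0–2 effectors), an EPN
sharing probability (0.15) that reuses existing EPNs and creates hop nodes
and cross-compartment arcs, complexes with 2–4 scattered degree-0 members
(occasionally nested one level), and compartments nested to a configurable
depth.  Glyph sizes are typical SBGN: EPNs 40–70 × 25–40, processes
20 × 20.  Everything derives from one seed; the same seed yields
byte-identical SBGN-ML.

What passing tests on these maps do *not* show: real pathway topologies
have hub distributions, stoichiometries and compartment structures the
generator does not model, so absolute orientation ratios on real maps may
differ; the relative improvement of the SBGN phase over the draft phase is
the transferable claim.

## Numerical and design choices

* Angle evaluation via `atan2(|cross|, dot)`; the 180° sign tie breaks
  positive, and decision windows make any such choice self-correcting.
* Degenerate zero-length neighbor vectors (a node exactly on its
  connection point) count as maximally deviated (180°) in the metric and
  the accumulator; the scalar `signed_angle` raises instead, since a
  caller passing degenerate geometry usually has a bug.
* Repulsion between *entities* (leaves plus packed/empty compounds) rather
  than between siblings per nesting level: sibling-scoped repulsion would
  make ports invisible to EPNs, removing the lateral force that separates
  the substrate and product sides.  Movement still uses cart semantics, so
  compound nesting behaves as expected; compartments separate through
  their contents.
* `ap = 211` (a curiously specific period) is used as published.
* Degree counts ignore rigid edges everywhere, so the dummy machinery is
  invisible to every heuristic.
* Rectangle overlap predicates use a 1e-9 interior tolerance so grid-
  snapped placements that touch at one ulp do not count as overlapping.
* SBGN-ML 0.2 is read and written; glyph nesting wins over
  `compartmentRef` when both appear; unknown arc classes map to a neutral
  OTHER kind with a logged warning; pre-existing port coordinates in input
  files are discarded and recomputed by layout.  The writer is canonical
  (fixed attribute order, two-decimal coordinates, arc anchors derived
  from the quantized values), so write → read → write is byte-identical.

## Problem sizes

The test suite exercises the full pipeline on thirty synthetic maps of
50–300 nodes with the default iteration budgets (200 draft + up to 1000
SBGN-phase iterations), the complexity check on maps of ~50–400 nodes, and
the packing properties on one hundred random rectangle sets; the
reproduction script uses twelve paired maps plus six compound-free maps.
These sizes match the regime the method targets (maps up to a few hundred
nodes).

## Known limitations

* No special treatment of reversible/irreversible processes, logic
  operators (they pass through as unspecified glyphs/neutral arcs), edge
  routing or bend points.
* Edge crossings are counted center-to-center/port-to-center on straight
  segments, not on glyph-boundary-clipped edges.
* The orientation ratio saturates below 1.0 on processes with many
  neighbors at the default 45° tolerance (see above).
* No grid acceleration for repulsion: cost is quadratic per iteration,
  fine for a few hundred nodes, slow beyond a few thousand.
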