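# sbgnpd-layout

Automatic layout for SBGN **process description (PD)** maps — the standard
notation in which systems biologists draw molecular reactions.  Generic
graph layout algorithms ignore three conventions that make PD maps
readable: substrates and products must attach at an **input** and an
**output port** on *opposite* sides of each process node, the degree-0
members of molecular complexes should be **tiled compactly** instead of
floating apart, and cellular **compartments** must enclose their contents
as nested compounds.  This package implements a force-directed layout that
enforces all three, with SBGN-ML 0.2 input/output, a synthetic PD map
generator for testing, and a small CLI.

It is aimed at tool builders and analysts who need presentable PD maps
from pathway databases or model pipelines without manual editing.

## Algorithm

The layout is a two-phase **compound spring embedder** over the compound
graph C = (V, E, F) (nodes, adjacency edges, inclusion forest):

1. **Draft phase** — classic forces: Hooke springs on edges
   (F = k_s(d − l), ideal length l = 70), inverse-square repulsion
   (F = k_r/d²) between movable entities, constant gravity toward the
   owner compound's center.  A compound moves as a "cart" with its whole
   nested graph.  Cooling anneals linearly to zero.

2. **SBGN phase** — each process gains two negligible-size port nodes held
   by rigid (force-free) edges inside a process-container compound, so the
   unit translates rigidly while substrate arcs pull on the input port and
   product arcs on the output port.  A **rotational force**

   ‖F_t(P)‖ = | Σᵢ αᵢ + Σᵢ βᵢ + Σᵢ γᵢ |

   sums the signed angular deviations of the n_s substrates, n_p products
   and n_e effectors from their ideal directions (angle magnitude from the
   normalized dot product, sign from a left test).  Accumulated over a
   short window, it triggers one discrete re-orientation per window: a
   180° port swap when most deviations are obtuse, else a 90° rotation
   (clockwise for positive sign) when the normalized sum exceeds a
   threshold c90 = 70°.  A gathering heuristic periodically teleports
   degree-1 substrates/products into a disc of radius ad = 50 around their
   highest-degree peer, and effectors next to the nearer of their two ideal
   anchors.  The phase stops when movement converges *and* every process
   edge is properly oriented (deviation ≤ the angle tolerance *at* = 45°).

Before both phases, every compound containing only degree-0 descendants
(molecular complexes, chiefly) has its members packed by row **tiling**
(polyomino packing and visibility-graph compaction are also available) and
carries them as a rigid block through layout.

Success is reported as the **ratio of properly oriented edges**, plus the
classic criteria: drawing area, total edge length, edge crossings, and the
**adjusted fullness** of each packed complex.

## Worked example

```sh
$ sbgnpd generate -o demo.sbgn --seed 4 --processes 3 --complexes 1 --compartments 1
wrote 16 glyphs, 11 arcs to demo.sbgn

$ sbgnpd layout demo.sbgn -o demo_laid_out.sbgn --seed 4
properly oriented ratio: 0.909
edge crossings: 1
```

The first command emits a synthetic PD map: 3 processes with their
substrates/products/effectors, one complex with scattered members, one
compartment.  The second lays it out: of the 11 substrate/product/effector
arcs, 10 end within 45° of their ideal direction (ratio 0.909) and the
drawing has a single edge crossing.  The output file is valid SBGN-ML 0.2;
each process glyph carries its two `<port>` elements placed according to
the orientation the layout chose:

```xml
<glyph id="comp0" class="compartment">
  <bbox x="-92.50" y="-52.25" w="558.05" h="377.91"/>
</glyph>
<glyph id="e0" class="macromolecule" compartmentRef="comp0">
  <bbox x="97.27" y="145.28" w="50.81" h="36.70"/>
</glyph>
```

Options: `--packing tiling|polyomino|none`, `--angle-tolerance`,
`--phase1-iters`, `--ideal-edge-length`, `--config params.yaml` (any
`LayoutParams` field), `--report report.jsonl` (one JSON record per run,
convenient for averaging over seeds).  The same functionality is available
as a library:

```python
from sbgnpd import read_map, write_map, layout_pipeline, LayoutParams

pd = read_map("demo.sbgn")
pd, report = layout_pipeline(pd, LayoutParams(seed=4))
write_map(pd, "demo_laid_out.sbgn")
print(report.properly_oriented_ratio, report.edge_crossing_count)
```

See `docs/methods.md` for the model, parameters and their defaults, and
known limitations.

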