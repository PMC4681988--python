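"""Pipeline orchestration and layout quality metrics.

The full layout runs: pack disconnected members → attach process ports →
draft force-directed phase → SBGN phase (rotations, gathering) → detach
ports → report.  The report carries the standard drawing criteria (area,
total edge length, edge crossings) plus the SBGN-specific success measure,
the ratio of properly oriented process edges at the configured angle
tolerance.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .compound_graph import CompoundGraph, EdgeKind, NodeKind, Point
from .cose_core import ForceEngine, LayoutParams, run_phase1, scatter_initial
from .packing import Placement, adjusted_fullness, pack_disconnected
from .sbgn_phase import (
    attach_ports,
    detach_ports,
    properly_oriented_ratio,
    run_phase2,
    signed_angle,
)
from .sbgnml_io import PDMap


@dataclass
class LayoutReport:
    properly_oriented_ratio: float
    total_edge_length: float
    edge_crossing_count: int
    drawing_area: float
    complex_fullness: dict[str, float]
    phase1_iterations: int
    phase2_iterations: int
    rotation_count: int
    swap_count: int
    packed_compounds: list[str]
    seed: int
    params: dict

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def layout_pipeline(pd: PDMap, params: Optional[LayoutParams] = None,
                    packing: str = "tiling",
                    ) -> tuple[PDMap, LayoutReport]:
    """Lay out a PD map in place and measure the result."""
    params = params or LayoutParams()
    rng = random.Random(params.seed)
    cg = pd.graph

    packed = pack_disconnected(cg, method=packing) if packing != "none" \
        else []
    units = attach_ports(cg, params)
    scatter_initial(cg, params, rng)
    k1, engine = run_phase1(cg, params, units)
    res2 = run_phase2(cg, units, params, rng, engine)

    # persist final port geometry, then drop the dummy machinery
    for unit in units:
        info = pd.port_info(unit.process)
        info.in_xy = (unit.input_port.rect.cx, unit.input_port.rect.cy)
        info.out_xy = (unit.output_port.rect.cx, unit.output_port.rect.cy)
    detach_ports(cg, units)
    cg.update_bounds()

    report = LayoutReport(
        properly_oriented_ratio=res2.final_ratio,
        total_edge_length=total_edge_length(pd),
        edge_crossing_count=crossing_count(pd),
        drawing_area=drawing_area(cg),
        complex_fullness=complex_fullness(cg),
        phase1_iterations=k1,
        phase2_iterations=res2.iterations,
        rotation_count=res2.rotation_count,
        swap_count=res2.swap_count,
        packed_compounds=packed,
        seed=params.seed,
        params=params.to_dict(),
    )
    return pd, report


# ------------------------------------------------------------------ metrics
def _edge_segments(pd: PDMap) -> list[tuple[str, str, float, float, float,
                                            float]]:
    """(source id, target id, x1, y1, x2, y2) per non-rigid edge, anchored
    port-to-center for process arcs and center-to-center otherwise."""
    segs = []
    for e in pd.graph.edges:
        if e.kind is EdgeKind.RIGID:
            continue

        def anchor(node, opposite_kind):
            if node.kind is NodeKind.PROCESS:
                info = pd.port_info(node)
                if e.kind is EdgeKind.CONSUMPTION:
                    return info.in_xy
                if e.kind is EdgeKind.PRODUCTION:
                    return info.out_xy
            return (node.rect.cx, node.rect.cy)

        x1, y1 = anchor(e.source, None)
        x2, y2 = anchor(e.target, None)
        segs.append((e.source.id, e.target.id, x1, y1, x2, y2))
    return segs


def total_edge_length(pd: PDMap) -> float:
    return sum(math.hypot(x2 - x1, y2 - y1)
               for _, _, x1, y1, x2, y2 in _edge_segments(pd))


def drawing_area(cg: CompoundGraph) -> float:
    bounds = cg.graph_bounds(cg.root)
    return bounds.area if bounds is not None else 0.0


def complex_fullness(cg: CompoundGraph, aspect: float = 1.0
                     ) -> dict[str, float]:
    """Adjusted fullness of every complex with members."""
    out = {}
    for comp in cg.compounds():
        if comp.kind is not NodeKind.COMPLEX or not comp.child.nodes:
            continue
        placements = [Placement(m.id, m.rect) for m in comp.child.nodes]
        out[comp.id] = adjusted_fullness(placements, aspect)
    return out


def _proper_cross(ax, ay, bx, by, cx, cy, dx, dy) -> bool:
    """Strict intersection of open segments AB and CD."""

    def orient(ox, oy, px, py, qx, qy) -> float:
        return (px - ox) * (qy - oy) - (py - oy) * (qx - ox)

    d1 = orient(cx, cy, dx, dy, ax, ay)
    d2 = orient(cx, cy, dx, dy, bx, by)
    d3 = orient(ax, ay, bx, by, cx, cy)
    d4 = orient(ax, ay, bx, by, dx, dy)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) \
        and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0


def crossing_count(pd: PDMap) -> int:
    """Number of edge pairs whose straight-line segments properly cross;
    pairs sharing an endpoint glyph are excluded."""
    segs = _edge_segments(pd)
    count = 0
    for i in range(len(segs)):
        si, ti, ax, ay, bx, by = segs[i]
        for j in range(i + 1, len(segs)):
            sj, tj, cx, cy, dx, dy = segs[j]
            if {si, ti} & {sj, tj}:
                continue
            if _proper_cross(ax, ay, bx, by, cx, cy, dx, dy):
                count += 1
    return count


def ratio_from_written_map(pd: PDMap, at: float = 45.0,
                           ideal_edge_length: float = 70.0) -> float:
    """Properly-oriented ratio recomputed purely from serialized geometry
    (process centers, port coordinates and EPN centers), so the metric can
    be verified on a written SBGN-ML file without re-running layout."""
    total = ok = 0
    for e in pd.graph.edges:
        if e.kind not in (EdgeKind.CONSUMPTION, EdgeKind.PRODUCTION,
                          EdgeKind.EFFECTOR):
            continue
        if e.source.kind is NodeKind.PROCESS:
            proc, epn = e.source, e.target
        elif e.target.kind is NodeKind.PROCESS:
            proc, epn = e.target, e.source
        else:
            continue
        info = pd.port_info(proc)
        c = (proc.rect.cx, proc.rect.cy)
        axv = (info.out_xy[0] - info.in_xy[0],
               info.out_xy[1] - info.in_xy[1])
        n = math.hypot(*axv)
        if n == 0:
            continue
        axv = (axv[0] / n, axv[1] / n)
        if e.kind is EdgeKind.CONSUMPTION:
            conn = Point(*info.in_xy)
            ideal = Point(conn.x - axv[0], conn.y - axv[1])
        elif e.kind is EdgeKind.PRODUCTION:
            conn = Point(*info.out_xy)
            ideal = Point(conn.x + axv[0], conn.y + axv[1])
        else:
            conn = Point(*c)
            px, py = -axv[1], axv[0]
            a0 = Point(c[0] + px * ideal_edge_length,
                       c[1] + py * ideal_edge_length)
            a1 = Point(c[0] - px * ideal_edge_length,
                       c[1] - py * ideal_edge_length)
            ec = epn.rect.center
            d0 = (ec.x - a0.x) ** 2 + (ec.y - a0.y) ** 2
            d1 = (ec.x - a1.x) ** 2 + (ec.y - a1.y) ** 2
            ideal = a0 if d0 <= d1 else a1
        total += 1
        try:
            if abs(signed_angle(conn, epn.rect.center, ideal)) <= at:
                ok += 1
        except ValueError:
            pass   # degenerate geometry counts as improperly oriented
    return ok / total if total else 1.0
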