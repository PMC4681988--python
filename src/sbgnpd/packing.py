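"""Rectangle packing for disconnected nodes (molecular complex members).

Members of a molecular complex are all degree zero, so any packer may place
them freely; complexes nest, so packing runs bottom-up (deepest first).  Two
packers are provided: row-based tiling (the default — complexes typically
hold few members of similar size) and polyomino packing on a grid, which
only pays off for large member counts.  A visibility-graph compactor can
squeeze a placement further in one of the four axis directions.

Packing quality is measured by *adjusted fullness*: total item area over
the area of the tightest enclosing rectangle coerced to a target aspect
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import networkx as nx

from .compound_graph import CompoundGraph, Node, Rect

#: Default gap between packed items, layout units.
DEFAULT_SPACING = 5.0


@dataclass
class Placement:
    """A rectangle position assigned by a packer."""

    item: object   # caller-supplied id (index or node id)
    rect: Rect


class Direction(Enum):
    """Scan direction; named by where items move during compaction."""

    BOTTOM_TO_TOP = "bottom-to-top"   # toward smaller y
    TOP_TO_BOTTOM = "top-to-bottom"   # toward larger y
    LEFT_TO_RIGHT = "left-to-right"   # toward larger x
    RIGHT_TO_LEFT = "right-to-left"   # toward smaller x


# -------------------------------------------------------------------- tiling
def tile(dims: Sequence[tuple[float, float]], spacing: float = 0.0,
         aspect: float = 1.0) -> list[Placement]:
    """Row-based first-fit tiling by decreasing height.

    Items are sorted by decreasing height (stable, ties keep input order)
    and filled greedily into rows whose width tracks
    ``sqrt(total area x aspect)``.  Returns placements keyed by input index.
    """
    if not dims:
        return []
    for w, h in dims:
        if w <= 0 or h <= 0:
            raise ValueError("item dimensions must be positive")
    order = sorted(range(len(dims)), key=lambda i: (-dims[i][1], i))
    total_area = sum(w * h for w, h in dims)
    target_w = math.sqrt(total_area * aspect)
    placements: list[Placement] = []
    x = y = 0.0
    row_h = 0.0
    for i in order:
        w, h = dims[i]
        if x > 0.0 and x + w > target_w + 1e-9:
            y += row_h + spacing
            x = 0.0
            row_h = 0.0
        placements.append(Placement(i, Rect(x, y, w, h)))
        x += w + spacing
        row_h = max(row_h, h)
    placements.sort(key=lambda p: p.item)
    return placements


# ----------------------------------------------------------------- polyomino
def polyomino_pack(dims: Sequence[tuple[float, float]],
                   grid_step: Optional[float] = None) -> list[Placement]:
    """Grid-rasterized packing: each rectangle becomes a polyomino of grid
    cells, pieces are placed largest-first at the free anchor closest to the
    packing center.  ``grid_step`` defaults to half the shortest item side.
    """
    if not dims:
        return []
    for w, h in dims:
        if w <= 0 or h <= 0:
            raise ValueError("item dimensions must be positive")
    if grid_step is None:
        grid_step = min(min(w, h) for w, h in dims) / 2.0
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    order = sorted(range(len(dims)), key=lambda i: (-dims[i][0] * dims[i][1],
                                                    i))
    occupied: set[tuple[int, int]] = set()
    placements: list[Placement] = []
    for i in order:
        w, h = dims[i]
        cw = max(1, math.ceil(w / grid_step - 1e-9))
        ch = max(1, math.ceil(h / grid_step - 1e-9))
        anchor = _closest_free_anchor(occupied, cw, ch)
        ax, ay = anchor
        for gx in range(ax, ax + cw):
            for gy in range(ay, ay + ch):
                occupied.add((gx, gy))
        placements.append(
            Placement(i, Rect(ax * grid_step, ay * grid_step, w, h)))
    placements.sort(key=lambda p: p.item)
    return placements


def _closest_free_anchor(occupied: set[tuple[int, int]], cw: int,
                         ch: int) -> tuple[int, int]:
    """Free anchor minimizing the distance of the piece center to the
    origin; ties broken lexicographically for determinism."""
    radius = 1
    while True:
        lo, hi = -radius - max(cw, ch), radius + 1
        candidates = []
        for ax in range(lo, hi):
            for ay in range(lo, hi):
                cx = (ax + cw / 2.0)
                cy = (ay + ch / 2.0)
                candidates.append((cx * cx + cy * cy, ax, ay))
        candidates.sort()
        for _, ax, ay in candidates:
            if all((gx, gy) not in occupied
                   for gx in range(ax, ax + cw)
                   for gy in range(ay, ay + ch)):
                return (ax, ay)
        radius *= 2


# ------------------------------------------------------------------ fullness
def bounding_box(placements: Sequence[Placement]) -> Rect:
    if not placements:
        raise ValueError("empty placement set")
    x0 = min(p.rect.x for p in placements)
    y0 = min(p.rect.y for p in placements)
    x1 = max(p.rect.right for p in placements)
    y1 = max(p.rect.bottom for p in placements)
    return Rect(x0, y0, x1 - x0, y1 - y0)


def adjusted_fullness(placements: Sequence[Placement],
                      aspect: float = 1.0) -> float:
    """Total item area over the area of the enclosing box grown along one
    axis to the requested width/height aspect ratio."""
    if not placements:
        raise ValueError("empty placement set")
    box = bounding_box(placements)
    w, h = max(box.width, 1e-12), max(box.height, 1e-12)
    if w / h < aspect:
        w = aspect * h
    else:
        h = w / aspect
    total = sum(p.rect.area for p in placements)
    return total / (w * h)


# ---------------------------------------------------------------- visibility
@dataclass
class VisibilityGraph:
    graph: "nx.DiGraph"
    direction: Direction


def _axis_sign(direction: Direction) -> float:
    """+1 when movement increases the axis coordinate."""
    return 1.0 if direction in (Direction.TOP_TO_BOTTOM,
                                Direction.LEFT_TO_RIGHT) else -1.0


def _axis_interval(rect: Rect, direction: Direction) -> tuple[float, float]:
    """Rect extent along the movement axis in the transformed coordinate
    t = sign * coord, so movement always increases t; returns (t0, t1)
    with t1 the leading (facing) edge."""
    if direction is Direction.TOP_TO_BOTTOM:
        return (rect.y, rect.bottom)
    if direction is Direction.BOTTOM_TO_TOP:
        return (-rect.bottom, -rect.y)
    if direction is Direction.LEFT_TO_RIGHT:
        return (rect.x, rect.right)
    return (-rect.right, -rect.x)


def _perp_span(rect: Rect, direction: Direction) -> tuple[float, float]:
    if direction in (Direction.BOTTOM_TO_TOP, Direction.TOP_TO_BOTTOM):
        return (rect.x, rect.right)
    return (rect.y, rect.bottom)


def visibility_graph(placements: Sequence[Placement],
                     direction: Direction) -> VisibilityGraph:
    """Directed acyclic visibility graph: edge u→v when v lies strictly
    ahead of u in the scan direction, v's perpendicular span fully covers
    u's facing span (complete visibility), and no third rectangle intrudes
    into the corridor between them.  Overlapping input is rejected."""
    for a in range(len(placements)):
        for b in range(a + 1, len(placements)):
            if placements[a].rect.overlaps(placements[b].rect):
                raise ValueError("visibility requires overlap-free input")
    g = nx.DiGraph()
    for p in placements:
        g.add_node(p.item)
    for u in placements:
        _, u_lead = _axis_interval(u.rect, direction)
        u_lo, u_hi = _perp_span(u.rect, direction)
        for v in placements:
            if v is u:
                continue
            v_trail, _ = _axis_interval(v.rect, direction)
            if v_trail < u_lead - 1e-9:
                continue   # v not strictly ahead of u
            v_lo, v_hi = _perp_span(v.rect, direction)
            if v_lo > u_lo + 1e-9 or v_hi < u_hi - 1e-9:
                continue   # v does not cover u's whole facing span
            blocked = False
            for w in placements:
                if w is u or w is v:
                    continue
                w_t0, w_t1 = _axis_interval(w.rect, direction)
                w_lo, w_hi = _perp_span(w.rect, direction)
                if (w_t1 > u_lead + 1e-9 and w_t0 < v_trail - 1e-9
                        and w_hi > u_lo + 1e-9 and w_lo < u_hi - 1e-9):
                    blocked = True
                    break
            if not blocked:
                g.add_edge(u.item, v.item)
    if not nx.is_directed_acyclic_graph(g):   # pragma: no cover - invariant
        raise AssertionError("visibility graph must be acyclic")
    return VisibilityGraph(g, direction)


# ---------------------------------------------------------------- compaction
def compact(placements: Sequence[Placement], direction: Direction,
            spacing: float = 0.0) -> list[Placement]:
    """Slide each item as far as possible in the scan direction.

    Items are processed front-to-back (a linear extension of the
    visibility DAG); each stops at ``spacing`` behind the nearest blocking
    item already in place, or at the original bounding-box boundary.  The
    bounding-box area never increases and no overlaps are introduced.
    """
    if not placements:
        return []
    result = [Placement(p.item, p.rect.copy()) for p in placements]
    sgn = _axis_sign(direction)
    boundary = max(_axis_interval(p.rect, direction)[1] for p in result)
    order = sorted(range(len(result)),
                   key=lambda i: (-_axis_interval(result[i].rect,
                                                  direction)[1], i))
    placed: list[int] = []
    for i in order:
        r = result[i].rect
        _, lead = _axis_interval(r, direction)
        lo, hi = _perp_span(r, direction)
        limit = boundary
        for j in placed:
            jr = result[j].rect
            j_lo, j_hi = _perp_span(jr, direction)
            if j_hi <= lo + 1e-9 or j_lo >= hi - 1e-9:
                continue   # no perpendicular overlap, cannot block
            j_trail = _axis_interval(jr, direction)[0]
            limit = min(limit, j_trail - spacing)
        if limit > lead:   # move only forward (toward the boundary)
            delta = (limit - lead) * sgn
            if direction in (Direction.BOTTOM_TO_TOP,
                             Direction.TOP_TO_BOTTOM):
                r.translate(0.0, delta)
            else:
                r.translate(delta, 0.0)
        placed.append(i)
    return result


# ------------------------------------------------------- map-level packing
def pack_disconnected(cg: CompoundGraph, method: str = "tiling",
                      spacing: float = DEFAULT_SPACING,
                      aspect: float = 1.0,
                      grid_step: Optional[float] = None) -> list[str]:
    """Pack the members of every compound that contains no edges, bottom-up.

    A compound qualifies when its child graph is non-empty and no edge
    (intra- or inter-graph) touches any node inside it; its members are
    packed, marked position-fixed relative to the compound, and the
    compound shrinks to the packed bounding box plus margin.  Compounds
    containing any connected member are left untouched.  Returns the ids of
    the packed compounds.
    """
    if method not in ("tiling", "polyomino"):
        raise ValueError(f"unknown packing method {method!r}")
    packed: list[str] = []

    def descendants_connected(comp: Node) -> bool:
        stack = list(comp.child.nodes)
        while stack:
            n = stack.pop()
            if n.edges:
                return True
            if n.child is not None:
                stack.extend(n.child.nodes)
        return False

    def visit(node: Node) -> None:
        if node.child is None:
            return
        for child in node.child.nodes:
            visit(child)
        if not node.child.nodes or descendants_connected(node):
            return
        members = node.child.nodes
        dims = [(m.rect.width, m.rect.height) for m in members]
        if method == "tiling":
            placements = tile(dims, spacing=spacing, aspect=aspect)
        else:
            placements = polyomino_pack(dims, grid_step=grid_step)
        box = bounding_box(placements)
        # keep the packed block centered where the compound was
        ox = node.rect.cx - box.width / 2.0 - box.x
        oy = node.rect.cy - box.height / 2.0 - box.y
        for m, p in zip(members, placements):
            dx = (p.rect.x + ox) - m.rect.x
            dy = (p.rect.y + oy) - m.rect.y
            cg.translate_subtree(m, dx, dy)
            m.fixed = True
        cg.update_bounds(node)
        packed.append(node.id)

    for top in list(cg.root.nodes):
        visit(top)
    return packed
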