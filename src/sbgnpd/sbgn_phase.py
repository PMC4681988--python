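"""SBGN-specific layout phase.

Process nodes acquire dummy machinery — two negligible-size port nodes held
by rigid edges inside a process-container compound — so that substrate arcs
pull on the input port and product arcs on the output port while the unit
translates rigidly.  A *rotational force* (the signed sum of the angular
deviations of substrates, products and effectors from their ideal
directions) drives discrete 90° rotations and 180° port swaps; a gathering
heuristic periodically teleports free (degree-1) neighbors next to a
high-degree seed and effectors next to their ideal anchors.

Angle sign convention (screen coordinates, y down): with the connection
point c, neighbor n and ideal point i, the left test
``(n.x-c.x)(i.y-c.y) - (n.y-c.y)(i.x-c.x) > 0`` marks a left turn and gives
the angle a negative sign; right turns (and the 0°/180° ties) are positive.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .compound_graph import (
    CompoundGraph,
    Edge,
    EdgeKind,
    Node,
    NodeKind,
    Point,
    Rect,
)
from .cose_core import ForceEngine, LayoutParams, cooling_at

PORT_SIZE = 1.0          # "negligible dimensions"
CONTAINER_MARGIN = 1.0   # container wraps its unit tightly


class Orientation(Enum):
    LEFT_TO_RIGHT = "left-to-right"
    RIGHT_TO_LEFT = "right-to-left"
    TOP_TO_BOTTOM = "top-to-bottom"
    BOTTOM_TO_TOP = "bottom-to-top"


#: Orientation axis: unit vector from the process center toward the output
#: port, in screen coordinates (y grows downward).
_AXIS = {
    Orientation.LEFT_TO_RIGHT: (1.0, 0.0),
    Orientation.TOP_TO_BOTTOM: (0.0, 1.0),
    Orientation.RIGHT_TO_LEFT: (-1.0, 0.0),
    Orientation.BOTTOM_TO_TOP: (0.0, -1.0),
}

#: Clockwise (visual, y-down) 90° rotation cycle.
_CW_CYCLE = [
    Orientation.LEFT_TO_RIGHT,
    Orientation.TOP_TO_BOTTOM,
    Orientation.RIGHT_TO_LEFT,
    Orientation.BOTTOM_TO_TOP,
]

_OPPOSITE = {
    Orientation.LEFT_TO_RIGHT: Orientation.RIGHT_TO_LEFT,
    Orientation.RIGHT_TO_LEFT: Orientation.LEFT_TO_RIGHT,
    Orientation.TOP_TO_BOTTOM: Orientation.BOTTOM_TO_TOP,
    Orientation.BOTTOM_TO_TOP: Orientation.TOP_TO_BOTTOM,
}


class RotationAction(Enum):
    NONE = "none"
    CW_90 = "cw90"
    CCW_90 = "ccw90"
    SWAP_180 = "swap180"


_INVERSE_ACTION = {
    RotationAction.CW_90: RotationAction.CCW_90,
    RotationAction.CCW_90: RotationAction.CW_90,
    RotationAction.SWAP_180: RotationAction.SWAP_180,
}


@dataclass
class IdealDirections:
    """Desired neighbor directions of a process unit for its orientation."""

    substrate_dir: Point   # unit vector out of the input port
    product_dir: Point     # unit vector out of the output port
    effector_anchors: tuple[Point, Point]  # two ideal effector positions


@dataclass
class ProcessUnit:
    process: Node
    input_port: Node
    output_port: Node
    container: Node
    rigid_edges: tuple[Edge, Edge]
    orientation: Orientation
    port_offset: float

    def axis(self) -> tuple[float, float]:
        return _AXIS[self.orientation]

    def place_ports(self) -> None:
        ax, ay = self.axis()
        cx, cy = self.process.rect.cx, self.process.rect.cy
        self.input_port.rect.set_center(cx - ax * self.port_offset,
                                        cy - ay * self.port_offset)
        self.output_port.rect.set_center(cx + ax * self.port_offset,
                                         cy + ay * self.port_offset)

    def ideal_directions(self, ideal_edge_length: float) -> IdealDirections:
        ax, ay = self.axis()
        px, py = -ay, ax   # perpendicular to the port axis
        cx, cy = self.process.rect.cx, self.process.rect.cy
        return IdealDirections(
            substrate_dir=Point(-ax, -ay),
            product_dir=Point(ax, ay),
            effector_anchors=(
                Point(cx + px * ideal_edge_length, cy + py * ideal_edge_length),
                Point(cx - px * ideal_edge_length, cy - py * ideal_edge_length),
            ),
        )

    def substrates(self) -> list[Node]:
        return [e.other(self.input_port) for e in self.input_port.edges
                if e.kind is EdgeKind.CONSUMPTION]

    def products(self) -> list[Node]:
        return [e.other(self.output_port) for e in self.output_port.edges
                if e.kind is EdgeKind.PRODUCTION]

    def effectors(self) -> list[Node]:
        return [e.other(self.process) for e in self.process.edges
                if e.kind is EdgeKind.EFFECTOR]


@dataclass
class RotationAccumulator:
    """Signed-angle tally of one process over a decision window."""

    signed_sum: float = 0.0
    samples: int = 0
    obtuse: int = 0

    def add(self, angle: float) -> None:
        self.signed_sum += angle
        self.samples += 1
        if abs(angle) > 90.0:
            self.obtuse += 1

    def reset(self) -> None:
        self.signed_sum = 0.0
        self.samples = 0
        self.obtuse = 0


# -------------------------------------------------------------------- angles
def signed_angle(connection: Point, neighbor: Point, ideal: Point) -> float:
    """Signed angular deviation of ``neighbor`` from the ray
    connection→ideal, in degrees within [-180, 180].

    Magnitude is the arccos of the normalized dot product, evaluated as
    atan2(|cross|, dot) for numerical stability near 0° and 180°; the sign
    comes from the left test (left turn → negative, ties → positive).
    """
    nx, ny = neighbor.x - connection.x, neighbor.y - connection.y
    ix, iy = ideal.x - connection.x, ideal.y - connection.y
    if (nx == 0.0 and ny == 0.0) or (ix == 0.0 and iy == 0.0):
        raise ValueError("degenerate geometry: zero-length vector")
    dot = nx * ix + ny * iy
    left = nx * iy - ny * ix
    mag = math.degrees(math.atan2(abs(left), dot))
    return -mag if left > 0.0 else mag


def _signed_angles_vec(nvec: np.ndarray, dvec: np.ndarray) -> np.ndarray:
    """Vectorized signed angles between neighbor vectors and ideal-direction
    vectors.  Degenerate (zero-length) neighbor vectors yield 180°."""
    nn = np.sqrt((nvec * nvec).sum(axis=1))
    dot = (nvec * dvec).sum(axis=1)
    left = nvec[:, 0] * dvec[:, 1] - nvec[:, 1] * dvec[:, 0]
    mag = np.degrees(np.arctan2(np.abs(left), dot))
    ang = np.where(left > 0.0, -mag, mag)
    return np.where(nn < 1e-12, 180.0, ang)


# --------------------------------------------------------------- port attach
def attach_ports(cg: CompoundGraph,
                 params: Optional[LayoutParams] = None) -> list[ProcessUnit]:
    """Equip every process with two ports, two rigid edges and a container
    compound; consumption arcs are re-anchored to the input port and
    production arcs to the output port.  Initial orientation is
    left-to-right."""
    params = params or LayoutParams()
    units: list[ProcessUnit] = []
    for process in [n for n in cg.iter_nodes()
                    if n.kind is NodeKind.PROCESS]:
        if any(e.kind is EdgeKind.RIGID for e in process.edges):
            raise ValueError(f"process {process.id!r} already has ports")
        parent = process.parent_node
        container = cg.add_node(f"{process.id}__unit",
                                NodeKind.PROCESS_CONTAINER,
                                process.rect.copy(), parent=parent)
        container.margin = CONTAINER_MARGIN
        cg.reparent(process, container)
        offset = process.rect.width / 2.0 + params.port_gap
        pin = cg.add_node(f"{process.id}__pin", NodeKind.PORT,
                          Rect(0, 0, PORT_SIZE, PORT_SIZE), parent=container)
        pout = cg.add_node(f"{process.id}__pout", NodeKind.PORT,
                           Rect(0, 0, PORT_SIZE, PORT_SIZE), parent=container)
        r1 = cg.add_edge(f"{process.id}__rig_in", process, pin, EdgeKind.RIGID)
        r2 = cg.add_edge(f"{process.id}__rig_out", process, pout,
                         EdgeKind.RIGID)
        for edge in list(process.edges):
            if edge.kind is EdgeKind.CONSUMPTION:
                _move_endpoint(edge, process, pin)
            elif edge.kind is EdgeKind.PRODUCTION:
                _move_endpoint(edge, process, pout)
        unit = ProcessUnit(process, pin, pout, container, (r1, r2),
                           Orientation.LEFT_TO_RIGHT, offset)
        unit.place_ports()
        cg.update_bounds(container)
        units.append(unit)
    return units


def detach_ports(cg: CompoundGraph, units: Sequence[ProcessUnit]) -> None:
    """Inverse of :func:`attach_ports`: arcs re-anchored to the process,
    dummy nodes/edges removed, coordinates kept."""
    for unit in units:
        for port in (unit.input_port, unit.output_port):
            for edge in list(port.edges):
                if edge.kind is EdgeKind.RIGID:
                    cg.remove_edge(edge)
                else:
                    _move_endpoint(edge, port, unit.process)
        parent = unit.container.parent_node
        cg.reparent(unit.process, parent)
        cg.remove_node(unit.input_port)
        cg.remove_node(unit.output_port)
        cg.remove_node(unit.container)


def _move_endpoint(edge: Edge, old: Node, new: Node) -> None:
    if edge.source is old:
        edge.source = new
    elif edge.target is old:
        edge.target = new
    else:
        raise ValueError("node is not an endpoint of the edge")
    old.edges.remove(edge)
    new.edges.append(edge)


# ---------------------------------------------------------- rotational force
def _neighbor_terms(unit: ProcessUnit, ideal_edge_length: float):
    """(connection, neighbor-center, ideal-point) triples for every
    substrate, product and effector of the unit."""
    ideals = unit.ideal_directions(ideal_edge_length)
    pin_c = unit.input_port.rect.center
    pout_c = unit.output_port.rect.center
    proc_c = unit.process.rect.center
    terms = []
    for epn in unit.substrates():
        ideal = Point(pin_c.x + ideals.substrate_dir.x,
                      pin_c.y + ideals.substrate_dir.y)
        terms.append((pin_c, epn.rect.center, ideal))
    for epn in unit.products():
        ideal = Point(pout_c.x + ideals.product_dir.x,
                      pout_c.y + ideals.product_dir.y)
        terms.append((pout_c, epn.rect.center, ideal))
    for epn in unit.effectors():
        c = epn.rect.center
        a0, a1 = ideals.effector_anchors
        d0 = (c.x - a0.x) ** 2 + (c.y - a0.y) ** 2
        d1 = (c.x - a1.x) ** 2 + (c.y - a1.y) ** 2
        anchor = a0 if d0 <= d1 else a1
        terms.append((proc_c, c, anchor))
    return terms


def rotational_force(unit: ProcessUnit, cg: CompoundGraph,
                     ideal_edge_length: float = 70.0) -> float:
    """Signed sum of the angular deviations of all neighbors of the unit;
    its absolute value is the rotational-force magnitude, its sign the
    rotation direction."""
    total = 0.0
    for conn, nb, ideal in _neighbor_terms(unit, ideal_edge_length):
        try:
            total += signed_angle(conn, nb, ideal)
        except ValueError:
            total += 180.0   # degenerate: maximally deviated
    return total


def decide_rotation(unit: ProcessUnit, acc: RotationAccumulator,
                    params: LayoutParams) -> RotationAction:
    """Rotation decision for one window: the (more drastic) 180° port swap
    when the obtuse fraction exceeds ``c180``, else a 90° rotation when the
    per-sample normalized signed sum exceeds ``c90``, signed positive → CW."""
    if acc.samples == 0:
        return RotationAction.NONE
    if acc.obtuse / acc.samples > params.c180:
        return RotationAction.SWAP_180
    normalized = acc.signed_sum / acc.samples
    if abs(normalized) > params.c90:
        return RotationAction.CW_90 if normalized > 0 \
            else RotationAction.CCW_90
    return RotationAction.NONE


def rotate_unit(unit: ProcessUnit, action: RotationAction) -> ProcessUnit:
    """Apply a discrete rotation: 90° steps walk the CW cycle
    L2R→T2B→R2L→B2T; the 180° swap exchanges the port positions.  The
    process rect itself is unchanged."""
    if action is RotationAction.NONE:
        raise ValueError("cannot apply RotationAction.NONE")
    if action is RotationAction.SWAP_180:
        unit.orientation = _OPPOSITE[unit.orientation]
    else:
        i = _CW_CYCLE.index(unit.orientation)
        step = 1 if action is RotationAction.CW_90 else -1
        unit.orientation = _CW_CYCLE[(i + step) % 4]
    unit.place_ports()
    return unit


def select_and_apply_rotation(
    cg: CompoundGraph,
    units: Sequence[ProcessUnit],
    accs: Sequence[RotationAccumulator],
    params: LayoutParams,
    rng: random.Random,
) -> Optional[tuple[ProcessUnit, RotationAction]]:
    """Collect qualifying units, veto candidates whose action would increase
    the measured rotational force (descent guard), apply exactly one chosen
    uniformly at random, and reset every accumulator."""
    candidates: list[tuple[ProcessUnit, RotationAction]] = []
    for unit, acc in zip(units, accs):
        action = decide_rotation(unit, acc, params)
        if action is RotationAction.NONE:
            continue
        before = abs(rotational_force(unit, cg, params.ideal_edge_length))
        rotate_unit(unit, action)
        after = abs(rotational_force(unit, cg, params.ideal_edge_length))
        rotate_unit(unit, _INVERSE_ACTION[action])
        if after <= before + 1e-9:
            candidates.append((unit, action))
    chosen: Optional[tuple[ProcessUnit, RotationAction]] = None
    if candidates:
        chosen = candidates[rng.randrange(len(candidates))]
        rotate_unit(chosen[0], chosen[1])
    for acc in accs:
        acc.reset()
    return chosen


# ----------------------------------------------------- gathering heuristic
def approximate_locations(cg: CompoundGraph, units: Sequence[ProcessUnit],
                          params: LayoutParams, rng: random.Random) -> None:
    """Location enhancement: per process, degree-1 substrates (products) are
    teleported uniformly into the disc of radius ``ad`` around the
    highest-degree substrate (product); degree-1 effectors are teleported
    near the nearer of the two ideal effector anchors.  Higher-degree "hop"
    nodes are never moved."""

    def disc_point(cx: float, cy: float) -> tuple[float, float]:
        r = params.ad * math.sqrt(rng.random())
        th = rng.uniform(0.0, 2.0 * math.pi)
        return cx + r * math.cos(th), cy + r * math.sin(th)

    for unit in units:
        for members in (unit.substrates(), unit.products()):
            if not members:
                continue
            degs = [cg.degree(n) for n in members]
            seed = members[degs.index(max(degs))]
            sx, sy = seed.rect.cx, seed.rect.cy
            for node, deg in zip(members, degs):
                if deg == 1 and not node.fixed:
                    node.rect.set_center(*disc_point(sx, sy))
        effs = unit.effectors()
        if effs:
            a0, a1 = unit.ideal_directions(
                params.ideal_edge_length).effector_anchors
            for node in effs:
                if cg.degree(node) != 1 or node.fixed:
                    continue
                c = node.rect.center
                d0 = (c.x - a0.x) ** 2 + (c.y - a0.y) ** 2
                d1 = (c.x - a1.x) ** 2 + (c.y - a1.y) ** 2
                anchor = a0 if d0 <= d1 else a1
                node.rect.set_center(*disc_point(anchor.x, anchor.y))


# ------------------------------------------------------- orientation metric
def edge_orientation_angles(cg: CompoundGraph, units: Sequence[ProcessUnit],
                            ideal_edge_length: float = 70.0) -> list[float]:
    """Signed deviation angle of every substrate/product/effector edge."""
    angles = []
    for unit in units:
        for conn, nb, ideal in _neighbor_terms(unit, ideal_edge_length):
            try:
                angles.append(signed_angle(conn, nb, ideal))
            except ValueError:
                angles.append(180.0)
    return angles


def properly_oriented_ratio(cg: CompoundGraph, units: Sequence[ProcessUnit],
                            at: float = 45.0,
                            ideal_edge_length: float = 70.0) -> float:
    """Fraction of process edges whose deviation is within the angle
    tolerance ``at``; a map with no such edges scores 1.0."""
    angles = edge_orientation_angles(cg, units, ideal_edge_length)
    if not angles:
        return 1.0
    ok = sum(1 for a in angles if abs(a) <= at)
    return ok / len(angles)


# -------------------------------------------------- vectorized angle field
class AngleField:
    """Vectorized per-iteration evaluation of all neighbor deviation angles,
    shared by the rotational-force accumulation and the orientation test."""

    def __init__(self, engine: ForceEngine, units: Sequence[ProcessUnit]):
        self.engine = engine
        self.units = list(units)
        s_epn, s_unit, p_epn, p_unit, e_epn, e_unit = [], [], [], [], [], []
        for ui, u in enumerate(self.units):
            for epn in u.substrates():
                s_epn.append(engine.index[epn.id])
                s_unit.append(ui)
            for epn in u.products():
                p_epn.append(engine.index[epn.id])
                p_unit.append(ui)
            for epn in u.effectors():
                e_epn.append(engine.index[epn.id])
                e_unit.append(ui)
        self.s_epn = np.array(s_epn, dtype=int)
        self.s_unit = np.array(s_unit, dtype=int)
        self.p_epn = np.array(p_epn, dtype=int)
        self.p_unit = np.array(p_unit, dtype=int)
        self.e_epn = np.array(e_epn, dtype=int)
        self.e_unit = np.array(e_unit, dtype=int)
        self.n_units = len(self.units)

    def axes(self) -> np.ndarray:
        return np.array([u.axis() for u in self.units]) \
            if self.units else np.zeros((0, 2))

    def compute(self, ideal_edge_length: float
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (angles, owning-unit indices) over all process edges."""
        eng = self.engine
        axes = self.axes()
        out_ang, out_unit = [], []
        if len(self.s_epn):
            conn = eng.pos[eng.u_pin][self.s_unit]
            d = -axes[self.s_unit]
            ang = _signed_angles_vec(eng.pos[self.s_epn] - conn, d)
            out_ang.append(ang)
            out_unit.append(self.s_unit)
        if len(self.p_epn):
            conn = eng.pos[eng.u_pout][self.p_unit]
            d = axes[self.p_unit]
            ang = _signed_angles_vec(eng.pos[self.p_epn] - conn, d)
            out_ang.append(ang)
            out_unit.append(self.p_unit)
        if len(self.e_epn):
            conn = eng.pos[eng.u_proc][self.e_unit]
            perp = np.stack([-axes[self.e_unit, 1], axes[self.e_unit, 0]],
                            axis=1)
            a0 = conn + perp * ideal_edge_length
            a1 = conn - perp * ideal_edge_length
            epn = eng.pos[self.e_epn]
            d0 = ((epn - a0) ** 2).sum(axis=1)
            d1 = ((epn - a1) ** 2).sum(axis=1)
            anchor = np.where((d0 <= d1)[:, None], a0, a1)
            ang = _signed_angles_vec(epn - conn, anchor - conn)
            out_ang.append(ang)
            out_unit.append(self.e_unit)
        if not out_ang:
            return np.zeros(0), np.zeros(0, dtype=int)
        return np.concatenate(out_ang), np.concatenate(out_unit)


@dataclass
class Phase2Result:
    iterations: int
    rotation_count: int
    swap_count: int
    final_ratio: float


def run_phase2(cg: CompoundGraph, units: Sequence[ProcessUnit],
               params: LayoutParams, rng: random.Random,
               engine: Optional[ForceEngine] = None) -> Phase2Result:
    """SBGN phase: cooled force iterations starting from ``ccool`` with
    rotational-force accumulation, one rotation/swap per ``rp``-iteration
    window, and the gathering heuristic every ``ap`` iterations.  Stops when
    movement has converged and every process edge is properly oriented, or
    after ``max_iter`` iterations."""
    units = list(units)
    if engine is None:
        engine = ForceEngine(cg, params, units)
    afield = AngleField(engine, units)
    accs = [RotationAccumulator() for _ in units]
    acc_sum = np.zeros(len(units))
    acc_cnt = np.zeros(len(units), dtype=int)
    acc_obt = np.zeros(len(units), dtype=int)
    rotations = swaps = 0
    engine.state.last_max_displacement = math.inf
    t = 0
    while t < params.max_iter:
        t += 1
        if params.ap > 0 and t % params.ap == 0:
            approximate_locations(cg, units, params, rng)
            engine.read_geometry()
        if engine.state.last_max_displacement < params.convergence_threshold:
            ang, _ = afield.compute(params.ideal_edge_length)
            if len(ang) == 0 or np.abs(ang).max() <= params.at:
                break
        cg.update_bounds()
        engine.read_geometry()
        engine.calc_spring_forces()
        engine.calc_repulsion_forces()
        engine.calc_gravitational_forces()
        ang, owner = afield.compute(params.ideal_edge_length)
        if len(ang):
            np.add.at(acc_sum, owner, ang)
            np.add.at(acc_cnt, owner, 1)
            np.add.at(acc_obt, owner, (np.abs(ang) > 90.0).astype(int))
        engine.transfer_unit_forces()
        if params.rp > 0 and t % params.rp == 0 and units:
            for i, acc in enumerate(accs):
                acc.signed_sum = float(acc_sum[i])
                acc.samples = int(acc_cnt[i])
                acc.obtuse = int(acc_obt[i])
            applied = select_and_apply_rotation(cg, units, accs, params, rng)
            acc_sum[:] = 0.0
            acc_cnt[:] = 0
            acc_obt[:] = 0
            if applied is not None:
                if applied[1] is RotationAction.SWAP_180:
                    swaps += 1
                else:
                    rotations += 1
                engine.read_geometry()
        engine.move_nodes(cooling_at(params, params.ccool, t,
                                     params.max_iter))
    cg.update_bounds()
    ratio = properly_oriented_ratio(cg, units, params.at,
                                    params.ideal_edge_length)
    return Phase2Result(iterations=t, rotation_count=rotations,
                        swap_count=swaps, final_ratio=ratio)
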