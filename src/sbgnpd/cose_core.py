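"""Generic compound spring embedder (phase 1).

Force scheme: linear (Hooke) springs on adjacency edges, inverse-square
repulsion between sibling entities of each nesting level, and a
constant-magnitude gravitational pull toward the center of the owning
graph's bounds.  A compound node and its nested graph move as one entity (a
"cart"): the compound's own displacement is propagated to every descendant.

SBGN dummy machinery is honored here: rigid edges exert no spring force, a
process and its own ports do not repel each other, and process/port nodes
feel no gravity.  Ports are re-pinned to their process after every movement.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .compound_graph import CompoundGraph, EdgeKind, Node, NodeKind


@dataclass
class LayoutParams:
    """Tunable constants of the two-phase layout.

    Angles are degrees, lengths are layout units.  ``ad`` (approximation
    distance), ``ap`` (approximation period), ``rp`` (rotation period),
    ``c90`` (90-degree rotation force threshold, average degrees per
    neighbor sample), ``c180`` (obtuse-majority ratio) and ``ip1`` (phase-1
    iteration cap) carry the published defaults.
    """

    #: rest length of edge springs; sized so that two typical EPN glyphs
    #: (40-70 units wide) per process side fit inside the angle-tolerance
    #: cone without overlapping
    ideal_edge_length: float = 70.0
    spring_constant: float = 0.45
    repulsion_constant: float = 4500.0
    gravity_constant: float = 0.8
    #: "linear" anneals the cooling factor to zero across the iteration
    #: budget (the spring embedder freezes); "multiplicative" decays by
    #: ``cooling_factor`` per iteration down to ``cooling_floor``.
    cooling_schedule: str = "linear"
    cooling_factor: float = 0.99
    cooling_floor: float = 0.05
    initial_cooling: float = 1.0
    max_displacement: float = 100.0
    convergence_threshold: float = 1.0
    ip1: int = 200
    ccool: float = 0.3
    at: float = 45.0
    ad: float = 50.0
    ap: int = 211
    rp: int = 2
    c90: float = 70.0
    c180: float = 0.5
    max_iter: int = 1000
    port_gap: float = 2.0
    overlap_force: float = 25.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "LayoutParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class ForceState:
    """Instrumentation of the iterative solver."""

    iterations: int = 0
    pair_evals: int = 0
    edge_evals: int = 0
    last_max_displacement: float = math.inf


class ForceEngine:
    """Vectorized force evaluation and movement over a compound graph.

    The node rects remain the source of truth: geometry is read from them at
    the start of each iteration and written back after movement, so code
    operating on the object model between iterations (rotations, gathering
    teleports) composes transparently.
    """

    def __init__(self, cg: CompoundGraph, params: LayoutParams,
                 units: Sequence = ()) -> None:
        self.cg = cg
        self.params = params
        self.units = list(units)
        self.state = ForceState()

        self.nodes: list[Node] = list(cg.iter_nodes())
        self.index = {n.id: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.pos = np.zeros((n, 2))
        self.half = np.zeros((n, 2))
        self.forces = np.zeros((n, 2))

        kinds = [nd.kind for nd in self.nodes]
        self.gravity_exempt = np.array(
            [k in (NodeKind.PROCESS, NodeKind.PORT) for k in kinds])
        self.own_movable = np.array(
            [not nd.fixed and nd.kind is not NodeKind.PORT
             for nd in self.nodes])

        # sibling groups (used for gravity): (member indices, parent or -1)
        self.groups: list[tuple[np.ndarray, int]] = []
        for graph in cg.graphs():
            members = graph.nodes
            if not members:
                continue
            if all(m.fixed for m in members):
                continue  # packed complex: members are rigid decoration
            gidx = np.array([self.index[m.id] for m in members])
            pidx = self.index[graph.parent.id] if graph.parent else -1
            self.groups.append((gidx, pidx))

        # repulsion entities: every movable leaf plus packed/empty
        # compounds treated as wholes; a process and its own ports excluded
        # pairwise per the dummy-machinery rules
        def is_entity(nd: Node) -> bool:
            if nd.fixed:
                return False
            if not nd.is_compound:
                return True
            kids = nd.child.nodes
            return not kids or all(c.fixed for c in kids)

        self.entities = np.array([self.index[nd.id] for nd in self.nodes
                                  if is_entity(nd)], dtype=int)
        ent_local = {gi: j for j, gi in enumerate(self.entities)}
        excl_pairs = []
        for u in self.units:
            pj = ent_local.get(self.index[u.process.id])
            for port in (u.input_port, u.output_port):
                qj = ent_local.get(self.index[port.id])
                if pj is not None and qj is not None:
                    excl_pairs.append((pj, qj))
        self.repulsion_excl = np.array(excl_pairs, dtype=int) \
            if excl_pairs else None

        # edges with spring forces
        src, tgt = [], []
        for e in cg.edges:
            if e.kind is EdgeKind.RIGID:
                continue
            src.append(self.index[e.source.id])
            tgt.append(self.index[e.target.id])
        self.e_src = np.array(src, dtype=int)
        self.e_tgt = np.array(tgt, dtype=int)

        # compounds in top-down order for cart displacement propagation
        self.compound_children: list[tuple[int, np.ndarray]] = []
        for comp in cg.compounds():
            if not comp.child.nodes:
                continue
            ci = self.index[comp.id]
            kids = np.array([self.index[c.id] for c in comp.child.nodes])
            self.compound_children.append((ci, kids))

        # process units: (process, in port, out port, container) indices
        self.u_proc = np.array([self.index[u.process.id] for u in self.units],
                               dtype=int)
        self.u_pin = np.array([self.index[u.input_port.id]
                               for u in self.units], dtype=int)
        self.u_pout = np.array([self.index[u.output_port.id]
                                for u in self.units], dtype=int)
        self.u_cont = np.array([self.index[u.container.id]
                                for u in self.units], dtype=int)

    # ------------------------------------------------------------------ sync
    def read_geometry(self) -> None:
        for i, nd in enumerate(self.nodes):
            r = nd.rect
            self.pos[i, 0] = r.x + r.width / 2.0
            self.pos[i, 1] = r.y + r.height / 2.0
            self.half[i, 0] = r.width / 2.0
            self.half[i, 1] = r.height / 2.0

    def write_geometry(self) -> None:
        for i, nd in enumerate(self.nodes):
            nd.rect.set_center(self.pos[i, 0], self.pos[i, 1])

    # ---------------------------------------------------------------- forces
    def calc_spring_forces(self) -> None:
        if len(self.e_src) == 0:
            return
        p = self.params
        d = self.pos[self.e_tgt] - self.pos[self.e_src]
        dist = np.sqrt((d * d).sum(axis=1))
        dist = np.maximum(dist, 1e-9)
        mag = p.spring_constant * (dist - p.ideal_edge_length)
        f = d / dist[:, None] * mag[:, None]
        np.add.at(self.forces, self.e_src, f)
        np.add.at(self.forces, self.e_tgt, -f)
        self.state.edge_evals += len(self.e_src)

    def calc_repulsion_forces(self) -> None:
        p = self.params
        gidx = self.entities
        n = len(gidx)
        if n < 2:
            return
        pts = self.pos[gidx]
        hf = self.half[gidx]
        diff = pts[:, None, :] - pts[None, :, :]   # vector j -> i
        dist2 = (diff * diff).sum(axis=2)
        np.fill_diagonal(dist2, np.inf)
        dist = np.sqrt(dist2)
        # rect overlap test on center distance vs summed half extents
        sumh = hf[:, None, :] + hf[None, :, :]
        overlap = (np.abs(diff) < sumh).all(axis=2)
        np.fill_diagonal(overlap, False)
        mag = p.repulsion_constant / np.maximum(dist2, 1e-6)
        mag = np.where(overlap, p.overlap_force, mag)
        safe = np.maximum(dist, 1e-9)
        dirs = diff / safe[:, :, None]
        # coincident centers: deterministic separating direction
        coincident = dist < 1e-9
        if coincident.any():
            ii, jj = np.nonzero(coincident)
            dirs[ii, jj, 0] = np.sign(ii - jj)
            dirs[ii, jj, 1] = 0.0
        if self.repulsion_excl is not None:
            a, b = self.repulsion_excl[:, 0], self.repulsion_excl[:, 1]
            mag[a, b] = 0.0
            mag[b, a] = 0.0
        f = (dirs * mag[:, :, None]).sum(axis=1)
        np.add.at(self.forces, gidx, f)
        self.state.pair_evals += n * (n - 1) // 2

    def calc_gravitational_forces(self) -> None:
        p = self.params
        root_center = None
        for gidx, pidx in self.groups:
            if pidx >= 0:
                center = self.pos[pidx]
            else:
                if root_center is None:
                    lo = (self.pos[gidx] - self.half[gidx]).min(axis=0)
                    hi = (self.pos[gidx] + self.half[gidx]).max(axis=0)
                    root_center = (lo + hi) / 2.0
                center = root_center
            vec = center[None, :] - self.pos[gidx]
            dist = np.sqrt((vec * vec).sum(axis=1))
            mask = (dist > 1e-9) & ~self.gravity_exempt[gidx]
            f = np.zeros_like(vec)
            nz = np.nonzero(mask)[0]
            f[nz] = vec[nz] / dist[nz, None] * p.gravity_constant
            np.add.at(self.forces, gidx, f)

    def transfer_unit_forces(self) -> None:
        """Algorithm-1 transfer: a process unit translates rigidly.

        The forces accumulated on the two ports (and the process itself) are
        shifted to the enclosing container compound, then zeroed.
        """
        if len(self.u_proc) == 0:
            return
        for arr in (self.u_pin, self.u_pout, self.u_proc):
            np.add.at(self.forces, self.u_cont, self.forces[arr])
            self.forces[arr] = 0.0

    # -------------------------------------------------------------- movement
    def move_nodes(self, cooling: float) -> float:
        """Displace nodes by cooled forces (cart semantics); returns the
        maximum total displacement.  Forces are reset afterwards."""
        p = self.params
        disp = self.forces * cooling
        norm = np.sqrt((disp * disp).sum(axis=1))
        over = norm > p.max_displacement
        if over.any():
            disp[over] *= (p.max_displacement / norm[over])[:, None]
        disp[~self.own_movable] = 0.0
        # cart: children inherit their compound's displacement (top-down)
        for ci, kids in self.compound_children:
            disp[kids] += disp[ci]
        self.pos += disp
        self.forces[:] = 0.0
        self.reimpose_ports()
        self.write_geometry()
        self.state.iterations += 1
        total = np.sqrt((disp * disp).sum(axis=1))
        self.state.last_max_displacement = float(total.max()) if len(total) \
            else 0.0
        return self.state.last_max_displacement

    def reimpose_ports(self) -> None:
        """Pin each port at exactly ±port_offset from its process center
        along the orientation axis."""
        for u in self.units:
            ax, ay = u.axis()
            pi, po = self.index[u.input_port.id], self.index[u.output_port.id]
            pr = self.index[u.process.id]
            self.pos[pi] = self.pos[pr] - np.array([ax, ay]) * u.port_offset
            self.pos[po] = self.pos[pr] + np.array([ax, ay]) * u.port_offset

    # ------------------------------------------------------------- iteration
    def iterate(self, cooling: float) -> float:
        self.cg.update_bounds()
        self.read_geometry()
        self.calc_spring_forces()
        self.calc_repulsion_forces()
        self.calc_gravitational_forces()
        self.transfer_unit_forces()
        return self.move_nodes(cooling)


def scatter_initial(cg: CompoundGraph, params: LayoutParams,
                    rng: random.Random) -> None:
    """Random initial placement in a square sized to the total node area.

    Free leaves are placed independently; a packed compound (all members
    position-fixed) is translated as a rigid unit; other compounds derive
    their bounds from their children afterwards.
    """
    leaves = [n for n in cg.iter_nodes()
              if not n.is_compound and n.kind is not NodeKind.PORT]
    total_area = sum(n.rect.area for n in leaves) or 1.0
    side = 2.0 * math.sqrt(total_area) + params.ideal_edge_length

    def place(node: Node) -> None:
        cx, cy = rng.uniform(0, side), rng.uniform(0, side)
        if node.is_compound:
            dx, dy = cx - node.rect.cx, cy - node.rect.cy
            cg.translate_subtree(node, dx, dy)
        else:
            node.rect.set_center(cx, cy)

    def visit(nodes: list[Node]) -> None:
        for node in nodes:
            if node.fixed or node.kind is NodeKind.PORT:
                continue
            packed = (node.is_compound and node.child.nodes
                      and all(c.fixed for c in node.child.nodes))
            if packed:
                place(node)
            elif node.is_compound:
                visit(node.child.nodes)
            else:
                place(node)

    visit(cg.root.nodes)
    cg.update_bounds()


def run_phase1(cg: CompoundGraph, params: LayoutParams,
               units: Sequence = (), engine: Optional[ForceEngine] = None,
               ) -> tuple[int, ForceEngine]:
    """Draft layout: cooled force iterations, at most ``ip1`` of them.

    Stops early once the maximum displacement falls below the convergence
    threshold.  Returns the iteration count and the engine (for reuse and
    instrumentation).
    """
    if engine is None:
        engine = ForceEngine(cg, params, units)
    k = 0
    for k in range(1, params.ip1 + 1):
        cooling = cooling_at(params, params.initial_cooling, k, params.ip1)
        maxdisp = engine.iterate(cooling)
        if maxdisp < params.convergence_threshold:
            break
    cg.update_bounds()
    return k, engine


def cooling_at(params: LayoutParams, initial: float, t: int,
               cap: int) -> float:
    """Cooling factor at iteration ``t`` of a phase with budget ``cap``."""
    if params.cooling_schedule == "linear":
        return initial * max(0.0, 1.0 - (t - 1) / max(cap, 1))
    return max(initial * params.cooling_factor ** (t - 1),
               params.cooling_floor)
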