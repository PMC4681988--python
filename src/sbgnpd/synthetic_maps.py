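"""Seeded generators of SBGN-PD-structured maps and rectangle sets.

A process description map is essentially a bipartite compound graph:
entity pool nodes (EPNs) connect only to process nodes, molecular complexes
contain degree-0 members, and cellular compartments nest arbitrarily.  The
generator emulates exactly that structure with controllable counts; it makes
no claim of biological realism (no kinetics, no real pathway topology).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .compound_graph import CompoundGraph, EdgeKind, NodeKind, Rect
from .sbgnml_io import PDMap

_EPN_CHOICES = [
    ("macromolecule", NodeKind.MACROMOLECULE, 0.6),
    ("simple chemical", NodeKind.SIMPLE_CHEMICAL, 0.25),
    ("unspecified entity", NodeKind.UNSPECIFIED, 0.15),
]
_EFFECTOR_CLASSES = ["catalysis", "stimulation", "inhibition", "modulation"]


@dataclass
class MapSpec:
    """Structural parameters of one synthetic PD map."""

    process_count: int = 10
    substrates_per_process: tuple[int, int] = (1, 3)
    products_per_process: tuple[int, int] = (1, 3)
    effectors_per_process: tuple[int, int] = (0, 2)
    complex_count: int = 2
    members_per_complex: tuple[int, int] = (2, 4)
    compartment_count: int = 2
    nesting_depth: int = 2
    epn_sharing_probability: float = 0.15
    #: chance that a complex participates in a reaction as substrate/product
    complex_arc_probability: float = 0.3
    epn_width: tuple[float, float] = (40.0, 70.0)
    epn_height: tuple[float, float] = (25.0, 40.0)
    process_size: float = 20.0
    #: side of the square in which initial coordinates are drawn
    scatter: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("process_count", "complex_count", "compartment_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.epn_sharing_probability <= 1.0:
            raise ValueError("epn_sharing_probability must be in [0, 1]")
        if self.epn_sharing_probability >= 1.0 and self.process_count <= 1:
            raise ValueError(
                "EPN sharing demands at least two processes")


def spec_for_node_count(n: int, seed: int = 0, simple: bool = False,
                        **overrides) -> MapSpec:
    """Size a :class:`MapSpec` so the generated map has roughly ``n`` nodes.

    With ``simple=True`` the map has no compound structures (no complexes,
    no compartments) — the regime where orientation success is highest.
    """
    spec = MapSpec(seed=seed, **overrides)
    if simple:
        spec.complex_count = 0
        spec.compartment_count = 0
    # expected nodes per process: itself + fresh substrate/product/effector
    s = sum(spec.substrates_per_process) / 2.0
    p = sum(spec.products_per_process) / 2.0
    e = sum(spec.effectors_per_process) / 2.0
    fresh = (s + p + e) * (1.0 - spec.epn_sharing_probability)
    per_process = 1.0 + fresh
    overhead = spec.compartment_count + spec.complex_count * (
        1.0 + sum(spec.members_per_complex) / 2.0)
    spec.process_count = max(1, round((n - overhead) / per_process))
    return spec


def generate_pd_map(spec: MapSpec) -> PDMap:
    """Build a random PD map: bipartite EPN-process connectivity, every
    process with at least one substrate and one product, complexes holding
    scattered degree-0 members, compartments nested to the requested depth.
    Deterministic for a fixed seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    pd = PDMap()
    cg = pd.graph
    counter = {"e": 0, "a": 0}

    def epn_rect() -> Rect:
        w = rng.uniform(*spec.epn_width)
        h = rng.uniform(*spec.epn_height)
        x = rng.uniform(0, spec.scatter)
        y = rng.uniform(0, spec.scatter)
        return Rect(x, y, w, h)

    def new_epn(parent, prefix: str = "e"):
        r = rng.random()
        acc = 0.0
        cls, kind = _EPN_CHOICES[-1][:2]
        for c, k, w in _EPN_CHOICES:
            acc += w
            if r < acc:
                cls, kind = c, k
                break
        nid = f"{prefix}{counter['e']}"
        counter["e"] += 1
        node = cg.add_node(nid, kind, epn_rect(), parent=parent)
        pd.glyph_class_by_id[nid] = cls
        return node

    def new_arc(u, v, cls: str, kind: EdgeKind):
        aid = f"a{counter['a']}"
        counter["a"] += 1
        cg.add_edge(aid, u, v, kind)
        pd.arc_class_by_id[aid] = cls

    # compartments, nested up to the requested depth
    compartments: list[tuple[object, int]] = []   # (node, depth)
    for i in range(spec.compartment_count):
        parents = [(None, 0)] + [(n, d) for n, d in compartments
                                 if d + 1 < spec.nesting_depth]
        parent, depth = parents[rng.randrange(len(parents))]
        node = cg.add_node(f"comp{i}", NodeKind.COMPARTMENT,
                           Rect(rng.uniform(0, spec.scatter),
                                rng.uniform(0, spec.scatter), 200, 200),
                           parent=parent)
        pd.glyph_class_by_id[node.id] = "compartment"
        compartments.append((node, depth + 1))

    comp_nodes = [n for n, _ in compartments]

    def random_container():
        if comp_nodes and rng.random() < 0.7:
            return comp_nodes[rng.randrange(len(comp_nodes))]
        return None

    # processes with their neighborhoods
    processes = []
    epn_pool: list = []
    for i in range(spec.process_count):
        parent = random_container()
        s = spec.process_size
        proc = cg.add_node(f"p{i}", NodeKind.PROCESS,
                           Rect(rng.uniform(0, spec.scatter),
                                rng.uniform(0, spec.scatter), s, s),
                           parent=parent)
        pd.glyph_class_by_id[proc.id] = "process"
        processes.append(proc)

        def pick_neighbor():
            candidates = [n for n in epn_pool
                          if not any(e.other(n) is proc for e in n.edges)]
            if candidates and rng.random() < spec.epn_sharing_probability:
                return candidates[rng.randrange(len(candidates))]
            node = new_epn(parent)
            epn_pool.append(node)
            return node

        n_s = max(1, rng.randint(*spec.substrates_per_process))
        n_p = max(1, rng.randint(*spec.products_per_process))
        n_e = rng.randint(*spec.effectors_per_process)
        for _ in range(n_s):
            new_arc(pick_neighbor(), proc, "consumption",
                    EdgeKind.CONSUMPTION)
        for _ in range(n_p):
            new_arc(proc, pick_neighbor(), "production", EdgeKind.PRODUCTION)
        for _ in range(n_e):
            cls = _EFFECTOR_CLASSES[rng.randrange(len(_EFFECTOR_CLASSES))]
            new_arc(pick_neighbor(), proc, cls, EdgeKind.EFFECTOR)

    # molecular complexes with scattered degree-0 members
    for i in range(spec.complex_count):
        parent = random_container()
        cx = cg.add_node(f"cx{i}", NodeKind.COMPLEX,
                         Rect(rng.uniform(0, spec.scatter),
                              rng.uniform(0, spec.scatter), 300, 300),
                         parent=parent)
        pd.glyph_class_by_id[cx.id] = "complex"
        for j in range(rng.randint(*spec.members_per_complex)):
            member = new_epn(cx, prefix=f"cx{i}m")
            # scatter members over a wide area inside the complex
            member.rect.x = cx.rect.x + rng.uniform(0, 250)
            member.rect.y = cx.rect.y + rng.uniform(0, 250)
        if rng.random() < 0.25:   # complexes may nest recursively
            sub = cg.add_node(f"cx{i}s", NodeKind.COMPLEX,
                              Rect(cx.rect.x + rng.uniform(0, 250),
                                   cx.rect.y + rng.uniform(0, 250), 80, 80),
                              parent=cx)
            pd.glyph_class_by_id[sub.id] = "complex"
            for _ in range(2):
                m = new_epn(sub, prefix=f"cx{i}s_m")
                m.rect.x = sub.rect.x + rng.uniform(0, 100)
                m.rect.y = sub.rect.y + rng.uniform(0, 100)
        if processes and rng.random() < spec.complex_arc_probability:
            proc = processes[rng.randrange(len(processes))]
            if rng.random() < 0.5:
                new_arc(cx, proc, "consumption", EdgeKind.CONSUMPTION)
            else:
                new_arc(proc, cx, "production", EdgeKind.PRODUCTION)

    cg.update_bounds()
    return pd


def generate_rect_set(n: int, width_range: tuple[float, float],
                      height_range: tuple[float, float],
                      seed: int = 0) -> list[tuple[float, float]]:
    """n rectangle dimensions sampled uniformly from the given ranges."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    return [(rng.uniform(*width_range), rng.uniform(*height_range))
            for _ in range(n)]
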