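"""Compound (nested) graph model for SBGN process description maps.

A compound graph C = (V, E, F) consists of nodes V, adjacency edges E and
inclusion edges F.  Inclusion is represented here by each compound node
owning a child :class:`Graph`; the inclusion edge set F is implicit (one
edge per parented node) and is required to form a forest.

Geometry uses the screen convention of SBGN-ML: a rectangle is stored as its
top-left corner plus extent, and y grows downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

#: Default margin (layout units) added around a compound's children.
DEFAULT_COMPOUND_MARGIN = 10.0
#: Minimum extent of a compound whose child graph is empty.
DEFAULT_MIN_COMPOUND_SIZE = 20.0


class NodeKind(Enum):
    MACROMOLECULE = "macromolecule"
    SIMPLE_CHEMICAL = "simple chemical"
    COMPLEX = "complex"
    COMPARTMENT = "compartment"
    UNSPECIFIED = "unspecified entity"
    PROCESS = "process"
    # Dummy kinds used internally by the layout; never serialized.
    PORT = "port"
    PROCESS_CONTAINER = "process container"


#: Kinds that own a child graph.
COMPOUND_KINDS = frozenset(
    {NodeKind.COMPLEX, NodeKind.COMPARTMENT, NodeKind.PROCESS_CONTAINER}
)
#: Entity pool node kinds (molecular species glyphs).
EPN_KINDS = frozenset(
    {NodeKind.MACROMOLECULE, NodeKind.SIMPLE_CHEMICAL, NodeKind.COMPLEX,
     NodeKind.UNSPECIFIED}
)
DUMMY_KINDS = frozenset({NodeKind.PORT, NodeKind.PROCESS_CONTAINER})


class EdgeKind(Enum):
    CONSUMPTION = "consumption"
    PRODUCTION = "production"
    EFFECTOR = "effector"
    RIGID = "rigid"
    OTHER = "other"


@dataclass
class Point:
    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass
class Rect:
    """Axis-aligned rectangle, (x, y) top-left corner, y growing downward."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError("rectangle extent must be non-negative")

    @property
    def cx(self) -> float:
        return self.x + self.width / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.height / 2.0

    @property
    def center(self) -> Point:
        return Point(self.cx, self.cy)

    @property
    def right(self) -> float:
        return self.x + self.width

    @property
    def bottom(self) -> float:
        return self.y + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def set_center(self, x: float, y: float) -> None:
        self.x = x - self.width / 2.0
        self.y = y - self.height / 2.0

    def translate(self, dx: float, dy: float) -> None:
        self.x += dx
        self.y += dy

    def contains(self, other: "Rect", tol: float = 1e-6) -> bool:
        return (
            self.x - tol <= other.x
            and self.y - tol <= other.y
            and other.right <= self.right + tol
            and other.bottom <= self.bottom + tol
        )

    def overlaps(self, other: "Rect", tol: float = 1e-9) -> bool:
        """Interior overlap; boundaries touching (within ``tol``) do not
        count."""
        return (
            self.x + tol < other.right
            and other.x + tol < self.right
            and self.y + tol < other.bottom
            and other.y + tol < self.bottom
        )

    def copy(self) -> "Rect":
        return Rect(self.x, self.y, self.width, self.height)


class Graph:
    """One nesting level: the child graph of a compound node (or the root)."""

    __slots__ = ("parent", "nodes")

    def __init__(self, parent: Optional["Node"] = None) -> None:
        self.parent = parent
        self.nodes: list[Node] = []


class Node:
    __slots__ = ("id", "kind", "rect", "owner", "child", "edges", "fixed",
                 "margin", "label")

    def __init__(self, node_id: str, kind: NodeKind, rect: Rect) -> None:
        self.id = node_id
        self.kind = kind
        self.rect = rect
        self.owner: Optional[Graph] = None
        self.child: Optional[Graph] = None
        self.edges: list[Edge] = []
        #: Packed complex members are position-fixed relative to their parent.
        self.fixed = False
        self.margin: Optional[float] = None  # per-node override
        self.label: Optional[str] = None

    @property
    def is_compound(self) -> bool:
        return self.child is not None

    @property
    def parent_node(self) -> Optional["Node"]:
        return self.owner.parent if self.owner is not None else None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id!r}, {self.kind.value})"


class Edge:
    __slots__ = ("id", "source", "target", "kind")

    def __init__(self, edge_id: str, source: Node, target: Node,
                 kind: EdgeKind) -> None:
        self.id = edge_id
        self.source = source
        self.target = target
        self.kind = kind

    def other(self, node: Node) -> Node:
        return self.target if node is self.source else self.source

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Edge({self.id!r}, {self.source.id}->{self.target.id}, {self.kind.value})"


class CompoundGraph:
    """Nested graph with geometry.

    ``margin`` is the default padding added around a compound's children when
    its bounds are recomputed; individual nodes may override it.
    """

    def __init__(self, margin: float = DEFAULT_COMPOUND_MARGIN,
                 min_compound_size: float = DEFAULT_MIN_COMPOUND_SIZE) -> None:
        self.root = Graph()
        self.nodes: dict[str, Node] = {}
        self.edges: list[Edge] = []
        self.margin = margin
        self.min_compound_size = min_compound_size
        self._edge_ids: set[str] = set()

    # ------------------------------------------------------------------ build
    def add_node(self, node_id: str, kind: NodeKind, rect: Rect,
                 parent: Optional[Node] = None) -> Node:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        node = Node(node_id, kind, rect)
        if kind in COMPOUND_KINDS:
            node.child = Graph(parent=node)
        if parent is None:
            graph = self.root
        else:
            if parent.id not in self.nodes:
                raise ValueError(f"parent {parent.id!r} not in map")
            if not parent.is_compound:
                raise ValueError(f"parent {parent.id!r} is not a compound node")
            graph = parent.child
        node.owner = graph
        graph.nodes.append(node)
        self.nodes[node_id] = node
        return node

    def add_edge(self, edge_id: str, u: Node, v: Node, kind: EdgeKind) -> Edge:
        if edge_id in self._edge_ids:
            raise ValueError(f"duplicate edge id {edge_id!r}")
        if u is v:
            raise ValueError("self-loops are not allowed")
        for n in (u, v):
            if self.nodes.get(n.id) is not n:
                raise ValueError(f"endpoint {n.id!r} not in map")
        edge = Edge(edge_id, u, v, kind)
        self.edges.append(edge)
        self._edge_ids.add(edge_id)
        u.edges.append(edge)
        v.edges.append(edge)
        return edge

    def remove_edge(self, edge: Edge) -> None:
        self.edges.remove(edge)
        self._edge_ids.discard(edge.id)
        edge.source.edges.remove(edge)
        edge.target.edges.remove(edge)

    def remove_node(self, node: Node) -> None:
        """Remove a leaf node (no child graph members, no incident edges)."""
        if node.child is not None and node.child.nodes:
            raise ValueError("cannot remove a compound with children")
        if node.edges:
            raise ValueError("cannot remove a node with incident edges")
        node.owner.nodes.remove(node)
        del self.nodes[node.id]

    def reparent(self, node: Node, parent: Optional[Node]) -> None:
        """Move ``node`` (with its subtree) into another compound's graph."""
        target = self.root if parent is None else parent.child
        if target is None:
            raise ValueError("new parent is not a compound node")
        # forest check: node must not be an ancestor of parent
        anc = parent
        while anc is not None:
            if anc is node:
                raise ValueError("reparenting would create an inclusion cycle")
            anc = anc.parent_node
        node.owner.nodes.remove(node)
        node.owner = target
        target.nodes.append(node)

    # ------------------------------------------------------------- structure
    def degree(self, node: Node) -> int:
        """SBGN-role degree: rigid (dummy) edges are invisible to heuristics."""
        return sum(1 for e in node.edges if e.kind is not EdgeKind.RIGID)

    def iter_nodes(self, graph: Optional[Graph] = None) -> Iterator[Node]:
        """All nodes, depth-first in insertion order."""
        graph = graph or self.root
        for node in graph.nodes:
            yield node
            if node.child is not None:
                yield from self.iter_nodes(node.child)

    def compounds(self) -> Iterator[Node]:
        for node in self.iter_nodes():
            if node.is_compound:
                yield node

    def graphs(self) -> Iterator[Graph]:
        yield self.root
        for node in self.compounds():
            yield node.child

    def inclusion_edge_count(self) -> int:
        """|F| — one inclusion edge per node living inside some compound."""
        return sum(1 for n in self.iter_nodes() if n.owner is not self.root)

    def check_forest(self) -> bool:
        """Verify the inclusion structure is a forest rooted at the root graph."""
        seen: set[int] = set()
        for node in self.nodes.values():
            anc = node.parent_node
            hops = 0
            while anc is not None:
                if anc is node or hops > len(self.nodes):
                    return False
                anc = anc.parent_node
                hops += 1
            seen.add(id(node))
        # every node reachable from the root exactly once
        reachable = [id(n) for n in self.iter_nodes()]
        return len(reachable) == len(self.nodes) and set(reachable) == seen

    # -------------------------------------------------------------- geometry
    def _margin_of(self, node: Node) -> float:
        return self.margin if node.margin is None else node.margin

    def update_bounds(self, compound: Optional[Node] = None) -> Optional[Rect]:
        """Recursively resize compounds to fit their children plus margin.

        With no argument, every compound in the map is updated bottom-up and
        the tight bounds of the root graph are returned (``None`` for an
        empty map).  An empty child graph keeps the compound centered at its
        current position with the configured minimum size.
        """
        if compound is None:
            for top in self.root.nodes:
                if top.is_compound:
                    self.update_bounds(top)
            return self.graph_bounds(self.root)
        if compound.child is None:
            raise ValueError(f"{compound.id!r} is not a compound node")
        for child in compound.child.nodes:
            if child.is_compound:
                self.update_bounds(child)
        bounds = self.graph_bounds(compound.child)
        m = self._margin_of(compound)
        if bounds is None:
            s = self.min_compound_size
            compound.rect = Rect(compound.rect.cx - s / 2,
                                 compound.rect.cy - s / 2, s, s)
        else:
            compound.rect = Rect(bounds.x - m, bounds.y - m,
                                 bounds.width + 2 * m, bounds.height + 2 * m)
        return compound.rect

    @staticmethod
    def graph_bounds(graph: Graph) -> Optional[Rect]:
        if not graph.nodes:
            return None
        x0 = min(n.rect.x for n in graph.nodes)
        y0 = min(n.rect.y for n in graph.nodes)
        x1 = max(n.rect.right for n in graph.nodes)
        y1 = max(n.rect.bottom for n in graph.nodes)
        return Rect(x0, y0, x1 - x0, y1 - y0)

    def translate_subtree(self, node: Node, dx: float, dy: float) -> None:
        node.rect.translate(dx, dy)
        if node.child is not None:
            for c in node.child.nodes:
                self.translate_subtree(c, dx, dy)

    def all_finite(self) -> bool:
        return all(
            math.isfinite(v)
            for n in self.nodes.values()
            for v in (n.rect.x, n.rect.y, n.rect.width, n.rect.height)
        )

    def containment_ok(self, tol: float = 1e-6) -> bool:
        """Every node's rect inside its parent compound's rect, all levels."""
        for node in self.nodes.values():
            parent = node.parent_node
            if parent is not None and not parent.rect.contains(node.rect, tol):
                return False
        return True
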