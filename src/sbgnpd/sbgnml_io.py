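"""SBGN-ML (process description) reading and writing.

Maps the 0.2 dialect (http://sbgn.org/libsbgn/0.2) onto the internal
compound-graph model: compartments and complexes become compound nodes
(explicit glyph nesting wins over ``compartmentRef`` when both are present),
arcs become typed edges, and process ``<port>`` declarations are re-anchored
to the owning process node internally while their ids are preserved for
output.  The writer is canonical: a fixed attribute order and number format
make write→read→write byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Optional, Union

from lxml import etree

from .compound_graph import (
    CompoundGraph,
    Edge,
    EdgeKind,
    Node,
    NodeKind,
    Rect,
)

logger = logging.getLogger(__name__)

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
PD_LANGUAGE = "process description"

#: Default extent used when a glyph carries no bbox.
DEFAULT_GLYPH_SIZE = (40.0, 40.0)

GLYPH_CLASS_TO_KIND = {
    "macromolecule": NodeKind.MACROMOLECULE,
    "simple chemical": NodeKind.SIMPLE_CHEMICAL,
    "complex": NodeKind.COMPLEX,
    "compartment": NodeKind.COMPARTMENT,
    "unspecified entity": NodeKind.UNSPECIFIED,
    "nucleic acid feature": NodeKind.MACROMOLECULE,
    "perturbing agent": NodeKind.UNSPECIFIED,
    "process": NodeKind.PROCESS,
    "omitted process": NodeKind.PROCESS,
    "uncertain process": NodeKind.PROCESS,
    "association": NodeKind.PROCESS,
    "dissociation": NodeKind.PROCESS,
}

ARC_CLASS_TO_KIND = {
    "consumption": EdgeKind.CONSUMPTION,
    "production": EdgeKind.PRODUCTION,
    "catalysis": EdgeKind.EFFECTOR,
    "stimulation": EdgeKind.EFFECTOR,
    "inhibition": EdgeKind.EFFECTOR,
    "modulation": EdgeKind.EFFECTOR,
    "necessary stimulation": EdgeKind.EFFECTOR,
}

KIND_TO_GLYPH_CLASS = {
    NodeKind.MACROMOLECULE: "macromolecule",
    NodeKind.SIMPLE_CHEMICAL: "simple chemical",
    NodeKind.COMPLEX: "complex",
    NodeKind.COMPARTMENT: "compartment",
    NodeKind.UNSPECIFIED: "unspecified entity",
    NodeKind.PROCESS: "process",
}


@dataclass
class PortInfo:
    """Serialized port ids and coordinates of one process glyph."""

    in_id: str
    out_id: str
    in_xy: tuple[float, float]
    out_xy: tuple[float, float]


@dataclass
class PDMap:
    """A compound graph annotated with SBGN glyph/arc classes."""

    graph: CompoundGraph = field(default_factory=CompoundGraph)
    glyph_class_by_id: dict[str, str] = field(default_factory=dict)
    arc_class_by_id: dict[str, str] = field(default_factory=dict)
    #: original arc endpoint reference strings (may name ports)
    arc_refs: dict[str, tuple[str, str]] = field(default_factory=dict)
    ports: dict[str, PortInfo] = field(default_factory=dict)
    language: str = PD_LANGUAGE

    def processes(self) -> list[Node]:
        return [n for n in self.graph.iter_nodes()
                if n.kind is NodeKind.PROCESS]

    def port_info(self, process: Node) -> PortInfo:
        """Port record for a process, synthesizing defaults when absent."""
        info = self.ports.get(process.id)
        if info is None:
            r = process.rect
            info = PortInfo(
                in_id=f"{process.id}.1",
                out_id=f"{process.id}.2",
                in_xy=(r.x, r.cy),
                out_xy=(r.right, r.cy),
            )
            self.ports[process.id] = info
        return info


class SBGNReadError(ValueError):
    pass


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _fmt(v: float) -> str:
    # fixed two-decimal format; format(parse(format(x))) == format(x)
    return f"{float(v):.2f}"


# ---------------------------------------------------------------------- read
def read_map(source: Union[str, bytes, IO[bytes]]) -> PDMap:
    """Parse an SBGN-ML PD document into a :class:`PDMap`.

    ``source`` may be a filename, raw bytes, or a binary file object.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()
    map_el = None
    for el in root.iter():
        if _local(el.tag) == "map":
            map_el = el
            break
    if map_el is None:
        raise SBGNReadError("document contains no <map> element")
    language = map_el.get("language", "")
    if language != PD_LANGUAGE:
        raise SBGNReadError(
            f"unsupported map language {language!r}; expected {PD_LANGUAGE!r}")

    pd = PDMap()
    cg = pd.graph

    # -- glyphs: collect records in document order, then create nodes,
    #    deferring glyphs whose compartmentRef target is not built yet.
    records: list[dict] = []

    def walk_glyph(el, nesting_parent: Optional[str]) -> None:
        gid = el.get("id")
        if gid is None:
            raise SBGNReadError("glyph without id")
        cls = el.get("class", "unspecified entity")
        rec = {
            "id": gid,
            "class": cls,
            "nesting_parent": nesting_parent,
            "compartment_ref": el.get("compartmentRef"),
            "bbox": None,
            "label": None,
            "ports": [],
        }
        records.append(rec)
        for sub in el:
            tag = _local(sub.tag)
            if tag == "bbox":
                rec["bbox"] = tuple(
                    float(sub.get(k)) for k in ("x", "y", "w", "h"))
            elif tag == "label":
                rec["label"] = sub.get("text")
            elif tag == "port":
                rec["ports"].append(
                    (sub.get("id"), float(sub.get("x", "0")),
                     float(sub.get("y", "0"))))
            elif tag == "glyph":
                walk_glyph(sub, gid)

    for el in map_el:
        if _local(el.tag) == "glyph":
            walk_glyph(el, None)

    pending = list(records)
    port_owner: dict[str, str] = {}
    while pending:
        progressed = False
        deferred = []
        for rec in pending:
            parent_id = rec["nesting_parent"] or rec["compartment_ref"]
            if parent_id is not None and parent_id not in cg.nodes:
                deferred.append(rec)
                continue
            kind = GLYPH_CLASS_TO_KIND.get(rec["class"])
            if kind is None:
                logger.warning("unknown glyph class %r mapped to unspecified",
                               rec["class"])
                kind = NodeKind.UNSPECIFIED
            if rec["bbox"] is not None:
                x, y, w, h = rec["bbox"]
                rect = Rect(x, y, w, h)
            else:
                rect = Rect(0.0, 0.0, *DEFAULT_GLYPH_SIZE)
            parent = cg.nodes[parent_id] if parent_id else None
            node = cg.add_node(rec["id"], kind, rect, parent=parent)
            node.label = rec["label"]
            pd.glyph_class_by_id[rec["id"]] = rec["class"]
            if kind is NodeKind.PROCESS and rec["ports"]:
                ps = rec["ports"]
                if len(ps) >= 2:
                    pd.ports[rec["id"]] = PortInfo(
                        in_id=ps[0][0], out_id=ps[1][0],
                        in_xy=(ps[0][1], ps[0][2]),
                        out_xy=(ps[1][1], ps[1][2]))
                for pid, _, _ in ps:
                    port_owner[pid] = rec["id"]
            progressed = True
        pending = deferred
        if pending and not progressed:
            missing = {r["nesting_parent"] or r["compartment_ref"]
                       for r in pending}
            raise SBGNReadError(
                f"unresolvable glyph parent reference(s): {sorted(missing)}")

    # -- arcs
    for el in map_el:
        if _local(el.tag) != "arc":
            continue
        aid = el.get("id")
        cls = el.get("class", "")
        src_ref, tgt_ref = el.get("source"), el.get("target")
        if src_ref is None or tgt_ref is None:
            raise SBGNReadError(f"arc {aid!r} missing source/target")

        def resolve(ref: str) -> Node:
            if ref in cg.nodes:
                return cg.nodes[ref]
            if ref in port_owner:
                return cg.nodes[port_owner[ref]]
            raise SBGNReadError(f"arc {aid!r} references unknown glyph {ref!r}")

        kind = ARC_CLASS_TO_KIND.get(cls)
        if kind is None:
            logger.warning("unknown arc class %r mapped to OTHER", cls)
            kind = EdgeKind.OTHER
        cg.add_edge(aid, resolve(src_ref), resolve(tgt_ref), kind)
        pd.arc_class_by_id[aid] = cls
        pd.arc_refs[aid] = (src_ref, tgt_ref)
    return pd


# --------------------------------------------------------------------- write
def write_map(pd: PDMap, sink: Union[str, IO[bytes], None] = None) -> bytes:
    """Serialize a :class:`PDMap` to SBGN-ML 0.2.

    Dummy port/container nodes and rigid edges are never emitted.  Returns
    the document bytes; ``sink`` may name a file or be a binary file object.
    """
    nsmap = {None: SBGN_NS}
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap=nsmap)
    map_el = etree.SubElement(root, f"{{{SBGN_NS}}}map")
    map_el.set("language", pd.language)

    def glyph_class(node: Node) -> str:
        cls = pd.glyph_class_by_id.get(node.id)
        if cls is None:
            cls = KIND_TO_GLYPH_CLASS.get(node.kind, "unspecified entity")
        return cls

    def emit_glyph(node: Node, container, compartment_ref: Optional[str]):
        el = etree.SubElement(container, f"{{{SBGN_NS}}}glyph")
        el.set("id", node.id)
        el.set("class", glyph_class(node))
        if compartment_ref is not None:
            el.set("compartmentRef", compartment_ref)
        if node.label is not None:
            lab = etree.SubElement(el, f"{{{SBGN_NS}}}label")
            lab.set("text", node.label)
        r = node.rect
        bbox = etree.SubElement(el, f"{{{SBGN_NS}}}bbox")
        for k, v in (("x", r.x), ("y", r.y), ("w", r.width), ("h", r.height)):
            bbox.set(k, _fmt(v))
        if node.kind is NodeKind.PROCESS:
            info = pd.port_info(node)
            for pid, (px, py) in ((info.in_id, info.in_xy),
                                  (info.out_id, info.out_xy)):
                p = etree.SubElement(el, f"{{{SBGN_NS}}}port")
                p.set("id", pid)
                p.set("x", _fmt(px))
                p.set("y", _fmt(py))
        return el

    def emit_level(nodes, xml_parent, compartment_ref: Optional[str]):
        for node in nodes:
            if node.kind in (NodeKind.PORT, NodeKind.PROCESS_CONTAINER):
                continue
            if node.kind is NodeKind.COMPARTMENT:
                emit_glyph(node, xml_parent, compartment_ref)
                # compartment members are siblings in XML, linked by ref
                emit_level(node.child.nodes, xml_parent, node.id)
            elif node.kind is NodeKind.COMPLEX:
                el = emit_glyph(node, xml_parent, compartment_ref)
                emit_level(node.child.nodes, el, None)
            else:
                emit_glyph(node, xml_parent, compartment_ref)

    emit_level(pd.graph.root.nodes, map_el, None)

    for edge in pd.graph.edges:
        if edge.kind is EdgeKind.RIGID:
            continue
        arc = etree.SubElement(map_el, f"{{{SBGN_NS}}}arc")
        arc.set("id", edge.id)
        arc.set("class", pd.arc_class_by_id.get(edge.id,
                                                _default_arc_class(edge)))
        src_ref, tgt_ref = pd.arc_refs.get(edge.id) or _default_refs(pd, edge)
        arc.set("source", src_ref)
        arc.set("target", tgt_ref)
        sx, sy, ex, ey = _arc_anchor_coords(pd, edge, src_ref, tgt_ref)
        start = etree.SubElement(arc, f"{{{SBGN_NS}}}start")
        start.set("x", _fmt(sx))
        start.set("y", _fmt(sy))
        end = etree.SubElement(arc, f"{{{SBGN_NS}}}end")
        end.set("x", _fmt(ex))
        end.set("y", _fmt(ey))

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if isinstance(sink, str):
        with open(sink, "wb") as fh:
            fh.write(data)
    elif sink is not None:
        sink.write(data)
    return data


def _default_arc_class(edge: Edge) -> str:
    return {
        EdgeKind.CONSUMPTION: "consumption",
        EdgeKind.PRODUCTION: "production",
        EdgeKind.EFFECTOR: "modulation",
        EdgeKind.OTHER: "unknown influence",
    }.get(edge.kind, "unknown influence")


def _resolve_dummy_port(node: Node) -> tuple[Node, str]:
    """Owning process and side ('in'/'out') of a dummy PORT node."""
    container = node.owner.parent
    process = next(n for n in container.child.nodes
                   if n.kind is NodeKind.PROCESS)
    ports = [n for n in container.child.nodes if n.kind is NodeKind.PORT]
    side = "in" if ports and node is ports[0] else "out"
    return process, side


def _endpoint_ref(pd: PDMap, node: Node, edge: Edge) -> str:
    if node.kind is NodeKind.PORT:
        process, side = _resolve_dummy_port(node)
        info = pd.port_info(process)
        return info.in_id if side == "in" else info.out_id
    if node.kind is NodeKind.PROCESS:
        if edge.kind is EdgeKind.CONSUMPTION and node is edge.target:
            return pd.port_info(node).in_id
        if edge.kind is EdgeKind.PRODUCTION and node is edge.source:
            return pd.port_info(node).out_id
    return node.id


def _default_refs(pd: PDMap, edge: Edge) -> tuple[str, str]:
    """Endpoint reference strings when none were recorded: consumption arcs
    target the input port, production arcs leave the output port; dummy
    port endpoints resolve to the owning process's serialized port ids."""
    refs = (_endpoint_ref(pd, edge.source, edge),
            _endpoint_ref(pd, edge.target, edge))
    pd.arc_refs[edge.id] = refs
    return refs


def _arc_anchor_coords(pd: PDMap, edge: Edge, src_ref: str,
                       tgt_ref: str) -> tuple[float, float, float, float]:
    # anchors are derived from values quantized to the serialization
    # precision so that a re-serialized document is byte-identical
    def q(v: float) -> float:
        return float(_fmt(v))

    def point(node: Node, ref: str) -> tuple[float, float]:
        if node.kind is NodeKind.PORT:
            node = _resolve_dummy_port(node)[0]
        if node.kind is NodeKind.PROCESS:
            info = pd.port_info(node)
            if ref == info.in_id:
                return (q(info.in_xy[0]), q(info.in_xy[1]))
            if ref == info.out_id:
                return (q(info.out_xy[0]), q(info.out_xy[1]))
        return (q(node.rect.x) + q(node.rect.width) / 2.0,
                q(node.rect.y) + q(node.rect.height) / 2.0)

    sx, sy = point(edge.source, src_ref)
    ex, ey = point(edge.target, tgt_ref)
    return sx, sy, ex, ey


# ------------------------------------------------------------- JSON fixtures
def write_json_map(pd: PDMap, sink: Union[str, IO[str], None] = None) -> str:
    """Minimal JSON fixture format (nodes: id/kind/rect/parent; edges)."""
    nodes = []
    for node in pd.graph.iter_nodes():
        parent = node.parent_node
        nodes.append({
            "id": node.id,
            "kind": node.kind.value,
            "rect": [node.rect.x, node.rect.y, node.rect.width,
                     node.rect.height],
            "parent": parent.id if parent else None,
        })
    edges = [{"id": e.id, "src": e.source.id, "tgt": e.target.id,
              "kind": e.kind.value} for e in pd.graph.edges]
    text = json.dumps({"nodes": nodes, "edges": edges}, indent=1)
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            fh.write(text)
    elif sink is not None:
        sink.write(text)
    return text


def read_json_map(source: Union[str, IO[str]]) -> PDMap:
    if isinstance(source, str):
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
    else:
        data = json.load(source)
    pd = PDMap()
    cg = pd.graph
    for rec in data["nodes"]:
        parent = cg.nodes[rec["parent"]] if rec.get("parent") else None
        node = cg.add_node(rec["id"], NodeKind(rec["kind"]),
                           Rect(*rec["rect"]), parent=parent)
        pd.glyph_class_by_id[node.id] = node.kind.value
    for rec in data["edges"]:
        cg.add_edge(rec["id"], cg.nodes[rec["src"]], cg.nodes[rec["tgt"]],
                    EdgeKind(rec["kind"]))
    return pd
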