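"""Read/write the workflow XML dialect and canonical byte forms.

The dialect nests each node's outgoing hyperedges inside its ``<node>``
element; destination references are child ``<node>`` elements of the edge::

    <graph>
      <node id="A" entrypoint="True">
        <edge id="e1">
          <node id="B"/>
          <node id="C"/>
        </edge>
      </node>
      ...
    </graph>

A ``nonblocking="True"`` attribute on any destination marks the whole
hyperedge asynchronous (the prose semantics: asynchrony is a property of the
edge; the writer places the flag on the first destination).  Optional
``<init name=".." value=".."/>`` children of a top-level node carry initial
values (value text is JSON, falling back to a plain string).
"""

from __future__ import annotations

import json
import re

from lxml import etree

from .model import Hyperedge, ServiceNode, ValidationError, WorkflowGraph, validate_graph

__all__ = [
    "parse_workflow_xml",
    "write_workflow_xml",
    "to_adjacency",
    "from_adjacency",
    "canonical_bytes",
    "graph_to_dict",
    "graph_from_dict",
]

_ID_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_TRUE = {"true", "1"}
_FALSE = {"false", "0"}

# typographic quotes produced by copy-pasting definitions out of documents
_QUOTE_MAP = {0x201C: '"', 0x201D: '"', 0x2018: "'", 0x2019: "'"}


def _parse_bool(raw: str, where: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError([f"{where}: invalid boolean literal {raw!r}"])


def parse_workflow_xml(text: str | bytes) -> WorkflowGraph:
    """Parse a workflow definition into a :class:`WorkflowGraph`.

    Raises :class:`ValidationError` on duplicate node/edge ids, empty edge
    destinations or malformed boolean attributes; malformed XML raises
    ``lxml.etree.XMLSyntaxError``.
    """
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    text = text.translate(_QUOTE_MAP)
    root = etree.fromstring(text.encode("utf-8"))
    if root.tag != "graph":
        raise ValidationError([f"root element must be <graph>, got <{root.tag}>"])

    nodes: list[ServiceNode] = []
    edges: list[Hyperedge] = []
    seen_nodes: set[str] = set()
    seen_edges: set[str] = set()

    for node_el in root.iterchildren("node"):
        nid = node_el.get("id")
        if not nid or not _ID_RE.match(nid):
            raise ValidationError([f"node with missing or invalid id {nid!r}"])
        if nid in seen_nodes:
            raise ValidationError([f"duplicate node id {nid}"])
        seen_nodes.add(nid)
        entry = _parse_bool(node_el.get("entrypoint", "False"), f"node {nid}")
        init: dict = {}
        for init_el in node_el.iterchildren("init"):
            name = init_el.get("name", "init")
            raw = init_el.get("value", "")
            try:
                init[name] = json.loads(raw)
            except (json.JSONDecodeError, ValueError):
                init[name] = raw
        nodes.append(ServiceNode(nid, entrypoint=entry, initial_values=init))

        for edge_el in node_el.iterchildren("edge"):
            eid = edge_el.get("id")
            if not eid or not _ID_RE.match(eid):
                raise ValidationError([f"edge with missing or invalid id {eid!r}"])
            if eid in seen_edges:
                raise ValidationError([f"duplicate edge id {eid}"])
            seen_edges.add(eid)
            dests: list[str] = []
            blocking = True
            for dest_el in edge_el.iterchildren("node"):
                did = dest_el.get("id")
                if not did:
                    raise ValidationError([f"edge {eid}: destination without id"])
                dests.append(did)
                if _parse_bool(dest_el.get("nonblocking", "False"), f"edge {eid}"):
                    blocking = False
            if not dests:
                raise ValidationError([f"edge {eid}: empty destinations"])
            edges.append(Hyperedge(eid, nid, tuple(dests), blocking=blocking))

    return WorkflowGraph(nodes, edges)


def write_workflow_xml(g: WorkflowGraph, *, require_valid: bool = True) -> str:
    """Serialize a graph to the XML dialect (deterministic element order)."""
    if require_valid:
        violations = validate_graph(g)
        if violations:
            raise ValidationError(violations)
    root = etree.Element("graph")
    for node in sorted(g.nodes, key=lambda n: n.id):
        el = etree.SubElement(root, "node", id=node.id)
        if node.entrypoint:
            el.set("entrypoint", "True")
        for name in sorted(node.initial_values):
            etree.SubElement(
                el, "init", name=name, value=json.dumps(node.initial_values[name])
            )
        for edge in g.out_edges(node.id):
            edge_el = etree.SubElement(el, "edge", id=edge.id)
            for i, dest in enumerate(edge.destinations):
                dest_el = etree.SubElement(edge_el, "node", id=dest)
                if not edge.blocking and i == 0:
                    dest_el.set("nonblocking", "True")
    return etree.tostring(
        root, pretty_print=True, encoding="unicode"
    )


def to_adjacency(g: WorkflowGraph) -> list[dict]:
    """The {source, [destinations]} pairs, one per hyperedge, sorted by id."""
    return [
        {
            "edge": e.id,
            "source": e.source,
            "destinations": list(e.destinations),
            "blocking": e.blocking,
        }
        for e in g.sorted_edges()
    ]


def from_adjacency(nodes: list[ServiceNode], adjacency: list[dict]) -> WorkflowGraph:
    """Inverse of :func:`to_adjacency` given the node inventory."""
    edges = [
        Hyperedge(
            a["edge"], a["source"], tuple(a["destinations"]), a.get("blocking", True)
        )
        for a in adjacency
    ]
    return WorkflowGraph(list(nodes), edges)


def canonical_bytes(g: WorkflowGraph) -> bytes:
    """Deterministic serialization: equal graphs (up to declaration order)
    produce identical bytes.  Bindings are opaque and excluded."""
    lines = []
    for node in sorted(g.nodes, key=lambda n: n.id):
        init = json.dumps(node.initial_values, sort_keys=True, separators=(",", ":"))
        lines.append(f"node\t{node.id}\t{int(node.entrypoint)}\t{init}")
    for e in g.sorted_edges():
        dests = ",".join(e.destinations)
        lines.append(f"edge\t{e.id}\t{e.source}\t{dests}\t{int(e.blocking)}")
    return ("\n".join(lines) + "\n").encode("utf-8")


def graph_to_dict(g: WorkflowGraph) -> dict:
    """JSON-safe structural dump (debug/transport form)."""
    return {
        "nodes": [
            {
                "id": n.id,
                "entrypoint": n.entrypoint,
                "initial_values": n.initial_values,
            }
            for n in sorted(g.nodes, key=lambda n: n.id)
        ],
        "edges": to_adjacency(g),
    }


def graph_from_dict(d: dict) -> WorkflowGraph:
    nodes = [
        ServiceNode(n["id"], n.get("entrypoint", False), dict(n.get("initial_values", {})))
        for n in d["nodes"]
    ]
    return from_adjacency(nodes, d["edges"])
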