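"""Directed-hypergraph workflow model.

A workflow is a set of labeled service nodes plus *hyperedges*, each relating a
single source node to one or more destination nodes.  A hyperedge delivers the
*identical* output of its source to every destination (split outputs are two
separate edges); no intermediate node may sit on an edge.  Edges are either
blocking (synchronous: the destination waits for a fresh value each iteration)
or non-blocking (asynchronous: the latest value is merged into the
destination's local variables without waiting).

Workflows are classified by increasing expressiveness:

* ``DAG``  -- acyclic, all edges single-destination,
* ``DG``   -- contains a directed cycle (dicycle), all edges single-destination,
* ``DHG``  -- at least one multi-destination hyperedge (cycles optional),

with DAGs a subset of DGs a subset of DHGs.  Dicycles are what standard
acyclic workflow engines cannot express; this module detects them as strongly
connected components so the transform layer can eliminate them from the
control plane.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

import networkx as nx

__all__ = [
    "ServiceNode",
    "Hyperedge",
    "WorkflowGraph",
    "WorkflowClass",
    "ValidationError",
    "validate_graph",
    "classify",
    "find_dicycles",
    "Schedule",
    "iteration_schedule",
]


class ValidationError(ValueError):
    """Raised when an operation requires a valid graph but got violations."""

    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


@dataclass
class ServiceNode:
    """A labeled service node.

    ``initial_values`` seed the node's contextual variables and supply the
    very first value consumed over loop-carried edges (iteration 1 has no
    previous iteration to read from).  ``binding`` is an opaque reference to
    the executable behind the node (an in-process callable or an endpoint);
    it never participates in structural equality or serialization.
    """

    id: str
    entrypoint: bool = False
    initial_values: dict[str, Any] = field(default_factory=dict)
    binding: Callable | str | None = field(default=None, compare=False, repr=False)


@dataclass
class Hyperedge:
    """A {source, [destinations]} relation.

    Destination order is not semantic (all destinations receive the same
    value), so destinations are normalized to a sorted tuple.
    """

    id: str
    source: str
    destinations: tuple[str, ...]
    blocking: bool = True

    def __post_init__(self) -> None:
        self.destinations = tuple(sorted(self.destinations))


class WorkflowClass(enum.Enum):
    DAG = "DAG"
    DG = "DG"
    DHG = "DHG"


@dataclass
class WorkflowGraph:
    """Nodes plus single-source multi-destination hyperedges."""

    nodes: list[ServiceNode] = field(default_factory=list)
    hyperedges: list[Hyperedge] = field(default_factory=list)

    # -- convenience accessors (deterministic: sorted by id) ---------------

    def node_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes)

    def node(self, node_id: str) -> ServiceNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def edge(self, edge_id: str) -> Hyperedge:
        for e in self.hyperedges:
            if e.id == edge_id:
                return e
        raise KeyError(edge_id)

    def sorted_edges(self) -> list[Hyperedge]:
        return sorted(self.hyperedges, key=lambda e: e.id)

    def edge_pairs(self) -> list[tuple[str, str, str, bool]]:
        """Flattened (edge_id, source, destination, blocking) tuples."""
        out = []
        for e in self.sorted_edges():
            for d in e.destinations:
                out.append((e.id, e.source, d, e.blocking))
        return out

    def out_edges(self, node_id: str) -> list[Hyperedge]:
        return [e for e in self.sorted_edges() if e.source == node_id]

    def in_pairs(self, node_id: str) -> list[tuple[str, str, bool]]:
        """Inbound (edge_id, source, blocking) tuples for a node."""
        return [
            (eid, src, blocking)
            for eid, src, dst, blocking in self.edge_pairs()
            if dst == node_id
        ]

    def entrypoints(self) -> list[str]:
        return sorted(n.id for n in self.nodes if n.entrypoint)

    def copy(self) -> "WorkflowGraph":
        return WorkflowGraph(
            nodes=[
                ServiceNode(n.id, n.entrypoint, dict(n.initial_values), n.binding)
                for n in self.nodes
            ],
            hyperedges=[
                Hyperedge(e.id, e.source, e.destinations, e.blocking)
                for e in self.hyperedges
            ],
        )

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.id for n in self.nodes)
        for eid, src, dst, blocking in self.edge_pairs():
            g.add_edge(src, dst)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WorkflowGraph):
            return NotImplemented
        mine = sorted(
            (n.id, n.entrypoint, tuple(sorted(n.initial_values.items())))
            for n in self.nodes
        )
        theirs = sorted(
            (n.id, n.entrypoint, tuple(sorted(n.initial_values.items())))
            for n in other.nodes
        )
        return mine == theirs and sorted(
            (e.id, e.source, e.destinations, e.blocking) for e in self.hyperedges
        ) == sorted(
            (e.id, e.source, e.destinations, e.blocking) for e in other.hyperedges
        )

    __hash__ = None  # type: ignore[assignment]


def graph(
    nodes: Iterable[str | ServiceNode],
    edges: Iterable[tuple | Hyperedge] = (),
    entrypoint: str | None = None,
    initial_values: Mapping[str, Mapping[str, Any]] | None = None,
) -> WorkflowGraph:
    """Terse constructor used by tests and examples.

    ``edges`` items may be ``Hyperedge`` or tuples
    ``(id, source, destinations[, blocking])``.
    """
    ns = []
    for n in nodes:
        if isinstance(n, ServiceNode):
            ns.append(n)
        else:
            ns.append(ServiceNode(n, entrypoint == n))
    if entrypoint is None and ns and not any(n.entrypoint for n in ns):
        ns[0].entrypoint = True
    if initial_values:
        for n in ns:
            if n.id in initial_values:
                n.initial_values.update(initial_values[n.id])
    es = []
    for e in edges:
        if isinstance(e, Hyperedge):
            es.append(e)
        else:
            eid, src, dests, *rest = e
            if isinstance(dests, str):
                dests = (dests,)
            es.append(Hyperedge(eid, src, tuple(dests), rest[0] if rest else True))
    return WorkflowGraph(ns, es)


# ---------------------------------------------------------------------------
# validation / classification / dicycles
# ---------------------------------------------------------------------------


def validate_graph(g: WorkflowGraph) -> list[str]:
    """Enumerate every structural invariant violation (empty list = valid).

    Violations are reported, never raised, so callers can surface all of them
    at once.
    """
    violations: list[str] = []
    seen_nodes: set[str] = set()
    for n in g.nodes:
        if not n.id:
            violations.append("node with empty id")
            continue
        if n.id in seen_nodes:
            violations.append(f"duplicate node id {n.id}")
        seen_nodes.add(n.id)
    if g.nodes and not any(n.entrypoint for n in g.nodes):
        violations.append("no entrypoint node")
    seen_edges: set[str] = set()
    for e in g.hyperedges:
        if not e.id:
            violations.append("edge with empty id")
        if e.id in seen_edges:
            violations.append(f"duplicate edge id {e.id}")
        seen_edges.add(e.id)
        if not e.destinations:
            violations.append(f"edge {e.id}: empty destinations")
        if len(set(e.destinations)) != len(e.destinations):
            violations.append(f"edge {e.id}: duplicate destinations")
        if e.source not in seen_nodes and e.source not in {n.id for n in g.nodes}:
            violations.append(f"edge {e.id}: unknown node {e.source}")
        declared = {n.id for n in g.nodes}
        for d in e.destinations:
            if d not in declared:
                violations.append(f"edge {e.id}: unknown node {d}")
    return violations


def _require_valid(g: WorkflowGraph) -> None:
    violations = validate_graph(g)
    if violations:
        raise ValidationError(violations)


def classify(g: WorkflowGraph) -> WorkflowClass:
    """Most specific workflow class: DAG, DG (dicycle present) or DHG."""
    _require_valid(g)
    if any(len(e.destinations) > 1 for e in g.hyperedges):
        return WorkflowClass.DHG
    if find_dicycles(g):
        return WorkflowClass.DG
    return WorkflowClass.DAG


def find_dicycles(g: WorkflowGraph) -> list[set[str]]:
    """Strongly connected components containing at least one edge.

    Each component is returned as a node-id set; the union of the returned
    sets is exactly the set of nodes lying on some dicycle.  Components are
    ordered lexicographically by their smallest member.
    """
    _require_valid(g)
    dg = g.to_digraph()
    comps = []
    for comp in nx.strongly_connected_components(dg):
        if len(comp) > 1 or dg.has_edge(next(iter(comp)), next(iter(comp))):
            comps.append(set(comp))
    return sorted(comps, key=lambda c: min(c))


# ---------------------------------------------------------------------------
# iteration schedule
# ---------------------------------------------------------------------------


@dataclass
class Schedule:
    """Deterministic execution order and loop-carried edge classification.

    ``order`` lists all nodes: condensation components in topological order,
    nodes within a strongly connected component in their within-iteration
    order.  ``loop_carried`` holds the (edge_id, destination) pairs whose
    value crosses the iteration boundary: the destination consumes the
    source's *previous* iteration output (iteration 1 consumes the
    destination's declared initial value instead).
    """

    order: list[str]
    position: dict[str, int]
    sccs: list[set[str]]
    scc_of: dict[str, int | None]
    loop_carried: set[tuple[str, str]]

    def in_loop(self, node_id: str) -> bool:
        return self.scc_of.get(node_id) is not None


def iteration_schedule(g: WorkflowGraph) -> Schedule:
    """Derive the within-iteration order and the loop-carried edges.

    Within each SCC a Kahn-style elimination runs over the *blocking*
    intra-SCC edges; whenever it stalls (every remaining node waits on a not
    yet ordered source) the entrypoint member -- else the lexicographically
    smallest remaining member -- is forced, and its still-unsatisfied
    blocking in-edges become loop-carried.  Non-blocking edges never gate the
    order.
    """
    _require_valid(g)
    sccs = find_dicycles(g)
    scc_of: dict[str, int | None] = {n.id: None for n in g.nodes}
    for i, comp in enumerate(sccs):
        for v in comp:
            scc_of[v] = i

    # condensation components in deterministic topological order
    dg = g.to_digraph()
    cond_members: list[set[str]] = [set(c) for c in sccs]
    for v in g.node_ids():
        if scc_of[v] is None:
            cond_members.append({v})
    comp_index = {v: i for i, comp in enumerate(cond_members) for v in comp}
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(cond_members)))
    for eid, src, dst, blocking in g.edge_pairs():
        a, b = comp_index[src], comp_index[dst]
        if a != b:
            cond.add_edge(a, b)
    comp_order = list(
        nx.lexicographical_topological_sort(cond, key=lambda i: min(cond_members[i]))
    )

    entries = set(g.entrypoints())
    loop_carried: set[tuple[str, str]] = set()
    order: list[str] = []

    for ci in comp_order:
        members = cond_members[ci]
        if len(members) == 1 and scc_of[next(iter(members))] is None:
            order.append(next(iter(members)))
            continue
        # within-SCC Kahn with forced picks
        remaining = set(members)
        ordered_in: set[str] = set()
        intra_in: dict[str, list[tuple[str, str]]] = {v: [] for v in members}
        for eid, src, dst, blocking in g.edge_pairs():
            if blocking and src in members and dst in members:
                intra_in[dst].append((eid, src))
        while remaining:
            ready = sorted(
                v
                for v in remaining
                if all(src in ordered_in for _, src in intra_in[v])
            )
            if ready:
                pick = ready[0]
            else:
                stuck_entries = sorted(remaining & entries)
                pick = stuck_entries[0] if stuck_entries else min(remaining)
                for eid, src in intra_in[pick]:
                    if src not in ordered_in:
                        loop_carried.add((eid, pick))
            remaining.discard(pick)
            ordered_in.add(pick)
            order.append(pick)

    return Schedule(
        order=order,
        position={v: i for i, v in enumerate(order)},
        sccs=sccs,
        scc_of=scc_of,
        loop_carried=loop_carried,
    )
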