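"""Loop elimination: cyclic workflows to orchestrator-mediated acyclic plans.

A dicycle breaks the acyclic representation that standard workflow engines
require.  The transform keeps the acyclic portion of a workflow intact and,
for every strongly connected component (SCC), moves the component-internal
edges out of the control plane into *data channels*; a single logically
centralized orchestrator node ``O`` takes the component's place in the
control graph: every edge entering the component is redirected to ``O`` and
``O`` gains one hyperedge fanning out to the component members.  The loop
participants then run as persistent instances exchanging data directly while
the orchestrator drives iterations and evaluates the exit condition.

Simple loops (a single cycle with no split/merge) can alternatively be
*unrolled* into a DAG of N chained body copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import networkx as nx

from .model import (
    Hyperedge,
    Schedule,
    ServiceNode,
    ValidationError,
    WorkflowGraph,
    find_dicycles,
    iteration_schedule,
    validate_graph,
)

__all__ = [
    "ExitCondition",
    "DataChannel",
    "TransformedWorkflow",
    "UnsupportedLoopError",
    "insert_orchestrator",
    "unroll_simple_loop",
    "partition_dag_segments",
    "arrow_notation",
]


class UnsupportedLoopError(ValueError):
    pass


@dataclass
class ExitCondition:
    """When to leave a loop: at the Nth iteration, and/or when a named
    predicate over the loop participants' context snapshots holds.

    At least one of the two must be present; ``max_iterations`` must be >= 1.
    """

    max_iterations: int | None = None
    predicate: Callable[[dict], bool] | None = None
    predicate_name: str | None = None

    def __post_init__(self) -> None:
        if self.max_iterations is None and self.predicate is None:
            raise ValueError("exit condition needs max_iterations or a predicate")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class DataChannel:
    """A dicycle edge demoted from the control plane to the data plane."""

    edge_id: str
    source: str
    dest: str
    blocking: bool = True


@dataclass
class TransformedWorkflow:
    """An acyclic control plan plus the orthogonal data channels."""

    original: WorkflowGraph
    control_graph: WorkflowGraph
    data_channels: list[DataChannel]
    loop_participants: set[str]
    exit_condition: ExitCondition
    orchestrator_id: str | None = None
    schedule: Schedule | None = None
    dag_segments: list[WorkflowGraph] = field(default_factory=list)

    @property
    def has_loop(self) -> bool:
        return bool(self.loop_participants)


def _fresh_id(wanted: str, taken: set[str]) -> str:
    cand = wanted
    while cand in taken:
        cand += "_"
    return cand


def insert_orchestrator(
    g: WorkflowGraph, exit: ExitCondition
) -> TransformedWorkflow:
    """Eliminate every dicycle from the control plane.

    Acyclic inputs pass through untouched (no orchestrator node, empty loop
    state).  For cyclic inputs, per SCC: internal edges become data channels,
    entering edges are redirected to the orchestrator node, and the
    orchestrator fans out to the SCC members.  Edges leaving an SCC keep
    their source but are only triggered once the exit condition fires.
    """
    violations = validate_graph(g)
    if violations:
        raise ValidationError(violations)

    schedule = iteration_schedule(g)
    sccs = schedule.sccs
    if not sccs:
        return TransformedWorkflow(
            original=g,
            control_graph=g,
            data_channels=[],
            loop_participants=set(),
            exit_condition=exit,
            orchestrator_id=None,
            schedule=schedule,
            dag_segments=partition_segments_of(g, set()),
        )

    loop_nodes = set().union(*sccs)
    taken_nodes = {n.id for n in g.nodes}
    o_id = _fresh_id("O", taken_nodes)
    taken_edges = {e.id for e in g.hyperedges}

    # nodes from which some loop is reachable: a loop output feeding them
    # must travel on the data plane, otherwise the single (logically
    # centralized) O node would sit on a control dicycle of its own
    dg = g.to_digraph()
    reaches_loop: set[str] = set(loop_nodes)
    rev = dg.reverse(copy=False)
    for start in loop_nodes:
        reaches_loop.update(nx.descendants(rev, start))

    channels: list[DataChannel] = []
    control_edges: list[Hyperedge] = []
    scc_of = schedule.scc_of

    for e in g.sorted_edges():
        src_comp = scc_of[e.source]
        new_dests = []
        for d in e.destinations:
            if src_comp is not None:
                # sourced inside a loop: internal edges, edges into another
                # loop, and edges whose downstream re-enters a loop are all
                # data channels (released per iteration inside the SCC, at
                # exit otherwise); only pure downstream destinations stay in
                # the control plane
                if scc_of[d] == src_comp or d in reaches_loop:
                    channels.append(DataChannel(e.id, e.source, d, e.blocking))
                else:
                    new_dests.append(d)
            elif scc_of[d] is not None:
                new_dests.append(o_id)  # edge entering a loop from outside
            else:
                new_dests.append(d)
        if not new_dests:
            continue
        new_dests = sorted(set(new_dests))
        control_edges.append(Hyperedge(e.id, e.source, tuple(new_dests), e.blocking))

    nodes = [ServiceNode(n.id, n.entrypoint, dict(n.initial_values), n.binding) for n in g.nodes]
    nodes.append(ServiceNode(o_id, entrypoint=False))
    for comp in sccs:
        eid = _fresh_id(f"o-{min(comp)}", taken_edges)
        taken_edges.add(eid)
        control_edges.append(Hyperedge(eid, o_id, tuple(sorted(comp))))

    control = WorkflowGraph(nodes, control_edges)
    if find_dicycles(control):  # pragma: no cover - structural guarantee
        raise AssertionError("control graph must be acyclic after transformation")

    return TransformedWorkflow(
        original=g,
        control_graph=control,
        data_channels=channels,
        loop_participants=loop_nodes,
        exit_condition=exit,
        orchestrator_id=o_id,
        schedule=schedule,
        dag_segments=partition_segments_of(g, loop_nodes),
    )


def partition_segments_of(
    g: WorkflowGraph, loop_nodes: set[str]
) -> list[WorkflowGraph]:
    """Weakly connected DAG segments left once the loops are cut out.

    Drops every edge internal to an SCC and every edge *sourced* at a loop
    participant (those are released by the orchestrator after the loop), then
    takes the weakly connected components of what remains.  Loop participants
    left with no incident edge belong to no segment -- they are reachable
    only through the orchestrator and are covered by ``loop_participants``.
    """
    kept: list[Hyperedge] = []
    for e in g.sorted_edges():
        if e.source in loop_nodes:
            continue
        dests = tuple(d for d in e.destinations)
        kept.append(Hyperedge(e.id, e.source, dests, e.blocking))

    und = nx.Graph()
    for n in g.nodes:
        if n.id not in loop_nodes:
            und.add_node(n.id)
    for e in kept:
        for d in e.destinations:
            und.add_edge(e.source, d)

    segments = []
    for comp in sorted(nx.connected_components(und), key=min):
        seg_nodes = [n for n in g.nodes if n.id in comp]
        seg_edges = [
            Hyperedge(
                e.id,
                e.source,
                tuple(d for d in e.destinations if d in comp),
                e.blocking,
            )
            for e in kept
            if e.source in comp and any(d in comp for d in e.destinations)
        ]
        segments.append(WorkflowGraph(seg_nodes, seg_edges))
    return segments


def partition_dag_segments(tw: TransformedWorkflow) -> list[WorkflowGraph]:
    """DAG segments of a transformed workflow (see
    :func:`partition_segments_of`)."""
    return [seg.copy() for seg in tw.dag_segments]


def unroll_simple_loop(body: WorkflowGraph, n_iterations: int) -> WorkflowGraph:
    """Unroll a single simple cycle into a DAG of N chained body copies.

    The body's nodes must form exactly one simple cycle (each node one
    inbound and one outbound single-destination edge).  Copy ``k`` of node
    ``A`` is named ``A#k``; executing the unrolled DAG equals N sequential
    traversals of the loop.  Nested or multiple loops are rejected: those are
    handled by :func:`insert_orchestrator` instead.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    violations = validate_graph(body)
    if violations:
        raise ValidationError(violations)
    sccs = find_dicycles(body)
    if len(sccs) != 1 or sccs[0] != {n.id for n in body.nodes}:
        raise UnsupportedLoopError("body must be a single cycle over all nodes")
    succ: dict[str, tuple[str, str]] = {}
    for e in body.hyperedges:
        if len(e.destinations) != 1 or e.source in succ:
            raise UnsupportedLoopError("body must be a simple cycle (no split/merge)")
        succ[e.source] = (e.id, e.destinations[0])
    if len(succ) != len(body.nodes):
        raise UnsupportedLoopError("body must be a simple cycle")

    entries = body.entrypoints()
    start = entries[0] if entries else min(succ)
    ring = [start]
    while True:
        nxt = succ[ring[-1]][1]
        if nxt == start:
            break
        ring.append(nxt)

    nodes: list[ServiceNode] = []
    edges: list[Hyperedge] = []
    for k in range(1, n_iterations + 1):
        for v in ring:
            base = body.node(v)
            nodes.append(
                ServiceNode(
                    f"{v}#{k}",
                    entrypoint=(k == 1 and v == start),
                    initial_values=dict(base.initial_values) if k == 1 else {},
                    binding=base.binding,
                )
            )
    for k in range(1, n_iterations + 1):
        for i, v in enumerate(ring):
            eid, nxt = succ[v]
            if i + 1 < len(ring):
                edges.append(Hyperedge(f"{eid}#{k}", f"{v}#{k}", (f"{nxt}#{k}",)))
            elif k < n_iterations:
                edges.append(Hyperedge(f"{eid}#{k}", f"{v}#{k}", (f"{nxt}#{k + 1}",)))
    return WorkflowGraph(nodes, edges)


def arrow_notation(g: WorkflowGraph) -> str:
    """Human-readable edge summary, e.g. ``A→B, B→(C+D), E→O, O→(F+G)``."""
    parts = []
    for e in g.sorted_edges():
        dest = (
            e.destinations[0]
            if len(e.destinations) == 1
            else "(" + "+".join(e.destinations) + ")"
        )
        arrow = "→" if e.blocking else "⇢"
        parts.append(f"{e.source}{arrow}{dest}")
    return ", ".join(parts)
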