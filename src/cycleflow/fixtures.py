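"""Reference workflow definitions and simple service bindings.

These are the small worked examples used throughout the documentation, the
examples/ scripts and the test-suite: a five-node closed-loop hypergraph
workflow (XML dialect), the chain-with-terminal-loop workflow
``A→B→(C+D)→E→F↔G`` and the mid-loop workflow ``A→B→(C+D)→E↔F→(G+H)→I``.
"""

from __future__ import annotations

from typing import Any, Callable

from .model import Hyperedge, ServiceNode, WorkflowGraph
from .runtime import PerEdge

__all__ = [
    "EXAMPLE_DHG_XML",
    "example_dhg_graph",
    "chain_tail_loop_graph",
    "chain_mid_loop_graph",
    "two_node_loop_graph",
    "increment",
    "arith_binding",
    "increment_bindings",
]

# Five services; e1..e4 fan the data forward, e5 feeds E's output back to B
# asynchronously, e6 closes the loop back to the entrypoint A synchronously.
EXAMPLE_DHG_XML = """\
<graph>
 <node id="A" entrypoint="True">
  <edge id="e1">
   <node id="B" />
   <node id="C" />
  </edge>
 </node>
 <node id="B">
  <edge id="e2">
   <node id="C" />
   <node id="D" />
  </edge>
 </node>
 <node id="C">
  <edge id="e3">
   <node id="D" />
   <node id="E" />
  </edge>
 </node>
 <node id="D">
  <edge id="e4">
   <node id="E" />
  </edge>
 </node>
 <node id="E">
  <edge id="e5">
   <node id="B" nonblocking="True"/>
  </edge>
  <edge id="e6">
   <node id="A" />
  </edge>
 </node>
</graph>
"""


def example_dhg_graph() -> WorkflowGraph:
    """The five-node closed-loop example as an in-memory graph."""
    from .xmlio import parse_workflow_xml

    return parse_workflow_xml(EXAMPLE_DHG_XML)


def chain_tail_loop_graph() -> WorkflowGraph:
    """``A→B→(C+D)→E→F↔G``: a chain feeding a terminal two-node dicycle."""
    return WorkflowGraph(
        nodes=[
            ServiceNode("A", entrypoint=True),
            ServiceNode("B"),
            ServiceNode("C"),
            ServiceNode("D"),
            ServiceNode("E"),
            ServiceNode("F"),
            ServiceNode("G"),
        ],
        hyperedges=[
            Hyperedge("e1", "A", ("B",)),
            Hyperedge("e2", "B", ("C", "D")),
            Hyperedge("e3", "C", ("E",)),
            Hyperedge("e4", "D", ("E",)),
            Hyperedge("e5", "E", ("F",)),
            Hyperedge("e6", "F", ("G",)),
            Hyperedge("e7", "G", ("F",)),
        ],
    )


def chain_mid_loop_graph() -> WorkflowGraph:
    """``A→B→(C+D)→E↔F→(G+H)→I``: a dicycle in the middle of two DAG
    segments."""
    return WorkflowGraph(
        nodes=[
            ServiceNode("A", entrypoint=True),
            ServiceNode("B"),
            ServiceNode("C"),
            ServiceNode("D"),
            ServiceNode("E"),
            ServiceNode("F"),
            ServiceNode("G"),
            ServiceNode("H"),
            ServiceNode("I"),
        ],
        hyperedges=[
            Hyperedge("e1", "A", ("B",)),
            Hyperedge("e2", "B", ("C", "D")),
            Hyperedge("e3", "C", ("E",)),
            Hyperedge("e4", "D", ("E",)),
            Hyperedge("e5", "E", ("F",)),
            Hyperedge("e6", "F", ("E",)),
            Hyperedge("e7", "F", ("G", "H")),
            Hyperedge("e8", "G", ("I",)),
            Hyperedge("e9", "H", ("I",)),
        ],
    )


def two_node_loop_graph(
    a: str = "PM", b: str = "CTL", init: Any = 0
) -> WorkflowGraph:
    """A minimal two-node closed loop ``a↔b`` (entrypoint ``a``)."""
    return WorkflowGraph(
        nodes=[
            ServiceNode(a, entrypoint=True, initial_values={"init": init}),
            ServiceNode(b),
        ],
        hyperedges=[
            Hyperedge("fwd", a, (b,)),
            Hyperedge("back", b, (a,)),
        ],
    )


def increment(inputs: dict, variables: dict) -> Any:
    """x -> x + 1 over the aggregated input (declared init when no input)."""
    vals = [v for v in inputs.values() if v is not None]
    x = sum(vals) if vals else variables.get("init", 0)
    return x + 1


def arith_binding(a: int = 1, b: int = 0) -> Callable:
    """Integer-arithmetic service: out = a * sum(blocking inputs) + b.

    Nodes with no (non-None) blocking inputs fall back to their declared
    ``init`` contextual variable.
    """

    def fn(inputs: dict, variables: dict) -> int:
        vals = [v for v in inputs.values() if v is not None]
        x = sum(vals) if vals else variables.get("init", 0)
        out = a * x + b
        variables["last"] = out
        return out

    return fn


def increment_bindings(g: WorkflowGraph) -> dict[str, Callable]:
    return {n.id: increment for n in g.nodes}
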