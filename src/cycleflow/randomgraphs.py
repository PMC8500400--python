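"""Randomized workflow generator for equivalence and invariant testing.

Generates structured random workflows: a layered random DAG backbone (every
non-root node has at least one blocking parent among earlier nodes, a
fraction of edges are multi-destination hyperedges), optionally closed into
one or two disjoint dicycles by adding a back edge over a contiguous node
block.  Every node gets an integer-arithmetic binding and a small integer
initial value, so execution traces are exactly comparable across engines.

These graphs deliberately use blocking edges only: asynchronous delivery
order is not deterministic for arbitrary topologies (see the methods note),
so asynchronous semantics are exercised on the structured worked examples
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fixtures import arith_binding
from .model import Hyperedge, ServiceNode, WorkflowGraph

__all__ = ["RandomWorkflow", "random_workflow"]


@dataclass
class RandomWorkflow:
    graph: WorkflowGraph
    bindings: dict[str, Callable]
    n_sccs: int


def random_workflow(
    rng: np.random.Generator,
    max_nodes: int = 8,
    max_sccs: int = 2,
    p_hyper: float = 0.3,
) -> RandomWorkflow:
    """Draw one random workflow with at most ``max_sccs`` dicycles."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    nodes = [
        ServiceNode(
            names[i],
            entrypoint=(i == 0),
            initial_values={"init": int(rng.integers(0, 5))},
        )
        for i in range(n)
    ]
    edges: list[Hyperedge] = []
    eid = 0

    def add_edge(src: int, dests: list[int]) -> None:
        nonlocal eid
        eid += 1
        edges.append(Hyperedge(f"e{eid}", names[src], tuple(names[d] for d in dests)))

    # backbone: each node i >= 1 consumes from one earlier node; some edges
    # fan out to an extra later destination (a hyperedge)
    for i in range(1, n):
        src = int(rng.integers(0, i))
        dests = [i]
        if rng.random() < p_hyper:
            extra = int(rng.integers(i, n))
            if extra != i and extra not in dests:
                dests.append(extra)
        add_edge(src, dests)

    # close up to max_sccs disjoint contiguous blocks into loops
    n_sccs = int(rng.integers(0, max_sccs + 1)) if n >= 3 else int(rng.integers(0, 2))
    blocks: list[tuple[int, int]] = []
    cursor = 0
    for _ in range(n_sccs):
        if cursor >= n - 1:
            break
        lo = int(rng.integers(cursor, n - 1))
        hi = int(rng.integers(lo + 1, n))
        blocks.append((lo, hi))
        cursor = hi + 1
    for lo, hi in blocks:
        # guarantee a forward path lo -> hi inside the block, then close it
        for j in range(lo + 1, hi + 1):
            if not any(
                e.source in names[lo:j] and names[j] in e.destinations for e in edges
            ):
                add_edge(int(rng.integers(lo, j)), [j])
        add_edge(hi, [lo])

    bindings = {
        names[i]: arith_binding(int(rng.integers(1, 3)), int(rng.integers(-2, 3)))
        for i in range(n)
    }
    return RandomWorkflow(
        graph=WorkflowGraph(nodes, edges), bindings=bindings, n_sccs=len(blocks)
    )
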