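"""Single-process reference simulator.

A deliberately simple, single-threaded fixed-point iteration over the
*original* (possibly cyclic) workflow graph.  It defines the value semantics
that the concurrent engine must reproduce and serves as the independent
oracle in the test-suite: no channels, no threads, no orchestrator -- just a
loop over the iteration schedule.

Semantics (shared definition, see :func:`cycleflow.model.iteration_schedule`):

* Nodes outside any SCC execute exactly once, in condensation order.
* Nodes inside an SCC execute once per iteration, N times, in the
  within-iteration order.
* A blocking input from outside the SCC is consumed at iteration 1 only.
* A blocking forward intra-SCC input carries the source's same-iteration
  output; a loop-carried input carries the previous iteration's output
  (iteration 1 reads the destination's declared initial value).
* A non-blocking input merges the latest available source output into the
  destination's contextual variables (keyed by edge id) without waiting.
* Edges leaving an SCC deliver only the source's final-iteration output,
  after the exit condition fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

from .model import WorkflowGraph, iteration_schedule
from .runtime import PerEdge, initial_for, resolve_bindings

__all__ = ["SimulationResult", "simulate"]


@dataclass
class SimulationResult:
    outputs: dict[str, list[Any]]
    contexts: dict[str, dict[str, Any]]
    iterations: int

    def final_values(self) -> dict[str, Any]:
        return {k: v[-1] for k, v in self.outputs.items() if v}

    def state(self) -> dict:
        """Snapshot for resuming (hot-update two-phase simulation)."""
        return {
            "outputs": {k: list(v) for k, v in self.outputs.items()},
            "contexts": {k: dict(v) for k, v in self.contexts.items()},
            "iterations": self.iterations,
        }


def _edge_value(out: Any, edge_id: str) -> Any:
    if isinstance(out, PerEdge):
        return out.get(edge_id)
    return out


def simulate(
    g: WorkflowGraph,
    bindings: Mapping[str, Callable],
    n_iterations: int,
    predicate: Callable[[dict], bool] | None = None,
    state: dict | None = None,
) -> SimulationResult:
    """Run the workflow to the exit condition and return the full trace.

    ``state`` resumes from a previous :meth:`SimulationResult.state` snapshot
    (used to cross-check hot updates: simulate the old graph up to the
    boundary, then the modified graph from the carried state).
    """
    sched = iteration_schedule(g)
    binding_of = resolve_bindings(g, bindings)

    if state is None:
        outputs: dict[str, list[Any]] = {n.id: [] for n in g.nodes}
        contexts: dict[str, dict[str, Any]] = {
            n.id: dict(n.initial_values) for n in g.nodes
        }
        done_iters = 0
    else:
        outputs = {n.id: list(state["outputs"].get(n.id, [])) for n in g.nodes}
        contexts = {n.id: dict(state["contexts"].get(n.id, {})) for n in g.nodes}
        done_iters = state["iterations"]

    in_pairs = {n.id: [] for n in g.nodes}
    for eid, src, dst, blocking in g.edge_pairs():
        in_pairs[dst].append((eid, src, blocking))

    pos = sched.position
    scc_of = sched.scc_of

    def latest(src: str) -> Any | None:
        return outputs[src][-1] if outputs[src] else None

    def run_node(v: str, n: int) -> None:
        """Execute node v for (loop) iteration n; n=1 for one-shot nodes."""
        inputs: dict[str, Any] = {}
        ctx = contexts[v]
        comp = scc_of[v]
        for eid, src, blocking in sorted(in_pairs[v]):
            same_comp = comp is not None and scc_of[src] == comp
            if blocking:
                if not same_comp:
                    if n == 1:
                        val = latest(src)
                        inputs[eid] = _edge_value(val, eid)
                elif (eid, v) in sched.loop_carried:
                    if n == 1:
                        inputs[eid] = initial_for(g.node(v), eid)
                    else:
                        inputs[eid] = _edge_value(outputs[src][n - 2], eid)
                else:
                    inputs[eid] = _edge_value(outputs[src][n - 1], eid)
            else:
                # async merge: latest available at this point of the schedule
                if not same_comp:
                    if outputs[src]:
                        ctx[eid] = _edge_value(outputs[src][-1], eid)
                else:
                    idx = n - 1 if pos[src] < pos[v] else n - 2
                    if 0 <= idx < len(outputs[src]):
                        ctx[eid] = _edge_value(outputs[src][idx], eid)
        out = binding_of[v](inputs, ctx)
        outputs[v].append(out)

    comp_seen: set[int] = set()
    n_total = done_iters
    for v in sched.order:
        comp = scc_of[v]
        if comp is None:
            if not outputs[v]:  # one-shot nodes that already ran are skipped on resume
                run_node(v, 1)
            continue
        if comp in comp_seen:
            continue
        comp_seen.add(comp)
        members = [u for u in sched.order if scc_of[u] == comp]
        n = done_iters
        while n < n_iterations:
            n += 1
            for u in members:
                run_node(u, n)
            if predicate is not None and predicate(contexts):
                break
        n_total = n

    return SimulationResult(outputs=outputs, contexts=contexts, iterations=n_total)
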