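"""Workflow execution front door.

``run_workflow`` takes a definition (XML text or an in-memory graph), derives
the workflow id as a hash of the canonical representation, transforms cyclic
definitions into an orchestrator-mediated plan, registers them, starts one
persistent service instance per node and collects the per-iteration trace.
Acyclic definitions execute without any orchestrator mediation (plain-DAG
pass-through: the orchestrator sees zero loop events).
"""

from __future__ import annotations

import hashlib
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

from .model import ValidationError, WorkflowGraph, validate_graph
from .orchestrator import Orchestrator
from .runtime import Hub, run_service_loop
from .transform import ExitCondition, insert_orchestrator
from .xmlio import canonical_bytes, parse_workflow_xml

__all__ = ["WorkflowResult", "compute_wf_id", "run_workflow"]


def compute_wf_id(canonical: bytes, salt: bytes = b"") -> str:
    """Deterministic 64-hex-char workflow id: SHA-256 of the canonical form.

    ``salt`` distinguishes concurrent runs of one template (each run needs
    its own registration); the default empty salt is the plain content hash.
    """
    h = hashlib.sha256()
    h.update(canonical)
    if salt:
        h.update(b"\x00")
        h.update(salt)
    return h.hexdigest()


@dataclass
class WorkflowResult:
    """Outcome of one workflow run."""

    wf_id: str
    status: str  # completed | failed | aborted
    outputs: dict[str, list[Any]]  # per-node output trace, one entry per execution
    final_contexts: dict[str, dict[str, Any]]
    iterations: int
    duration_s: float
    loop_participants: set[str] = field(default_factory=set)
    failed_node: str | None = None
    error: str | None = None
    token_log: dict[str, list[str]] = field(default_factory=dict)

    def final_values(self) -> dict[str, Any]:
        return {k: v[-1] for k, v in self.outputs.items() if v}

    def trace(self) -> dict[str, list[Any]]:
        return self.outputs


def run_workflow(
    definition: str | bytes | WorkflowGraph,
    bindings: Mapping[str, Callable] | None = None,
    inputs: Mapping[str, Mapping[str, Any]] | None = None,
    *,
    max_iterations: int | None = None,
    exit_condition: ExitCondition | None = None,
    mode: str = "direct",
    orchestrator: Orchestrator | None = None,
    service_timeout: float = 30.0,
    run_timeout: float = 120.0,
    salt: bytes = b"",
    update_plan: tuple[int, WorkflowGraph] | None = None,
) -> WorkflowResult:
    """Execute a workflow definition to its exit condition.

    ``inputs`` merges values into node initial values ({node_id: {name:
    value}}); ``update_plan=(k, new_graph)`` schedules a hot update effective
    at the first iteration boundary at or after iteration ``k``.
    """
    if isinstance(definition, (str, bytes)):
        graph = parse_workflow_xml(definition)
    else:
        graph = definition.copy()
    # the id hashes the definition as written; run inputs are initialization,
    # not part of the workflow's identity
    wf_id = compute_wf_id(canonical_bytes(graph), salt)
    if inputs:
        for node in graph.nodes:
            merged = inputs.get(node.id) or inputs.get(node.id.split("#", 1)[0])
            if merged:
                node.initial_values.update(merged)

    violations = validate_graph(graph)
    if violations:
        raise ValidationError(violations)

    if exit_condition is None:
        exit_condition = ExitCondition(max_iterations=max_iterations or 1)
    tw = insert_orchestrator(graph, exit_condition)

    hub = Hub(graph, bindings)
    hub.include_context = exit_condition.predicate is not None

    orch = orchestrator
    registered = False
    if tw.has_loop:
        if orch is None:
            orch = Orchestrator()
        attach_hub = None if getattr(orch, "remote", False) else hub
        orch.register_workflow(wf_id, tw, mode=mode, hub=attach_hub)
        registered = True
        if getattr(orch, "remote", False) and mode == "via-orchestrator":
            hub.mail_fetch = lambda node_id: orch.fetch_mail(wf_id, node_id)
        if update_plan is not None:
            k, new_graph = update_plan
            orch.update_workflow(wf_id, new_graph, after_iteration=k)

    t0 = time.monotonic()
    threads = []
    for node in sorted(graph.nodes, key=lambda n: n.id):
        t = threading.Thread(
            target=run_service_loop,
            args=(node.id, hub, orch if tw.has_loop else None, wf_id, mode, service_timeout),
            daemon=True,
            name=f"{wf_id[:8]}:{node.id}",
        )
        threads.append(t)
    for t in threads:
        t.start()

    deadline = time.monotonic() + run_timeout
    for t in threads:
        t.join(max(0.0, deadline - time.monotonic()))
    hung = [t for t in threads if t.is_alive()]
    duration = time.monotonic() - t0

    if hung and hub.failed is None:
        hub.fail(hung[0].name.split(":", 1)[1], "run timeout")
        for t in hung:
            t.join(1.0)

    if tw.has_loop:
        n_iter = max(
            (len(hub.outputs[v]) for v in tw.loop_participants if v in hub.outputs),
            default=0,
        )
        if registered:
            try:
                orch.deregister(wf_id)
            except Exception:
                pass
    else:
        n_iter = 1

    failed_node, error = (hub.failed or (None, None))
    status = "failed" if hub.failed else "completed"
    return WorkflowResult(
        wf_id=wf_id,
        status=status,
        outputs=hub.outputs,
        final_contexts={k: dict(v.variables) for k, v in hub.final_contexts.items()},
        iterations=n_iter,
        duration_s=duration,
        loop_participants=set(tw.loop_participants),
        failed_node=failed_node,
        error=error,
        token_log=hub.token_log,
    )
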