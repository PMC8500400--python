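"""Event-driven service runtime: persistent instances over data channels.

Each service node runs as one *persistent* instance for the whole workflow
(the same instance serves every iteration, so contextual variables survive
across loop traversals).  Per iteration an instance

1. blocks until a fresh value arrived on every inbound *blocking* edge
   (synchronous execution),
2. merges the latest value of every inbound *non-blocking* edge into its
   contextual variables without waiting (asynchronous updates apply to the
   subsequent execution),
3. runs its binding on the gathered inputs and contextual variables,
4. emits the resulting value identically to every destination of each
   outgoing hyperedge, and
5. reports iteration completion to the orchestrator, looping until an exit
   action (or a local failure) stops it.

Values on edges that leave a loop are buffered and flushed only when the
exit condition fires, so downstream DAG segments observe the loop's final
state.

Binding calling convention: ``binding(inputs, variables) -> output`` where
``inputs`` maps inbound edge ids to values and ``variables`` is the node's
mutable contextual-variable dict.  A plain return value is broadcast on all
outgoing hyperedges; returning :class:`PerEdge` ({edge_id: value}) splits
distinct outputs over distinct edges.
"""

from __future__ import annotations

import threading
import time
import uuid
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

from .messages import ControlAction, Event
from .model import Schedule, ServiceNode, WorkflowGraph, iteration_schedule

__all__ = [
    "PerEdge",
    "ServiceContext",
    "InputBinding",
    "ServiceTimeout",
    "BindingError",
    "Hub",
    "gather_sync_inputs",
    "apply_async_updates",
    "run_service_loop",
    "initial_for",
    "resolve_bindings",
]

_POLL = 0.005


class PerEdge(dict):
    """Marker mapping {edge_id: value} for split (per-edge) outputs."""


class ServiceTimeout(RuntimeError):
    pass


class BindingError(RuntimeError):
    pass


class _Aborted(RuntimeError):
    pass


class _ExitSignal(RuntimeError):
    pass


@dataclass
class ServiceContext:
    """A node's persistent state: contextual variables, iteration counter and
    a stable instance token (constant across all iterations of one run)."""

    node_id: str
    variables: dict[str, Any]
    iteration: int = 0
    instance_token: str = field(default_factory=lambda: uuid.uuid4().hex)


@dataclass(frozen=True)
class InputBinding:
    """A value consumed from one inbound edge during one iteration."""

    edge_id: str
    value: Any
    producer_iteration: int
    blocking: bool


def initial_for(node: ServiceNode, edge_id: str) -> Any:
    """Initial value consumed over a loop-carried edge at iteration 1."""
    if edge_id in node.initial_values:
        return node.initial_values[edge_id]
    return node.initial_values.get("init")


def resolve_bindings(
    g: WorkflowGraph, bindings: Mapping[str, Callable] | None
) -> dict[str, Callable]:
    """Map every node to its executable.

    Lookup order: explicit mapping by node id, mapping by base id (the part
    before ``#`` -- unrolled copies share their template's binding), then the
    node's own attached callable.
    """
    bindings = bindings or {}
    out: dict[str, Callable] = {}
    for node in g.nodes:
        base = node.id.split("#", 1)[0]
        fn = bindings.get(node.id) or bindings.get(base)
        if fn is None and callable(node.binding):
            fn = node.binding
        if fn is None:
            raise BindingError(f"no binding resolvable for node {node.id}")
        out[node.id] = fn
    return out


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------


class _BlockingSlot:
    """Per-(edge, destination) channel of iteration-tagged values.

    Duplicate delivery of the same (tag, value) is idempotent.
    """

    def __init__(self) -> None:
        self._values: dict[int, Any] = {}
        self._lock = threading.Lock()

    def put(self, tag: int, value: Any) -> None:
        with self._lock:
            self._values[tag] = value

    def try_get(self, tag: int) -> tuple[bool, Any]:
        with self._lock:
            if tag in self._values:
                return True, self._values[tag]
        return False, None


class _AsyncSlot:
    """Depth-1 latest-value mailbox: last write wins, older values dropped."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self._has = False
        self._value: Any = None
        self._tag = 0
        self._seq = 0

    def put(self, tag: int, value: Any) -> None:
        with self._lock:
            self._seq += 1
            self._has, self._value, self._tag = True, value, tag

    def peek(self) -> tuple[bool, Any, int]:
        with self._lock:
            return self._has, self._value, self._tag


class _Inbox:
    """Per-node queue of control actions."""

    def __init__(self) -> None:
        self._items: deque[ControlAction] = deque()
        self._lock = threading.Lock()

    def push(self, action: ControlAction) -> None:
        with self._lock:
            self._items.append(action)

    def take_exit(self) -> bool:
        with self._lock:
            for a in list(self._items):
                if a.kind == "exit":
                    self._items.remove(a)
                    return True
        return False

    def peek_exit(self) -> bool:
        with self._lock:
            return any(a.kind == "exit" for a in self._items)

    def take_start(self, iteration: int) -> bool:
        with self._lock:
            for a in list(self._items):
                if a.kind == "start-iteration" and a.iteration == iteration:
                    self._items.remove(a)
                    return True
                if a.kind == "start-iteration" and a.iteration < iteration:
                    self._items.remove(a)  # stale
        return False


# inbound-edge classification kinds
_OUTSIDE = "outside"        # blocking, source outside the node's SCC
_FORWARD = "forward"        # blocking, same SCC, same-iteration value
_LOOPBACK = "loopback"      # blocking, same SCC, previous-iteration value


@dataclass
class _NodeInfo:
    role: str                     # "loop" | "once"
    gated: bool                   # waits for start-iteration actions
    inbound: list[tuple[str, str, str]]        # (edge_id, source, kind) blocking only
    inbound_async: list[tuple[str, str, bool]]  # (edge_id, source, same_scc)
    out_pairs: list[tuple[str, str, bool, bool]]  # (edge_id, dest, blocking, same_scc)


class _Plan:
    """Execution wiring derived from the current (possibly hot-updated)
    workflow graph; nodes re-read it at every iteration boundary."""

    def __init__(self, graph: WorkflowGraph, schedule: Schedule | None = None):
        self.graph = graph
        self.schedule = schedule or iteration_schedule(graph)
        sched = self.schedule
        self.node_info: dict[str, _NodeInfo] = {}
        for node in graph.nodes:
            v = node.id
            comp = sched.scc_of[v]
            inbound: list[tuple[str, str, str]] = []
            inbound_async: list[tuple[str, str, bool]] = []
            for eid, src, blocking in sorted(graph.in_pairs(v)):
                same = comp is not None and sched.scc_of[src] == comp
                if blocking:
                    if not same:
                        inbound.append((eid, src, _OUTSIDE))
                    elif (eid, v) in sched.loop_carried:
                        inbound.append((eid, src, _LOOPBACK))
                    else:
                        inbound.append((eid, src, _FORWARD))
                else:
                    inbound_async.append((eid, src, same))
            out_pairs = []
            for e in graph.out_edges(v):
                for d in e.destinations:
                    same = comp is not None and sched.scc_of[d] == comp
                    out_pairs.append((e.id, d, e.blocking, same))
            self.node_info[v] = _NodeInfo(
                role="loop" if comp is not None else "once",
                gated=any(k == _LOOPBACK for _, _, k in inbound),
                inbound=inbound,
                inbound_async=inbound_async,
                out_pairs=out_pairs,
            )


class Hub:
    """Shared in-process channel fabric for one workflow run."""

    def __init__(self, graph: WorkflowGraph, bindings: Mapping[str, Callable] | None):
        self.plan = _Plan(graph)
        self.bindings = resolve_bindings(graph, bindings)
        self._slots: dict[tuple[str, str], Any] = {}
        self._slots_lock = threading.Lock()
        self._inboxes: dict[str, _Inbox] = {n.id: _Inbox() for n in graph.nodes}
        self.outputs: dict[str, list[Any]] = {n.id: [] for n in graph.nodes}
        self._outputs_lock = threading.Lock()
        self.final_contexts: dict[str, ServiceContext] = {}
        self.token_log: dict[str, list[str]] = {n.id: [] for n in graph.nodes}
        self.leave_buffers: dict[str, dict[tuple[str, str], Any]] = {
            n.id: {} for n in graph.nodes
        }
        self.failed: tuple[str, str] | None = None  # (node, reason)
        self.mail_fetch: Callable[[str], list[dict]] | None = None
        self.include_context: bool = False
        self._async_latest: dict[str, tuple[int, Any]] = {}

    # -- channels -----------------------------------------------------------

    def _slot(self, edge_id: str, dest: str, blocking: bool):
        key = (edge_id, dest)
        with self._slots_lock:
            slot = self._slots.get(key)
            if slot is None:
                slot = _BlockingSlot() if blocking else _AsyncSlot()
                self._slots[key] = slot
            return slot

    def push_data(self, edge_id: str, dest: str, tag: int, value: Any, blocking: bool) -> None:
        self._slot(edge_id, dest, blocking).put(tag, value)
        if not blocking:
            self._async_latest[edge_id] = (tag, value)

    def inbox(self, node_id: str) -> _Inbox:
        return self._inboxes[node_id]

    def distribute(self, actions: list[ControlAction]) -> None:
        for a in actions:
            box = self._inboxes.get(a.target_node)
            if box is not None:
                box.push(a)

    def record(self, node_id: str, value: Any) -> None:
        with self._outputs_lock:
            self.outputs[node_id].append(value)

    def fail(self, node_id: str, reason: str) -> None:
        if self.failed is None:
            self.failed = (node_id, reason)

    def rewire(self, graph: WorkflowGraph) -> None:
        """Swap the wiring at an iteration boundary (hot update).  The node
        inventory must be unchanged; running instances keep their contexts."""
        old = {n.id for n in self.plan.graph.nodes}
        new = {n.id for n in graph.nodes}
        if old != new:
            raise ValueError("hot update may not add or remove nodes")
        self.plan = _Plan(graph)
        # the latest value of an async edge is a property of the edge: a
        # redirected destination picks up the last published value
        for node_id, info in self.plan.node_info.items():
            for eid, _src, _same in info.inbound_async:
                if eid in self._async_latest:
                    slot = self._slot(eid, node_id, blocking=False)
                    if not slot.peek()[0]:
                        slot.put(*self._async_latest[eid])

    def drain_mail(self, node_id: str) -> None:
        """Pull pending data deliveries for a node from a remote orchestrator
        mailbox (HTTP via-orchestrator transport) into local channels."""
        if self.mail_fetch is None:
            return
        for item in self.mail_fetch(node_id):
            self.push_data(
                item["edge"], item["dest"], item["tag"], item["value"], item["blocking"]
            )


# ---------------------------------------------------------------------------
# the three runtime operations
# ---------------------------------------------------------------------------


def _wait_blocking(
    hub: Hub, node_id: str, edge_id: str, tag: int, timeout: float
) -> Any:
    slot = hub._slot(edge_id, node_id, blocking=True)
    deadline = time.monotonic() + timeout
    while True:
        hub.drain_mail(node_id)
        ok, value = slot.try_get(tag)
        if ok:
            return value
        if hub.failed is not None:
            raise _Aborted()
        if hub.inbox(node_id).peek_exit():
            hub.inbox(node_id).take_exit()
            raise _ExitSignal()
        if time.monotonic() > deadline:
            raise ServiceTimeout(
                f"node {node_id}: no value on edge {edge_id} (iteration {tag}) "
                f"within {timeout}s"
            )
        time.sleep(_POLL)


def gather_sync_inputs(
    node_id: str, hub: Hub, n: int, timeout: float = 30.0
) -> dict[str, Any]:
    """Block until one fresh value arrived per inbound blocking edge.

    Returns {edge_id: value} tagged for iteration ``n``: forward intra-loop
    edges carry the same-iteration value, loop-carried edges the previous
    iteration's (the declared initial value at n=1), and edges from outside
    the loop are consumed at n=1 only.  Nodes with no inbound blocking edges
    return immediately with an empty mapping.
    """
    info = hub.plan.node_info[node_id]
    node = hub.plan.graph.node(node_id)
    inputs: dict[str, Any] = {}
    for eid, src, kind in info.inbound:
        if kind == _OUTSIDE:
            if n == 1 or info.role == "once":
                inputs[eid] = _wait_blocking(hub, node_id, eid, 1, timeout)
        elif kind == _LOOPBACK:
            if n == 1:
                inputs[eid] = initial_for(node, eid)
            else:
                inputs[eid] = _wait_blocking(hub, node_id, eid, n - 1, timeout)
        else:  # forward
            inputs[eid] = _wait_blocking(hub, node_id, eid, n, timeout)
    return inputs


def apply_async_updates(ctx: ServiceContext, hub: Hub, node_id: str) -> ServiceContext:
    """Merge the latest value of each inbound non-blocking edge into the
    contextual variables (keyed by edge id); absent updates leave variables
    unchanged, and no waiting ever happens."""
    hub.drain_mail(node_id)
    info = hub.plan.node_info[node_id]
    for eid, src, same in info.inbound_async:
        has, value, _tag = hub._slot(eid, node_id, blocking=False).peek()
        if has:
            ctx.variables[eid] = value
    return ctx


def _edge_value(out: Any, edge_id: str) -> Any:
    return out.get(edge_id) if isinstance(out, PerEdge) else out


def _deliver(hub, orch, wf_id, mode, edge_id, dest, tag, value, blocking) -> None:
    if mode == "via-orchestrator" and orch is not None:
        orch.handle_event(
            Event(
                wf_id,
                dest,
                max(tag, 1),
                "data-available",
                payload={
                    "edge": edge_id,
                    "dest": dest,
                    "tag": tag,
                    "value": value,
                    "blocking": blocking,
                },
            )
        )
    else:
        hub.push_data(edge_id, dest, tag, value, blocking)


def _emit(node_id, out, hub, orch, wf_id, mode, n) -> None:
    info = hub.plan.node_info[node_id]
    for eid, dest, blocking, same in info.out_pairs:
        value = _edge_value(out, eid)
        if info.role == "once":
            _deliver(hub, orch, wf_id, mode, eid, dest, 1, value, blocking)
        elif same:
            _deliver(hub, orch, wf_id, mode, eid, dest, n, value, blocking)
        else:
            # leaving a loop: only the final iteration's value is released
            hub.leave_buffers[node_id][(eid, dest)] = value


def _flush_leaving(node_id, hub, orch, wf_id, mode) -> None:
    info = hub.plan.node_info.get(node_id)
    buffered = hub.leave_buffers[node_id]
    for (eid, dest), value in sorted(buffered.items()):
        blocking = True
        if info is not None:
            for e2, d2, b2, _s in info.out_pairs:
                if e2 == eid and d2 == dest:
                    blocking = b2
        _deliver(hub, orch, wf_id, mode, eid, dest, 1, value, blocking)
    buffered.clear()


def run_service_loop(
    node_id: str,
    hub: Hub,
    orch,
    wf_id: str,
    mode: str = "direct",
    timeout: float = 30.0,
) -> ServiceContext:
    """Execute one persistent service instance until its exit condition.

    This is the thread body for every node of a running workflow.  Loop
    participants iterate until the orchestrator sends an exit action;
    one-shot nodes execute exactly once (and never contact the orchestrator,
    preserving plain-DAG pass-through).
    """
    node = hub.plan.graph.node(node_id)
    ctx = ServiceContext(node_id, dict(node.initial_values))
    n = 1
    try:
        while hub.failed is None:
            info = hub.plan.node_info[node_id]
            if info.role == "loop" and n > 1 and info.gated:
                got_start = False
                deadline = time.monotonic() + timeout
                while not got_start:
                    if hub.inbox(node_id).take_exit():
                        raise _ExitSignal()
                    got_start = hub.inbox(node_id).take_start(n)
                    if got_start:
                        break
                    if hub.failed is not None:
                        raise _Aborted()
                    if time.monotonic() > deadline:
                        raise ServiceTimeout(f"node {node_id}: no start action for n={n}")
                    hub.drain_mail(node_id)
                    time.sleep(_POLL)
            elif info.role == "loop" and hub.inbox(node_id).take_exit():
                break

            inputs = gather_sync_inputs(node_id, hub, n, timeout)
            apply_async_updates(ctx, hub, node_id)
            out = hub.bindings[node_id](inputs, ctx.variables)
            ctx.iteration = n
            hub.token_log[node_id].append(ctx.instance_token)
            hub.record(node_id, out)
            _emit(node_id, out, hub, orch, wf_id, mode, n)

            if info.role == "once":
                break

            payload = {}
            if hub.include_context:
                payload["context"] = dict(ctx.variables)
            actions = orch.handle_event(
                Event(wf_id, node_id, n, "iteration-complete", payload=payload)
            )
            hub.distribute(actions)
            if hub.inbox(node_id).take_exit():
                break
            n += 1
    except _ExitSignal:
        pass
    except _Aborted:
        pass
    except ServiceTimeout as exc:
        hub.fail(node_id, str(exc))
    except Exception as exc:  # binding or channel failure
        hub.fail(node_id, f"{type(exc).__name__}: {exc}")
    finally:
        try:
            _flush_leaving(node_id, hub, orch, wf_id, mode)
        except Exception:
            pass
        hub.final_contexts[node_id] = ctx
    return ctx
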