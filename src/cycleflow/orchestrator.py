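"""The logically centralized control-plane service.

The orchestrator registers transformed workflows, routes lightweight control
events, decides the next control actions, evaluates exit conditions and
applies hot workflow updates.  It never touches the bulk data path when
running in ``direct`` mode; in ``via-orchestrator`` mode data updates are
relayed through it as well (the deployment evaluated in the closed-loop use
case), either straight into the run's channel fabric (in-process) or into a
per-node mailbox polled by remote service clients.

Control protocol (per registered workflow):

* ``iteration-complete`` from node ``v`` at iteration ``n`` advances ``v``'s
  progress counter;
* while the exit condition has not fired, a ``start-iteration(n+1)`` action
  is issued (once) to every loop participant that consumes a loop-carried
  channel from ``v`` -- those nodes are gated by the orchestrator, all others
  proceed data-driven;
* a node whose own counter reaches N receives ``exit``; once every
  participant of an SCC reached N (or the exit predicate holds at an
  iteration boundary) outstanding ``exit`` actions go to the whole SCC.
  Exits are issued at most once per node.
* duplicate or stale events are dropped by a (node, iteration, kind) dedup
  key, so replaying an event log reproduces the identical action log.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from typing import Any

from .messages import ControlAction, Event
from .model import ValidationError, WorkflowGraph, validate_graph
from .transform import ExitCondition, TransformedWorkflow, insert_orchestrator

__all__ = ["RegistrationRecord", "Orchestrator", "check_exit"]


class RegistrationError(ValueError):
    pass


class RoutingError(KeyError):
    pass


@dataclass
class RegistrationRecord:
    """Per-workflow control-plane state."""

    wf_id: str
    tw: TransformedWorkflow
    mode: str = "via-orchestrator"
    counters: dict[str, int] = field(default_factory=dict)
    exited: set[str] = field(default_factory=set)
    started: set[tuple[str, int]] = field(default_factory=set)
    seen: set[tuple] = field(default_factory=set)
    context_snapshots: dict[str, dict] = field(default_factory=dict)
    event_log: list[Event] = field(default_factory=list)
    action_log: list[ControlAction] = field(default_factory=list)
    pending_update: tuple[WorkflowGraph, int] | None = None  # (graph, after_iteration)
    hub: Any = None
    status: str = "registered"

    @property
    def loop_participants(self) -> set[str]:
        return set(self.tw.loop_participants)

    def scc_members(self, node_id: str) -> set[str]:
        for comp in self.tw.schedule.sccs:
            if node_id in comp:
                return set(comp)
        return set()


def check_exit(record: RegistrationRecord, snapshot: dict | None = None, n: int | None = None) -> bool:
    """True iff the iteration bound is reached or the exit predicate holds."""
    exit_cond = record.tw.exit_condition
    if n is None:
        n = max(record.counters.values(), default=0)
    if exit_cond.max_iterations is not None and n >= exit_cond.max_iterations:
        return True
    if exit_cond.predicate is not None and snapshot is not None:
        return bool(exit_cond.predicate(snapshot))
    return False


class Orchestrator:
    """In-process control-plane service (the HTTP layer wraps this)."""

    def __init__(self) -> None:
        self._records: dict[str, RegistrationRecord] = {}
        self._lock = threading.RLock()
        self._mailboxes: dict[tuple[str, str], list[dict]] = {}

    # -- registration -------------------------------------------------------

    def register_workflow(
        self,
        wf_id: str,
        tw: TransformedWorkflow,
        mode: str = "via-orchestrator",
        hub: Any = None,
    ) -> RegistrationRecord:
        with self._lock:
            if wf_id in self._records:
                raise RegistrationError(f"workflow {wf_id} already registered")
            rec = RegistrationRecord(
                wf_id=wf_id,
                tw=tw,
                mode=mode,
                counters={v: 0 for v in sorted(tw.loop_participants)},
                hub=hub,
            )
            self._records[wf_id] = rec
            return rec

    def deregister(self, wf_id: str) -> None:
        with self._lock:
            self._records.pop(wf_id, None)
            for key in [k for k in self._mailboxes if k[0] == wf_id]:
                del self._mailboxes[key]

    def record(self, wf_id: str) -> RegistrationRecord:
        with self._lock:
            rec = self._records.get(wf_id)
        if rec is None:
            raise RoutingError(f"unknown workflow {wf_id}")
        return rec

    def status(self, wf_id: str) -> dict:
        rec = self.record(wf_id)
        return {
            "wf_id": wf_id,
            "status": rec.status,
            "counters": dict(rec.counters),
            "exited": sorted(rec.exited),
            "loop_participants": sorted(rec.loop_participants),
        }

    # -- events -------------------------------------------------------------

    def handle_event(self, ev: Event) -> list[ControlAction]:
        rec = self.record(ev.wf_id)
        with self._lock:
            if ev.kind == "data-available":
                return self._handle_data(rec, ev)
            if ev.kind == "heartbeat":
                return []
            key = (ev.node_id, ev.iteration, ev.kind)
            if key in rec.seen:
                return []  # duplicate delivery: idempotent
            if ev.kind == "iteration-complete":
                if ev.iteration < rec.counters.get(ev.node_id, 0):
                    return []  # stale
            rec.seen.add(key)
            rec.event_log.append(ev)
            if ev.kind == "update-request":
                return []
            return self._handle_iteration_complete(rec, ev)

    def _handle_data(self, rec: RegistrationRecord, ev: Event) -> list[ControlAction]:
        p = ev.payload
        key = ("data", p["edge"], p["dest"], p["tag"])
        if key in rec.seen:
            return []
        rec.seen.add(key)
        if rec.hub is not None:
            rec.hub.push_data(p["edge"], p["dest"], p["tag"], p["value"], p["blocking"])
        else:
            self._mailboxes.setdefault((rec.wf_id, p["dest"]), []).append(dict(p))
        return []

    def fetch_mail(self, wf_id: str, node_id: str) -> list[dict]:
        """Drain pending data deliveries for a remote service client."""
        with self._lock:
            items = self._mailboxes.pop((wf_id, node_id), [])
        return items

    def _handle_iteration_complete(
        self, rec: RegistrationRecord, ev: Event
    ) -> list[ControlAction]:
        v, n = ev.node_id, ev.iteration
        if v not in rec.counters:
            return []  # one-shot nodes never loop; ignore defensively
        rec.counters[v] = max(rec.counters[v], n)
        rec.status = "running"
        if "context" in ev.payload:
            rec.context_snapshots[v] = ev.payload["context"]

        actions: list[ControlAction] = []
        exit_cond = rec.tw.exit_condition
        members = rec.scc_members(v)
        at_boundary = all(rec.counters[w] == n for w in members)

        # hot update pending: apply at a quiescent boundary
        if rec.pending_update is not None and at_boundary:
            new_graph, after = rec.pending_update
            if n >= after:
                actions.extend(self._apply_update(rec, new_graph))
                if v not in rec.counters:  # loop dissolved
                    self._log(rec, actions)
                    return actions
                members = rec.scc_members(v)
                exit_cond = rec.tw.exit_condition

        n_max = exit_cond.max_iterations
        predicate_fired = (
            at_boundary
            and exit_cond.predicate is not None
            and rec.context_snapshots
            and check_exit(rec, rec.context_snapshots, n=0)
        )

        if predicate_fired or (n_max is not None and n >= n_max):
            targets = members if predicate_fired else {
                w for w in members if rec.counters[w] >= (n_max or 0)
            }
            if n_max is not None and all(rec.counters[w] >= n_max for w in members):
                targets = set(members)
            for w in sorted(targets):
                if w not in rec.exited:
                    rec.exited.add(w)
                    actions.append(ControlAction(w, "exit", n))
            if rec.exited >= rec.loop_participants:
                rec.status = "exiting"
        else:
            for eid, dest in sorted(rec.tw.schedule.loop_carried):
                if dest not in members:
                    continue
                edge = next(
                    (e for e in rec.tw.original.hyperedges if e.id == eid), None
                )
                if edge is None or edge.source != v:
                    continue
                nxt = n + 1
                if n_max is not None and nxt > n_max:
                    continue  # never over-run the bound
                if (dest, nxt) not in rec.started and dest not in rec.exited:
                    rec.started.add((dest, nxt))
                    actions.append(ControlAction(dest, "start-iteration", nxt))

        self._log(rec, actions)
        return actions

    @staticmethod
    def _log(rec: RegistrationRecord, actions: list[ControlAction]) -> None:
        rec.action_log.extend(actions)

    # -- hot update ----------------------------------------------------------

    def update_workflow(
        self, wf_id: str, new_graph: WorkflowGraph, after_iteration: int = 0
    ) -> dict:
        """Replace a workflow definition at the next iteration boundary.

        Running service instances keep their contexts; the node inventory
        must stay unchanged.  Invalid graphs are rejected and the old plan is
        left untouched.
        """
        violations = validate_graph(new_graph)
        if violations:
            raise ValidationError(violations)
        rec = self.record(wf_id)
        with self._lock:
            old = {n.id for n in rec.tw.original.nodes}
            new = {n.id for n in new_graph.nodes}
            if old != new:
                raise ValidationError(["hot update may not add or remove nodes"])
            if new_graph == rec.tw.original:
                return {"wf_id": wf_id, "update": "noop"}
            if (
                after_iteration == 0
                and rec.status == "registered"
                and not any(rec.counters.values())
            ):
                acts = self._apply_update(rec, new_graph)
                rec.action_log.extend(acts)
                if rec.hub is not None:
                    rec.hub.distribute(acts)
                return {"wf_id": wf_id, "update": "applied"}
            rec.pending_update = (new_graph, after_iteration)
            return {"wf_id": wf_id, "update": "pending"}

    def _apply_update(
        self, rec: RegistrationRecord, new_graph: WorkflowGraph
    ) -> list[ControlAction]:
        new_tw = insert_orchestrator(new_graph, rec.tw.exit_condition)
        old_participants = set(rec.counters)
        new_participants = set(new_tw.loop_participants)
        actions: list[ControlAction] = []
        for w in sorted(old_participants - new_participants):
            if w not in rec.exited:
                rec.exited.add(w)
                actions.append(ControlAction(w, "exit", rec.counters.get(w, 0)))
            rec.counters.pop(w, None)
        for w in sorted(new_participants - old_participants):
            rec.counters[w] = 0
        rec.tw = new_tw
        rec.pending_update = None
        if rec.hub is not None:
            rec.hub.rewire(new_graph)
        return actions

    # -- misc ---------------------------------------------------------------

    def loop_event_count(self, wf_id: str) -> int:
        return len(self.record(wf_id).event_log)

    @property
    def remote(self) -> bool:
        return False
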