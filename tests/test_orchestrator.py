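"""Control-plane semantics: registration, event routing, exits, hot updates."""

import pytest

import cycleflow as cf
from cycleflow.messages import Event
from cycleflow.model import graph as make_graph
from cycleflow.orchestrator import Orchestrator, RegistrationError, RoutingError, check_exit
from cycleflow.fixtures import two_node_loop_graph

EXIT20 = cf.ExitCondition(max_iterations=20)


def register_loop(orch, wf_id="wf", n=20, graph=None):
    g = graph if graph is not None else two_node_loop_graph("PM", "CTL", init=0)
    tw = cf.insert_orchestrator(g, cf.ExitCondition(max_iterations=n))
    return orch.register_workflow(wf_id, tw), g


def drive_full_loop(orch, wf_id, n_max, members=("PM", "CTL")):
    """Feed the complete event sequence of one run; return actions per event."""
    log = []
    for n in range(1, n_max + 1):
        for v in members:
            log.append((v, n, orch.handle_event(Event(wf_id, v, n, "iteration-complete"))))
    return log


class TestRegistration:
    def test_loop_record_has_zero_counters(self, tail_loop):
        orch = Orchestrator()
        tw = cf.insert_orchestrator(tail_loop, EXIT20)
        rec = orch.register_workflow("w1", tw)
        assert rec.loop_participants == {"F", "G"}
        assert rec.counters == {"F": 0, "G": 0}

    def test_dag_record_is_passive(self):
        orch = Orchestrator()
        g = make_graph(["A", "B"], [("e1", "A", "B")])
        rec = orch.register_workflow("w1", cf.insert_orchestrator(g, EXIT20))
        assert rec.counters == {}

    def test_duplicate_wf_id_conflicts(self):
        orch = Orchestrator()
        register_loop(orch, "dup")
        with pytest.raises(RegistrationError):
            register_loop(orch, "dup")

    def test_hundred_registrations_are_isolated(self):
        orch = Orchestrator()
        for i in range(100):
            register_loop(orch, f"wf{i}", n=3)
        solo = Orchestrator()
        register_loop(solo, "wf0", n=3)
        expected = drive_full_loop(solo, "wf0", 3)
        for i in (0, 42, 99):
            got = drive_full_loop(orch, f"wf{i}", 3)
            assert [(v, n, [a.to_dict() for a in acts]) for v, n, acts in got] == [
                (v, n, [a.to_dict() for a in acts]) for v, n, acts in expected
            ]


class TestHandleEvent:
    def test_completion_starts_gated_successor(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=20)
        orch.handle_event(Event("wf", "PM", 3, "iteration-complete"))
        actions = orch.handle_event(Event("wf", "CTL", 3, "iteration-complete"))
        assert [a.to_dict() for a in actions] == [
            {"target_node": "PM", "kind": "start-iteration", "iteration": 4}
        ]

    def test_exit_reaches_both_nodes_at_the_bound(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=3)
        log = drive_full_loop(orch, "wf", 3)
        exits = [
            (a.target_node, n)
            for _v, n, acts in log
            for a in acts
            if a.kind == "exit"
        ]
        assert sorted(a for a, _n in exits) == ["CTL", "PM"]
        assert all(n == 3 for _a, n in exits)

    def test_no_start_beyond_the_bound(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=3)
        log = drive_full_loop(orch, "wf", 3)
        starts = [a.iteration for _v, _n, acts in log for a in acts
                  if a.kind == "start-iteration"]
        assert starts and max(starts) <= 3

    def test_exit_issued_at_most_once_per_node(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=2)
        log = drive_full_loop(orch, "wf", 2)
        exits = [a.target_node for _v, _n, acts in log for a in acts if a.kind == "exit"]
        assert sorted(exits) == ["CTL", "PM"]

    def test_duplicate_events_are_idempotent(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=20)
        ev = Event("wf", "PM", 1, "iteration-complete")
        first = orch.handle_event(ev)
        assert orch.handle_event(Event("wf", "PM", 1, "iteration-complete")) == []
        assert orch.record("wf").counters["PM"] == 1
        assert first is not None

    def test_unknown_workflow_is_routing_error(self):
        orch = Orchestrator()
        with pytest.raises(RoutingError):
            orch.handle_event(Event("ghost", "PM", 1, "iteration-complete"))

    def test_replaying_event_log_reproduces_action_log(self):
        orch = Orchestrator()
        register_loop(orch, "wf", n=4)
        drive_full_loop(orch, "wf", 4)
        rec = orch.record("wf")
        replay = Orchestrator()
        register_loop(replay, "wf", n=4)
        for ev in rec.event_log:
            replay.handle_event(ev)
        assert [a.to_dict() for a in replay.record("wf").action_log] == [
            a.to_dict() for a in rec.action_log
        ]

    def test_concurrent_workflow_actions_never_cross(self):
        orch = Orchestrator()
        register_loop(orch, "x", n=3)
        g2 = two_node_loop_graph("P2", "C2", init=0)
        register_loop(orch, "y", n=3, graph=g2)
        # interleave events of both workflows
        for n in range(1, 4):
            for v, wf in (("PM", "x"), ("P2", "y"), ("CTL", "x"), ("C2", "y")):
                for a in orch.handle_event(Event(wf, v, n, "iteration-complete")):
                    if wf == "x":
                        assert a.target_node in {"PM", "CTL"}
                    else:
                        assert a.target_node in {"P2", "C2"}


class TestCheckExit:
    def test_bound_reached(self):
        orch = Orchestrator()
        rec, _ = register_loop(orch, "wf", n=20)
        rec.counters = {"PM": 20, "CTL": 20}
        assert check_exit(rec) is True

    def test_bound_not_reached(self):
        orch = Orchestrator()
        rec, _ = register_loop(orch, "wf", n=20)
        rec.counters = {"PM": 19, "CTL": 19}
        assert check_exit(rec) is False

    def test_improvement_predicate_fires_when_oracle_says(self):
        # objective trace converging geometrically; predicate: improvement
        # of the best value < 1e-6 over the last 5 iterations
        trace = [1 - 0.5**k for k in range(1, 41)]

        def improvement_converged(contexts):
            hist = contexts["CTL"]["history"]
            return len(hist) >= 6 and (max(hist) - max(hist[:-5])) < 1e-6

        # oracle: recompute the firing iteration directly from the trace
        fire_at = next(
            k for k in range(6, 41)
            if trace[k - 1] - trace[k - 6] < 1e-6
        )
        exit_cond = cf.ExitCondition(max_iterations=40, predicate=improvement_converged)
        orch = Orchestrator()
        g = two_node_loop_graph("PM", "CTL", init=0)
        tw = cf.insert_orchestrator(g, exit_cond)
        rec = orch.register_workflow("wf", tw)
        fired = None
        for n in range(1, 41):
            orch.handle_event(Event("wf", "PM", n, "iteration-complete"))
            acts = orch.handle_event(Event(
                "wf", "CTL", n, "iteration-complete",
                payload={"context": {"history": trace[:n]}},
            ))
            if any(a.kind == "exit" for a in acts):
                fired = n
                break
        assert fired == fire_at


class TestHotUpdate:
    def test_identical_graph_is_noop(self):
        orch = Orchestrator()
        _, g = register_loop(orch, "wf", n=5)
        assert orch.update_workflow("wf", g.copy())["update"] == "noop"

    def test_invalid_update_rejected_old_plan_kept(self):
        orch = Orchestrator()
        _, g = register_loop(orch, "wf", n=5)
        bad = g.copy()
        bad.nodes = bad.nodes[:1]
        with pytest.raises(cf.ValidationError):
            orch.update_workflow("wf", bad)
        assert orch.record("wf").tw.original == g

    def test_node_inventory_must_not_change(self):
        orch = Orchestrator()
        _, g = register_loop(orch, "wf", n=5)
        bigger = g.copy()
        bigger.nodes.append(cf.ServiceNode("X"))
        with pytest.raises(cf.ValidationError):
            orch.update_workflow("wf", bigger)

    def test_update_removing_loop_exits_at_boundary(self):
        orch = Orchestrator()
        _, g = register_loop(orch, "wf", n=10)
        drive_full_loop(orch, "wf", 2)
        acyclic = g.copy()
        acyclic.hyperedges = [e for e in acyclic.hyperedges if e.id != "back"]
        assert orch.update_workflow("wf", acyclic)["update"] == "pending"
        orch.handle_event(Event("wf", "PM", 3, "iteration-complete"))
        acts = orch.handle_event(Event("wf", "CTL", 3, "iteration-complete"))
        assert sorted(a.target_node for a in acts if a.kind == "exit") == ["CTL", "PM"]
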