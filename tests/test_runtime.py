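"""Service-instance semantics: blocking gather, async mailbox, emission."""

import itertools
import threading

import pytest

import cycleflow as cf
from cycleflow.fixtures import example_dhg_graph, increment, increment_bindings
from cycleflow.model import graph as make_graph
from cycleflow.runtime import (
    Hub,
    PerEdge,
    ServiceContext,
    ServiceTimeout,
    apply_async_updates,
    gather_sync_inputs,
)


def example_hub():
    g = example_dhg_graph()
    g.node("A").initial_values["init"] = 0
    return Hub(g, increment_bindings(g))


class TestGatherSyncInputs:
    def test_node_b_waits_for_e1_but_not_e5(self):
        """At n=2, B blocks on the synchronous hyperedge from A only; the
        non-blocking feedback edge from E never gates its iteration."""
        hub = example_hub()
        got = {}

        def consumer():
            got["inputs"] = gather_sync_inputs("B", hub, 2, timeout=5.0)

        t = threading.Thread(target=consumer, daemon=True)
        t.start()
        t.join(0.1)
        assert t.is_alive()  # still blocked: e1's iteration-2 value missing
        hub.push_data("e1", "B", 2, 41, blocking=True)
        t.join(5.0)
        assert not t.is_alive()
        assert got["inputs"] == {"e1": 41}  # e5 absent: async edges never gathered

    def test_no_inbound_blocking_edges_returns_immediately(self):
        g = make_graph(["A", "B"], [("e1", "A", "B", False)])
        hub = Hub(g, {"A": increment, "B": increment})
        assert gather_sync_inputs("B", hub, 1, timeout=0.5) == {}

    def test_out_of_order_delivery_equals_ordered(self):
        """Node D consumes e2 (from B) and e3 (from C); any channel delivery
        order yields the same gathered set."""
        results = []
        for order in itertools.permutations([("e2", 7), ("e3", 9)]):
            hub = example_hub()
            for eid, val in order:
                hub.push_data(eid, "D", 1, val, blocking=True)
            results.append(gather_sync_inputs("D", hub, 1, timeout=2.0))
        assert results[0] == results[1] == {"e2": 7, "e3": 9}

    def test_loop_carried_edge_reads_initial_value_at_first_iteration(self):
        hub = example_hub()
        inputs = gather_sync_inputs("A", hub, 1, timeout=1.0)
        assert inputs == {"e6": 0}  # A's declared initial value

    def test_timeout_raises(self):
        hub = example_hub()
        with pytest.raises(ServiceTimeout):
            gather_sync_inputs("B", hub, 1, timeout=0.05)


class TestApplyAsyncUpdates:
    def test_no_pending_updates_leaves_context_unchanged(self):
        hub = example_hub()
        ctx = ServiceContext("B", {"init": 5})
        apply_async_updates(ctx, hub, "B")
        assert ctx.variables == {"init": 5}

    def test_last_write_wins(self):
        """Two queued updates on e5: only the newest value is retained."""
        hub = example_hub()
        hub.push_data("e5", "B", 1, 10, blocking=False)
        hub.push_data("e5", "B", 2, 20, blocking=False)
        ctx = ServiceContext("B", {})
        apply_async_updates(ctx, hub, "B")
        assert ctx.variables["e5"] == 20

    def test_update_applies_to_subsequent_execution_not_current(self, increment_ring):
        """A value landing on the async edge mid-iteration is visible only at
        the next execution."""
        g = example_dhg_graph()
        g.node("A").initial_values["init"] = 0
        seen = []

        def b_binding(inputs, variables):
            seen.append(variables.get("e5"))
            return sum(v for v in inputs.values() if v is not None) + 1

        bindings = increment_bindings(g)
        bindings["B"] = b_binding
        res = cf.run_workflow(g, bindings, max_iterations=3, run_timeout=15, service_timeout=5)
        assert res.status == "completed"
        # E emits e5 during iteration n; B reads it at n+1
        assert seen[0] is None
        assert seen[1:] == res.outputs["E"][: len(seen) - 1]


class TestServiceLoop:
    def test_increment_cycle_ends_at_fifteen(self, increment_ring):
        g, bindings = increment_ring
        res = cf.run_workflow(g, bindings, max_iterations=5, run_timeout=15, service_timeout=5)
        assert res.status == "completed"
        # oracle: sequential simulation, 3 increments x 5 iterations on 0
        assert res.final_values()["C"] == 15
        assert res.outputs["C"] == [3, 6, 9, 12, 15]

    def test_single_node_identity_run(self):
        g = make_graph(["A"], [], entrypoint="A", initial_values={"A": {"init": 7}})
        res = cf.run_workflow(
            g, {"A": lambda inputs, var: var.get("init")}, max_iterations=1,
            run_timeout=10, service_timeout=5,
        )
        assert res.status == "completed"
        assert res.final_contexts["A"]["init"] == 7
        assert res.outputs["A"] == [7]

    def test_instance_token_constant_across_iterations(self, increment_ring):
        """One persistent instance serves all iterations (no re-instantiation)."""
        g, bindings = increment_ring
        res = cf.run_workflow(g, bindings, max_iterations=5, run_timeout=15, service_timeout=5)
        for node, tokens in res.token_log.items():
            assert len(tokens) == 5
            assert len(set(tokens)) == 1

    def test_multi_destination_hyperedge_delivers_equal_values(self):
        g = example_dhg_graph()
        g.node("A").initial_values["init"] = 0
        seen = {"B": [], "C": []}

        def spy(node):
            def fn(inputs, variables):
                seen[node].append(inputs.get("e1"))
                return sum(v for v in inputs.values() if v is not None) + 1
            return fn

        bindings = increment_bindings(g)
        bindings["B"] = spy("B")
        bindings["C"] = spy("C")
        res = cf.run_workflow(g, bindings, max_iterations=4, run_timeout=15, service_timeout=5)
        assert res.status == "completed"
        assert seen["B"] == seen["C"] == res.outputs["A"]

    def test_synchronous_lockstep_counters_differ_by_at_most_one(self):
        g = example_dhg_graph()
        g.node("A").initial_values["init"] = 0
        orch = cf.Orchestrator()
        counters = {v: 0 for v in "ABCDE"}
        spreads = []
        original = orch.handle_event

        def tracking(ev):
            if ev.kind == "iteration-complete":
                counters[ev.node_id] = ev.iteration
                spreads.append(max(counters.values()) - min(counters.values()))
            return original(ev)

        orch.handle_event = tracking
        res = cf.run_workflow(
            example_dhg_graph(), increment_bindings(g), inputs={"A": {"init": 0}},
            max_iterations=6, orchestrator=orch, run_timeout=15, service_timeout=5,
        )
        assert res.status == "completed"
        assert max(spreads) <= 1

    def test_async_edge_absence_never_deadlocks(self):
        """Removing every non-blocking value source leaves consumers live."""
        g = example_dhg_graph()
        g.node("A").initial_values["init"] = 0
        bindings = increment_bindings(g)
        # E emits nothing usable on e5 (None) -- B must still iterate freely
        res = cf.run_workflow(g, bindings, max_iterations=3, run_timeout=15, service_timeout=5)
        assert res.status == "completed"
        assert len(res.outputs["B"]) == 3

    def test_split_outputs_travel_on_separate_edges(self):
        g = make_graph(
            ["A", "B", "C"],
            [("eb", "A", "B"), ("ec", "A", "C")],
            entrypoint="A",
        )

        def splitter(inputs, variables):
            return PerEdge({"eb": 10, "ec": 20})

        def passthrough(inputs, variables):
            return list(inputs.values())[0]

        res = cf.run_workflow(
            g, {"A": splitter, "B": passthrough, "C": passthrough},
            run_timeout=10, service_timeout=5,
        )
        assert res.status == "completed"
        assert res.final_values()["B"] == 10
        assert res.final_values()["C"] == 20

    def test_binding_exception_fails_run_with_node_recorded(self, increment_ring):
        g, bindings = increment_ring

        def boom(inputs, variables):
            raise RuntimeError("sensor offline")

        bindings = dict(bindings)
        bindings["B"] = boom
        res = cf.run_workflow(g, bindings, max_iterations=3, run_timeout=10, service_timeout=2)
        assert res.status == "failed"
        assert res.failed_node == "B"
        assert "sensor offline" in res.error
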