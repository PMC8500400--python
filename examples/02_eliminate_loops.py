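"""Eliminate dicycles from the control plane.

Transforms the two reference workflows: a chain feeding a terminal two-node
loop, and a loop sitting between two DAG segments.  In both cases the loop's
internal edges move to the data plane and a single orchestrator node O takes
the loop's place in the (now acyclic) control graph.
"""

import cycleflow as cf
from cycleflow.fixtures import chain_mid_loop_graph, chain_tail_loop_graph

exit_cond = cf.ExitCondition(max_iterations=20)

for name, g in (
    ("terminal loop  A→B→(C+D)→E→F↔G", chain_tail_loop_graph()),
    ("mid-chain loop A→B→(C+D)→E↔F→(G+H)→I", chain_mid_loop_graph()),
):
    tw = cf.insert_orchestrator(g, exit_cond)
    print(name)
    print("  control plane:", cf.arrow_notation(tw.control_graph))
    print("  data channels:", ", ".join(f"{c.source}→{c.dest}" for c in tw.data_channels))
    print("  loop nodes:   ", sorted(tw.loop_participants))
    print("  DAG segments: ", [sorted(s.node_ids()) for s in tw.dag_segments])
    print()

# The control plane is acyclic (any engine can run it); the loop members keep
# exchanging data directly over the channels while O decides, per iteration,
# whether to start the next round or fire the exit condition.

# A simple loop can instead be unrolled into a DAG of N chained body copies:
from cycleflow.model import graph as make_graph

ring = make_graph(
    ["A", "B", "C"],
    [("eab", "A", "B"), ("ebc", "B", "C"), ("eca", "C", "A")],
    entrypoint="A",
)
unrolled = cf.unroll_simple_loop(ring, 3)
print("unrolled A→B→C→A, N=3:", cf.arrow_notation(unrolled))
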