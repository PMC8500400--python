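"""Parse a workflow definition and inspect its structure.

Builds the five-node closed-loop example from its XML text, prints the
{source, [destinations]} adjacency the engine works with, the workflow class
(DAG / DG / DHG) and the dicycle that makes it unrunnable on an acyclic-only
engine.
"""

import cycleflow as cf
from cycleflow.fixtures import EXAMPLE_DHG_XML

g = cf.parse_workflow_xml(EXAMPLE_DHG_XML)

print("nodes:      ", ", ".join(g.node_ids()))
print("entrypoint: ", ", ".join(g.entrypoints()))
print("adjacency:")
for pair in cf.to_adjacency(g):
    flag = "blocking" if pair["blocking"] else "non-blocking"
    print(f"  {pair['edge']}: {pair['source']} -> {pair['destinations']}  ({flag})")
print("class:      ", cf.classify(g).value)
print("dicycles:   ", [sorted(c) for c in cf.find_dicycles(g)])

# The class is DHG because e1..e3 deliver one identical output to several
# destinations, and the return edges e5/e6 put all five services on a
# directed cycle -- the structure a plain DAG engine cannot express.
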