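# cycleflow

A workflow engine for **closed-loop pipelines**: workflows that contain
feedback cycles, such as closed-loop neuromodulation control systems where a
controller repeatedly stimulates a neural model and adapts to the measured
response.

Standard scientific workflow engines execute directed *acyclic* graphs: a
fixed start, a fixed end, no cycles. Control systems do not fit that mold —
their essence is the dicycle. cycleflow represents workflows as **directed
hypergraphs** (DHGs) and makes them runnable on the software-defined-networking
idea of separating planes:

* **data plane** — service nodes exchange values directly over channels, one
  persistent instance per node so local context survives across iterations;
* **control plane** — a logically centralized *orchestrator* `O` replaces
  every dicycle in the control graph: loop-internal edges move to the data
  plane, edges entering the loop are redirected to `O`, and `O` drives
  iterations with lightweight events until an exit condition (the Nth
  iteration, or a predicate) fires.

Formally, a workflow `W = A→B→(C+D)→E→F↔G` (where `(C+D)` is a hyperedge
delivering one identical output to C and D, and `F↔G` is a dicycle) becomes
the acyclic control plan

```
W = A→B→(C+D)→E→O→(F+G),   fₙ = F(G(fₙ₋₁)),  gₙ = G(F(gₙ₋₁)),  n ≤ N
```

with data channels `{F→G, G→F}`. Simple loops can alternatively be *unrolled*
into a DAG of N chained body copies (`A#1→B#1→…→A#N→…`).

The package provides, as a library plus a thin `cycleflow` CLI:

* the DHG data model with validation, DAG/DG/DHG classification and dicycle
  detection (`cycleflow.model`);
* an XML dialect reader/writer and a canonical byte form whose SHA-256 is the
  workflow id (`cycleflow.xmlio`, `cycleflow.executor`);
* the loop-elimination transform, loop unrolling and DAG-segment partitioning
  (`cycleflow.transform`);
* the orchestrator (in-process object and a REST/JSON HTTP server) and the
  event-driven service runtime (`cycleflow.orchestrator`, `cycleflow.runtime`,
  `cycleflow.httpd`);
* a single-threaded reference simulator that defines the value semantics and
  cross-checks every execution path (`cycleflow.simulator`);
* a closed-loop neuromodulation demo — Bayesian optimization (GPR surrogate,
  UCB acquisition) of stimulation amplitude and frequency against a synthetic
  neural plant (`cycleflow.neuromod`);
* a concurrency load harness (`cycleflow.bench`).

## Worked example

`examples/04_bayesian_optimization_demo.py` runs the two-node plant↔controller
workflow through the orchestrator for 20 iterations (5 burn-in):

```
iter  phase         amplitude  freq(Hz)  gamma-power  best-so-far
   1  burn-in           6.370     48.89       0.5993       0.5993
   2  burn-in           0.410     31.16       0.0003       0.5993
   ...
   6  model-guided      6.452     56.70       0.9197       0.9197
  10  model-guided      6.582     62.62       0.9979       0.9979
  14  model-guided      6.504     61.90       1.0000       1.0000
  20  model-guided      6.498     61.91       1.0000       1.0000

best found: amplitude=6.500, frequency=62.00 Hz, gamma-band power=1.0000
true optimum: amplitude=6.5, frequency=62.0 Hz, peak=1.0
```

Each row is one loop iteration: the controller proposes stimulation
parameters, the plant returns the γ-band power of the excitatory population,
and `best-so-far` (non-decreasing by construction) tracks the incumbent. After
the random burn-in, the surrogate-guided proposals recover the synthetic
plant's known optimum essentially exactly.

The other example scripts cover parsing/classification, loop elimination and
unrolling, executing a cyclic workflow with a simulator cross-check, and the
concurrency load test. The same capabilities are reachable from a shell:

```bash
cycleflow inspect workflow.xml          # class, adjacency, dicycles
cycleflow transform workflow.xml        # orchestrator-mediated control plan
cycleflow run workflow.xml --max-iter 5 # execute to the exit condition
cycleflow demo --budget 20 --burn-in 5  # closed-loop optimization demo
cycleflow loadtest --k 100 --rampup 1   # concurrency test
```

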