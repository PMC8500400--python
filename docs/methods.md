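# Methods

## Workflow model

A workflow is a set of labeled service nodes plus hyperedges, each a
`{source, [destinations]}` relation: the source's output is delivered
*identically* to every destination. Distinct per-destination outputs are
modeled as separate edges (a binding returns a `PerEdge` mapping); hyperedges
never have intermediate nodes or multiple sources. Edges are blocking
(synchronous — the destination waits for a fresh value each iteration) or
non-blocking (asynchronous — the latest value is merged into the
destination's contextual variables without waiting). Classification is by
most specific class: `DAG` (acyclic, single-destination edges), `DG` (a
dicycle present, single-destination edges), `DHG` (any multi-destination
hyperedge). Dicycles are detected as strongly connected components (SCCs),
not individual simple cycles: orchestrator insertion needs the full
loop-participant set, and simple-cycle counts explode combinatorially. A
bidirectional edge `A↔B` is stored as two directed edges.

## Execution semantics (the iteration schedule)

Cyclic execution needs a convention for which values cross the iteration
boundary. The engine derives, per graph, a deterministic *iteration
schedule*: condensation components in topological order; within an SCC a
Kahn elimination over blocking intra-SCC edges that, when stalled, forces the
entrypoint member (else the lexicographically smallest) and marks its
still-unsatisfied blocking in-edges **loop-carried**. Then:

* nodes outside any SCC execute exactly once; nodes in an SCC execute once
  per iteration, N times;
* a blocking forward intra-SCC edge carries the same-iteration value; a
  loop-carried edge carries the previous iteration's value (iteration 1 reads
  the destination's declared initial value);
* blocking inputs from outside the SCC are consumed at iteration 1 only;
* non-blocking edges are depth-1 latest-value mailboxes (last write wins),
  merged into contextual variables keyed by edge id before each execution —
  a value arriving mid-iteration affects the *next* execution;
* edges leaving an SCC release only the final iteration's value, after the
  exit condition fires, so downstream DAG segments observe the loop's final
  state;
* when one variable arrives over both a blocking and a non-blocking edge, the
  blocking value defines the iteration's dataflow (inputs and contextual
  variables are separate namespaces, keyed by edge id).

This schedule is a *definition*, implemented once and consumed by two fully
independent execution paths: the single-threaded reference simulator
(`cycleflow.simulate`, a plain fixed-point loop over the original cyclic
graph) and the live engine (one thread per persistent service instance,
channels, orchestrator events). Trace equality between the two is the
package's core correctness check, asserted over randomized workflows in both
transport modes.

Bindings follow `binding(inputs, variables) -> output`: `inputs` maps inbound
edge ids to values, `variables` is the node's mutable contextual-variable
dict (seeded from declared initial values and persisted across iterations —
one instance per node for the whole run, never re-instantiated, which is what
makes cross-iteration context possible at all).

## Loop elimination

Per SCC: internal edges become data channels; edges entering the SCC from
outside are redirected to the single orchestrator node `O`; `O` gains one
hyperedge fanning out to the SCC members. Edges *sourced* inside an SCC whose
destination can reach any SCC also travel on the data plane (released at
exit) — with one logically centralized `O`, keeping such an edge in the
control graph would put `O` itself on a dicycle whenever one loop feeds
another; `O` already sequences the loops, so only loop outputs feeding pure
downstream DAG segments stay in the control plane. This guarantees the
control graph is acyclic for arbitrary input (property-tested over randomized
graphs with up to three SCCs) while preserving the printed worked examples.

DAG segments are the weakly connected components left after dropping
SCC-internal edges and edges sourced at loop participants; a loop member with
no remaining incident edge belongs to no segment (it is reachable only
through the orchestrator) — segments are pairwise disjoint and
`union(segments) ∪ loop participants` covers all nodes.

Simple loops (one cycle, no split/merge) can be unrolled instead:
N chained copies `A#1→B#1→…→C#N`, copy 1 carrying the initial values.
Unrolling rejects nested/multiple loops; those go through the orchestrator.

## Orchestrator protocol

Workflows register under an id that is the SHA-256 of the canonical byte form
(sorted nodes/edges, normalized attributes; declaration order never matters).
An optional salt distinguishes concurrent runs of one template — each needs
its own registration. Per `iteration-complete(v, n)` event:

* `n < N`: a `start-iteration(n+1)` action is issued (once per (node,
  iteration)) to each loop participant consuming a loop-carried channel from
  `v`. Only those *gated* nodes wait on the orchestrator; all other loop
  members proceed data-driven, so control messages stay sparse.
* `v`'s own counter reaching N draws an `exit` for `v`; once all members of
  the SCC reach N (or an exit predicate holds at an iteration boundary, i.e.
  all counters equal), outstanding exits go to the whole SCC. Exits are
  issued at most once per node, and no `start-iteration(n)` with `n > N` is
  ever produced, so every synchronous loop participant executes exactly N
  times.
* duplicate or stale events are dropped by a (node, iteration, kind) dedup
  key; replaying an event log reproduces the action log exactly.

Data transport is configurable: `direct` (node-to-node channels, the
architectural default) or `via-orchestrator` (data updates relayed through
the orchestrator, the deployment used in the closed-loop demo). The
orchestrator is an in-process object; `cycleflow.httpd` exposes the same
surface over HTTP/JSON (`POST /workflows`, `POST /workflows/{id}/events`,
`PUT /workflows/{id}`, `GET /workflows/{id}/status`, `DELETE`), built on the
standard library's threaded HTTP server with service nodes as lightweight
REST clients; in the remote via-orchestrator mode, deliveries are queued in
per-node mailboxes that clients poll. Exit predicates are in-process
callables and do not travel over HTTP.

Hot updates replace a registered definition at a quiescent iteration
boundary (all loop counters equal, at or after a requested iteration);
running instances keep their contexts. Updates may rewire edges and
attributes but not add or remove nodes — new nodes would need new instances
mid-run. The latest value of an async edge is treated as a property of the
edge, so a redirected destination picks up the last published value; this
makes the post-update trace equal a two-phase reference simulation (old graph
to the boundary, modified graph from the carried state). A quiescent boundary
is guaranteed when each loop-carried source is the last node of the iteration
order, which holds for all single-back-edge loops.

Timeouts: a service waiting on a blocking channel gives up after a
configurable per-gather timeout (default 30 s) and fails the run with the
node recorded; a whole-run deadline backs it up.

## Closed-loop optimization demo

A two-node workflow: the controller proposes stimulation parameters
(amplitude in model units over [0, 10]; frequency over the γ band,
30–100 Hz), the plant returns the objective, and the loop-carried channel
feeds each observation back to the controller. The controller spends the
first B iterations (default 5) on uniform random proposals, then fits a GPR
surrogate (squared-exponential kernel plus white noise on unit-box
standardized inputs, hyperparameters by marginal-likelihood maximization with
2 restarts, seeded) and maximizes the UCB acquisition μ + κσ (κ = 2.0 by
default) via a 32×32 grid scan (ties to the lowest index) plus L-BFGS-B
refinement — fully deterministic given the seed, so the orchestrated run and
a monolithic in-process loop produce identical observation sequences.

The plant is a **synthetic stand-in**, not a biophysical model: a Gaussian
response surface `peak·exp(−[(a−a*)²/2σ_a² + (f−f*)²/2σ_f²])` with a single
known optimum at (6.5, 62 Hz) and optional seeded observation noise (default
off). σ per axis is chosen so the half-maximum ellipse covers ~15% of the
parameter box (σ ≈ 0.1856 × box width). Its purpose is a controlled testbed
with a grid-search-verifiable optimum; passing tests show the engine and the
optimizer work, not that any real neural population behaves this way — it
has none of a real mean-field model's dynamics, multimodality or
state-dependence.

## Concurrency harness

`run_load_test` launches K independent runs of one template against a single
orchestrator, start times jittered uniformly over a ramp-up window. Every
run is salted to its own workflow id; a completed run whose trace differs
from the solo reference counts as a failure (contamination), as does a
timeout. Reported mean/median/deviation latency and throughput are
recomputable from the raw per-run CSV log. Absolute throughput/latency are
machine-dependent; the stable claims are 100% success and perfect isolation
at K = 100 with a 1 s ramp-up (the scale used in tests and the acceptance
script; K is a parameter).

## Problem sizes and numerical choices

The test-suite and acceptance script use: 50 randomized workflows (≤ 8
nodes, ≤ 2 SCCs, integer-arithmetic bindings, N ≤ 10) × 2 transport modes
for simulator equivalence; 200 randomized graphs (≤ 12 nodes, ≤ 3 SCCs) for
acyclicity/conservation; budget 20 / burn-in 5 and 20 seeds for the demo
(optimum-recovery criterion: median best-parameter error within 10% of the
box diagonal against a 200×200 grid oracle; superiority over paired random
search at α = 0.05); K = 100 for concurrency. The randomized corpus uses
blocking edges only: asynchronous delivery timing is inherently racy in
arbitrary topologies, and the engine's traces are deterministic exactly when
async producers are ordered by blocking dependencies — true of the
structured examples where async semantics are asserted.

Channel waits poll at 5 ms; iteration tags make duplicate delivery
idempotent. The parser normalizes typographic quotes before XML parsing
(definitions copy-pasted from documents parse verbatim) and accepts
case-insensitive boolean literals, emitting `True`/`False`.

## Known limitations

* One orchestrator process; no replication, persistence, or authentication.
* Hot updates cannot change the node inventory, and with multiple
  loop-carried back edges per SCC a quiescent boundary may not be observed.
* Async determinism is conditional (above); per-destination distinct values
  on one hyperedge are by design impossible — use separate edges.
* No delegation of DAG segments to external workflow engines; bindings are
  in-process callables (or services behind the HTTP transport), not
  container images.
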