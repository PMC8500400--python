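"""Desk-scale concurrency test of the orchestrator.

Starts 100 independent runs of a tiny two-node loop against one orchestrator,
with start times jittered over a 1-second ramp-up.  Every run's trace is
compared to a solo run of the same template, so any cross-workflow
contamination in the control plane counts as a failure.
"""

from cycleflow.bench import run_load_test
from cycleflow.fixtures import increment_bindings, two_node_loop_graph

template = two_node_loop_graph(init=0)
metrics = run_load_test(
    k=100,
    rampup_s=1.0,
    template=template,
    bindings=increment_bindings(template),
    n_iterations=3,
    seed=0,
)

print(f"concurrency:        {metrics.k} workflows, {metrics.rampup_s:.0f}s ramp-up")
print(f"successes/failures: {metrics.successes}/{metrics.failures} "
      f"(success rate {metrics.success_rate:.1%})")
print(f"latency:            mean {metrics.latency_mean_s * 1e3:.1f} ms, "
      f"median {metrics.latency_median_s * 1e3:.1f} ms, "
      f"sd {metrics.latency_sd_s * 1e3:.1f} ms")
print(f"throughput:         {metrics.throughput_per_min:.0f} completed workflows/min")
print(f"isolated traces:    {sum(r.matches_solo for r in metrics.records)}/{metrics.k}")

# Latency here is end-to-end per workflow (3 loop iterations each, in-process
# transport); metrics.write_csv(path) dumps the raw per-run log so every
# aggregate can be recomputed independently.
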