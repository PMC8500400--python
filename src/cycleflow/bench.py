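"""Concurrency load harness for the orchestrator.

Launches K independent runs of one workflow template against a single
orchestrator, with start times jittered uniformly over a ramp-up window
(emulating a load-generator startup period), and reports success rate,
latency statistics and throughput.  Correctness matters more than the raw
numbers at desk scale: every concurrent run's trace is compared against the
solo run of the same template, so any cross-workflow contamination in the
control plane shows up as a failure.
"""

from __future__ import annotations

import csv
import statistics
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .executor import run_workflow
from .model import WorkflowGraph
from .orchestrator import Orchestrator
from .simulator import simulate

__all__ = ["LoadMetrics", "RunRecord", "run_load_test"]


@dataclass
class RunRecord:
    index: int
    wf_id: str
    start: float
    end: float
    status: str
    matches_solo: bool

    @property
    def latency(self) -> float:
        return self.end - self.start


@dataclass
class LoadMetrics:
    k: int
    rampup_s: float
    successes: int
    failures: int
    latency_mean_s: float
    latency_median_s: float
    latency_sd_s: float
    throughput_per_min: float
    wall_s: float
    records: list[RunRecord] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return self.successes / self.k if self.k else 0.0

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "wf_id", "start", "end", "latency_s", "status", "matches_solo"])
            for r in self.records:
                w.writerow(
                    [r.index, r.wf_id, f"{r.start:.6f}", f"{r.end:.6f}",
                     f"{r.latency:.6f}", r.status, int(r.matches_solo)]
                )


def run_load_test(
    k: int,
    rampup_s: float,
    template: WorkflowGraph,
    bindings: Mapping[str, Callable],
    n_iterations: int = 3,
    mode: str = "via-orchestrator",
    timeout_s: float = 30.0,
    seed: int = 0,
    orchestrator: Orchestrator | None = None,
) -> LoadMetrics:
    """Run ``k`` concurrent instances of ``template`` through one orchestrator.

    Each run is salted with its index so every instance registers under its
    own workflow id.  A per-run timeout counts as a failure; a completed run
    whose trace differs from the solo reference also counts as a failure
    (data contamination).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    orch = orchestrator or Orchestrator()
    reference = simulate(template, bindings, n_iterations).outputs

    import numpy as np

    rng = np.random.default_rng(seed)
    delays = rng.uniform(0.0, rampup_s, size=k) if rampup_s > 0 else [0.0] * k

    records: list[RunRecord | None] = [None] * k
    t_wall = time.monotonic()

    def worker(i: int) -> None:
        time.sleep(float(delays[i]))
        t0 = time.monotonic()
        try:
            res = run_workflow(
                template,
                bindings,
                max_iterations=n_iterations,
                mode=mode,
                orchestrator=orch,
                salt=str(i).encode(),
                service_timeout=timeout_s,
                run_timeout=timeout_s,
            )
            ok = res.status == "completed"
            match = res.outputs == reference
            records[i] = RunRecord(
                i, res.wf_id, t0, time.monotonic(),
                res.status if match or not ok else "contaminated",
                matches_solo=match,
            )
        except Exception as exc:
            records[i] = RunRecord(i, "", t0, time.monotonic(), f"error: {exc}", False)

    threads = [threading.Thread(target=worker, args=(i,), daemon=True) for i in range(k)]
    for t in threads:
        t.start()
    for t in threads:
        t.join(timeout_s + rampup_s + 30.0)
    wall = time.monotonic() - t_wall

    done = [r for r in records if r is not None]
    successes = sum(1 for r in done if r.status == "completed" and r.matches_solo)
    failures = k - successes
    lats = [r.latency for r in done] or [0.0]
    return LoadMetrics(
        k=k,
        rampup_s=rampup_s,
        successes=successes,
        failures=failures,
        latency_mean_s=statistics.fmean(lats),
        latency_median_s=statistics.median(lats),
        latency_sd_s=statistics.pstdev(lats) if len(lats) > 1 else 0.0,
        throughput_per_min=successes / wall * 60.0 if wall > 0 else 0.0,
        wall_s=wall,
        records=done,
    )
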