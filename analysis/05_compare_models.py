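#!/usr/bin/env python
"""Benchmark the five representations on shape-signal and null cohorts.

Runs the paired five-model comparison (baseline, delta-2, delta-6,
trajectory, ensemble) over 10 seeded shape-signal cohorts and 3 no-signal
cohorts.  The expected ordering: trajectory (and delta-2, which also sees
the month-2 detour) near-perfect, baseline and delta-6 at chance, ensemble
carried by its trajectory half; on null cohorts everything at chance.
Writes results/benchmark_aucs.csv and results/benchmark_summary.csv.
"""

from pathlib import Path

import pandas as pd

from radkinetics import benchmark

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    shape = benchmark.run_signal_benchmark("shape", seeds=range(10))
    shape["cohort"] = "shape"
    null = benchmark.run_signal_benchmark("none", seeds=range(3))
    null["cohort"] = "none"
    all_runs = pd.concat([shape, null])
    all_runs.to_csv(RESULTS / "benchmark_aucs.csv", index=False)

    summary = (
        all_runs.groupby(["cohort", "representation"])["auc"]
        .agg(["mean", "std"])
        .round(3)
        .reset_index()
    )
    summary.to_csv(RESULTS / "benchmark_summary.csv", index=False)
    print(summary.to_string(index=False))

    m = benchmark.mean_aucs(shape)
    print(
        f"\ntrajectory - baseline = {m['trajectory'] - m['baseline']:+.3f}; "
        f"trajectory - delta6 = {m['trajectory'] - m['delta6']:+.3f} "
        "(shape cohorts)"
    )
    print(
        "the trajectory encoding recovers a signal that baseline and "
        "6-month delta representations are blind to."
    )


if __name__ == "__main__":
    main()
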