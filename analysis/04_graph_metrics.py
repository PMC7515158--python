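#!/usr/bin/env python
"""Weighted graph metrics for every stored adjacency matrix.

Computes local strength, betweenness, efficiency and clustering plus the
global node-averages and transitivity for each (scan, estimator). The full
wide table (one row per matrix) goes to scratch/analysis/metrics.csv; the
per-estimator global-metric summary to results/global_metrics_summary.csv.
"""

from pathlib import Path

from connrep import io
from connrep.graph_metrics import compute_metrics

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    paths = sorted((SCRATCH / "matrices").glob("*.csv"))
    sets = [compute_metrics(io.read_matrix(p)) for p in paths]
    frame = io.metrics_to_dataframe(sets)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(SCRATCH / "metrics.csv", index=False, float_format="%.12g")
    summary = frame.groupby("method")[
        ["global_strength", "global_efficiency", "global_clustering",
         "transitivity"]].mean()
    summary.to_csv(RESULTS / "global_metrics_summary.csv",
                   float_format="%.6g")
    print(f"metrics for {len(sets)} matrices -> scratch/analysis/metrics.csv")
    print("mean global metrics by estimator:")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
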