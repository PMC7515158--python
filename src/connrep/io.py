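"""Reading and writing of stage artifacts (text only: TSV/CSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .connectivity import ConnectivityMatrix
from .graph_metrics import LOCAL_METRICS, GraphMetricSet

__all__ = [
    "write_matrix",
    "read_matrix",
    "metrics_to_dataframe",
]


def write_matrix(matrix: ConnectivityMatrix, out_dir: str | Path) -> Path:
    """One CSV per matrix (header = node ids) plus a JSON sidecar with the
    method tag and provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{matrix.subject_id}_{matrix.scan_position}_{matrix.method}"
    path = out_dir / f"{stem}.csv"
    pd.DataFrame(matrix.weights, columns=matrix.node_ids).to_csv(
        path, index=False, float_format="%.12g")
    sidecar = {
        "method": matrix.method,
        "directed": matrix.directed,
        "subject_id": matrix.subject_id,
        "scan_position": matrix.scan_position,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_matrix(csv_path: str | Path) -> ConnectivityMatrix:
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(csv_path)
    return ConnectivityMatrix(
        weights=frame.to_numpy(dtype=float),
        method=sidecar["method"],
        directed=sidecar["directed"],
        subject_id=sidecar["subject_id"],
        scan_position=sidecar["scan_position"],
        node_ids=list(frame.columns),
    )


def metrics_to_dataframe(metric_sets: list[GraphMetricSet]) -> pd.DataFrame:
    """One row per (subject, scan, method): global metrics plus wide
    columns for every local metric and node."""
    rows = []
    for ms in metric_sets:
        row = {
            "subject_id": ms.subject_id,
            "scan_position": ms.scan_position,
            "method": ms.method,
            "global_strength": ms.global_strength,
            "global_efficiency": ms.global_efficiency,
            "global_clustering": ms.global_clustering,
            "transitivity": ms.transitivity,
        }
        for metric in LOCAL_METRICS:
            values = ms.local(metric)
            for i, v in enumerate(values):
                row[f"{metric}_node{i + 1}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)
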