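#!/usr/bin/env python
"""Estimate the four adjacency-matrix types for every demo scan.

Selects the mGC model order by the median Schwarz criterion across scans,
then writes Pearson, partial-correlation, state-space mGC and mTE matrices
(CSV + JSON sidecars) under scratch/analysis/matrices/.
"""

from pathlib import Path

from connrep import io
from connrep.connectivity import (
    granger_matrix,
    partial_matrix,
    pearson_matrix,
    select_var_order,
    transfer_entropy_matrix,
)
from connrep.preprocess import standardize_record
from connrep.synthetic import load_cohort

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"
SEED = 42


def main() -> None:
    records = [standardize_record(r)
               for r in load_cohort(SCRATCH / "preprocessed")]
    order = select_var_order(records, max_order=6)
    print(f"median-Schwarz VAR order across {len(records)} scans: {order}")
    out = SCRATCH / "matrices"
    for i, rec in enumerate(records):
        for matrix in (pearson_matrix(rec), partial_matrix(rec),
                       granger_matrix(rec, order),
                       transfer_entropy_matrix(rec, rng_seed=SEED + i)):
            io.write_matrix(matrix, out)
    print(f"wrote {4 * len(records)} matrices to {out}")


if __name__ == "__main__":
    main()
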