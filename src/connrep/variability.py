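"""Intra- vs inter-subject normalized-difference (ND) distributions.

The scan-rescan design gives every subject 4 scans. Intra-subject variability
is measured over all C(4,2) = 6 scan pairs of each subject; inter-subject
variability over repeated "pseudo-subjects": quadruples of scans drawn from
4 distinct subjects, balanced so each quadruple contains exactly one first,
second, third and fourth scan (controlling for habituation along the scan
sequence). Each quadruple contributes its 6 pairs, so S subjects and S
repeats both yield 6S ND values per feature stream.

For scalar features (graph metrics) ND(a, b) = (a - b) / (a + b), signed and
bounded in [-1, 1]; for adjacency matrices the Frobenius form
ND = ||a - b||_F^2 / ||a + b||_F^2 is used, bounded in [0, 1] for
nonnegative matrices.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .graph_metrics import GLOBAL_METRICS, LOCAL_METRICS, GraphMetricSet

__all__ = [
    "NDValue",
    "QuadrupleSet",
    "nd_scalar",
    "nd_matrix",
    "enumerate_intra_quadruples",
    "sample_inter_quadruples",
    "build_nd_distributions",
    "nd_to_dataframe",
]

ScanKey = tuple[str, int]  # (subject_id, scan_position)


@dataclass(frozen=True)
class NDValue:
    """A single normalized difference with its provenance."""

    value: float
    pair_kind: str            # intra | inter
    level: str                # matrix | global_metric | local_metric
    method: str
    metric_name: str | None = None
    node_id: str | None = None
    pair_provenance: tuple[ScanKey, ScanKey] | None = None

    def __post_init__(self) -> None:
        if self.pair_kind not in ("intra", "inter"):
            raise ValueError(f"bad pair_kind {self.pair_kind!r}")
        if self.level not in ("matrix", "global_metric", "local_metric"):
            raise ValueError(f"bad level {self.level!r}")
        if self.level == "matrix" and not 0.0 <= self.value <= 1.0:
            raise ValueError("matrix-level ND must lie in [0, 1]")
        if self.level != "matrix" and not -1.0 <= self.value <= 1.0:
            raise ValueError("scalar ND must lie in [-1, 1]")
        if (self.node_id is not None) != (self.level == "local_metric"):
            raise ValueError("node_id present iff level == 'local_metric'")


@dataclass(frozen=True)
class QuadrupleSet:
    """Four scans: one subject's full scan set (intra) or four distinct
    subjects covering scan positions 1-4 exactly once (inter)."""

    members: tuple[ScanKey, ScanKey, ScanKey, ScanKey]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"bad kind {self.kind!r}")
        positions = sorted(pos for _, pos in self.members)
        if positions != [1, 2, 3, 4]:
            raise ValueError("quadruple must cover scan positions 1-4")
        subjects = {sid for sid, _ in self.members}
        if self.kind == "intra" and len(subjects) != 1:
            raise ValueError("intra quadruple must come from one subject")
        if self.kind == "inter" and len(subjects) != 4:
            raise ValueError("inter quadruple needs 4 distinct subjects")

    def pairs(self) -> list[tuple[ScanKey, ScanKey]]:
        """All 6 unordered pairs, each oriented earlier-position first."""
        ordered = sorted(self.members, key=lambda k: k[1])
        return list(itertools.combinations(ordered, 2))


def nd_scalar(a: float, b: float) -> float:
    """Signed, bounded normalized difference (a - b) / (a + b).

    Both arguments are nonnegative for the metrics in scope; ND(0, 0) is
    defined as 0 (identical degenerate values register no difference).
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("nd_scalar requires finite inputs")
    s = a + b
    if s == 0:
        if a == 0 and b == 0:
            return 0.0
        raise ValueError("a + b == 0 with nonzero parts is out of scope")
    if s < 0:
        raise ValueError("metrics in scope are nonnegative (a + b < 0)")
    return (a - b) / s


def nd_matrix(a: ConnectivityMatrix, b: ConnectivityMatrix,
              sqrt: bool = False) -> float:
    """Frobenius-form ND between two same-method adjacency matrices:
    trace((a-b)(a-b)') / trace((a+b)(a+b)'). With ``sqrt=True`` the square
    root (a ratio of Frobenius distances) is returned instead; the two
    variants are monotonically related and rank-identical."""
    if a.weights.shape != b.weights.shape:
        raise ValueError("matrix shapes differ")
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method!r} vs {b.method!r}")
    num = float(np.sum((a.weights - b.weights) ** 2))
    den = float(np.sum((a.weights + b.weights) ** 2))
    if den == 0:
        return 0.0
    val = num / den
    return float(np.sqrt(val)) if sqrt else val


def _key_of(scan) -> ScanKey:
    return (scan.subject_id, scan.scan_position)


def enumerate_intra_quadruples(cohort: Sequence) -> list[QuadrupleSet]:
    """One intra quadruple per subject (requires exactly 4 scans each)."""
    by_subject: dict[str, list[ScanKey]] = defaultdict(list)
    for scan in cohort:
        by_subject[scan.subject_id].append(_key_of(scan))
    quads = []
    for subject, keys in by_subject.items():
        positions = sorted(pos for _, pos in keys)
        if positions != [1, 2, 3, 4]:
            raise ValueError(
                f"subject {subject!r} does not have scans at positions 1-4 "
                f"(found {positions})")
        quads.append(QuadrupleSet(tuple(sorted(keys, key=lambda k: k[1])), "intra"))
    return quads


def sample_inter_quadruples(cohort: Sequence, n_repeats: int,
                            rng_seed: int) -> list[QuadrupleSet]:
    """Balanced inter-subject quadruples, sampled without replacement
    within each repeat.

    Each repeat draws 4 distinct subjects and assigns them the scan
    positions 1-4 in random order, so every quadruple holds exactly one
    first, second, third and fourth scan. Deterministic given the seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    available: dict[str, set[int]] = defaultdict(set)
    for scan in cohort:
        available[scan.subject_id].add(scan.scan_position)
    subjects = sorted(s for s, pos in available.items()
                      if {1, 2, 3, 4} <= pos)
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects with scans at positions 1-4")
    rng = np.random.default_rng(rng_seed)
    quads = []
    for _ in range(n_repeats):
        chosen = rng.choice(len(subjects), size=4, replace=False)
        positions = rng.permutation(4) + 1
        members = tuple(sorted(
            ((subjects[s], int(p)) for s, p in zip(chosen, positions)),
            key=lambda k: k[1]))
        quads.append(QuadrupleSet(members, "inter"))
    return quads


def build_nd_distributions(
    quadruples: Iterable[QuadrupleSet],
    matrices: Mapping[ScanKey, Mapping[str, ConnectivityMatrix]] | None = None,
    metric_sets: Mapping[ScanKey, Mapping[str, GraphMetricSet]] | None = None,
    sqrt_matrix_nd: bool = False,
) -> list[NDValue]:
    """All ND values for the requested feature streams.

    ``matrices`` / ``metric_sets`` map (subject, scan position) -> method ->
    feature. Matrix-level ND uses the Frobenius form; global metrics yield
    one scalar ND per method x metric; local metrics one per method x
    metric x node. Scalar pairs are oriented earlier scan position minus
    later. Raises KeyError naming the scan if a referenced feature is
    missing.
    """
    out: list[NDValue] = []
    for quad in quadruples:
        for key_a, key_b in quad.pairs():
            prov = (key_a, key_b)
            if matrices is not None:
                ma, mb = _lookup(matrices, key_a), _lookup(matrices, key_b)
                for method in ma:
                    out.append(NDValue(
                        value=nd_matrix(ma[method], mb[method], sqrt=sqrt_matrix_nd),
                        pair_kind=quad.kind, level="matrix", method=method,
                        pair_provenance=prov))
            if metric_sets is not None:
                ga, gb = _lookup(metric_sets, key_a), _lookup(metric_sets, key_b)
                for method in ga:
                    sa, sb = ga[method], gb[method]
                    for metric in GLOBAL_METRICS:
                        out.append(NDValue(
                            value=nd_scalar(sa.global_(metric), sb.global_(metric)),
                            pair_kind=quad.kind, level="global_metric",
                            method=method, metric_name=metric,
                            pair_provenance=prov))
                    for metric in LOCAL_METRICS:
                        la, lb = sa.local(metric), sb.local(metric)
                        for node in range(la.size):
                            out.append(NDValue(
                                value=nd_scalar(float(la[node]), float(lb[node])),
                                pair_kind=quad.kind, level="local_metric",
                                method=method, metric_name=metric,
                                node_id=f"node{node + 1}",
                                pair_provenance=prov))
    return out


def _lookup(features: Mapping, key: ScanKey):
    try:
        return features[key]
    except KeyError as exc:
        raise KeyError(f"no features for scan {key}") from exc


def nd_to_dataframe(nd_values: Iterable[NDValue]) -> pd.DataFrame:
    """Long-format table of ND values (one row per value)."""
    rows = []
    for v in nd_values:
        (sa, pa), (sb, pb) = v.pair_provenance or (("", 0), ("", 0))
        rows.append({
            "pair_kind": v.pair_kind, "level": v.level, "method": v.method,
            "metric": v.metric_name or "", "node": v.node_id or "",
            "value": v.value, "subject_a": sa, "scan_a": pa,
            "subject_b": sb, "scan_b": pb,
        })
    return pd.DataFrame(rows)
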