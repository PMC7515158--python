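"""Nonparametric comparison of intra- vs inter-subject ND distributions.

Each intra-vs-inter contrast is a two-sided Mann-Whitney U test with effect
size ES = median(inter) - median(intra); a positive ES means scans of the
same subject are more alike than scans of different subjects. Node effects
on local-metric variability are tested by pooling ND values over all
(metric, method) streams per node (4 metrics x 4 estimators = 16 streams)
and applying a Kruskal-Wallis test across nodes, followed by pairwise
post-hoc Mann-Whitney tests. p-values are uncorrected by default, with
opt-in Benjamini-Hochberg or Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .graph_metrics import LOCAL_METRICS
from .variability import NDValue

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "compare_intra_inter",
    "node_effect_test",
    "posthoc_pairwise",
    "local_significance_summary",
]


@dataclass
class ComparisonResult:
    """Mann-Whitney U p-value, effect size and group sizes for one contrast."""

    p_value: float
    effect_size: float
    n_intra: int
    n_inter: int
    context: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.n_intra <= 0 or self.n_inter <= 0:
            raise ValueError("group sizes must be positive")


def _filter(nd: Iterable[NDValue], level=None, method=None, metric=None,
            node=None) -> list[NDValue]:
    out = []
    for v in nd:
        if level is not None and v.level != level:
            continue
        if method is not None and v.method != method:
            continue
        if metric is not None and v.metric_name != metric:
            continue
        if node is not None and v.node_id != node:
            continue
        out.append(v)
    return out


def compare_intra_inter(nd: Iterable[NDValue], level: str | None = None,
                        method: str | None = None, metric: str | None = None,
                        node: str | None = None) -> ComparisonResult:
    """Two-sided Mann-Whitney U on the intra vs inter ND values matching
    the context filter; ES = median(inter) - median(intra)."""
    subset = _filter(nd, level, method, metric, node)
    intra = np.array([v.value for v in subset if v.pair_kind == "intra"])
    inter = np.array([v.value for v in subset if v.pair_kind == "inter"])
    if intra.size == 0 or inter.size == 0:
        raise ValueError("both intra and inter groups must be non-empty")
    _, p = mannwhitneyu(inter, intra, alternative="two-sided")
    es = float(np.median(inter) - np.median(intra))
    return ComparisonResult(
        p_value=float(p), effect_size=es,
        n_intra=int(intra.size), n_inter=int(inter.size),
        context={"level": level, "method": method, "metric": metric, "node": node},
    )


def node_effect_test(nd: Iterable[NDValue], pair_kind: str,
                     expected_streams: int = 16):
    """Kruskal-Wallis test of a node (anatomical-localization) effect on
    local-metric ND values.

    Per node, ND values are pooled over all (metric, method) streams —
    16 streams when all 4 metrics x 4 estimators are present; fewer streams
    trigger a warning and the available ones are pooled. Returns
    ``(p_value, per_node_samples)`` with nodes ordered by id.
    """
    if pair_kind not in ("intra", "inter"):
        raise ValueError(f"bad pair_kind {pair_kind!r}")
    local = [v for v in nd
             if v.level == "local_metric" and v.pair_kind == pair_kind]
    per_node: dict[str, list[float]] = {}
    streams: dict[str, set] = {}
    for v in local:
        per_node.setdefault(v.node_id, []).append(v.value)
        streams.setdefault(v.node_id, set()).add((v.metric_name, v.method))
    if len(per_node) < 2:
        raise ValueError("need local-metric ND values for at least 2 nodes")
    for node, found in streams.items():
        if len(found) < expected_streams:
            logger.warning("node %s: only %d of %d (metric, method) streams "
                           "present; pooling available ones",
                           node, len(found), expected_streams)
    keys = sorted(per_node, key=lambda s: (len(s), s))
    samples = {k: np.asarray(per_node[k]) for k in keys}
    _, p = kruskal(*samples.values())
    return float(p), samples


def posthoc_pairwise(per_node_samples: Mapping[str, np.ndarray],
                     correction: str | None = None) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests between all node pairs.

    Returns a symmetric p-value matrix (DataFrame indexed by node). With
    ``correction`` in {"bh", "bonferroni"} an adjusted copy is returned
    instead of the raw p-values.
    """
    nodes = list(per_node_samples)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes for post-hoc comparisons")
    k = len(nodes)
    pmat = np.ones((k, k))
    raw = []
    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            _, p = mannwhitneyu(per_node_samples[nodes[a]],
                                per_node_samples[nodes[b]],
                                alternative="two-sided")
            raw.append(float(p))
            pairs.append((a, b))
    if correction is not None:
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
        raw = list(multipletests(raw, method=method)[1])
    for (a, b), p in zip(pairs, raw):
        pmat[a, b] = pmat[b, a] = p
    return pd.DataFrame(pmat, index=nodes, columns=nodes)


def local_significance_summary(nd: Sequence[NDValue], alpha: float = 0.05,
                               correction: str | None = None) -> pd.DataFrame:
    """Per (method, metric): counts of nodes with significant intra-vs-inter
    differences, split by effect-size sign.

    One Mann-Whitney test per node; ``n_sig_pos`` counts nodes where
    inter-subject variability significantly exceeds intra-subject
    variability (ES > 0), ``n_sig_neg`` the reverse.
    """
    methods = sorted({v.method for v in nd if v.level == "local_metric"})
    rows = []
    for method in methods:
        for metric in LOCAL_METRICS:
            subset = _filter(nd, level="local_metric", method=method,
                             metric=metric)
            nodes = sorted({v.node_id for v in subset},
                           key=lambda s: (len(s), s))
            results = [compare_intra_inter(subset, node=node) for node in nodes]
            pvals = [r.p_value for r in results]
            if correction is not None:
                m = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
                pvals = list(multipletests(pvals, method=m)[1])
            n_pos = sum(1 for r, p in zip(results, pvals)
                        if p < alpha and r.effect_size > 0)
            n_neg = sum(1 for r, p in zip(results, pvals)
                        if p < alpha and r.effect_size < 0)
            rows.append({"method": method, "metric": metric,
                         "n_nodes": len(nodes), "n_sig_pos": n_pos,
                         "n_sig_neg": n_neg, "n_sig": n_pos + n_neg})
    return pd.DataFrame(rows)
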