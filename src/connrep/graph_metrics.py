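"""Weighted graph metrics in Brain Connectivity Toolbox conventions.

Local metrics per node: strength, shortest-path betweenness centrality,
local efficiency and clustering coefficient; whole-network metrics: the node
averages of strength / efficiency / clustering, plus transitivity. Directed
matrices (mGC, mTE) use the directed generalizations (total in+out strength,
Fagiolo clustering); undirected ones (Pearson, partial correlation) the
weighted undirected forms (Onnela clustering).

Conventions, stated because they are the silent degrees of freedom of
weighted graph analysis:

* path lengths are reciprocal weights (1/w); a zero weight is no edge;
* weights are normalized by the matrix maximum before clustering,
  efficiency and transitivity (they are cube-rooted there, so the scale
  must be bounded by 1); strength and betweenness use raw weights;
* betweenness uses Brandes accumulation (shortest-path multiplicities
  counted fractionally), over unordered source-target pairs for undirected
  graphs and ordered pairs for directed ones;
* "global efficiency" is the average of the LOCAL efficiencies (the
  convention of the analysis this package reproduces), not the classic
  inverse-shortest-path global efficiency;
* disconnected pairs have infinite distance (zero inverse-distance
  contribution); isolated nodes get local metrics 0.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "GraphMetricSet",
    "compute_metrics",
    "weighted_betweenness",
    "metrics_reference_check",
    "LOCAL_METRICS",
    "GLOBAL_METRICS",
]

LOCAL_METRICS = ("strength", "betweenness", "efficiency", "clustering")
GLOBAL_METRICS = ("strength", "efficiency", "clustering", "transitivity")


@dataclass
class GraphMetricSet:
    """Per-node local metrics and whole-network global metrics for one scan
    and one estimator. Globals (except transitivity) are node averages of
    the corresponding local metrics."""

    local_strength: np.ndarray
    local_betweenness: np.ndarray
    local_efficiency: np.ndarray
    local_clustering: np.ndarray
    global_strength: float
    global_efficiency: float
    global_clustering: float
    transitivity: float
    method: str = "pearson"
    subject_id: str | None = None
    scan_position: int | None = None

    def local(self, name: str) -> np.ndarray:
        return getattr(self, f"local_{name}")

    def global_(self, name: str) -> float:
        if name == "transitivity":
            return self.transitivity
        return getattr(self, f"global_{name}")


def _dijkstra(lengths: np.ndarray, source: int):
    """Single-source Dijkstra on a dense length matrix (inf = no edge).

    Returns distances and, per node, the number of distinct shortest paths
    from the source (Brandes sigma) and the predecessor lists.
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[source] = 0.0
    sigma[source] = 1.0
    visited = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    order = []
    while heap:
        d, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        order.append(u)
        for v in range(n):
            luv = lengths[u, v]
            if not np.isfinite(luv) or visited[v]:
                continue
            nd = d + luv
            if nd < dist[v] - 1e-14:
                dist[v] = nd
                sigma[v] = sigma[u]
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-14:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = 1.0 / weights
    lengths[weights == 0] = np.inf
    np.fill_diagonal(lengths, np.inf)
    return lengths


def weighted_betweenness(weights: np.ndarray, directed: bool) -> np.ndarray:
    """Brandes betweenness with lengths 1/w and fractional multiplicity."""
    n = weights.shape[0]
    lengths = _length_matrix(weights)
    bc = np.zeros(n)
    for s in range(n):
        dist, sigma, preds, order = _dijkstra(lengths, s)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if not directed:
        bc /= 2.0
    return bc


def _all_pairs_distances(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    lengths = _length_matrix(weights)
    d = np.empty((n, n))
    for s in range(n):
        d[s], *_ = _dijkstra(lengths, s)
    return d


def _local_efficiency(weights_norm: np.ndarray) -> np.ndarray:
    """Weighted local efficiency: for each node, cube-root-weighted inverse
    distances among its neighbours, distances computed on the
    neighbour-induced subgraph (directed and undirected handled uniformly
    via the in+out symmetrization)."""
    w = weights_norm
    n = w.shape[0]
    adj = (w != 0).astype(float)
    eff = np.zeros(n)
    for u in range(n):
        nb = np.where((w[u, :] != 0) | (w[:, u] != 0))[0]
        if nb.size < 2:
            continue
        sw = np.cbrt(w[u, nb]) + np.cbrt(w[nb, u])
        sub = w[np.ix_(nb, nb)]
        dist = _all_pairs_distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dist
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        e = np.cbrt(inv)
        se = e + e.T
        numer = float(np.sum(np.outer(sw, sw) * se)) / 2.0
        if numer == 0:
            continue
        sa = adj[u, nb] + adj[nb, u]
        denom = np.sum(sa) ** 2 - np.sum(sa ** 2)
        if denom > 0:
            eff[u] = numer / denom
    return eff


def _clustering(weights_norm: np.ndarray, directed: bool) -> np.ndarray:
    w = weights_norm
    n = w.shape[0]
    adj = (w != 0).astype(float)
    if not directed:
        cr = np.cbrt(w)
        cyc = np.diag(cr @ cr @ cr)
        k = adj.sum(axis=1)
        denom = k * (k - 1)
    else:
        s = np.cbrt(w) + np.cbrt(w.T)
        cyc = np.diag(s @ s @ s) / 2.0
        ktot = adj.sum(axis=0) + adj.sum(axis=1)
        kbi = np.diag(adj @ adj)
        denom = ktot * (ktot - 1) - 2.0 * kbi
    out = np.zeros(n)
    mask = denom > 0
    out[mask] = cyc[mask] / denom[mask]
    return out


def _transitivity(weights_norm: np.ndarray, directed: bool) -> float:
    w = weights_norm
    adj = (w != 0).astype(float)
    if not directed:
        cr = np.cbrt(w)
        cyc = np.trace(cr @ cr @ cr)
        k = adj.sum(axis=1)
        denom = np.sum(k * (k - 1))
    else:
        s = np.cbrt(w) + np.cbrt(w.T)
        cyc = np.trace(s @ s @ s) / 2.0
        ktot = adj.sum(axis=0) + adj.sum(axis=1)
        kbi = np.diag(adj @ adj)
        denom = np.sum(ktot * (ktot - 1) - 2.0 * kbi)
    if denom <= 0:
        return 0.0
    return float(cyc / denom)


def compute_metrics(matrix: ConnectivityMatrix) -> GraphMetricSet:
    """All local and global weighted graph metrics for one adjacency matrix."""
    w = matrix.weights
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and nonnegative")
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w.copy()
    if matrix.directed:
        strength = w.sum(axis=0) + w.sum(axis=1)  # total = in + out
    else:
        strength = w.sum(axis=1)
    betweenness = weighted_betweenness(w, matrix.directed)
    efficiency = _local_efficiency(wn)
    clustering = _clustering(wn, matrix.directed)
    return GraphMetricSet(
        local_strength=strength,
        local_betweenness=betweenness,
        local_efficiency=efficiency,
        local_clustering=clustering,
        global_strength=float(strength.mean()),
        global_efficiency=float(efficiency.mean()),
        global_clustering=float(clustering.mean()),
        transitivity=_transitivity(wn, matrix.directed),
        method=matrix.method,
        subject_id=matrix.subject_id,
        scan_position=matrix.scan_position,
    )


def metrics_reference_check(matrix: ConnectivityMatrix, atol: float = 1e-8) -> dict:
    """Cross-check strength, betweenness and clustering against networkx.

    Returns a report dict with per-metric maximum absolute deviations and
    an ``agreed`` flag (all deviations <= ``atol``); disagreeing metrics are
    listed under ``disagreements``.
    """
    import networkx as nx

    w = matrix.weights
    n = matrix.n_nodes
    g = nx.DiGraph() if matrix.directed else nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(w)
    for i, j in zip(rows, cols):
        if not matrix.directed and i > j:
            continue
        g.add_edge(int(i), int(j), weight=float(w[i, j]),
                   length=1.0 / float(w[i, j]))

    computed = compute_metrics(matrix)
    report: dict = {"deviations": {}, "disagreements": []}

    if matrix.directed:
        ref_strength = np.array([g.in_degree(i, weight="weight")
                                 + g.out_degree(i, weight="weight")
                                 for i in range(n)])
    else:
        ref_strength = np.array([g.degree(i, weight="weight") for i in range(n)])
    ref_bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    ref_bc = np.array([ref_bc[i] for i in range(n)])
    gn = g.copy()
    wmax = w.max()
    for u, v, data in gn.edges(data=True):
        data["weight"] = data["weight"] / wmax if wmax > 0 else 0.0
    ref_clust = nx.clustering(gn, weight="weight")
    ref_clust = np.array([ref_clust[i] for i in range(n)])

    for name, ours, ref in [
        ("strength", computed.local_strength, ref_strength),
        ("betweenness", computed.local_betweenness, ref_bc),
        ("clustering", computed.local_clustering, ref_clust),
    ]:
        dev = float(np.max(np.abs(ours - ref))) if n else 0.0
        report["deviations"][name] = dev
        if dev > atol:
            bad = np.where(np.abs(ours - ref) > atol)[0].tolist()
            report["disagreements"].append({"metric": name, "nodes": bad})
    report["agreed"] = not report["disagreements"]
    return report
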