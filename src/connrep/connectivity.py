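"""Connectivity estimators: Pearson, partial correlation, state-space
multivariate Granger causality (mGC) and multivariate transfer entropy (mTE).

All four estimators map one standardized scan to an N x N nonnegative
weighted adjacency matrix with zero diagonal: symmetric for the undirected
correlation measures, generally asymmetric for mGC/mTE. Negative values are
clipped to zero so every matrix satisfies the nonnegativity the downstream
graph metrics and the bounded matrix-asymmetry statistic require.

mGC uses the single-fit state-space route: one full VAR fit per scan, then
per-source reduced innovation variances from the discrete algebraic Riccati
equation of the sub-process state-space model, instead of refitting biased
reduced VARs. mTE uses greedy non-uniform embedding (past terms of all
nodes up to a maximum lag, added while they significantly lower the
conditional entropy of the target's present) with a linear-Gaussian entropy
estimator, under which TE = GC / 2 in nats for Gaussian data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from statsmodels.tsa.api import VAR

from .preprocess import ScanRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "VarModel",
    "METHODS",
    "pearson_matrix",
    "partial_matrix",
    "fit_var",
    "select_var_order",
    "granger_matrix",
    "granger_matrix_refit",
    "granger_from_var",
    "transfer_entropy_matrix",
]

METHODS = ("pearson", "partial", "gc", "te")
_DIRECTED = {"pearson": False, "partial": False, "gc": True, "te": True}


@dataclass
class ConnectivityMatrix:
    """N x N nonnegative weighted adjacency with method tag and provenance."""

    weights: np.ndarray
    method: str
    directed: bool
    subject_id: str | None = None
    scan_position: int | None = None
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n, m = self.weights.shape
        if n != m:
            raise ValueError("adjacency matrix must be square")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.directed != _DIRECTED[self.method]:
            raise ValueError(f"method {self.method!r} has fixed directedness "
                             f"{_DIRECTED[self.method]}")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if not self.directed and not np.allclose(self.weights, self.weights.T):
            raise ValueError("undirected matrix must be symmetric")
        if self.node_ids is None:
            self.node_ids = [f"node{i + 1}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class VarModel:
    """A fitted VAR(p): coefficients (p x N x N, target-row convention),
    ML innovation covariance, and the Schwarz (BIC) score of the fit."""

    order: int
    coefficients: np.ndarray
    innovation_covariance: np.ndarray
    schwarz_score: float

    def __post_init__(self) -> None:
        from .synthetic import companion_spectral_radius
        radius = companion_spectral_radius(self.coefficients)
        if radius >= 1.0:
            logger.warning("fitted VAR is non-stationary (radius %.3f)", radius)


def _check_standardized(record: ScanRecord) -> np.ndarray:
    x = record.timeseries
    sds = np.std(x, axis=0, ddof=1)
    if np.any(sds == 0):
        bad = int(np.where(sds == 0)[0][0])
        raise ValueError(f"node {bad} has zero variance")
    return x


def pearson_matrix(record: ScanRecord) -> ConnectivityMatrix:
    """Pearson correlation adjacency; negative correlations set to zero."""
    x = _check_standardized(record)
    if record.n_timepoints <= record.n_nodes:
        raise ValueError("need more time points than nodes")
    w = np.corrcoef(x, rowvar=False)
    w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return ConnectivityMatrix(w, "pearson", False,
                              record.subject_id, record.scan_position)


def partial_matrix(record: ScanRecord, ridge: float = 0.0) -> ConnectivityMatrix:
    """Partial correlation from the inverse correlation (precision) matrix.

    weight[i, j] = max(0, -P[i, j] / sqrt(P[i, i] P[j, j])). A small
    ``ridge`` added to the correlation diagonal rescues near-singular inputs.
    """
    x = _check_standardized(record)
    if record.n_timepoints <= record.n_nodes:
        raise ValueError("need more time points than nodes")
    corr = np.corrcoef(x, rowvar=False)
    if ridge > 0:
        corr = corr + ridge * np.eye(corr.shape[0])
    try:
        precision = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; pass ridge > 0") from exc
    d = np.sqrt(np.diag(precision))
    w = -precision / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, None)
    return ConnectivityMatrix(w, "partial", False,
                              record.subject_id, record.scan_position)


def fit_var(record: ScanRecord, order: int) -> VarModel:
    """OLS VAR fit (no trend term; series are standardized)."""
    x = _check_standardized(record)
    t, n = x.shape
    if t - order <= n * order:
        raise ValueError("series too short for requested VAR order")
    res = VAR(x).fit(order, trend="n")
    sigma = np.asarray(res.sigma_u_mle)
    return VarModel(order=order, coefficients=np.asarray(res.coefs),
                    innovation_covariance=sigma, schwarz_score=float(res.bic))


def _schwarz_scores(record: ScanRecord, max_order: int) -> np.ndarray:
    """BIC at each order 1..max_order, all fit on the common effective
    sample (first ``max_order`` points dropped) so scores are comparable."""
    x = _check_standardized(record)
    t, n = x.shape
    teff = t - max_order
    y = x[max_order:]
    lags = np.concatenate([x[max_order - l: t - l] for l in range(1, max_order + 1)],
                          axis=1)
    scores = np.empty(max_order)
    for p in range(1, max_order + 1):
        xp = lags[:, : n * p]
        beta, *_ = np.linalg.lstsq(xp, y, rcond=None)
        resid = y - xp @ beta
        sigma = resid.T @ resid / teff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            scores[p - 1] = np.inf
            continue
        scores[p - 1] = logdet + (np.log(teff) / teff) * p * n * n
    return scores


def select_var_order(records: list[ScanRecord], max_order: int = 8) -> int:
    """Order minimizing the median Schwarz (BIC) score across records."""
    if not records:
        raise ValueError("no records supplied")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    all_scores = np.array([_schwarz_scores(r, max_order) for r in records])
    median_scores = np.median(all_scores, axis=0)
    return int(np.argmin(median_scores)) + 1


def _companion(coefficients: np.ndarray) -> np.ndarray:
    p, n, _ = coefficients.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(coefficients, axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def _riccati_iterate(a, c, q, r, s, tol=1e-10, max_iter=10_000):
    """Fixed-point iteration of the filtering Riccati difference equation
    (fallback when the direct DARE solver fails)."""
    p = q.copy()
    for _ in range(max_iter):
        apc = a @ p @ c.T + s
        gain = np.linalg.solve(c @ p @ c.T + r, apc.T).T
        p_next = a @ p @ a.T + q - gain @ apc.T
        p_next = (p_next + p_next.T) / 2
        if np.max(np.abs(p_next - p)) < tol:
            return p_next
        p = p_next
    raise np.linalg.LinAlgError("Riccati iteration did not converge")


def _reduced_innovation_variances(model: VarModel, keep: np.ndarray) -> np.ndarray:
    """Innovation variances of the sub-process over ``keep`` implied by the
    full VAR, via the innovations-form state space and its DARE.

    The full VAR in companion form is x_t = A x_{t-1} + B e_t; observing
    z_t = C0 x_t gives, with state s_t = x_{t-1},
    z_t = (C0 A) s_t + (C0 B) e_t, so the filtering DARE with
    Q = B Sig B', R = Sig[keep, keep], S = Q C0' yields the steady-state
    prediction covariance P and reduced innovation covariance
    V = (C0 A) P (C0 A)' + R.
    """
    coeffs, sigma = model.coefficients, model.innovation_covariance
    p, n, _ = coeffs.shape
    a = _companion(coeffs)
    q = np.zeros((n * p, n * p))
    q[:n, :n] = sigma
    c0 = np.zeros((keep.size, n * p))
    c0[np.arange(keep.size), keep] = 1.0
    cbar = c0 @ a
    r = sigma[np.ix_(keep, keep)]
    s = q @ c0.T
    try:
        pmat = scipy.linalg.solve_discrete_are(a.T, cbar.T, q, r, s=s)
    except (np.linalg.LinAlgError, ValueError):
        pmat = _riccati_iterate(a, cbar, q, r, s)
    v = cbar @ pmat @ cbar.T + r
    return np.diag(v)


def granger_from_var(model: VarModel) -> np.ndarray:
    """Conditional GC matrix (source row, target column) from a fitted VAR.

    F[i, j] = ln(reduced innovation variance of j with i's past excluded /
    full innovation variance of j), reduced variances from the sub-process
    DARE. Negative numerical estimates are clipped to zero.
    """
    sigma = model.innovation_covariance
    n = sigma.shape[0]
    f = np.zeros((n, n))
    for i in range(n):
        keep = np.array([j for j in range(n) if j != i])
        try:
            reduced = _reduced_innovation_variances(model, keep)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"Riccati solve failed for reduced model excluding node {i}"
            ) from exc
        for pos, j in enumerate(keep):
            f[i, j] = np.log(reduced[pos] / sigma[j, j])
    return np.clip(f, 0.0, None)


def granger_matrix(record: ScanRecord, order: int) -> ConnectivityMatrix:
    """State-space conditional multivariate Granger causality."""
    model = fit_var(record, order)
    f = granger_from_var(model)
    return ConnectivityMatrix(f, "gc", True,
                              record.subject_id, record.scan_position)


def granger_matrix_refit(record: ScanRecord, order: int) -> ConnectivityMatrix:
    """Dual-regression conditional GC: explicitly refit the reduced VAR
    omitting each source. Slower and biased relative to the state-space
    route; kept as an independent cross-check."""
    x = _check_standardized(record)
    t, n = x.shape
    full = fit_var(record, order)
    sigma_full = np.diag(full.innovation_covariance)
    f = np.zeros((n, n))
    y_all = x[order:]
    lags = np.concatenate([x[order - l: t - l] for l in range(1, order + 1)], axis=1)
    for i in range(n):
        keep_cols = np.array([l * n + j for l in range(order)
                              for j in range(n) if j != i])
        xp = lags[:, keep_cols]
        for j in range(n):
            if j == i:
                continue
            yj = y_all[:, j]
            beta, *_ = np.linalg.lstsq(xp, yj, rcond=None)
            resid = yj - xp @ beta
            var_red = resid @ resid / resid.size
            f[i, j] = np.log(var_red / sigma_full[j])
    f = np.clip(f, 0.0, None)
    return ConnectivityMatrix(f, "gc", True,
                              record.subject_id, record.scan_position)


def _lagged_design(x: np.ndarray, max_lag: int):
    """Candidate matrix of all past terms: column k*max_lag + (l-1) holds
    node k at lag l, aligned with the present values x[max_lag:]."""
    t, n = x.shape
    present = x[max_lag:]
    cols = [x[max_lag - l: t - l, k] for k in range(n) for l in range(1, max_lag + 1)]
    return present, np.column_stack(cols)


def transfer_entropy_matrix(record: ScanRecord, max_lag: int = 5,
                            alpha: float = 0.05, n_shuffles: int = 100,
                            rng_seed: int = 0, return_embedding: bool = False):
    """Multivariate transfer entropy with greedy non-uniform embedding.

    For each target, candidate past terms (every node, lags 1..max_lag) are
    added greedily while the best addition lowers the conditional entropy of
    the target's present significantly (one-sided, level ``alpha``) under a
    permutation null: ``n_shuffles`` random permutations of the target's
    current residual, scored by the MAXIMUM entropy decrease over all open
    candidates so the selection-of-the-best step is corrected for. Entropies
    use the linear-Gaussian estimator, CE = 0.5 ln(2 pi e * residual
    variance), so every evaluation reduces to a Schur complement of the
    candidate covariance matrix. TE(i -> j) is the conditional-entropy gap
    between embeddings with and without i's selected past terms (nats).

    With ``return_embedding=True`` also returns, per target node, the list
    of selected ``(source_node, lag)`` terms in selection order.
    """
    x = _check_standardized(record)
    t, n = x.shape
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    rng = np.random.default_rng(rng_seed)
    present, cand = _lagged_design(x, max_lag)
    teff = present.shape[0]
    m = np.concatenate([present, cand], axis=1)
    m = m - m.mean(axis=0)
    g = m.T @ m / teff
    n_cand = cand.shape[1]
    cand_node = np.repeat(np.arange(n), max_lag)  # node of each candidate column

    te = np.zeros((n, n))
    embeddings: dict[int, list[tuple[int, int]]] = {}
    for j in range(n):
        yi = j  # index of target present in g
        var_y = g[yi, yi]
        selected: list[int] = []
        remaining = list(range(n_cand))
        ginv = np.zeros((0, 0))
        resid = var_y
        while remaining:
            cand_idx = n + np.array(remaining)
            sel_arr = n + np.array(selected) if selected else np.array([], dtype=int)
            g_sc = g[np.ix_(sel_arr, cand_idx)]
            a = ginv @ g_sc  # (k, m)
            gy_s = g[yi, sel_arr]
            num = g[yi, cand_idx] - gy_s @ a
            den = np.diag(g[np.ix_(cand_idx, cand_idx)]).copy() - np.sum(g_sc * a, axis=0)
            ok = den > 1e-12 * var_y
            if not np.any(ok):
                break
            gain = np.where(ok, num ** 2 / np.where(ok, den, 1.0), -np.inf)
            best_pos = int(np.argmax(gain))
            best = remaining[best_pos]
            best_gain = gain[best_pos]

            # permutation test with max-statistic correction: permute the
            # target's current residual and take, per permutation, the
            # largest gain over all open candidates
            m_sel = m[:, sel_arr]
            resid_vec = m[:, yi] - m_sel @ (ginv @ gy_s)
            c_perp = m[:, cand_idx] - m_sel @ a
            idx = np.argsort(rng.random((n_shuffles, teff)), axis=1)
            r_perm = resid_vec[idx].T  # teff x n_shuffles
            g_null = c_perp.T @ r_perm / teff  # m x n_shuffles
            with np.errstate(divide="ignore", invalid="ignore"):
                gain_null = g_null ** 2 / den[:, None]
            gain_null[~ok] = 0.0
            threshold = np.quantile(gain_null.max(axis=0), 1.0 - alpha)
            if best_gain <= threshold:
                break
            selected.append(best)
            remaining.remove(best)
            sel_idx = n + np.array(selected)
            gsel = g[np.ix_(sel_idx, sel_idx)]
            try:
                ginv = np.linalg.inv(gsel)
            except np.linalg.LinAlgError:
                logger.warning("ill-conditioned embedding for target %d; "
                               "dropping term %d", j, best)
                selected.pop()
                continue
            resid = resid - best_gain

        embeddings[j] = [(s // max_lag, s % max_lag + 1) for s in selected]
        if not selected:
            continue
        sel_idx = n + np.array(selected)
        full_var = _conditional_variance(g, yi, sel_idx)
        for i in range(n):
            if i == j:
                continue
            sub = [s for s in selected if cand_node[s] != i]
            if len(sub) == len(selected):
                continue  # no term from source i selected -> TE = 0
            sub_idx = n + np.array(sub)
            red_var = _conditional_variance(g, yi, sub_idx) if sub else g[yi, yi]
            te[i, j] = 0.5 * np.log(red_var / full_var)
    te = np.clip(te, 0.0, None)
    np.fill_diagonal(te, 0.0)
    matrix = ConnectivityMatrix(te, "te", True,
                                record.subject_id, record.scan_position)
    if return_embedding:
        return matrix, embeddings
    return matrix


def _conditional_variance(g: np.ndarray, yi: int, cond_idx: np.ndarray) -> float:
    if cond_idx.size == 0:
        return float(g[yi, yi])
    gyx = g[yi, cond_idx]
    gxx = g[np.ix_(cond_idx, cond_idx)]
    return float(g[yi, yi] - gyx @ np.linalg.solve(gxx, gyx))
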