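"""Per-scan preprocessing: stationarity checks, standardization, blind HRF deconvolution.

Node time series enter the connectivity estimators only after (optional)
hemodynamic deconvolution, verification of stationarity with the augmented
Dickey-Fuller (ADF) test, and z-scoring. Series that fail the ADF check are
flagged and logged, not dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gamma as gamma_dist
from statsmodels.tsa.stattools import adfuller

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRecord",
    "DegenerateSeriesError",
    "check_stationarity",
    "standardize",
    "standardize_record",
    "deconvolve_hrf",
    "double_gamma_hrf",
    "lag_points",
]


class DegenerateSeriesError(ValueError):
    """Raised for constant / zero-variance input series."""


@dataclass
class ScanRecord:
    """One resting-state scan: a T x N node time-series matrix plus identity.

    The scan-rescan design has 2 sessions on 2 different days with 2 scans
    per session, giving a global ``scan_position`` of 1-4. ``timeseries``
    rows are time points, columns are nodes (gICA subnetworks).
    """

    subject_id: str
    timeseries: np.ndarray
    scan_position: int = 1
    tr_seconds: float = 0.72
    standardized: bool = False

    session_index: int = field(init=False)
    scan_in_session: int = field(init=False)

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.timeseries.ndim != 2:
            raise ValueError("timeseries must be a 2-D (T x N) array")
        t, n = self.timeseries.shape
        if t < 50:
            raise ValueError(f"need at least 50 time points, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 nodes, got {n}")
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError("timeseries contains non-finite entries")
        if self.scan_position < 1:
            raise ValueError("scan_position must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        # global order 1-4 <-> (session 1-2, scan-in-session 1-2)
        self.session_index = (self.scan_position - 1) // 2 + 1
        self.scan_in_session = (self.scan_position - 1) % 2 + 1

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.timeseries.shape[1]

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.scan_position)


def check_stationarity(series: np.ndarray, alpha: float = 0.05):
    """ADF unit-root test with information-criterion lag selection.

    Returns ``(is_stationary, adf_statistic, p_value)`` where stationarity
    means the unit-root null is rejected at ``alpha``.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 50:
        raise ValueError("series too short for a meaningful ADF test (T >= 50)")
    if np.std(series) == 0:
        raise DegenerateSeriesError("constant series has no unit-root behaviour to test")
    stat, pvalue, *_ = adfuller(series, autolag="AIC")
    return bool(pvalue < alpha), float(stat), float(pvalue)


def standardize(series: np.ndarray) -> np.ndarray:
    """Z-score a vector to zero mean and unit sample standard deviation."""
    series = np.asarray(series, dtype=float)
    mean = np.mean(series)
    sd = np.std(series, ddof=1)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateSeriesError("zero-variance series cannot be standardized")
    return (series - mean) / sd


def standardize_record(record: ScanRecord) -> ScanRecord:
    """Standardize every node's series of a scan (columns independently)."""
    cols = [standardize(record.timeseries[:, j]) for j in range(record.n_nodes)]
    return replace(record, timeseries=np.column_stack(cols), standardized=True)


def lag_points(max_lag_seconds: float, tr_seconds: float) -> int:
    """Convert a lag in seconds to sample points (round half up)."""
    return int(math.floor(max_lag_seconds / tr_seconds + 0.5))


def double_gamma_hrf(tr_seconds: float, duration_seconds: float = 32.0,
                     peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR.

    Peak at ~6 s, undershoot at ~16 s, undershoot-to-peak ratio 1/6
    (the SPM-style canonical shape), normalized to unit peak.
    """
    t = np.arange(0.0, duration_seconds, tr_seconds)
    h = gamma_dist.pdf(t, peak) - ratio * gamma_dist.pdf(t, undershoot)
    return h / np.max(h)


def _detect_pseudo_events(z: np.ndarray, threshold_sd: float) -> np.ndarray:
    """Indices of local maxima exceeding ``threshold_sd`` (point-process premise)."""
    interior = np.arange(1, z.size - 1)
    is_peak = (z[interior] > z[interior - 1]) & (z[interior] >= z[interior + 1])
    return interior[is_peak & (z[interior] > threshold_sd)]


def _fit_hrf(triggered_mean: np.ndarray, tr_seconds: float,
             window: int) -> np.ndarray | None:
    """Fit a double-gamma HRF to a peak-aligned event-triggered mean.

    ``triggered_mean`` spans ``[-(window-1), window-1]`` samples around the
    detected signal peaks; a free onset parameter absorbs the (unknown)
    neural-event-to-peak delay so the returned HRF is sampled from its own
    onset — a pure-delay error here would time-shift the recovered activity.

    Returns ``None`` when the double-gamma shape cannot explain the
    triggered response (fit failure, poor R**2, or a kernel peaking at the
    window edge): that signals the point-process premise does not hold for
    this node and deconvolution would inject arbitrary node-specific phase
    shifts rather than remove hemodynamic blur.
    """
    half = window - 1
    u = (np.arange(triggered_mean.size) - half) * tr_seconds

    def model(t, onset, peak, undershoot, ratio, amplitude):
        return amplitude * (gamma_dist.pdf(t - onset, peak)
                            - ratio * gamma_dist.pdf(t - onset, undershoot))

    t_hrf = np.arange(window) * tr_seconds
    try:
        popt, _ = curve_fit(
            model, u, triggered_mean,
            p0=(-6.0, 6.0, 16.0, 1.0 / 6.0,
                max(float(np.max(np.abs(triggered_mean))), 1e-3)),
            bounds=([-12.0, 2.0, 6.0, 0.0, 1e-6], [0.0, 12.0, 30.0, 2.0, 50.0]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        logger.warning("double-gamma fit did not converge")
        return None
    fitted = model(u, *popt)
    ss_res = float(np.sum((triggered_mean - fitted) ** 2))
    ss_tot = float(np.sum((triggered_mean - triggered_mean.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    _, peak, undershoot, ratio, amplitude = popt
    hrf = amplitude * (gamma_dist.pdf(t_hrf, peak)
                       - ratio * gamma_dist.pdf(t_hrf, undershoot))
    top = np.max(np.abs(hrf))
    # R^2 >= 0.8 separates genuinely hemodynamic triggered responses
    # (median ~0.98 on HRF-convolved data) from the autocorrelation bumps
    # of non-hemodynamic series (95th percentile ~0.78)
    if r2 < 0.8 or top == 0 or int(np.argmax(np.abs(hrf))) >= window - 2:
        logger.warning("triggered response is not HRF-like (R^2=%.2f)", r2)
        return None
    return hrf / top


def _wiener_deconvolve(z: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Wiener deconvolution with a regularization floor on the HRF spectrum."""
    t = z.size
    h = np.zeros(t)
    h[: hrf.size] = hrf
    hf = np.fft.rfft(h)
    power = np.abs(hf) ** 2
    floor = 1e-3 * np.max(power)
    zf = np.fft.rfft(z)
    return np.fft.irfft(zf * np.conj(hf) / (power + floor), n=t)


def deconvolve_hrf(record: ScanRecord, max_lag_seconds: float = 10.0,
                   threshold_sd: float = 1.0) -> ScanRecord:
    """Simplified blind hemodynamic deconvolution of a standardized scan.

    Per node: (i) pseudo-events are detected as local maxima exceeding
    ``threshold_sd`` standard deviations; (ii) a node-specific HRF is
    estimated as the event-triggered mean over a window of
    ``round(max_lag_seconds / tr)`` points (14 points at TR 0.72 s and a
    10 s maximum lag), refined by a double-gamma fit; (iii) latent activity
    is recovered by Wiener deconvolution and re-standardized. Nodes with
    fewer than 3 events pass through unchanged with a warning.
    """
    window = lag_points(max_lag_seconds, record.tr_seconds)
    if window < 2:
        raise ValueError("max-lag window must span at least 2 time points")
    if not record.standardized:
        raise ValueError("deconvolve_hrf expects a standardized ScanRecord")

    out = np.empty_like(record.timeseries)
    half = window - 1
    for j in range(record.n_nodes):
        z = record.timeseries[:, j]
        events = _detect_pseudo_events(z, threshold_sd)
        events = events[(events - half >= 0) & (events + window <= z.size)]
        if events.size < 3:
            logger.warning(
                "node %d of %s scan %d: %d pseudo-events (<3); passing through",
                j, record.subject_id, record.scan_position, events.size,
            )
            out[:, j] = z
            continue
        triggered = np.mean([z[e - half: e + window] for e in events], axis=0)
        hrf = _fit_hrf(triggered, record.tr_seconds, window)
        if hrf is None:
            logger.warning(
                "node %d of %s scan %d: triggered response not HRF-like; "
                "passing through", j, record.subject_id, record.scan_position)
            out[:, j] = z
            continue
        recovered = _wiener_deconvolve(z, hrf)
        out[:, j] = standardize(recovered)
    return replace(record, timeseries=out, standardized=True)
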