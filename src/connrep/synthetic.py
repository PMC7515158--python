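"""Synthetic scan-rescan cohorts with known directed ground truth.

The generator emulates the statistical structure the variability analysis
assumes: each subject has an individual directed coupling pattern (a
perturbation of a shared population pattern), each scan adds a smaller
scan-level perturbation plus fresh innovations, and intra-subject similarity
therefore exceeds inter-subject similarity by a controllable margin. The
generative model is a sparse stable VAR(p): it realizes directed, lagged
coupling that correlation, partial correlation, Granger causality and
transfer entropy can all detect, and it admits analytic oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ScanRecord, double_gamma_hrf, standardize_record

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "NonStationaryModelError",
    "companion_spectral_radius",
    "generate_cohort",
    "generate_var_fixture",
    "write_cohort",
    "load_cohort",
]

BURN_IN = 200  # discarded VAR start-up steps
MAX_RESAMPLE_ATTEMPTS = 100


class NonStationaryModelError(RuntimeError):
    """Raised when no stationary coefficient perturbation can be drawn."""


@dataclass
class CohortSpec:
    """Parameters of the simulated scan-rescan cohort.

    Defaults mirror the scan-rescan design of the source data: 4 scans per
    subject (2 sessions x 2 scans), 15 nodes, 1200 time points per scan at
    TR 0.72 s. ``subject_sd`` and ``scan_jitter_sd`` set the intra/inter
    variance split; the default jitter is a quarter of the subject spread,
    so same-subject scans are more alike than different-subject scans.
    """

    n_subjects: int = 50
    n_scans_per_subject: int = 4
    n_nodes: int = 15
    n_timepoints: int = 1200
    tr_seconds: float = 0.72
    var_order: int = 3
    population_coupling_density: float = 0.2
    subject_sd: float = 0.10
    scan_jitter_sd: float = 0.025
    innovation_sd: float = 1.0
    hrf_enabled: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_timepoints < 50:
            raise ValueError("counts must be positive (T >= 50, N >= 2)")
        if self.n_scans_per_subject < 2:
            raise ValueError("need at least 2 scans per subject")
        if self.var_order < 1:
            raise ValueError("var_order must be >= 1")
        if not 0.0 <= self.population_coupling_density <= 1.0:
            raise ValueError("population_coupling_density must be in [0, 1]")
        if self.subject_sd < 0 or self.scan_jitter_sd < 0:
            raise ValueError("perturbation scales must be >= 0")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be > 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")


@dataclass
class GroundTruth:
    """True coefficients behind a cohort, for parameter-recovery testing.

    ``true_edge_mask[i, j]`` is True when node i drives node j at some lag
    (source-to-target orientation, matching connectivity-matrix convention).
    """

    population_coefficients: np.ndarray  # (p, N, N), target-row convention
    subject_coefficients: np.ndarray     # (S, p, N, N)
    true_edge_mask: np.ndarray           # (N, N) bool, zero diagonal

    def __post_init__(self) -> None:
        np.fill_diagonal(self.true_edge_mask, False)


def companion_spectral_radius(coefficients: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stationary iff < 1)."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim == 2:
        coefficients = coefficients[None]
    p, n, _ = coefficients.shape
    companion = np.zeros((n * p, n * p))
    companion[:n] = np.concatenate(coefficients, axis=1)
    if p > 1:
        companion[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _simulate_var(coefficients: np.ndarray, n_timepoints: int,
                  innovation_sd: float, rng: np.random.Generator) -> np.ndarray:
    p, n, _ = coefficients.shape
    total = n_timepoints + BURN_IN
    y = np.zeros((total + p, n))
    innov = rng.normal(scale=innovation_sd, size=(total, n))
    for t in range(total):
        acc = innov[t]
        for lag in range(p):
            acc = acc + coefficients[lag] @ y[p + t - 1 - lag]
        y[p + t] = acc
    return y[p + BURN_IN:]


def _population_coefficients(spec: CohortSpec, rng: np.random.Generator):
    """Sparse directed coupling rescaled to companion spectral radius 0.8.

    Scaling lag-l coefficients by s**l scales every companion eigenvalue by
    s, so the rescaling hits the target radius exactly.
    """
    p, n = spec.var_order, spec.n_nodes
    coeffs = np.zeros((p, n, n))
    # self-dynamics at lag 1
    coeffs[0][np.diag_indices(n)] = rng.uniform(0.3, 0.6, size=n)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rng.random() < spec.population_coupling_density:
                mask[i, j] = True  # i drives j
                lag = rng.integers(0, p)
                sign = rng.choice([-1.0, 1.0])
                coeffs[lag][j, i] = sign * rng.uniform(0.2, 0.4)
    radius = companion_spectral_radius(coeffs)
    target = 0.8
    scale = target / radius
    for lag in range(p):
        coeffs[lag] *= scale ** (lag + 1)
    return coeffs, mask


def _perturb(coefficients: np.ndarray, sd: float,
             rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise on the nonzero coefficients, kept stationary
    by rejection-resampling (the sparsity pattern is preserved)."""
    if sd == 0:
        return coefficients.copy()
    nz = coefficients != 0
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        perturbed = coefficients.copy()
        perturbed[nz] += rng.normal(scale=sd, size=int(nz.sum()))
        if companion_spectral_radius(perturbed) < 1.0:
            return perturbed
    raise NonStationaryModelError(
        f"no stationary perturbation found in {MAX_RESAMPLE_ATTEMPTS} attempts "
        f"(sd={sd})"
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[ScanRecord], GroundTruth]:
    """Simulate a full scan-rescan cohort.

    Every scan is a fresh VAR simulation from the subject's coefficients
    plus scan-level coefficient jitter, with a 200-step burn-in discarded.
    With ``hrf_enabled`` each node's series is convolved with the canonical
    double-gamma HRF sampled at TR before standardization. All emitted
    series are standardized to zero mean, unit sample variance.
    """
    spec.validate()
    pop_rng = np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(0,)))
    pop_coeffs, mask = _population_coefficients(spec, pop_rng)

    hrf = double_gamma_hrf(spec.tr_seconds) if spec.hrf_enabled else None
    records: list[ScanRecord] = []
    subject_coeffs = np.empty((spec.n_subjects, spec.var_order,
                               spec.n_nodes, spec.n_nodes))
    width = len(str(spec.n_subjects))
    for s in range(spec.n_subjects):
        subj_seq = np.random.SeedSequence(spec.rng_seed, spawn_key=(1, s))
        subj_rng = np.random.default_rng(subj_seq)
        subject_coeffs[s] = _perturb(pop_coeffs, spec.subject_sd, subj_rng)
        subject_id = f"sub{s + 1:0{width}d}"
        for scan in range(1, spec.n_scans_per_subject + 1):
            scan_rng = np.random.default_rng(
                np.random.SeedSequence(spec.rng_seed, spawn_key=(2, s, scan)))
            coeffs = _perturb(subject_coeffs[s], spec.scan_jitter_sd, scan_rng)
            series = _simulate_var(coeffs, spec.n_timepoints,
                                   spec.innovation_sd, scan_rng)
            if hrf is not None:
                series = np.column_stack([
                    np.convolve(series[:, j], hrf)[: spec.n_timepoints]
                    for j in range(spec.n_nodes)
                ])
            record = ScanRecord(subject_id=subject_id, timeseries=series,
                                scan_position=scan, tr_seconds=spec.tr_seconds)
            records.append(standardize_record(record))
    truth = GroundTruth(population_coefficients=pop_coeffs,
                        subject_coefficients=subject_coeffs,
                        true_edge_mask=mask)
    return records, truth


def generate_var_fixture(coefficients: np.ndarray, n_timepoints: int,
                         innovation_sd: float = 1.0, rng_seed: int = 0,
                         tr_seconds: float = 0.72) -> ScanRecord:
    """One multivariate series from exact, user-supplied VAR coefficients.

    Used by estimator-validation tests; deterministic given the seed.
    Raises on non-stationary coefficients.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim == 2:
        coefficients = coefficients[None]
    radius = companion_spectral_radius(coefficients)
    if radius >= 1.0:
        raise NonStationaryModelError(
            f"supplied coefficients are non-stationary (spectral radius {radius:.3f})")
    rng = np.random.default_rng(rng_seed)
    series = _simulate_var(coefficients, n_timepoints, innovation_sd, rng)
    record = ScanRecord(subject_id="fixture", timeseries=series,
                        scan_position=1, tr_seconds=tr_seconds)
    return standardize_record(record)


def write_cohort(records: list[ScanRecord], truth: GroundTruth | None,
                 out_dir: str | Path) -> list[Path]:
    """Write scans as whitespace-delimited text (one file per scan,
    ``<subject>_<scan>.txt``) plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        path = out_dir / f"{rec.subject_id}_{rec.scan_position}.txt"
        np.savetxt(path, rec.timeseries, fmt="%.10g")
        paths.append(path)
    if truth is not None:
        sidecar = out_dir / "ground_truth.json"
        sidecar.write_text(json.dumps({
            "population_coefficients": truth.population_coefficients.tolist(),
            "subject_coefficients": truth.subject_coefficients.tolist(),
            "true_edge_mask": truth.true_edge_mask.astype(int).tolist(),
        }))
        paths.append(sidecar)
    return paths


def load_cohort(in_dir: str | Path, tr_seconds: float = 0.72) -> list[ScanRecord]:
    """Read ``<subject>_<scan>.txt`` whitespace-delimited scan files
    (the dialect of HCP 'PTN' node time-series files)."""
    in_dir = Path(in_dir)
    records = []
    for path in sorted(in_dir.glob("*_*.txt")):
        subject_id, scan = path.stem.rsplit("_", 1)
        series = np.loadtxt(path)
        records.append(ScanRecord(subject_id=subject_id, timeseries=series,
                                  scan_position=int(scan),
                                  tr_seconds=tr_seconds))
    if not records:
        raise FileNotFoundError(f"no scan files found under {in_dir}")
    return records
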