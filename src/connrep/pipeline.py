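"""End-to-end orchestration: simulate/ingest -> preprocess -> connectivity
-> graph metrics -> variability -> statistics, with reproducible seeding and
a content-hash manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity, graph_metrics, io, preprocess, stats, synthetic, variability

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_all", "load_config"]

_VALID_METHODS = set(connectivity.METHODS)


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


#: Published configuration schema: field -> (type, validator description).
CONFIG_SCHEMA = {
    "input_dir": "str | null — directory of <subject>_<scan>.txt files; "
                 "null means simulate from `cohort`",
    "cohort": "mapping of CohortSpec fields (used when input_dir is null)",
    "deconvolve": "bool — apply blind HRF deconvolution",
    "check_stationarity": "bool — run the ADF check and log failures",
    "methods": "subset of ['pearson', 'partial', 'gc', 'te']",
    "var_order": "'auto' or positive int — mGC model order policy",
    "max_var_order": "int — search bound when var_order == 'auto'",
    "te_max_lag": "int — mTE embedding maximum lag",
    "n_inter_repeats": "int or null — inter-subject quadruples "
                       "(default: one per subject)",
    "seed": "int — root seed for sampling and shuffle tests",
    "correction": "null | 'bh' | 'bonferroni' — multiple-testing policy",
    "sqrt_matrix_nd": "bool — report Frobenius-distance (sqrt) matrix ND",
}


@dataclass
class RunConfig:
    """Validated configuration of one full analysis run."""

    input_dir: str | None = None
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    deconvolve: bool = False
    check_stationarity: bool = True
    methods: tuple[str, ...] = connectivity.METHODS
    var_order: str | int = "auto"
    max_var_order: int = 6
    te_max_lag: int = 5
    n_inter_repeats: int | None = None
    seed: int = 0
    correction: str | None = None
    sqrt_matrix_nd: bool = False

    def validate(self) -> None:
        unknown = set(m for m in self.methods) - _VALID_METHODS
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}; "
                              f"valid: {sorted(_VALID_METHODS)}")
        if not self.methods:
            raise ConfigError("at least one method is required")
        if isinstance(self.var_order, str):
            if self.var_order != "auto":
                raise ConfigError("var_order must be 'auto' or a positive int")
        elif self.var_order < 1:
            raise ConfigError("var_order must be >= 1")
        if self.max_var_order < 1 or self.te_max_lag < 1:
            raise ConfigError("max_var_order and te_max_lag must be >= 1")
        if self.correction not in (None, "bh", "bonferroni"):
            raise ConfigError("correction must be null, 'bh' or 'bonferroni'")
        if self.n_inter_repeats is not None and self.n_inter_repeats < 1:
            raise ConfigError("n_inter_repeats must be >= 1")
        if self.input_dir is None:
            try:
                self.cohort.validate()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    if "cohort" in raw:
        raw["cohort"] = synthetic.CohortSpec(**raw["cohort"])
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    config = RunConfig(**raw)
    config.validate()
    return config


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_all(config: RunConfig, out_dir: str | Path) -> dict[str, str]:
    """Execute the full analysis; returns the {file: sha256} manifest.

    Identical config and seed give identical manifests. Any stage failure
    aborts with the stage name; partial outputs stay under a FAILED marker.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(_config_json(config))
    stage = "setup"
    try:
        stage = "ingest"
        t0 = _stage(stage)
        if config.input_dir is not None:
            records = synthetic.load_cohort(config.input_dir)
            records = [preprocess.standardize_record(r) for r in records]
        else:
            records, truth = synthetic.generate_cohort(config.cohort)
            synthetic.write_cohort(records, truth, out_dir / "scans")

        stage = "preprocess"
        _stage(stage)
        if config.deconvolve:
            records = [preprocess.deconvolve_hrf(r) for r in records]
        if config.check_stationarity:
            flagged = 0
            for r in records:
                for j in range(r.n_nodes):
                    ok, _, _ = preprocess.check_stationarity(r.timeseries[:, j])
                    flagged += not ok
            logger.info("ADF: %d non-stationary node series flagged (kept)", flagged)

        stage = "connectivity"
        _stage(stage)
        if "gc" in config.methods:
            order = (connectivity.select_var_order(records, config.max_var_order)
                     if config.var_order == "auto" else int(config.var_order))
            logger.info("mGC model order: %s", order)
        matrices: dict = {}
        for rec in records:
            per_method = {}
            for method in config.methods:
                if method == "pearson":
                    mat = connectivity.pearson_matrix(rec)
                elif method == "partial":
                    mat = connectivity.partial_matrix(rec)
                elif method == "gc":
                    mat = connectivity.granger_matrix(rec, order)
                else:
                    mat = connectivity.transfer_entropy_matrix(
                        rec, max_lag=config.te_max_lag,
                        rng_seed=_scan_seed(config.seed, rec))
                io.write_matrix(mat, out_dir / "matrices")
                per_method[method] = mat
            matrices[rec.key] = per_method

        stage = "metrics"
        _stage(stage)
        metric_sets = {
            key: {m: graph_metrics.compute_metrics(mat)
                  for m, mat in per_method.items()}
            for key, per_method in matrices.items()
        }
        flat = [ms for per in metric_sets.values() for ms in per.values()]
        io.metrics_to_dataframe(flat).to_csv(
            out_dir / "metrics.csv", index=False, float_format="%.12g")

        stage = "variability"
        _stage(stage)
        intra = variability.enumerate_intra_quadruples(records)
        n_repeats = config.n_inter_repeats or len(intra)
        inter = variability.sample_inter_quadruples(records, n_repeats,
                                                   rng_seed=config.seed)
        nd = variability.build_nd_distributions(
            intra + inter, matrices=matrices, metric_sets=metric_sets,
            sqrt_matrix_nd=config.sqrt_matrix_nd)
        variability.nd_to_dataframe(nd).to_csv(
            out_dir / "nd.csv", index=False, float_format="%.12g")

        stage = "stats"
        _stage(stage)
        report = _stats_report(nd, config)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                        sort_keys=True))
        stats.local_significance_summary(
            nd, correction=config.correction).to_csv(
            out_dir / "local_significance.csv", index=False)
        logger.info("pipeline done in %.1f s", time.perf_counter() - t0)
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = _manifest(out_dir)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest


def _scan_seed(root_seed: int, record) -> int:
    digest = hashlib.sha256(
        f"{root_seed}:{record.subject_id}:{record.scan_position}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _config_json(config: RunConfig) -> str:
    data = asdict(config)
    data["methods"] = list(config.methods)
    return json.dumps(data, indent=1, sort_keys=True)


def _comparison_dict(result) -> dict:
    return {"p_value": result.p_value, "effect_size": result.effect_size,
            "n_intra": result.n_intra, "n_inter": result.n_inter}


def _stats_report(nd, config: RunConfig) -> dict:
    report: dict = {"matrix": {}, "global_metric": {}, "kruskal_wallis": {}}
    for method in config.methods:
        report["matrix"][method] = _comparison_dict(
            stats.compare_intra_inter(nd, level="matrix", method=method))
        report["global_metric"][method] = {
            metric: _comparison_dict(stats.compare_intra_inter(
                nd, level="global_metric", method=method, metric=metric))
            for metric in graph_metrics.GLOBAL_METRICS
        }
    for kind in ("intra", "inter"):
        expected = len(graph_metrics.LOCAL_METRICS) * len(config.methods)
        p, samples = stats.node_effect_test(nd, kind,
                                            expected_streams=expected)
        entry: dict = {"p_value": p}
        if p < 0.05:
            posthoc = stats.posthoc_pairwise(samples,
                                             correction=config.correction)
            entry["posthoc"] = {
                "nodes": list(posthoc.columns),
                "p_values": [[round(float(x), 12) for x in row]
                             for row in posthoc.to_numpy()],
            }
        report["kruskal_wallis"][kind] = entry
    return report


def _manifest(out_dir: Path) -> dict[str, str]:
    manifest = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(out_dir))] = digest
    return manifest
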