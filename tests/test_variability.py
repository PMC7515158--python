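"""ND statistic, quadruple construction and distribution building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connrep.connectivity import ConnectivityMatrix
from connrep.variability import (
    NDValue,
    QuadrupleSet,
    build_nd_distributions,
    enumerate_intra_quadruples,
    nd_matrix,
    nd_scalar,
    nd_to_dataframe,
    sample_inter_quadruples,
)


class Key:
    """Minimal scan stand-in: identity only (no time series needed)."""

    def __init__(self, subject_id, scan_position):
        self.subject_id = subject_id
        self.scan_position = scan_position


def cohort_keys(n_subjects, positions=(1, 2, 3, 4)):
    return [Key(f"s{i:04d}", p) for i in range(n_subjects) for p in positions]


nonneg = st.floats(min_value=0, max_value=1e6, allow_nan=False)


class TestNdScalar:
    @pytest.mark.parametrize("a,b,expected",
                             [(5.0, 5.0, 0.0), (1.0, 0.0, 1.0),
                              (3.0, 1.0, 0.5), (0.0, 0.0, 0.0)])
    def test_examples(self, a, b, expected):
        assert nd_scalar(a, b) == pytest.approx(expected)

    @given(a=nonneg, b=nonneg)
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetric_and_bounded(self, a, b):
        v = nd_scalar(a, b)
        assert -1.0 <= v <= 1.0
        assert nd_scalar(b, a) == pytest.approx(-v, abs=1e-12)

    @given(a=nonneg, b=nonneg,
           c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariant(self, a, b, c):
        assert nd_scalar(c * a, c * b) == pytest.approx(nd_scalar(a, b),
                                                        abs=1e-9)

    def test_negative_sum_rejected(self):
        with pytest.raises(ValueError):
            nd_scalar(-3.0, 1.0)


def _mat(w, method="gc"):
    directed = method in ("gc", "te")
    return ConnectivityMatrix(w, method, directed)


class TestNdMatrix:
    def test_identical_matrices_give_zero(self):
        w = np.abs(np.random.default_rng(0).normal(size=(4, 4)))
        np.fill_diagonal(w, 0)
        assert nd_matrix(_mat(w), _mat(w.copy())) == 0.0

    def test_zero_versus_nonzero_is_one(self):
        w = np.zeros((3, 3))
        w[0, 1] = 2.0
        assert nd_matrix(_mat(w), _mat(np.zeros((3, 3)))) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        a = np.array([[0.0, 2.0], [0.0, 0.0]])
        b = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert nd_matrix(_mat(a), _mat(b)) == pytest.approx(1.0 / 9.0)
        assert nd_matrix(_mat(a), _mat(b), sqrt=True) == pytest.approx(1.0 / 3.0)

    def test_symmetric_in_arguments_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = np.abs(rng.normal(size=(5, 5)))
            b = np.abs(rng.normal(size=(5, 5)))
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            v = nd_matrix(_mat(a), _mat(b))
            assert 0.0 <= v <= 1.0
            assert nd_matrix(_mat(b), _mat(a)) == pytest.approx(v)
            assert nd_matrix(_mat(3 * a), _mat(3 * b)) == pytest.approx(v)

    def test_method_mismatch_rejected(self):
        w = np.zeros((3, 3))
        with pytest.raises(ValueError):
            nd_matrix(_mat(w, "gc"), _mat(w, "te"))


class TestQuadruples:
    def test_full_cohort_counts(self):
        cohort = cohort_keys(1003)
        intra = enumerate_intra_quadruples(cohort)
        assert len(intra) == 1003
        assert sum(len(q.pairs()) for q in intra) == 6018
        inter = sample_inter_quadruples(cohort, n_repeats=1003, rng_seed=0)
        assert sum(len(q.pairs()) for q in inter) == 6018

    def test_single_subject_has_six_pairs(self):
        intra = enumerate_intra_quadruples(cohort_keys(1))
        assert len(intra) == 1
        assert len(intra[0].pairs()) == 6

    def test_missing_scan_errors_with_subject_name(self):
        cohort = cohort_keys(2)[:-1]  # drop one scan of subject s0001
        with pytest.raises(ValueError, match="s0001"):
            enumerate_intra_quadruples(cohort)

    def test_inter_invariants_hold_for_every_quadruple(self):
        cohort = cohort_keys(10)
        for quad in sample_inter_quadruples(cohort, 200, rng_seed=3):
            subjects = {s for s, _ in quad.members}
            positions = sorted(p for _, p in quad.members)
            assert len(subjects) == 4
            assert positions == [1, 2, 3, 4]

    def test_inter_sampling_deterministic(self):
        cohort = cohort_keys(8)
        a = sample_inter_quadruples(cohort, 50, rng_seed=11)
        b = sample_inter_quadruples(cohort, 50, rng_seed=11)
        assert a == b

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            sample_inter_quadruples(cohort_keys(3), 5, rng_seed=0)

    def test_invalid_quadruples_rejected(self):
        with pytest.raises(ValueError):
            QuadrupleSet((("a", 1), ("a", 2), ("a", 3), ("b", 4)), "intra")
        with pytest.raises(ValueError):
            QuadrupleSet((("a", 1), ("b", 2), ("c", 3), ("c", 4)), "inter")
        with pytest.raises(ValueError):
            QuadrupleSet((("a", 1), ("b", 1), ("c", 3), ("d", 4)), "inter")


def _feature_tables(cohort, methods=("pearson", "gc"), n_nodes=3, jitter=0.0):
    rng = np.random.default_rng(0)
    matrices = {}
    for key in {(s.subject_id, s.scan_position) for s in cohort}:
        per = {}
        for method in methods:
            w = np.full((n_nodes, n_nodes), 0.5)
            np.fill_diagonal(w, 0)
            if jitter:
                w = w + rng.uniform(0, jitter, w.shape)
                np.fill_diagonal(w, 0)
            directed = method in ("gc", "te")
            if not directed:
                w = (w + w.T) / 2
            per[method] = ConnectivityMatrix(w, method, directed)
        matrices[key] = per
    return matrices


class TestBuildDistributions:
    def test_matrix_level_counting(self):
        cohort = cohort_keys(10)
        quads = enumerate_intra_quadruples(cohort)
        matrices = _feature_tables(cohort, methods=("pearson", "partial",
                                                    "gc", "te"), jitter=0.1)
        nd = build_nd_distributions(quads, matrices=matrices)
        assert len(nd) == 10 * 6 * 4
        assert all(v.level == "matrix" for v in nd)

    def test_identical_features_give_all_zero(self):
        cohort = cohort_keys(4)
        quads = enumerate_intra_quadruples(cohort)
        nd = build_nd_distributions(quads,
                                    matrices=_feature_tables(cohort))
        assert all(v.value == 0.0 for v in nd)

    def test_local_metric_counting(self):
        from connrep.graph_metrics import compute_metrics

        cohort = cohort_keys(1)
        quads = enumerate_intra_quadruples(cohort)
        matrices = _feature_tables(cohort, methods=("pearson", "partial",
                                                    "gc", "te"),
                                   n_nodes=15, jitter=0.3)
        metric_sets = {k: {m: compute_metrics(mat) for m, mat in per.items()}
                       for k, per in matrices.items()}
        nd = build_nd_distributions(quads, metric_sets=metric_sets)
        local = [v for v in nd if v.level == "local_metric"]
        # per pair: 15 nodes x 4 metrics x 4 methods = 240
        assert len(local) == 6 * 240
        glob = [v for v in nd if v.level == "global_metric"]
        assert len(glob) == 6 * 4 * 4

    def test_missing_feature_raises_with_key(self):
        cohort = cohort_keys(4)
        quads = enumerate_intra_quadruples(cohort)
        matrices = _feature_tables(cohort)
        del matrices[("s0000", 3)]
        with pytest.raises(KeyError, match="s0000"):
            build_nd_distributions(quads, matrices=matrices)

    def test_dataframe_round_trip_columns(self):
        cohort = cohort_keys(4)
        quads = enumerate_intra_quadruples(cohort)
        nd = build_nd_distributions(quads,
                                    matrices=_feature_tables(cohort, jitter=0.2))
        frame = nd_to_dataframe(nd)
        assert list(frame.columns) == ["pair_kind", "level", "method",
                                       "metric", "node", "value",
                                       "subject_a", "scan_a",
                                       "subject_b", "scan_b"]
        assert len(frame) == len(nd)
        assert (frame.scan_a < frame.scan_b).all()


class TestNDValueInvariants:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            NDValue(value=1.2, pair_kind="intra", level="matrix", method="gc")
        with pytest.raises(ValueError):
            NDValue(value=-0.1, pair_kind="intra", level="matrix", method="gc")
        with pytest.raises(ValueError):
            NDValue(value=-1.5, pair_kind="inter", level="global_metric",
                    method="gc", metric_name="strength")

    def test_node_id_only_for_local(self):
        with pytest.raises(ValueError):
            NDValue(value=0.0, pair_kind="intra", level="matrix",
                    method="gc", node_id="node1")
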