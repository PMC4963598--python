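import numpy as np
import pytest

from colonyqc import (
    DegenerateDataError,
    FeatureTable,
    InvalidSpecError,
    KernelSpec,
    KnnClassifier,
    KnnFamily,
    MulticlassSVMClassifier,
    SVMFamily,
    apply_scaler,
    fit_scaler,
    knn_k_grid,
    loo_evaluate,
    nested_loo_evaluate,
    performance_measures,
    svm_c_grid,
    svm_rbf_grid,
)
from colonyqc.evaluation import results_table, validate_structure_id
from colonyqc.knn import KnnSpec


class TestGrids:
    def test_printed_cardinalities(self):
        assert len(svm_c_grid()) == 31
        assert len(svm_rbf_grid()) == 961
        assert len(knn_k_grid()) == 12

    def test_bounds_and_order(self):
        cs = svm_c_grid()
        assert cs[0] == 2.0**-15 and cs[-1] == 2.0**15
        assert cs == sorted(cs)
        pairs = svm_rbf_grid()
        assert pairs[0] == (2.0**-15, 2.0**-15) and pairs[-1] == (2.0**15, 2.0**15)
        # canonical order: ascending C, then ascending sigma
        assert pairs[:31] == [(2.0**-15, s) for s in cs]


class TestScaler:
    def test_two_point_example(self):
        s = fit_scaler(np.array([[0.0], [2.0]]))
        assert s.mu[0] == 1.0 and s.sd[0] == pytest.approx(np.sqrt(2))
        assert apply_scaler(s, np.array([[1.0]]))[0, 0] == 0.0

    def test_self_application_standardizes(self, rng):
        X = rng.random((20, 5)) * 40 - 7
        Z = apply_scaler(fit_scaler(X), X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_scales_to_zero(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        Z = apply_scaler(fit_scaler(X), X)
        np.testing.assert_array_equal(Z[:, 1], 0.0)


class TestPerformanceMeasures:
    def test_perfect_diagonal(self):
        tp, tpr, acc = performance_measures(np.diag([41, 74, 58]))
        assert acc == 100.0
        np.testing.assert_array_equal(tpr, [100.0, 100.0, 100.0])

    def test_majority_column_recovers_class_proportion(self):
        cm = np.array([[0, 41, 0], [0, 74, 0], [0, 58, 0]])
        _, _, acc = performance_measures(cm)
        assert round(acc, 1) == 42.8

    def test_published_knn_row_arithmetic(self):
        # tp (24, 55, 29) against class sizes (41, 74, 58)
        cm = np.array([[24, 10, 7], [10, 55, 9], [15, 14, 29]])
        tp, tpr, acc = performance_measures(cm)
        np.testing.assert_array_equal(tp, [24, 55, 29])
        np.testing.assert_allclose(np.round(tpr, 1), [58.5, 74.3, 50.0])
        assert round(acc, 1) == 62.4

    def test_accuracy_is_size_weighted_tpr(self, rng):
        cm = rng.integers(0, 20, (3, 3))
        tp, tpr, acc = performance_measures(cm)
        sizes = cm.sum(axis=1)
        assert acc == pytest.approx(np.sum(tpr * sizes) / cm.sum())

    def test_empty_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            performance_measures(np.zeros((3, 3), dtype=int))


class _PerfectStub:
    """Predicts via nearest training row's label: perfect on separable data."""

    def fit(self, X, y):
        self.X, self.y = X, y
        return self

    def predict_one(self, x):
        return int(self.y[np.argmin(np.sum((self.X - x) ** 2, axis=1))])


class _ConstantStub:
    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict_one(self, x):
        return self.label


class TestPlainLOO:
    def test_perfect_classifier_gives_diagonal(self, blobs_small):
        res = loo_evaluate(_PerfectStub(), blobs_small)
        assert res.accuracy == 100.0
        assert np.all(res.confusion == np.diag([5, 5, 5]))

    def test_constant_majority_on_benchmark_composition(self, table_shaped):
        res = loo_evaluate(_ConstantStub(2), table_shaped)
        assert round(res.accuracy, 1) == 42.8

    def test_two_points_one_per_class_1nn_forced_wrong(self):
        tab = FeatureTable(np.array([[0.0], [1.0]]), np.array([1, 2]))
        res = loo_evaluate(KnnClassifier(KnnSpec(1)), tab)
        assert res.accuracy == 0.0


class TestNestedLOO:
    def test_singleton_grid_equals_plain_loo_bitwise(self, blobs_small):
        fam = KnnFamily("euclidean", "equal")
        nested = nested_loo_evaluate(fam, [3], blobs_small)
        plain = loo_evaluate(KnnClassifier(KnnSpec(3)), blobs_small)
        np.testing.assert_array_equal(nested.confusion, plain.confusion)
        assert all(p == 3 for p in nested.per_fold_params)

    def test_per_fold_params_recorded(self, blobs_small):
        fam = KnnFamily("euclidean", "equal")
        res = nested_loo_evaluate(fam, [1, 3, 5], blobs_small)
        assert len(res.per_fold_params) == len(blobs_small)
        assert set(res.per_fold_params) <= {1, 3, 5}

    def test_heldout_mutation_cannot_change_selection(self, blobs_small):
        # corrupting the held-out row must not leak into fold i's selection
        fam = SVMFamily("ova", KernelSpec("linear"))
        grid = [2.0**e for e in (-2, 0, 2)]
        base = nested_loo_evaluate(fam, grid, blobs_small)
        corrupted = FeatureTable(
            blobs_small.features.copy(), blobs_small.labels.copy()
        )
        corrupted.features[4] += 1e3  # mutate one held-out example
        res = nested_loo_evaluate(fam, grid, corrupted)
        assert res.per_fold_params[4] == base.per_fold_params[4]

    def test_empty_grid_rejected(self, blobs_small):
        with pytest.raises(InvalidSpecError):
            nested_loo_evaluate(KnnFamily("euclidean", "equal"), [], blobs_small)


class TestAdapters:
    def test_structure_validation(self):
        with pytest.raises(InvalidSpecError):
            validate_structure_id("dag", 5)
        with pytest.raises(InvalidSpecError):
            validate_structure_id("tree", 2)
        with pytest.raises(InvalidSpecError):
            validate_structure_id("ova", 1)
        validate_structure_id("dag", 2)
        validate_structure_id("tree", 6)

    def test_svm_classifier_fits_all_schemes(self, blobs_small):
        for scheme, sid in [("ova", None), ("ovo", None), ("dag", 1), ("tree", 5)]:
            clf = MulticlassSVMClassifier(scheme, KernelSpec("linear", C=100.0), sid)
            clf.fit(blobs_small.features, blobs_small.labels)
            preds = [clf.predict_one(x) for x in blobs_small.features]
            assert np.array_equal(preds, blobs_small.labels), scheme

    def test_results_table_layout(self, blobs_small):
        res = loo_evaluate(_PerfectStub(), blobs_small)
        df = results_table([("stub", res)])
        assert list(df.columns) == ["arrangement", "Bad", "Good", "Semigood", "ACC"]
        assert df.loc[0, "ACC"] == "100.0%"
        assert df.loc[0, "Good"] == "5 (100.0%)"
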