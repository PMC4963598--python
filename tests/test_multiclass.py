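import numpy as np
import pytest

import colonyqc.multiclass as mc
from colonyqc import (
    DegenerateDataError,
    FeatureTable,
    InvalidSpecError,
    KernelSpec,
    enumerate_dag_structures,
    enumerate_tree_orders,
    predict_dagsvm,
    predict_ova,
    predict_ovo,
    predict_tree,
    resolve_tie_1nn,
    train_ova,
    train_ovo,
    train_tree,
)

LINEAR = KernelSpec("linear", C=1e4)


@pytest.fixture(scope="module")
def blob_model_data(blobs60):
    return blobs60


class TestOVA:
    def test_three_classes_three_binaries(self, blobs_small):
        model = train_ova(blobs_small, LINEAR)
        assert set(model.binaries) == {1, 2, 3}

    def test_binary_labeling_definition(self, blobs_small):
        model = train_ova(blobs_small, LINEAR)
        b2 = model.binaries[2]
        expect = np.where(blobs_small.labels == 2, 1.0, -1.0)
        np.testing.assert_array_equal(b2.train_y, expect)
        # every binary sees the full training set
        assert all(b.train_X.shape[0] == len(blobs_small) for b in model.binaries.values())

    def test_two_class_table_gives_sign_flipped_binaries(self, rng):
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(8, 1, (5, 3))])
        tab = FeatureTable(X, np.r_[[1] * 5, [2] * 5])
        model = train_ova(tab, LINEAR)
        np.testing.assert_array_equal(model.binaries[1].train_y, -model.binaries[2].train_y)

    def test_unique_positive_wins(self, blobs60):
        model = train_ova(blobs60, LINEAR)
        for c in (1, 2, 3):
            x = blobs60.features[blobs60.labels == c][0]
            assert predict_ova(model, x) == c

    def test_all_negative_dispatches_to_full_tie(self, blobs60):
        model = train_ova(blobs60, LINEAR)
        # the global centroid sits on the "rest" side of every binary
        x = blobs60.features.mean(axis=0)
        values = [mc.decision_value(model.binaries[c], x) for c in (1, 2, 3)]
        assert all(v < 0 for v in values)  # premise: every classifier says "rest"
        assert predict_ova(model, x) == resolve_tie_1nn(model.tie_table, [1, 2, 3], x)


class TestOVO:
    def test_pair_count_and_keys(self, blobs_small):
        model = train_ovo(blobs_small, LINEAR)
        assert set(model.binaries) == {(1, 2), (1, 3), (2, 3)}

    def test_pair_binary_never_sees_third_class(self, blobs_small):
        model = train_ovo(blobs_small, LINEAR)
        b13 = model.binaries[(1, 3)]
        n1 = int(np.sum(blobs_small.labels == 1))
        n3 = int(np.sum(blobs_small.labels == 3))
        assert b13.train_X.shape[0] == n1 + n3

    def test_vote_conservation(self, blobs60, rng):
        model = train_ovo(blobs60, LINEAR)
        m = len(model.classes)
        for _ in range(10):
            votes = mc.pairwise_votes(model, rng.normal(0, 5, 8))
            assert sum(votes.values()) == m * (m - 1) // 2

    def test_majority_vote_wins(self, blobs60):
        model = train_ovo(blobs60, LINEAR)
        for c in (1, 2, 3):
            x = blobs60.features[blobs60.labels == c][1]
            assert predict_ovo(model, x) == c

    def test_shares_binaries_with_dag_training(self, blobs_small):
        ovo = train_ovo(blobs_small, LINEAR)
        dag = train_ovo(blobs_small, LINEAR, scheme="dagsvm")
        for key in ovo.binaries:
            np.testing.assert_array_equal(ovo.binaries[key].alphas, dag.binaries[key].alphas)
            assert ovo.binaries[key].bias == dag.binaries[key].bias


class TestDag:
    def test_enumeration_m3(self):
        structs = enumerate_dag_structures(3)
        assert [s.root_pair for s in structs] == [(1, 2), (1, 3), (2, 3)]

    def test_enumeration_m2_and_m4(self):
        assert len(enumerate_dag_structures(2)) == 1
        assert len(enumerate_dag_structures(4)) == 6

    def test_m_below_2_rejected(self):
        with pytest.raises(InvalidSpecError):
            enumerate_dag_structures(1)

    def test_all_structures_agree_with_ovo_on_consistent_preferences(self, blobs60):
        model = train_ovo(blobs60, LINEAR, scheme="dagsvm")
        structs = enumerate_dag_structures(3)
        for i in range(0, len(blobs60), 7):
            x = blobs60.features[i]
            votes = mc.pairwise_votes(model, x)
            ranked = sorted(votes.values(), reverse=True)
            if ranked != [2, 1, 0]:
                continue  # only a total order guarantees agreement
            expected = predict_ovo(model, x)
            for s in structs:
                assert predict_dagsvm(model, s, x) == expected

    def test_exactly_m_minus_1_evaluations(self, blobs_small, monkeypatch):
        model = train_ovo(blobs_small, LINEAR, scheme="dagsvm")
        calls = []
        real = mc.decision_value
        monkeypatch.setattr(mc, "decision_value", lambda b, x: calls.append(1) or real(b, x))
        predict_dagsvm(model, enumerate_dag_structures(3)[0], blobs_small.features[0])
        assert len(calls) == 2  # M - 1 for M = 3

    def test_elimination_semantics(self, blobs60):
        # root (1, 2): when 1 beats 2, the next evaluated pair is (1, 3)
        model = train_ovo(blobs60, LINEAR, scheme="dagsvm")
        x = blobs60.features[blobs60.labels == 1][0]
        assert mc.decision_value(model.binaries[(1, 2)], x) > 0
        assert predict_dagsvm(model, enumerate_dag_structures(3)[0], x) == 1


class TestTree:
    def test_enumeration_counts(self):
        assert [t.elimination_order for t in enumerate_tree_orders(3)] == [
            (1, 2), (2, 1), (3, 1)
        ]
        assert len(enumerate_tree_orders(2)) == 1
        assert len(enumerate_tree_orders(4)) == 12

    def test_node_training_subsets(self, table_shaped):
        # root of order (bad, ...) sees all 173 rows; the second node only
        # the good+semigood rows (74 + 58 = 132)
        order = enumerate_tree_orders(3)[0]  # (1, 2)
        model = train_tree(table_shaped, LINEAR, order)
        assert model.binaries[1].train_X.shape[0] == 173
        assert model.binaries[2].train_X.shape[0] == 132

    def test_order_definition(self, blobs_small):
        # order rooted at good: root = good vs {bad, semigood}, then bad vs semigood
        order = enumerate_tree_orders(3)[1]
        assert order.elimination_order == (2, 1)
        model = train_tree(blobs_small, LINEAR, order)
        root_y = model.binaries[2].train_y
        assert int(np.sum(root_y == 1)) == int(np.sum(blobs_small.labels == 2))

    def test_all_orders_perfect_on_separable_blobs(self, blobs60):
        for order in enumerate_tree_orders(3):
            model = train_tree(blobs60, LINEAR, order)
            preds = [predict_tree(model, x) for x in blobs60.features]
            assert np.array_equal(preds, blobs60.labels)

    def test_at_most_m_minus_1_evaluations(self, blobs_small, monkeypatch):
        model = train_tree(blobs_small, LINEAR, enumerate_tree_orders(3)[0])
        calls = []
        real = mc.decision_value
        monkeypatch.setattr(mc, "decision_value", lambda b, x: calls.append(1) or real(b, x))
        predict_tree(model, blobs_small.features[0])
        assert len(calls) <= 2


class TestTieSolver:
    def test_exact_match_returns_its_class(self, blobs_small):
        x = blobs_small.features[blobs_small.labels == 3][0]
        assert resolve_tie_1nn(blobs_small, [1, 2, 3], x) == 3

    def test_singleton_tie_short_circuits(self, blobs_small):
        assert resolve_tie_1nn(blobs_small, [2], np.full(4, 1e9)) == 2

    def test_matches_exhaustive_argmin(self, rng):
        X = rng.random((10, 5))
        y = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1])
        tab = FeatureTable(X, y)
        for _ in range(20):
            x = rng.random(5)
            best = min(range(10), key=lambda i: (np.sum((X[i] - x) ** 2), i))
            assert resolve_tie_1nn(tab, [1, 2, 3], x) == y[best]

    def test_empty_tie_rejected(self, blobs_small):
        with pytest.raises(DegenerateDataError):
            resolve_tie_1nn(blobs_small, [], np.zeros(4))
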