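import numpy as np
import pytest

from dectico.features import FeatureMatrix, build_feature_matrix
from dectico.kpls import KernelSpec
from dectico.selection import (
    ClassifierSpec,
    DectICO,
    FinalModel,
    SelectionLadder,
    SelectionRound,
    dectico_select,
    default_ladder,
    loocv_accuracy,
    pick_optimal,
    static_select,
    train_final,
)
from dectico.seq_io import load_model, read_manifest, save_model
from tests.conftest import make_planted_matrix


class TestLadder:
    def test_strict_descent_enforced(self):
        with pytest.raises(ValueError, match="descending"):
            SelectionLadder((100, 100, 10))

    def test_default_ladder_halves_to_floor(self):
        lad = default_ladder(852)
        assert lad.sizes[0] == 852
        assert all(a > b for a, b in zip(lad.sizes, lad.sizes[1:]))
        assert lad.sizes[-1] >= 10

    def test_head_must_match_dimension(self, planted_matrix):
        with pytest.raises(ValueError, match="ladder head"):
            DectICO(planted_matrix, ladder=SelectionLadder((999, 10)))


class TestLoocv:
    def test_separable_clusters_are_perfect(self, small_labeled_matrix):
        assert loocv_accuracy(small_labeled_matrix, ClassifierSpec()) == 1.0

    def test_two_samples_one_per_class_always_wrong(self):
        fm = FeatureMatrix(
            ["a", "b"], ["x"], np.array([[0.0], [1.0]]), labels=np.array([1, -1])
        )
        # each fold trains on one class, predicts it, and is wrong
        assert loocv_accuracy(fm, ClassifierSpec(kernel="linear")) == 0.0

    def test_accuracy_within_unit_interval_and_deterministic(self, planted_matrix):
        a1 = loocv_accuracy(planted_matrix, ClassifierSpec())
        a2 = loocv_accuracy(planted_matrix, ClassifierSpec())
        assert 0.0 <= a1 <= 1.0
        assert a1 == a2


class TestPickOptimal:
    def _round(self, k, n, acc):
        return SelectionRound(k=k, selected=[f"f{i}" for i in range(n)], accuracy=acc)

    def test_tie_prefers_fewer_features(self):
        rounds = [
            self._round(0, 100, 0.8),
            self._round(1, 50, 0.9),
            self._round(2, 10, 0.9),
        ]
        assert pick_optimal(rounds) == 2

    def test_accuracy_primary(self):
        rounds = [self._round(0, 100, 0.95), self._round(1, 50, 0.90)]
        assert pick_optimal(rounds) == 0

    def test_single_round(self):
        assert pick_optimal([self._round(0, 5, 0.7)]) == 0


class TestDynamicSelection:
    def test_identity_ladder_no_selection_rounds(self, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000,)))
        assert len(res.rounds) == 1
        assert res.rounds[0].n_features == 1000
        assert 0.0 <= res.rounds[0].accuracy <= 1.0

    def test_planted_features_recovered(self):
        fm = make_planted_matrix(seed=7)
        res = dectico_select(fm, SelectionLadder((1000, 100, 10)))
        recovered = sum(1 for nm in res.rounds[-1].selected if nm.startswith("inf"))
        assert recovered >= 8

    def test_nested_feature_sets(self, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000, 200, 40, 10)))
        for prev, cur in zip(res.rounds, res.rounds[1:]):
            assert set(cur.selected) <= set(prev.selected)

    def test_some_rung_separates_planted_data(self, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000, 100, 10)))
        assert res.best_accuracy == 1.0

    def test_determinism(self, planted_matrix):
        r1 = dectico_select(planted_matrix, SelectionLadder((1000, 50)))
        r2 = dectico_select(planted_matrix, SelectionLadder((1000, 50)))
        assert r1.rounds[-1].selected == r2.rounds[-1].selected
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        assert r1.optimal_round_index == r2.optimal_round_index

    def test_summary_mentions_optimal(self, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000, 10)))
        text = res.summary()
        assert "optimal" in text and "dynamic" in text


class TestStaticSelection:
    def test_single_rung_equals_dynamic(self, planted_matrix):
        lad = SelectionLadder((1000, 100))
        dyn = dectico_select(planted_matrix, lad)
        sta = static_select(planted_matrix, lad)
        assert dyn.rounds[-1].selected == sta.rounds[-1].selected
        assert dyn.accuracies[-1] == sta.accuracies[-1]

    def test_static_sets_always_nested(self, planted_matrix):
        res = static_select(planted_matrix, SelectionLadder((1000, 300, 30, 5)))
        for prev, cur in zip(res.rounds, res.rounds[1:]):
            assert set(cur.selected) <= set(prev.selected)
        assert res.mode == "static"

    def test_dynamic_at_least_as_good_usually(self):
        wins = 0
        for seed in range(10):
            fm = make_planted_matrix(seed, n_features=400)
            lad = SelectionLadder((400, 40, 10))
            dyn = dectico_select(fm, lad)
            sta = static_select(fm, lad)
            wins += dyn.best_accuracy >= sta.best_accuracy
        assert wins >= 7


class TestFinalModelAndPredict:
    def test_training_accuracy_on_separable_data(self, small_labeled_matrix):
        final = train_final(small_labeled_matrix, ClassifierSpec())
        pred = final.predict(small_labeled_matrix.values)
        np.testing.assert_array_equal(pred, small_labeled_matrix.labels)

    def test_serialization_round_trip(self, tmp_path, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000, 20)))
        path = tmp_path / "model.json"
        save_model(res.final_model.to_dict(), path)
        back = FinalModel.from_dict(load_model(path))
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, len(back.feature_names)))
        np.testing.assert_array_equal(back.predict(X), res.final_model.predict(X))

    def test_decision_matches_sklearn(self, planted_matrix):
        from sklearn.svm import SVC

        sub = planted_matrix.restrict([f"inf{j}" for j in range(10)])
        final = train_final(sub, ClassifierSpec())
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
        clf.fit(sub.values, sub.labels)
        np.testing.assert_allclose(
            final.decision_function(sub.values),
            clf.decision_function(sub.values),
            atol=1e-10,
        )

    def test_missing_feature_column_errors(self, planted_matrix):
        res = dectico_select(planted_matrix, SelectionLadder((1000, 5)))
        missing = res.final_model.feature_names[0]
        remaining = [n for n in planted_matrix.feature_names if n != missing]
        with pytest.raises(KeyError, match=missing):
            res.predict(planted_matrix.restrict(remaining))

    def test_single_class_rejected(self, small_labeled_matrix):
        small_labeled_matrix.labels[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            train_final(small_labeled_matrix, ClassifierSpec())


class TestManifestWorkflow:
    def test_fit_and_predict_from_manifest(self, fasta_manifest):
        model = DectICO.from_manifest(
            str(fasta_manifest), k=2, ladder=SelectionLadder((20, 5)),
        )
        res = model.fit()
        sids, labels, decisions = res.predict_manifest(str(fasta_manifest))
        assert len(sids) == 4
        assert set(labels) <= {1, -1}
        assert decisions.shape == (4,)

    def test_empty_manifest_predicts_empty(self, fasta_manifest, tmp_path):
        model = DectICO.from_manifest(
            str(fasta_manifest), k=2, ladder=SelectionLadder((20, 5))
        )
        res = model.fit()
        empty = tmp_path / "empty.tsv"
        empty.write_text("sample_id\tpaths\n")
        sids, labels, decisions = res.predict_manifest(str(empty))
        assert sids == [] and labels.size == 0
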