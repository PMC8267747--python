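"""The 13 classification procedures and the suite runner."""

import numpy as np
import pytest

from arclass.dataset import LabeledDataset
from arclass.fingerprints import Fingerprint
from arclass.procedures import (
    ProcedureClassifier,
    ProcedureConfig,
    classify,
    run_suite,
)


def tiny_training_set():
    """Hand-built screen: two binders with deep scores and left-side bits,
    two non-binders with shallow scores and right-side bits (length 8)."""
    fps = [
        Fingerprint("11000000"),
        Fingerprint("11100000"),
        Fingerprint("00000011"),
        Fingerprint("00000111"),
    ]
    scores = np.array([-9.0, -8.5, -5.0, -5.5])
    labels = np.array([1, 1, 0, 0])
    return LabeledDataset(
        ids=["a1", "a2", "b1", "b2"], fingerprints=fps, scores=scores, labels=labels
    )


def make_query_X(bit_strings, scores):
    bits = np.vstack([Fingerprint(b).bits for b in bit_strings]).astype(float)
    return np.hstack([np.asarray(scores, float)[:, None], bits])


@pytest.fixture
def fitted():
    ds = tiny_training_set()

    def fit(pid, **kw):
        clf = ProcedureClassifier(procedure=pid, **kw)
        clf.fit(ds.X(), ds.labels)
        return clf

    return fit


class TestThresholdRule:
    def test_strong_score_is_binder(self, fitted):
        clf = fitted(1)
        X = make_query_X(["10000000"], [-11.91])  # a known strong binder score
        assert clf.predict(X)[0] == 1

    def test_zero_and_boundary_scores(self, fitted):
        clf = fitted(1)
        X = make_query_X(["10000000"] * 3, [0.0, -7.0, -6.99])
        # 0 sentinel -> non-binder; the -7 tie classifies binder (<=).
        assert clf.predict(X).tolist() == [0, 1, 0]


class TestBayesRules:
    def test_procedure_4_sends_zeros_to_nonbinder(self, fitted):
        p2, p4 = fitted(2), fitted(4)
        X = make_query_X(["10000000"] * 2, [0.0, -9.0])
        pred2, pred4 = p2.predict(X), p4.predict(X)
        assert pred4[0] == 0
        assert pred4[1] == pred2[1] == 1  # deep score: both call binder


class TestFingerprintRules:
    def test_procedure_5_uses_closer_panel(self, fitted):
        clf = fitted(5)
        X = make_query_X(["11100000", "00000111"], [0.0, 0.0])
        assert clf.predict(X).tolist() == [1, 0]

    def test_procedure_6_matches_1_on_nonzero_and_5_on_zero(self, fitted):
        p1, p5, p6 = fitted(1), fitted(5), fitted(6)
        X = make_query_X(
            ["11100000", "00000111", "11100000", "00000111"],
            [-8.0, -8.0, 0.0, 0.0],
        )
        pred = p6.predict(X)
        assert pred[:2].tolist() == p1.predict(X)[:2].tolist()
        assert pred[2:].tolist() == p5.predict(X)[2:].tolist()

    def test_procedure_7_rechecks_fingerprint_nonbinders_by_score(self, fitted):
        p7 = fitted(7)
        # Inactive-like fingerprint but a deep docking score: rule 5 says
        # non-binder, the threshold then overrides to binder.
        X = make_query_X(["00000111", "00000111"], [-9.0, -5.0])
        assert p7.predict(X).tolist() == [1, 0]
        # Active-like fingerprint is accepted outright, whatever the score.
        X2 = make_query_X(["11100000"], [0.0])
        assert p7.predict(X2)[0] == 1


class TestCascades:
    def test_procedure_9_tie_falls_through_to_logistic(self, fitted):
        p8, p9 = fitted(8), fitted(9)
        # Query equidistant to both panels (avgD_Act == avgD_Inact) with a
        # zero score: the only unresolved case, decided by procedure 8.
        X = make_query_X(["11000011"], [0.0])
        clf9 = p9
        d_act, d_inact = clf9.panel_.avg_distances([Fingerprint("11000011")])
        assert d_act[0] == pytest.approx(d_inact[0], abs=1e-12)
        assert p9.predict(X)[0] == p8.predict(X)[0]

    def test_procedure_9_resolves_nonties_without_logistic(self, fitted):
        p5, p9 = fitted(5), fitted(9)
        X = make_query_X(["11100000", "00000111"], [0.0, 0.0])
        assert p9.predict(X).tolist() == p5.predict(X).tolist()

    def test_procedure_10_consensus_short_circuit(self, fitted):
        p10 = fitted(10)
        # Deep score (Bayes: binder) + active-like fingerprint (panel: binder):
        # agreement decides without the logistic fallback.
        X = make_query_X(["11100000"], [-9.0])
        assert p10.predict(X)[0] == 1
        # Shallow score + inactive-like fingerprint: agreement on non-binder.
        X2 = make_query_X(["00000111"], [-5.0])
        assert p10.predict(X2)[0] == 0


class TestConsensusModel:
    def test_published_model_is_pure_function(self, fitted):
        clf_a = fitted(13, published=True)
        clf_b = fitted(13, published=True)
        X = make_query_X(["11100000", "00000111", "11000011"], [-9.0, 0.0, -6.0])
        np.testing.assert_array_equal(clf_a.predict(X), clf_b.predict(X))
        np.testing.assert_array_equal(clf_a.predict(X), clf_a.predict(X))

    def test_refit_mode_trains_on_given_data(self, small_dataset):
        clf = ProcedureClassifier(procedure=13, published=False)
        clf.fit(small_dataset.X(), small_dataset.labels)
        assert 13 in clf.models_
        assert clf.models_[13].coef_.shape == (5,)

    def test_sklearn_protocol(self):
        clf = ProcedureClassifier(procedure=8, dock_threshold=-6.5)
        params = clf.get_params()
        assert params["procedure"] == 8
        clone = ProcedureClassifier(**params)
        assert clone.dock_threshold == -6.5
        clf.set_params(procedure=5)
        assert clf.procedure == 5
        with pytest.raises(ValueError, match="Invalid parameter"):
            clf.set_params(bogus=1)


class TestValidation:
    def test_unknown_procedure_rejected(self):
        ds = tiny_training_set()
        with pytest.raises(ValueError, match="unknown procedure"):
            ProcedureClassifier(procedure=14).fit(ds.X(), ds.labels)

    def test_single_class_rejected(self):
        ds = tiny_training_set()
        with pytest.raises(ValueError, match="both classes"):
            ProcedureClassifier(procedure=1).fit(ds.X(), np.ones(4, dtype=int))

    def test_positive_threshold_rejected(self):
        ds = tiny_training_set()
        with pytest.raises(ValueError, match="negative"):
            ProcedureClassifier(procedure=1, dock_threshold=2.0).fit(
                ds.X(), ds.labels
            )
        with pytest.raises(ValueError, match="negative"):
            ProcedureConfig(dock_threshold=1.0)

    def test_predict_before_fit_raises(self):
        from arclass._base import NotFittedError

        with pytest.raises(NotFittedError):
            ProcedureClassifier(procedure=1).predict(np.zeros((1, 9)))


class TestSuite:
    def test_thirteen_consistent_rows(self, small_dataset):
        table = run_suite(small_dataset)
        assert len(table) == 13
        assert table["procedure"].tolist() == list(range(1, 14))
        n_act, n_inact = small_dataset.n_active, small_dataset.n_inactive
        assert ((table["TP"] + table["FN"]) == n_act).all()
        assert ((table["TN"] + table["FP"]) == n_inact).all()

    def test_procedure_6_equals_1_on_nonzero_scores(self, small_dataset):
        X, y = small_dataset.X(), small_dataset.labels
        preds = {
            pid: ProcedureClassifier(procedure=pid).fit(X, y).predict_training()
            for pid in (1, 6)
        }
        nonzero = small_dataset.scores != 0
        np.testing.assert_array_equal(preds[1][nonzero], preds[6][nonzero])

    def test_consensus_outranks_bare_threshold(self, default_dataset):
        """On data drawn from the generative model the five-descriptor
        consensus should dominate the raw score threshold."""
        table = run_suite(default_dataset).set_index("procedure")
        assert table.loc[13, "MCC"] >= table.loc[1, "MCC"]

    def test_single_class_dataset_rejected(self, small_dataset):
        ds = LabeledDataset(
            ids=small_dataset.ids,
            fingerprints=small_dataset.fingerprints,
            scores=small_dataset.scores,
            labels=np.ones(len(small_dataset), dtype=int),
        )
        with pytest.raises(ValueError, match="both classes"):
            run_suite(ds)

    def test_functional_wrapper_matches_estimator(self, small_dataset):
        X, y = small_dataset.X(), small_dataset.labels
        via_fn = classify(5, X, y)
        via_cls = ProcedureClassifier(procedure=5).fit(X, y).predict_training()
        np.testing.assert_array_equal(via_fn, via_cls)


class TestLeaveSelfOut:
    def test_training_distances_exclude_own_fingerprint(self):
        ds = tiny_training_set()
        clf = ProcedureClassifier(procedure=5).fit(ds.X(), ds.labels)
        desc = clf._train_desc
        # With self included, a1's average distance to the active panel would
        # be biased toward 0 by its own zero self-distance.
        from arclass.fingerprints import avg_distance

        expected = avg_distance(
            ds.fingerprints[0], [ds.fingerprints[0], ds.fingerprints[1]], exclude_index=0
        )
        assert desc.avgd_act[0] == pytest.approx(expected, abs=1e-12)
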