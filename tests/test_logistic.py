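"""Maximum-likelihood logistic regression and the packaged consensus model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from arclass.logistic import (
    PROCEDURE13_FEATURES,
    DescriptorVector,
    LogisticRegressionMLE,
    PerfectSeparationWarning,
    procedure13_model,
)


def simulate_logit(rng, n=5000, beta=-1.0, alpha=2.0):
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(beta + alpha * x)).astype(int)
    return x[:, None], y


class TestFit:
    def test_recovers_planted_coefficients(self, rng):
        X, y = simulate_logit(rng)
        m = LogisticRegressionMLE().fit(X, y)
        assert m.converged_
        assert m.intercept_ == pytest.approx(-1.0, abs=0.15)
        assert m.coef_[0] == pytest.approx(2.0, abs=0.15)

    def test_null_effect_coefficient_near_zero(self, rng):
        n = 4000
        X = rng.normal(size=(n, 1))
        y = rng.integers(0, 2, n)  # label independent of the feature
        m = LogisticRegressionMLE().fit(X, y)
        # ~3 standard errors of a null logistic coefficient at this n.
        assert abs(m.coef_[0]) < 3 * 2 / math.sqrt(n)

    def test_fitted_ll_beats_intercept_only(self, rng):
        X, y = simulate_logit(rng, n=800)
        full = LogisticRegressionMLE().fit(X, y)
        n, n1 = len(y), int(y.sum())
        null_ll = n1 * math.log(n1 / n) + (n - n1) * math.log(1 - n1 / n)
        assert full.ll_ >= null_ll
        assert full.ll_ <= 0

    def test_gradient_vanishes_at_mle(self, rng):
        X, y = simulate_logit(rng, n=2000)
        m = LogisticRegressionMLE().fit(X, y)
        assert np.max(np.abs(m.score_vector(X, y))) < 1e-6

    def test_row_permutation_invariance(self, rng):
        X, y = simulate_logit(rng, n=1000)
        m1 = LogisticRegressionMLE().fit(X, y)
        perm = rng.permutation(len(y))
        m2 = LogisticRegressionMLE().fit(X[perm], y[perm])
        assert m2.intercept_ == pytest.approx(m1.intercept_, abs=1e-8)
        assert m2.coef_[0] == pytest.approx(m1.coef_[0], abs=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y = simulate_logit(rng, n=1500)
        ours = LogisticRegressionMLE().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert ours.intercept_ == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.coef_[0] == pytest.approx(ref.params[1], abs=1e-6)
        assert ours.ll_ == pytest.approx(ref.llf, abs=1e-8)

    def test_perfect_separation_warns_not_explodes(self):
        X = np.linspace(-2, 2, 40)[:, None]
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(PerfectSeparationWarning):
            m = LogisticRegressionMLE().fit(X, y)
        assert not m.converged_
        assert np.all(np.isfinite(m.coef_))

    def test_singular_design_raises(self):
        X = np.ones((30, 2))  # duplicate constant columns
        y = np.array([0, 1] * 15)
        with pytest.raises(ValueError, match="singular|collinear"):
            LogisticRegressionMLE().fit(X, y)

    def test_one_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            LogisticRegressionMLE().fit(np.ones((5, 1)), np.ones(5, dtype=int))


class TestPredict:
    def test_zero_linear_predictor_gives_half(self):
        m = LogisticRegressionMLE()
        m.intercept_, m.coef_ = 0.0, np.array([1.0])
        assert m.predict_proba(np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_probability_monotone_in_linear_predictor(self):
        m = LogisticRegressionMLE()
        m.intercept_, m.coef_ = 0.3, np.array([1.5])
        p = m.predict_proba(np.linspace(-5, 5, 50)[:, None])
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_feature_name_mismatch_raises(self):
        m = LogisticRegressionMLE(feature_names=["a", "b"])
        m.intercept_, m.coef_ = 0.0, np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="missing feature"):
            m.predict_proba(pd.DataFrame({"a": [1.0], "c": [2.0]}))


class TestLogLikelihood:
    def test_intercept_only_closed_form(self, rng):
        # An intercept-only model predicts the base rate for every row; its
        # log-likelihood has the closed form n1*log(n1/n) + n0*log(n0/n).
        n, n1 = 500, 140
        y = np.concatenate([np.ones(n1, dtype=int), np.zeros(n - n1, dtype=int)])
        m = LogisticRegressionMLE()
        m.intercept_, m.coef_ = math.log(n1 / (n - n1)), np.array([0.0])
        expected = n1 * math.log(n1 / n) + (n - n1) * math.log(1 - n1 / n)
        assert m.log_likelihood(rng.normal(size=(n, 1)), y) == pytest.approx(
            expected, abs=1e-8
        )

    def test_matches_per_row_loop_oracle(self, rng):
        X, y = simulate_logit(rng, n=300)
        m = LogisticRegressionMLE().fit(X, y)
        p = m.predict_proba(X)
        loop = sum(
            math.log(pi) if yi else math.log(1 - pi) for pi, yi in zip(p, y)
        )
        assert m.log_likelihood(X, y) == pytest.approx(loop, abs=1e-9)

    def test_perfect_probabilities_give_ll_near_zero(self):
        m = LogisticRegressionMLE()
        m.intercept_, m.coef_ = 0.0, np.array([100.0])
        X = np.array([[-1.0], [1.0], [1.0]])
        y = np.array([0, 1, 1])
        assert m.log_likelihood(X, y) == pytest.approx(0.0, abs=1e-6)


class TestPackagedConsensusModel:
    def test_published_coefficients_verbatim(self):
        m = procedure13_model()
        assert m.intercept_ == 26.169
        np.testing.assert_array_equal(
            m.coef_, [-0.0175, -98.582, 66.953, 3.584, -8.594]
        )
        assert tuple(m.feature_names) == PROCEDURE13_FEATURES
        assert m.ll_ == -407.619

    def test_all_zero_descriptors_probability(self):
        m = procedure13_model()
        p = m.predict_prob_one(DescriptorVector(0, 0, 0, 0, 0))
        assert p == pytest.approx(1 / (1 + math.exp(-26.169)), abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_json_round_trip(self):
        m = procedure13_model()
        restored = LogisticRegressionMLE.from_json(m.to_json())
        assert restored.intercept_ == m.intercept_
        np.testing.assert_array_equal(restored.coef_, m.coef_)


class TestDescriptorVector:
    def test_validates_ranges(self):
        with pytest.raises(ValueError, match="avgD_Act"):
            DescriptorVector(0, 1.5, 0, 0, 0)
        with pytest.raises(ValueError, match="P_Inact"):
            DescriptorVector(0, 0, 0, 0, -1)
        with pytest.raises(ValueError, match="not finite"):
            DescriptorVector(math.nan, 0, 0, 0, 0)
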