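"""Unpenalized logistic regression fitted by maximum likelihood (IRLS).

The compound-level model is

    P = 1 / (1 + exp(-Y)),   Y = beta + sum_i alpha_i * X_i

with coefficients chosen to maximize the Bernoulli log-likelihood
``LL = sum_j [ y_j log p_j + (1 - y_j) log(1 - p_j) ]``.  Fitting uses
iteratively reweighted least squares (Newton-Raphson on the log-likelihood)
with a relative-LL convergence test.  No regularization is applied by
default; an optional small ridge exists solely as a diagnostic fallback for
separated data.

The published five-descriptor consensus model for androgen-receptor binding
ships as a packaged JSON file and is returned ready to use by
:func:`procedure13_model`.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources

import numpy as np
from scipy.special import expit

from ._base import BaseEstimator, NotFittedError, as_binary_labels, check_is_fitted

__all__ = [
    "LogisticRegressionMLE",
    "PerfectSeparationWarning",
    "procedure13_model",
    "DescriptorVector",
    "PROCEDURE13_FEATURES",
]

PROCEDURE13_FEATURES = (
    "ChimpDockScore",
    "avgD_Act",
    "avgD_Inact",
    "P_Act_dockChimp",
    "P_Inact",
)

_PROB_EPS = 1e-15
_ETA_CLIP = 35.0  # beyond this expit saturates in double precision


class PerfectSeparationWarning(UserWarning):
    """The design separates the classes; the MLE does not exist."""


class DescriptorVector:
    """The five descriptors of the consensus binding model.

    ``ChimpDockScore`` is the docking score in kcal/mol (0 sentinel allowed);
    ``avgD_Act``/``avgD_Inact`` are mean Tanimoto distances to the known
    binder / non-binder panels, in [0, 1]; ``P_Act_dockChimp``/``P_Inact``
    are the class-conditional Gaussian densities of the score.
    """

    __slots__ = PROCEDURE13_FEATURES

    def __init__(self, ChimpDockScore, avgD_Act, avgD_Inact, P_Act_dockChimp, P_Inact):
        vals = (ChimpDockScore, avgD_Act, avgD_Inact, P_Act_dockChimp, P_Inact)
        for name, v in zip(PROCEDURE13_FEATURES, vals):
            v = float(v)
            if not np.isfinite(v):
                raise ValueError(f"descriptor {name} is not finite: {v}")
            setattr(self, name, v)
        for name in ("avgD_Act", "avgD_Inact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("P_Act_dockChimp", "P_Inact"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROCEDURE13_FEATURES])


def _clamped_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class LogisticRegressionMLE(BaseEstimator):
    """Plain maximum-likelihood logistic regression.

    Parameters
    ----------
    tol : float, default 1e-8
        Convergence tolerance on the relative change of the log-likelihood.
    max_iter : int, default 100
        Newton/IRLS iteration cap.
    ridge : float, default 0.0
        Optional tiny L2 penalty used only to keep the Newton step defined on
        separated or collinear designs; 0 disables it (plain MLE).
    feature_names : sequence of str, optional
        Names attached to the columns; enforced when predicting from a
        pandas DataFrame or :class:`DescriptorVector`.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    ll_ : float
        Log-likelihood at the fitted coefficients (<= 0).
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        ridge: float = 0.0,
        feature_names=None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.feature_names = feature_names

    # -- design handling ---------------------------------------------------
    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, DescriptorVector):
            X = X.as_array()[None, :]
        if hasattr(X, "columns"):  # pandas DataFrame
            if self.feature_names is not None:
                missing = [n for n in self.feature_names if n not in X.columns]
                if missing:
                    raise ValueError(f"missing feature columns: {missing}")
                X = X[list(self.feature_names)]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features "
                f"({list(self.feature_names)}), got {X.shape[1]}"
            )
        return X

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = self._as_matrix(X)
        y = as_binary_labels(y)
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("features and labels differ in length")
        n1 = int(y.sum())
        if n1 == 0 or n1 == n:
            raise ValueError("both classes must be present to fit")

        design = np.hstack([np.ones((n, 1)), X])
        theta = np.zeros(p + 1)
        theta[0] = np.log(n1 / (n - n1))  # intercept-only start
        eta = design @ theta
        prob = expit(eta)
        ll = _clamped_ll(y, prob)

        converged = False
        n_iter = 0
        small_steps = 0
        for n_iter in range(1, self.max_iter + 1):
            w = np.clip(prob * (1.0 - prob), 1e-10, None)
            hess = (design * w[:, None]).T @ design
            if self.ridge > 0:
                hess = hess + self.ridge * np.eye(p + 1)
            grad = design.T @ (y - prob)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "singular design matrix: features are collinear "
                    "(or the data are separated with ridge=0)"
                ) from exc
            # Halve the step while it worsens the likelihood.
            new_ll = -np.inf
            for _ in range(30):
                cand = theta + step
                cand_eta = design @ cand
                cand_prob = expit(cand_eta)
                new_ll = _clamped_ll(y, cand_prob)
                if new_ll >= ll - 1e-12:
                    break
                step = step / 2.0
            theta, eta, prob = cand, cand_eta, cand_prob
            rel = abs(new_ll - ll) / max(abs(ll), 1.0)
            ll = new_ll
            # Require two consecutive sub-tolerance steps: the extra Newton
            # iteration polishes the solution so the score vector vanishes
            # well below the LL-based stopping precision.
            small_steps = small_steps + 1 if rel < self.tol else 0
            if small_steps >= 2:
                converged = True
                break

        separated = self._detect_separation(y, eta, ll)
        if separated:
            warnings.warn(
                "complete or quasi-complete separation detected: the maximum-"
                "likelihood estimate does not exist; coefficients reflect the "
                "iterate where fitting stopped and converged_ is False",
                PerfectSeparationWarning,
                stacklevel=2,
            )
            converged = False

        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:].copy()
        self.ll_ = ll
        self.converged_ = bool(converged)
        self.n_iter_ = n_iter
        return self

    @staticmethod
    def _detect_separation(y: np.ndarray, eta: np.ndarray, ll: float) -> bool:
        # All fitted margins correctly signed and the likelihood essentially
        # saturated (LL -> 0): the coefficients are diverging, the hallmark
        # of complete or quasi-complete separation.
        sign_ok = np.all((eta > 0) == (y == 1))
        return bool(sign_ok and ll > -1e-4)

    # -- prediction ---------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = self._as_matrix(X)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"model has {self.coef_.shape[0]} coefficients but X has "
                f"{X.shape[1]} columns"
            )
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        """P(class 1) per row, strictly inside (0, 1)."""
        p = expit(self.decision_function(X))
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def predict_prob_one(self, x: DescriptorVector) -> float:
        """Probability for a single descriptor vector."""
        return float(self.predict_proba(x)[0])

    def log_likelihood(self, X, y) -> float:
        """Bernoulli log-likelihood of ``(X, y)`` under the fitted model."""
        y = as_binary_labels(y)
        return _clamped_ll(y, self.predict_proba(X))

    def score_vector(self, X, y) -> np.ndarray:
        """Gradient of the log-likelihood at the fitted coefficients."""
        check_is_fitted(self, "coef_")
        X = self._as_matrix(X)
        y = as_binary_labels(y)
        resid = y - self.predict_proba(X)
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        return design.T @ resid

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "feature_names": list(self.feature_names)
            if self.feature_names is not None
            else None,
            "beta": self.intercept_,
            "alphas": self.coef_.tolist(),
            "ll": self.ll_,
            "meta": {
                "converged": self.converged_,
                "n_iter": self.n_iter_,
                "tol": self.tol,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticRegressionMLE":
        model = cls(feature_names=d.get("feature_names"))
        model.intercept_ = float(d["beta"])
        model.coef_ = np.asarray(d["alphas"], dtype=float)
        model.ll_ = d.get("ll")
        meta = d.get("meta") or {}
        model.converged_ = bool(meta.get("converged", True))
        model.n_iter_ = int(meta.get("n_iter", 0))
        return model

    @classmethod
    def from_json(cls, s: str) -> "LogisticRegressionMLE":
        return cls.from_dict(json.loads(s))


def procedure13_model() -> LogisticRegressionMLE:
    """The packaged five-descriptor consensus model with published coefficients.

    The returned estimator is already "fitted": its intercept and coefficients
    are the published values (on raw descriptor scales, unstandardized) and it
    predicts through the ordinary logistic link with a 0.5 cut-off.
    """
    payload = (
        resources.files("arclass").joinpath("data/eq11_model.json").read_text()
    )
    return LogisticRegressionMLE.from_dict(json.loads(payload))
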