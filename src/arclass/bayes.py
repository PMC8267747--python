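"""Class-conditional Gaussian ("naive Bayesian") classifier on docking scores.

One Gaussian density is fitted per class (binders / non-binders) over the
docking scores in kcal/mol; a compound is called a binder when its density
under the binder class exceeds the density under the non-binder class, i.e.
by the density ratio.  A docking score of exactly 0 is a sentinel meaning
"no pose produced" and is excluded from fitting by default (half the screen
typically fails to pose, which would otherwise corrupt both class means),
while prediction still accepts 0 as an input value.
"""

from __future__ import annotations

import json
import math

import numpy as np

from ._base import BaseEstimator, as_1d_float, as_binary_labels, check_is_fitted

__all__ = [
    "GaussianScoreBayes",
    "gaussian_density",
    "fit_gaussian_classes",
    "classify_bayes",
]


def gaussian_density(x, mu: float, sigma: float, printed_variant: bool = False):
    """Normal density with mean ``mu`` and standard deviation ``sigma``.

    ``printed_variant=True`` reproduces a corrupted textbook rendering in
    which the exponent denominator reads 2*pi*sigma**2 instead of 2*sigma**2;
    it exists only for sensitivity checks and is never the default.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    denom = 2.0 * math.pi * sigma**2 if printed_variant else 2.0 * sigma**2
    out = norm * np.exp(-((x - mu) ** 2) / denom)
    return out if out.ndim else float(out)


class GaussianScoreBayes(BaseEstimator):
    """Two class-conditional Gaussians over docking scores.

    Parameters
    ----------
    exclude_zero : bool, default True
        Drop the 0 kcal/mol sentinel scores ("no docking pose") before
        fitting each class Gaussian.
    printed_variant : bool, default False
        Evaluate densities with the corrupted exponent (see
        :func:`gaussian_density`).

    Attributes
    ----------
    mu_act_, sigma_act_, mu_inact_, sigma_inact_ : float
        Per-class sample mean and standard deviation (n-1 denominator),
        kcal/mol.
    n_act_, n_inact_ : int
        Number of scores actually used per class.
    zeros_excluded_ : bool
        Whether sentinel scores were dropped during fitting.
    """

    def __init__(self, exclude_zero: bool = True, printed_variant: bool = False):
        self.exclude_zero = exclude_zero
        self.printed_variant = printed_variant

    def fit(self, X, y):
        scores = as_1d_float(X, "scores")
        y = as_binary_labels(y)
        if scores.shape[0] != y.shape[0]:
            raise ValueError("scores and labels differ in length")
        return self._fit_arrays(scores[y == 1], scores[y == 0])

    def _fit_arrays(self, scores_act: np.ndarray, scores_inact: np.ndarray):
        stats = []
        for name, vals in (("active", scores_act), ("inactive", scores_inact)):
            vals = np.asarray(vals, dtype=float)
            if self.exclude_zero:
                vals = vals[vals != 0.0]
            if vals.size < 2:
                raise ValueError(
                    f"{name} class has {vals.size} usable scores; need >= 2"
                )
            sd = float(np.std(vals, ddof=1))
            if sd == 0.0:
                raise ValueError(
                    f"{name} class scores are all identical; sigma would be 0"
                )
            stats.append((float(np.mean(vals)), sd, int(vals.size)))
        (self.mu_act_, self.sigma_act_, self.n_act_) = stats[0]
        (self.mu_inact_, self.sigma_inact_, self.n_inact_) = stats[1]
        self.zeros_excluded_ = bool(self.exclude_zero)
        return self

    def density(self, x, which: str):
        check_is_fitted(self, "mu_act_")
        if which == "active":
            mu, sigma = self.mu_act_, self.sigma_act_
        elif which == "inactive":
            mu, sigma = self.mu_inact_, self.sigma_inact_
        else:
            raise ValueError("which must be 'active' or 'inactive'")
        return gaussian_density(x, mu, sigma, self.printed_variant)

    def density_ratio(self, x):
        """P_act(x) / P_inact(x); the feature fed to downstream regressions."""
        return self.density(x, "active") / self.density(x, "inactive")

    def decision_function(self, X):
        scores = as_1d_float(X, "scores")
        return np.log(self.density(scores, "active")) - np.log(
            self.density(scores, "inactive")
        )

    def predict(self, X):
        """1 (binder) where the active-class density strictly exceeds the
        inactive-class density; exact ties go to non-binder (conservative
        for an imbalanced screen)."""
        scores = as_1d_float(X, "scores")
        return (
            self.density(scores, "active") > self.density(scores, "inactive")
        ).astype(int)

    # -- serialization ----------------------------------------------------
    _FIELDS = ("mu_act_", "sigma_act_", "mu_inact_", "sigma_inact_", "n_act_", "n_inact_")

    def to_dict(self) -> dict:
        check_is_fitted(self, "mu_act_")
        d = {f.rstrip("_"): getattr(self, f) for f in self._FIELDS}
        d["zeros_excluded"] = self.zeros_excluded_
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianScoreBayes":
        model = cls(exclude_zero=bool(d["zeros_excluded"]))
        for f in cls._FIELDS:
            setattr(model, f, d[f.rstrip("_")])
        model.zeros_excluded_ = bool(d["zeros_excluded"])
        return model

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaussianScoreBayes":
        return cls.from_dict(json.loads(s))


def fit_gaussian_classes(
    scores_act, scores_inact, exclude_zero: bool = True
) -> GaussianScoreBayes:
    """Fit the two class Gaussians from per-class score lists."""
    return GaussianScoreBayes(exclude_zero=exclude_zero)._fit_arrays(
        np.asarray(scores_act, dtype=float), np.asarray(scores_inact, dtype=float)
    )


def classify_bayes(score: float, model: GaussianScoreBayes) -> tuple[int, float]:
    """Classify one docking score; returns (label, density ratio).

    Label 1 (binder) iff the active-class density strictly exceeds the
    inactive-class density; the ratio is returned for downstream features.
    """
    d_act = float(model.density(score, "active"))
    d_inact = float(model.density(score, "inactive"))
    return int(d_act > d_inact), d_act / d_inact
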