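"""The 13 binding-classification procedures, from a bare docking-score
threshold to the five-descriptor consensus logistic model.

Each procedure maps a compound's (docking score, fingerprint) pair to
binder (1) / non-binder (0).  The building blocks are:

* a score threshold (default -7 kcal/mol, roughly sub-micromolar Kd;
  scores at or below the threshold are binders — the 0 "no pose" sentinel
  always lands above it),
* the class-conditional Gaussian density ratio on scores (``bayes``),
* average Tanimoto distances to the known binder / non-binder panels
  (``avgD_Act`` / ``avgD_Inact``; a compound is fingerprint-classified as a
  binder when it sits strictly closer to the binder panel), and
* logistic regressions fitted by maximum likelihood on combinations of
  those quantities.

Procedures::

     1  score <= threshold
     2  Gaussian density ratio on the raw score
     3  univariate logistic on the density ratio
     4  0-score => non-binder, otherwise procedure 2
     5  avgD_Act < avgD_Inact
     6  non-zero score => procedure 1; zero score => procedure 5
     7  procedure 5 first; its non-binders re-judged by procedure 1
     8  logistic on [score, avgD_Act - avgD_Inact]
     9  cascade of 6; zero-score compounds whose average distances tie
        fall through to procedure 8
    10  procedures 2 and 5 when they agree, else procedure 8
    11  logistic on [score, avgD difference, density ratio]
    12  logistic on [avgD_Act, avgD_Inact, P_act, P_inact]
    13  logistic on all five descriptors (refit, or the packaged published
        coefficients when ``published=True``)

Training-set evaluation uses leave-self-out for the panel distances: a
compound never contributes its own fingerprint to its class average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._base import BaseEstimator, as_binary_labels, check_is_fitted
from .bayes import GaussianScoreBayes
from .dataset import LabeledDataset
from .fingerprints import ReferencePanel, pack_bit_matrix, average_distance_matrix
from .logistic import LogisticRegressionMLE, procedure13_model, PROCEDURE13_FEATURES
from .metrics import confusion, metrics_from_confusion, METRIC_COLUMNS

__all__ = [
    "ProcedureConfig",
    "ProcedureClassifier",
    "classify",
    "run_suite",
    "PROCEDURE_NAMES",
]

PROCEDURE_NAMES = {
    1: "Docking score threshold",
    2: "Bayesian on scores",
    3: "Logistic regression on Bayesian",
    4: "Modified Bayesian",
    5: "Fingerprints (ECFP)",
    6: "Docking scores then ECFP",
    7: "ECFP then docking scores",
    8: "Logistic regr. on docking scores and ECFP",
    9: "Consensus Docking and ECFP else 8",
    10: "Consensus Bayesian and ECFP else 8",
    11: "Logistic regr. on docking scores and ECFP and ratio of Bayesian",
    12: "Logistic regression on Bayesian avgs. and fingerprints",
    13: "Logistic regression on docking scores and Bayesian avgs. and fingerprints",
}

_TIE_EPS = 1e-12


@dataclass
class ProcedureConfig:
    """Shared knobs for the procedure suite."""

    dock_threshold: float = -7.0  # kcal/mol; <= threshold is a binder
    logistic_tol: float = 1e-8
    logistic_max_iter: int = 100
    leave_self_out: bool = True
    exclude_zero: bool = True
    published: bool = False

    def __post_init__(self):
        if self.dock_threshold >= 0:
            raise ValueError("dock_threshold must be negative (kcal/mol)")


@dataclass
class _Descriptors:
    """Per-compound derived quantities shared by the procedures."""

    scores: np.ndarray
    avgd_act: np.ndarray
    avgd_inact: np.ndarray
    p_act: np.ndarray
    p_inact: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        return self.p_act / self.p_inact

    @property
    def avgd_diff(self) -> np.ndarray:
        return self.avgd_act - self.avgd_inact

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ChimpDockScore": self.scores,
                "avgD_Act": self.avgd_act,
                "avgD_Inact": self.avgd_inact,
                "P_Act_dockChimp": self.p_act,
                "P_Inact": self.p_inact,
            }
        )


class ProcedureClassifier(BaseEstimator):
    """One of the 13 procedures as a fit/predict classifier.

    The feature matrix ``X`` has the docking score in column 0 and the
    fingerprint bits in the remaining columns, as produced by
    :meth:`arclass.dataset.LabeledDataset.X`.

    Parameters
    ----------
    procedure : int in 1..13
    dock_threshold : float
        Binder cut-off on the docking score, kcal/mol (ties classify binder).
    exclude_zero : bool
        Exclude the 0 sentinel when fitting the class Gaussians.
    published : bool
        For procedure 13, use the packaged published coefficients instead of
        refitting on the training set.
    leave_self_out : bool
        Exclude a training compound's own fingerprint from its class average
        distance when computing training descriptors.
    """

    def __init__(
        self,
        procedure: int = 13,
        dock_threshold: float = -7.0,
        exclude_zero: bool = True,
        published: bool = False,
        leave_self_out: bool = True,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.procedure = procedure
        self.dock_threshold = dock_threshold
        self.exclude_zero = exclude_zero
        self.published = published
        self.leave_self_out = leave_self_out
        self.tol = tol
        self.max_iter = max_iter

    # -- shared machinery ---------------------------------------------------
    def _split_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError(
                "X must be 2-D with the docking score in column 0 and "
                "fingerprint bits after it"
            )
        scores = X[:, 0]
        bits = X[:, 1:]
        if not np.isin(bits, (0.0, 1.0)).all():
            raise ValueError("fingerprint columns must be 0/1")
        return scores, bits.astype(np.uint8)

    def fit(self, X, y):
        if self.procedure not in PROCEDURE_NAMES:
            raise ValueError(f"unknown procedure id {self.procedure}; expected 1..13")
        if self.dock_threshold >= 0:
            raise ValueError("dock_threshold must be negative (kcal/mol)")
        scores, bits = self._split_X(X)
        y = as_binary_labels(y)
        if y.shape[0] != scores.shape[0]:
            raise ValueError("X and y differ in length")
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError("training data must contain both classes")

        self.bayes_ = GaussianScoreBayes(exclude_zero=self.exclude_zero).fit(scores, y)
        self.panel_ = ReferencePanel(
            actives=[_Row(bits[i]) for i in np.nonzero(y == 1)[0]],
            inactives=[_Row(bits[i]) for i in np.nonzero(y == 0)[0]],
        )
        # Panel row occupied by each training compound within its own class.
        pos_in_class = np.full(y.size, -1, dtype=int)
        pos_in_class[y == 1] = np.arange(int(y.sum()))
        exc_act = np.where(y == 1, pos_in_class, -1)
        pos_in_class = np.full(y.size, -1, dtype=int)
        pos_in_class[y == 0] = np.arange(int((y == 0).sum()))
        exc_inact = np.where(y == 0, pos_in_class, -1)

        train_desc = self._descriptors(
            scores,
            bits,
            exclude_active=exc_act if self.leave_self_out else None,
            exclude_inactive=exc_inact if self.leave_self_out else None,
        )
        self.models_ = self._fit_logistics(train_desc, y)
        self._train_desc = train_desc
        self._train_y = y
        return self

    def _descriptors(self, scores, bits, exclude_active=None, exclude_inactive=None):
        packed, counts, length = pack_bit_matrix(bits)
        if length != self.panel_.length:
            raise ValueError(
                f"fingerprint length {length} != fitted panel length "
                f"{self.panel_.length}"
            )
        d_act = average_distance_matrix(
            packed, counts, self.panel_._act_packed, self.panel_._act_counts, exclude_active
        )
        d_inact = average_distance_matrix(
            packed,
            counts,
            self.panel_._inact_packed,
            self.panel_._inact_counts,
            exclude_inactive,
        )
        return _Descriptors(
            scores=scores,
            avgd_act=d_act,
            avgd_inact=d_inact,
            p_act=np.asarray(self.bayes_.density(scores, "active")),
            p_inact=np.asarray(self.bayes_.density(scores, "inactive")),
        )

    def _fit_logistics(self, desc: _Descriptors, y: np.ndarray) -> dict:
        """Fit the logistic submodels a procedure may invoke.

        Procedure 8's model serves as the fallback stage of 9 and 10, so it
        is fitted whenever any of 8-10 runs.
        """
        needed = {
            3: {3},
            8: {8},
            9: {8},
            10: {8},
            11: {11},
            12: {12},
            13: set() if self.published else {13},
        }.get(self.procedure, set())
        spec = {
            3: (["BayesRatio"], desc.ratio[:, None]),
            8: (
                ["ChimpDockScore", "avgD_diff"],
                np.column_stack([desc.scores, desc.avgd_diff]),
            ),
            11: (
                ["ChimpDockScore", "avgD_diff", "BayesRatio"],
                np.column_stack([desc.scores, desc.avgd_diff, desc.ratio]),
            ),
            12: (
                ["avgD_Act", "avgD_Inact", "P_Act_dockChimp", "P_Inact"],
                np.column_stack(
                    [desc.avgd_act, desc.avgd_inact, desc.p_act, desc.p_inact]
                ),
            ),
            13: (list(PROCEDURE13_FEATURES), desc.frame().to_numpy()),
        }
        models = {}
        for key in needed:
            names, feats = spec[key]
            models[key] = LogisticRegressionMLE(
                tol=self.tol, max_iter=self.max_iter, feature_names=names
            ).fit(feats, y)
        if self.procedure == 13 and self.published:
            models[13] = procedure13_model()
        return models

    # -- the decision rules ---------------------------------------------------
    def _apply(self, pid: int, desc: _Descriptors) -> np.ndarray:
        s = desc.scores
        r1 = (s <= self.dock_threshold).astype(int)
        if pid == 1:
            return r1
        r2 = (desc.p_act > desc.p_inact).astype(int)
        if pid == 2:
            return r2
        if pid == 3:
            return self.models_[3].predict(desc.ratio[:, None])
        if pid == 4:
            return np.where(s == 0.0, 0, r2)
        r5 = (desc.avgd_act < desc.avgd_inact).astype(int)
        if pid == 5:
            return r5
        if pid == 6:
            return np.where(s != 0.0, r1, r5)
        if pid == 7:
            return np.where(r5 == 1, 1, r1)
        if pid == 8:
            return self.models_[8].predict(
                np.column_stack([s, desc.avgd_diff])
            )
        if pid == 9:
            p8 = self.models_[8].predict(np.column_stack([s, desc.avgd_diff]))
            tie = np.abs(desc.avgd_diff) <= _TIE_EPS
            stage2 = np.where((s == 0.0) & tie, p8, r5)
            return np.where(s != 0.0, r1, stage2)
        if pid == 10:
            p8 = self.models_[8].predict(np.column_stack([s, desc.avgd_diff]))
            return np.where(r2 == r5, r2, p8)
        if pid == 11:
            return self.models_[11].predict(
                np.column_stack([s, desc.avgd_diff, desc.ratio])
            )
        if pid == 12:
            return self.models_[12].predict(
                np.column_stack(
                    [desc.avgd_act, desc.avgd_inact, desc.p_act, desc.p_inact]
                )
            )
        if pid == 13:
            return self.models_[13].predict(desc.frame())
        raise ValueError(f"unknown procedure id {pid}")

    def _probabilities(self, pid: int, desc: _Descriptors) -> np.ndarray | None:
        """Final-stage logistic probability where the procedure has one."""
        if pid == 3:
            return self.models_[3].predict_proba(desc.ratio[:, None])
        if pid == 8:
            return self.models_[8].predict_proba(
                np.column_stack([desc.scores, desc.avgd_diff])
            )
        if pid == 11:
            return self.models_[11].predict_proba(
                np.column_stack([desc.scores, desc.avgd_diff, desc.ratio])
            )
        if pid == 12:
            return self.models_[12].predict_proba(
                np.column_stack(
                    [desc.avgd_act, desc.avgd_inact, desc.p_act, desc.p_inact]
                )
            )
        if pid == 13:
            return self.models_[13].predict_proba(desc.frame())
        return None

    # -- public surface --------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bayes_")
        scores, bits = self._split_X(X)
        return self._apply(self.procedure, self._descriptors(scores, bits))

    def predict_proba_final(self, X) -> np.ndarray | None:
        """Probability from the procedure's final logistic stage, or None for
        purely rule-based procedures."""
        check_is_fitted(self, "bayes_")
        scores, bits = self._split_X(X)
        return self._probabilities(self.procedure, self._descriptors(scores, bits))

    def predict_training(self) -> np.ndarray:
        """Predictions on the training compounds with leave-self-out panel
        distances, i.e. the in-sample evaluation used for a procedure table."""
        check_is_fitted(self, "bayes_")
        return self._apply(self.procedure, self._train_desc)


class _Row:
    """Adapter presenting a bit row as a minimal fingerprint for panel packing."""

    __slots__ = ("length", "packed", "n_set", "_bits")

    def __init__(self, bits: np.ndarray):
        self._bits = np.asarray(bits, dtype=np.uint8)
        self.length = int(self._bits.size)
        self.packed = np.packbits(self._bits)
        self.n_set = int(np.bitwise_count(self.packed).sum())

    @property
    def bits(self):
        return self._bits


def classify(procedure_id: int, X, y_train, X_train=None, config: ProcedureConfig | None = None):
    """Functional wrapper: fit procedure ``procedure_id`` on training data and
    classify ``X``.  When ``X_train`` is None, ``X`` itself is the training
    set and predictions use leave-self-out distances."""
    config = config or ProcedureConfig()
    clf = ProcedureClassifier(
        procedure=procedure_id,
        dock_threshold=config.dock_threshold,
        exclude_zero=config.exclude_zero,
        published=config.published,
        leave_self_out=config.leave_self_out,
        tol=config.logistic_tol,
        max_iter=config.logistic_max_iter,
    )
    if X_train is None:
        clf.fit(X, y_train)
        return clf.predict_training()
    clf.fit(X_train, y_train)
    return clf.predict(X)


def run_suite(
    dataset: LabeledDataset, config: ProcedureConfig | None = None
) -> pd.DataFrame:
    """Fit the shared models once and evaluate all 13 procedures in-sample.

    Returns one row per procedure with the confusion matrix and the full
    metrics suite, in the layout of a screening-performance table.
    """
    config = config or ProcedureConfig()
    if dataset.labels is None:
        raise ValueError("run_suite needs a labeled dataset")
    y = dataset.labels
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("dataset must contain both classes")

    # One classifier fits every shared component; per-procedure logistic
    # models are fitted on demand below.
    base = ProcedureClassifier(
        procedure=13,
        dock_threshold=config.dock_threshold,
        exclude_zero=config.exclude_zero,
        published=config.published,
        leave_self_out=config.leave_self_out,
        tol=config.logistic_tol,
        max_iter=config.logistic_max_iter,
    )
    X = dataset.X()
    base.fit(X, y)
    desc, models = base._train_desc, base.models_
    # Complete the submodel set the other procedures need.
    for pid in (3, 8, 11, 12, 13):
        if pid not in models:
            helper = ProcedureClassifier(
                procedure=pid,
                dock_threshold=config.dock_threshold,
                exclude_zero=config.exclude_zero,
                published=config.published,
                leave_self_out=config.leave_self_out,
                tol=config.logistic_tol,
                max_iter=config.logistic_max_iter,
            )
            helper.bayes_ = base.bayes_
            helper.panel_ = base.panel_
            models.update(helper._fit_logistics(desc, y))

    rows = []
    for pid in range(1, 14):
        preds = base._apply(pid, desc)
        cm = confusion(y, preds)
        report = metrics_from_confusion(cm)
        row = {
            "procedure": pid,
            "name": PROCEDURE_NAMES[pid],
            "TP": cm.TP,
            "TN": cm.TN,
            "FP": cm.FP,
            "FN": cm.FN,
        }
        row.update({k: getattr(report, k) for k in METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)
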