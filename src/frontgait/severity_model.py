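"""UPDRS-gait severity classification with a PUK-kernel one-vs-all SVM.

The Pearson-VII universal kernel (PUK)

    k(u, v) = 1 / [1 + (2 * ||u - v|| * sqrt(2**(1/omega) - 1) / sigma)**2]**omega

interpolates between Lorentzian- and Gaussian-like shapes via the tailing
factor ``omega`` and half-width ``sigma``; the defaults (omega=0.2, sigma=1.0)
are the tuned operating point for the gait features.  Severity levels 0/1/2
are separated by three binary soft-margin SVMs (one-vs-all) on a precomputed
PUK Gram matrix; features are standardized with training-split statistics
before the kernel because the five features carry heterogeneous units
(seconds, Hz, dimensionless).

Evaluation follows stratified k-fold cross-validation: per-fold accuracy,
a pooled confusion matrix, per-class TPR, and per-class ROC/AUC from the
pooled out-of-fold decision scores.  A Kruskal-Wallis rank test screens each
feature for severity-level differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import InputError

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PUKParams:
    """PUK kernel shape parameters: tailing factor omega, half-width sigma."""

    omega: float = 0.2
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise InputError("omega must be positive")
        if not self.sigma > 0:
            raise InputError("sigma must be positive")


def _puk_from_sqdist(sq_dist: np.ndarray, omega: float, sigma: float) -> np.ndarray:
    # (2 d sqrt(2^(1/w)-1) / s)^2  ==  4 (2^(1/w)-1) d^2 / s^2
    scale = 4.0 * (2.0 ** (1.0 / omega) - 1.0) / sigma**2
    return (1.0 + scale * np.maximum(sq_dist, 0.0)) ** (-omega)


def puk_kernel(v1, v2, params: PUKParams = PUKParams()) -> float:
    """PUK kernel value for a pair of feature vectors; 1 iff v1 == v2."""
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(_puk_from_sqdist(np.sum((a - b) ** 2), params.omega, params.sigma))


def gram_matrix(X, Y=None, params: PUKParams = PUKParams()) -> np.ndarray:
    """PUK kernel matrix between the rows of X and Y (Y defaults to X).

    Symmetric with unit diagonal when Y is X; entries in (0, 1]; positive
    semi-definite up to numerical tolerance (the PUK is a valid kernel).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be 2-D (n_samples, n_features)")
    if not np.isfinite(X).all():
        raise InputError("non-finite feature values")
    if Y is None:
        Y = X
    else:
        Y = np.asarray(Y, dtype=float)
        if not np.isfinite(Y).all():
            raise InputError("non-finite feature values")
    sq = cdist(X, Y, metric="sqeuclidean")
    return _puk_from_sqdist(sq, params.omega, params.sigma)


class PukSvc(ClassifierMixin, BaseEstimator):
    """One-vs-all SVM with the PUK kernel and training-split standardization.

    One binary soft-margin SVM is fitted per class on the precomputed PUK
    Gram matrix of standardized features; prediction takes the argmax of the
    per-class decision scores, ties broken toward the lower class index.

    Parameters
    ----------
    omega, sigma : float
        PUK shape parameters (defaults 0.2 and 1.0).
    C : float
        Soft-margin regularization constant of each binary SVM.
    """

    def __init__(self, omega: float = 0.2, sigma: float = 1.0, C: float = 1.0) -> None:
        self.omega = omega
        self.sigma = sigma
        self.C = C

    def _params(self) -> PUKParams:
        return PUKParams(omega=self.omega, sigma=self.sigma)

    def fit(self, X, y) -> "PukSvc":
        X, y = check_X_y(X, y)
        if not np.isfinite(X).all():
            raise InputError("non-finite feature values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise InputError("training data contains a single class")
        if (counts < 2).any():
            raise InputError("each class needs at least 2 training samples")
        self.classes_ = classes
        self.scaler_ = StandardScaler().fit(X)
        self.X_fit_ = self.scaler_.transform(X)
        gram = gram_matrix(self.X_fit_, params=self._params())
        self.estimators_ = []
        for cls in classes:
            svc = SVC(C=self.C, kernel="precomputed")
            svc.fit(gram, (y == cls).astype(int))
            self.estimators_.append(svc)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class one-vs-all decision scores, shape (n_samples, n_classes)."""
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        if not np.isfinite(X).all():
            raise InputError("non-finite feature values")
        gram = gram_matrix(self.scaler_.transform(X), self.X_fit_, params=self._params())
        return np.column_stack([est.decision_function(gram) for est in self.estimators_])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        # np.argmax takes the first maximum: ties resolve toward lower class index
        return self.classes_[np.argmax(scores, axis=1)]


def train_one_vs_all(
    X,
    y,
    params: PUKParams = PUKParams(),
    C: float = 1.0,
) -> PukSvc:
    """Functional wrapper: fit a :class:`PukSvc` on a labelled feature matrix."""
    return PukSvc(omega=params.omega, sigma=params.sigma, C=C).fit(X, y)


@dataclass
class EvalReport:
    """Cross-validation evaluation: fold accuracies, pooled confusion matrix,
    per-class TPR and ROC/AUC, macro-averaged AUC."""

    classes: list
    fold_accuracies: list
    confusion_matrix: np.ndarray  # rows = true class, columns = predicted
    per_class_tpr: dict
    roc_points: dict  # class -> {"fpr": [...], "tpr": [...]}
    auc: dict
    macro_auc: float
    seed: int
    n_samples: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "classes": [int(c) for c in self.classes],
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
            "per_class_tpr": {str(k): float(v) for k, v in self.per_class_tpr.items()},
            "roc_points": {
                str(k): {kk: [float(x) for x in vv] for kk, vv in v.items()}
                for k, v in self.roc_points.items()
            },
            "auc": {str(k): float(v) for k, v in self.auc.items()},
            "macro_auc": float(self.macro_auc),
            "seed": int(self.seed),
            "n_samples": int(self.n_samples),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cross_validate(
    X,
    y,
    *,
    params: PUKParams = PUKParams(),
    C: float = 1.0,
    n_folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of the PUK-SVM.

    Folds partition the data (every sample is tested exactly once); the model
    — including feature standardization — is refitted on each training split.
    ROC curves and AUC are computed per class from the pooled out-of-fold
    decision scores; the macro average of the per-class AUCs is the headline
    number.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < n_folds).any():
        raise InputError(
            f"every class needs >= n_folds={n_folds} samples, got counts {dict(zip(classes, counts))}"
        )
    base = PukSvc(omega=params.omega, sigma=params.sigma, C=C)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof_scores = np.full((len(y), len(classes)), np.nan)
    oof_pred = np.empty(len(y), dtype=y.dtype)
    tested = np.zeros(len(y), dtype=int)
    fold_accuracies = []
    for train_idx, test_idx in skf.split(X, y):
        model = clone(base).fit(X[train_idx], y[train_idx])
        scores = model.decision_function(X[test_idx])
        # per-fold models always see all classes under stratification
        oof_scores[test_idx] = scores
        pred = model.classes_[np.argmax(scores, axis=1)]
        oof_pred[test_idx] = pred
        tested[test_idx] += 1
        fold_accuracies.append(float(np.mean(pred == y[test_idx])))
    assert (tested == 1).all(), "CV bookkeeping: every sample must be tested exactly once"

    confusion = sk_confusion_matrix(y, oof_pred, labels=classes)
    row_sums = confusion.sum(axis=1)
    per_class_tpr = {
        cls: float(confusion[i, i] / row_sums[i]) if row_sums[i] else 0.0
        for i, cls in enumerate(classes)
    }
    roc_points, aucs = {}, {}
    for i, cls in enumerate(classes):
        fpr, tpr, _ = sk_roc_curve((y == cls).astype(int), oof_scores[:, i])
        roc_points[cls] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        aucs[cls] = float(sk_auc(fpr, tpr))
    return EvalReport(
        classes=list(classes),
        fold_accuracies=fold_accuracies,
        confusion_matrix=confusion,
        per_class_tpr=per_class_tpr,
        roc_points=roc_points,
        auc=aucs,
        macro_auc=float(np.mean(list(aucs.values()))),
        seed=seed,
        n_samples=len(y),
    )


@dataclass
class RankTestResult:
    """Kruskal-Wallis screen of each feature across severity levels."""

    per_feature: dict = field(default_factory=dict)
    # per_feature[name] = {"H": float, "p_value": float, "mean_ranks": {level: float}}

    def to_dict(self) -> dict:
        return {
            name: {
                "H": float(res["H"]),
                "p_value": float(res["p_value"]),
                "mean_ranks": {str(k): float(v) for k, v in res["mean_ranks"].items()},
            }
            for name, res in self.per_feature.items()
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def rank_test(
    table: pd.DataFrame,
    feature_cols: Optional[list[str]] = None,
    label_col: str = "label",
) -> RankTestResult:
    """Kruskal-Wallis one-way rank test of each feature across levels.

    Mid-ranks handle ties; H carries the tie correction and p comes from the
    chi-square approximation with (levels - 1) degrees of freedom.  When all
    values of a feature are identical across groups the test degenerates to
    H = 0, p = 1.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in (label_col, "recording_id", "flags")]
    levels = sorted(table[label_col].unique())
    if len(levels) < 2:
        raise InputError("rank test needs at least 2 severity levels")
    if (table.groupby(label_col).size() < 2).any():
        raise InputError("rank test needs at least 2 samples per level")
    result = RankTestResult()
    for name in feature_cols:
        values = table[name].to_numpy(dtype=float)
        groups = [values[table[label_col].to_numpy() == lvl] for lvl in levels]
        if np.ptp(values) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        ranks = stats.rankdata(values)
        mean_ranks = {
            lvl: float(ranks[table[label_col].to_numpy() == lvl].mean()) for lvl in levels
        }
        result.per_feature[name] = {"H": float(h), "p_value": float(p), "mean_ranks": mean_ranks}
    return result


def save_model(model: PukSvc, path) -> None:
    """Serialize a fitted model (with format version) to a single file."""
    check_is_fitted(model, "estimators_")
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> PukSvc:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise InputError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
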