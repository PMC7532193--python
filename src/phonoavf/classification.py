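"""Six-class bruit classification and confusion-matrix quality indicators.

The primary classifier is a k-nearest-neighbours rule with the Manhattan
(city-block) metric and distance-weighted voting, k = 7: each of the k
nearest training vectors votes for its class with weight 1/d.  A query that
coincides exactly with training vectors (d = 0) is decided by those exact
matches alone, their mass split equally.  Per-class probabilities are the
normalized vote weights.

Evaluation follows the equal-class-weight (macro) convention: confusion
matrices are reported as row percentages, recall_c = M[c,c]/100, precision_c
divides the diagonal by its column sum, and the aggregate accuracy is the
mean of the per-class recalls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import EmptyInputError, FeatureMismatchError
from .io import CLASS_LABELS

logger = logging.getLogger(__name__)

DEFAULT_K = 7


def manhattan_distance(u: np.ndarray, v: np.ndarray) -> float:
    """City-block distance Σ|u_i − v_i| between two feature vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.abs(u - v).sum())


class DistanceWeightedKNN(BaseEstimator, ClassifierMixin):
    """k-NN classifier with Manhattan metric and 1/d-weighted voting.

    Parameters
    ----------
    k : int, default 7
        Number of neighbours; must not exceed the training-set size.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit`` (severity order for A–F).
    X_, y_ : ndarray
        Stored training vectors and integer-coded labels (instance-based
        model: the training set *is* the model).

    Notes
    -----
    Ties at the k-th distance are broken by training-set order.  Probability
    ties in ``predict`` are broken toward the more severe (later) class.
    """

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(X) == 0:
            raise EmptyInputError("empty training set")
        if not 1 <= self.k <= len(X):
            raise ValueError(f"k={self.k} must be in [1, n_train={len(X)}]")
        self.classes_, self.y_ = np.unique(y, return_inverse=True)
        self.X_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        D = cdist(X, self.X_, metric="cityblock")
        # stable argsort == ties at the k-th distance broken by training order
        order = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        probs = np.zeros((len(X), len(self.classes_)))
        for i in range(len(X)):
            idx = order[i]
            d = D[i, idx]
            cls = self.y_[idx]
            if np.any(d == 0.0):
                hits = cls[d == 0.0]
                w = np.full(len(hits), 1.0 / len(hits))
                np.add.at(probs[i], hits, w)
            else:
                w = 1.0 / d
                np.add.at(probs[i], cls, w)
                probs[i] /= probs[i].sum()
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # argmax with ties toward the later (more severe) class
        rev_best = np.argmax(probs[:, ::-1], axis=1)
        best = probs.shape[1] - 1 - rev_best
        return self.classes_[best]


def knn_predict(
    train_X, train_y, query, k: int = DEFAULT_K
) -> dict:
    """Class probabilities of a single query under the distance-weighted rule.

    Thin functional wrapper over :class:`DistanceWeightedKNN`.
    """
    model = DistanceWeightedKNN(k=k).fit(train_X, train_y)
    p = model.predict_proba(np.atleast_2d(query))[0]
    return dict(zip(model.classes_.tolist(), p.tolist()))


def svm_baseline(C: float = 10.0, gamma: str | float = "auto", seed: int = 0):
    """RBF support-vector baseline (standardized inputs, γ = 1/n_features)."""
    return make_pipeline(
        StandardScaler(), SVC(C=C, gamma=gamma, probability=True, random_state=seed)
    )


def rf_baseline(n_estimators: int = 100, seed: int = 0):
    """Random-forest baseline with a fixed seed for determinism."""
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)


# ---------------------------------------------------------------------------
# Confusion matrices and quality indicators


@dataclass
class QualityIndicators:
    """Per-class precision/recall/F-score and macro accuracy.

    ``acc`` is the unweighted mean of per-class recalls — the convention in
    which a row-percentage confusion matrix is read as counts over equally
    sized classes.
    """

    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    acc: float
    labels: tuple = CLASS_LABELS

    def rounded(self, ndigits: int = 2) -> dict:
        """Reporting form: half-up rounding to ``ndigits`` decimals."""
        r = lambda a: [round_half_up(v, ndigits) for v in np.atleast_1d(a)]
        return {
            "precision": r(self.precision),
            "recall": r(self.recall),
            "f_score": r(self.f_score),
            "acc": round_half_up(self.acc, ndigits),
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with halves away from zero (0.805 → 0.81)."""
    scale = 10**ndigits
    return np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)


def confusion_matrix_percent(y_true, y_pred, labels=CLASS_LABELS) -> pd.DataFrame:
    """Row-percentage confusion matrix (true classes in rows)."""
    labels = list(labels)
    counts = pd.crosstab(
        pd.Categorical(y_true, categories=labels),
        pd.Categorical(y_pred, categories=labels),
        dropna=False,
    ).reindex(index=labels, columns=labels, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        logger.warning("classes %s have no true instances; their rows are zero",
                       list(totals.index[totals == 0]))
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    return pct.fillna(0.0)


def quality_indicators(matrix) -> QualityIndicators:
    """Precision/recall/F-score per class and macro accuracy of a matrix.

    ``matrix`` is a row-percentage confusion matrix (DataFrame or array,
    true classes in rows).  Rows are treated as counts over equally sized
    classes of 100: recall_c = M[c,c]/100, precision_c = M[c,c]/column-sum,
    acc = trace/(100·n_classes).  A zero column yields precision 0 (logged).
    """
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = M.shape[0]
    diag = np.diag(M)
    recall = diag / 100.0
    colsum = M.sum(axis=0)
    precision = np.zeros(n)
    for c in range(n):
        if colsum[c] == 0:
            logger.warning("no predictions for class %d; precision reported as 0", c)
        else:
            precision[c] = diag[c] / colsum[c]
    denom = precision + recall
    f_score = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    acc = float(diag.sum() / (100.0 * n))
    labels = tuple(matrix.index) if isinstance(matrix, pd.DataFrame) else CLASS_LABELS[:n]
    return QualityIndicators(
        precision=precision, recall=recall, f_score=f_score, acc=acc, labels=labels
    )


def evaluate_cv(estimator, X, y, groups, splitter) -> tuple[pd.DataFrame, QualityIndicators]:
    """Aggregate cross-validated predictions into a confusion matrix.

    Runs ``splitter`` over (X, y, groups), fits a clone of ``estimator`` per
    fold, pools the held-out predictions, and returns the row-percentage
    matrix plus its quality indicators.  Folds whose training part misses a
    class are still fitted (the classifier simply cannot predict the absent
    class); this is logged.
    """
    from sklearn.base import clone

    from .selection import iter_splits

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    preds = np.empty(len(y), dtype=y.dtype)
    seen = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in iter_splits(splitter, X, y, groups):
        if len(np.unique(y[train_idx])) < len(np.unique(y)):
            logger.info("fold training part misses a class; fold kept, coverage reduced")
        model = clone(estimator).fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
        seen[test_idx] = True
    matrix = confusion_matrix_percent(y[seen], preds[seen], labels=np.unique(y).tolist())
    return matrix, quality_indicators(matrix)


def aggregate_recording(per_segment: list[dict | np.ndarray], labels=CLASS_LABELS) -> dict:
    """Recording-level class probabilities from per-segment probabilities.

    The probability of a class is the fraction of segments whose most
    probable class it is (ties within a segment go to the more severe
    class) — the dominant bar of the device's chart, with lateral bars from
    segments misread due to noise.
    """
    if not per_segment:
        raise EmptyInputError("no per-segment probabilities to aggregate")
    labels = list(labels)
    counts = dict.fromkeys(labels, 0)
    for p in per_segment:
        if isinstance(p, dict):
            vec = np.array([p.get(lbl, 0.0) for lbl in labels])
        else:
            vec = np.asarray(p, dtype=np.float64)
        best = len(vec) - 1 - int(np.argmax(vec[::-1]))
        counts[labels[best]] += 1
    total = len(per_segment)
    return {lbl: counts[lbl] / total for lbl in labels}


# ---------------------------------------------------------------------------
# Model persistence: k-NN is instance-based, so the artifact is the stored
# training set plus its configuration.


def save_model(path: str | Path, model: DistanceWeightedKNN, feature_names: list[str]) -> None:
    check_is_fitted(model, "X_")
    payload = {
        "kind": "distance-weighted-knn",
        "k": model.k,
        "metric": "manhattan",
        "weighting": "distance",
        "feature_names": list(feature_names),
        "classes": model.classes_.tolist(),
        "train_X": model.X_.tolist(),
        "train_y": model.classes_[model.y_].tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[DistanceWeightedKNN, list[str]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "distance-weighted-knn":
        raise FeatureMismatchError(f"{path}: not a k-NN model artifact")
    model = DistanceWeightedKNN(k=payload["k"])
    model.fit(np.array(payload["train_X"]), np.array(payload["train_y"]))
    return model, list(payload["feature_names"])
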