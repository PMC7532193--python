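"""Feature ranking and subset selection under exchangeable CV schemes.

Four rankers order the candidate features:

* ``CorrelationRanker`` — |Pearson correlation| between each feature and the
  ordinal severity code (A=1 … F=6); a pure filter, no classifier involved.
* ``ForwardSearchRanker`` — greedy wrapper: repeatedly add the feature that
  maximizes the cross-validated macro F-score of the target classifier.
* ``JoinedPairsRanker`` — wrapper over feature *pairs*: every unordered pair
  is scored by cross-validated macro F-score; a feature is ranked by the best
  pair it participates in, so jointly informative features surface even when
  individually weak.
* ``PCARanker`` — filter: features scored by their absolute loadings on the
  principal components covering 95% of variance, weighted by explained
  variance ratio.

Two CV schemes are supported.  Plain stratified 10-fold mixes cycles of the
same patient across train and test, which lets an instance-based classifier
learn patient identity rather than fistula state and overestimates quality;
leave-one-patient-out (LOPO) holds out every vector of one patient per fold
and is the honest scheme for new-patient generalization.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .classification import DistanceWeightedKNN
from .errors import SchemeError
from .io import label_index

logger = logging.getLogger(__name__)

#: The eight third-octave bands retained by the study's selection analysis:
#: energy in 60–140 Hz and 280–700 Hz.
DEFAULT_SELECTED_FEATURES = ("T_63", "T_80", "T_100", "T_125", "T_315", "T_400", "T_500", "T_630")


def default_selected_features() -> list[str]:
    """The eight band features the default classification model uses."""
    return list(DEFAULT_SELECTED_FEATURES)


def make_cv(kind: str = "lopo", n_splits: int = 10, seed: int = 0):
    """CV splitter factory: ``"kfold"`` (stratified, shuffled) or ``"lopo"``."""
    if kind == "kfold":
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    if kind == "lopo":
        return LeaveOneGroupOut()
    raise SchemeError(f"unknown CV scheme {kind!r}; expected 'kfold' or 'lopo'")


def check_cv_feasible(splitter, y, groups) -> None:
    if isinstance(splitter, LeaveOneGroupOut):
        if groups is None or len(np.unique(groups)) < 2:
            raise SchemeError("leave-one-patient-out requires ≥ 2 distinct patients")


def iter_splits(splitter, X, y, groups):
    """Iterate CV splits, tolerating splitters that ignore ``groups``."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="The groups parameter is ignored")
        yield from splitter.split(X, y, groups)


def cv_predict(estimator, X, y, groups, splitter) -> np.ndarray:
    """Pooled held-out predictions over all folds of ``splitter``."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    check_cv_feasible(splitter, y, groups)
    preds = np.empty(len(y), dtype=y.dtype)
    for train_idx, test_idx in iter_splits(splitter, X, y, groups):
        model = clone(estimator).fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    return preds


def cv_macro_f_score(estimator, X, y, groups, splitter) -> float:
    """Macro F-score of pooled cross-validated predictions."""
    preds = cv_predict(estimator, X, y, groups, splitter)
    return float(f1_score(y, preds, average="macro", zero_division=0))


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64), list(features.columns)
    X = np.asarray(features, dtype=np.float64)
    return X, [f"f{j}" for j in range(X.shape[1])]


class _RankerBase(BaseEstimator):
    """Shared fitted attributes: ``ordered_features_`` (best first), ``scores_``."""

    def to_report(self) -> dict:
        return {
            "method": type(self).__name__,
            "ordered_features": list(self.ordered_features_),
            "scores": {f: float(s) for f, s in zip(self.ordered_features_, self.scores_)},
        }


class CorrelationRanker(_RankerBase):
    """Rank features by |Pearson r| against the ordinal class code A=1…F=6.

    Zero-variance features get score 0; ties keep input feature order.
    """

    def fit(self, X, y, groups=None):
        X, names = _as_matrix(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("correlation ranking needs ≥ 2 classes present")
        if len(y) < 3:
            raise ValueError("correlation ranking needs ≥ 3 samples")
        codes = np.array([label_index(lbl) + 1 if isinstance(lbl, str) else lbl for lbl in y],
                         dtype=np.float64)
        scores = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.std(col) == 0 or np.std(codes) == 0:
                scores[j] = 0.0
            else:
                scores[j] = abs(np.corrcoef(col, codes)[0, 1])
        order = np.argsort(-scores, kind="stable")
        self.ordered_features_ = [names[j] for j in order]
        self.scores_ = scores[order]
        return self


class ForwardSearchRanker(_RankerBase):
    """Greedy forward wrapper selection under a CV scheme.

    At each step the feature whose addition maximizes the cross-validated
    macro F-score of ``estimator`` joins the subset; the ranking is the order
    of addition.  Ties keep input feature order.  ``max_features`` bounds the
    search depth (None = rank everything).
    """

    def __init__(self, estimator=None, cv=None, max_features: int | None = None):
        self.estimator = estimator
        self.cv = cv
        self.max_features = max_features

    def fit(self, X, y, groups=None):
        X, names = _as_matrix(X)
        y = np.asarray(y)
        est = self.estimator if self.estimator is not None else DistanceWeightedKNN()
        cv = self.cv if self.cv is not None else make_cv("kfold")
        check_cv_feasible(cv, y, groups)
        depth = X.shape[1] if self.max_features is None else min(self.max_features, X.shape[1])
        chosen: list[int] = []
        step_scores: list[float] = []
        remaining = list(range(X.shape[1]))
        while len(chosen) < depth:
            best_j, best_score = None, -np.inf
            for j in remaining:
                cols = chosen + [j]
                score = cv_macro_f_score(est, X[:, cols], y, groups, cv)
                if score > best_score:  # strict: ties keep earlier feature order
                    best_j, best_score = j, score
            chosen.append(best_j)
            remaining.remove(best_j)
            step_scores.append(best_score)
        self.ordered_features_ = [names[j] for j in chosen]
        self.scores_ = np.array(step_scores)
        return self


class JoinedPairsRanker(_RankerBase):
    """Rank features by the best CV F-score of any pair containing them.

    Every unordered feature pair is evaluated with the target classifier
    under the CV scheme; a feature's score is the maximum over its pairs.
    Ties are broken by the feature's second-best pair score, then by input
    feature order.
    """

    def __init__(self, estimator=None, cv=None):
        self.estimator = estimator
        self.cv = cv

    def fit(self, X, y, groups=None):
        X, names = _as_matrix(X)
        y = np.asarray(y)
        n = X.shape[1]
        if n < 2:
            raise ValueError("joined-pairs ranking needs ≥ 2 features")
        est = self.estimator if self.estimator is not None else DistanceWeightedKNN()
        cv = self.cv if self.cv is not None else make_cv("kfold")
        check_cv_feasible(cv, y, groups)
        pair_scores: dict[tuple[int, int], float] = {}
        for a, b in itertools.combinations(range(n), 2):
            pair_scores[(a, b)] = cv_macro_f_score(est, X[:, [a, b]], y, groups, cv)
        per_feature: list[list[float]] = [[] for _ in range(n)]
        for (a, b), s in pair_scores.items():
            per_feature[a].append(s)
            per_feature[b].append(s)
        best = np.array([max(s) for s in per_feature])
        second = np.array([sorted(s)[-2] if len(s) > 1 else max(s) for s in per_feature])
        order = sorted(range(n), key=lambda j: (-best[j], -second[j], j))
        self.ordered_features_ = [names[j] for j in order]
        self.scores_ = best[np.array(order)]
        self.pair_scores_ = {(names[a], names[b]): s for (a, b), s in pair_scores.items()}
        return self


class PCARanker(_RankerBase):
    """Rank features by their loadings on the leading principal components.

    Features are standardized internally; the score of feature j is
    Σ_k EVR_k · |loading_jk| over the leading components whose cumulative
    explained-variance ratio first reaches ``variance_coverage``.

    The default coverage (0.5) keeps only the components carrying the
    dominant correlated structure.  Pushing coverage towards 1 includes the
    near-noise components, where the orthonormality of the loading matrix
    makes Σ EVR·|loading| nearly equal for every feature — rewarding
    features whose variance is spread diffusely over many small components
    rather than the informative ones concentrated in the leading few.
    """

    def __init__(self, variance_coverage: float = 0.5, standardize: bool = True):
        self.variance_coverage = variance_coverage
        self.standardize = standardize

    def fit(self, X, y=None, groups=None):
        X, names = _as_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("PCA ranking needs ≥ 2 samples")
        Z = StandardScaler().fit_transform(X) if self.standardize else X
        pca = PCA().fit(Z)
        evr = pca.explained_variance_ratio_
        n_comp = int(np.searchsorted(np.cumsum(evr), self.variance_coverage) + 1)
        n_comp = min(n_comp, len(evr))
        scores = np.zeros(X.shape[1])
        for k in range(n_comp):
            scores += evr[k] * np.abs(pca.components_[k])
        order = np.argsort(-scores, kind="stable")
        self.ordered_features_ = [names[j] for j in order]
        self.scores_ = scores[order]
        return self


# ---------------------------------------------------------------------------
# Functional wrappers


def rank_by_correlation(features, labels) -> CorrelationRanker:
    return CorrelationRanker().fit(features, labels)


def rank_by_forward_search(features, labels, patient_ids=None, classifier=None, cv=None,
                           max_features=None) -> ForwardSearchRanker:
    return ForwardSearchRanker(estimator=classifier, cv=cv, max_features=max_features).fit(
        features, labels, groups=patient_ids
    )


def rank_by_joined_pairs(features, labels, patient_ids=None, classifier=None, cv=None
                         ) -> JoinedPairsRanker:
    return JoinedPairsRanker(estimator=classifier, cv=cv).fit(features, labels, groups=patient_ids)


def rank_by_pca(features) -> PCARanker:
    return PCARanker().fit(features)


def subset_curve(ranking, features, labels, patient_ids=None, classifier=None, cv=None
                 ) -> pd.DataFrame:
    """Macro F-score of the classifier on the top-n ranked features, n = 2…N.

    ``ranking`` is a fitted ranker or an ordered feature-name list.  Returns a
    frame with columns ``n_features, f_score`` — the subset-size curve whose
    maximum picks the final feature set.
    """
    ordered = ranking.ordered_features_ if hasattr(ranking, "ordered_features_") else list(ranking)
    X, names = _as_matrix(features)
    name_to_col = {nm: j for j, nm in enumerate(names)}
    missing = [f for f in ordered if f not in name_to_col]
    if missing:
        raise ValueError(f"ranking references unknown features {missing}")
    est = classifier if classifier is not None else DistanceWeightedKNN()
    splitter = cv if cv is not None else make_cv("kfold")
    y = np.asarray(labels)
    rows = []
    for n in range(2, len(ordered) + 1):
        cols = [name_to_col[f] for f in ordered[:n]]
        score = cv_macro_f_score(est, X[:, cols], y, patient_ids, splitter)
        rows.append({"n_features": n, "f_score": score})
    return pd.DataFrame(rows)
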