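"""Ranking methods, CV schemes, and the subset-size curve."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phonoavf import selection
from phonoavf.classification import DistanceWeightedKNN
from phonoavf.errors import SchemeError
from phonoavf.selection import (
    CorrelationRanker,
    ForwardSearchRanker,
    JoinedPairsRanker,
    PCARanker,
    cv_macro_f_score,
    make_cv,
)


def _toy_classes(rng, n_per_class=20, informative=2, noise=4, sep=4.0):
    """Linearly separable multi-class toy with planted informative columns."""
    labels = ["A", "B", "C"]
    rows, y, groups = [], [], []
    for c, lbl in enumerate(labels):
        centre = np.zeros(informative + noise)
        centre[:informative] = c * sep
        block = rng.standard_normal((n_per_class, informative + noise)) + centre
        rows.append(block)
        y += [lbl] * n_per_class
        groups += [f"{lbl}{i % 4}" for i in range(n_per_class)]
    X = np.vstack(rows)
    names = [f"inf{j}" for j in range(informative)] + [f"noise{j}" for j in range(noise)]
    return pd.DataFrame(X, columns=names), np.array(y), np.array(groups)


class TestCorrelationRanker:
    def test_planted_feature_first(self, rng):
        y = np.repeat(list("ABCDEF"), 30)
        codes = np.repeat(np.arange(1, 7), 30)
        X = pd.DataFrame(
            {
                "planted": codes + rng.normal(0, 0.1, size=180),
                "noise": rng.standard_normal(180),
                "constant": np.ones(180),
            }
        )
        r = CorrelationRanker().fit(X, y)
        assert r.ordered_features_[0] == "planted"
        assert r.ordered_features_[-1] == "constant"
        assert r.scores_[-1] == 0.0

    def test_matches_pearson_formula(self, rng):
        y = np.array(["A", "A", "B", "B", "C", "C"])
        codes = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        X = pd.DataFrame(rng.standard_normal((6, 3)), columns=["a", "b", "c"])
        r = CorrelationRanker().fit(X, y)
        expected = {}
        for name in X.columns:
            v = X[name].to_numpy()
            num = np.sum((v - v.mean()) * (codes - codes.mean()))
            den = np.sqrt(np.sum((v - v.mean()) ** 2) * np.sum((codes - codes.mean()) ** 2))
            expected[name] = abs(num / den)
        order = sorted(expected, key=lambda n: -expected[n])
        assert r.ordered_features_ == order
        np.testing.assert_allclose(r.scores_, [expected[n] for n in r.ordered_features_])

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            CorrelationRanker().fit(X, ["A", "A", "A"])


class TestForwardSearchRanker:
    def test_informative_features_chosen_first(self, rng):
        X, y, groups = _toy_classes(rng)
        r = ForwardSearchRanker(cv=make_cv("kfold", n_splits=5, seed=0)).fit(X, y)
        assert set(r.ordered_features_[:2]) == {"inf0", "inf1"}

    def test_single_feature(self, rng):
        X = pd.DataFrame({"only": rng.standard_normal(30)})
        y = np.repeat(["A", "B"], 15)
        r = ForwardSearchRanker(cv=make_cv("kfold", n_splits=3, seed=0)).fit(X, y)
        assert r.ordered_features_ == ["only"]

    def test_first_steps_match_exhaustive_search(self, rng):
        X, y, _ = _toy_classes(rng, informative=2, noise=1)
        cv = make_cv("kfold", n_splits=4, seed=1)
        est = DistanceWeightedKNN(k=3)
        r = ForwardSearchRanker(estimator=est, cv=cv, max_features=2).fit(X, y)
        names = list(X.columns)
        # oracle: exhaustive singletons, then pairs containing the best one
        singles = {n: cv_macro_f_score(est, X[[n]].to_numpy(), y, None, cv) for n in names}
        best1 = max(names, key=lambda n: singles[n])
        pairs = {
            n: cv_macro_f_score(est, X[[best1, n]].to_numpy(), y, None, cv)
            for n in names
            if n != best1
        }
        best2 = max(pairs, key=lambda n: pairs[n])
        assert r.ordered_features_[:2] == [best1, best2]

    def test_lopo_with_one_patient_rejected(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "b": rng.standard_normal(20)})
        y = np.repeat(["A", "B"], 10)
        with pytest.raises(SchemeError):
            ForwardSearchRanker(cv=make_cv("lopo")).fit(X, y, groups=np.repeat("p1", 20))


class TestJoinedPairsRanker:
    def test_jointly_informative_pair_beats_weak_single(self, rng):
        # checkerboard: x0, x1 individually uninformative, jointly separating
        n = 120
        x0 = rng.choice([0.0, 1.0], n) + rng.normal(0, 0.05, n)
        x1 = rng.choice([0.0, 1.0], n) + rng.normal(0, 0.05, n)
        y = np.where((np.round(x0) + np.round(x1)) % 2 == 0, "A", "B")
        weak = np.where(y == "A", 0.0, 0.4) + rng.normal(0, 1.0, n)
        X = pd.DataFrame({"x0": x0, "x1": x1, "weak": weak})
        r = JoinedPairsRanker(cv=make_cv("kfold", n_splits=5, seed=0)).fit(X, y)
        assert set(r.ordered_features_[:2]) == {"x0", "x1"}

    def test_two_features_share_pair_score(self, rng):
        X, y, _ = _toy_classes(rng, informative=2, noise=0)
        r = JoinedPairsRanker(cv=make_cv("kfold", n_splits=4, seed=0)).fit(X, y)
        assert len(r.pair_scores_) == 1
        assert r.scores_[0] == r.scores_[1]

    def test_pair_scores_match_enumeration(self, rng):
        X, y, _ = _toy_classes(rng, informative=2, noise=2)
        cv = make_cv("kfold", n_splits=4, seed=2)
        est = DistanceWeightedKNN(k=3)
        r = JoinedPairsRanker(estimator=est, cv=cv).fit(X, y)
        names = list(X.columns)
        for a, b in itertools.combinations(names, 2):
            expected = cv_macro_f_score(est, X[[a, b]].to_numpy(), y, None, cv)
            assert r.pair_scores_[(a, b)] == pytest.approx(expected)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            JoinedPairsRanker().fit(pd.DataFrame({"a": [1.0, 2.0]}), ["A", "B"])


class TestPCARanker:
    def test_variance_order_without_standardization(self, rng):
        X = pd.DataFrame(
            {
                "v3": rng.normal(0, np.sqrt(3), 500),
                "v2": rng.normal(0, np.sqrt(2), 500),
                "v1": rng.normal(0, 1, 500),
            }
        )
        r = PCARanker(standardize=False, variance_coverage=0.95).fit(X)
        assert r.ordered_features_ == ["v3", "v2", "v1"]

    def test_duplicated_feature_symmetric_scores(self, rng):
        base = rng.standard_normal(200)
        X = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.standard_normal(200)})
        r = PCARanker().fit(X)
        scores = dict(zip(r.ordered_features_, r.scores_))
        assert scores["a"] == pytest.approx(scores["b"], abs=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        r = PCARanker(variance_coverage=0.5).fit(X)
        # independent oracle: covariance eigen-decomposition of standardized data
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        cov = np.cov(Z, rowvar=False, ddof=1)
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        evr = lam / lam.sum()
        K = int(np.searchsorted(np.cumsum(evr), 0.5) + 1)
        scores = sum(evr[k] * np.abs(vec[:, k]) for k in range(K))
        expected_order = [f"f{j}" for j in np.argsort(-scores, kind="stable")]
        assert r.ordered_features_ == expected_order
        np.testing.assert_allclose(
            np.sort(r.scores_), np.sort(scores), atol=1e-8
        )


class TestCVSchemes:
    def test_lopo_never_leaks_patients(self, selection_cohort_features):
        from conftest import split_xyg

        X, y, groups = split_xyg(
            selection_cohort_features, selection.default_selected_features()
        )
        lopo = make_cv("lopo")
        for train, test in lopo.split(X, y, groups):
            assert not set(groups[train]) & set(groups[test])
            assert len(set(groups[test])) == 1

    def test_unknown_scheme(self):
        with pytest.raises(SchemeError):
            make_cv("bootstrap")


class TestSubsetCurve:
    def test_reaches_one_on_separable_data_and_matches_full_eval(self, rng):
        X, y, groups = _toy_classes(rng, sep=6.0)
        cv = make_cv("kfold", n_splits=5, seed=0)
        est = DistanceWeightedKNN(k=3)
        ranking = ForwardSearchRanker(estimator=est, cv=cv).fit(X, y)
        curve = selection.subset_curve(ranking, X, y, classifier=est, cv=cv)
        assert list(curve["n_features"]) == list(range(2, len(X.columns) + 1))
        assert curve["f_score"].max() == pytest.approx(1.0)
        full = cv_macro_f_score(est, X.to_numpy(), y, None, cv)
        assert curve["f_score"].iloc[-1] == pytest.approx(full)

    def test_unknown_feature_rejected(self, rng):
        X, y, _ = _toy_classes(rng)
        with pytest.raises(ValueError):
            selection.subset_curve(["bogus", "inf0"], X, y)


class TestDefaultSelection:
    def test_eight_band_set(self):
        names = selection.default_selected_features()
        assert names == ["T_63", "T_80", "T_100", "T_125", "T_315", "T_400", "T_500", "T_630"]
        from phonoavf.features import band_feature_names

        assert set(names) <= set(band_feature_names())


class TestOptimismEffect:
    def test_kfold_exceeds_lopo_with_patient_effects(
        self, default_cohort_features, nosd_cohort_features
    ):
        """Vector-level 10-fold CV learns patient identity; LOPO does not."""
        from conftest import split_xyg
        from phonoavf.classification import evaluate_cv

        names = selection.default_selected_features()
        accs = {}
        for key, tab in (("sd", default_cohort_features), ("nosd", nosd_cohort_features)):
            X, y, g = split_xyg(tab, names)
            for scheme in ("kfold", "lopo"):
                _, q = evaluate_cv(
                    DistanceWeightedKNN(), X, y, g, make_cv(scheme, seed=3)
                )
                accs[(key, scheme)] = q.acc
        assert accs[("sd", "kfold")] > accs[("sd", "lopo")]
        assert abs(accs[("nosd", "kfold")] - accs[("nosd", "lopo")]) < 0.05
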