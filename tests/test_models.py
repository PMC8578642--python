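"""PU classifiers, cross-validation, metrics and their oracles."""

import numpy as np
import pandas as pd
import pytest

from mlpp.labels import park_marcotte_split
from mlpp.metrics import evaluate, partial_auroc, pathway_percentile_comparison
from mlpp.models import (
    AdaSampleClassifier,
    PUBaggingClassifier,
    PURandomForestClassifier,
    VanillaBoostedClassifier,
    cross_validate,
    hidden_positive_experiment,
    make_classifier,
    prediction_matrix,
)

ALL_FRAMEWORKS = [
    PURandomForestClassifier(random_state=0),
    VanillaBoostedClassifier(random_state=0, min_child_samples=5),
    PUBaggingClassifier(random_state=0, min_child_samples=5),
    AdaSampleClassifier(random_state=0, min_child_samples=5),
]


def separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 3))
    y = (X[:, 0] > 0.5).astype(int)
    return X, y


class TestClassifiers:
    @pytest.mark.parametrize("clf", ALL_FRAMEWORKS,
                             ids=lambda c: type(c).__name__)
    def test_separable_toy_reaches_perfect_training_auroc(self, clf):
        X, y = separable()
        p = clf.fit(X, y).predict_proba(X)
        assert p.shape == (len(X), 2)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert evaluate(p[:, 1], y, n_bootstrap=0).auroc == pytest.approx(1.0, abs=0.01)

    def test_label_permutation_gives_chance_auroc(self):
        rng = np.random.default_rng(1)
        aucs = []
        for seed in range(10):
            X, y = separable(n=300, seed=seed)
            y_perm = rng.permutation(y)
            X_test, y_test = separable(n=300, seed=100 + seed)
            y_test = rng.permutation(y_test)
            clf = PURandomForestClassifier(random_state=seed).fit(X, y_perm)
            aucs.append(
                evaluate(clf.predict_proba(X_test)[:, 1], y_test,
                         n_bootstrap=0).auroc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_input_errors(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError):
            PURandomForestClassifier().fit(X, np.ones(10))

    def test_deterministic_under_seed(self):
        X, y = separable()
        p1 = PURandomForestClassifier(random_state=4).fit(X, y).predict_proba(X)
        p2 = PURandomForestClassifier(random_state=4).fit(X, y).predict_proba(X)
        assert (p1 == p2).all()

    def test_make_classifier_dispatch(self):
        assert isinstance(make_classifier("rf"), PURandomForestClassifier)
        assert isinstance(make_classifier("pubag"), PUBaggingClassifier)
        with pytest.raises(ValueError):
            make_classifier("boosted-nonsense")

    def test_planted_signal_recovered(self, small_training):
        feats, y, *_ = small_training
        rng = np.random.default_rng(0)
        test = rng.random(len(y)) < 0.3
        clf = PURandomForestClassifier(random_state=0).fit(
            feats.to_numpy()[~test], y.to_numpy()[~test])
        p = clf.predict_proba(feats.to_numpy()[test])[:, 1]
        assert evaluate(p, y.to_numpy()[test], n_bootstrap=0).auroc >= 0.8


class TestCrossValidate:
    def test_fold_training_and_test_disjoint(self, small_training):
        feats, y, *_ = small_training
        folds = park_marcotte_split(list(feats.index), n_folds=3, seed=0)
        cv = cross_validate(feats, y, folds,
                            PURandomForestClassifier(n_trees=50, random_state=0))
        for fold, rep in zip(folds, cv.fold_reports):
            assert not set(fold.train_pairs) & set(fold.test_pairs)
            assert rep["all"] is not None
        assert 0.5 < cv.median("auroc") <= 1.0
        assert set(cv.predictions.index).issubset(set(feats.index))

    def test_metrics_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        y = (rng.random(500) < 0.4).astype(int)
        perm = rng.permutation(500)
        a = evaluate(scores, y, n_bootstrap=0)
        b = evaluate(scores[perm], y[perm], n_bootstrap=0)
        assert a.auroc == pytest.approx(b.auroc, abs=1e-12)
        assert a.average_precision == pytest.approx(b.average_precision, abs=1e-12)


class TestHiddenPositives:
    def test_seed_reproducible_hiding(self, small_training):
        feats, y, *_ = small_training
        est = PURandomForestClassifier(n_trees=50, random_state=0)
        r1 = hidden_positive_experiment(feats, y, 0.3, est, seed=11)
        r2 = hidden_positive_experiment(feats, y, 0.3, est, seed=11)
        assert list(r1["hidden_pairs"]) == list(r2["hidden_pairs"])

    def test_fraction_bounds(self, small_training):
        feats, y, *_ = small_training
        with pytest.raises(ValueError):
            hidden_positive_experiment(feats, y, 1.5)

    def test_hidden_positives_score_above_negatives(self, small_training):
        feats, y, *_ = small_training
        est = PURandomForestClassifier(random_state=0)
        r = hidden_positive_experiment(feats, y, 0.3, est, seed=0)
        assert np.median(r["probs_hidden_positive"]) > \
            np.median(r["probs_negative"])
        assert r["auroc_hidden_vs_negative"] > 0.6


class TestEvaluate:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        rep = evaluate(s, y, n_bootstrap=0)
        assert rep.auroc == 1.0
        assert rep.partial_auroc == pytest.approx(1.0)
        assert rep.average_precision == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 5000)
        s = rng.random(10_000)
        assert evaluate(s, y, n_bootstrap=0).auroc == pytest.approx(0.5, abs=0.05)

    def test_hand_computed_roc_and_ap(self):
        # printed toy vector; oracle: explicit pair counting / step AP
        y = np.array([1, 0, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        n_pos, n_neg = 3, 3
        wins = sum((si > sj) for si, yi in zip(s, y) if yi
                   for sj, yj in zip(s, y) if not yj)
        assert evaluate(s, y, n_bootstrap=0).auroc == pytest.approx(
            wins / (n_pos * n_neg))
        # AP by step interpolation: precision at each positive hit
        order = np.argsort(-s)
        hits, ap = 0, 0.0
        for rank, idx in enumerate(order, start=1):
            if y[idx]:
                hits += 1
                ap += hits / rank
        ap /= n_pos
        assert evaluate(s, y, n_bootstrap=0).average_precision == \
            pytest.approx(ap)

    def test_partial_auroc_bruteforce(self, rng):
        """Trapezoid oracle over the restricted ROC, random instances."""
        from sklearn.metrics import roc_curve

        for _ in range(10):
            y = (rng.random(60) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            s = rng.random(60)
            fpr, tpr, _ = roc_curve(y, s)
            grid = np.linspace(0, 0.1, 2001)
            tpr_i = np.interp(grid, fpr, tpr)
            expected = np.trapezoid(tpr_i, grid) / 0.1
            assert partial_auroc(y, s) == pytest.approx(expected, abs=1e-3)

    def test_bootstrap_ci_contains_point(self):
        rng = np.random.default_rng(0)
        y = (rng.random(300) < 0.5).astype(int)
        s = y * 0.5 + rng.random(300) * 0.6
        rep = evaluate(s, y, n_bootstrap=200, seed=0)
        lo, hi = rep.ci["auroc"]
        assert lo <= rep.auroc <= hi

    def test_single_class_is_nan(self):
        rep = evaluate([0.1, 0.9], [1, 1], n_bootstrap=0)
        assert np.isnan(rep.auroc)


class TestPathwayPercentiles:
    def pairs_index(self, pairs):
        return pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])

    def test_top_ranked_pathway_reaches_100(self):
        pw = {("a", "b"), ("a", "c")}
        univ = sorted(pw) + [("d", "e"), ("d", "f"), ("e", "f")]
        scores = pd.Series([5.0, 4.0, 1.0, 2.0, 3.0],
                           index=self.pairs_index(univ))
        out = pathway_percentile_comparison({"m": scores}, {"pw": pw})
        assert out.loc["pw", "m"] == pytest.approx(90.0)  # ranks 5,4 of 5

    def test_percentiles_uniform_over_pairs(self, rng):
        univ = [(f"g{i}", f"g{j}") for i in range(10) for j in range(i + 1, 10)]
        scores = pd.Series(rng.random(len(univ)), index=self.pairs_index(univ))
        out = pathway_percentile_comparison(
            {"m": scores}, {"all": set(univ)})
        # median percentile of the full universe is ~50
        assert out.loc["all", "m"] == pytest.approx(50.0, abs=2.0)

    def test_toy_medians_match_hand_enumeration(self):
        univ = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e")]
        m1 = pd.Series([4.0, 3.0, 2.0, 1.0], index=self.pairs_index(univ))
        m2 = pd.Series([1.0, 2.0, 3.0, 4.0], index=self.pairs_index(univ))
        out = pathway_percentile_comparison(
            {"m1": m1, "m2": m2}, {"pw": {("a", "b"), ("d", "e")}})
        # m1: ranks 4 and 1 -> percentiles 100, 25 -> median 62.5
        assert out.loc["pw", "m1"] == pytest.approx(62.5)
        assert out.loc["pw", "m2"] == pytest.approx(62.5)

    def test_empty_pathway_skipped(self):
        univ = [("a", "b")]
        scores = pd.Series([1.0], index=self.pairs_index(univ))
        out = pathway_percentile_comparison({"m": scores}, {"pw": {("x", "y")}})
        assert out.empty


class TestPredictionMatrix:
    def test_symmetric_with_zero_diagonal(self):
        probs = pd.Series(
            [0.9, 0.2],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("b", "c")]))
        m = prediction_matrix(probs)
        assert m.loc["a", "b"] == m.loc["b", "a"] == 0.9
        assert m.loc["b", "c"] == 0.2
        assert (np.diag(m.to_numpy()) == 0).all()
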