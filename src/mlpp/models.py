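"""Positive-unlabeled ensemble classifiers over clade-covariance features.

Functional-interaction labels only record confirmed positives; every
other pair is unlabeled (a mixture of hidden positives and true
negatives).  Four PU frameworks are provided as sklearn-style
estimators (fit / predict_proba / get_params):

* ``rf`` (default) — a random-forest-mode ensemble: 200 trees, row
  subsampling 0.5, feature subsampling 0.5, 128 max leaves.  Backed by
  sklearn's RandomForestClassifier so each tree's leaf stores class
  fractions and the ensemble probability is the exact per-tree
  average — the property the additive per-clade attribution relies on.
* ``vanilla`` — a plain 200-tree gradient-boosted classifier (LightGBM)
  treating unlabeled as negative.
* ``pubag`` — PU bagging: positives constant, unlabeled bootstrapped
  per bag; 10-tree boosted base learners.
* ``adasample`` — adaptive sampling: instances drawn per iteration with
  probability proportional to the previous iteration's class
  probability; 2 iterations, subsample 0.3, ensemble of 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .labels import Fold, canonical_pair
from .metrics import MetricReport, evaluate

__all__ = [
    "PURandomForestClassifier",
    "VanillaBoostedClassifier",
    "PUBaggingClassifier",
    "AdaSampleClassifier",
    "make_classifier",
    "cross_validate",
    "CVResult",
    "hidden_positive_experiment",
    "prediction_matrix",
]


def _validate_pu(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            "PU training needs both a positive (1) and an unlabeled/negative "
            f"(0) class; got classes {classes.tolist()}"
        )
    return X, y


class PURandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest-mode PU classifier (the default framework).

    Unlabeled pairs are treated as negatives; robustness to label noise
    comes from the heavy row/feature subsampling.  The fitted forest is
    exposed as ``forest_`` with per-tree structure, enabling exact
    additive (TreeSHAP) per-clade attribution on the probability scale.
    """

    def __init__(
        self,
        n_trees: int = 200,
        subsample_rows: float = 0.5,
        subsample_features: float = 0.5,
        max_leaves: int = 128,
        random_state: int | None = 0,
    ):
        self.n_trees = n_trees
        self.subsample_rows = subsample_rows
        self.subsample_features = subsample_features
        self.max_leaves = max_leaves
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_pu(X, y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.subsample_features,
            max_leaf_nodes=self.max_leaves,
            bootstrap=True,
            max_samples=self.subsample_rows,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _lgbm(n_trees: int, random_state, **kw):
    import lightgbm as lgb

    return lgb.LGBMClassifier(
        n_estimators=n_trees,
        random_state=random_state,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
        **kw,
    )


class VanillaBoostedClassifier(BaseEstimator, ClassifierMixin):
    """Plain gradient-boosted trees with unlabeled treated as negative."""

    def __init__(self, n_trees: int = 200, min_child_samples: int = 20,
                 random_state: int | None = 0):
        self.n_trees = n_trees
        self.min_child_samples = min_child_samples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_pu(X, y)
        self.model_ = _lgbm(
            self.n_trees, self.random_state,
            min_child_samples=self.min_child_samples,
        ).fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class PUBaggingClassifier(BaseEstimator, ClassifierMixin):
    """PU bagging: positives constant, unlabeled resampled per bag.

    Each bag trains a small boosted learner (10 trees by default, row
    and feature subsampling 0.5) on all positives plus a bootstrap of
    the unlabeled pool the same size as the positive set; the ensemble
    probability is the bag average.
    """

    def __init__(
        self,
        n_bags: int = 20,
        base_trees: int = 10,
        subsample_rows: float = 0.5,
        subsample_features: float = 0.5,
        min_child_samples: int = 20,
        random_state: int | None = 0,
    ):
        self.n_bags = n_bags
        self.base_trees = base_trees
        self.subsample_rows = subsample_rows
        self.subsample_features = subsample_features
        self.min_child_samples = min_child_samples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_pu(X, y)
        rng = np.random.default_rng(self.random_state)
        pos = np.flatnonzero(y == 1)
        unl = np.flatnonzero(y == 0)
        self.models_ = []
        for b in range(self.n_bags):
            bag_unl = rng.choice(unl, size=len(pos), replace=True)
            idx = np.concatenate([pos, bag_unl])
            m = _lgbm(
                self.base_trees,
                int(rng.integers(0, 2**31 - 1)),
                subsample=self.subsample_rows,
                subsample_freq=1,
                colsample_bytree=self.subsample_features,
                min_child_samples=self.min_child_samples,
            ).fit(X[idx], y[idx])
            self.models_.append(m)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        p1 = np.mean([m.predict_proba(X)[:, 1] for m in self.models_], axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class AdaSampleClassifier(BaseEstimator, ClassifierMixin):
    """Adaptive-sampling PU ensemble.

    Training instances for each member of the ensemble are drawn with
    probability proportional to the previous iteration's predicted
    probability of belonging to their own class (positives by P(1|x),
    unlabeled by P(0|x), renormalized within class).  Runs for
    ``n_iterations`` rounds (2 by default) with subsample fraction 0.3
    and a final ensemble of 20 ten-tree boosted learners.
    """

    def __init__(
        self,
        n_iterations: int = 2,
        n_ensemble: int = 20,
        base_trees: int = 10,
        subsample: float = 0.3,
        min_child_samples: int = 20,
        random_state: int | None = 0,
    ):
        self.n_iterations = n_iterations
        self.n_ensemble = n_ensemble
        self.base_trees = base_trees
        self.subsample = subsample
        self.min_child_samples = min_child_samples
        self.random_state = random_state

    def _sample(self, rng, idx, weights, size):
        w = np.asarray(weights, dtype=float)
        w = np.clip(w, 1e-9, None)
        w = w / w.sum()
        return rng.choice(idx, size=size, replace=False, p=w, shuffle=False)

    def fit(self, X, y):
        X, y = _validate_pu(X, y)
        rng = np.random.default_rng(self.random_state)
        pos = np.flatnonzero(y == 1)
        unl = np.flatnonzero(y == 0)
        n_pos = max(2, int(round(self.subsample * len(pos))))
        n_unl = max(2, int(round(self.subsample * len(unl))))
        w_pos = np.ones(len(pos))
        w_unl = np.ones(len(unl))
        models = []
        for _ in range(self.n_iterations):
            models = []
            for _ in range(self.n_ensemble):
                ip = self._sample(rng, pos, w_pos, n_pos)
                iu = self._sample(rng, unl, w_unl, n_unl)
                idx = np.concatenate([ip, iu])
                m = _lgbm(
                    self.base_trees,
                    int(rng.integers(0, 2**31 - 1)),
                    min_child_samples=self.min_child_samples,
                ).fit(X[idx], y[idx])
                models.append(m)
            p1 = np.mean([m.predict_proba(X)[:, 1] for m in models], axis=0)
            w_pos = p1[pos]
            w_unl = 1.0 - p1[unl]
        self.models_ = models
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        p1 = np.mean([m.predict_proba(X)[:, 1] for m in self.models_], axis=0)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


FRAMEWORKS = {
    "rf": PURandomForestClassifier,
    "vanilla": VanillaBoostedClassifier,
    "pubag": PUBaggingClassifier,
    "adasample": AdaSampleClassifier,
}


def make_classifier(framework: str = "rf", random_state: int | None = 0, **kw):
    """Instantiate a PU framework by name."""
    try:
        cls = FRAMEWORKS[framework]
    except KeyError:
        raise ValueError(
            f"unknown framework {framework!r}; expected one of {sorted(FRAMEWORKS)}"
        ) from None
    return cls(random_state=random_state, **kw)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Per-fold metrics (overall / per stratum / paralog-excluded) and
    fold-level test predictions."""

    fold_reports: list[dict[str, MetricReport | None]]
    predictions: pd.Series            # pair -> fold-averaged probability
    per_fold_predictions: list[pd.Series] = field(default_factory=list)
    models: list = field(default_factory=list)

    def median(self, metric: str = "auroc", group: str = "all") -> float:
        vals = [
            getattr(r[group], metric)
            for r in self.fold_reports
            if r.get(group) is not None and np.isfinite(getattr(r[group], metric))
        ]
        return float(np.median(vals)) if vals else float("nan")


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: list[Fold],
    estimator=None,
    paralog_flags: pd.Series | None = None,
    n_bootstrap: int = 0,
    keep_models: bool = False,
    seed: int = 0,
) -> CVResult:
    """Train per fold on training pairs only; report metrics by stratum.

    ``features`` is indexed by (gene_a, gene_b); ``labels`` is 1 for
    positive pairs and 0 for unlabeled negatives, aligned with it.
    Empty strata report None.  Test predictions are averaged over the
    folds in which a pair was held out.
    """
    if estimator is None:
        estimator = PURandomForestClassifier(random_state=seed)
    labels = labels.loc[features.index]
    reports: list[dict[str, MetricReport | None]] = []
    per_fold_preds: list[pd.Series] = []
    models = []
    for fold in folds:
        train_idx = features.index.isin(fold.train_pairs)
        test_idx = features.index.isin(fold.test_pairs)
        model = clone(estimator).fit(
            features.to_numpy()[train_idx], labels.to_numpy()[train_idx]
        )
        test_feats = features[test_idx]
        probs = pd.Series(
            model.predict_proba(test_feats.to_numpy())[:, 1], index=test_feats.index
        )
        per_fold_preds.append(probs)
        y_test = labels[test_idx]
        rep: dict[str, MetricReport | None] = {
            "all": _safe_evaluate(probs, y_test, n_bootstrap, seed)
        }
        strata = pd.Series(
            [fold.strata.get(p, "") for p in test_feats.index], index=test_feats.index
        )
        for stratum in ("C1", "C2", "C3"):
            mask = strata == stratum
            rep[stratum] = _safe_evaluate(
                probs[mask], y_test[mask], n_bootstrap, seed
            )
        if paralog_flags is not None:
            keep = ~paralog_flags.reindex(test_feats.index).fillna(0).astype(bool)
            rep["no_paralogs"] = _safe_evaluate(
                probs[keep], y_test[keep], n_bootstrap, seed
            )
        reports.append(rep)
        if keep_models:
            models.append(model)
    averaged = pd.concat(per_fold_preds).groupby(level=[0, 1]).mean()
    return CVResult(reports, averaged, per_fold_preds, models)


def _safe_evaluate(scores: pd.Series, y: pd.Series, n_bootstrap: int,
                   seed: int) -> MetricReport | None:
    y = np.asarray(y).astype(int)
    if len(y) == 0 or len(np.unique(y)) < 2:
        return None
    return evaluate(np.asarray(scores, dtype=float), y,
                    n_bootstrap=n_bootstrap, seed=seed)


# ---------------------------------------------------------------------------
# Hidden-positive experiment


def hidden_positive_experiment(
    features: pd.DataFrame,
    labels: pd.Series,
    hidden_fraction: float,
    estimator=None,
    seed: int = 0,
) -> dict:
    """Hide a fraction of positives as unlabeled and measure recovery.

    The stated fraction of positive pairs is relabeled as unlabeled
    before training; the report gives the auROC of hidden positives vs
    true negatives plus the three predicted-probability distributions
    (kept positives, hidden positives, negatives).
    """
    if not 0 < hidden_fraction < 1:
        raise ValueError("hidden_fraction must be in (0, 1)")
    if estimator is None:
        estimator = PURandomForestClassifier(random_state=seed)
    labels = labels.loc[features.index].astype(int)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels.to_numpy() == 1)
    n_hidden = max(1, int(round(hidden_fraction * len(pos_idx))))
    hidden = rng.choice(pos_idx, size=n_hidden, replace=False)
    y_train = labels.to_numpy().copy()
    y_train[hidden] = 0

    model = clone(estimator).fit(features.to_numpy(), y_train)
    p1 = model.predict_proba(features.to_numpy())[:, 1]
    is_hidden = np.zeros(len(labels), dtype=bool)
    is_hidden[hidden] = True
    is_neg = labels.to_numpy() == 0
    mask = is_hidden | is_neg
    rep = evaluate(p1[mask], is_hidden[mask].astype(int), n_bootstrap=0)
    return {
        "hidden_fraction": hidden_fraction,
        "auroc_hidden_vs_negative": rep.auroc,
        "probs_kept_positive": p1[(labels.to_numpy() == 1) & ~is_hidden],
        "probs_hidden_positive": p1[is_hidden],
        "probs_negative": p1[is_neg],
        "hidden_pairs": features.index[is_hidden],
        "model": model,
    }


# ---------------------------------------------------------------------------
# Prediction matrix


def prediction_matrix(probs: pd.Series, genes=None) -> pd.DataFrame:
    """Symmetric gene x gene probability matrix from pair predictions.

    ``probs`` is indexed by (gene_a, gene_b).  The diagonal is 0 and
    pairs without a prediction stay 0.
    """
    pairs = [canonical_pair(a, b) for a, b in probs.index]
    if genes is None:
        genes = sorted({g for p in pairs for g in p})
    idx = pd.Index(genes)
    mat = np.zeros((len(idx), len(idx)))
    ia = idx.get_indexer([p[0] for p in pairs])
    ib = idx.get_indexer([p[1] for p in pairs])
    ok = (ia >= 0) & (ib >= 0)
    mat[ia[ok], ib[ok]] = probs.to_numpy()[ok]
    mat[ib[ok], ia[ok]] = probs.to_numpy()[ok]
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=idx, columns=idx)
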