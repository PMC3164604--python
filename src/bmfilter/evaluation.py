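"""Cross-validated evaluation of feature-selection methods.

Two protocols are provided.  In the *selection-inside-CV* protocol
(:func:`cv_selection_eval`) the data are split into stratified folds; on
each iteration the nine training folds are used both to rank the features
and to train the classifier, and the reserved fold supplies the AUC — so
the held-out samples never influence feature selection.  In the
*train/validation split* protocol (:func:`split_eval`) features are ranked
once on a training set and the AUC grid comes from cross-validation
entirely within the validation set using that fixed ranking.

AUC is the Mann–Whitney probability that a random experiment sample
receives a higher classifier score than a random control sample, ties
counted one half.  Fold AUCs are averaged, not pooled.

A deliberately leaky mode (selection on all samples before the CV) exists
only as a negative control for verifying that the honest protocol does not
inflate AUC on null data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .bmi import BmiConfig, bmi_scores
from .comparators import (
    chi_squared,
    discretize,
    info_gain,
    moderated_t,
    relief_f,
    welch_t,
    window_t,
)
from .data_model import DataError, ExpressionDataset, ScoreTable

SelectionFn = Callable[[ExpressionDataset], ScoreTable]


def _bmi_select(data: ExpressionDataset) -> ScoreTable:
    return bmi_scores(data, BmiConfig())[1]


def _modt_select(data: ExpressionDataset) -> ScoreTable:
    return moderated_t(data)[0]


#: method id -> selection callable with package defaults
SELECTION_METHODS: dict[str, SelectionFn] = {
    "bmi": _bmi_select,
    "ig": lambda d: info_gain(d, discretize(d, "mdl")),
    "chi2": lambda d: chi_squared(d, discretize(d, "mdl")),
    "relieff": lambda d: relief_f(d),
    "ttest": welch_t,
    "modt": _modt_select,
    "windowt": lambda d: window_t(d),
}


def resolve_method(method: str | SelectionFn) -> SelectionFn:
    if callable(method):
        return method
    try:
        return SELECTION_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown selection method {method!r}; known: {sorted(SELECTION_METHODS)}"
        ) from None


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_experiment > score_control) + P(tie)/2.

    ``labels`` may be control/experiment strings or a 0/1 indicator
    (experiment = 1).  Both groups must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        pos = labels == "experiment"
    else:
        pos = labels.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: a group is absent from the test samples")
    r = rankdata(scores, method="average")
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

class ClassifierAdapter(Protocol):
    """fit on training data, then emit a continuous experiment-likeness score."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter": ...
    def score_samples(self, X: np.ndarray) -> np.ndarray: ...


class GaussianNB:
    """Native Gaussian naive Bayes; score = posterior probability of experiment.

    Matrices are samples × features.  Per-feature variances are floored at a
    small fraction of the largest feature variance so constant features do
    not produce degenerate densities.
    """

    def __init__(self, var_smoothing: float = 1e-9) -> None:
        self.var_smoothing = var_smoothing

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.array([0, 1])
        eps = self.var_smoothing * max(float(X.var(axis=0).max()), 1e-30)
        self.theta_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        self.var_ = np.stack([X[y == c].var(axis=0) + eps for c in (0, 1)])
        self.log_prior_ = np.log(np.array([(y == c).mean() for c in (0, 1)]))
        return self

    def _joint_log_lik(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], 2))
        for c in (0, 1):
            jll[:, c] = self.log_prior_[c] - 0.5 * np.sum(
                np.log(2.0 * np.pi * self.var_[c])
                + (X - self.theta_[c]) ** 2 / self.var_[c],
                axis=1,
            )
        return jll

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_lik(X)
        m = jll.max(axis=1, keepdims=True)
        p = np.exp(jll - m)
        return p[:, 1] / p.sum(axis=1)


class KNearestNeighbors:
    """Native k-NN; score = inverse-distance-weighted experiment fraction.

    Euclidean distances; with k=1 the score is the nearest neighbor's label
    (distance ties resolved to the lowest training index).
    """

    def __init__(self, k: int = 1) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNearestNeighbors":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=int)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = np.sqrt(((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        k = min(self.k, self.X_.shape[0])
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            nn = np.argsort(d[i], kind="stable")[:k]  # stable => lowest index on ties
            w = 1.0 / (d[i, nn] + 1e-12)
            out[i] = float((w * self.y_[nn]).sum() / w.sum())
        return out


class SklearnAdapter:
    """Wrap any sklearn classifier exposing predict_proba or decision_function."""

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnAdapter":
        self.estimator.fit(X, y)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, list(est.classes_).index(1)]
        return np.asarray(est.decision_function(X), dtype=float)


def get_classifier(name: str, seed: int = 0) -> ClassifierAdapter:
    """Resolve a classifier id: ``nb``, ``knn``, ``knn:<k>`` or ``sklearn:<name>``."""
    if name == "nb":
        return GaussianNB()
    if name == "knn":
        return KNearestNeighbors(k=1)
    if name.startswith("knn:"):
        return KNearestNeighbors(k=int(name.split(":", 1)[1]))
    if name.startswith("sklearn:"):
        kind = name.split(":", 1)[1]
        if kind == "svm":
            from sklearn.svm import SVC

            return SklearnAdapter(SVC(kernel="linear", random_state=seed))
        if kind == "rf":
            from sklearn.ensemble import RandomForestClassifier

            return SklearnAdapter(RandomForestClassifier(random_state=seed))
        if kind == "mlp":
            from sklearn.neural_network import MLPClassifier

            return SklearnAdapter(MLPClassifier(random_state=seed, max_iter=500))
        raise ValueError(f"unknown sklearn classifier: {kind}")
    raise ValueError(f"unknown classifier: {name}")


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Per-sample fold indices (stratified by group when requested)."""

    n_folds: int
    fold_of: np.ndarray
    stratified: bool
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold


def make_folds(
    data: ExpressionDataset, n_folds: int = 10, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    y = data.y
    fold_of = np.empty(data.n_samples, dtype=int)
    cls = (
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    )
    # split a sample-ID-sorted view so fold membership is a function of the
    # sample IDs, not of storage order
    order = np.argsort(np.asarray(data.sample_ids, dtype=object), kind="stable")
    for f, (_, test_idx) in enumerate(cls.split(np.zeros_like(y), y[order])):
        fold_of[order[test_idx]] = f
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of, stratified=stratified, seed=seed)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """AUC as a function of the number of selected features, per fold."""

    method: str
    classifier: str
    feature_counts: np.ndarray
    auc_grid: np.ndarray  # folds × feature counts; NaN = skipped fold
    mean_auc: np.ndarray
    best_auc: float
    best_n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(self.auc_grid.shape[0]):
            for j, n in enumerate(self.feature_counts):
                rows.append(
                    {
                        "method": self.method,
                        "classifier": self.classifier,
                        "fold": f,
                        "n_features": int(n),
                        "auc": self.auc_grid[f, j],
                    }
                )
        return pd.DataFrame(rows)


def _summarize(method_id, classifier_id, counts, grid) -> CvResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_auc = np.nanmean(grid, axis=0)
    j = int(np.nanargmax(mean_auc))
    return CvResult(
        method=method_id,
        classifier=classifier_id,
        feature_counts=counts,
        auc_grid=grid,
        mean_auc=mean_auc,
        best_auc=float(mean_auc[j]),
        best_n=int(counts[j]),
    )


def _grid_for_ranking(
    train: ExpressionDataset,
    test: ExpressionDataset,
    ranked: list[str],
    classifier: ClassifierAdapter,
    counts: np.ndarray,
) -> np.ndarray:
    """AUC per feature count for one train/test split and a fixed ranking."""
    out = np.full(len(counts), np.nan)
    y_test = test.y
    if y_test.min() == y_test.max():
        warnings.warn("single-class test fold skipped")
        return out
    y_train = train.y
    for j, n in enumerate(counts):
        feats = ranked[: int(n)]
        Xtr = train.subset_features(feats).values.T
        Xte = test.subset_features(feats).values.T
        clf = classifier.fit(Xtr, y_train)
        out[j] = auc(clf.score_samples(Xte), y_test)
    return out


def _counts(n_max: int, n_features: int) -> np.ndarray:
    if n_max > n_features:
        warnings.warn(f"n_max={n_max} exceeds feature count; capped at {n_features}")
        n_max = n_features
    return np.arange(1, n_max + 1)


def cv_selection_eval(
    data: ExpressionDataset,
    method: str | SelectionFn,
    classifier: str | ClassifierAdapter = "nb",
    n_folds: int = 10,
    n_max: int = 60,
    seed: int = 0,
    leaky: bool = False,
) -> CvResult:
    """Selection-inside-CV: rank features on the training folds only.

    For each fold, the selection method runs on the other ``n_folds - 1``
    folds, the classifier is trained there on the top-n features for
    n = 1..n_max, and the reserved fold provides the AUC; the grid is then
    averaged over reserved folds.  ``leaky=True`` ranks once on all samples
    first — a negative control that demonstrates selection bias, never an
    evaluation mode.
    """
    select = resolve_method(method)
    clf_id = classifier if isinstance(classifier, str) else type(classifier).__name__
    clf = get_classifier(classifier, seed) if isinstance(classifier, str) else classifier
    folds = make_folds(data, n_folds=n_folds, seed=seed)
    counts = _counts(n_max, data.n_features)
    grid = np.full((n_folds, len(counts)), np.nan)
    leaky_ranking = select(data).top(data.n_features) if leaky else None
    for f in range(n_folds):
        test_mask = folds.test_mask(f)
        train = data.subset_samples(~test_mask)
        test = data.subset_samples(test_mask)
        ranked = leaky_ranking if leaky else select(train).top(data.n_features)
        grid[f] = _grid_for_ranking(train, test, ranked, clf, counts)
    method_id = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    return _summarize(method_id, clf_id, counts, grid)


def split_eval(
    train: ExpressionDataset,
    valid: ExpressionDataset,
    method: str | SelectionFn,
    classifier: str | ClassifierAdapter = "nb",
    n_folds: int = 10,
    n_max: int = 60,
    seed: int = 0,
) -> CvResult:
    """Train/validation protocol: select once on train, cross-validate in valid.

    The ranking is computed once from the training set; the AUC grid comes
    from ``n_folds``-fold CV entirely within the validation set using that
    fixed ranked list.
    """
    if train.feature_ids != valid.feature_ids:
        raise DataError("train and validation sets must share the same feature list")
    select = resolve_method(method)
    clf_id = classifier if isinstance(classifier, str) else type(classifier).__name__
    clf = get_classifier(classifier, seed) if isinstance(classifier, str) else classifier
    ranked = select(train).top(train.n_features)
    folds = make_folds(valid, n_folds=n_folds, seed=seed)
    counts = _counts(n_max, valid.n_features)
    grid = np.full((n_folds, len(counts)), np.nan)
    for f in range(n_folds):
        test_mask = folds.test_mask(f)
        grid[f] = _grid_for_ranking(
            valid.subset_samples(~test_mask), valid.subset_samples(test_mask),
            ranked, clf, counts,
        )
    method_id = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    return _summarize(method_id, clf_id, counts, grid)


def median_ranks(
    data: ExpressionDataset,
    methods: list[str],
    query: list[str],
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Median over folds of each query feature's rank, per selection method.

    Mirrors the rank-stability readout for externally validated genes: each
    fold's ranking uses only the training portion, and the median of the
    fold-wise ranks is reported (method rows × query-feature columns).
    """
    unknown = [q for q in query if q not in data.feature_ids]
    if unknown:
        raise KeyError(f"unknown query feature(s): {', '.join(unknown[:5])}")
    folds = make_folds(data, n_folds=n_folds, seed=seed)
    out = {}
    for method in methods:
        select = resolve_method(method)
        per_fold = np.empty((n_folds, len(query)))
        for f in range(n_folds):
            table = select(data.subset_samples(~folds.test_mask(f)))
            per_fold[f] = [table.rank_of(q) for q in query]
        out[method] = np.median(per_fold, axis=0)
    return pd.DataFrame(out, index=query).T


def confusion_metrics(
    predictions: np.ndarray, truth: np.ndarray
) -> tuple[float, float, float]:
    """(specificity, sensitivity, accuracy) of binary predictions.

    Sensitivity is the recall of the experiment class, specificity the
    recall of the control class.  Labels may be strings or 0/1.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)

    def as01(a: np.ndarray) -> np.ndarray:
        return (a == "experiment").astype(int) if a.dtype.kind in "OUS" else a.astype(int)

    p, t = as01(predictions), as01(truth)
    if (t == 1).sum() == 0 or (t == 0).sum() == 0:
        raise DataError("confusion metrics need both classes in the truth")
    sensitivity = float((p[t == 1] == 1).mean())
    specificity = float((p[t == 0] == 0).mean())
    accuracy = float((p == t).mean())
    return specificity, sensitivity, accuracy
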