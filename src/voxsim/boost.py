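"""AdaBoost with binned indicating-vector weak learners.

The weak classifier for feature *i* cuts the feature's training range into
M uniform bins and attaches a +/-1 label to each bin (the *indicating
vector* L): the label of a bin is the sign of the summed sample weights
(weight x class) of the training samples falling in it.  Prediction reads
the label of the bin the feature value falls into, clamping out-of-range
values to the end bins.  The classical decision stump is the M = 2 special
case.

The boosting loop is standard discrete AdaBoost: at round t the feature
whose fitted weak classifier has the smallest weighted error eps_t is
selected (ties to the lowest feature index), weighted by
``alpha_t = 0.5 ln((1 - eps_t)/eps_t)``, and the sample distribution is
re-weighted by ``D_{t+1}(i) = D_t(i) exp(-alpha_t y_i h_t(x_i)) / Z_t``.
Training stops after the configured number of rounds, when no weak
classifier beats chance (eps >= 0.5), or after a zero-error round.

The ensemble score ``f(x) = sum_t alpha_t h_t(x)`` classifies through its
sign and regresses through the logistic transform
``P(y=+1|x) = e^f / (e^f + e^-f)``.  Summing alpha_t over the rounds in
which a feature was selected gives its cumulated weight, the feature-
importance measure that maps model structure back onto brain voxels.

Because bin edges are fixed by the training min/max of each feature (they
do not depend on the sample weights), bin assignments are computed once
and every round costs O(samples x features).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

_EPS_FLOOR = 1e-10


@dataclass(frozen=True)
class BinnedWeakClassifier:
    """A single-feature histogram classifier with a +/-1 label per bin."""

    feature_index: int
    lo: float
    hi: float
    n_bins: int
    labels: np.ndarray  # +/-1 per bin

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.size != self.n_bins or not np.all(np.abs(labels) == 1):
            raise ValueError("indicating vector must hold one +/-1 label per bin")
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")
        object.__setattr__(self, "labels", labels)

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        """Uniform-bin index of each value, clamped to the end bins."""
        values = np.asarray(values, dtype=float)
        if self.hi == self.lo:
            return np.zeros(values.shape, dtype=int)
        raw = np.floor((values - self.lo) * self.n_bins / (self.hi - self.lo))
        return np.clip(raw, 0, self.n_bins - 1).astype(int)

    def predict_values(self, values: np.ndarray) -> np.ndarray:
        """Predict +/-1 from raw feature-i values."""
        return self.labels[self.bin_index(values)].astype(int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict +/-1 from full feature matrices/vectors."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return self.predict_values(X[self.feature_index : self.feature_index + 1])[0]
        return self.predict_values(X[:, self.feature_index])


def _fill_undecided(labels: np.ndarray, decided: np.ndarray, majority: int) -> np.ndarray:
    """Resolve empty/tied bins: copy the nearest decided bin's label.

    Distance ties go to the lower bin index; if no bin is decided, every
    bin takes the global weighted-majority label.
    """
    idx = np.flatnonzero(decided)
    if idx.size == 0:
        return np.full(labels.size, majority, dtype=np.int8)
    out = labels.copy()
    undecided = np.flatnonzero(~decided)
    if undecided.size:
        pos = np.searchsorted(idx, undecided)
        left = idx[np.clip(pos - 1, 0, idx.size - 1)]
        right = idx[np.clip(pos, 0, idx.size - 1)]
        use_left = (pos == idx.size) | (
            (pos > 0) & (undecided - left <= right - undecided)  # tie -> lower index
        )
        out[undecided] = labels[np.where(use_left, left, right)]
    return out


def fit_weak(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray, n_bins: int
) -> tuple[BinnedWeakClassifier, float]:
    """Fit one binned weak classifier on a single feature.

    Bin edges span the training min/max of ``x`` in ``n_bins`` uniform
    intervals; each bin's label is the sign of the summed weighted labels
    of the samples inside it (weighted voting).  Returns the classifier
    and its weighted training error.  A constant feature degenerates to a
    single bin predicting the weighted majority label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    weights = np.asarray(weights, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not np.all(np.abs(y) == 1):
        raise ValueError("labels must be +/-1")
    lo, hi = float(np.min(x)), float(np.max(x))
    majority = 1 if float(np.sum(weights * y)) >= 0 else -1
    if lo == hi:
        clf = BinnedWeakClassifier(0, lo, hi, 1, np.array([majority]))
    else:
        stub = BinnedWeakClassifier(0, lo, hi, n_bins, np.ones(n_bins, dtype=np.int8))
        bins = stub.bin_index(x)
        score = np.bincount(bins, weights=weights * y, minlength=n_bins)
        labels = np.where(score >= 0, 1, -1).astype(np.int8)
        labels = _fill_undecided(labels, score != 0, majority)
        clf = BinnedWeakClassifier(0, lo, hi, n_bins, labels)
    err = float(np.sum(weights[clf.predict_values(x) != y]))
    return clf, err


def predict_weak(h: BinnedWeakClassifier, V: np.ndarray) -> int:
    """Apply a weak classifier to one full feature vector."""
    V = np.asarray(V, dtype=float)
    return int(h.labels[h.bin_index(np.array([V[h.feature_index]]))[0]])


class BinnedAdaBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost over binned single-feature weak classifiers.

    Parameters
    ----------
    n_bins : int, default 20
        Number of uniform bins M per weak classifier.
    n_rounds : int, default 1000
        Maximum boosting rounds T.

    Attributes
    ----------
    estimators_ : list of BinnedWeakClassifier
    estimator_weights_ : ndarray, the round weights alpha_t
    estimator_errors_ : ndarray, the weighted errors eps_t
    normalizers_ : ndarray, the distribution normalizers Z_t
    cumulated_weights_ : ndarray (n_features,), sum of alpha_t per feature
    feature_importances_ : cumulated weights normalized to sum 1

    Training is deterministic given the input arrays: feature ties break to
    the lowest index and the sample order is taken as given.
    """

    def __init__(self, n_bins: int = 20, n_rounds: int = 1000):
        self.n_bins = n_bins
        self.n_rounds = n_rounds

    def fit(self, X, y) -> "BinnedAdaBoostClassifier":
        X, y = check_X_y(X, y)
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"expected exactly 2 classes, got {self.classes_.size}")
        y_pm = np.where(y == self.classes_[1], 1, -1)
        m, p = X.shape
        self.n_features_in_ = p

        lo = X.min(axis=0)
        hi = X.max(axis=0)
        span = hi - lo
        constant = span == 0
        M = self.n_bins
        # bin assignment is weight-independent: compute once
        with np.errstate(divide="ignore", invalid="ignore"):
            B = np.floor((X - lo) * M / np.where(constant, 1.0, span))
        B = np.clip(B, 0, M - 1).astype(np.int64)
        B[:, constant] = 0
        flat = (B + np.arange(p, dtype=np.int64) * M).ravel()
        pm_pos = (y_pm == 1).astype(float)
        pm_neg = 1.0 - pm_pos

        D = np.full(m, 1.0 / m)
        self.estimators_: list[BinnedWeakClassifier] = []
        alphas: list[float] = []
        errors: list[float] = []
        normalizers: list[float] = []
        self.cumulated_weights_ = np.zeros(p)

        for _ in range(self.n_rounds):
            w_pos = np.bincount(flat, weights=np.repeat(D * pm_pos, p), minlength=p * M)
            w_neg = np.bincount(flat, weights=np.repeat(D * pm_neg, p), minlength=p * M)
            score = (w_pos - w_neg).reshape(p, M)
            labels = np.where(score >= 0, 1, -1).astype(np.int8)
            majority = 1 if float(np.sum(D * y_pm)) >= 0 else -1
            decided = score != 0
            for j in np.flatnonzero(~decided.all(axis=1)):
                labels[j] = _fill_undecided(labels[j], decided[j], majority)
            # eps_j = sum over bins of the weight mass on the losing side
            eps_all = np.where(labels == 1, w_neg.reshape(p, M), w_pos.reshape(p, M)).sum(axis=1)
            eps_all[constant] = np.inf  # constant features carry no split
            j_best = int(np.argmin(eps_all))  # argmin takes the lowest index on ties
            eps = float(eps_all[j_best])
            if eps >= 0.5 or not np.isfinite(eps):
                if not self.estimators_:
                    warnings.warn("no weak classifier beats chance; empty ensemble")
                break
            alpha = 0.5 * np.log((1.0 - eps) / max(eps, _EPS_FLOOR))
            h = BinnedWeakClassifier(j_best, float(lo[j_best]), float(hi[j_best]), M, labels[j_best])
            self.estimators_.append(h)
            alphas.append(float(alpha))
            errors.append(eps)
            self.cumulated_weights_[j_best] += alpha
            if eps == 0.0:
                normalizers.append(float(np.sum(D)))  # no reweighting after a perfect round
                break
            pred = labels[j_best][B[:, j_best]]
            D = D * np.exp(-alpha * y_pm * pred)
            Z = float(D.sum())
            normalizers.append(Z)
            D /= Z

        self.estimator_weights_ = np.asarray(alphas)
        self.estimator_errors_ = np.asarray(errors)
        self.normalizers_ = np.asarray(normalizers)
        total = self.cumulated_weights_.sum()
        self.feature_importances_ = (
            self.cumulated_weights_ / total if total > 0 else np.zeros(p)
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        """Ensemble score f(x) = sum_t alpha_t h_t(x)."""
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        f = np.zeros(X.shape[0])
        for h, alpha in zip(self.estimators_, self.estimator_weights_):
            f += alpha * h.predict(X)
        return f

    def predict(self, X) -> np.ndarray:
        """Sign of the score; a zero score falls to the first class."""
        f = self.decision_function(X)
        return np.where(f > 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X) -> np.ndarray:
        """P(y = +1 | x) = e^f / (e^f + e^-f), computed overflow-free."""
        p1 = expit(2.0 * self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])


class BinnedAdaBoostRegressor(BaseEstimator, RegressorMixin):
    """Boosted-logistic regression of labels in [0, 1].

    Labels are binarized at ``binarize_threshold`` (the label median when
    None), a :class:`BinnedAdaBoostClassifier` is boosted on the binary
    problem, and the regression output is the logistic transform of the
    ensemble score, a value in [0, 1].
    """

    def __init__(
        self,
        n_bins: int = 100,
        n_rounds: int = 1000,
        binarize_threshold: float | None = None,
    ):
        self.n_bins = n_bins
        self.n_rounds = n_rounds
        self.binarize_threshold = binarize_threshold

    def fit(self, X, y) -> "BinnedAdaBoostRegressor":
        X, y = check_X_y(X, y)
        if np.min(y) < 0 or np.max(y) > 1:
            raise ValueError("regression labels must lie in [0, 1]")
        thr = self.binarize_threshold
        self.threshold_ = float(np.median(y)) if thr is None else float(thr)
        y_pm = np.where(y > self.threshold_, 1, -1)
        self.classifier_ = BinnedAdaBoostClassifier(self.n_bins, self.n_rounds)
        if np.unique(y_pm).size < 2:
            warnings.warn(
                f"all labels on one side of threshold {self.threshold_}; constant model"
            )
            self.constant_ = 1.0 if y_pm[0] == 1 else 0.0
        else:
            self.constant_ = None
            self.classifier_.fit(X, y_pm)
        self.n_features_in_ = X.shape[1]
        self.train_rmse_ = rmse(self.predict(X), y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        X = check_array(X)
        if self.constant_ is not None:
            return np.full(X.shape[0], self.constant_)
        return self.classifier_.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Functional wrappers and metrics


def adaboost_train(X, y, M: int = 20, T: int = 1000) -> BinnedAdaBoostClassifier:
    """Fit the boosted binned classifier (labels +/-1)."""
    return BinnedAdaBoostClassifier(n_bins=M, n_rounds=T).fit(X, y)


def regression_train(
    X, y, M: int = 100, T: int = 1000, binarize_threshold: float | None = None
) -> BinnedAdaBoostRegressor:
    """Fit boosted-logistic regression of labels in [0, 1]."""
    return BinnedAdaBoostRegressor(M, T, binarize_threshold).fit(X, y)


def predict_strong(clf: BinnedAdaBoostClassifier, V: np.ndarray) -> tuple[float, int]:
    """Score and +/-1 class of one feature vector; a zero score yields -1."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    f = float(clf.decision_function(V)[0]) if getattr(clf, "estimators_", None) else 0.0
    return f, (1 if f > 0 else -1)


def predict_probability(clf: BinnedAdaBoostClassifier, V: np.ndarray) -> float:
    """Logistic transform of the ensemble score, P(y=+1|V)."""
    f, _ = predict_strong(clf, V)
    return float(expit(2.0 * f))


def classification_error(clf, X, y) -> float:
    """Fraction of misclassified samples."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty sample set")
    return float(np.mean(clf.predict(X) != y))


def rmse(predicted, truth) -> float:
    """Root mean squared error of the difference vector."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((predicted - truth) ** 2)))


def cumulated_feature_weights(clf: BinnedAdaBoostClassifier) -> np.ndarray:
    """Per-feature sums of alpha_t over the rounds selecting the feature."""
    check_is_fitted(clf, "cumulated_weights_")
    return clf.cumulated_weights_.copy()


def top_features(clf: BinnedAdaBoostClassifier, n: int = 10) -> list[tuple[int, float]]:
    """The n features of largest cumulated weight, descending (ties by index)."""
    w = cumulated_feature_weights(clf)
    order = np.lexsort((np.arange(w.size), -w))
    return [(int(i), float(w[i])) for i in order[:n] if w[i] > 0]


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(clf: BinnedAdaBoostClassifier) -> dict:
    check_is_fitted(clf, "estimators_")
    return {
        "n_bins": clf.n_bins,
        "n_rounds": clf.n_rounds,
        "n_features": int(clf.n_features_in_),
        "classes": [float(c) for c in clf.classes_],
        "rounds": [
            {
                "feature": int(h.feature_index),
                "lo": h.lo,
                "hi": h.hi,
                "bins": int(h.n_bins),
                "labels": [int(v) for v in h.labels],
                "alpha": float(alpha),
                "error": float(eps),
            }
            for h, alpha, eps in zip(
                clf.estimators_, clf.estimator_weights_, clf.estimator_errors_
            )
        ],
    }


def save_model(clf: BinnedAdaBoostClassifier, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(clf), fh, indent=1)
        fh.write("\n")


def load_model(path) -> BinnedAdaBoostClassifier:
    with open(path) as fh:
        spec = json.load(fh)
    clf = BinnedAdaBoostClassifier(n_bins=spec["n_bins"], n_rounds=spec["n_rounds"])
    p = int(spec["n_features"])
    clf.n_features_in_ = p
    clf.classes_ = np.asarray(spec["classes"])
    clf.estimators_ = [
        BinnedWeakClassifier(
            r["feature"], r["lo"], r["hi"], r["bins"], np.asarray(r["labels"], dtype=np.int8)
        )
        for r in spec["rounds"]
    ]
    clf.estimator_weights_ = np.asarray([r["alpha"] for r in spec["rounds"]])
    clf.estimator_errors_ = np.asarray([r["error"] for r in spec["rounds"]])
    clf.normalizers_ = np.asarray([])
    clf.cumulated_weights_ = np.zeros(p)
    for r in spec["rounds"]:
        clf.cumulated_weights_[r["feature"]] += r["alpha"]
    total = clf.cumulated_weights_.sum()
    clf.feature_importances_ = clf.cumulated_weights_ / total if total > 0 else np.zeros(p)
    return clf
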