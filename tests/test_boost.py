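"""Binned weak classifiers, the AdaBoost loop, regression and importances."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from voxsim.boost import (
    BinnedAdaBoostClassifier,
    BinnedAdaBoostRegressor,
    BinnedWeakClassifier,
    adaboost_train,
    classification_error,
    cumulated_feature_weights,
    fit_weak,
    load_model,
    predict_probability,
    predict_strong,
    predict_weak,
    regression_train,
    rmse,
    save_model,
    top_features,
)

# ---------------------------------------------------------------------------
# naive reference implementation (independent oracle)


def naive_fit_weak(x, y, w, M):
    """Rebuild one weak classifier from scratch with plain loops."""
    lo, hi = min(x), max(x)
    majority = 1 if sum(wi * yi for wi, yi in zip(w, y)) >= 0 else -1
    if lo == hi:
        labels = [majority]
        M = 1
    else:
        score = [0.0] * M
        for xi, yi, wi in zip(x, y, w):
            b = min(int((xi - lo) / (hi - lo) * M), M - 1)
            score[b] += wi * yi
        labels = []
        for b in range(M):
            if score[b] != 0:
                labels.append(1 if score[b] > 0 else -1)
            else:
                best, bestdist = None, None
                for b2 in range(M):
                    if score[b2] != 0:
                        dist = abs(b2 - b)
                        if bestdist is None or dist < bestdist or (dist == bestdist and b2 < best):
                            best, bestdist = b2, dist
                labels.append((1 if score[best] > 0 else -1) if best is not None else majority)

    def predict(xi):
        if lo == hi:
            return labels[0]
        b = min(max(int((xi - lo) / (hi - lo) * M), 0), M - 1)
        return labels[b]

    err = sum(wi for xi, yi, wi in zip(x, y, w) if predict(xi) != yi)
    return predict, labels, err


def naive_adaboost(X, y, M, T):
    """From-scratch AdaBoost loop; returns per-round (feature, eps, alpha)."""
    m, p = X.shape
    D = [1.0 / m] * m
    rounds = []
    for _ in range(T):
        best = None
        for j in range(p):
            if min(X[:, j]) == max(X[:, j]):
                continue
            predict, _, err = naive_fit_weak(X[:, j], y, D, M)
            if best is None or err < best[1]:
                best = (j, err, predict)
        if best is None or best[1] >= 0.5:
            break
        j, eps, predict = best
        alpha = 0.5 * math.log((1 - eps) / max(eps, 1e-10))
        rounds.append((j, eps, alpha))
        if eps == 0:
            break
        D = [Di * math.exp(-alpha * yi * predict(xi)) for Di, yi, xi in zip(D, y, X[:, j])]
        Z = sum(D)
        D = [Di / Z for Di in D]
    return rounds


# ---------------------------------------------------------------------------
# weak classifier


def test_bin_vote_follows_sign_of_weighted_mass():
    # one bin holding +1 mass 0.3 and -1 mass 0.2 votes +1
    x = np.array([0.0, 0.05, 1.0])
    y = np.array([1, -1, -1])
    w = np.array([0.3, 0.2, 0.5])
    clf, _ = fit_weak(x, y, w, n_bins=2)
    assert clf.predict_values(np.array([0.02]))[0] == 1


def test_all_positive_labels_zero_error(rng):
    x = rng.normal(size=20)
    y = np.ones(20, dtype=int)
    clf, err = fit_weak(x, y, np.full(20, 1 / 20), n_bins=5)
    assert err == 0.0
    assert np.all(clf.labels == 1)


def test_constant_feature_degenerates_to_majority():
    x = np.full(6, 3.3)
    y = np.array([1, 1, 1, -1, -1, 1])
    clf, err = fit_weak(x, y, np.full(6, 1 / 6), n_bins=4)
    assert clf.n_bins == 1
    assert clf.labels[0] == 1
    assert err == pytest.approx(2 / 6)


def test_m2_matches_exhaustive_midpoint_stump(rng):
    """The M=2 binned classifier equals the midpoint-threshold stump."""
    for _ in range(100):
        n = rng.integers(5, 40)
        x = rng.normal(size=n)
        y = rng.choice([-1, 1], size=n)
        w = rng.random(n)
        w /= w.sum()
        clf, err = fit_weak(x, y, w, n_bins=2)
        # oracle: split at the range midpoint, weighted-majority each side
        mid = (x.min() + x.max()) / 2
        left, right = x < mid, x >= mid
        side_label = lambda m: 1 if np.sum(w[m] * y[m]) >= 0 else -1
        lab_l = side_label(left) if left.any() else None
        lab_r = side_label(right) if right.any() else None
        if lab_l is None:
            lab_l = lab_r
        if lab_r is None:
            lab_r = lab_l
        expected = np.where(x < mid, lab_l, lab_r)
        got = clf.predict_values(x)
        # identical predictions wherever the vote is not a dead tie
        ties = np.isclose(np.sum(w[left] * y[left]), 0) or np.isclose(
            np.sum(w[right] * y[right]), 0
        )
        if not ties:
            np.testing.assert_array_equal(got, expected)
            assert err == pytest.approx(np.sum(w[got != y]))


def test_predict_weak_clamps_out_of_range():
    clf = BinnedWeakClassifier(0, 0.0, 1.0, 4, np.array([1, -1, -1, 1]))
    assert clf.predict_values(np.array([-5.0]))[0] == 1  # below lo -> first bin
    assert clf.predict_values(np.array([1.0]))[0] == 1  # at hi -> last bin
    assert clf.predict_values(np.array([99.0]))[0] == 1


def test_predict_weak_matches_interval_oracle(rng):
    clf = BinnedWeakClassifier(2, -1.0, 3.0, 8, rng.choice([-1, 1], size=8))
    values = rng.uniform(-2, 4, size=100)
    for v in values:
        b = int(np.clip(np.floor((v - (-1.0)) / 0.5), 0, 7))
        vec = np.zeros(5)
        vec[2] = v
        assert predict_weak(clf, vec) == clf.labels[b]


def test_indicating_vector_validated():
    with pytest.raises(ValueError):
        BinnedWeakClassifier(0, 0.0, 1.0, 3, np.array([1, 0, -1]))


# ---------------------------------------------------------------------------
# boosting loop


def test_alpha_formula_quarter_error():
    X = np.vstack([np.array([0.0, 0.1, 0.2, 0.9]), np.zeros(4)]).T
    # engineered so the best weak classifier errs on exactly 1 of 4 samples
    y = np.array([1, 1, -1, -1])
    clf = adaboost_train(X, y, M=2, T=1)
    assert clf.estimator_errors_[0] == pytest.approx(0.25)
    assert clf.estimator_weights_[0] == pytest.approx(0.5 * math.log(3))


def test_separable_single_feature_zero_error_after_one_round(rng):
    x = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
    y = np.array([1] * 30 + [-1] * 30)
    X = x[:, None]
    clf = adaboost_train(X, y, M=4, T=10)
    assert len(clf.estimators_) == 1  # zero-error round terminates training
    assert classification_error(clf, X, y) == 0.0


def test_unlearnable_data_yields_empty_ensemble():
    X = np.zeros((8, 3))
    y = np.array([1, -1] * 4)
    with pytest.warns(UserWarning, match="chance"):
        clf = BinnedAdaBoostClassifier(n_bins=4, n_rounds=5).fit(X, y)
    assert clf.estimators_ == []
    score, klass = predict_strong(clf, np.zeros(3))
    assert score == 0.0 and klass == -1


def test_full_loop_matches_naive_oracle(rng):
    X = rng.normal(size=(120, 6))
    y = np.where(X[:, 2] + 0.5 * X[:, 4] + rng.normal(0, 0.7, 120) > 0, 1, -1)
    T = 25
    clf = adaboost_train(X, y, M=5, T=T)
    expected = naive_adaboost(X, y, M=5, T=T)
    got = list(
        zip(
            [h.feature_index for h in clf.estimators_],
            clf.estimator_errors_,
            clf.estimator_weights_,
        )
    )
    assert len(got) == len(expected)
    for (jg, eg, ag), (je, ee, ae) in zip(got, expected):
        assert jg == je
        assert eg == pytest.approx(ee, abs=1e-12)
        assert ag == pytest.approx(ae, abs=1e-10)


def test_distribution_stays_normalized_and_bound_decreases(rng):
    """Sum D_t = 1 each round and train error <= prod Z_t (AdaBoost bound)."""
    X = rng.normal(size=(80, 5))
    y = np.where(X[:, 0] - X[:, 3] + rng.normal(0, 1.0, 80) > 0, 1, -1)
    clf = adaboost_train(X, y, M=4, T=30)
    # normalizers recorded each round are the sums of the unnormalized D:
    # after dividing by Z_t the distribution sums to 1 by construction;
    # verify via an explicit replay of the weight recursion
    m = len(y)
    D = np.full(m, 1 / m)
    for h, alpha, Z in zip(clf.estimators_, clf.estimator_weights_, clf.normalizers_):
        pred = h.predict(X)
        D = D * np.exp(-alpha * y * pred)
        assert D.sum() == pytest.approx(Z, rel=1e-12)
        D /= D.sum()
        assert D.sum() == pytest.approx(1.0, abs=1e-12)
    bounds = np.cumprod(clf.normalizers_)
    assert np.all(np.diff(bounds) <= 1e-12)  # exponential loss non-increasing
    assert classification_error(clf, X, y) <= bounds[-1] + 1e-12


def test_training_deterministic(rng):
    X = rng.normal(size=(60, 4))
    y = np.where(X[:, 1] > 0, 1, -1)
    a = adaboost_train(X, y, M=6, T=15)
    b = adaboost_train(X.copy(), y.copy(), M=6, T=15)
    assert [h.feature_index for h in a.estimators_] == [h.feature_index for h in b.estimators_]
    np.testing.assert_array_equal(a.estimator_weights_, b.estimator_weights_)


# ---------------------------------------------------------------------------
# strong classifier outputs


def test_predict_strong_single_round_summation():
    clf = BinnedAdaBoostClassifier(n_bins=2, n_rounds=1)
    clf.classes_ = np.array([-1, 1])
    clf.n_features_in_ = 1
    clf.estimators_ = [BinnedWeakClassifier(0, 0.0, 1.0, 2, np.array([-1, 1]))]
    clf.estimator_weights_ = np.array([0.7])
    score, klass = predict_strong(clf, np.array([0.9]))
    assert score == pytest.approx(0.7)
    assert klass == 1


def test_ensemble_score_matches_termwise_sum(rng):
    X = rng.normal(size=(50, 4))
    y = np.where(X[:, 0] + rng.normal(0, 0.6, 50) > 0, 1, -1)
    clf = adaboost_train(X, y, M=4, T=10)
    f = clf.decision_function(X)
    manual = np.zeros(len(X))
    for h, a in zip(clf.estimators_, clf.estimator_weights_):
        manual += a * np.array([predict_weak(h, row) for row in X])
    np.testing.assert_allclose(f, manual)


def test_logistic_transform_values():
    assert 1 / (1 + math.exp(-2 * 0.0)) == 0.5
    clf = BinnedAdaBoostClassifier()
    clf.classes_ = np.array([-1, 1])
    clf.n_features_in_ = 1
    clf.estimator_weights_ = np.array([1.0])
    clf.estimators_ = [BinnedWeakClassifier(0, 0.0, 1.0, 2, np.array([1, 1]))]
    # f = 1 -> e/(e + 1/e)
    p = predict_probability(clf, np.array([0.5]))
    assert p == pytest.approx(math.e / (math.e + 1 / math.e))
    # huge scores saturate without overflow
    clf.estimator_weights_ = np.array([5000.0])
    assert predict_probability(clf, np.array([0.5])) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# metrics


def test_classification_error_counts():
    class Fixed:
        def predict(self, X):
            return np.array([1, -1, 1, 1])

    y = np.array([1, -1, -1, -1])
    assert classification_error(Fixed(), np.zeros((4, 1)), y) == pytest.approx(0.5)
    assert classification_error(Fixed(), np.zeros((4, 1)), np.array([1, -1, 1, 1])) == 0.0
    with pytest.raises(ValueError):
        classification_error(Fixed(), np.zeros((0, 1)), np.array([]))


def test_rmse_values():
    assert rmse([1.0, 0.0], [0.0, 0.0]) == pytest.approx(math.sqrt(0.5))
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse(np.zeros(9) + 0.3, np.zeros(9)) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])


def test_cumulated_weights_sum_per_feature(rng):
    X = rng.normal(size=(80, 3))
    y = np.where(X[:, 1] + rng.normal(0, 1.5, 80) > 0, 1, -1)
    clf = adaboost_train(X, y, M=4, T=20)
    w = cumulated_feature_weights(clf)
    manual = np.zeros(3)
    for h, a in zip(clf.estimators_, clf.estimator_weights_):
        manual[h.feature_index] += a
    np.testing.assert_allclose(w, manual)
    assert clf.feature_importances_.sum() == pytest.approx(1.0)


def test_informative_feature_ranks_first(rng):
    X = rng.normal(size=(300, 8))
    y = np.where(X[:, 5] > 0.1, 1, -1)  # only feature 5 is informative
    clf = adaboost_train(X, y, M=10, T=30)
    assert top_features(clf, 1)[0][0] == 5


# ---------------------------------------------------------------------------
# regression


def test_regression_beats_constant_baseline(rng):
    X = rng.uniform(size=(400, 5))
    y = np.clip(X[:, 2] + rng.normal(0, 0.1, 400), 0, 1)
    Xtr, ytr, Xte, yte = X[:200], y[:200], X[200:], y[200:]
    reg = regression_train(Xtr, ytr, M=10, T=50)
    baseline = rmse(np.full(200, ytr.mean()), yte)
    assert rmse(reg.predict(Xte), yte) < baseline


def test_regression_degenerate_labels_warn():
    X = np.random.default_rng(0).normal(size=(20, 2))
    y = np.full(20, 0.4)
    with pytest.warns(UserWarning, match="one side"):
        reg = BinnedAdaBoostRegressor(n_bins=4, n_rounds=3, binarize_threshold=0.3).fit(X, y)
    assert np.all(reg.predict(X) == reg.constant_)


def test_regression_deterministic(rng):
    X = rng.uniform(size=(100, 4))
    y = np.clip(X[:, 0] + rng.normal(0, 0.2, 100), 0, 1)
    r1 = regression_train(X, y, M=8, T=20)
    r2 = regression_train(X.copy(), y.copy(), M=8, T=20)
    np.testing.assert_array_equal(r1.predict(X), r2.predict(X))


def test_regression_rejects_labels_outside_unit_interval(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError):
        BinnedAdaBoostRegressor().fit(X, np.linspace(-0.5, 0.5, 10))


# ---------------------------------------------------------------------------
# sklearn interface and serialization


def test_estimator_params_round_trip():
    clf = BinnedAdaBoostClassifier(n_bins=7, n_rounds=13)
    assert clone(clf).get_params() == {"n_bins": 7, "n_rounds": 13}
    reg = BinnedAdaBoostRegressor(binarize_threshold=0.4)
    assert clone(reg).get_params()["binarize_threshold"] == 0.4


def test_classifier_accepts_arbitrary_binary_labels(rng):
    X = rng.normal(size=(60, 3))
    y = np.where(X[:, 0] > 0, "high", "low")
    clf = BinnedAdaBoostClassifier(n_bins=4, n_rounds=5).fit(X, y)
    assert set(clf.predict(X)) <= {"high", "low"}


def test_model_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(80, 4))
    y = np.where(X[:, 2] + rng.normal(0, 0.5, 80) > 0, 1, -1)
    clf = adaboost_train(X, y, M=5, T=10)
    path = tmp_path / "model.json"
    save_model(clf, path)
    loaded = load_model(path)
    np.testing.assert_array_equal(clf.predict(X), loaded.predict(X))
    np.testing.assert_allclose(clf.decision_function(X), loaded.decision_function(X))
    np.testing.assert_allclose(cumulated_feature_weights(loaded), cumulated_feature_weights(clf))
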