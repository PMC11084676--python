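"""PLS-DA core: algebraic equivalences against independent oracles,
cross-validation contracts, metric identities and permutation-test
calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from raman_pcad import (
    CVConfig,
    classify,
    compute_metrics,
    cross_validate,
    fit_pls,
    permutation_test,
    predict,
    select_n_lvs,
    transform,
)
from raman_pcad.plsda import bayes_threshold


def _random_problem(rng, n=10, p=5):
    x = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return x, y


def _trapezoid_auc(y, scores):
    """ROC integration oracle: sweep every threshold, integrate TPR
    over FPR with the trapezoid rule (ties handled by the diagonal
    segments the midrank statistic also produces)."""
    y = np.asarray(y)
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    tpr = [np.mean(scores[y == 1] >= t) for t in thresholds]
    fpr = [np.mean(scores[y == 0] >= t) for t in thresholds]
    tpr, fpr = np.r_[tpr, 1.0], np.r_[fpr, 1.0]
    return np.trapezoid(tpr, fpr)


class TestFit:
    def test_full_rank_pls_equals_least_squares(self, rng):
        x, y = _random_problem(rng)
        model = fit_pls(x, y, n_lv=5)
        xc = x - x.mean(axis=0)
        b_ols, *_ = np.linalg.lstsq(xc, y - y.mean(), rcond=None)
        yhat_ols = xc @ b_ols + y.mean()
        assert np.allclose(predict(model, x), yhat_ols, atol=1e-8)

    def test_scores_are_orthogonal(self, rng):
        x, y = _random_problem(rng, n=30, p=12)
        t = fit_pls(x, y, 6).t_scores
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_single_informative_column_dominates_b(self, rng):
        n = 40
        y = np.r_[np.zeros(20), np.ones(20)]
        x = rng.normal(scale=0.05, size=(n, 10))
        x[:, 3] = 2 * y + rng.normal(scale=0.01, size=n)
        model = fit_pls(x, y, 1)
        assert np.argmax(np.abs(model.b)) == 3
        r = np.corrcoef(predict(model, x), y)[0, 1]
        assert r > 0.99

    def test_requested_lv_bounded_by_rank(self, rng):
        x, y = _random_problem(rng, n=6, p=10)
        with pytest.raises(ValueError):
            fit_pls(x, y, 6)  # n-1 = 5 is the cap
        with pytest.raises(ValueError):
            fit_pls(x, np.zeros(6), 2)  # constant response

    def test_b_vector_equals_factorwise_prediction(self, rng):
        # two algebraically equivalent prediction routes must agree
        x, y = _random_problem(rng, n=25, p=15)
        model = fit_pls(x, y, 4)
        x_new = rng.normal(size=(8, 15))
        xc = x_new - model.x_mean
        acc = np.full(8, model.y_mean)
        for a in range(model.n_lv):
            t = xc @ model.w[:, a]
            acc = acc + model.q[a] * t
            xc = xc - np.outer(t, model.p_load[:, a])
        assert np.allclose(predict(model, x_new), acc, atol=1e-10)

    def test_training_set_prediction_reproduces_fit(self, rng):
        x, y = _random_problem(rng, n=20, p=8)
        model = fit_pls(x, y, 3)
        fitted = model.t_scores @ model.q + model.y_mean
        assert np.allclose(predict(model, x), fitted, atol=1e-10)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        x, y = _random_problem(rng, n=20, p=8)
        model = fit_pls(x, y, 3)
        assert predict(model, x.mean(axis=0))[0] == pytest.approx(
            y.mean(), abs=1e-12
        )

    def test_variable_mismatch_reports_expected_count(self, rng):
        x, y = _random_problem(rng, n=20, p=8)
        model = fit_pls(x, y, 2)
        with pytest.raises(ValueError, match="8 wavenumbers"):
            predict(model, np.zeros((3, 5)))

    def test_matches_reference_pls_implementation(self, rng):
        # independent cross-check against scikit-learn's PLS regression
        # (unscaled, same centering convention)
        from sklearn.cross_decomposition import PLSRegression

        x, y = _random_problem(rng, n=30, p=12)
        model = fit_pls(x, y, 4)
        ref = PLSRegression(n_components=4, scale=False).fit(x, y)
        assert np.allclose(
            predict(model, x), ref.predict(x).ravel(), atol=1e-8
        )

    def test_transform_recovers_training_scores(self, rng):
        x, y = _random_problem(rng, n=20, p=8)
        model = fit_pls(x, y, 3)
        assert np.allclose(transform(model, x), model.t_scores, atol=1e-10)


class TestClassify:
    def test_threshold_split(self):
        assert classify(np.array([0.9, 0.1]), 0.5).tolist() == ["PC", "H"]

    def test_tie_goes_to_healthy(self):
        assert classify(np.array([0.5]), 0.5).tolist() == ["H"]

    def test_all_below_threshold_gives_zero_sensitivity(self):
        y = np.array([1, 1, 0, 0])
        m = compute_metrics(y, np.array([0.1, 0.2, 0.0, 0.3]), threshold=0.5)
        assert m.sensitivity == 0.0


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics(
            np.array(["PC", "PC", "H", "H"]), np.array([0.9, 0.8, 0.2, 0.1])
        )
        assert m.auc == 1.0 and m.accuracy == 1.0

    def test_constant_scores_give_half_auc(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.3))
        assert m.auc == pytest.approx(0.5)

    def test_rank_auc_equals_trapezoid_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
            m = compute_metrics(y, scores)
            assert m.auc == pytest.approx(_trapezoid_auc(y, scores), abs=1e-10)

    def test_roc_sweep_matches_exhaustive_threshold_enumeration(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        scores = rng.normal(size=40)
        for thr in np.unique(scores):
            m = compute_metrics(y, scores, threshold=thr)
            tp = np.sum((scores > thr) & (y == 1))
            fn = np.sum((scores <= thr) & (y == 1))
            assert m.sensitivity == pytest.approx(tp / (tp + fn))

    @given(
        tp=st.integers(0, 20),
        fp=st.integers(0, 20),
        tn=st.integers(0, 20),
        fn=st.integers(0, 20),
    )
    def test_confusion_identities(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        y = np.r_[np.ones(tp + fn), np.zeros(tn + fp)]
        scores = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
        m = compute_metrics(y, scores, threshold=0.5)
        assert m.confusion == {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(4), np.arange(4.0))


class TestCrossValidation:
    def _toy(self, rng, n=12, p=4, shift=3.0):
        y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        x = rng.normal(size=(n, p))
        x[:, 0] += shift * y
        return x, y

    def test_leave_one_out_matches_brute_force_oracle(self, rng):
        x, y = self._toy(rng)
        cv = CVConfig(n_subsets=12, n_iterations=1, seed=0)
        res = cross_validate(x, y, 2, cv)
        yhat = np.empty(12)
        for i in range(12):  # hand-rolled LOO
            mask = np.arange(12) != i
            model = fit_pls(x[mask], y[mask], 2)
            yhat[i] = predict(model, x[i])[0]
        rmsecv_oracle = np.sqrt(np.mean((yhat - y) ** 2))
        assert res.rmsecv == pytest.approx(rmsecv_oracle, abs=1e-10)

    def test_separable_data_classified_perfectly(self, rng):
        # widely separated classes: the cross-validated model must be
        # error-free in the separable limit
        x, y = self._toy(rng, n=30, p=6, shift=10.0)
        res = cross_validate(x, y, 2, CVConfig(n_subsets=15, seed=1))
        assert res.metrics.accuracy == 1.0
        assert res.metrics.auc == 1.0

    def test_identical_seed_identical_result(self, rng):
        x, y = self._toy(rng, n=30, p=6)
        cv = CVConfig(n_subsets=10, n_iterations=3, seed=99)
        a = cross_validate(x, y, 2, cv)
        b = cross_validate(x, y, 2, cv)
        assert np.array_equal(a.yhat_cv, b.yhat_cv)

    def test_every_sample_predicted_each_iteration(self, rng):
        x, y = self._toy(rng, n=20, p=5)
        res = cross_validate(x, y, 2, CVConfig(n_subsets=5, n_iterations=4, seed=2))
        assert res.yhat_cv.shape == (4, 20)
        assert np.all(np.isfinite(res.yhat_cv))

    def test_no_leakage_on_pure_noise(self, rng):
        # p >> n pure noise: training fit is nearly perfect, but the
        # cross-validated accuracy must stay near chance
        n, p = 30, 100
        x = rng.normal(size=(n, p))
        y = np.r_[np.zeros(15), np.ones(15)]
        model = fit_pls(x, y, 5)
        train_acc = np.mean((predict(model, x) > 0.5) == (y == 1))
        res = cross_validate(x, y, 5, CVConfig(n_subsets=15, seed=3))
        assert train_acc > 0.9
        assert res.metrics.accuracy < 0.75


class TestLVSelection:
    def test_two_latent_dimensions_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 60, 20
            t1 = rng.normal(size=n)
            t2 = rng.normal(size=n)
            p1, p2 = rng.normal(size=p), rng.normal(size=p)
            x = np.outer(t1, p1) + np.outer(t2, p2) + rng.normal(scale=0.02, size=(n, p))
            y = 0.7 * t1 + 0.4 * t2 + rng.normal(scale=0.02, size=n)
            lv, _ = select_n_lvs(x, y, 6, CVConfig(n_subsets=10, seed=seed))
            hits += lv == 2
        assert hits >= 18

    def test_rank_deficient_curve_ties_break_to_fewest(self, rng):
        # two identical columns: rank 1, so the RMSECV curve is flat
        # beyond the first LV and the tie must resolve to 1
        n = 16
        y = np.r_[np.zeros(8), np.ones(8)]
        col = y + rng.normal(scale=0.3, size=n)
        x = np.column_stack([col, col])
        lv, curve = select_n_lvs(x, y, 4, CVConfig(n_subsets=8, seed=0))
        assert lv == 1
        assert np.allclose(curve, curve[0])

    def test_curve_nonnegative(self, rng):
        x, y = rng.normal(size=(20, 6)), rng.integers(0, 2, size=20).astype(float)
        y[:2] = [0, 1]
        _, curve = select_n_lvs(x, y, 5, CVConfig(n_subsets=10, seed=1))
        assert np.all(curve >= 0)


class TestPermutation:
    def test_p_value_lower_bound_attained_when_separable(self, rng):
        n = 30
        y = np.r_[np.zeros(15), np.ones(15)]
        x = rng.normal(size=(n, 5))
        x[:, 0] += 4 * y
        res = permutation_test(
            x, y, 2, CVConfig(n_subsets=15, seed=0), n_perm=49, seed=1
        )
        assert res.p_value == pytest.approx(1 / 50)
        assert res.p_value >= 1 / (res.n_perm + 1)

    def test_null_data_not_significant(self, rng):
        x = rng.normal(size=(24, 10))
        y = np.r_[np.zeros(12), np.ones(12)]
        res = permutation_test(
            x, y, 2, CVConfig(n_subsets=12, seed=5), n_perm=49, seed=2
        )
        assert res.p_value > 0.05


class TestBayesThreshold:
    def test_symmetric_classes_give_midpoint(self, rng):
        scores = np.r_[rng.normal(0.2, 0.1, 200), rng.normal(0.8, 0.1, 200)]
        y = np.r_[np.zeros(200), np.ones(200)]
        thr = bayes_threshold(scores, y)
        assert thr == pytest.approx(0.5, abs=0.03)
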