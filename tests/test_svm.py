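"""SMO linear SVM: analytic anchors, oracle agreement, splits, CV,
recursive feature elimination and final model selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from embrisk import svm
from embrisk.svm import (
    FINAL_C_GRID,
    RFE_C_GRID,
    LabeledDataset,
    LinearSVMModel,
    SMOLinearSVC,
    cross_validate,
    predict,
    select_final_model,
    smo_train,
    split_train_test,
    svm_rfe,
)


def _data(x, y, names=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    names = names or [f"g{j}" for j in range(x.shape[1])]
    return LabeledDataset(x, np.asarray(y), names)


def _qp_dual_optimum(X, y, C):
    """Brute-force dual solution via SLSQP (small n only)."""
    Q = np.outer(y, y) * (X @ X.T)
    n = len(y)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.fun, res.x


class TestSMOAnchors:
    def test_two_point_max_margin_solution(self):
        """x=0 (y=-1), x=2 (y=+1) with large C: w=1, b=-1, alpha=(.5,.5)."""
        clf = SMOLinearSVC(C=100.0).fit(np.array([[0.0], [2.0]]),
                                        np.array([-1, 1]))
        assert clf.coef_[0] == pytest.approx([1.0])
        assert clf.intercept_[0] == pytest.approx(-1.0)
        assert clf.alpha_ == pytest.approx([0.5, 0.5])
        assert clf.decision_function(np.array([[0.0], [2.0]])) == \
            pytest.approx([-1.0, 1.0])

    def test_duplicated_dataset_same_hyperplane(self):
        # holds when no multiplier sits at the box bound (margin-limited
        # fit); each duplicate then takes half the original multiplier
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[:, 0] += 2.0 * y
        a = SMOLinearSVC(C=50.0, tol=1e-8).fit(X, y)
        b = SMOLinearSVC(C=50.0, tol=1e-8).fit(np.vstack([X, X]),
                                               np.concatenate([y, y]))
        assert np.all(a.alpha_ < 50.0 - 1e-9)
        assert np.allclose(a.coef_, b.coef_, atol=1e-3)
        assert a.intercept_[0] == pytest.approx(b.intercept_[0], abs=1e-3)

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = np.where(rng.random(50) > 0.5, 1, -1)
        clf = SMOLinearSVC(C=0.7).fit(X, y)
        assert np.all(clf.alpha_ >= -1e-12)
        assert np.all(clf.alpha_ <= 0.7 + 1e-12)
        assert abs(clf.alpha_ @ clf._y_pm) < 1e-9
        assert clf.kkt_gap_ <= clf.tol

    def test_weight_vector_reproducible_from_alpha(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = np.where(X[:, 1] > 0, 1, -1)
        clf = SMOLinearSVC(C=1.0).fit(X, y)
        w = X.T @ (clf.alpha_ * clf._y_pm)
        assert np.allclose(w, clf.coef_[0], atol=1e-8)

    def test_nonconvergence_raises_with_diagnostics(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = np.where(rng.random(200) > 0.5, 1, -1)
        with pytest.raises(svm.ConvergenceError) as exc:
            SMOLinearSVC(C=5.0, max_iter=10).fit(X, y)
        assert exc.value.C == 5.0
        assert exc.value.gap > 1e-3


class TestSMOOracle:
    def test_dual_objective_matches_qp_solver(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            d = int(rng.integers(1, 6))
            C = float(rng.choice([0.1, 1.0, 10.0]))
            X = rng.normal(size=(n, d))
            y = np.where(rng.random(n) < 0.5, -1, 1)
            if len(np.unique(y)) < 2:
                y[0] = -y[0]
            clf = SMOLinearSVC(C=C, tol=1e-8).fit(X, y)
            obj, alpha = _qp_dual_optimum(X, y, C)
            assert clf.dual_objective_ == pytest.approx(obj, abs=1e-6)
            # decision values agree where the optimum is unique enough
            w_ref = X.T @ (alpha * y)
            assert np.allclose(clf.coef_[0], w_ref, atol=1e-4)

    def test_matches_reference_linear_svc(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=80) > 0, 1, -1)
        ours = SMOLinearSVC(C=1.0, tol=1e-6).fit(X, y)
        ref = SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, y)
        assert np.allclose(ours.coef_, ref.coef_, atol=1e-3)
        assert ours.intercept_[0] == pytest.approx(ref.intercept_[0], abs=1e-3)

    def test_training_accuracy_monotone_in_C(self):
        rng = np.random.default_rng(34)
        X = rng.normal(size=(80, 3))
        y = np.where(X[:, 0] + rng.normal(0, 1.2, 80) > 0, 1, -1)
        accs = []
        for C in RFE_C_GRID:
            clf = SMOLinearSVC(C=C).fit(X, y)
            accs.append((clf.predict(X) == y).mean())
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))


class TestPredict:
    def _model(self):
        return LinearSVMModel(
            gene_names=["g0"], w=np.array([1.0]), b=-1.0, C=1.0,
            alpha=np.array([0.5, 0.5]), support_indices=np.array([0, 1]),
            scaler_mean=np.zeros(1), scaler_scale=np.ones(1),
        )

    def test_positive_side(self):
        assert predict(self._model(), np.array([[2.0]])) == [1]

    def test_on_hyperplane_maps_to_positive(self):
        assert predict(self._model(), np.array([[1.0]])) == [1]

    def test_sign_flip_flips_all_predictions(self):
        m = self._model()
        flipped = LinearSVMModel(
            gene_names=m.gene_names, w=-m.w, b=-m.b, C=m.C, alpha=m.alpha,
            support_indices=m.support_indices, scaler_mean=m.scaler_mean,
            scaler_scale=m.scaler_scale,
        )
        X = np.array([[0.0], [2.0], [5.0]])
        assert np.array_equal(predict(m, X), -predict(flipped, X))

    def test_missing_panel_gene_is_an_error(self):
        with pytest.raises(KeyError, match="g0"):
            predict(self._model(), np.zeros((2, 2)), gene_names=["a", "b"])

    def test_serialization_round_trip(self):
        m = self._model()
        back = LinearSVMModel.from_text(m.to_text())
        assert np.array_equal(back.w, m.w)
        assert back.b == m.b and back.C == m.C
        assert np.array_equal(back.gene_names, m.gene_names)


class TestSplit:
    def test_stratified_counts(self):
        rng = np.random.default_rng(0)
        data = _data(rng.normal(size=(200, 2)), [1] * 100 + [-1] * 100)
        train, test = split_train_test(data, 0.7, seed=1)
        assert (train.y == 1).sum() == 70 and (train.y == -1).sum() == 70
        assert (test.y == 1).sum() == 30 and (test.y == -1).sum() == 30

    def test_full_fraction_warns_with_empty_test(self):
        data = _data(np.random.default_rng(1).normal(size=(10, 2)),
                     [1] * 5 + [-1] * 5)
        with pytest.warns(UserWarning, match="empty"):
            train, test = split_train_test(data, 1.0, seed=0)
        assert test.n_cells == 0 and train.n_cells == 10

    def test_same_seed_same_split(self):
        data = _data(np.random.default_rng(2).normal(size=(40, 2)),
                     [1] * 20 + [-1] * 20)
        a1, b1 = split_train_test(data, 0.7, seed=9)
        a2, b2 = split_train_test(data, 0.7, seed=9)
        assert np.array_equal(a1.x, a2.x) and np.array_equal(b1.x, b2.x)

    def test_tiny_class_rejected(self):
        data = _data(np.zeros((3, 1)), [1, 1, -1])
        with pytest.raises(ValueError):
            split_train_test(data, 0.7)


class TestCrossValidate:
    def test_separable_data_scores_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[:, 0] += 3 * y
        assert cross_validate(_data(X, y), C=1.0, k=10, seed=0) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = np.where(rng.random(200) > 0.5, 1, -1)
        acc = cross_validate(_data(X, y), C=1.0, k=5, seed=0)
        assert abs(acc - 0.5) < 0.1

    def test_two_folds_on_four_points(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([-1, -1, 1, 1])
        acc = cross_validate(_data(X, y), C=10.0, k=2, seed=0)
        assert 0.0 <= acc <= 1.0

    def test_k_exceeding_class_size_rejected(self):
        data = _data(np.random.default_rng(2).normal(size=(10, 1)),
                     [1] * 5 + [-1] * 5)
        with pytest.raises(ValueError, match="k="):
            cross_validate(data, C=1.0, k=6)


class TestRFE:
    def test_planted_informative_features_selected(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 23))
        y = np.where(rng.random(n) > 0.5, 1, -1)
        X[y == 1, :3] += 3.0  # strong planted signal in g0..g2
        res = svm_rfe(_data(X, y), seed=1)
        assert {"g0", "g1", "g2"} <= set(res.selected_panel)
        assert res.best_accuracy == 1.0

    def test_all_noise_plateaus_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 10))
        y = np.array([1, -1] * 30)
        res = svm_rfe(_data(X, y), C_grid=(0.2, 1.0), cv_k=5, seed=2)
        assert res.best_accuracy < 0.8

    def test_constant_feature_eliminated_first(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.full(40, 3.0), rng.normal(size=40)])
        y = np.where(X[:, 1] > 0, 1, -1)
        res = svm_rfe(_data(X, y, names=["const", "signal"]),
                      C_grid=(1.0,), cv_k=5, seed=0)
        assert res.ranked_genes[0] == "const"
        assert res.selected_panel == ["signal"]

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="2 features"):
            svm_rfe(_data(np.zeros((10, 1)), [1, -1] * 5))

    def test_accuracy_path_covers_all_subset_sizes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 12))
        y = np.where(X[:, 0] > 0, 1, -1)
        res = svm_rfe(_data(X, y), C_grid=(1.0,), cv_k=4, seed=0)
        sizes = res.cv_accuracy_path["size"].tolist()
        assert sizes[0] == 12 and sizes[-1] == 1
        assert all(a > b for a, b in zip(sizes, sizes[1:]))


class TestFinalModel:
    def _separable(self, seed, n=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) > 0.5, 1, -1)
        X[:, 0] += 4.0 * y
        return _data(X, y)

    def test_smallest_perfect_C_wins(self):
        train = self._separable(0)
        tests = [self._separable(s) for s in (1, 2)]
        model, metrics = select_final_model(train, tests, ["g0", "g1", "g2"],
                                            C_grid=(0.05, 0.2, 1.2))
        best = metrics.groupby("C")["accuracy"].mean()
        assert best.max() == 1.0
        assert model.C == 0.05

    def test_singleton_grid_returns_that_model(self):
        train = self._separable(3)
        model, metrics = select_final_model(train, [self._separable(4)],
                                            ["g0", "g1", "g2"], C_grid=(0.6,))
        assert model.C == 0.6
        assert set(metrics.C) == {0.6}

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5 -> precision = recall = F1 = 0.75
        y_true = np.array([1, 1, 1, 1, -1, -1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, 1, -1, -1, -1, -1, -1])
        m = svm._metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            select_final_model(self._separable(5), [self._separable(6)], [])

    def test_empty_test_set_rejected(self):
        train = self._separable(7)
        empty = LabeledDataset(train.x[:0], train.y[:0], train.gene_names)
        with pytest.raises(ValueError, match="empty"):
            select_final_model(train, [empty], ["g0"])


def test_smo_train_wrapper_matches_estimator():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 2))
    y = np.where(X[:, 0] > 0, 1, -1)
    a = smo_train(_data(X, y), C=1.0)
    b = SMOLinearSVC(C=1.0).fit(X, y)
    assert np.allclose(a.coef_, b.coef_)
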