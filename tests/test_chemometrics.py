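"""PCA against an eigendecomposition oracle; SVM against dual-QP and
scikit-learn cross-checks; persistence round-trips."""

from __future__ import annotations

import numpy as np
import pytest

import sersid
from sersid.chemometrics import LinearClassifierModel, load_model, save_model


def eig_pca_oracle(X):
    """Brute-force oracle: eigendecomposition of the covariance matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order] / vals.sum(), vecs[:, order].T


def svm_dual_oracle(X, y_signed, C):
    """Brute-force soft-margin SVM oracle for tiny problems.

    Enumerates every active-set pattern of the dual (each multiplier at 0,
    at C, or free), solves the KKT equations for the free multipliers and
    the bias, and returns the (w, b) of the unique feasible pattern.
    """
    from itertools import product

    n = len(y_signed)
    K = X @ X.T
    Q = (y_signed[:, None] * y_signed[None, :]) * K
    tol = 1e-9
    for pattern in product((0, 1, 2), repeat=n):  # 0: alpha=0, 1: alpha=C, 2: free
        free = [i for i in range(n) if pattern[i] == 2]
        if not free:
            continue
        alpha = np.where(np.array(pattern) == 1, C, 0.0)
        # KKT: for free i, sum_j Q_ij a_j + y_i b = 1; plus sum y_i a_i = 0
        m = len(free)
        A = np.zeros((m + 1, m + 1))
        rhs = np.zeros(m + 1)
        for r, i in enumerate(free):
            A[r, :m] = Q[i, free]
            A[r, m] = y_signed[i]
            rhs[r] = 1.0 - Q[i][alpha > 0] @ alpha[alpha > 0]
        A[m, :m] = y_signed[free]
        rhs[m] = -alpha @ y_signed
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        alpha[free] = sol[:m]
        b = sol[m]
        if np.any(alpha < -tol) or np.any(alpha > C + tol):
            continue
        w = ((alpha * y_signed)[:, None] * X).sum(axis=0)
        margins = y_signed * (X @ w + b)
        ok = True
        for i in range(n):
            if pattern[i] == 0 and margins[i] < 1.0 - 1e-7:
                ok = False
            elif pattern[i] == 1 and margins[i] > 1.0 + 1e-7:
                ok = False
        if ok:
            # recompute b from the final multipliers: with no strictly free
            # support vector b is only determined up to an interval, whose
            # midpoint is the libSVM convention
            eps = 1e-8
            strictly_free = (alpha > eps) & (alpha < C - eps)
            if strictly_free.any():
                b = float(
                    np.mean(y_signed[strictly_free] - X[strictly_free] @ w)
                )
            else:
                # positive class: alpha=0 -> b >= 1 - w.x ; alpha=C -> b <= 1 - w.x
                # negative class: alpha=0 -> b <= -1 - w.x; alpha=C -> b >= -1 - w.x
                lowers = [
                    y_signed[i] - X[i] @ w
                    for i in range(n)
                    if (y_signed[i] > 0 and alpha[i] < eps)
                    or (y_signed[i] < 0 and alpha[i] > C - eps)
                ]
                uppers = [
                    y_signed[i] - X[i] @ w
                    for i in range(n)
                    if (y_signed[i] > 0 and alpha[i] > C - eps)
                    or (y_signed[i] < 0 and alpha[i] < eps)
                ]
                b = float((max(lowers) + min(uppers)) / 2.0)
            return w, float(b)
    raise AssertionError("no feasible KKT pattern found")


class TestPCAFit:
    def test_rank_two_matrix_needs_two_components(self, rng):
        t1, t2 = rng.normal(size=(2, 30))
        mix = rng.uniform(0.2, 1.0, size=(12, 2))
        X = mix @ np.vstack([t1, t2])
        model = sersid.pca_fit(X, 5)
        assert abs(model.explained_variance_ratio[:2].sum() - 1.0) < 1e-10
        assert np.all(model.explained_variance_ratio[2:] < 1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        for _ in range(10):
            X = rng.normal(size=(5, 7))
            model = sersid.pca_fit(X, 4)
            ratio_ref, vecs_ref = eig_pca_oracle(X)
            np.testing.assert_allclose(
                model.explained_variance_ratio, ratio_ref[:4], atol=1e-8
            )
            for i in range(4):
                dot = abs(np.dot(model.loadings[i], vecs_ref[i]))
                assert dot > 1.0 - 1e-8  # equal up to sign

    def test_duplicating_rows_leaves_loadings_unchanged(self, rng):
        X = rng.normal(size=(6, 9))
        a = sersid.pca_fit(X, 3)
        b = sersid.pca_fit(np.vstack([X, X]), 3)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)

    def test_loadings_are_orthonormal_with_fixed_sign(self, rng):
        X = rng.normal(size=(20, 15))
        model = sersid.pca_fit(X, 6)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(sersid.ValidationError):
            sersid.pca_fit(rng.normal(size=(5, 7)), 6)


class TestPCAProject:
    def test_training_scores_are_centered(self, rng):
        X = rng.normal(size=(25, 10))
        model = sersid.pca_fit(X, 4)
        scores = sersid.pca_project(model, X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_model_mean_projects_to_zero(self, rng):
        model = sersid.pca_fit(rng.normal(size=(25, 10)), 4)
        np.testing.assert_allclose(
            sersid.pca_project(model, model.mean), 0.0, atol=1e-12
        )

    def test_model_mean_not_test_mean_is_subtracted(self, rng):
        X = rng.normal(size=(25, 10))
        model = sersid.pca_fit(X, 4)
        shifted = rng.normal(size=(10, 10)) + 5.0
        expected = (shifted - model.mean) @ model.loadings.T
        np.testing.assert_allclose(
            sersid.pca_project(model, shifted), expected, atol=1e-12
        )

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        X = rng.normal(size=(20, 12))
        k = 5
        model = sersid.pca_fit(X, k)
        scores = sersid.pca_project(model, X)
        recon = scores @ model.loadings + model.mean
        err = np.sum((X - recon) ** 2)
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        discarded = np.sum(s[k:] ** 2)
        np.testing.assert_allclose(err, discarded, rtol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        model = sersid.pca_fit(rng.normal(size=(10, 8)), 2)
        with pytest.raises(sersid.ValidationError):
            sersid.pca_project(model, rng.normal(size=(3, 9)))


class TestSVM:
    def test_separable_clouds_classified_perfectly(self, rng):
        a = rng.normal(size=(30, 2)) * 0.2
        b = rng.normal(size=(30, 2)) * 0.2 + np.array([10.0, 0.0])
        X = np.vstack([a, b])
        y = ["A"] * 30 + ["B"] * 30
        model = sersid.svm_train(X, y, 1.0)
        assert np.all(sersid.svm_predict(model, X) == np.array(y, dtype=object))

    def test_maximum_margin_midpoint_toy(self):
        """Two class columns at x1=0 and x1=2: the boundary sits at x1=1."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = ["A", "A", "B", "B"]
        model = sersid.svm_train(X, y, 1.0)
        midpoint_decision = np.array([1.0, 0.5]) @ model.pair_weights[0] + model.pair_biases[0]
        assert abs(midpoint_decision) < 1e-6
        assert sersid.svm_predict(model, np.array([[0.9, 0.5]]))[0] == "A"
        assert sersid.svm_predict(model, np.array([[1.1, 0.5]]))[0] == "B"

    def test_agrees_with_dual_qp_oracle(self, rng):
        """Six-point 2-class problems: decision values match the dual QP."""
        for trial in range(5):
            X = rng.normal(size=(6, 2))
            y = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
            model = sersid.svm_train(X, y, 1.0)
            y_signed = np.where(y == "A", 1.0, -1.0)  # positive = first label
            w_ref, b_ref = svm_dual_oracle(X, y_signed, 1.0)
            grid = rng.normal(size=(20, 2))
            dec = grid @ model.pair_weights[0] + model.pair_biases[0]
            dec_ref = grid @ w_ref + b_ref
            np.testing.assert_allclose(dec, dec_ref, atol=1e-4)

    def test_predictions_match_reference_solver(self, rng):
        """Dual route: in-package voting equals the libSVM predict path."""
        from sklearn.svm import SVC

        for k in (2, 3, 4):
            X = rng.normal(size=(80, 3))
            y = np.array([f"c{int(i)}" for i in rng.integers(0, k, 80)])
            model = sersid.svm_train(X, y, 1.0)
            clf = SVC(kernel="linear", C=1.0).fit(X, y)
            grid = rng.normal(size=(100, 3))
            np.testing.assert_array_equal(
                sersid.svm_predict(model, grid), clf.predict(grid).astype(object)
            )

    def test_vote_tie_goes_to_earliest_label(self):
        """Engineered 3-way vote tie among A, B, C -> A wins."""
        # zero weights: decisions are the biases alone, for every input
        biases = {"AB": 1.0, "AC": -1.0, "AD": 1.0, "BC": 1.0, "BD": 1.0, "CD": 1.0}
        model = LinearClassifierModel(
            class_labels=("A", "B", "C", "D"),
            pair_weights=np.zeros((6, 2)),
            pair_biases=np.array([biases[p] for p in ("AB", "AC", "AD", "BC", "BD", "CD")]),
            cost_C=1.0,
        )
        # votes: A=2 (AB, AD), B=2 (BC, BD), C=2 (AC, CD), D=0
        assert sersid.svm_predict(model, np.zeros((1, 2)))[0] == "A"

    def test_training_order_permutation_stable(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([f"c{int(i)}" for i in rng.integers(0, 3, 40)])
        grid = rng.normal(size=(60, 3))
        base = sersid.svm_predict(sersid.svm_train(X, y, 1.0), grid)
        perm = rng.permutation(40)
        shuffled = sersid.svm_predict(sersid.svm_train(X[perm], y[perm], 1.0), grid)
        np.testing.assert_array_equal(base, shuffled)

    def test_prediction_row_independence(self, rng):
        X = rng.normal(size=(30, 2))
        y = ["A"] * 15 + ["B"] * 15
        model = sersid.svm_train(X, y, 1.0)
        grid = rng.normal(size=(10, 2))
        base = sersid.svm_predict(model, grid)
        extended = sersid.svm_predict(model, np.vstack([grid, np.zeros(2)]))
        np.testing.assert_array_equal(extended[:10], base)

    def test_single_class_rejected(self, rng):
        with pytest.raises(sersid.ValidationError):
            sersid.svm_train(rng.normal(size=(10, 2)), ["A"] * 10, 1.0)

    def test_held_out_accuracy_on_separable_data(self, rng):
        """>= 99% held-out accuracy on well-separated 4-class clouds."""
        correct = total = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
            X = np.vstack([r.normal(size=(30, 2)) * 0.5 + c for c in centers])
            y = np.repeat([f"c{i}" for i in range(4)], 30)
            idx = r.permutation(120)
            train, test = idx[:60], idx[60:]
            model = sersid.svm_train(X[train], y[train], 1.0)
            pred = sersid.svm_predict(model, X[test])
            correct += int(np.sum(pred == y[test].astype(object)))
            total += len(test)
        assert correct / total >= 0.99


class TestPersistence:
    def test_pca_round_trip(self, tmp_path, rng):
        model = sersid.pca_fit(rng.normal(size=(10, 6)), 3)
        path = tmp_path / "pca.txt"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.mean, model.mean, rtol=1e-10)
        np.testing.assert_allclose(back.loadings, model.loadings, rtol=1e-10)
        np.testing.assert_allclose(
            back.explained_variance_ratio, model.explained_variance_ratio, rtol=1e-10
        )

    def test_classifier_round_trip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(40, 3))
        y = [f"c{int(i)}" for i in rng.integers(0, 3, 40)]
        model = sersid.svm_train(X, y, 2.5)
        path = tmp_path / "svm.txt"
        save_model(model, path)
        back = load_model(path)
        assert back.class_labels == model.class_labels
        assert back.cost_C == 2.5
        grid = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(
            sersid.svm_predict(back, grid), sersid.svm_predict(model, grid)
        )
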