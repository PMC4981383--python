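import shutil
import subprocess

import numpy as np
import pytest

from mixmc.containers import NumericMatrix
from mixmc.splsda import (
    ConvergenceError,
    CvResult,
    cross_validate,
    default_keepx_grid,
    fit_splsda,
    predict,
    predict_per_component,
    soft_threshold_keep,
    transform,
    tune_keepx,
)


def nipals_pls2(X, Y, n_comp, max_iter=20000, tol=1e-13):
    """Independent dense PLS-2 reference: classic NIPALS iterating in
    sample space, regression deflation of both blocks on the X score."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    W = np.zeros((X.shape[1], n_comp))
    T = np.zeros((X.shape[0], n_comp))
    for h in range(n_comp):
        u = Y[:, np.argmax(Y.var(axis=0))].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t / (t @ t)
            u_new = Y @ c / (c @ c)
            if np.linalg.norm(u_new - u) < tol * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        p_vec = X.T @ t / (t @ t)
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, c)
        W[:, h], T[:, h] = w, t
    return W, T


def dummy(labels):
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        Y[np.asarray(labels) == cls, k] = 1.0
    return Y


def toy_problem(rng, n_per=10, p=20, shift=2.0, classes=("a", "b", "c")):
    labels = np.repeat(list(classes), n_per)
    X = rng.normal(size=(len(labels), p))
    for k, cls in enumerate(classes):
        X[labels == cls, k] += shift
    return X, labels


class TestSoftThreshold:
    def test_frozen_example(self):
        # threshold = 3rd largest |.| = 0.1; survivors shrunk, renormalized
        u = soft_threshold_keep(np.array([0.9, -0.5, 0.1]), keep=2)
        np.testing.assert_allclose(u, [0.8, -0.4, 0.0], atol=1e-12)
        u /= np.linalg.norm(u)
        np.testing.assert_allclose(u, [0.894427, -0.447214, 0.0], atol=1e-6)

    def test_keep_all_is_identity(self):
        u = np.array([0.3, -0.2, 0.5])
        np.testing.assert_allclose(soft_threshold_keep(u, 3), u)

    def test_exact_nnz_for_random_vectors(self, rng):
        for _ in range(20):
            p = rng.integers(3, 40)
            keep = int(rng.integers(1, p + 1))
            u = rng.normal(size=p)
            out = soft_threshold_keep(u, keep)
            assert np.count_nonzero(out) == keep
            # signs of survivors preserved
            nz = out != 0
            assert np.all(np.sign(out[nz]) == np.sign(u[nz]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold_keep(np.ones(3), 0)
        with pytest.raises(ValueError):
            soft_threshold_keep(np.ones(3), 4)


class TestFit:
    def test_dense_fit_matches_independent_nipals(self, rng):
        X, labels = toy_problem(rng, n_per=10, p=20)
        model = fit_splsda(X, labels, n_comp=3, keepX=None)
        W, T = nipals_pls2(X, dummy(labels), n_comp=3)
        for h in range(3):
            sign = np.sign(W[:, h] @ model.x_loadings[:, h]) or 1.0
            np.testing.assert_allclose(
                model.x_loadings[:, h], sign * W[:, h], atol=1e-8
            )
            np.testing.assert_allclose(
                model.x_scores[:, h], sign * T[:, h], atol=1e-8
            )

    def test_single_discriminative_feature_found_with_keepx_one(self, rng):
        X = rng.normal(size=(30, 8), scale=0.3)
        labels = np.array(["a"] * 15 + ["b"] * 15)
        X[:15, 0] += 5.0  # classes differ only on feature 0
        model = fit_splsda(X, labels, n_comp=1, keepX=1)
        nz = np.flatnonzero(model.x_loadings[:, 0])
        assert nz.tolist() == [0]

    def test_sparsity_exactness_random_keepx(self, rng):
        X, labels = toy_problem(rng, n_per=8, p=25)
        keepX = [int(rng.integers(1, 26)) for _ in range(3)]
        model = fit_splsda(X, labels, n_comp=3, keepX=keepX)
        nnz = np.count_nonzero(model.x_loadings, axis=0)
        assert nnz.tolist() == keepX

    def test_loadings_unit_norm_scores_orthogonal(self, rng):
        X, labels = toy_problem(rng)
        model = fit_splsda(X, labels, n_comp=3, keepX=[5, 5, 5])
        np.testing.assert_allclose(
            np.linalg.norm(model.x_loadings, axis=0), 1.0, atol=1e-10
        )
        T = model.x_scores
        G = T.T @ T
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_training_error_non_increasing_with_components(self, rng):
        X, labels = toy_problem(rng, n_per=12, p=15, shift=1.5)
        model = fit_splsda(X, labels, n_comp=3, keepX=[5, 5, 5])
        preds = predict_per_component(model, X)
        errs = [(preds[:, h] != labels).mean() for h in range(3)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_invalid_inputs_rejected(self, rng):
        X, labels = toy_problem(rng)
        with pytest.raises(ValueError, match="keepX"):
            fit_splsda(X, labels, n_comp=1, keepX=[999])
        with pytest.raises(ValueError, match="2 classes"):
            fit_splsda(X, ["a"] * len(labels), n_comp=1)

    def test_matches_mixomics_reference(self, rng, tmp_path):
        """Cross-check loadings against the mixOmics R implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        X, labels = toy_problem(rng, n_per=10, p=12)
        np.savetxt(tmp_path / "X.tsv", X, delimiter="\t")
        (tmp_path / "y.txt").write_text("\n".join(labels) + "\n")
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(mixOmics))\n'
            'X <- as.matrix(read.table("X.tsv", sep="\\t"))\n'
            'y <- factor(readLines("y.txt"))\n'
            'fit <- splsda(X, y, ncomp=2, keepX=c(4,4), scale=FALSE,'
            ' near.zero.var=FALSE)\n'
            'write.table(fit$loadings$X, "ref_loadings.tsv", sep="\\t",'
            ' col.names=FALSE, row.names=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", script.name], cwd=tmp_path,
            capture_output=True, text=True, timeout=300,
        )
        if proc.returncode != 0:
            pytest.skip(f"mixOmics unavailable: {proc.stderr[-200:]}")
        ref = np.loadtxt(tmp_path / "ref_loadings.tsv", delimiter="\t")
        model = fit_splsda(X, labels, n_comp=2, keepX=[4, 4])
        for h in range(2):
            a, b = model.x_loadings[:, h], ref[:, h]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-3


class TestPredict:
    def test_perfectly_separated_training_set(self, rng):
        X, labels = toy_problem(rng, shift=6.0)
        model = fit_splsda(X, labels, n_comp=2, keepX=[4, 4])
        assert (predict(model, X) != labels).sum() == 0

    def test_centroid_agrees_with_brute_force(self, rng):
        X, labels = toy_problem(rng)
        model = fit_splsda(X, labels, n_comp=2, keepX=[6, 6])
        Xnew = rng.normal(size=(15, X.shape[1]))
        preds = predict(model, Xnew, distance="centroid", train_labels=labels)
        # brute force nearest centroid in score space
        Tn = transform(model, Xnew)
        classes = sorted(set(labels))
        cents = {c: model.x_scores[labels == c].mean(axis=0) for c in classes}
        for i in range(15):
            expected = min(classes, key=lambda c: np.linalg.norm(Tn[i] - cents[c]))
            assert preds[i] == expected

    def test_mahalanobis_runs_and_is_valid(self, rng):
        X, labels = toy_problem(rng)
        model = fit_splsda(X, labels, n_comp=2, keepX=[6, 6])
        preds = predict(model, X, distance="mahalanobis", train_labels=labels)
        assert set(preds) <= set(labels)

    def test_feature_mismatch_rejected(self, rng):
        X, labels = toy_problem(rng)
        model = fit_splsda(X, labels, n_comp=1, keepX=[3])
        with pytest.raises(ValueError, match="feature"):
            predict(model, rng.normal(size=(3, X.shape[1] + 1)))


class TestCrossValidate:
    def test_separable_data_near_zero_error(self, rng):
        X, labels = toy_problem(rng, n_per=20, p=15, shift=6.0,
                                classes=("a", "b"))
        cv = cross_validate(X, labels, n_comp=1, keepX=5, folds=5,
                            repeats=2, seed=11)
        assert cv.overall_error[0] < 0.02

    def test_fixed_seed_reproduces_result(self, rng):
        X, labels = toy_problem(rng)
        a = cross_validate(X, labels, n_comp=2, keepX=5, folds=4, repeats=3, seed=9)
        b = cross_validate(X, labels, n_comp=2, keepX=5, folds=4, repeats=3, seed=9)
        np.testing.assert_array_equal(a.overall_error, b.overall_error)
        np.testing.assert_array_equal(a.per_class_error, b.per_class_error)

    def test_different_seed_changes_folds(self, rng):
        X = rng.normal(size=(40, 30))
        labels = np.array(["a", "b"] * 20)
        a = cross_validate(X, labels, n_comp=1, keepX=10, folds=5, seed=1)
        b = cross_validate(X, labels, n_comp=1, keepX=10, folds=5, seed=2)
        assert not np.array_equal(a.per_class_error.to_numpy(),
                                  b.per_class_error.to_numpy())

    def test_permuted_labels_near_chance(self, rng):
        """Balanced 2-class noise: CV error should hover around 0.5."""
        X = rng.normal(size=(60, 30))
        labels = np.array(["a", "b"] * 30)
        cv = cross_validate(X, labels, n_comp=1, keepX=10, folds=5,
                            repeats=4, seed=5)
        assert 0.35 < cv.overall_error[0] < 0.65

    def test_balanced_error_equals_overall_for_balanced_classes(self, rng):
        X, labels = toy_problem(rng, n_per=10)
        cv = cross_validate(X, labels, n_comp=2, keepX=5, folds=5, seed=3)
        np.testing.assert_allclose(
            cv.balanced_error, cv.overall_error, atol=0.15
        )

    def test_multilevel_grouping_keeps_subjects_together(self, rng):
        """Subject-level folding: within-decomposition recomputed per split
        without error even for strong subject effects."""
        n_subj, n_cls = 12, 3
        subjects = np.repeat([f"s{i}" for i in range(n_subj)], n_cls)
        labels = np.tile([f"c{k}" for k in range(n_cls)], n_subj)
        subj_eff = rng.normal(size=(n_subj, 8)) * 3
        X = rng.normal(size=(n_subj * n_cls, 8))
        X += np.repeat(subj_eff, n_cls, axis=0)
        for k in range(n_cls - 1):
            X[labels == f"c{k}", k] += 1.0
        cv = cross_validate(X, labels, subjects=subjects, n_comp=2, keepX=4,
                            folds=4, repeats=2, seed=13, multilevel=True)
        assert np.all(cv.overall_error <= 1.0)


class TestTune:
    def test_grid_minimum_is_chosen_with_parsimony_ties(self, rng):
        X, labels = toy_problem(rng, n_per=15, p=12, shift=5.0)
        tuned = tune_keepx(X, labels, keepX_grid=[2, 4, 8], max_comp=2,
                           folds=4, repeats=2, seed=21)
        for h, k in enumerate(tuned.chosen_keepX, start=1):
            grid = tuned.error_surface[tuned.error_surface["component"] == h]
            best = grid["mean_error"].min()
            ties = grid[grid["mean_error"] <= best + 1e-12]["keepX"]
            assert k == ties.min()

    def test_full_grid_reduces_to_dense_model(self, rng):
        X, labels = toy_problem(rng, n_per=8, p=10, shift=4.0)
        tuned = tune_keepx(X, labels, keepX_grid=[10], max_comp=1,
                           folds=4, repeats=2, seed=2)
        assert tuned.chosen_keepX == [10]
        dense = fit_splsda(X, labels, n_comp=1, keepX=None)
        np.testing.assert_allclose(
            np.abs(tuned.final_model.x_loadings),
            np.abs(dense.x_loadings), atol=1e-8,
        )

    def test_error_surface_reproducible_under_seed(self, rng):
        X, labels = toy_problem(rng, n_per=8, p=10)
        a = tune_keepx(X, labels, keepX_grid=[3, 6], max_comp=1,
                       folds=4, repeats=2, seed=8)
        b = tune_keepx(X, labels, keepX_grid=[3, 6], max_comp=1,
                       folds=4, repeats=2, seed=8)
        np.testing.assert_array_equal(
            a.error_surface["mean_error"], b.error_surface["mean_error"]
        )

    def test_grid_value_beyond_p_rejected(self, rng):
        X, labels = toy_problem(rng, p=10)
        with pytest.raises(ValueError, match="grid"):
            tune_keepx(X, labels, keepX_grid=[500], max_comp=1, folds=3)

    def test_default_grid_capped_at_p(self):
        assert max(default_keepx_grid(37)) <= 37
        assert default_keepx_grid(300)[-1] == 200
        assert 5 in default_keepx_grid(300)
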