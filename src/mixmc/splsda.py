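"""Multiclass sparse partial least squares discriminant analysis.

PLS-DA regresses a centered dummy matrix Y (one indicator column per
class) on the feature matrix X by maximizing, component after component,
the covariance between linear combinations of the two blocks. The sparse
variant applies a componentwise Lasso (soft-thresholding of the X weight
vector) so that exactly ``keepX[h]`` features carry nonzero weight on
component h — those are the discriminative features the model selects.

The number of features per component (and the number of components) is
chosen by repeated stratified cross-validation: the grid value with the
lowest mean classification error wins, parsimony breaking ties.

For repeated-measures designs the model is fit on the within-subject
matrix (see :mod:`mixmc.multilevel`); cross-validation then folds at the
subject level and recomputes the decomposition inside each training split
so that subject means never leak across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .containers import NumericMatrix
from .multilevel import within_variation

__all__ = [
    "SplsdaModel",
    "CvResult",
    "TuneResult",
    "fit_splsda",
    "predict",
    "predict_per_component",
    "cross_validate",
    "tune_keepx",
    "default_keepx_grid",
]

logger = logging.getLogger(__name__)

# later components sit on noise-dominated residuals whose two leading
# singular directions can be near-degenerate; the alternation then crawls
# through a saddle and needs well over 500 iterations to settle
_MAX_ITER = 5000
_TOL = 1e-6


class ConvergenceError(RuntimeError):
    pass


def soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``u`` so exactly ``keep`` entries stay nonzero.

    The threshold is the (keep+1)-th largest absolute value; survivors are
    shrunk toward zero by it, signs preserved. Exact ties at the threshold
    (measure zero for continuous data) are retained with a negligible
    weight so the sparsity contract holds.
    """
    p = u.size
    if not 1 <= keep <= p:
        raise ValueError(f"keepX must lie in [1, {p}], got {keep}")
    if keep == p:
        return u.copy()
    absu = np.abs(u)
    order = np.argsort(-absu, kind="stable")
    lam = absu[order[keep]]
    out = np.zeros_like(u)
    kept = order[:keep]
    out[kept] = np.sign(u[kept]) * (absu[kept] - lam)
    ties = kept[out[kept] == 0]
    if ties.size:
        out[ties] = np.sign(u[ties]) * max(lam, 1.0) * 1e-12
    return out


@dataclass
class SplsdaModel:
    """Fitted sparse PLS-DA model.

    ``x_loadings`` (p x H) hold the unit-norm sparse weight vectors,
    ``x_scores`` (n x H) the latent variates t_h = X_h u_h. ``x_proj`` and
    ``y_proj`` are the deflation regressors (P and C of the PLS recursion)
    needed for prediction.
    """

    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_proj: np.ndarray
    y_proj: np.ndarray
    keepX: list[int]
    class_labels: list[str]
    feature_ids: list[str]
    sample_ids: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def n_comp(self) -> int:
        return self.x_loadings.shape[1]

    def selected_features(self, component: int | None = None) -> list[str]:
        """Feature ids with nonzero loading on one component (or any)."""
        if component is None:
            mask = np.any(self.x_loadings != 0, axis=1)
        else:
            mask = self.x_loadings[:, component] != 0
        return [f for f, m in zip(self.feature_ids, mask) if m]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x_scores,
            index=self.sample_ids,
            columns=[f"comp{i + 1}" for i in range(self.n_comp)],
        )

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x_loadings,
            index=self.feature_ids,
            columns=[f"comp{i + 1}" for i in range(self.n_comp)],
        )


def _dummy_matrix(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((labels.size, len(classes)))
    for k, cls in enumerate(classes):
        Y[labels == cls, k] = 1.0
    return Y


def _fix_sign(u: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry is positive."""
    i = int(np.argmax(np.abs(u)))
    return -u if u[i] < 0 else u


def fit_splsda(
    X: NumericMatrix | np.ndarray,
    labels: np.ndarray | list[str],
    n_comp: int = 2,
    keepX: int | list[int] | None = None,
    feature_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X
        Samples x features matrix (columns are centered internally). With a
        repeated-measures design, pass the within-subject matrix.
    labels
        Class label per row; at least two distinct classes.
    n_comp
        Number of latent components H.
    keepX
        Number of features with nonzero weight per component — a single
        integer, a list of length ``n_comp``, or None for the dense model
        (all p features kept).
    """
    if isinstance(X, NumericMatrix):
        feature_ids = list(X.feature_ids)
        sample_ids = list(X.sample_ids)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(Xv.shape[1])]
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(Xv.shape[0])]
    labels = np.asarray([str(l) for l in labels])
    n, p = Xv.shape
    if labels.size != n:
        raise ValueError(f"{labels.size} labels for {n} rows")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for discriminant analysis")
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    if keepX is None:
        keepX = [p] * n_comp
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * n_comp
    else:
        keepX = [int(k) for k in keepX]
    if len(keepX) != n_comp:
        raise ValueError(f"keepX has {len(keepX)} entries for {n_comp} components")
    for k in keepX:
        if not 1 <= k <= p:
            raise ValueError(f"keepX value {k} outside [1, {p}]")

    Y = _dummy_matrix(labels, classes)
    x_mean = Xv.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xh = Xv - x_mean
    Yh = Y - y_mean

    K = len(classes)
    U = np.zeros((p, n_comp))
    V = np.zeros((K, n_comp))
    T = np.zeros((n, n_comp))
    S = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    C = np.zeros((K, n_comp))

    for h in range(n_comp):
        M = Xh.T @ Yh  # p x K cross-covariance
        # dominant singular pair as the starting point
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        u_prev = None
        for _ in range(_MAX_ITER):
            u_new = soft_threshold_keep(M @ v, keepX[h])
            nrm = np.linalg.norm(u_new)
            if nrm == 0:
                raise ConvergenceError(
                    f"component {h + 1}: weight vector collapsed to zero"
                )
            u_new = u_new / nrm
            # v proportional to M'u keeps the covariance u'Mv non-negative,
            # so the alternation is a monotone ascent
            v_new = M.T @ u_new
            v_new = v_new / np.linalg.norm(v_new)
            if np.linalg.norm(u_new - u) < _TOL:
                u, v = u_new, v_new
                break
            # the thresholded alternation can settle into a 2-cycle between
            # two equally-covariant supports; accept the current iterate
            if u_prev is not None and np.linalg.norm(u_new - u_prev) < _TOL:
                logger.debug("component %d: 2-cycle detected, accepting iterate", h + 1)
                u, v = u_new, v_new
                break
            u_prev, u, v = u, u_new, v_new
        else:
            raise ConvergenceError(
                f"component {h + 1}: no convergence in {_MAX_ITER} iterations"
            )
        # deterministic sign convention, applied jointly so u'Mv is unchanged
        if u[int(np.argmax(np.abs(u)))] < 0:
            u, v = -u, -v

        t = Xh @ u
        tt = t @ t
        if tt <= 0:
            raise ConvergenceError(f"component {h + 1}: degenerate score vector")
        c = Yh.T @ t / tt
        ph = Xh.T @ t / tt
        s = Yh @ v

        U[:, h], V[:, h], T[:, h], S[:, h] = u, v, t, s
        P[:, h], C[:, h] = ph, c
        # regression deflation of both blocks on the X score
        Xh = Xh - np.outer(t, ph)
        Yh = Yh - np.outer(t, c)

    return SplsdaModel(
        x_loadings=U,
        y_loadings=V,
        x_scores=T,
        y_scores=S,
        x_proj=P,
        y_proj=C,
        keepX=keepX,
        class_labels=classes,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def _rotation(model: SplsdaModel) -> np.ndarray:
    """W* = U (P'U)^-1, mapping centered X to score space in one product."""
    PU = model.x_proj.T @ model.x_loadings
    return model.x_loadings @ np.linalg.inv(PU)


def transform(model: SplsdaModel, Xnew: NumericMatrix | np.ndarray) -> np.ndarray:
    """Project new samples onto the model's latent components."""
    Xv = Xnew.values if isinstance(Xnew, NumericMatrix) else np.asarray(Xnew, float)
    if Xv.shape[1] != model.x_loadings.shape[0]:
        raise ValueError(
            f"feature mismatch: model has {model.x_loadings.shape[0]} features, "
            f"input has {Xv.shape[1]}"
        )
    if isinstance(Xnew, NumericMatrix) and Xnew.feature_ids != model.feature_ids:
        raise ValueError("feature ids of new data do not match the model")
    return (Xv - model.x_mean) @ _rotation(model)


def predict_per_component(
    model: SplsdaModel,
    Xnew: NumericMatrix | np.ndarray,
    distance: str = "max",
    train_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted class per row for each truncation of the model.

    Returns an (n_new, H) array of labels: column h-1 is the prediction of
    the model restricted to its first h components. ``train_labels`` is
    required for the centroid and mahalanobis distances.
    """
    Tn = transform(model, Xnew)
    n_new, H = Tn.shape
    out = np.empty((n_new, H), dtype=object)
    classes = np.asarray(model.class_labels)
    if distance == "max":
        for h in range(1, H + 1):
            ypred = Tn[:, :h] @ model.y_proj[:, :h].T + model.y_mean
            out[:, h - 1] = classes[np.argmax(ypred, axis=1)]
    elif distance in ("centroid", "mahalanobis"):
        if train_labels is None:
            raise ValueError(f"distance={distance!r} needs train_labels")
        train_labels = np.asarray([str(l) for l in train_labels])
        for h in range(1, H + 1):
            out[:, h - 1] = _nearest_centroid(
                model.x_scores[:, :h], train_labels, Tn[:, :h], classes,
                mahalanobis=(distance == "mahalanobis"),
            )
    else:
        raise ValueError(f"unknown prediction distance {distance!r}")
    return out


def predict(
    model: SplsdaModel,
    Xnew: NumericMatrix | np.ndarray,
    distance: str = "max",
    train_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted class per row using the full model.

    ``distance='max'`` takes the argmax of the predicted dummy outcome;
    ``'centroid'`` assigns the nearest class centroid in latent score
    space (``train_labels`` required); ``'mahalanobis'`` uses the pooled
    within-class score covariance for a naive Mahalanobis distance.
    """
    Tn = transform(model, Xnew)
    classes = np.asarray(model.class_labels)
    if distance == "max":
        ypred = Tn @ model.y_proj.T + model.y_mean
        return classes[np.argmax(ypred, axis=1)]
    if distance in ("centroid", "mahalanobis"):
        if train_labels is None:
            raise ValueError(f"distance={distance!r} needs train_labels")
        train_labels = np.asarray([str(l) for l in train_labels])
        return _nearest_centroid(
            model.x_scores, train_labels, Tn, classes,
            mahalanobis=(distance == "mahalanobis"),
        )
    raise ValueError(f"unknown prediction distance {distance!r}")


def _nearest_centroid(
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    new_scores: np.ndarray,
    classes: np.ndarray,
    mahalanobis: bool = False,
) -> np.ndarray:
    centroids = np.stack(
        [train_scores[train_labels == cls].mean(axis=0) for cls in classes]
    )
    if mahalanobis:
        resid = train_scores - centroids[
            np.searchsorted(classes, train_labels)
        ]
        cov = np.cov(resid, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(resid.shape[1])
        VI = np.linalg.inv(cov)
    else:
        VI = np.eye(train_scores.shape[1])
    diffs = new_scores[:, None, :] - centroids[None, :, :]
    d2 = np.einsum("nkp,pq,nkq->nk", diffs, VI, diffs)
    return classes[np.argmin(d2, axis=1)]


# --------------------------------------------------------------------------
# cross-validation


@dataclass
class CvResult:
    """Classification error rates per component count from repeated CV."""

    overall_error: np.ndarray  # mean over repeats, per component 1..H
    overall_sd: np.ndarray
    balanced_error: np.ndarray
    balanced_sd: np.ndarray
    per_class_error: pd.DataFrame  # classes x components, mean over repeats
    folds: int
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        for arr in (self.overall_error, self.balanced_error):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("error rates must lie in [0, 1]")
        if np.any(self.overall_sd < 0) or np.any(self.balanced_sd < 0):
            raise ValueError("standard deviations must be >= 0")


def _make_splits(
    labels: np.ndarray,
    subjects: np.ndarray | None,
    folds: int,
    seed: int,
    grouped: bool,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One set of CV splits whose training halves contain every class."""
    classes = set(labels)
    for attempt in range(10):
        rs = seed + 1000 * attempt
        if grouped and subjects is not None:
            splitter = StratifiedGroupKFold(
                n_splits=folds, shuffle=True, random_state=rs
            )
            split_iter = splitter.split(labels[:, None], labels, groups=subjects)
        else:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(labels[:, None], labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits = [(tr, te) for tr, te in split_iter]
        ok = all(
            set(labels[tr]) == classes and te.size > 0 for tr, te in splits
        )
        if ok:
            if attempt:
                logger.warning("refolded %d times to keep all classes in training", attempt)
            return splits
    raise RuntimeError("could not build folds keeping every class in training")


def _fold_matrices(
    Xv: np.ndarray,
    subjects: np.ndarray | None,
    train: np.ndarray,
    test: np.ndarray,
    multilevel: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Training/test matrices for one fold, recomputing the within-subject
    decomposition on each side of the split when multilevel is requested."""
    if not multilevel:
        return Xv[train], Xv[test]
    assert subjects is not None
    nm_train = NumericMatrix(
        values=Xv[train],
        sample_ids=[f"r{i}" for i in train],
        feature_ids=[f"f{j}" for j in range(Xv.shape[1])],
    )
    nm_test = NumericMatrix(
        values=Xv[test],
        sample_ids=[f"r{i}" for i in test],
        feature_ids=[f"f{j}" for j in range(Xv.shape[1])],
    )
    w_train = within_variation(nm_train, subjects[train], allow_singletons=True)
    w_test = within_variation(nm_test, subjects[test], allow_singletons=True)
    return w_train.within.values, w_test.within.values


def cross_validate(
    X: NumericMatrix | np.ndarray,
    labels: np.ndarray | list[str],
    subjects: np.ndarray | list[str] | None = None,
    n_comp: int = 2,
    keepX: int | list[int] | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    distance: str = "max",
    multilevel: bool = False,
    legacy_cv: bool = False,
) -> CvResult:
    """Repeated stratified k-fold cross-validation of sparse PLS-DA.

    Reports the mean and standard deviation (across repeats) of the
    overall and balanced classification error rates for every component
    count 1..``n_comp``, plus per-class error rates.

    With ``multilevel=True`` (and ``subjects`` given) folds are drawn at
    the subject level and the within-subject decomposition is recomputed
    on each training split, so subject means never leak between training
    and test. ``legacy_cv=True`` instead folds rows of the precomputed
    within-matrix directly (pass the within-matrix as ``X``).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    Xv = X.values if isinstance(X, NumericMatrix) else np.asarray(X, float)
    labels = np.asarray([str(l) for l in labels])
    subj = None if subjects is None else np.asarray([str(s) for s in subjects])
    if multilevel and not legacy_cv and subj is None:
        raise ValueError("multilevel CV needs subject ids")
    grouped = multilevel and not legacy_cv
    recompute = multilevel and not legacy_cv
    classes = sorted(set(labels))

    per_repeat_overall = np.zeros((repeats, n_comp))
    per_repeat_balanced = np.zeros((repeats, n_comp))
    per_class_sum = np.zeros((len(classes), n_comp))

    for r in range(repeats):
        splits = _make_splits(labels, subj, folds, seed + r, grouped)
        truth_all: list[np.ndarray] = []
        pred_all: list[np.ndarray] = []
        for train, test in splits:
            Xtr, Xte = _fold_matrices(Xv, subj, train, test, recompute)
            model = fit_splsda(Xtr, labels[train], n_comp=n_comp, keepX=keepX)
            if distance == "max":
                preds = predict_per_component(model, Xte, distance="max")
            else:
                Tn = transform(model, Xte)
                preds = np.empty((test.size, n_comp), dtype=object)
                for h in range(1, n_comp + 1):
                    preds[:, h - 1] = _nearest_centroid(
                        model.x_scores[:, :h], labels[train], Tn[:, :h],
                        np.asarray(model.class_labels),
                        mahalanobis=(distance == "mahalanobis"),
                    )
            truth_all.append(labels[test])
            pred_all.append(preds)
        truth = np.concatenate(truth_all)
        preds = np.vstack(pred_all)
        wrong = preds != truth[:, None]
        per_repeat_overall[r] = wrong.mean(axis=0)
        class_err = np.stack(
            [wrong[truth == cls].mean(axis=0) for cls in classes]
        )
        per_repeat_balanced[r] = class_err.mean(axis=0)
        per_class_sum += class_err

    comp_cols = [f"comp{h}" for h in range(1, n_comp + 1)]
    return CvResult(
        overall_error=per_repeat_overall.mean(axis=0),
        overall_sd=per_repeat_overall.std(axis=0, ddof=1 if repeats > 1 else 0),
        balanced_error=per_repeat_balanced.mean(axis=0),
        balanced_sd=per_repeat_balanced.std(axis=0, ddof=1 if repeats > 1 else 0),
        per_class_error=pd.DataFrame(
            per_class_sum / repeats, index=classes, columns=comp_cols
        ),
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


# --------------------------------------------------------------------------
# tuning


@dataclass
class TuneResult:
    """Cross-validated error surface and the chosen sparsity per component."""

    error_surface: pd.DataFrame  # columns: component, keepX, mean_error, sd_error
    chosen_keepX: list[int]
    n_comp: int
    final_model: SplsdaModel
    seed: int

    def __post_init__(self) -> None:
        for h, k in enumerate(self.chosen_keepX, start=1):
            grid = self.error_surface[self.error_surface["component"] == h]
            best = grid["mean_error"].min()
            row = grid[grid["keepX"] == k]
            if row.empty or row["mean_error"].iloc[0] > best + 1e-12:
                raise ValueError(
                    f"chosen keepX={k} does not attain the minimum on component {h}"
                )


def default_keepx_grid(p: int) -> list[int]:
    """Sparsity grid {5,10,...,50} union {60,80,...,200}, capped at p."""
    grid = sorted(set(list(range(5, 51, 5)) + list(range(60, 201, 20))))
    grid = [k for k in grid if k <= p]
    if not grid:
        grid = sorted({max(1, p // 2), p})
    return grid


def tune_keepx(
    X: NumericMatrix | np.ndarray,
    labels: np.ndarray | list[str],
    subjects: np.ndarray | list[str] | None = None,
    keepX_grid: list[int] | None = None,
    max_comp: int = 3,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    distance: str = "max",
    multilevel: bool = False,
    legacy_cv: bool = False,
) -> TuneResult:
    """Sequential per-component tuning of the sparsity parameter keepX.

    For each component h, with earlier components fixed at their chosen
    keepX, every grid value is evaluated by repeated cross-validation (the
    same folds for every candidate) and the value with the lowest mean
    error at component h is chosen, ties going to the smallest keepX.
    Components stop being added once the mean error no longer improves on
    the previous component by more than one standard deviation. The final
    model is refit on the entire data set.
    """
    Xv = X.values if isinstance(X, NumericMatrix) else np.asarray(X, float)
    p = Xv.shape[1]
    if keepX_grid is None:
        keepX_grid = default_keepx_grid(p)
    keepX_grid = sorted(set(int(k) for k in keepX_grid))
    for k in keepX_grid:
        if not 1 <= k <= p:
            raise ValueError(f"grid value {k} outside [1, {p}]")
    labels_arr = np.asarray([str(l) for l in labels])
    subj = None if subjects is None else np.asarray([str(s) for s in subjects])
    grouped = multilevel and not legacy_cv
    recompute = multilevel and not legacy_cv

    all_splits = [
        _make_splits(labels_arr, subj, folds, seed + r, grouped)
        for r in range(repeats)
    ]

    rows = []
    chosen: list[int] = []
    prev_best = np.inf
    for h in range(1, max_comp + 1):
        stats: dict[int, tuple[float, float]] = {}
        for k in keepX_grid:
            keepX = chosen + [k]
            per_repeat = np.zeros(repeats)
            for r, splits in enumerate(all_splits):
                wrong_n = 0
                total_n = 0
                for train, test in splits:
                    Xtr, Xte = _fold_matrices(Xv, subj, train, test, recompute)
                    model = fit_splsda(
                        Xtr, labels_arr[train], n_comp=h, keepX=keepX
                    )
                    preds = predict(
                        model, Xte, distance=distance,
                        train_labels=labels_arr[train],
                    )
                    wrong_n += int((preds != labels_arr[test]).sum())
                    total_n += test.size
                per_repeat[r] = wrong_n / total_n
            mean_err = float(per_repeat.mean())
            sd_err = float(per_repeat.std(ddof=1 if repeats > 1 else 0))
            stats[k] = (mean_err, sd_err)
            rows.append(
                {"component": h, "keepX": k, "mean_error": mean_err, "sd_error": sd_err}
            )
        best_k = min(stats, key=lambda k: (stats[k][0], k))
        best_err, best_sd = stats[best_k]
        logger.info(
            "component %d: keepX=%d, mean error %.4f (sd %.4f)",
            h, best_k, best_err, best_sd,
        )
        if h > 1 and not (prev_best - best_err > best_sd):
            logger.info("component %d adds no improvement > 1 sd; stopping", h)
            break
        chosen.append(best_k)
        prev_best = best_err

    surface = pd.DataFrame(rows)
    if recompute:
        nm = NumericMatrix(
            values=Xv,
            sample_ids=[f"r{i}" for i in range(Xv.shape[0])],
            feature_ids=[f"f{j}" for j in range(p)],
        )
        fit_X = within_variation(nm, subj, allow_singletons=True).within.values
    else:
        fit_X = Xv
    feature_ids = list(X.feature_ids) if isinstance(X, NumericMatrix) else None
    sample_ids = list(X.sample_ids) if isinstance(X, NumericMatrix) else None
    final = fit_splsda(
        fit_X, labels_arr, n_comp=len(chosen), keepX=chosen,
        feature_ids=feature_ids, sample_ids=sample_ids,
    )
    return TuneResult(
        error_surface=surface,
        chosen_keepX=chosen,
        n_comp=len(chosen),
        final_model=final,
        seed=seed,
    )
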