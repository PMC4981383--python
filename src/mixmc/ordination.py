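"""Unsupervised exploration: PCA on transformed data, PCoA on dissimilarities.

PCA is applied to log-ratio coordinates (ILR by preference, whose p-1
orthonormal coordinates avoid the singular covariance of CLR data).
Principal coordinate analysis (classical multidimensional scaling) embeds
any sample-wise dissimilarity matrix — typically Bray-Curtis on counts —
into Euclidean coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SkPCA

from .containers import CountTable, NumericMatrix

__all__ = ["OrdinationResult", "DistanceMatrix", "pca", "bray_curtis", "pcoa"]

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Low-dimensional sample coordinates with per-axis explained variance."""

    scores: NumericMatrix  # samples x components
    explained_fraction: np.ndarray
    loadings: NumericMatrix | None = None  # PCA only
    eigenvalues: np.ndarray | None = None  # PCoA only
    n_negative_eigenvalues: int = 0

    def __post_init__(self) -> None:
        ef = np.asarray(self.explained_fraction, dtype=float)
        if np.any(ef < -1e-12) or np.any(ef > 1 + 1e-12):
            raise ValueError("explained fractions must lie in [0, 1]")
        if np.any(np.diff(ef) > 1e-10):
            raise ValueError("explained fractions must be non-increasing")
        if ef.sum() > 1 + 1e-8:
            raise ValueError("explained fractions must sum to <= 1")
        self.explained_fraction = ef


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("one sample id per row required")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(self.values))) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")


def pca(
    X: NumericMatrix,
    n_comp: int = 2,
    center: bool = True,
    scale: bool = False,
) -> OrdinationResult:
    """Principal component analysis of a samples x features matrix.

    Log-ratio coordinates share a scale, so the default is centering
    without unit-variance scaling.
    """
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_comp <= max_comp:
        raise ValueError(f"n_comp must lie in [1, {max_comp}] for a {n}x{p} matrix")
    vals = X.values.astype(float)
    if scale:
        sd = vals.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.argmax(sd == 0))
            raise ValueError(
                f"constant column {X.feature_ids[j]!r} cannot be scaled"
            )
        mean = vals.mean(axis=0)
        vals = (vals - mean) / sd
        center = False  # already centered above
    model = _SkPCA(n_components=n_comp, svd_solver="full")
    if not center:
        # sklearn always centers; shift so its centering is a no-op
        vals = vals - vals.mean(axis=0)
    coords = model.fit_transform(vals)
    comp_ids = [f"PC{i + 1}" for i in range(n_comp)]
    return OrdinationResult(
        scores=NumericMatrix(
            values=coords, sample_ids=list(X.sample_ids), feature_ids=comp_ids
        ),
        explained_fraction=model.explained_variance_ratio_,
        loadings=NumericMatrix(
            values=model.components_.T,
            sample_ids=list(X.feature_ids),
            feature_ids=comp_ids,
        ),
    )


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    d(A, B) = 1 - 2 * sum_k min(A_k, B_k) / (sum A + sum B), in [0, 1].
    """
    counts = table.values.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} is all-zero; Bray-Curtis undefined")
    dist = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(values=dist, sample_ids=list(table.sample_ids))


def pcoa(D: DistanceMatrix, n_comp: int = 2) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling) of a dissimilarity.

    Eigendecomposes the double-centered matrix -0.5 * J D^2 J; coordinates
    are eigenvectors scaled by sqrt of their (positive) eigenvalues.
    Negative eigenvalues — present when D is non-Euclidean, e.g.
    Bray-Curtis — are dropped and their count reported; explained fractions
    are taken over the positive eigenvalues.
    """
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    n = D.values.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.values**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    n_pos = int(positive.sum())
    n_neg = int((eigvals < -tol).sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalue; dissimilarity is degenerate")
    if n_neg:
        logger.info("PCoA: dropped %d negative eigenvalues", n_neg)
    k = min(n_comp, n_pos)
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)
    comp_ids = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=NumericMatrix(
            values=coords, sample_ids=list(D.sample_ids), feature_ids=comp_ids
        ),
        explained_fraction=lam / eigvals[positive].sum(),
        eigenvalues=eigvals[:n_pos],
        n_negative_eigenvalues=n_neg,
    )
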