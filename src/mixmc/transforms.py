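"""Normalizations mapping OTU counts to analyzable matrices.

Two branches are supported:

* **Log-ratio branch** — total sum scaling (TSS) turns counts into
  proportions on the simplex; the centered log ratio (CLR) or isometric log
  ratio (ILR) transform then maps the simplex to Euclidean space. Counts
  must be strictly positive first (see :mod:`mixmc.preprocess`).
* **Cumulative sum scaling (CSS)** — per-sample scaling by the partial sum
  of counts up to a data-driven quantile, resisting the bias that total-sum
  scaling suffers under community undersampling.

CLR of a composition x = (x1..xp) is y_j = log(x_j / g(x)) with g the
geometric mean; rows of the output sum to zero. ILR uses pivot coordinates,
y_i = sqrt(i/(i+1)) * log(g(x_1..x_i) / x_{i+1}), i = 1..p-1, an orthonormal
basis of the CLR hyperplane, so Euclidean distance on ILR coordinates is
the Aitchison distance.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CompositionMatrix, CountTable, NumericMatrix

__all__ = [
    "tss",
    "clr",
    "ilr",
    "ilr_basis",
    "css",
    "css_auto_percentile",
    "normalize",
]

logger = logging.getLogger(__name__)


def tss(table: CountTable) -> CompositionMatrix:
    """Total sum scaling: divide each count by its sample's total.

    Every entry must be positive (add a pseudocount first on the log-ratio
    branch); the output rows live on the unit simplex.
    """
    counts = table.values.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    if np.any(counts <= 0):
        raise ValueError(
            "TSS for the log-ratio branch needs strictly positive counts; "
            "apply add_pseudocount (or multiplicative replacement) first"
        )
    return CompositionMatrix(
        values=counts / totals[:, None],
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


def clr(comp: CompositionMatrix) -> NumericMatrix:
    """Centered log ratio transform; output rows sum to zero."""
    logx = np.log(comp.values)
    y = logx - logx.mean(axis=1, keepdims=True)
    return NumericMatrix(
        values=y,
        sample_ids=list(comp.sample_ids),
        feature_ids=list(comp.feature_ids),
    )


def ilr_basis(p: int) -> np.ndarray:
    """(p-1) x p pivot-coordinate contrast matrix V with V @ V.T = I and V @ 1 = 0.

    Row i (1-based): sqrt(i/(i+1)) * (1/i, ..., 1/i, -1, 0, ..., 0).
    """
    if p < 2:
        raise ValueError("need at least 2 parts for ILR")
    V = np.zeros((p - 1, p))
    for i in range(1, p):
        V[i - 1, :i] = np.sqrt(i / (i + 1.0)) / i
        V[i - 1, i] = -np.sqrt(i / (i + 1.0))
    return V


def ilr(comp: CompositionMatrix) -> NumericMatrix:
    """Isometric log ratio transform in pivot coordinates (p-1 features)."""
    p = comp.n_features
    V = ilr_basis(p)
    y = np.log(comp.values) @ V.T  # V @ 1 = 0, so the geometric mean cancels
    return NumericMatrix(
        values=y,
        sample_ids=list(comp.sample_ids),
        feature_ids=[f"ilr_{i + 1}" for i in range(p - 1)],
    )


def css_auto_percentile(
    table: CountTable, rel_change: float = 0.1
) -> float:
    """Data-driven CSS quantile level.

    For each candidate level l, take each sample's l-quantile of its
    positive counts and measure the median absolute deviation of those
    sample quantiles from their across-sample mean. Scanning upward from
    the median, the chosen level is the smallest at which the relative
    change of this instability measure between successive levels exceeds
    ``rel_change``; 0.5 when the scan never triggers or is unstable.
    """
    counts = table.values.astype(float)
    levels = np.arange(0.50, 1.00, 0.01)
    quantiles = np.empty((len(levels), table.n_samples))
    for j in range(table.n_samples):
        positive = np.sort(counts[j][counts[j] > 0])
        if positive.size == 0:
            raise ValueError(f"sample {table.sample_ids[j]!r} has no counts")
        quantiles[:, j] = np.quantile(positive, levels)
    ref = quantiles.mean(axis=1, keepdims=True)
    mad = np.median(np.abs(quantiles - ref), axis=1)
    for k in range(1, len(levels)):
        prev = mad[k - 1]
        if prev <= 0:
            continue
        if abs(mad[k] - prev) / prev > rel_change:
            return float(levels[k])
    return 0.5


def css(
    table: CountTable,
    percentile: float | str = "auto",
    log_base: float | str | None = 2,
    scale: float = 1000.0,
) -> NumericMatrix:
    """Cumulative sum scaling normalization.

    Each sample j is rescaled by s_j / ``scale`` where s_j is the sum of
    sample j's counts that are <= its own chosen quantile, making samples
    comparable on the portion of the count distribution that is relatively
    invariant to sequencing depth. With ``log_base`` set, the normalized
    values are transformed as log_base(value + 1) afterwards.

    Parameters
    ----------
    percentile
        Quantile level in (0, 1), or ``"auto"`` for the data-driven choice
        of :func:`css_auto_percentile`.
    log_base
        2 (default), ``"e"``/``numpy.e``, or None for no log.
    scale
        Normalization constant dividing the scaling factors (default 1000).
    """
    if table.n_samples < 2:
        raise ValueError("CSS needs at least 2 samples")
    counts = table.values.astype(float)
    if percentile == "auto":
        level = css_auto_percentile(table)
        logger.info("CSS auto percentile: %.2f", level)
    else:
        level = float(percentile)
        if not 0 < level < 1:
            raise ValueError("percentile must lie in (0, 1)")

    norm = np.empty_like(counts)
    for j in range(table.n_samples):
        row = counts[j]
        positive = row[row > 0]
        if positive.size == 0:
            raise ValueError(f"sample {table.sample_ids[j]!r} has no counts")
        q = np.quantile(positive, level)
        s_j = row[row <= q].sum()
        if s_j <= 0:
            raise ValueError(
                f"zero CSS scaling factor for sample {table.sample_ids[j]!r}"
            )
        norm[j] = row / (s_j / scale)

    if log_base is not None and log_base != "none":
        base = np.e if log_base in ("e", np.e) else float(log_base)
        norm = np.log1p(norm) / np.log(base)
    return NumericMatrix(
        values=norm,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


def normalize(
    table: CountTable,
    method: str,
    pseudocount: int = 1,
    css_percentile: float | str = "auto",
    css_log_base: float | str | None = 2,
) -> NumericMatrix | CompositionMatrix:
    """Dispatch the named normalization branch.

    ``tss`` returns proportions; ``tss-clr`` and ``tss-ilr`` pseudocount,
    scale, then log-ratio transform; ``css`` cumulative-sum scales the raw
    counts (no pseudocount).
    """
    from .preprocess import add_pseudocount

    method = method.lower()
    if method == "css":
        return css(table, percentile=css_percentile, log_base=css_log_base)
    if method in ("tss", "tss-clr", "tss-ilr"):
        comp = tss(add_pseudocount(table, pseudocount))
        if method == "tss":
            return comp
        return clr(comp) if method == "tss-clr" else ilr(comp)
    raise ValueError(f"unknown normalization method {method!r}")
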