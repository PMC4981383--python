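"""Prefiltering and zero handling for sparse OTU count tables.

The filtering rules counteract sequencing error: drop samples with fewer
than 10 total counts, then drop OTUs whose aggregate count across all
remaining samples is below 0.01% of the table's grand total. Log-ratio
transforms additionally need strictly positive entries, supplied either by
a pseudocount offset or by multiplicative zero replacement.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CountTable

__all__ = [
    "filter_samples",
    "filter_otus",
    "prefilter",
    "add_pseudocount",
    "multiplicative_replacement",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLE_TOTAL = 10
DEFAULT_MIN_OTU_PROP = 1e-4  # 0.01% of the grand total


def filter_samples(
    table: CountTable, min_total: int = DEFAULT_MIN_SAMPLE_TOTAL
) -> CountTable:
    """Drop samples whose total OTU count is below ``min_total``.

    Survivor order is preserved; values are untouched.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.sample_totals()
    keep = np.flatnonzero(totals >= min_total)
    if keep.size == 0:
        raise ValueError("empty table after sample filter")
    dropped = table.n_samples - keep.size
    if dropped:
        logger.info("sample filter: dropped %d / %d samples", dropped, table.n_samples)
    return table.select_samples(keep)


def filter_otus(table: CountTable, min_prop: float = DEFAULT_MIN_OTU_PROP) -> CountTable:
    """Drop OTUs whose aggregate proportion of the grand total is below ``min_prop``.

    An OTU is kept iff sum(counts) / grand_total >= min_prop — removal is
    strictly below the threshold, so an OTU sitting exactly at it survives.
    Apply after :func:`filter_samples`, so the grand total reflects the
    retained samples.
    """
    if not 0 <= min_prop < 1:
        raise ValueError("min_prop must lie in [0, 1)")
    grand_total = table.values.sum()
    if grand_total == 0:
        raise ValueError("cannot filter OTUs on an all-zero table")
    props = table.otu_totals() / grand_total
    keep = np.flatnonzero(props >= min_prop)
    if keep.size == 0:
        raise ValueError("empty table after OTU filter")
    dropped = table.n_features - keep.size
    if dropped:
        logger.info("OTU filter: dropped %d / %d OTUs", dropped, table.n_features)
    return table.select_features(keep)


def prefilter(
    table: CountTable,
    min_sample_total: int = DEFAULT_MIN_SAMPLE_TOTAL,
    min_otu_prop: float = DEFAULT_MIN_OTU_PROP,
) -> CountTable:
    """Sample filter followed by OTU filter (in that order)."""
    return filter_otus(filter_samples(table, min_sample_total), min_otu_prop)


def add_pseudocount(table: CountTable, value: int = 1) -> CountTable:
    """Add a positive offset to every count so log ratios are defined.

    Used on the log-ratio branch (TSS -> CLR/ILR) only; cumulative-sum
    scaling operates on the raw counts and must not be pseudocounted.
    """
    if value <= 0:
        raise ValueError("pseudocount must be > 0")
    return CountTable(
        values=table.values + value,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


def multiplicative_replacement(table: CountTable, delta: float | None = None) -> np.ndarray:
    """Replace zeros in the row-proportions with a small delta, rescaling
    the positive parts so each row still sums to one.

    Returns a strictly positive samples x OTUs array of proportions.
    Alternative to :func:`add_pseudocount` for the log-ratio branch.
    """
    counts = table.values.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("all-zero sample; filter samples first")
    props = counts / totals
    if delta is None:
        # conventional choice: below the smallest observable proportion
        delta = 1.0 / (totals.max() ** 2)
    out = props.copy()
    for i in range(out.shape[0]):
        zeros = out[i] == 0
        k = zeros.sum()
        if k:
            out[i, zeros] = delta
            out[i, ~zeros] *= 1.0 - k * delta
    if np.any(out <= 0):
        raise ValueError("delta too large: replacement produced non-positive parts")
    return out
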