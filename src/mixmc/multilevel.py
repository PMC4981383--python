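"""Within-subject variance decomposition for repeated-measures designs.

When the same subjects are sampled in several habitats, the variation
*between* subjects often dwarfs the variation *between* habitats. Splitting
the data matrix into a between-subject part (each row replaced by its
subject's mean) and a within-subject part (each row's deviation from its
subject mean) removes the subject effect; the within part is the input to
downstream PCA or sPLS-DA. The split is exact: within + between
reconstructs the input, and each subject's within rows average to zero.

This decomposition ignores any ordering of the repeated measurements, so it
is not suited to time-course designs where the time effect is the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NumericMatrix

__all__ = ["DecompositionResult", "within_variation"]

logger = logging.getLogger(__name__)


@dataclass
class DecompositionResult:
    """Additive split X = within + between, row-aligned with the input."""

    within: NumericMatrix
    between: NumericMatrix
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.within.shape != self.between.shape:
            raise ValueError("within and between must have identical shapes")
        if len(self.subject_ids) != self.within.n_samples:
            raise ValueError("one subject id per row required")


def within_variation(
    X: NumericMatrix,
    subjects: np.ndarray | list[str],
    allow_singletons: bool = False,
) -> DecompositionResult:
    """Split ``X`` into within- and between-subject parts.

    Parameters
    ----------
    X
        Samples x features matrix, already log-ratio or CSS transformed.
    subjects
        Subject id for each row; every subject needs >= 2 rows unless
        ``allow_singletons`` is set (then a singleton's within row is zero,
        with a warning).

    Returns
    -------
    DecompositionResult
        ``within`` rows are deviations from the subject mean (the grand
        mean is *not* added back; downstream methods center columns
        anyway); ``between`` rows are the subject means.
    """
    subjects = np.asarray([str(s) for s in subjects])
    if len(subjects) != X.n_samples:
        raise ValueError(
            f"{len(subjects)} subject ids for {X.n_samples} rows"
        )
    counts = pd.Series(subjects).value_counts()
    singletons = sorted(counts.index[counts < 2])
    if singletons:
        if not allow_singletons:
            raise ValueError(
                "subjects with a single observation cannot be decomposed: "
                f"{singletons[:10]}" + ("..." if len(singletons) > 10 else "")
            )
        logger.warning(
            "%d singleton subjects: their within rows are zero", len(singletons)
        )

    frame = pd.DataFrame(X.values)
    between_vals = frame.groupby(subjects).transform("mean").to_numpy()
    within_vals = X.values - between_vals

    ids = list(X.sample_ids)
    feats = list(X.feature_ids)
    return DecompositionResult(
        within=NumericMatrix(values=within_vals, sample_ids=ids, feature_ids=feats),
        between=NumericMatrix(values=between_vals, sample_ids=ids, feature_ids=feats),
        subject_ids=subjects,
    )
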