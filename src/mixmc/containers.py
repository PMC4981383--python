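"""Core data containers shared across the pipeline.

All matrices are oriented samples x features (OTUs). Ingest code is
responsible for transposing external formats (e.g. QIIME-classic tables,
which store OTUs in rows) into this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "CompositionMatrix",
    "NumericMatrix",
    "SampleMetadata",
    "Lineage",
    "Taxonomy",
    "RANKS",
]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class _LabelledMatrix:
    """A 2-D array with unique row (sample) and column (feature) labels."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = _check_ids(self.sample_ids, "sample ids")
        self.feature_ids = _check_ids(self.feature_ids, "feature ids")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {p} matrix columns"
            )
        self._validate()

    def _validate(self) -> None:  # overridden by subclasses
        pass

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame):
        return cls(
            values=frame.to_numpy(),
            sample_ids=list(frame.index.astype(str)),
            feature_ids=list(frame.columns.astype(str)),
        )

    def select_samples(self, keep: Sequence[int]):
        keep = list(keep)
        return type(self)(
            values=self.values[keep, :],
            sample_ids=[self.sample_ids[i] for i in keep],
            feature_ids=list(self.feature_ids),
        )

    def select_features(self, keep: Sequence[int]):
        keep = list(keep)
        return type(self)(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in keep],
        )


class CountTable(_LabelledMatrix):
    """Non-negative integer OTU abundances, samples x OTUs."""

    def _validate(self) -> None:
        vals = self.values
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("count table must be numeric")
        if np.any(~np.isfinite(vals.astype(float))):
            raise ValueError("count table contains non-finite entries")
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.feature_ids[j]!r}"
            )
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals, rounded, atol=1e-8):
                raise ValueError("count table entries must be integers")
            self.values = rounded.astype(np.int64)
        else:
            self.values = vals.astype(np.int64)

    @property
    def otu_ids(self) -> list[str]:
        return self.feature_ids

    def sample_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)


class CompositionMatrix(_LabelledMatrix):
    """Strictly positive proportions; every row lies on the unit simplex."""

    def _validate(self) -> None:
        self.values = self.values.astype(float)
        if np.any(self.values <= 0):
            raise ValueError("composition entries must be strictly positive")
        rowsums = self.values.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-10):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValueError(
                f"row {self.sample_ids[bad]!r} sums to {rowsums[bad]!r}, not 1"
            )

    @property
    def otu_ids(self) -> list[str]:
        return self.feature_ids


class NumericMatrix(_LabelledMatrix):
    """A real-valued samples x features matrix (CLR/ILR/CSS output, scores...)."""

    def _validate(self) -> None:
        self.values = self.values.astype(float)
        if np.any(~np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")


@dataclass
class SampleMetadata:
    """Per-sample design information: subject and class label.

    One record per sample; supervised analyses need at least two distinct
    class labels, repeated-measures analyses need subjects observed more
    than once.
    """

    frame: pd.DataFrame  # index = sample_id; columns subject_id, class_label

    REQUIRED = ("subject_id", "class_label")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique()
            raise ValueError(f"duplicated sample_id: {list(dupes[:5])}")
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        for col in self.REQUIRED:
            self.frame[col] = self.frame[col].astype(str)

    @classmethod
    def from_records(
        cls,
        sample_ids: Iterable[str],
        subject_ids: Iterable[str],
        class_labels: Iterable[str],
    ) -> "SampleMetadata":
        frame = pd.DataFrame(
            {"subject_id": list(subject_ids), "class_label": list(class_labels)},
            index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
        )
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def classes(self) -> list[str]:
        return sorted(self.frame["class_label"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        self._require(sample_ids)
        return self.frame.loc[list(sample_ids), "class_label"].to_numpy()

    def subjects_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        self._require(sample_ids)
        return self.frame.loc[list(sample_ids), "subject_id"].to_numpy()

    def _require(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(
                f"samples missing from metadata: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )

    def unbalanced_cells(self) -> pd.DataFrame:
        """Subject x class cells observed more than once (repeated class)."""
        counts = (
            self.frame.groupby(["subject_id", "class_label"])
            .size()
            .rename("n")
            .reset_index()
        )
        return counts[counts["n"] > 1]


RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX_TO_RANK.items()}


@dataclass(frozen=True)
class Lineage:
    """An ordered Greengenes-style taxonomic lineage; missing ranks are None."""

    ranks: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {r: self.ranks.get(r) or None for r in RANKS}
        object.__setattr__(self, "ranks", clean)

    def __getitem__(self, rank: str) -> str | None:
        return self.ranks[rank]

    def at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; choose from {RANKS}")
        return self.ranks[rank]

    def to_string(self) -> str:
        parts = []
        for rank in RANKS:
            name = self.ranks[rank]
            parts.append(f"{_RANK_TO_PREFIX[rank]}{name or ''}")
        # trim trailing empty ranks for compactness
        while parts and parts[-1].endswith("__"):
            parts.pop()
        return "; ".join(parts)

    def named_ranks(self) -> list[tuple[str, str]]:
        return [(r, n) for r, n in self.ranks.items() if n is not None]


@dataclass
class Taxonomy:
    """Mapping of OTU id to its :class:`Lineage`."""

    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __getitem__(self, otu_id: str) -> Lineage:
        return self.lineages[otu_id]

    def get(self, otu_id: str) -> Lineage | None:
        return self.lineages.get(otu_id)

    def name_at(self, otu_id: str, rank: str) -> str | None:
        lin = self.lineages.get(otu_id)
        return None if lin is None else lin.at(rank)

    def __len__(self) -> int:
        return len(self.lineages)
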