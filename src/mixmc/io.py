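"""Reading and writing OTU tables, sample metadata and taxonomy strings.

Supported table formats:

* QIIME-classic TSV: an optional first line ``# Constructed from biom file``,
  a header line starting with ``#OTU ID``, one row per OTU and one column per
  sample, optionally a trailing ``taxonomy`` column of Greengenes lineage
  strings. Stored OTUs-in-rows; transposed to samples x OTUs at ingest.
* Plain TSV with samples in rows (header = OTU ids).
* BIOM-JSON (version 1.0, dense or sparse) via the same contract.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    RANKS,
    CountTable,
    Lineage,
    SampleMetadata,
    Taxonomy,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_biom_json",
    "read_metadata",
    "write_metadata",
    "parse_taxonomy",
    "read_taxonomy_table",
]

logger = logging.getLogger(__name__)

_OTU_HEADER = "#OTU ID"

_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_RANK = dict(zip(_PREFIXES, RANKS))


def parse_taxonomy(lineage: str) -> Lineage:
    """Parse a Greengenes-style lineage string into ordered ranks.

    Tokens carry rank prefixes (``k__``, ``p__``, ...); an empty name after
    the prefix marks a missing rank. A token with an unknown prefix is kept,
    with a warning, at the next unfilled rank.
    """
    ranks: dict[str, str | None] = {r: None for r in RANKS}
    filled = 0
    for token in str(lineage).split(";"):
        token = token.strip().strip('"')
        if not token:
            continue
        prefix = token[:3]
        if prefix in _PREFIX_RANK:
            rank = _PREFIX_RANK[prefix]
            name = token[3:].strip()
            ranks[rank] = name or None
            filled = max(filled, RANKS.index(rank) + 1)
        else:
            if filled >= len(RANKS):
                warnings.warn(f"lineage token {token!r} beyond last rank; dropped")
                continue
            warnings.warn(
                f"lineage token {token!r} has no rank prefix; "
                f"stored at rank {RANKS[filled]!r}"
            )
            ranks[RANKS[filled]] = token
            filled += 1
    return Lineage(ranks)


def _parse_numeric_body(frame: pd.DataFrame, path: Path) -> np.ndarray:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna() & frame.notna()
        if mask.any().any():
            row, col = next(
                (r, c) for r in frame.index for c in frame.columns if mask.at[r, c]
            )
            raise ValueError(
                f"{path}: non-numeric value {frame.at[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        raise ValueError(f"{path}: missing values in table body")
    return numeric.to_numpy()


def read_count_table(
    path: str | Path,
    orientation: str = "auto",
) -> tuple[CountTable, Taxonomy | None]:
    """Read a tab-separated OTU count table.

    Parameters
    ----------
    path
        TSV file. A header cell ``#OTU ID`` (QIIME-classic) marks
        OTUs-in-rows; such tables are transposed to the internal
        samples x OTUs orientation. A trailing ``taxonomy`` column is split
        off into a :class:`~mixmc.containers.Taxonomy`.
    orientation
        ``auto`` (header sentinel decides), ``samples_in_rows`` or
        ``otus_in_rows``.

    Returns
    -------
    (CountTable, Taxonomy | None)
        The taxonomy is None when the file carries no taxonomy column.
    """
    path = Path(path)
    if orientation not in ("auto", "samples_in_rows", "otus_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    with path.open() as fh:
        first = fh.readline()
        skiprows = 1 if first.startswith("# ") else 0

    frame = pd.read_csv(
        path, sep="\t", skiprows=skiprows, header=0, index_col=0, dtype=str
    )
    frame.index = frame.index.astype(str)
    header_is_otu = (frame.index.name or "").strip() == _OTU_HEADER

    if orientation == "auto":
        otus_in_rows = header_is_otu
    else:
        otus_in_rows = orientation == "otus_in_rows"

    taxonomy: Taxonomy | None = None
    if otus_in_rows and frame.columns[-1].strip().lower() == "taxonomy":
        tax_col = frame.iloc[:, -1]
        frame = frame.iloc[:, :-1]
        taxonomy = Taxonomy(
            {str(otu): parse_taxonomy(lin) for otu, lin in tax_col.items()}
        )

    values = _parse_numeric_body(frame, path)
    if otus_in_rows:
        table = CountTable(
            values=values.T,
            sample_ids=list(frame.columns.astype(str)),
            feature_ids=list(frame.index),
        )
    else:
        table = CountTable(
            values=values,
            sample_ids=list(frame.index),
            feature_ids=list(frame.columns.astype(str)),
        )
    logger.info(
        "read %s: %d samples x %d OTUs", path, table.n_samples, table.n_features
    )
    return table, taxonomy


def write_count_table(
    table: CountTable,
    path: str | Path,
    taxonomy: Taxonomy | None = None,
) -> None:
    """Write a QIIME-classic TSV (OTUs in rows, ``#OTU ID`` header)."""
    path = Path(path)
    frame = table.to_frame().T
    frame.index.name = _OTU_HEADER
    if taxonomy is not None:
        frame["taxonomy"] = [
            taxonomy[otu].to_string() if otu in taxonomy else ""
            for otu in frame.index
        ]
    with path.open("w") as fh:
        fh.write("# Constructed from biom file\n")
        frame.to_csv(fh, sep="\t")


def read_biom_json(path: str | Path) -> tuple[CountTable, Taxonomy | None]:
    """Read a BIOM format 1.0 (JSON) OTU table."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_otus, n_samples = doc["shape"]
    dense = np.zeros((n_otus, n_samples))
    if doc.get("matrix_type") == "dense":
        dense[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = v
    lineages: dict[str, Lineage] = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            lineage = tax if isinstance(tax, str) else "; ".join(tax)
            lineages[str(row["id"])] = parse_taxonomy(lineage)
    taxonomy = Taxonomy(lineages) if lineages else None
    table = CountTable(
        values=dense.T, sample_ids=sample_ids, feature_ids=otu_ids
    )
    return table, taxonomy


def read_metadata(
    path: str | Path, table: CountTable | None = None
) -> SampleMetadata:
    """Read a sample metadata TSV with columns sample_id, subject_id, class_label.

    When ``table`` is given, every sample in the table must have a metadata
    record; missing samples raise an error naming them. Subjects sampled
    more than once for the same class are accepted but logged as unbalanced.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    frame = frame.set_index("sample_id")
    meta = SampleMetadata(frame)
    if table is not None:
        missing = [s for s in table.sample_ids if s not in meta.frame.index]
        if missing:
            raise ValueError(
                f"{path}: samples present in the count table but missing from "
                f"metadata: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    unbalanced = meta.unbalanced_cells()
    if len(unbalanced):
        logger.warning(
            "unbalanced design: %d subject x class cells with repeats (e.g. %s)",
            len(unbalanced),
            unbalanced.iloc[0].to_dict(),
        )
    logger.info(
        "read %s: %d samples, %d subjects, %d classes",
        path, len(meta.frame), len(meta.subjects), len(meta.classes),
    )
    return meta


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    frame = meta.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_taxonomy_table(path: str | Path) -> Taxonomy:
    """Read a two-column TSV: otu_id <TAB> lineage string (no header required)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if str(frame.iloc[0, 0]).lower() in ("otu_id", "#otu id", "feature id"):
        frame = frame.iloc[1:]
    return Taxonomy(
        {
            str(otu): parse_taxonomy(lin)
            for otu, lin in zip(frame.iloc[:, 0], frame.iloc[:, 1])
        }
    )
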