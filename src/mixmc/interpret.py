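"""Interpretable outputs for a fitted sparse PLS-DA model.

A selected OTU is assigned to the class (body site, habitat...) in which
its median normalized abundance is highest — medians are taken on the
normalized matrix used for the fit, *before* any multilevel decomposition,
so they retain abundance meaning. The contribution table drives two plot
formats: a per-component contribution barplot (exported as TSV) and a
GraPhlAn circular cladogram annotation file, where marker size tracks the
median count in the assigned class and marker color encodes the sign of
the loading (yellow positive, black negative).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import NumericMatrix, Taxonomy
from .splsda import SplsdaModel

__all__ = [
    "ContributionTable",
    "assign_contributions",
    "export_graphlan",
    "EllipseParams",
    "confidence_ellipse",
    "export_ellipses",
]

logger = logging.getLogger(__name__)

POSITIVE_COLOR = "#ffff00"  # yellow: positive loading weight
NEGATIVE_COLOR = "#000000"  # black: negative loading weight
TIE_COLOR = "#808080"  # grey: tied class medians


@dataclass
class ContributionTable:
    """Selected OTUs with loading weight, assigned class and taxonomy.

    One row per (component, OTU) pair with nonzero loading, ordered within
    each component by decreasing |loading|. ``assigned_class`` attains the
    maximum median; exact ties are flagged and all tied classes listed.
    """

    frame: pd.DataFrame

    COLUMNS = (
        "component",
        "otu_id",
        "loading",
        "assigned_class",
        "tie",
        "tied_classes",
        "rank_in_component",
        "taxonomy",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"contribution table missing columns {missing}")
        if (self.frame["loading"] == 0).any():
            raise ValueError("contribution table must only hold selected OTUs")

    def for_component(self, component: int) -> pd.DataFrame:
        return self.frame[self.frame["component"] == component]

    def counts_per_class(self) -> pd.DataFrame:
        """Number of selected OTUs contributing to each class per component
        (ties counted for every tied class)."""
        rows = []
        for _, row in self.frame.iterrows():
            classes = row["tied_classes"].split("|") if row["tie"] else [row["assigned_class"]]
            for cls in classes:
                rows.append({"component": row["component"], "class": cls})
        counts = (
            pd.DataFrame(rows).groupby(["class", "component"]).size().rename("n")
        )
        return counts.reset_index().pivot(
            index="class", columns="component", values="n"
        ).fillna(0).astype(int)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def assign_contributions(
    model: SplsdaModel,
    normalized: NumericMatrix,
    labels: np.ndarray | list[str],
    taxonomy: Taxonomy | None = None,
    taxonomy_rank: str = "family",
) -> ContributionTable:
    """Build the contribution table for every selected OTU of the model.

    Parameters
    ----------
    model
        Fitted sparse PLS-DA model.
    normalized
        The normalized matrix the model was derived from (TSS(+CLR) or
        CSS), *before* multilevel decomposition; medians are computed on it.
    labels
        Class label per row of ``normalized``.
    taxonomy, taxonomy_rank
        Optional lineage lookup; the name at ``taxonomy_rank`` is attached
        to each row (empty when unknown).
    """
    if list(normalized.feature_ids) != list(model.feature_ids):
        raise ValueError("OTU ids of the normalized matrix do not match the model")
    labels = np.asarray([str(l) for l in labels])
    if labels.size != normalized.n_samples:
        raise ValueError("one label per sample required")
    classes = sorted(set(labels))
    values = normalized.values

    medians = {
        cls: np.median(values[labels == cls], axis=0) for cls in classes
    }
    median_mat = np.stack([medians[cls] for cls in classes])  # K x p

    rows = []
    for h in range(model.n_comp):
        loadings = model.x_loadings[:, h]
        sel = np.flatnonzero(loadings != 0)
        sel = sel[np.argsort(-np.abs(loadings[sel]), kind="stable")]
        for rank_pos, j in enumerate(sel, start=1):
            col = median_mat[:, j]
            top = col.max()
            winners = [classes[k] for k in np.flatnonzero(col == top)]
            tie = len(winners) > 1
            if tie:
                logger.debug(
                    "component %d OTU %s: tied medians across %s",
                    h + 1, model.feature_ids[j], winners,
                )
            row = {
                "component": h + 1,
                "otu_id": model.feature_ids[j],
                "loading": float(loadings[j]),
                "assigned_class": winners[0] if not tie else "|".join(winners),
                "tie": tie,
                "tied_classes": "|".join(winners) if tie else "",
                "rank_in_component": rank_pos,
                "taxonomy": (
                    taxonomy.name_at(model.feature_ids[j], taxonomy_rank) or ""
                    if taxonomy is not None
                    else ""
                ),
            }
            for cls in classes:
                row[f"median_{cls}"] = float(medians[cls][j])
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(ContributionTable.COLUMNS) + [
        f"median_{cls}" for cls in classes
    ])
    return ContributionTable(frame)


_CLASS_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def export_graphlan(
    contrib: ContributionTable,
    taxonomy: Taxonomy,
    annotation_path: str | Path,
    tree_path: str | Path | None = None,
    min_marker_size: float = 4.0,
    max_marker_size: float = 20.0,
) -> int:
    """Write GraPhlAn annotation (and optional tree) files for a cladogram.

    Each selected OTU becomes a clade whose marker size grows monotonically
    with its median normalized count in the assigned class, whose marker
    color encodes the loading sign (yellow positive, black negative; grey
    for tied assignments), and whose background color is keyed to the
    assigned class. OTUs without a lineage are skipped with a warning.

    Returns the number of OTUs written.
    """
    annotation_path = Path(annotation_path)
    frame = contrib.frame
    classes = sorted(
        {c for cell in frame["assigned_class"] for c in cell.split("|")}
    )
    class_color = {
        cls: _CLASS_PALETTE[i % len(_CLASS_PALETTE)] for i, cls in enumerate(classes)
    }

    median_cols = [c for c in frame.columns if c.startswith("median_")]

    def assigned_median(row) -> float:
        cls = row["assigned_class"].split("|")[0]
        return row[f"median_{cls}"]

    lines = ["clade_separation\t0.5", "branch_thickness\t1.0"]
    clades: list[str] = []
    written = 0
    if len(frame):
        med = frame.apply(assigned_median, axis=1).to_numpy(dtype=float)
        lo, hi = float(med.min()), float(med.max())
        span = hi - lo
        for (_, row), m in zip(frame.iterrows(), med):
            otu = row["otu_id"]
            lineage = taxonomy.get(otu)
            if lineage is None or not lineage.named_ranks():
                logger.warning("OTU %s has no lineage; skipped in cladogram", otu)
                continue
            clade = ".".join(name for _, name in lineage.named_ranks()) + f".{otu}"
            size = (
                min_marker_size
                if span == 0
                else min_marker_size + (m - lo) / span * (max_marker_size - min_marker_size)
            )
            if row["tie"]:
                color = TIE_COLOR
                bg = TIE_COLOR
            else:
                color = POSITIVE_COLOR if row["loading"] > 0 else NEGATIVE_COLOR
                bg = class_color[row["assigned_class"]]
            lines.append(f"{clade}\tclade_marker_size\t{size:.3f}")
            lines.append(f"{clade}\tclade_marker_color\t{color}")
            lines.append(f"{clade}\tannotation_background_color\t{bg}")
            clades.append(clade)
            written += 1
    annotation_path.write_text("\n".join(lines) + "\n")
    if tree_path is not None:
        Path(tree_path).write_text("\n".join(clades) + ("\n" if clades else ""))
    logger.info("wrote GraPhlAn annotation for %d OTUs to %s", written, annotation_path)
    return written


@dataclass
class EllipseParams:
    """A per-class confidence ellipse in a 2-D score plane."""

    class_label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_degrees: float  # orientation of the major axis
    level: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "angle_degrees": self.angle_degrees,
            "level": self.level,
            "degenerate": self.degenerate,
        }


def confidence_ellipse(
    scores: NumericMatrix | np.ndarray,
    labels: np.ndarray | list[str],
    level: float = 0.95,
    components: tuple[int, int] = (0, 1),
) -> list[EllipseParams]:
    """Per-class confidence ellipses on a 2-D score plane.

    Each ellipse is centered on the class mean with axes along the
    eigenvectors of the class covariance, scaled by
    sqrt(chi2.ppf(level, df=2) * eigenvalue) — the contour containing the
    requested probability mass of a fitted bivariate Gaussian.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    vals = scores.values if isinstance(scores, NumericMatrix) else np.asarray(scores, float)
    labels = np.asarray([str(l) for l in labels])
    i, j = components
    pts = vals[:, [i, j]]
    r2 = _stats.chi2.ppf(level, df=2)
    out = []
    for cls in sorted(set(labels)):
        sub = pts[labels == cls]
        if sub.shape[0] < 3:
            raise ValueError(f"class {cls!r} has < 3 samples; ellipse undefined")
        center = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        degenerate = bool(eigvals[-1] <= 1e-12 * max(eigvals[0], 1.0))
        if degenerate:
            logger.warning("class %s: singular covariance, degenerate ellipse", cls)
            eigvals = np.clip(eigvals, 0.0, None)
        axes = np.sqrt(r2 * eigvals)
        angle = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
        out.append(
            EllipseParams(
                class_label=cls,
                center=(float(center[0]), float(center[1])),
                semi_axes=(float(axes[0]), float(axes[1])),
                angle_degrees=angle,
                level=level,
                degenerate=degenerate,
            )
        )
    return out


def export_ellipses(ellipses: list[EllipseParams], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in ellipses], indent=2) + "\n"
    )
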