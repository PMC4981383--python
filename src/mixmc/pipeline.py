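"""End-to-end pipeline orchestration.

Runs filter -> (pseudocount) -> normalize -> (multilevel) -> {pca | tune +
sparse PLS-DA} -> interpretation, writing every intermediate matrix, a
machine-readable manifest (package version, seed, parameters, content
hashes of inputs and outputs) and logs into a results directory. Any stage
failure aborts with the stage name; partial outputs are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .containers import CountTable, NumericMatrix, SampleMetadata, Taxonomy
from .interpret import assign_contributions, confidence_ellipse, export_ellipses, export_graphlan
from .io import read_count_table, read_metadata, write_count_table, write_metadata
from .multilevel import within_variation
from .ordination import bray_curtis, pca, pcoa
from .preprocess import prefilter
from .splsda import cross_validate, tune_keepx
from .synth import SynthConfig, simulate_counts, synthetic_taxonomy
from .transforms import normalize

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(mat, path: Path) -> None:
    mat.to_frame().to_csv(path, sep="\t")


DEFAULTS: dict[str, Any] = {
    "min_sample_total": 10,
    "min_otu_prop": 1e-4,
    "pseudocount": 1,
    "normalization": "tss-clr",  # tss | tss-clr | tss-ilr | css
    "css_percentile": "auto",
    "css_log_base": 2,
    "multilevel": False,
    "analysis": "splsda",  # pca | splsda
    "n_comp": 2,
    "keepX": None,  # fixed keepX list; None = tune
    "keepX_grid": None,
    "max_comp": 2,
    "folds": 5,
    "repeats": 2,
    "distance": "max",
    "legacy_cv": False,
    "taxonomy_rank": "family",
    "seed": 0,
}


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the multivariate pipeline described by ``config``.

    The config names either input files (``table``, ``metadata``,
    optionally ``taxonomy``) or a ``simulate`` block of
    :class:`~mixmc.synth.SynthConfig` overrides, plus any of the keys in
    :data:`DEFAULTS`. Returns the manifest dictionary (also written to
    ``manifest.json`` in ``out_dir``).
    """
    cfg = {**DEFAULTS, **config}
    unknown = set(cfg) - set(DEFAULTS) - {"table", "metadata", "taxonomy", "simulate"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if cfg["normalization"] == "css" and "pseudocount" in config:
        raise ValueError(
            "pseudocount applies to the log-ratio branch only; "
            "CSS operates on raw counts"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: cfg[k] for k in DEFAULTS},
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    taxonomy: Taxonomy | None = None
    try:
        stage("load")
        if "simulate" in cfg:
            sim_cfg = SynthConfig(**{**cfg["simulate"], "seed": seed})
            table, meta, truth = simulate_counts(sim_cfg)
            taxonomy = synthetic_taxonomy(table.otu_ids, seed=seed)
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "discriminative": truth.discriminative,
                        "fold_change": truth.fold_change,
                    },
                    indent=2,
                )
            )
            record("truth", out / "truth.json")
            write_count_table(table, out / "simulated_counts.tsv", taxonomy)
            write_metadata(meta, out / "simulated_metadata.tsv")
            record("simulated_counts", out / "simulated_counts.tsv")
            record("simulated_metadata", out / "simulated_metadata.tsv")
        else:
            table_path = Path(cfg["table"])
            meta_path = Path(cfg["metadata"])
            manifest["inputs"]["table"] = {
                "path": str(table_path), "sha256": _sha256(table_path)
            }
            manifest["inputs"]["metadata"] = {
                "path": str(meta_path), "sha256": _sha256(meta_path)
            }
            table, taxonomy = read_count_table(table_path)
            meta = read_metadata(meta_path, table)
            if cfg.get("taxonomy"):
                from .io import read_taxonomy_table

                taxonomy = read_taxonomy_table(cfg["taxonomy"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("filter")
        table = prefilter(
            table, int(cfg["min_sample_total"]), float(cfg["min_otu_prop"])
        )
        write_count_table(table, out / "filtered_counts.tsv")
        record("filtered_counts", out / "filtered_counts.tsv")
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    labels = meta.labels_for(table.sample_ids)
    subjects = meta.subjects_for(table.sample_ids)

    try:
        stage("normalize")
        method = cfg["normalization"]
        if cfg["analysis"] == "splsda" and method == "tss-ilr":
            raise ValueError(
                "feature selection needs one coordinate per OTU; "
                "use tss-clr or css for the supervised branch"
            )
        if cfg["analysis"] == "pca" and method == "tss-clr":
            logger.info("PCA on CLR coordinates has a singular covariance; "
                        "tss-ilr is the preferred unsupervised branch")
        normalized = normalize(
            table,
            method,
            pseudocount=int(cfg["pseudocount"]),
            css_percentile=cfg["css_percentile"],
            css_log_base=cfg["css_log_base"],
        )
        _write_matrix(normalized, out / "normalized.tsv")
        record("normalized", out / "normalized.tsv")
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    X = NumericMatrix(
        values=np.asarray(normalized.values, float),
        sample_ids=list(normalized.sample_ids),
        feature_ids=list(normalized.feature_ids),
    )
    analysis_X = X
    try:
        if cfg["multilevel"]:
            stage("multilevel")
            decomp = within_variation(X, subjects, allow_singletons=True)
            analysis_X = decomp.within
            _write_matrix(decomp.within, out / "within_matrix.tsv")
            record("within_matrix", out / "within_matrix.tsv")
    except Exception as exc:
        raise PipelineError("multilevel", exc) from exc

    results: dict[str, Any] = {}
    if cfg["analysis"] == "pca":
        try:
            stage("pca")
            res = pca(analysis_X, n_comp=int(cfg["n_comp"]))
            _write_matrix(res.scores, out / "pca_scores.tsv")
            record("pca_scores", out / "pca_scores.tsv")
            results["explained_fraction"] = res.explained_fraction.tolist()
        except Exception as exc:
            raise PipelineError("pca", exc) from exc
    elif cfg["analysis"] == "splsda":
        try:
            if cfg["keepX"] is None:
                stage("tune")
                tuned = tune_keepx(
                    X if cfg["multilevel"] else analysis_X,
                    labels,
                    subjects=subjects if cfg["multilevel"] else None,
                    keepX_grid=cfg["keepX_grid"],
                    max_comp=int(cfg["max_comp"]),
                    folds=int(cfg["folds"]),
                    repeats=int(cfg["repeats"]),
                    seed=seed,
                    distance=cfg["distance"],
                    multilevel=bool(cfg["multilevel"]),
                    legacy_cv=bool(cfg["legacy_cv"]),
                )
                model = tuned.final_model
                tuned.error_surface.to_csv(
                    out / "tuning_surface.tsv", sep="\t", index=False
                )
                record("tuning_surface", out / "tuning_surface.tsv")
                results["chosen_keepX"] = tuned.chosen_keepX
                results["n_comp"] = tuned.n_comp
                keepX = tuned.chosen_keepX
                n_comp = tuned.n_comp
            else:
                keepX = [int(k) for k in cfg["keepX"]]
                n_comp = len(keepX)
                from .splsda import fit_splsda

                stage("splsda")
                model = fit_splsda(analysis_X, labels, n_comp=n_comp, keepX=keepX)
                results["chosen_keepX"] = keepX
                results["n_comp"] = n_comp

            stage("cv")
            cv = cross_validate(
                X if cfg["multilevel"] else analysis_X,
                labels,
                subjects=subjects if cfg["multilevel"] else None,
                n_comp=n_comp,
                keepX=keepX,
                folds=int(cfg["folds"]),
                repeats=int(cfg["repeats"]),
                seed=seed,
                distance=cfg["distance"],
                multilevel=bool(cfg["multilevel"]),
                legacy_cv=bool(cfg["legacy_cv"]),
            )
            results["cv_error_per_component"] = cv.overall_error.tolist()
            results["cv_balanced_error"] = cv.balanced_error.tolist()
            cv.per_class_error.to_csv(out / "cv_per_class_error.tsv", sep="\t")
            record("cv_per_class_error", out / "cv_per_class_error.tsv")

            stage("interpret")
            model.loadings_frame().to_csv(out / "loadings.tsv", sep="\t")
            record("loadings", out / "loadings.tsv")
            model.scores_frame().to_csv(out / "scores.tsv", sep="\t")
            record("scores", out / "scores.tsv")
            contrib = assign_contributions(
                model, X, labels, taxonomy=taxonomy,
                taxonomy_rank=cfg["taxonomy_rank"],
            )
            contrib.to_tsv(out / "contributions.tsv")
            record("contributions", out / "contributions.tsv")
            if taxonomy is not None:
                export_graphlan(
                    contrib, taxonomy,
                    out / "graphlan_annotation.txt",
                    out / "graphlan_tree.txt",
                )
                record("graphlan_annotation", out / "graphlan_annotation.txt")
                record("graphlan_tree", out / "graphlan_tree.txt")
            if model.n_comp >= 2:
                ellipses = confidence_ellipse(model.x_scores, labels)
                export_ellipses(ellipses, out / "ellipses.json")
                record("ellipses", out / "ellipses.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("splsda", exc) from exc
    else:
        raise PipelineError(
            "analysis", ValueError(f"unknown analysis {cfg['analysis']!r}")
        )

    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
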