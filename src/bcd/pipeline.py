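"""End-to-end pipeline: counts -> normalized -> HVG -> scaled -> PCA ->
corrected covariance -> whitened coordinates -> kNN -> Leiden -> UMAP.

``run_arrays`` is the in-memory core used by tests and scripts;
``run_pipeline`` wraps it with file I/O, artifact writing and a manifest
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, FeatureMatrix
from .metric import (
    BatchDesign,
    CorrectedCovariance,
    compute_corrected_covariance,
    whiten,
)
from .preprocess import normalize_cells, select_hvg, subset_genes, scale_genes, pca
from .downstream import (
    NeighborGraph,
    ClusterAssignment,
    EvaluationReport,
    build_knn_graph,
    cluster,
    embed_2d,
    evaluate,
)
from .io import read_counts, read_metadata, write_json

__all__ = ["RunConfig", "PipelineResult", "run_arrays", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Round-trips losslessly through JSON (``to_json``/``from_json``).
    """

    counts_path: str | None = None
    meta_path: str | None = None
    counts_format: str | None = None
    orientation: str | None = None
    batch_col: str = "sample"
    label_cols: list[str] = field(default_factory=lambda: ["day"])
    n_hvg: int = 150
    n_pcs: int = 30
    length_scale: float = 1.0
    ridge: float | str = "auto"
    k_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0
    use_bcd: bool = True
    embed: bool = True
    outdir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    pcs: FeatureMatrix
    coords: FeatureMatrix  # whitened coordinates (or raw PCs when use_bcd=False)
    cov: CorrectedCovariance | None
    graph: NeighborGraph
    clusters: ClusterAssignment
    embedding: np.ndarray | None
    report: EvaluationReport | None


def run_arrays(
    counts: CountMatrix,
    meta: pd.DataFrame,
    config: RunConfig,
    truth: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the pipeline on in-memory inputs.

    ``meta`` must contain ``cell_id``, the batch column and the label
    columns, covering every cell in ``counts``.  When ``truth`` (or
    ``meta`` itself) carries a ``type`` column, an evaluation report is
    produced.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    missing = [c for c in counts.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"metadata is missing cells, e.g. {missing[:5]}")
    meta = meta.loc[counts.cell_ids].reset_index().rename(columns={"index": "cell_id"})

    normalized = normalize_cells(counts)
    hvg = select_hvg(normalized, config.n_hvg)
    scaled = scale_genes(subset_genes(normalized, hvg.selected_genes))
    n_pcs = min(config.n_pcs, min(scaled.shape) - 1)
    pcs = pca(scaled, n_pcs)

    cov = None
    if config.use_bcd:
        design = BatchDesign.from_frame(
            meta, config.batch_col, config.label_cols, config.length_scale
        )
        cov = compute_corrected_covariance(pcs, design, ridge=config.ridge)
        coords = whiten(pcs, cov)
    else:
        coords = pcs

    graph = build_knn_graph(coords, config.k_neighbors)
    clusters = cluster(graph, resolution=config.resolution, seed=config.seed)
    embedding = embed_2d(coords, seed=config.seed) if config.embed else None

    report = None
    if truth is None and "type" in meta.columns:
        truth = meta
    if truth is not None and "type" in truth.columns:
        report = evaluate(clusters, truth, X_whitened=coords)
    return PipelineResult(
        pcs=pcs,
        coords=coords,
        cov=cov,
        graph=graph,
        clusters=clusters,
        embedding=embedding,
        report=report,
    )


def _write_matrix(fm: FeatureMatrix, path: Path) -> None:
    pd.DataFrame(fm.values, index=fm.cell_ids, columns=fm.feature_ids).to_csv(
        path, index_label="cell_id"
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs, run, write all artifacts."""
    if config.counts_path is None or config.meta_path is None:
        raise ValueError("counts_path and meta_path are required")
    counts = read_counts(
        config.counts_path, fmt=config.counts_format, orientation=config.orientation
    )
    meta = read_metadata(config.meta_path)
    result = run_arrays(counts, meta, config)

    outdir = Path(config.outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    _write_matrix(result.pcs, outdir / "pca.csv")
    _write_matrix(result.coords, outdir / "coordinates.csv")
    pd.DataFrame(
        {"cell_id": counts.cell_ids, "cluster": result.clusters.labels}
    ).to_csv(outdir / "clusters.csv", index=False)
    if result.embedding is not None:
        pd.DataFrame(
            {
                "cell_id": counts.cell_ids,
                "x": result.embedding[:, 0],
                "y": result.embedding[:, 1],
            }
        ).to_csv(outdir / "embedding.csv", index=False)
    if result.report is not None:
        write_json(asdict(result.report), outdir / "evaluation.json")
    manifest = {
        "config": json.loads(config.to_json()),
        "bcd_version": __version__,
        "numpy_version": np.__version__,
        "n_cells": counts.n_cells,
        "n_genes": counts.n_genes,
        "n_clusters": result.clusters.n_clusters,
        "sigma_condition_number": (
            result.cov.condition_number if result.cov is not None else None
        ),
        "ridge": result.cov.ridge if result.cov is not None else None,
    }
    write_json(manifest, outdir / "manifest.json")
    return result
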