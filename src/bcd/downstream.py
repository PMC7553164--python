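"""Downstream graph clustering, embedding and evaluation.

Consumes whitened coordinates (where Euclidean distance equals the
batch-corrected distance): exact kNN graph, Leiden community detection on
it, UMAP embedding, and scoring against simulator ground truth (adjusted
Rand index, batch-mixing entropy, silhouette).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .containers import FeatureMatrix
from ._neighbors import exact_knn

__all__ = [
    "NeighborGraph",
    "ClusterAssignment",
    "EvaluationReport",
    "build_knn_graph",
    "cluster",
    "embed_2d",
    "evaluate",
    "batch_mixing_entropy",
    "within_type_mixing",
]


@dataclass
class NeighborGraph:
    """Per-cell nearest neighbours under the whitened (BCD) metric."""

    indices: np.ndarray
    distances: np.ndarray
    k_neighbors: int
    cell_ids: np.ndarray = None

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids, contiguous from 0."""

    labels: np.ndarray
    resolution: float
    seed: int
    cell_ids: np.ndarray = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class EvaluationReport:
    """Cluster quality vs ground truth.

    ari: adjusted Rand index against true type labels, in [-1, 1].
    batch_mixing: cluster-size-weighted normalized entropy of sample
        composition within predicted clusters, in [0, 1] (1 = perfectly
        mixed samples).
    silhouette: mean silhouette of the clustering in whitened coordinates
        (NaN when not computable).
    """

    ari: float
    batch_mixing: float
    silhouette: float


def _coords(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.cell_ids
    return np.asarray(X, dtype=float), None


def build_knn_graph(X_whitened, k_neighbors: int) -> NeighborGraph:
    """Exact Euclidean kNN in whitened space; ties broken by cell index."""
    coords, ids = _coords(X_whitened)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 cells to build a neighbour graph")
    k = min(k_neighbors, coords.shape[0] - 1)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    idx, dist = exact_knn(coords, k)
    return NeighborGraph(indices=idx, distances=dist, k_neighbors=k, cell_ids=ids)


def cluster(
    graph: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Leiden community detection on the undirected kNN graph.

    Modularity-style (RB configuration) objective at the given resolution;
    deterministic for a fixed seed.  Leiden communities are connected, so
    disconnected graph components never share a cluster.  Cluster ids are
    relabelled contiguously in order of first appearance.
    """
    import igraph as ig
    import leidenalg

    n = graph.n_cells
    edges = set()
    for i in range(n):
        for j in graph.indices[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a != b:
                edges.add((a, b))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = np.asarray(part.membership, dtype=np.int64)
    # contiguous ids in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty_like(membership)
    for i, m in enumerate(membership):
        labels[i] = remap.setdefault(int(m), len(remap))
    return ClusterAssignment(
        labels=labels, resolution=resolution, seed=seed, cell_ids=graph.cell_ids
    )


def embed_2d(
    X_whitened,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """UMAP layout of the whitened coordinates; deterministic given seed."""
    import umap

    coords, _ = _coords(X_whitened)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to embed")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=int(seed),
        # spectral init needs enough points for the sparse eigensolver
        init="spectral" if n > 10 else "random",
    )
    return np.asarray(reducer.fit_transform(coords), dtype=float)


def _normalized_entropy(counts: np.ndarray, n_categories: int) -> float:
    """Entropy of a count vector normalized by log(n_categories)."""
    if n_categories < 2:
        return 0.0
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(n_categories))


def batch_mixing_entropy(labels: np.ndarray, samples: np.ndarray) -> float:
    """Cluster-size-weighted normalized entropy of samples within clusters."""
    labels = np.asarray(labels)
    samples = np.asarray(samples)
    n_samples = len(pd.unique(samples))
    total = len(labels)
    out = 0.0
    for c in np.unique(labels):
        mask = labels == c
        counts = pd.Series(samples[mask]).value_counts().to_numpy(dtype=float)
        out += mask.sum() / total * _normalized_entropy(counts, n_samples)
    return float(out)


def within_type_mixing(
    assign: ClusterAssignment, truth: pd.DataFrame, types=None
) -> pd.Series:
    """Per-true-type sample-mixing entropy of the predicted clustering.

    For each true type, restrict to its cells and compute the
    cluster-weighted normalized entropy of their sample labels (normalized
    by the number of samples contributing cells of that type).  Higher =
    the type's cells from different samples share clusters.
    """
    truth = _aligned_truth(assign, truth)
    if types is None:
        types = pd.unique(truth["type"])
    out = {}
    for t in types:
        mask = (truth["type"] == t).to_numpy()
        if not mask.any():
            continue
        sub_labels = assign.labels[mask]
        sub_samples = truth.loc[mask, "sample"].to_numpy()
        out[t] = batch_mixing_entropy(sub_labels, sub_samples)
    return pd.Series(out, dtype=float)


def _aligned_truth(assign: ClusterAssignment, truth: pd.DataFrame) -> pd.DataFrame:
    if len(truth) != len(assign.labels):
        raise ValueError("assignment and ground truth cover different cell sets")
    if assign.cell_ids is not None and "cell_id" in truth.columns:
        indexed = truth.set_index("cell_id")
        missing = [c for c in assign.cell_ids if c not in indexed.index]
        if missing:
            raise ValueError(f"ground truth is missing cells, e.g. {missing[:5]}")
        return indexed.loc[assign.cell_ids].reset_index()
    return truth.reset_index(drop=True)


def evaluate(
    assign: ClusterAssignment, truth: pd.DataFrame, X_whitened=None
) -> EvaluationReport:
    """Score a clustering against ground truth.

    ARI uses the standard pair-counting formula against ``truth["type"]``;
    batch mixing is the normalized sample entropy within predicted
    clusters; silhouette is computed in whitened coordinates when given.
    """
    truth = _aligned_truth(assign, truth)
    ari = float(adjusted_rand_score(truth["type"].to_numpy(), assign.labels))
    mixing = batch_mixing_entropy(assign.labels, truth["sample"].to_numpy())
    sil = float("nan")
    if X_whitened is not None:
        coords, _ = _coords(X_whitened)
        n_clusters = len(np.unique(assign.labels))
        if 2 <= n_clusters <= coords.shape[0] - 1:
            sil = float(silhouette_score(coords, assign.labels))
    return EvaluationReport(ari=ari, batch_mixing=mixing, silhouette=sil)
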