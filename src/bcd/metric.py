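"""The batch-corrected distance (BCD) metric.

Batch effects in longitudinal or spatial single-cell experiments are
systematic technical offsets between separately processed samples.  When
samples carry a temporal/spatial label, differences between batches
collected at *proximal* labels are mostly nuisance, while differences
between distant labels carry the biology (development, disease
progression).  BCD encodes this with a Mahalanobis-style distance

    d(x_i, x_j) = sqrt((x_i - x_j)^T (Sigma~ + ridge*I)^{-1} (x_i - x_j))

whose covariance is the locality-weighted between-batch scatter

    Sigma~ = sum_i sum_{j : i not in C_j} W_ij (x_i - m_j)(x_i - m_j)^T,

where C_j is the set of cells in batch j, m_j its centroid, and the weight
is a Gaussian kernel on the gap between the label tau_i of cell i's own
batch and the label t_j of batch j:

    W_ij = exp(-||tau_i - t_j||^2 / (2 l^2)).

Directions along which temporally/spatially close batches differ dominate
Sigma~ and are shrunk by its inverse; with W identically one the
construction reduces to the unweighted alternative-clustering metric of
Qi and Davidson.  The inverse lower Cholesky factor of Sigma~ + ridge*I is
a whitening transform under which plain Euclidean distance realizes BCD,
so any distance-based clustering or embedding method can consume it.
With k features (typically the top principal components) the cost is
O(n k^2 + k^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist, pdist, squareform

from .containers import FeatureMatrix
from ._neighbors import exact_knn

__all__ = [
    "BatchDesign",
    "LocalityWeights",
    "CorrectedCovariance",
    "DegenerateDesignError",
    "WhiteningError",
    "compute_locality_weights",
    "compute_batch_centroids",
    "compute_corrected_covariance",
    "whiten",
    "bcd_distance",
    "bcd_distance_squared",
    "pairwise_bcd",
    "KNNDistances",
]


class DegenerateDesignError(ValueError):
    """Raised when the batch design cannot support batch correction."""


class WhiteningError(RuntimeError):
    """Raised when Sigma~ + ridge*I is not positive definite."""


@dataclass
class BatchDesign:
    """Partition of cells into batches plus per-batch covariate labels.

    Parameters
    ----------
    batch_index : (n_cells,) int array mapping each cell to a batch.
    batch_ids : (n_batches,) ordered batch identifiers.
    batch_labels : (n_batches, d) real label vectors t_j — temporal,
        spatial, or a concatenation such as [week, location].  The scale of
        each component relative to ``length_scale`` is the user's choice.
    length_scale : kernel bandwidth l > 0 within which batches count as
        temporally/spatially close.
    """

    batch_index: np.ndarray
    batch_ids: np.ndarray
    batch_labels: np.ndarray
    length_scale: float = 1.0

    def __post_init__(self):
        self.batch_index = np.asarray(self.batch_index, dtype=np.int64)
        self.batch_ids = np.asarray(self.batch_ids, dtype=object)
        self.batch_labels = np.atleast_2d(np.asarray(self.batch_labels, dtype=float))
        if self.length_scale <= 0:
            raise ValueError(f"length_scale must be positive, got {self.length_scale}")
        B = len(self.batch_ids)
        if self.batch_labels.shape[0] != B:
            raise ValueError(
                f"{B} batches but {self.batch_labels.shape[0]} label vectors"
            )
        if not np.all(np.isfinite(self.batch_labels)):
            raise ValueError("batch labels contain non-finite entries")
        if self.batch_index.min(initial=0) < 0 or self.batch_index.max(initial=0) >= B:
            raise ValueError("batch_index entries outside [0, n_batches)")

    @classmethod
    def from_frame(
        cls,
        meta: pd.DataFrame,
        batch_col: str,
        label_cols: list[str] | str,
        length_scale: float = 1.0,
    ) -> "BatchDesign":
        """Build a design from per-cell metadata.

        Batches are ordered by first appearance; each batch must have a
        single consistent label vector across its cells.
        """
        if isinstance(label_cols, str):
            label_cols = [label_cols]
        for col in [batch_col, *label_cols]:
            if col not in meta.columns:
                raise ValueError(f"metadata is missing column {col!r}")
        batch_ids = meta[batch_col].drop_duplicates().to_numpy(dtype=object)
        lookup = {b: i for i, b in enumerate(batch_ids)}
        batch_index = meta[batch_col].map(lookup).to_numpy(dtype=np.int64)
        labels = np.empty((len(batch_ids), len(label_cols)), dtype=float)
        for b, i in lookup.items():
            sub = meta.loc[meta[batch_col] == b, label_cols].drop_duplicates()
            if len(sub) != 1:
                raise ValueError(f"batch {b!r} has inconsistent labels")
            labels[i] = sub.to_numpy(dtype=float)[0]
        return cls(batch_index, batch_ids, labels, length_scale)

    @property
    def n_cells(self) -> int:
        return self.batch_index.shape[0]

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)

    @property
    def label_dim(self) -> int:
        return self.batch_labels.shape[1]

    @property
    def cell_labels(self) -> np.ndarray:
        """tau_i: each cell inherits its batch's label vector."""
        return self.batch_labels[self.batch_index]


@dataclass
class LocalityWeights:
    """Gaussian locality kernel W_ij in (0, 1], cells x batches."""

    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (cells x batches)")
        if self.W.size and (self.W.min() <= 0 or self.W.max() > 1):
            raise ValueError("weights must lie in (0, 1]")


@dataclass
class CorrectedCovariance:
    """Sigma~ with its ridge and whitening factor.

    ``whitener`` is T = L^{-1} for the lower Cholesky factor L of
    Sigma~ + ridge*I, so that T (Sigma~ + ridge*I) T^T = I and Euclidean
    distance between rows of X T^T equals BCD between rows of X.
    """

    sigma_tilde: np.ndarray
    ridge: float
    whitener: np.ndarray

    @property
    def k(self) -> int:
        return self.sigma_tilde.shape[0]

    @property
    def regularized(self) -> np.ndarray:
        return self.sigma_tilde + self.ridge * np.eye(self.k)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.regularized))


class KNNDistances(NamedTuple):
    """Condensed kNN form of a distance matrix."""

    indices: np.ndarray
    distances: np.ndarray


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def compute_locality_weights(design: BatchDesign) -> LocalityWeights:
    """W_ij = exp(-||tau_i - t_j||^2 / (2 l^2)) for every cell i, batch j."""
    sq = cdist(design.cell_labels, design.batch_labels, metric="sqeuclidean")
    W = np.exp(-sq / (2.0 * design.length_scale**2))
    # guard against underflow to exactly 0 for very distant labels
    np.maximum(W, np.finfo(float).tiny, out=W)
    return LocalityWeights(W)


def compute_batch_centroids(X, design: BatchDesign) -> np.ndarray:
    """Arithmetic mean m_j of the rows of X in each batch C_j."""
    values = _values(X)
    if values.shape[0] != design.n_cells:
        raise ValueError("X and design disagree on the number of cells")
    sizes = np.bincount(design.batch_index, minlength=design.n_batches)
    if (sizes == 0).any():
        empty = design.batch_ids[sizes == 0].tolist()
        raise ValueError(f"batches with zero cells: {empty}")
    sums = np.zeros((design.n_batches, values.shape[1]))
    np.add.at(sums, design.batch_index, values)
    return sums / sizes[:, None]


def compute_corrected_covariance(
    X,
    design: BatchDesign,
    weights: LocalityWeights | None = None,
    ridge: float | str = "auto",
    normalize: bool = False,
) -> CorrectedCovariance:
    """Locality-weighted between-batch scatter and its whitener.

    Accumulates, one batch at a time, the weighted scatter of all cells
    *outside* batch j around its centroid m_j — never materializing the
    n x B individual outer products.

    Parameters
    ----------
    ridge : nonnegative diagonal regularizer added before the Cholesky
        factorization.  ``"auto"`` (default) uses 1e-6 * trace(Sigma~)/k,
        negligible when Sigma~ is well conditioned but enough to factor a
        rank-deficient scatter.
    normalize : divide Sigma~ by the total weight sum.  Off by default
        (the literal unnormalized sum); the overall scale rescales all
        distances jointly and leaves neighbour rankings unchanged.
    """
    values = _values(X)
    n, k = values.shape
    if design.n_batches < 2:
        raise DegenerateDesignError(
            "only one batch present: the between-batch sum is empty. "
            "A single batch needs no batch correction — use Euclidean "
            "distance (identity covariance) instead."
        )
    if weights is None:
        weights = compute_locality_weights(design)
    W = weights.W
    if W.shape != (n, design.n_batches):
        raise ValueError(
            f"weights shaped {W.shape}, expected {(n, design.n_batches)}"
        )
    centroids = compute_batch_centroids(values, design)
    S = np.zeros((k, k))
    total_w = 0.0
    for j in range(design.n_batches):
        outside = design.batch_index != j
        D = values[outside] - centroids[j]
        w = W[outside, j]
        S += D.T @ (D * w[:, None])
        total_w += w.sum()
    if normalize and total_w > 0:
        S /= total_w
    S = (S + S.T) / 2.0  # enforce exact symmetry
    if ridge == "auto":
        ridge = 1e-6 * np.trace(S) / k
    ridge = float(ridge)
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    A = S + ridge * np.eye(k)
    try:
        L = scipy.linalg.cholesky(A, lower=True)
    except scipy.linalg.LinAlgError as err:
        smallest = float(np.linalg.eigvalsh(A).min())
        raise WhiteningError(
            f"Sigma~ + ridge*I is not positive definite (smallest "
            f"eigenvalue {smallest:.3e}); increase ridge"
        ) from err
    whitener = scipy.linalg.solve_triangular(L, np.eye(k), lower=True)
    return CorrectedCovariance(sigma_tilde=S, ridge=ridge, whitener=whitener)


def whiten(X, cov: CorrectedCovariance) -> FeatureMatrix:
    """Transform rows by the whitener: Euclidean distance afterwards = BCD."""
    values = _values(X)
    if values.shape[1] != cov.k:
        raise ValueError(
            f"X has {values.shape[1]} features but the whitener expects {cov.k}"
        )
    out = values @ cov.whitener.T
    if isinstance(X, FeatureMatrix):
        ids = X.cell_ids
    else:
        ids = None
    features = np.array([f"BCD{i + 1}" for i in range(cov.k)], dtype=object)
    return FeatureMatrix(out, cell_ids=ids, feature_ids=features)


def bcd_distance_squared(x_i, x_j, cov: CorrectedCovariance) -> float:
    """Squared form (x_i - x_j)^T (Sigma~ + ridge*I)^{-1} (x_i - x_j)."""
    diff = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    if diff.shape != (cov.k,):
        raise ValueError(f"expected vectors of length {cov.k}")
    z = cov.whitener @ diff
    return float(z @ z)


def bcd_distance(x_i, x_j, cov: CorrectedCovariance) -> float:
    """Metric (square-root) form of the batch-corrected distance.

    The square root restores the triangle inequality that downstream
    graph/trajectory methods rely on; rankings are identical either way.
    """
    return float(np.sqrt(bcd_distance_squared(x_i, x_j, cov)))


def pairwise_bcd(
    X,
    cov: CorrectedCovariance,
    mode: str = "full",
    k_neighbors: int | None = None,
):
    """All-pairs (``mode="full"``) or kNN (``mode="knn"``) BCD distances.

    Both modes work in whitened coordinates, so cost is one O(n k^2)
    transform plus a Euclidean distance computation.
    """
    values = _values(whiten(X, cov))
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for pairwise distances")
    if mode == "full":
        return squareform(pdist(values))
    if mode == "knn":
        if k_neighbors is None:
            raise ValueError("knn mode requires k_neighbors")
        if k_neighbors >= n:
            raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
        idx, dist = exact_knn(values, k_neighbors)
        return KNNDistances(indices=idx, distances=dist)
    raise ValueError(f"unknown mode {mode!r}")
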