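"""Lightweight aligned-matrix containers shared across the package.

Two thin dataclasses carry the data through the pipeline: ``CountMatrix``
for raw nonnegative counts (sparse-capable) and ``FeatureMatrix`` for any
dense numeric cell x feature matrix (normalized expression, scaled values,
PC coordinates, whitened coordinates).  Both keep ordered, unique cell and
feature identifiers aligned with the rows/columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "FeatureMatrix"]


def _check_ids(ids, n: int, kind: str) -> np.ndarray:
    if ids is None:
        return np.array([f"{kind}{i}" for i in range(n)], dtype=object)
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(f"expected {n} {kind} identifiers, got shape {arr.shape}")
    if len(set(arr)) != n:
        raise ValueError(f"{kind} identifiers are not unique")
    return arr


@dataclass
class FeatureMatrix:
    """Dense cells x features matrix with aligned identifiers.

    Invariants: finite values, at least one cell and one feature, unique
    ``cell_ids`` and ``feature_ids``.
    """

    values: np.ndarray
    cell_ids: np.ndarray = None
    feature_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise ValueError("matrix must have at least one cell and one feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        self.cell_ids = _check_ids(self.cell_ids, n, "cell_")
        self.feature_ids = _check_ids(self.feature_ids, k, "feature_")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CountMatrix:
    """Nonnegative cells x genes count (or expression) matrix.

    ``counts`` may be a dense ndarray or any scipy sparse matrix; sparse
    input is kept sparse until a dense view is requested.
    """

    counts: object
    cell_ids: np.ndarray = None
    gene_ids: np.ndarray = None

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
            data = self.counts.data
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.ndim != 2:
                raise ValueError("counts must be a 2-D matrix")
            data = self.counts
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValueError("counts must be finite and nonnegative")
        n, g = self.counts.shape
        self.cell_ids = _check_ids(self.cell_ids, n, "cell_")
        self.gene_ids = _check_ids(self.gene_ids, g, "gene_")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        """Dense float view of the counts."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)
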