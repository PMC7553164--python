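"""Exact k-nearest-neighbour search with deterministic tie-breaking."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def exact_knn(coords: np.ndarray, k: int, chunk: int = 1024):
    """Exact Euclidean kNN (self excluded), ties broken by cell index.

    Returns (indices, distances), each of shape (n, k), rows sorted by
    ascending distance.  Brute force in row chunks; stable argsort makes
    equal-distance neighbours come out in index order.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be smaller than n_cells={n}")
    indices = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=float)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        rows = np.arange(stop - start)
        d[rows, start + rows] = np.inf  # exclude self
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        distances[start:stop] = np.take_along_axis(d, order, axis=1)
    return indices, distances
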