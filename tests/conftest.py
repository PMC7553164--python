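import numpy as np
import pytest

from bcd.metric import BatchDesign


def sigma_two_loop(X, batch_index, W):
    """Literal two-loop transcription of the corrected covariance sum.

    Independent oracle: per-cell, per-batch outer products accumulated
    naively, skipping a cell's own batch.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    B = W.shape[1]
    centroids = [X[batch_index == j].mean(axis=0) for j in range(B)]
    S = np.zeros((k, k))
    for i in range(n):
        for j in range(B):
            if batch_index[i] == j:
                continue
            d = X[i] - centroids[j]
            S += W[i, j] * np.outer(d, d)
    return S


def random_instance(rng, n=None, B=None, k=None, d=1):
    """Random feature matrix + batch design with scalar/vector labels."""
    n = n if n is not None else int(rng.integers(10, 201))
    B = B if B is not None else int(rng.integers(2, 9))
    k = k if k is not None else int(rng.integers(1, 11))
    # every batch nonempty
    batch_index = np.concatenate(
        [np.arange(B), rng.integers(0, B, size=n - B)]
    )
    rng.shuffle(batch_index)
    X = rng.normal(size=(n, k))
    labels = rng.normal(size=(B, d))
    design = BatchDesign(
        batch_index=batch_index,
        batch_ids=np.array([f"b{j}" for j in range(B)], dtype=object),
        batch_labels=labels,
        length_scale=float(rng.uniform(0.5, 2.0)),
    )
    return X, design


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
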