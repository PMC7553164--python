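"""Expression preprocessing chain feeding the metric.

Standard single-cell protocol, in order: per-cell sum normalization,
highly-variable-gene (HVG) selection by a variance-stabilizing
standardized-variance score, per-gene scaling to zero mean / unit sd, and
PCA.  The batch-corrected covariance is then computed on the PC
coordinates (gene space remains possible — any FeatureMatrix works).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import CountMatrix, FeatureMatrix

__all__ = [
    "HVGSelection",
    "normalize_cells",
    "select_hvg",
    "subset_genes",
    "scale_genes",
    "pca",
]


def _dense(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, CountMatrix):
        return X.dense(), X.cell_ids, X.gene_ids
    if isinstance(X, FeatureMatrix):
        return X.values, X.cell_ids, X.feature_ids
    arr = np.asarray(X, dtype=float)
    fm = FeatureMatrix(arr)
    return fm.values, fm.cell_ids, fm.feature_ids


@dataclass
class HVGSelection:
    """Result of highly-variable-gene selection.

    ``selected_genes`` holds the top-``n_hvg`` genes by standardized
    variance (descending; ties broken by input gene order);
    ``standardized_variance`` keeps the per-gene score for all genes.
    """

    selected_genes: np.ndarray
    standardized_variance: np.ndarray
    n_hvg: int


def normalize_cells(
    counts, scale_factor: float = 1.0, log1p: bool = False
) -> FeatureMatrix:
    """Scale each cell so its gene expression sums to one.

    The literal sum-to-one normalization (no library-size scale factor, no
    log transform) is the default; ``scale_factor`` and ``log1p`` are
    available for the customary variants and are off by default.
    """
    values, cell_ids, gene_ids = _dense(counts)
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = np.asarray(cell_ids)[totals <= 0][:10].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    out = values / totals[:, None] * scale_factor
    if log1p:
        out = np.log1p(out)
    return FeatureMatrix(out, cell_ids=cell_ids, feature_ids=gene_ids)


def select_hvg(
    counts, n_hvg: int, span: float = 0.3, clip_max: float | None = None
) -> HVGSelection:
    """Rank genes by variance-stabilized standardized variance.

    The established vst recipe: fit a smooth mean-variance trend across
    genes (lowess of log10 variance on log10 mean, span ``span``),
    standardize each gene's values by the trend-predicted standard
    deviation, clip standardized values at sqrt(n_cells) (``clip_max``
    overrides), and score each gene by the sample variance of its clipped
    standardized values.  Genes with zero variance or zero mean score 0.
    Ties are broken deterministically by gene order.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    values, _, gene_ids = _dense(counts)
    n, g = values.shape
    if n_hvg > g:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {g} available genes; returning all genes",
            UserWarning,
            stacklevel=2,
        )
        n_hvg = g
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1) if n > 1 else np.zeros(g)
    usable = (var > 0) & (mean > 0)
    scores = np.zeros(g)
    if usable.any():
        from statsmodels.nonparametric.smoothers_lowess import lowess

        logm = np.log10(mean[usable])
        logv = np.log10(var[usable])
        if np.ptp(logm) == 0:
            fitted = np.full(logm.shape, logv.mean())
        else:
            fitted = lowess(logv, logm, frac=span, return_sorted=False)
        expected_sd = np.sqrt(10.0**fitted)
        cmax = np.sqrt(n) if clip_max is None else float(clip_max)
        Z = (values[:, usable] - mean[usable]) / expected_sd
        np.minimum(Z, cmax, out=Z)
        scores[usable] = Z.var(axis=0, ddof=1)
    order = np.argsort(-scores, kind="stable")
    selected = np.asarray(gene_ids, dtype=object)[order[:n_hvg]]
    return HVGSelection(
        selected_genes=selected, standardized_variance=scores, n_hvg=n_hvg
    )


def subset_genes(X: FeatureMatrix, genes) -> FeatureMatrix:
    """Column subset in the order given by ``genes``."""
    lookup = {gid: i for i, gid in enumerate(X.feature_ids)}
    try:
        cols = [lookup[g] for g in genes]
    except KeyError as err:
        raise ValueError(f"gene {err.args[0]!r} not present in the matrix") from err
    return FeatureMatrix(
        X.values[:, cols],
        cell_ids=X.cell_ids,
        feature_ids=np.asarray(list(genes), dtype=object),
    )


def scale_genes(X, ddof: int = 1) -> FeatureMatrix:
    """Standardize each gene to mean 0 and sd 1 (sample sd, ddof=1).

    Constant genes map to all-zero columns rather than dividing by zero.
    """
    values, cell_ids, gene_ids = _dense(X)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof) if values.shape[0] > ddof else np.zeros(
        values.shape[1]
    )
    out = values - mean
    nonzero = sd > 0
    out[:, nonzero] /= sd[nonzero]
    out[:, ~nonzero] = 0.0
    return FeatureMatrix(out, cell_ids=cell_ids, feature_ids=gene_ids)


def pca(X, n_pcs: int, return_info: bool = False):
    """Top-``n_pcs`` principal-component coordinates.

    Deterministic sign convention: each axis is flipped so its
    largest-magnitude loading is positive.  With ``return_info`` a dict of
    explained variance ratios, loadings and the column means is returned
    alongside the coordinates.
    """
    values, cell_ids, _ = _dense(X)
    n, k = values.shape
    if n_pcs < 1 or n_pcs > min(n, k):
        raise ValueError(
            f"n_pcs must be in [1, {min(n, k)}] for a {n} x {k} matrix, got {n_pcs}"
        )
    model = PCA(n_components=n_pcs, svd_solver="full")
    coords = model.fit_transform(values)
    components = model.components_.copy()
    for c in range(n_pcs):
        pivot = np.argmax(np.abs(components[c]))
        if components[c, pivot] < 0:
            components[c] *= -1
            coords[:, c] *= -1
    fm = FeatureMatrix(
        coords,
        cell_ids=cell_ids,
        feature_ids=np.array([f"PC{i + 1}" for i in range(n_pcs)], dtype=object),
    )
    if return_info:
        info = {
            "explained_variance_ratio": model.explained_variance_ratio_.copy(),
            "components": components,
            "mean": model.mean_.copy(),
        }
        return fm, info
    return fm
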