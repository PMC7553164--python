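"""Readers and writers for the on-disk formats.

Counts come in as Matrix Market sparse triplets with gene/barcode sidecar
files (10x layout, genes x cells on disk by default) or as dense CSV/TSV
(cells x genes by default; both orientations overridable).  Metadata is a
delimited table with a ``cell_id`` column.  Duplicate coordinates in a
Matrix Market file are summed, per the format's convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_json",
]


def _read_lines(path: Path) -> np.ndarray:
    # sidecars may be 1-column (barcodes) or multi-column TSV (features);
    # the first column is the identifier
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return np.array(ids, dtype=object)


def read_counts(
    path,
    fmt: str | None = None,
    orientation: str | None = None,
    genes=None,
    barcodes=None,
    sep: str = ",",
) -> CountMatrix:
    """Read a count matrix into the cells x genes orientation.

    Parameters
    ----------
    fmt : ``"mtx"`` or ``"csv"``; inferred from the suffix when None.
    orientation : layout on disk — ``"genes_by_cells"`` (MTX default, the
        10x convention) or ``"cells_by_genes"`` (CSV default).
    genes, barcodes : sidecar paths for MTX input; default to
        ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` next to the
        matrix file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        orientation = orientation or "genes_by_cells"
        try:
            mat = scipy.io.mmread(path)
        except Exception as err:
            raise ValueError(f"failed to parse Matrix Market file {path}: {err}") from err
        mat = sp.csr_matrix(mat)  # sums duplicate coordinates
        if genes is None:
            for cand in ("genes.tsv", "features.tsv"):
                if (path.parent / cand).exists():
                    genes = path.parent / cand
                    break
        if barcodes is None and (path.parent / "barcodes.tsv").exists():
            barcodes = path.parent / "barcodes.tsv"
        gene_ids = _read_lines(Path(genes)) if genes else None
        cell_ids = _read_lines(Path(barcodes)) if barcodes else None
        if orientation == "genes_by_cells":
            mat = mat.T.tocsr()
        n, g = mat.shape
        if gene_ids is not None and len(gene_ids) != g:
            raise ValueError(
                f"{genes}: {len(gene_ids)} gene ids for a matrix with {g} genes"
            )
        if cell_ids is not None and len(cell_ids) != n:
            raise ValueError(
                f"{barcodes}: {len(cell_ids)} barcodes for a matrix with {n} cells"
            )
        return CountMatrix(mat, cell_ids=cell_ids, gene_ids=gene_ids)
    if fmt == "csv":
        orientation = orientation or "cells_by_genes"
        if path.suffix in (".tsv", ".txt"):
            sep = "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        return CountMatrix(
            df.to_numpy(dtype=float),
            cell_ids=df.index.to_numpy(dtype=object),
            gene_ids=df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(cm: CountMatrix, outdir, fmt: str = "mtx") -> Path:
    """Write counts; MTX goes out genes x cells with TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mat = cm.counts if sp.issparse(cm.counts) else sp.csr_matrix(cm.counts)
        target = outdir / "matrix.mtx"
        scipy.io.mmwrite(target, sp.coo_matrix(mat.T))
        (outdir / "genes.tsv").write_text(
            "".join(f"{g}\t{g}\n" for g in cm.gene_ids)
        )
        (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))
        return target
    if fmt == "csv":
        target = outdir / "counts.csv"
        pd.DataFrame(cm.dense(), index=cm.cell_ids, columns=cm.gene_ids).to_csv(target)
        return target
    raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path, cell_id_col: str = "cell_id") -> pd.DataFrame:
    """Read the per-cell metadata table (CSV/TSV by suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    meta = pd.read_csv(path, sep=sep)
    if cell_id_col not in meta.columns:
        raise ValueError(f"{path}: metadata is missing the {cell_id_col!r} column")
    return meta


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
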