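"""Loading, quality filtering, and normalization of expression matrices.

The pipeline operates on a cells × genes matrix. Raw counts are filtered
(low-expression genes first, then low-coverage cells), library-size scaled,
log-transformed, and reduced to the top-variance genes before any model
fitting happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread


class Space(str, Enum):
    """Which space the matrix values live in."""

    RAW_COUNTS = "raw_counts"
    LOG_NORMALIZED = "log_normalized"


@dataclass
class ExpressionMatrix:
    """A dense cells × genes expression matrix with row/column names.

    Attributes
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Expression values; nonnegative counts when ``space`` is raw.
    cell_ids, gene_ids : list of str
        Unique identifiers for rows and columns.
    space : Space
        ``raw_counts`` or ``log_normalized``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    space: Space = Space.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.space == Space.RAW_COUNTS and np.any(self.values < 0):
            raise ValueError("raw count matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write as cells × genes CSV with cell ids in the first column."""
        pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids).to_csv(path)


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_expression(
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "cells_by_genes",
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or MatrixMarket.

    Parameters
    ----------
    path : path
        Input file. CSV/TSV must carry a header row and first-column ids.
        MTX requires sidecar ``row_names`` / ``col_names`` text files
        (one id per line).
    fmt : {"csv", "tsv", "mtx"}
    orientation : {"cells_by_genes", "genes_by_cells"}
        How rows/columns of the *file* are laid out; output is always
        cells × genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise ValueError(f"non-numeric entries in {path}")
        values = df.to_numpy(dtype=float)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    elif fmt == "mtx":
        if row_names is None or col_names is None:
            raise ValueError("MTX input requires row_names and col_names files")
        mat = mmread(path)
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        rows = _read_names(Path(row_names))
        cols = _read_names(Path(col_names))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "genes_by_cells":
        values = values.T
        rows, cols = cols, rows

    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(f"negative entry at cell {rows[bad[0]]!r}, gene {cols[bad[1]]!r}")
    return ExpressionMatrix(values=values, cell_ids=rows, gene_ids=cols, space=Space.RAW_COUNTS)


def filter_low_expression(
    m: ExpressionMatrix,
    min_cells_frac: float = 0.01,
    min_genes_per_cell: int = 200,
) -> ExpressionMatrix:
    """Remove low-expression genes, then low-coverage cells.

    Genes detected (value > 0) in fewer than ``min_cells_frac * n_cells``
    cells are dropped first; then cells expressing fewer than
    ``min_genes_per_cell`` of the surviving genes are dropped. Survivor
    order is preserved.
    """
    if m.space != Space.RAW_COUNTS:
        raise ValueError("filtering expects raw counts")
    x = m.values
    gene_keep = (x > 0).sum(axis=0) >= min_cells_frac * m.n_cells
    if not gene_keep.any():
        raise ValueError("all genes removed; lower min_cells_frac")
    x = x[:, gene_keep]
    cell_keep = (x > 0).sum(axis=1) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError("all cells removed; lower min_genes_per_cell")
    return ExpressionMatrix(
        values=x[cell_keep],
        cell_ids=[c for c, k in zip(m.cell_ids, cell_keep) if k],
        gene_ids=[g for g, k in zip(m.gene_ids, gene_keep) if k],
        space=Space.RAW_COUNTS,
    )


def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size scale each cell and apply log1p.

    Each entry x becomes ``log(1 + scale * x / libsize)`` where libsize is
    the cell's total count. Zeros map to zeros.
    """
    if m.space != Space.RAW_COUNTS:
        raise ValueError("log_normalize expects raw counts")
    lib = m.values.sum(axis=1)
    if np.any(lib == 0):
        bad = m.cell_ids[int(np.argmax(lib == 0))]
        raise ValueError(f"cell {bad!r} has zero library size")
    values = np.log1p(scale * m.values / lib[:, None])
    return replace(m, values=values, space=Space.LOG_NORMALIZED)


def select_top_variance_genes(m: ExpressionMatrix, n_top: int = 2000) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with largest standard deviation.

    Genes are ranked by per-gene sd (descending); ties keep original file
    order. If fewer than ``n_top`` genes exist, all are kept (still
    reordered by sd).
    """
    if m.space != Space.LOG_NORMALIZED:
        raise ValueError("gene selection expects log-normalized values")
    sd = m.values.std(axis=0, ddof=0)
    # stable sort on -sd keeps original order within ties
    order = np.argsort(-sd, kind="stable")[: min(n_top, m.n_genes)]
    return replace(
        m,
        values=m.values[:, order],
        gene_ids=[m.gene_ids[i] for i in order],
    )
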