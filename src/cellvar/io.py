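"""Readers and writers for the on-disk formats used by the pipeline.

Counts travel as MatrixMarket coordinate files (genes are rows, cells are
columns) with sidecar `genes.tsv` / `cells.tsv` ID files, or as a single
TSV with gene IDs in the first column and cell IDs in the header. All
metadata tables are tab-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def write_counts_mtx(counts: pd.DataFrame, directory: str | Path, prefix: str = "counts") -> None:
    """Write a genes x cells count matrix as `<prefix>.mtx` plus sidecar ID files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.coo_matrix(np.asarray(counts.values))
    scipy.io.mmwrite(str(directory / f"{prefix}.mtx"), mat)
    counts.index.to_series().to_csv(directory / "genes.tsv", sep="\t", index=False, header=["gene_id"])
    counts.columns.to_series().to_csv(directory / "cells.tsv", sep="\t", index=False, header=["cell_id"])


def read_counts_mtx(directory: str | Path, prefix: str = "counts") -> pd.DataFrame:
    directory = Path(directory)
    mat = scipy.io.mmread(str(directory / f"{prefix}.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")["gene_id"].astype(str)
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")["cell_id"].astype(str)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match sidecar IDs "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(dense, index=genes.values, columns=cells.values)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(table: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    table.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
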