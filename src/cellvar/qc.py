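"""Cell quality control and normalization.

Cells are kept only when the capture site held exactly one intact cell,
at least 500,000 reads mapped to exons, and at most 10% of reads mapped
to mitochondrial genes. Depth normalization uses the median-of-ratios
size-factor estimator; batch structure is removed by per-gene location
and scale adjustment on log2(x + 1), nested within culture condition so
biological differences between conditions survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSEUDOCOUNT = 1.0  # the single pseudocount used for every log transform

_QC_COLUMNS = ("exon_reads", "total_reads", "mito_reads", "capture_ok")


@dataclass
class FilterReport:
    """Cells removed per criterion (a cell counts toward every criterion it fails)."""

    n_input: int
    n_kept: int
    n_bad_capture: int
    n_low_exon_reads: int
    n_high_mito: int


def filter_cells(
    cells: pd.DataFrame,
    min_exon_reads: int = 500_000,
    max_mito_fraction: float = 0.10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cell QC criteria; returns (kept cells, removal report)."""
    for col in _QC_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing required QC column {col!r}")
    bad_capture = ~cells["capture_ok"].astype(bool)
    low_exon = cells["exon_reads"] < min_exon_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = cells["mito_reads"] / cells["total_reads"]
    high_mito = mito_frac > max_mito_fraction
    keep = ~(bad_capture | low_exon | high_mito)
    report = FilterReport(
        n_input=len(cells),
        n_kept=int(keep.sum()),
        n_bad_capture=int(bad_capture.sum()),
        n_low_exon_reads=int(low_exon.sum()),
        n_high_mito=int(high_mito.sum()),
    )
    return cells.loc[keep].copy(), report


def size_factors(counts: pd.DataFrame, spike_mask: pd.Series | None = None) -> pd.Series:
    """Median-of-ratios per-cell size factors.

    For cell j, s_j is the median over reference genes g of
    count(g, j) / geomean_cells(count(g, .)); reference genes are those
    with a positive geometric mean, i.e. nonzero in every cell. Spike-in
    genes are excluded by default when a mask is given, since their counts
    track depth rather than cellular mRNA content.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 cells")
    mat = counts
    if spike_mask is not None:
        mat = counts.loc[~spike_mask.reindex(counts.index, fill_value=False).astype(bool)]
    vals = mat.to_numpy(dtype=float)
    all_positive = (vals > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene is expressed in every cell; filter to a common gene subset first"
        )
    logs = np.log(vals[all_positive])
    log_geomean = logs.mean(axis=1)
    s = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each cell's counts by its size factor."""
    if not counts.columns.equals(s.index):
        if set(counts.columns) != set(s.index):
            raise ValueError("size factors do not match the count matrix cells")
        s = s.reindex(counts.columns)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / s


def batch_adjust(
    norm: pd.DataFrame,
    batches: pd.Series,
    conditions: pd.Series | None = None,
) -> pd.DataFrame:
    """Remove per-gene batch location and scale effects on log2(x + 1).

    Within each condition (or globally when `conditions` is None), each
    gene's log values are standardized per batch and mapped back onto the
    condition's pooled mean and standard deviation, then back-transformed.
    A zero-variance batch maps to the pooled mean. Cell, gene and label
    order are untouched.
    """
    batches = batches.reindex(norm.columns)
    if batches.isna().any():
        raise ValueError("batch labels missing for some cells")
    if conditions is None:
        conditions = pd.Series("all", index=norm.columns)
    else:
        conditions = conditions.reindex(norm.columns)
    log = np.log2(norm.to_numpy(dtype=float) + PSEUDOCOUNT)
    out = log.copy()
    for cond in conditions.unique():
        cond_cols = np.flatnonzero(conditions.values == cond)
        pooled_mean = log[:, cond_cols].mean(axis=1)
        pooled_sd = log[:, cond_cols].std(axis=1, ddof=0)
        for b in batches.iloc[cond_cols].unique():
            cols = np.flatnonzero((batches.values == b) & (conditions.values == cond))
            if len(cols) < 2:
                raise ValueError(f"batch {b!r} has fewer than 2 cells")
            bm = log[:, cols].mean(axis=1)
            bs = log[:, cols].std(axis=1, ddof=0)
            z = np.where(bs[:, None] > 0, (log[:, cols] - bm[:, None]) / np.where(bs[:, None] > 0, bs[:, None], 1.0), 0.0)
            out[:, cols] = pooled_mean[:, None] + pooled_sd[:, None] * z
    adjusted = np.maximum(np.exp2(out) - PSEUDOCOUNT, 0.0)
    return pd.DataFrame(adjusted, index=norm.index, columns=norm.columns)
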