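"""Gene-gene correlation mining for regulatory-network candidates.

Pairwise Spearman correlations across cells over a chosen gene subset
(log2(x + 1) of normalized expression), with large-sample t-based
p-values and BH adjustment over the upper triangle. Candidate partners
of an anchor gene (e.g. a core pluripotency factor) are the significant
correlates outside the already-characterized set, ranked by |rho|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import PSEUDOCOUNT


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame  # genes x genes Spearman correlations
    p: pd.DataFrame  # per-pair two-sided p (t approximation)
    adj_p: pd.DataFrame  # BH over the upper triangle, mirrored
    constant_genes: list[str]  # genes with no rank variation: rho undefined


def correlation_matrix(
    values: pd.DataFrame, gene_subset: list[str], min_cells: int = 50
) -> CorrelationMatrix:
    """Pairwise Spearman correlation of a gene subset across cells."""
    missing = [g for g in gene_subset if g not in values.index]
    if missing:
        raise ValueError(f"subset genes absent from matrix: {missing}")
    if values.shape[1] < min_cells:
        raise ValueError(f"need at least {min_cells} cells, have {values.shape[1]}")
    logv = np.log2(values.loc[gene_subset] + PSEUDOCOUNT)
    arr = logv.to_numpy(dtype=float)
    n_cells = arr.shape[1]
    constant = [g for g, row in zip(gene_subset, arr) if np.all(row == row[0])]
    ranks = pd.DataFrame(arr.T).rank().to_numpy()  # mid-ranks, cells x genes
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    const_idx = [gene_subset.index(g) for g in constant]
    rho[const_idx, :] = np.nan
    rho[:, const_idx] = np.nan
    np.fill_diagonal(rho, 1.0)
    # large-sample t approximation: t = rho * sqrt((n-2)/(1-rho^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n_cells - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_cells - 2)
    np.fill_diagonal(p, np.nan)
    iu = np.triu_indices(len(gene_subset), k=1)
    flat = p[iu]
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(flat)
    if ok.any():
        adj_flat = np.full(flat.shape, np.nan)
        adj_flat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        adj[iu] = adj_flat
        adj[(iu[1], iu[0])] = adj_flat
    idx = pd.Index(gene_subset, name="gene_id")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        adj_p=pd.DataFrame(adj, index=idx, columns=idx),
        constant_genes=constant,
    )


def rank_candidates(
    cm: CorrelationMatrix,
    anchors: list[str],
    known: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate partners of each anchor gene by |Spearman rho|.

    Candidates are genes outside `known` (and not the anchor itself)
    whose pair with the anchor has BH-adjusted p < alpha. The sign column
    separates positive co-expression from mutual exclusion.
    """
    known = set(known or ())
    rows = []
    for anchor in anchors:
        if anchor not in cm.rho.index:
            raise ValueError(f"anchor gene {anchor!r} not in the correlation matrix")
        rho = cm.rho[anchor].drop(index=anchor)
        adj = cm.adj_p[anchor].drop(index=anchor)
        mask = (adj < alpha) & rho.notna() & ~rho.index.isin(known)
        ranked = rho[mask].abs().sort_values(ascending=False)
        for rank, gene in enumerate(ranked.index, start=1):
            rows.append(
                {
                    "anchor_gene": anchor,
                    "candidate_gene": gene,
                    "rho": float(rho[gene]),
                    "adj_p": float(adj[gene]),
                    "sign": int(np.sign(rho[gene])),
                    "rank": rank,
                }
            )
    return pd.DataFrame(
        rows, columns=["anchor_gene", "candidate_gene", "rho", "adj_p", "sign", "rank"]
    )
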