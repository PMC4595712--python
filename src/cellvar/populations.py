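"""Subpopulation structure, cell-cycle phase, 2C-like cells, mRNA content.

Cells are clustered hierarchically (average linkage) on a correlation
distance — 1 minus the Spearman correlation between cells computed over
a marker gene panel on log2(x + 1) — mirroring how marker-panel heatmaps
of embryonic stem cell cultures are usually organized. On top of the
clustering sit three detectors:

* a three-way cut on the union of pluripotency and differentiation
  panels, labeling clusters committed / intermediate / ground by their
  panel score ordering;
* a two-score cell-cycle phase caller (G1/S vs G2/M marker scores);
* a rare 2C-like cell detector requiring both a >= 10-fold marker
  enrichment of the minor cluster and elevated MERVL-like reporter
  expression.

Cellular mRNA content is estimated from spike-in genes: spikes are added
at fixed input per cell, so the ratio of endogenous (exon) counts to
spike counts in the *raw* matrix is proportional to how much mRNA the
cell contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .qc import PSEUDOCOUNT


@dataclass
class ClusterResult:
    linkage_tree: np.ndarray  # scipy linkage matrix
    cell_labels: pd.Series  # cluster id per cell at the chosen cut
    distance: pd.DataFrame  # cells x cells, 1 - Spearman rho
    panel_name: str
    group_means: pd.DataFrame = field(default_factory=pd.DataFrame)  # panel gene x cluster


def _panel_log_values(values: pd.DataFrame, panel: list[str], panel_name: str) -> pd.DataFrame:
    missing = [g for g in panel if g not in values.index]
    if missing:
        raise ValueError(f"panel {panel_name!r} genes absent from matrix: {missing}")
    return np.log2(values.loc[panel] + PSEUDOCOUNT)


def spearman_cell_distance(log_values: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman correlation between cells over the given genes.

    Spearman is computed as Pearson on within-cell mid-ranks, which
    keeps cells with a constant (e.g. all-zero) profile well-defined:
    they carry no rank signal and get rho 0 against every other cell.
    """
    ranks = log_values.rank(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho = np.nan_to_num(rho, nan=0.0)  # constant cells: no rank signal
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    return pd.DataFrame(dist, index=log_values.columns, columns=log_values.columns)


def _cut_sized_clusters(
    link: np.ndarray, dist: pd.DataFrame, k: int, min_size: int
) -> pd.Series:
    """Cut a tree into k clusters each holding >= min_size cells.

    Average linkage happily spends a cluster on a single outlying cell;
    to recover the k *populations* we deepen the cut until k clusters of
    adequate size appear, then attach every cell of an undersized
    cluster to the sized cluster it is nearest to on average.
    """
    n = dist.shape[0]
    for kk in range(k, min(n, k + 25) + 1):
        labels = hierarchy.fcluster(link, t=kk, criterion="maxclust")
        sizes = np.bincount(labels)
        big = [c for c in range(1, len(sizes)) if sizes[c] >= min_size]
        if len(big) == k:
            out = labels.copy()
            small_cells = np.flatnonzero(~np.isin(labels, big))
            for i in small_cells:
                mean_d = [dist.values[i, labels == c].mean() for c in big]
                out[i] = big[int(np.argmin(mean_d))]
            # renumber 1..k in order of appearance
            remap = {c: j + 1 for j, c in enumerate(pd.unique(out))}
            return pd.Series([remap[c] for c in out], index=dist.index, name="cluster")
        if len(big) > k:
            break
    raise ValueError(
        f"no cut yields exactly {k} clusters of >= {min_size} cells; "
        "the population structure does not match the requested k"
    )


def marker_panel_cluster(
    values: pd.DataFrame, panel: list[str], k: int, panel_name: str = "panel"
) -> ClusterResult:
    """Average-linkage hierarchical clustering of cells on a marker panel."""
    if len(panel) < 5:
        raise ValueError("marker panel needs at least 5 genes")
    if k < 2:
        raise ValueError("k must be at least 2")
    logv = _panel_log_values(values, panel, panel_name)
    dist = spearman_cell_distance(logv)
    link = hierarchy.linkage(squareform(dist.values, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(labels, index=values.columns, name="cluster")
    group_means = logv.T.groupby(labels).mean().T
    return ClusterResult(link, labels, dist, panel_name, group_means)


def delineate_serum_subpopulations(
    values: pd.DataFrame,
    pluripotency_panel: list[str],
    differentiation_panel: list[str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Split cells into committed / intermediate / ground subpopulations.

    Clusters with k=3 on the union panel, scores each cluster by its mean
    log2 expression of the pluripotency and differentiation panels, and
    requires the cluster lowest in pluripotency to also be highest in
    differentiation (the committed pattern); the cluster highest in
    pluripotency is the ground state. Returns (labels, score table with
    per-cluster proportions). Ambiguous score orderings raise, with the
    score table attached to the exception.
    """
    union = list(dict.fromkeys(pluripotency_panel + differentiation_panel))
    res = marker_panel_cluster(values, union, k=3, panel_name="pluri+diff")
    min_size = max(5, int(0.02 * values.shape[1]))
    res.cell_labels = _cut_sized_clusters(res.linkage_tree, res.distance, 3, min_size)
    logv = _panel_log_values(values, union, "pluri+diff")
    scores = pd.DataFrame(
        {
            "pluripotency_score": logv.loc[[g for g in pluripotency_panel]].mean(axis=0),
            "differentiation_score": logv.loc[[g for g in differentiation_panel]].mean(axis=0),
        }
    )
    per_cluster = scores.groupby(res.cell_labels).mean()
    per_cluster["n_cells"] = res.cell_labels.value_counts().reindex(per_cluster.index)
    per_cluster["proportion"] = per_cluster["n_cells"] / len(res.cell_labels)
    committed = per_cluster["pluripotency_score"].idxmin()
    ground = per_cluster["pluripotency_score"].idxmax()
    most_diff = per_cluster["differentiation_score"].idxmax()
    if committed != most_diff or committed == ground:
        raise ValueError(
            "ambiguous subpopulation structure: the lowest-pluripotency cluster "
            f"is not the highest-differentiation cluster\n{per_cluster}"
        )
    name_map = {committed: "committed", ground: "ground"}
    for c in per_cluster.index:
        name_map.setdefault(c, "intermediate")
    labels = res.cell_labels.map(name_map).rename("subpopulation")
    per_cluster.index = per_cluster.index.map(name_map)
    return labels, per_cluster


def assign_phase(
    values: pd.DataFrame,
    g1s_set: list[str],
    g2m_set: list[str],
    conditions: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call G1/S vs G2/M per cell from marker scores.

    Each marker gene's log2(x + 1) values are z-scored across cells (so
    set size and expression magnitude do not dominate) and averaged per
    set; the larger score wins, ties go to G1S. Returns the per-cell
    table and per-condition phase fractions.
    """
    present_g1s = [g for g in g1s_set if g in values.index]
    present_g2m = [g for g in g2m_set if g in values.index]
    if not present_g1s or not present_g2m:
        raise ValueError("a phase marker set is empty after intersecting with the matrix")
    if min(len(present_g1s), len(present_g2m)) < 5:
        warnings.warn("fewer than 5 phase markers present; calls may be noisy", stacklevel=2)

    def score(genes: list[str]) -> pd.Series:
        logv = np.log2(values.loc[genes] + PSEUDOCOUNT)
        sd = logv.std(axis=1, ddof=0)
        z = logv.sub(logv.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
        return z.mean(axis=0)

    table = pd.DataFrame(
        {"score_g1s": score(present_g1s), "score_g2m": score(present_g2m)}
    )
    table["phase"] = np.where(table["score_g2m"] > table["score_g1s"], "G2M", "G1S")
    if conditions is None:
        conditions = pd.Series("all", index=values.columns)
    fractions = (
        pd.crosstab(conditions.reindex(values.columns), table["phase"], normalize="index")
        .reindex(columns=["G1S", "G2M"], fill_value=0.0)
    )
    return table, fractions


def detect_2c_cells(
    values: pd.DataFrame,
    markers_2c: list[str],
    mervl_gene: str | None = None,
    fold_threshold: float = 10.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag rare 2C-like cells.

    Cells are clustered on the 2C marker panel (Spearman distance,
    average linkage). The candidate 2C group is the subtree of the
    dendrogram (holding between 3 and half of the cells) that maximizes
    the rank-sum z-score of per-cell mean marker expression inside
    versus outside — the z-score peaks at the true cluster boundary,
    where a raw enrichment ratio would favor the cluster's most extreme
    core. The candidate is flagged 2C-like only when its mean marker
    expression is >= fold_threshold times the remaining cells' mean AND
    the MERVL-like reporter is higher inside it (one-sided rank-sum
    p < 0.05). When either criterion fails, no cell is flagged. A plain
    two-way cut is not used because average linkage routinely spends the
    minor cluster on one or two outlying cells while a rare population
    sits deeper in the tree.
    """
    if values.shape[1] < 20:
        raise ValueError("2C detection needs at least 20 cells")
    res = marker_panel_cluster(values, markers_2c, k=2, panel_name="2C")
    n = values.shape[1]
    marker_mean = values.loc[markers_2c].mean(axis=0).to_numpy()  # per cell
    ranks = stats.rankdata(marker_mean)
    # every internal node of the tree is a candidate cluster; leaf sets and
    # rank sums accumulate through the merge list
    members: list[list[int]] = [[i] for i in range(n)]
    rank_sums: list[float] = list(ranks)
    best_cells: np.ndarray | None = None
    best_z = -np.inf
    for a, b, _, _ in res.linkage_tree:
        merged = members[int(a)] + members[int(b)]
        members.append(merged)
        rs = rank_sums[int(a)] + rank_sums[int(b)]
        rank_sums.append(rs)
        k = len(merged)
        if 3 <= k <= n // 2:
            z = (rs - k * (n + 1) / 2) / np.sqrt(k * (n - k) * (n + 1) / 12.0)
            if z > best_z:
                best_z = z
                best_cells = np.asarray(merged)
    minor_cells = values.columns[best_cells]
    major_cells = values.columns.difference(minor_cells, sort=False)
    mean_minor = float(values.loc[markers_2c, minor_cells].values.mean())
    mean_major = float(values.loc[markers_2c, major_cells].values.mean())
    # refine the candidate per cell: the subtree can carry along cells
    # with background-level markers (and miss the odd enriched cell), so
    # the final membership is every cell above the geometric midpoint of
    # the inside/outside means
    for _ in range(20):  # iterate to a fixed point
        if not mean_minor > mean_major > 0:
            break
        midpoint = float(np.sqrt(mean_minor * mean_major))
        refined = values.columns[marker_mean >= midpoint]
        if not 0 < len(refined) <= n // 2 or set(refined) == set(minor_cells):
            break
        minor_cells = refined
        major_cells = values.columns.difference(minor_cells, sort=False)
        mean_minor = float(values.loc[markers_2c, minor_cells].values.mean())
        mean_major = float(values.loc[markers_2c, major_cells].values.mean())
    fold = mean_minor / mean_major if mean_major > 0 else np.inf
    mervl_p = np.nan
    mervl_ok = True
    if mervl_gene is not None and mervl_gene in values.index:
        mervl_p = float(
            stats.mannwhitneyu(
                values.loc[mervl_gene, minor_cells],
                values.loc[mervl_gene, major_cells],
                alternative="greater",
            ).pvalue
        )
        mervl_ok = mervl_p < 0.05
    elif mervl_gene is not None:
        warnings.warn(
            f"MERVL gene {mervl_gene!r} absent; using the marker fold criterion only",
            stacklevel=2,
        )
    called = bool(fold >= fold_threshold and mervl_ok)
    flags = pd.Series(False, index=values.columns, name="is_2c")
    if called:
        flags.loc[minor_cells] = True
    evidence = pd.DataFrame(
        {
            "n_minor": [len(minor_cells)],
            "n_major": [len(major_cells)],
            "mean_marker_minor": [mean_minor],
            "mean_marker_major": [mean_major],
            "fold": [fold],
            "mervl_p": [mervl_p],
            "called": [called],
        }
    )
    return flags, evidence


def count_2c_de_direction(
    flags: pd.Series, values: pd.DataFrame, alpha: float = 0.05
) -> tuple[int, int, pd.DataFrame]:
    """Count genes up- and downregulated in 2C-like cells vs the rest.

    Per gene: two-sided rank-sum (Mann-Whitney) test, BH adjustment,
    direction by mean difference among genes with adjusted p < alpha.
    """
    flags = flags.reindex(values.columns).astype(bool)
    n_2c = int(flags.sum())
    if n_2c < 3:
        raise ValueError(f"only {n_2c} flagged cells; need >= 3 for the comparison")
    if n_2c == len(flags):
        raise ValueError("all cells flagged 2C: no reference group")
    a = values.loc[:, flags.values].values
    b = values.loc[:, ~flags.values].values
    keep = ~(np.all(a == a[:, :1], axis=1) & np.all(b == b[:, :1], axis=1) & (a[:, 0] == b[:, 0]))
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(a[keep], b[keep], axis=1, alternative="two-sided")
    table = pd.DataFrame(
        {
            "p": res.pvalue,
            "delta_mean": a[keep].mean(axis=1) - b[keep].mean(axis=1),
        },
        index=values.index[keep],
    )
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    sig = table["adj_p"] < alpha
    n_up = int((sig & (table["delta_mean"] > 0)).sum())
    n_down = int((sig & (table["delta_mean"] < 0)).sum())
    return n_up, n_down, table


def mrna_content(
    counts: pd.DataFrame,
    spike_mask: pd.Series,
    groups: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell mRNA-content proxy from raw counts.

    ratio = (sum of endogenous counts) / (sum of spike counts); spikes
    are at fixed input per cell, so the ratio tracks cellular mRNA
    content. Cells with zero spike counts are flagged undefined and
    excluded from group comparisons. `groups` may carry label columns
    (e.g. condition, phase); every pair of labels within each column is
    compared by two-sided rank-sum with BH adjustment across all pairs.
    """
    spike_mask = spike_mask.reindex(counts.index, fill_value=False).astype(bool)
    if not spike_mask.any():
        raise ValueError("no spike-in genes in the matrix")
    spike_sum = counts.loc[spike_mask.values].sum(axis=0)
    exon_sum = counts.loc[~spike_mask.values].sum(axis=0)
    table = pd.DataFrame({"exon_counts": exon_sum, "spike_counts": spike_sum})
    table["defined"] = table["spike_counts"] > 0
    with np.errstate(divide="ignore"):
        table["ratio"] = np.where(table["defined"], exon_sum / spike_sum, np.nan)
    comparisons = pd.DataFrame(
        columns=["grouping", "group_a", "group_b", "median_a", "median_b", "p"]
    )
    if groups is not None:
        rows = []
        usable = table.index[table["defined"]]
        for col in groups.columns:
            labels = groups.loc[usable, col]
            uniq = sorted(labels.dropna().unique())
            for i, ga in enumerate(uniq):
                for gb in uniq[i + 1 :]:
                    ra = table.loc[usable[labels == ga], "ratio"]
                    rb = table.loc[usable[labels == gb], "ratio"]
                    if len(ra) < 2 or len(rb) < 2:
                        continue
                    p = float(stats.mannwhitneyu(ra, rb, alternative="two-sided").pvalue)
                    rows.append(
                        {
                            "grouping": col,
                            "group_a": ga,
                            "group_b": gb,
                            "median_a": float(ra.median()),
                            "median_b": float(rb.median()),
                            "p": p,
                        }
                    )
        comparisons = pd.DataFrame(rows, columns=comparisons.columns)
        if len(comparisons):
            comparisons["adj_p"] = multipletests(comparisons["p"], method="fdr_bh")[1]
    return table, comparisons


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def build(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left = build(node.get_left())
        right = build(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return build(tree) + ";"
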