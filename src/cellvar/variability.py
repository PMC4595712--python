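"""Cell-to-cell expression variability: the DM statistic and its tests.

The squared coefficient of variation CV^2 = var / mean^2 of a gene's
normalized counts falls strongly with its mean expression (and, more
weakly, with gene length), so raw CV^2 cannot be compared between genes
or conditions. DM ("distance to the median") removes the trend: genes
are ordered by log10 mean, a running median m(mu) of log10 CV^2 is taken
in a fixed-size window over that ordering, and

    DM_g = log10 CV^2_g - m(mu_g).

Positive DM means a gene is more variable than same-expression genes;
DM is invariant to global rescaling of the expression values. An
optional second pass subtracts a running median of DM against log10
gene length.

Condition-level and gene-set-level comparisons built on DM:

* Friedman rank-sum test across >= 3 conditions with genes as blocks
  (transcriptome-wide heterogeneity differences);
* two-sided paired t-tests per gene set on DM and on mean expression,
  summarized as sign(t) * (-log10 p);
* permutation enrichment of gene sets among extreme-DM genes (mean set
  DM against same-size random draws);
* per-gene two-sample Kolmogorov-Smirnov comparison of expression
  distributions between conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection


def cv2(values: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and squared CV of expression across cells.

    `values` is genes x cells. Uses the unbiased (n-1) sample variance.
    Genes with zero mean get NaN cv2 and defined=False; downstream DM
    excludes them.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("cv2 needs a genes x cells matrix with at least 2 cells")
    mean = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(mean > 0, var / mean**2, np.nan)
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(
        {"mean": mean, "cv2": c, "defined": mean > 0}, index=index
    )


def running_median(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Running median of y over genes ordered by x, fixed odd window.

    Returns, aligned with the input order, the median of y over the
    window of `window` genes centered on each gene's rank in x. At the
    edges the nearest full window is used, so the first and last
    ceil(window/2) genes share the first/last full window's median.
    Ties in x are broken by input position (stable sort).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > n:
        raise ValueError(f"window {window} exceeds the number of genes {n}")
    order = np.argsort(x, kind="stable")
    ys = y[order]
    half = window // 2
    # median of each full window via a strided sliding view
    windows = np.lib.stride_tricks.sliding_window_view(ys, window)
    meds = np.median(windows, axis=1)
    m_sorted = np.empty(n)
    m_sorted[half : n - half] = meds
    m_sorted[:half] = meds[0]
    m_sorted[n - half :] = meds[-1]
    m = np.empty(n)
    m[order] = m_sorted
    return m


def dm(
    values: pd.DataFrame,
    window: int = 51,
    min_mean: float = 10.0,
    length_correct: bool = False,
    gene_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """DM table for a genes x cells normalized expression matrix.

    Genes below `min_mean` mean normalized counts, or with zero variance
    (log10 CV^2 undefined), are excluded. Columns: mean, cv2, log10_cv2,
    running_median_log10_cv2, dm, and dm_length_adj when length
    correction is requested (needs `gene_lengths` in nucleotides).
    """
    table = cv2(values)
    keep = table["defined"] & (table["mean"] >= min_mean) & (table["cv2"] > 0)
    table = table.loc[keep, ["mean", "cv2"]].copy()
    if len(table) < window:
        raise ValueError(
            f"only {len(table)} genes pass min_mean={min_mean}; window is {window}"
        )
    table["log10_mean"] = np.log10(table["mean"])
    table["log10_cv2"] = np.log10(table["cv2"])
    m = running_median(table["log10_mean"].values, table["log10_cv2"].values, window)
    table["running_median_log10_cv2"] = m
    table["dm"] = table["log10_cv2"] - m
    if length_correct:
        if gene_lengths is None:
            raise ValueError("length_correct=True needs gene_lengths")
        lengths = gene_lengths.reindex(table.index)
        if lengths.isna().any():
            missing = list(table.index[lengths.isna()])[:5]
            raise ValueError(f"gene lengths missing for {missing} ...")
        m_len = running_median(np.log10(lengths.values), table["dm"].values, window)
        table["dm_length_adj"] = table["dm"] - m_len
    return table


def compare_conditions_friedman(dm_by_condition: pd.DataFrame) -> tuple[float, float]:
    """Friedman rank-sum test of DM across conditions, genes as blocks.

    `dm_by_condition` is genes x conditions over the shared gene set
    (rows with any NaN are dropped). Needs >= 3 conditions; for two,
    use a Wilcoxon signed-rank test instead.
    """
    clean = dm_by_condition.dropna()
    if clean.shape[1] < 3:
        raise ValueError(
            "Friedman test needs >= 3 conditions; use a Wilcoxon signed-rank test for 2"
        )
    cols = [clean[c].values for c in clean.columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        return 0.0, 1.0  # all-tied ranks: no evidence of any difference
    stat, p = stats.friedmanchisquare(*cols)
    return float(stat), float(p)


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on differences; all-zero differences give t=0, p=1."""
    diffs = np.asarray(diffs, dtype=float)
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    if diffs.std(ddof=1) == 0:
        # constant nonzero difference: arbitrarily strong signal; report the
        # smallest positive p rather than dividing by zero
        return float(np.sign(diffs[0]) * np.inf), float(np.nextafter(0, 1))
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(p)


def go_term_paired_test(
    dm_a: pd.Series,
    dm_b: pd.Series,
    mean_a: pd.Series,
    mean_b: pd.Series,
    sets: GeneSetCollection,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """Per-gene-set paired comparison of DM and mean expression between
    two conditions.

    For each set, member genes with DM in both conditions are paired and
    a two-sided paired t-test is applied to the DM differences (a - b)
    and to the mean-expression differences. Reported per set:
    t statistics, raw p-values, sign(t) * (-log10 p) summaries, and BH
    adjusted p-values across sets. Sets with fewer than `min_set_size`
    paired genes are skipped (listed in the `skipped` attribute of the
    result's attrs).
    """
    shared = dm_a.dropna().index.intersection(dm_b.dropna().index)
    rows = []
    skipped = []
    for name in sets:
        members = [g for g in sets[name] if g in shared]
        if len(members) < min_set_size:
            skipped.append(name)
            continue
        d_dm = dm_a[members].values - dm_b[members].values
        d_mean = mean_a[members].values - mean_b[members].values
        t_dm, p_dm = _paired_t(d_dm)
        t_mean, p_mean = _paired_t(d_mean)
        rows.append(
            {
                "set_name": name,
                "n_genes_tested": len(members),
                "t_stat_dm": t_dm,
                "p_dm": p_dm,
                "t_stat_mean": t_mean,
                "p_mean": p_mean,
                "signed_log10_p_dm": np.sign(t_dm) * (-np.log10(p_dm)),
                "signed_log10_p_mean": np.sign(t_mean) * (-np.log10(p_mean)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "n_genes_tested",
            "t_stat_dm",
            "p_dm",
            "t_stat_mean",
            "p_mean",
            "signed_log10_p_dm",
            "signed_log10_p_mean",
        ],
    )
    if len(result):
        result["adj_p_dm"] = multipletests(result["p_dm"], method="fdr_bh")[1]
        result["adj_p_mean"] = multipletests(result["p_mean"], method="fdr_bh")[1]
    else:
        result["adj_p_dm"] = []
        result["adj_p_mean"] = []
    result.attrs["skipped"] = skipped
    return result


def extreme_dm_enrichment(
    dm_values: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    side: str = "high",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of gene sets among extreme-DM genes.

    Statistic: mean DM of the set's member genes. Null: `n_perm` draws of
    the same number of genes without replacement from all DM genes.
    Empirical p = (1 + #{null >= observed}) / (n_perm + 1) for side
    'high' (mirrored for 'low'); BH adjustment across sets.
    """
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    dm_clean = dm_values.dropna()
    pool = dm_clean.values
    n = len(pool)
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for name in sets:
        members = [g for g in sets[name] if g in dm_clean.index]
        k = len(members)
        if k == 0:
            continue
        if k > n:
            raise ValueError(f"set {name!r} is larger than the DM gene universe")
        observed = dm_clean[members].mean()
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = pool[rng.choice(n, k, replace=False)].mean()
        if side == "high":
            exceed = int((null >= observed).sum())
        else:
            exceed = int((null <= observed).sum())
        p = (1 + exceed) / (n_perm + 1)
        rows.append(
            {"set_name": name, "n_genes": k, "mean_dm": observed, "p": p}
        )
    result = pd.DataFrame(rows, columns=["set_name", "n_genes", "mean_dm", "p"])
    if len(result):
        result["adj_p"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["adj_p"] = []
    return result


def ks_compare_gene(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on one gene's
    normalized expression in two conditions."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if len(a) < 8 or len(b) < 8:
        import warnings

        warnings.warn("KS comparison with < 8 cells per side is underpowered", stacklevel=2)
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
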