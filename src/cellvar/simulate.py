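"""Synthetic mESC-like single-cell count data with known ground truth.

Emulates the structure of a multi-condition single-cell RNA-seq study of
mouse embryonic stem cells grown in serum, 2i and a2i media: negative-
binomially distributed counts, planted highly variable genes, three serum
subpopulations (ground / intermediate / differentiation-committed), two
cell-cycle phase groups, a rare 2C-like subpopulation marked by a
MERVL-like reporter, spike-in genes added at fixed input per cell, batch
location/scale effects, a correlated transcription-factor module, and
cells planted to fail quality control.

Counts are gamma-Poisson (negative binomial): for gene g in cell c with
mean mu and dispersion phi, var = mu + phi * mu^2. Baseline gene means are
log-normal; baseline dispersion follows the decreasing law
phi(mu) = a / mu + b times log-normal gene-specific noise, which produces
the falling CV^2-versus-mean trend that the DM statistic corrects for.

Spike-in genes are the exception to everything cellular: their means scale
with the cell's sequencing-depth factor only, never with its mRNA-content
multiplier or any biological label — this independence is what makes the
endogenous/spike read ratio a proxy for cellular mRNA content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from . import io as cvio

MERVL_GENE = "MERVL-reporter"

#: panel sizes for the built-in marker roles
_PANEL_SIZES = {
    "pluripotency": 20,
    "differentiation": 20,
    "G1S": 20,
    "G2M": 20,
    "2C": 20,
    "mito": 13,
}


@dataclass
class SubpopSpec:
    """One subpopulation: log2 shifts applied to the two marker panels.

    `pluri_fraction` / `diff_fraction` limit the shift to the first part
    of each panel, so populations can differ in *which* markers move,
    not just how far — e.g. an intermediate population that loses some
    pluripotency factors while keeping the core ones high.
    """

    label: str
    proportion: float
    pluri_shift: float = 0.0
    diff_shift: float = 0.0
    pluri_fraction: float = 1.0
    diff_fraction: float = 1.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the study layout.

    Cell numbers per condition (250 serum, 295 2i, 159 a2i) and batch
    counts (3/4/2) follow the study design; the planted 2C-like fraction
    (10 of 295, in 2i only) and the G2/M phase fractions (~60% in 2i,
    ~35% in a2i) follow its reported findings.
    """

    n_genes: int = 2000
    conditions: tuple[str, ...] = ("serum", "2i", "a2i")
    n_cells_per_condition: dict[str, int] = field(
        default_factory=lambda: {"serum": 250, "2i": 295, "a2i": 159}
    )
    n_batches_per_condition: dict[str, int] = field(
        default_factory=lambda: {"serum": 3, "2i": 4, "a2i": 2}
    )

    # baseline expression law (natural-log parameters of gene mean counts)
    baseline_log_mean_mu: float = 1.5
    baseline_log_mean_sigma: float = 1.8
    marker_log_mean_mu: float = 4.0
    marker_log_mean_sigma: float = 1.0

    # dispersion law phi(mu) = a/mu + b, log-normal gene noise
    dispersion_a: float = 2.0
    dispersion_b: float = 0.1
    dispersion_noise_sd: float = 0.25

    # highly variable genes
    hvg_fraction: float = 0.1
    hvg_fold: float = 4.0

    # subpopulations (serum splits; ground state only in 2i/a2i)
    subpop_spec: dict[str, list[SubpopSpec]] = field(
        default_factory=lambda: {
            "serum": [
                SubpopSpec("committed", 0.15, pluri_shift=-3.0, diff_shift=3.0),
                SubpopSpec(
                    "intermediate",
                    0.17,
                    pluri_shift=-1.5,
                    diff_shift=1.5,
                    pluri_fraction=0.5,
                    diff_fraction=0.5,
                ),
                SubpopSpec("ground", 0.68),
            ],
            "2i": [SubpopSpec("ground", 1.0)],
            "a2i": [SubpopSpec("ground", 1.0)],
        }
    )

    # cell cycle: log2 shift of each phase's markers in cells of that phase
    phase_shift: float = 1.5
    g2m_fraction: dict[str, float] = field(
        default_factory=lambda: {"serum": 0.50, "2i": 0.60, "a2i": 0.35}
    )

    # rare 2C-like cells (2i only by default), fold-enrichment of 2C markers
    twoc_proportion: dict[str, float] = field(default_factory=lambda: {"2i": 10 / 295})
    twoc_fold: float = 50.0
    twoc_fold_sigma: float = 0.5  # per-marker spread of the planted fold (log scale)
    mervl_fold: float = 200.0
    mervl_baseline_mean: float = 0.05
    twoc_marker_log_mean_mu: float = -0.5
    twoc_marker_log_mean_sigma: float = 0.5

    # spike-ins: fixed molecular input per cell
    n_spikes: int = 92
    spike_log_mean_mu: float = 2.5
    spike_log_mean_sigma: float = 1.0

    # per-cell multipliers
    content_sigma: float = 0.3  # log-normal spread of mRNA content
    content_by_condition: dict[str, float] = field(default_factory=lambda: {"2i": 0.5})
    content_g2m_factor: float = 1.4
    depth_sigma: float = 0.25  # log-normal spread of sequencing depth

    # batch effects on log2 means, plus per-batch dispersion scaling
    batch_location_sd: float = 0.10  # global per-batch shift
    batch_gene_location_sd: float = 0.10  # per-batch per-gene shift
    batch_scale_sd: float = 0.10  # log-sd of per-batch dispersion multiplier

    # correlated transcription-factor module (latent factor model)
    network_members: int = 5
    network_hub_loading: float = 0.9
    network_member_loading: float = 0.8

    # planted QC failures (fractions of each condition's cell count, extra cells)
    qc_low_depth_fraction: float = 0.05
    qc_high_mito_fraction: float = 0.03
    qc_capture_bad_fraction: float = 0.02
    low_depth_factor: float = 0.03
    high_mito_fold: float = 20.0

    # read-scale QC metrics
    reads_per_count: float = 100.0
    exon_fraction_mean: float = 0.65
    exon_fraction_sd: float = 0.03
    twoc_exon_fraction_drop: float = 0.15

    gene_length_range: tuple[float, float] = (500.0, 100_000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_spikes <= 0:
            raise ValueError("n_genes and n_spikes must be positive")
        for cond in self.conditions:
            if self.n_cells_per_condition.get(cond, 0) <= 0:
                raise ValueError(f"non-positive cell count for condition {cond!r}")
            if self.n_batches_per_condition.get(cond, 0) <= 0:
                raise ValueError(f"non-positive batch count for condition {cond!r}")
            props = [s.proportion for s in self.subpop_spec[cond]]
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(
                    f"subpopulation proportions for {cond!r} sum to {sum(props)}, not 1"
                )
            g2m = self.g2m_fraction[cond]
            if not 0.0 <= g2m <= 1.0:
                raise ValueError(f"g2m_fraction for {cond!r} outside [0, 1]")
        if self.hvg_fold <= 1.0:
            raise ValueError("hvg_fold must exceed 1")
        for cond, p in self.twoc_proportion.items():
            if not 0.0 <= p < 0.1:
                raise ValueError(f"2C proportion for {cond!r} must be in [0, 0.1)")
        n_markers = sum(_PANEL_SIZES.values()) + 1 + self.network_members + 1
        if self.n_genes < n_markers + 50:
            raise ValueError(f"n_genes must be at least {n_markers + 50}")


def _counts_by_proportion(n: int, proportions: list[float]) -> list[int]:
    """Split n into integer group sizes by largest remainder."""
    raw = [p * n for p in proportions]
    base = [math.floor(r) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for i in order[:short]:
        base[i] += 1
    return base


def _assign_roles(cfg: SimulationConfig) -> pd.DataFrame:
    """Lay out gene roles: markers first, then HVGs among the remainder."""
    ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    role = np.array(["none"] * cfg.n_genes, dtype=object)
    pos = 0
    panels: dict[str, list[str]] = {}
    for panel, size in _PANEL_SIZES.items():
        role[pos : pos + size] = panel
        panels[panel] = ids[pos : pos + size]
        pos += size
    ids[pos] = MERVL_GENE
    role[pos] = "mervl"
    pos += 1
    role[pos] = "network_hub"
    panels["network_hub"] = [ids[pos]]
    pos += 1
    role[pos : pos + cfg.network_members] = "network_member"
    panels["network_member"] = ids[pos : pos + cfg.network_members]
    pos += cfg.network_members

    var = pd.DataFrame(index=pd.Index(ids, name="gene_id"))
    var["role"] = role
    var["is_spike"] = False
    var["is_mito"] = role == "mito"
    n_hvg = int(round(cfg.hvg_fraction * (cfg.n_genes - pos)))
    is_hvg = np.zeros(cfg.n_genes, dtype=bool)
    is_hvg[pos : pos + n_hvg] = True
    var["is_hvg"] = is_hvg
    var.attrs["panels"] = panels
    return var


def simulate_dataset(config: SimulationConfig) -> ad.AnnData:
    """Draw a complete synthetic dataset.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``X``
    (cells x genes), full truth labels in ``obs`` (condition, batch,
    subpopulation, phase, is_2c, content/depth multipliers, QC metrics and
    fate), generator truth in ``var`` (role, is_spike, is_mito, is_hvg,
    gene length, baseline mean and dispersion), and the marker gene sets
    in ``uns["gene_sets"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    var = _assign_roles(config)
    panels = var.attrs["panels"]
    n_endog = config.n_genes

    # --- baseline gene means and dispersions -------------------------------
    base_mean = rng.lognormal(config.baseline_log_mean_mu, config.baseline_log_mean_sigma, n_endog)
    marker_roles = {"pluripotency", "differentiation", "G1S", "G2M", "network_hub", "network_member"}
    for i, role in enumerate(var["role"]):
        if role in marker_roles:
            base_mean[i] = rng.lognormal(config.marker_log_mean_mu, config.marker_log_mean_sigma)
        elif role == "mito":
            base_mean[i] = rng.lognormal(4.0, 0.5)
        elif role == "2C":
            base_mean[i] = rng.lognormal(
                config.twoc_marker_log_mean_mu, config.twoc_marker_log_mean_sigma
            )
        elif role == "mervl":
            base_mean[i] = config.mervl_baseline_mean
    # gene-specific multiplier around the mean-dispersion law; the law itself
    # is evaluated at the realized per-cell mean when counts are drawn
    phi_gene = rng.lognormal(0.0, config.dispersion_noise_sd, n_endog)
    phi_gene = phi_gene * np.where(var["is_hvg"], config.hvg_fold, 1.0)
    phi = (config.dispersion_a / base_mean + config.dispersion_b) * phi_gene
    lengths = np.exp(
        rng.uniform(np.log(config.gene_length_range[0]), np.log(config.gene_length_range[1]), n_endog)
    )
    var["length"] = np.round(lengths).astype(int)
    var["baseline_mean"] = base_mean
    var["baseline_dispersion"] = phi

    spike_mean = rng.lognormal(config.spike_log_mean_mu, config.spike_log_mean_sigma, config.n_spikes)
    spike_phi = (config.dispersion_a / spike_mean + config.dispersion_b) * rng.lognormal(
        0.0, config.dispersion_noise_sd, config.n_spikes
    )

    # --- cells -------------------------------------------------------------
    obs_rows: list[dict] = []
    for cond in config.conditions:
        n_good = config.n_cells_per_condition[cond]
        specs = config.subpop_spec[cond]
        sub_counts = _counts_by_proportion(n_good, [s.proportion for s in specs])
        sub_labels = np.repeat([s.label for s in specs], sub_counts)
        rng.shuffle(sub_labels)
        n_g2m = int(round(config.g2m_fraction[cond] * n_good))
        phase = np.array(["G1S"] * n_good, dtype=object)
        phase[rng.choice(n_good, n_g2m, replace=False)] = "G2M"
        is_2c = np.zeros(n_good, dtype=bool)
        n_2c = int(round(config.twoc_proportion.get(cond, 0.0) * n_good))
        if n_2c:
            is_2c[rng.choice(n_good, n_2c, replace=False)] = True
        n_fail = {
            "low_depth": int(round(config.qc_low_depth_fraction * n_good)),
            "high_mito": int(round(config.qc_high_mito_fraction * n_good)),
            "capture_bad": int(round(config.qc_capture_bad_fraction * n_good)),
        }
        fates = ["pass"] * n_good + sum(([k] * v for k, v in n_fail.items()), [])
        n_total = len(fates)
        n_batches = config.n_batches_per_condition[cond]
        for i in range(n_total):
            good = i < n_good
            obs_rows.append(
                {
                    "condition": cond,
                    "batch": f"{cond}{i % n_batches + 1}",
                    "subpopulation": sub_labels[i % n_good] if good else sub_labels[0],
                    "phase": phase[i % n_good] if good else "G1S",
                    "is_2c": bool(is_2c[i]) if good else False,
                    "qc_fate": fates[i],
                }
            )
    obs = pd.DataFrame(obs_rows)
    obs.index = pd.Index([f"cell{i + 1:04d}" for i in range(len(obs))], name="cell_id")
    n_cells = len(obs)

    content = rng.lognormal(0.0, config.content_sigma, n_cells)
    content *= np.array([config.content_by_condition.get(c, 1.0) for c in obs["condition"]])
    content *= np.where(obs["phase"] == "G2M", config.content_g2m_factor, 1.0)
    depth = rng.lognormal(0.0, config.depth_sigma, n_cells)
    depth *= np.where(obs["qc_fate"] == "low_depth", config.low_depth_factor, 1.0)
    obs["content_multiplier"] = content
    obs["depth_multiplier"] = depth
    obs["size_multiplier"] = content * depth  # what size factors should recover

    # --- per-cell log2 mean matrix (genes x cells) -------------------------
    log2_mu = np.tile(np.log2(base_mean)[:, None], (1, n_cells))
    gene_pos = {g: i for i, g in enumerate(var.index)}

    def rows(panel: str) -> np.ndarray:
        return np.array([gene_pos[g] for g in panels[panel]])

    for cond in config.conditions:
        for spec in config.subpop_spec[cond]:
            cells = np.flatnonzero(
                (obs["condition"] == cond) & (obs["subpopulation"] == spec.label)
            )
            if len(cells) == 0:
                continue
            n_pluri = int(round(spec.pluri_fraction * len(panels["pluripotency"])))
            n_diff = int(round(spec.diff_fraction * len(panels["differentiation"])))
            if n_pluri:
                log2_mu[np.ix_(rows("pluripotency")[:n_pluri], cells)] += spec.pluri_shift
            if n_diff:
                log2_mu[np.ix_(rows("differentiation")[:n_diff], cells)] += spec.diff_shift
    g2m_cells = np.flatnonzero(obs["phase"] == "G2M")
    g1s_cells = np.flatnonzero(obs["phase"] == "G1S")
    log2_mu[np.ix_(rows("G2M"), g2m_cells)] += config.phase_shift
    log2_mu[np.ix_(rows("G1S"), g1s_cells)] += config.phase_shift
    twoc_cells = np.flatnonzero(obs["is_2c"])
    if len(twoc_cells):
        # each marker gets its own enrichment fold (mean = twoc_fold): a
        # uniform fold would leave within-cell marker ranks unchanged and
        # be invisible to rank-correlation clustering
        sig = config.twoc_fold_sigma
        gene_folds = config.twoc_fold * rng.lognormal(-sig**2 / 2, sig, len(panels["2C"]))
        log2_mu[np.ix_(rows("2C"), twoc_cells)] += np.log2(gene_folds)[:, None]
        log2_mu[gene_pos[MERVL_GENE], twoc_cells] += np.log2(config.mervl_fold)

    # latent-factor TF module: shared cell score drives hub and members
    factor = rng.normal(0.0, 1.0, n_cells)
    log2_mu[rows("network_hub")[0], :] += config.network_hub_loading * factor
    for r in rows("network_member"):
        log2_mu[r, :] += config.network_member_loading * factor

    mito_rows = np.flatnonzero(var["is_mito"])
    hi_mito = np.flatnonzero(obs["qc_fate"] == "high_mito")
    if len(hi_mito):
        log2_mu[np.ix_(mito_rows, hi_mito)] += np.log2(config.high_mito_fold)

    # batch location/scale effects; the global location term is a
    # depth-like library effect and applies to spike-ins as well
    batches = obs["batch"].unique()
    disp_mult = np.ones(n_cells)
    batch_loc = np.zeros(n_cells)
    for b in batches:
        cells = np.flatnonzero(obs["batch"] == b)
        loc = rng.normal(0.0, config.batch_location_sd)
        loc_g = rng.normal(0.0, config.batch_gene_location_sd, n_endog)
        log2_mu[:, cells] += loc + loc_g[:, None]
        batch_loc[cells] = loc
        disp_mult[cells] = rng.lognormal(0.0, config.batch_scale_sd)

    mu = np.exp2(log2_mu) * (content * depth)[None, :]
    phi_mat = (config.dispersion_a / mu + config.dispersion_b) * phi_gene[:, None]
    phi_mat = np.maximum(phi_mat * disp_mult[None, :], 1e-8)
    endog_counts = rng.poisson(rng.gamma(1.0 / phi_mat, mu * phi_mat))

    # spikes: fixed input, scaled by depth and the batch library effect only
    spike_mu = spike_mean[:, None] * (depth * np.exp2(batch_loc))[None, :]
    spike_phi_mat = np.maximum(
        (config.dispersion_a / spike_mu + config.dispersion_b)
        * rng.lognormal(0.0, config.dispersion_noise_sd, config.n_spikes)[:, None],
        1e-8,
    )
    spike_counts = rng.poisson(rng.gamma(1.0 / spike_phi_mat, spike_mu * spike_phi_mat))

    counts = np.vstack([endog_counts, spike_counts])
    spike_var = pd.DataFrame(
        {
            "role": "spike",
            "is_spike": True,
            "is_mito": False,
            "is_hvg": False,
            "length": 1000,
            "baseline_mean": spike_mean,
            "baseline_dispersion": spike_phi,
        },
        index=pd.Index([f"Spike-{i + 1:03d}" for i in range(config.n_spikes)], name="gene_id"),
    )
    var_all = pd.concat([var, spike_var])

    # --- read-scale QC metrics ---------------------------------------------
    exon_reads = endog_counts.sum(axis=0) * config.reads_per_count
    exon_frac = rng.normal(config.exon_fraction_mean, config.exon_fraction_sd, n_cells)
    exon_frac -= np.where(obs["is_2c"], config.twoc_exon_fraction_drop, 0.0)
    exon_frac = np.clip(exon_frac, 0.3, 0.9)
    obs["exon_reads"] = np.round(exon_reads).astype(np.int64)
    obs["total_reads"] = np.round(exon_reads / exon_frac).astype(np.int64)
    obs["mito_reads"] = np.round(
        endog_counts[mito_rows].sum(axis=0) * config.reads_per_count
    ).astype(np.int64)
    obs["capture_ok"] = obs["qc_fate"].values != "capture_bad"

    gene_sets = GeneSetCollection(
        {
            "pluripotency_panel": panels["pluripotency"],
            "differentiation_panel": panels["differentiation"],
            "G1S_markers": panels["G1S"],
            "G2M_markers": panels["G2M"],
            "2C_markers": panels["2C"],
            "hvg_truth": list(var.index[var["is_hvg"]]),
            "tf_module": panels["network_hub"] + panels["network_member"],
        },
        descriptions={
            "pluripotency_panel": "planted pluripotency factors",
            "differentiation_panel": "planted differentiation markers",
            "G1S_markers": "planted G1/S phase markers",
            "G2M_markers": "planted G2/M phase markers",
            "2C_markers": "planted 2C-like state markers",
            "hvg_truth": "genes with inflated dispersion",
            "tf_module": "latent-factor correlated TF module (hub first)",
        },
    )

    adata = ad.AnnData(
        X=counts.T.astype(np.int64),
        obs=obs,
        var=var_all,
        uns={
            "gene_sets": gene_sets,
            "mervl_gene": MERVL_GENE,
            "network_hub": panels["network_hub"][0],
            "seed": config.seed,
        },
    )
    return adata


def counts_frame(adata: ad.AnnData, layer: str | None = None) -> pd.DataFrame:
    """Genes x cells DataFrame view of a dataset's counts."""
    mat = adata.X if layer is None else adata.layers[layer]
    return pd.DataFrame(np.asarray(mat).T, index=adata.var_names, columns=adata.obs_names)


def write_dataset(adata: ad.AnnData, directory: str | Path) -> None:
    """Write counts (MTX + TSV), cell/gene metadata TSVs, and gene sets GMT."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("refusing to write an empty dataset (0 cells or 0 genes)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts = counts_frame(adata)
    cvio.write_counts_mtx(counts, directory)
    cvio.write_counts_tsv(counts, directory / "counts.tsv")
    cvio.write_table(adata.obs, directory / "cell_metadata.tsv", index_label="cell_id")
    cvio.write_table(adata.var, directory / "gene_annotation.tsv", index_label="gene_id")
    gs = adata.uns.get("gene_sets")
    if gs is not None:
        gs.to_gmt(directory / "gene_sets.gmt")


def read_dataset(directory: str | Path) -> ad.AnnData:
    """Round-trip reader for :func:`write_dataset` output."""
    directory = Path(directory)
    counts = cvio.read_counts_mtx(directory)
    obs = cvio.read_table(directory / "cell_metadata.tsv", index_col="cell_id")
    var = cvio.read_table(directory / "gene_annotation.tsv", index_col="gene_id")
    uns = {}
    gmt = directory / "gene_sets.gmt"
    if gmt.exists():
        uns["gene_sets"] = GeneSetCollection.from_gmt(gmt)
    return ad.AnnData(X=counts.values.T.astype(np.int64), obs=obs, var=var, uns=uns)
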