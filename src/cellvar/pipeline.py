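"""End-to-end orchestration: simulate/load -> QC -> normalize -> DM ->
comparisons -> population structure -> mRNA content -> network mining.

Every stage writes a tab-separated table into the output directory and
registers itself in a JSON run manifest (package version, parameters,
seed, per-stage row counts). The manifest carries no wall-clock
timestamps, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cvio
from . import network as net
from . import populations as pop
from . import qc
from . import variability as vr
from .genesets import GeneSetCollection
from .simulate import SimulationConfig, simulate_dataset, counts_frame, write_dataset

log = logging.getLogger("cellvar")


@dataclass
class PipelineConfig:
    """Paths, stage parameters and the global seed for a pipeline run."""

    # inputs; left None when simulating
    counts_path: str | None = None  # directory with counts.mtx + sidecars
    cell_metadata: str | None = None
    gene_annotation: str | None = None
    gene_sets: str | None = None  # GMT

    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    outdir: str = "cellvar_out"
    seed: int = 0

    # QC
    min_exon_reads: int = 500_000
    max_mito_fraction: float = 0.10
    # DM
    dm_window: int = 51
    dm_min_mean: float = 10.0
    # enrichment
    n_perm: int = 1000
    # 2C detection
    fold_threshold: float = 10.0
    # which conditions host which analyses
    subpop_condition: str = "serum"
    twoc_condition: str = "2i"
    network_condition: str = "serum"
    skip_stages: tuple[str, ...] = ()

    def resolve_inputs(self) -> None:
        if self.simulate:
            return
        for name in ("counts_path", "cell_metadata", "gene_annotation", "gene_sets"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"config input {name} missing or absent: {path}")


def _load_inputs(cfg: PipelineConfig):
    import anndata as ad

    counts = cvio.read_counts_mtx(Path(cfg.counts_path))
    obs = cvio.read_table(cfg.cell_metadata, index_col="cell_id")
    var = cvio.read_table(cfg.gene_annotation, index_col="gene_id")
    sets = GeneSetCollection.from_gmt(cfg.gene_sets)
    adata = ad.AnnData(X=counts.values.T, obs=obs.loc[counts.columns], var=var.loc[counts.index])
    adata.uns["gene_sets"] = sets
    return adata


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    cfg.resolve_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "package": "cellvar",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
        },
        "stages": {},
    }

    def stage(name: str) -> bool:
        run = name not in cfg.skip_stages
        if run:
            log.info("stage %s", name)
        else:
            log.info("stage %s skipped", name)
        return run

    def record(name: str, seconds: float, **info) -> None:
        # timings go to the log only: the manifest must be seed-reproducible
        log.info("stage %s done in %.2fs", name, seconds)
        manifest["stages"][name] = dict(info)

    # --- simulate / load ---------------------------------------------------
    t0 = time.perf_counter()
    if cfg.simulate:
        cfg.sim.seed = cfg.seed
        adata = simulate_dataset(cfg.sim)
        write_dataset(adata, outdir / "dataset")
    else:
        adata = _load_inputs(cfg)
    sets: GeneSetCollection = adata.uns["gene_sets"]
    record("simulate" if cfg.simulate else "load", time.perf_counter() - t0,
           n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))

    counts = counts_frame(adata)
    obs = adata.obs
    var = adata.var

    # --- qc ----------------------------------------------------------------
    t0 = time.perf_counter()
    if stage("qc"):
        kept, report = qc.filter_cells(
            obs, min_exon_reads=cfg.min_exon_reads, max_mito_fraction=cfg.max_mito_fraction
        )
        cvio.write_table(kept, outdir / "cells_filtered.tsv", index_label="cell_id")
        record("qc", time.perf_counter() - t0, **vars(report))
        obs = kept
        counts = counts[kept.index]

    # --- normalize ---------------------------------------------------------
    t0 = time.perf_counter()
    spike_mask = var["is_spike"].astype(bool)
    s = qc.size_factors(counts, spike_mask=spike_mask)
    norm = qc.normalize(counts, s)
    adj = qc.batch_adjust(norm, obs["batch"], obs["condition"])
    cvio.write_table(s.to_frame(), outdir / "size_factors.tsv", index_label="cell_id")
    record("normalize", time.perf_counter() - t0, n_cells=int(len(s)))
    endog = adj.loc[~spike_mask.values]

    # --- dm ----------------------------------------------------------------
    t0 = time.perf_counter()
    dm_by_cond: dict[str, pd.DataFrame] = {}
    if stage("dm"):
        for cond in obs["condition"].unique():
            cells = obs.index[obs["condition"] == cond]
            dm_by_cond[cond] = vr.dm(
                endog[cells],
                window=cfg.dm_window,
                min_mean=cfg.dm_min_mean,
                length_correct=True,
                gene_lengths=var["length"],
            )
            cvio.write_table(
                dm_by_cond[cond], outdir / f"dm_{cond}.tsv", index_label="gene_id"
            )
        record("dm", time.perf_counter() - t0,
               genes_per_condition={c: int(len(t)) for c, t in dm_by_cond.items()})

    # --- condition & gene-set comparisons ----------------------------------
    t0 = time.perf_counter()
    if stage("compare") and len(dm_by_cond) >= 2:
        summary: dict = {}
        if len(dm_by_cond) >= 3:
            dm_wide = pd.DataFrame({c: t["dm"] for c, t in dm_by_cond.items()})
            stat, p = vr.compare_conditions_friedman(dm_wide)
            summary["friedman"] = {"statistic": stat, "p": p, "n_genes": int(len(dm_wide.dropna()))}
        conds = list(dm_by_cond)
        a, b = conds[0], conds[1]
        per_set = vr.go_term_paired_test(
            dm_by_cond[a]["dm"], dm_by_cond[b]["dm"],
            dm_by_cond[a]["mean"], dm_by_cond[b]["mean"], sets,
        )
        cvio.write_table(per_set, outdir / f"gene_set_comparison_{a}_vs_{b}.tsv")
        for cond, table in dm_by_cond.items():
            enr = vr.extreme_dm_enrichment(
                table["dm"], sets, n_perm=cfg.n_perm, side="high", rng=rng
            )
            cvio.write_table(enr, outdir / f"extreme_dm_enrichment_{cond}.tsv")
        with open(outdir / "condition_tests.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        record("compare", time.perf_counter() - t0, n_sets=int(len(per_set)))

    # --- population structure ----------------------------------------------
    labels = pd.DataFrame(index=obs.index)
    labels["condition"] = obs["condition"]
    t0 = time.perf_counter()
    if stage("subpop"):
        cells = obs.index[obs["condition"] == cfg.subpop_condition]
        sub_labels, score_table = pop.delineate_serum_subpopulations(
            endog[cells], sets["pluripotency_panel"], sets["differentiation_panel"]
        )
        labels.loc[cells, "subpopulation"] = sub_labels
        cvio.write_table(score_table, outdir / "subpopulation_scores.tsv", index_label="subpopulation")
        record("subpop", time.perf_counter() - t0,
               proportions={k: float(v) for k, v in score_table["proportion"].items()})

    t0 = time.perf_counter()
    if stage("cellcycle"):
        phase_table, fractions = pop.assign_phase(
            endog, sets["G1S_markers"], sets["G2M_markers"], conditions=obs["condition"]
        )
        labels["phase"] = phase_table["phase"]
        cvio.write_table(fractions, outdir / "phase_fractions.tsv", index_label="condition")
        record("cellcycle", time.perf_counter() - t0,
               g2m_fractions={c: float(fractions.loc[c, "G2M"]) for c in fractions.index})

    t0 = time.perf_counter()
    if stage("detect2c"):
        # rare-population detection runs on normalized (not batch-adjusted)
        # values: per-gene batch standardization flattens a signature that
        # lives in a handful of cells of one batch
        cells = obs.index[obs["condition"] == cfg.twoc_condition]
        flags, evidence = pop.detect_2c_cells(
            norm.loc[~spike_mask.values, cells], sets["2C_markers"],
            mervl_gene=adata.uns.get("mervl_gene"),
            fold_threshold=cfg.fold_threshold,
        )
        labels["is_2c"] = False
        labels.loc[cells, "is_2c"] = flags
        cvio.write_table(evidence, outdir / "twoc_evidence.tsv")
        n_up = n_down = 0
        if flags.sum() >= 3:
            n_up, n_down, de = pop.count_2c_de_direction(flags, norm.loc[~spike_mask.values, cells])
            cvio.write_table(de, outdir / "twoc_de.tsv", index_label="gene_id")
        record("detect2c", time.perf_counter() - t0,
               n_2c=int(flags.sum()), n_up=n_up, n_down=n_down)

    t0 = time.perf_counter()
    if stage("content"):
        group_cols = [c for c in ("condition", "phase") if c in labels.columns]
        content_table, comparisons = pop.mrna_content(
            counts, spike_mask, groups=labels[group_cols]
        )
        labels["content_ratio"] = content_table["ratio"]
        cvio.write_table(comparisons, outdir / "content_comparisons.tsv")
        record("content", time.perf_counter() - t0,
               n_defined=int(content_table["defined"].sum()))

    cvio.write_table(labels, outdir / "cell_labels.tsv", index_label="cell_id")

    # --- network mining ------------------------------------------------------
    t0 = time.perf_counter()
    if stage("network"):
        cells = obs.index[obs["condition"] == cfg.network_condition]
        subset = list(
            dict.fromkeys(
                sets.get("tf_module", [])
                + sets["pluripotency_panel"]
                + sets["differentiation_panel"]
            )
        )
        subset = [g for g in subset if g in endog.index]
        cm = net.correlation_matrix(endog.loc[:, cells], subset, min_cells=min(50, len(cells)))
        cvio.write_table(cm.rho, outdir / "correlation_matrix.tsv", index_label="gene_id")
        anchor = adata.uns.get("network_hub", subset[0])
        ranking = net.rank_candidates(cm, [anchor], known=set())
        cvio.write_table(ranking, outdir / "candidate_ranking.tsv")
        record("network", time.perf_counter() - t0,
               n_pairs=int(len(subset) * (len(subset) - 1) // 2), anchor=anchor)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(name)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
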