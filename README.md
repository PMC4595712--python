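# cellvar

Cell-to-cell expression variability analysis for multi-condition
single-cell RNA-seq, built around the **DM (distance-to-the-median)**
statistic.

Single-cell experiments that compare culture conditions or treatments —
the motivating case is mouse embryonic stem cells grown in serum, 2i and
a2i media — need to ask not just *which genes change in mean* but *which
genes change in cell-to-cell variability*. The squared coefficient of
variation CV²_g = σ²_g/μ²_g is the natural variability measure, but it
depends strongly on a gene's mean expression, so raw CV² cannot be
compared between genes or conditions. DM removes that dependence: genes
are ordered by log₁₀ mean expression, a running median m(μ) of log₁₀ CV²
is taken in a fixed window over that ordering, and

```
DM_g = log10 CV²_g − m(μ_g)
```

Positive DM marks a gene as more variable than genes of the same
expression level; DM is comparable across genes, conditions, and an
optional second pass removes gene-length dependence as well.

Around this statistic the package provides the full analysis a study of
this design needs:

- **`cellvar.qc`** — cell filtering (≥ 500,000 exon-mapped reads, ≤ 10%
  mitochondrial reads, intact capture), DESeq median-of-ratios size
  factors, and per-gene location/scale batch adjustment nested within
  condition;
- **`cellvar.variability`** — CV², running median, DM, Friedman test of
  transcriptome-wide heterogeneity across conditions, paired t-tests per
  gene set on DM and mean (sign(t)·−log₁₀p summaries, BH-adjusted),
  permutation enrichment of gene sets among extreme-DM genes, per-gene
  KS comparisons;
- **`cellvar.populations`** — hierarchical clustering on marker panels
  (1 − Spearman ρ, average linkage), a three-way
  committed/intermediate/ground subpopulation caller, G1/S vs G2/M phase
  assignment from z-scored marker scores, a rare 2C-like-cell detector
  (≥ 10-fold marker enrichment plus MERVL-reporter support), and
  spike-in-based per-cell mRNA-content estimation;
- **`cellvar.network`** — gene–gene Spearman correlation mining and
  anchor-based candidate ranking for regulatory-network discovery;
- **`cellvar.simulate`** — a negative-binomial generator that plants all
  of the above structure (HVGs, subpopulations, phases, rare 2C cells,
  spike-ins, batch effects, a correlated TF module) with complete truth
  labels, so every stage is testable without any download;
- **`cellvar.pipeline` / the `cellvar` CLI** — end-to-end orchestration
  with a YAML config, a JSON run manifest, and byte-reproducible outputs
  under a fixed seed.

## Worked example

```python
import cellvar as cv

cfg = cv.SimulationConfig(n_genes=1000, seed=1)   # study-layout defaults
ds = cv.simulate_dataset(cfg)
obs = ds.obs[ds.obs["qc_fate"] == "pass"]
counts = cv.counts_frame(ds)[obs.index]

s = cv.size_factors(counts, spike_mask=ds.var["is_spike"])
norm = cv.normalize(counts, s)
adj = cv.batch_adjust(norm, obs["batch"], obs["condition"])
endog = adj.loc[~ds.var["is_spike"].values]

serum = obs.index[obs["condition"] == "serum"]
print(cv.dm(endog[serum])[["mean", "cv2", "dm"]].head(3).round(3))

sets = ds.uns["gene_sets"]
labels, scores = cv.delineate_serum_subpopulations(
    endog[serum], sets["pluripotency_panel"], sets["differentiation_panel"]
)
print(scores[["n_cells", "proportion"]])

flags, evidence = cv.detect_2c_cells(
    norm.loc[~ds.var["is_spike"].values, obs.index[obs["condition"] == "2i"]],
    sets["2C_markers"], mervl_gene="MERVL-reporter",
)
print(f"2C-like cells: {int(flags.sum())}  fold={evidence['fold'][0]:.1f}")
```

prints

```
           mean    cv2     dm
gene_id
G00001   45.463  0.398  0.388
G00002   76.444  0.425  0.354
G00003   33.193  0.458  0.389
              n_cells  proportion
ground            168       0.672
committed          38       0.152
intermediate       44       0.176
2C-like cells: 10  fold=42.7
```

The DM column is each gene's variability above (positive) or below
(negative) genes of the same expression level. The subpopulation table
recovers the planted serum structure (0.68 ground / 0.15 committed /
0.17 intermediate), and the detector finds exactly the ten planted
2C-like cells among 295, with their marker enrichment fold.

The same run from a shell:

```
cellvar run-all --seed 1 --outdir out/
```

writes per-stage TSV tables (DM per condition, gene-set comparisons,
cell labels with subpopulation/phase/2C/content columns, the correlation
matrix and candidate ranking) plus `manifest.json` recording versions,
parameters, seed and per-stage counts.

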