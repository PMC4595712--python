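# Methods

`cellvar` analyzes cell-to-cell gene expression variability in
multi-condition single-cell RNA-seq experiments of the kind used to
compare mouse embryonic stem cell (mESC) culture conditions (serum, 2i,
a2i). This note records the models, the estimators, the numerical
choices, and what the synthetic-data generator does and does not
emulate.

## The DM statistic

For gene *g* with normalized expression values across cells, the squared
coefficient of variation is CV²_g = s²_g / μ²_g with the unbiased (n−1)
sample variance. CV² falls steeply with mean expression (shot noise
dominates low counts) and drifts with gene length, so raw CV² values are
not comparable between genes or conditions. The distance-to-the-median
statistic removes the mean trend nonparametrically:

1. keep genes with mean normalized counts ≥ `min_mean` (default 10) and
   positive variance;
2. order genes by log10 mean; take a running median *m*(μ_g) of
   log10 CV² in a centered window of `window` genes (default 51, odd);
3. DM_g = log10 CV²_g − m(μ_g).

At the edges of the ordering the nearest full window is used, so the
first and last ⌈w/2⌉ genes share the first/last full window's median.
Ties in the mean are broken by input position (stable sort). An optional
second pass subtracts a running median of DM against log10 gene length
(`length_correct=True`), for platforms where length drives residual
variance. DM is invariant to global rescaling of the expression values.

Window default: 51 genes is wide enough for a stable median at a few
thousand expressed genes and narrow enough not to flatten real curvature
of the CV²–mean trend; it is configurable and the brute-force oracle in
the test suite checks the exact windowing at any width.

Degenerate inputs: zero-mean genes are flagged undefined and excluded;
zero-variance genes (log10 CV² = −∞) are excluded before the running
median; fewer than `window` eligible genes is an error.

## Normalization and batch structure

Size factors use the DESeq median-of-ratios estimator: s_j = median over
reference genes of count(g,j) / geometric-mean over cells of count(g,·),
where reference genes are those nonzero in every cell. Spike-in genes
are excluded by default — their counts track sequencing depth, not
cellular mRNA content, and leaving them in would shrink exactly the
content differences the spike ratio is meant to expose. The estimator is
invariant to a global rescaling of all cells and equivariant to scaling
a single cell (up to geometric-mean recentering), both covered by tests.

Batch adjustment works per gene on log2(x+1) (pseudocount 1 everywhere
in the package): within each culture condition, each batch's values are
standardized (zero mean, unit variance; a zero-variance batch maps to
the pooled mean) and restored to the condition's pooled mean and
standard deviation, then back-transformed with a floor at zero. Nesting
within condition means condition differences — the object of study —
survive, while batch location and scale differences inside a condition
are removed exactly (per-gene batch means on the log scale agree to
machine precision for genes untouched by the zero floor).

One consequence worth knowing: per-gene standardization flattens any
signature carried by a handful of cells inside one batch. Rare-population
detection (the 2C-like caller) therefore runs on size-factor-normalized,
*not* batch-adjusted, values in the pipeline.

## Condition- and gene-set-level comparisons

* **Friedman rank-sum test** across ≥ 3 conditions with genes as blocks
  asks whether transcriptome-wide DM differs between conditions. An
  all-tied table returns statistic 0, p = 1 rather than NaN.
* **Paired t-tests per gene set** on DM and on mean expression between
  two conditions, summarized as sign(t)·(−log10 p) so heterogeneity
  changes can be read off orthogonally to expression changes. All-zero
  differences return t = 0, p = 1; sets with fewer than `min_set_size`
  (10) paired genes are skipped. Benjamini–Hochberg adjustment is
  applied across sets; raw and adjusted p are both reported.
* **Extreme-DM enrichment**: the statistic is the mean DM of a set's
  members; the null is `n_perm` same-size draws without replacement;
  p = (1 + #{null ≥ observed})/(n_perm + 1), mirrored for the low side.
  The smallest attainable p is 1/(n_perm+1) by construction. The mean
  was chosen over rank-based statistics for transparency; the
  permutation null makes no distributional assumption.
* **Per-gene KS tests** compare one gene's expression distribution
  between two conditions; below 8 cells per side a warning flags the
  comparison as underpowered.

All four test families are checked for null calibration (uniform
p-values) in the acceptance suite.

## Population structure

Cell–cell distance is 1 − Spearman ρ over a marker panel on log2(x+1),
with Spearman computed as Pearson on within-cell mid-ranks so that
all-zero cells are well-defined (ρ = 0). Clustering is agglomerative
with average linkage — a robust default for correlation distances and
consistent with how marker heatmaps are usually organized.

**Serum subpopulations.** Cells are cut into three clusters on the union
of the pluripotency and differentiation panels. Average linkage will
happily spend a cluster on one outlying cell, so the cut is deepened
until three clusters of at least max(5, 2% of cells) emerge; cells of
undersized clusters are attached to the nearest sized cluster by mean
distance. Labels come from panel scores: the cluster lowest in
pluripotency must also be highest in differentiation ("committed"), the
highest-pluripotency cluster is "ground", the remainder "intermediate".
A conflicting ordering raises an error carrying the score table instead
of guessing.

**Cell-cycle phase.** Each marker gene's log values are z-scored across
cells (so set size and expression magnitude do not dominate) and
averaged per set; a cell is G2/M when that score exceeds its G1/S score,
with ties going to G1/S deterministically.

**2C-like cells.** The candidate group is the subtree of the dendrogram
(between 3 cells and half the cells) maximizing the rank-sum z-score of
per-cell mean 2C-marker expression inside versus outside; the z-score
peaks at the true cluster boundary where a raw enrichment ratio would
favor the cluster's most extreme core, and a plain two-way cut is not
used because the minor branch of an average-linkage tree is typically an
outlier pair, not the rare population. Membership is then refined to a
fixed point: every cell above the geometric midpoint of the inside and
outside marker means. The refined group is flagged only if (i) its mean
marker expression is ≥ `fold_threshold` (default 10, the classical
definition of the 2C signature) times the remaining cells' mean, and
(ii) the MERVL-like reporter is higher inside (one-sided rank-sum
p < 0.05). Failing either gate flags nothing — clustering alone can
split a homogeneous population. Differential expression around the call
uses per-gene two-sided rank-sum tests with BH adjustment at 0.05,
counting up- versus downregulated genes by mean difference.

**mRNA content.** Spike-ins are added at fixed input per cell, so on raw
counts the ratio (endogenous sum)/(spike sum) is proportional to
cellular mRNA content; the ratio is invariant to uniform read
subsampling. Cells with zero spike counts are flagged and excluded from
comparisons. Group contrasts use two-sided rank-sum tests with BH
adjustment. Content comparisons are only meaningful among cells whose
lysates received the same spike input — in practice, within a spiked
batch.

## Correlation mining

Pairwise Spearman correlations over a gene subset on log2(x+1), with
mid-rank ties, large-sample t p-values, and BH adjustment over the upper
triangle; constant genes are flagged rather than silently dropped. For
an anchor gene, candidates are the significant correlates (adjusted
p < 0.05) outside the already-characterized set, ranked by |ρ| with the
sign kept to separate co-expression from mutual exclusion.

## The synthetic-data generator

Counts are gamma-Poisson (negative binomial): var = μ + φμ². Baseline
gene means are log-normal (ln-scale μ=1.5, σ=1.8 — a heavy-tailed law
with a realistic fraction of genes above the DM floor at a few hundred
thousand counts per cell); marker genes are drawn from a higher, wider
law (μ=4.0, σ=1.0) since panel genes are chosen to be well-measured and
to span an expression range, which is also what gives rank-correlation
distances their signal. Dispersion follows φ(μ) = a/μ + b (a=2, b=0.1)
times log-normal gene noise (sd 0.25), evaluated at the realized
per-cell mean so that a planted fold change moves a gene onto the law's
value at its new expression, as a mean–variance relation implies.
Highly variable genes get φ multiplied by `hvg_fold` (default 4).

Planted structure, with study-layout defaults:

* 250/295/159 cells passing QC in serum/2i/a2i, in 3/4/2 batches, plus
  extra cells planted to fail each QC criterion (5% low depth, 3% high
  mitochondrial fraction, 2% failed capture);
* serum splits 0.15/0.17/0.68 into committed (−3/+3 log2 on the full
  pluripotency/differentiation panels, mirroring near-silencing of core
  factors in committed cells), intermediate (±1.5 log2 on half of each
  panel — distinct in *which* markers move, as an intermediate state
  that loses some factors while keeping core ones high), and ground;
* two cell-cycle phase groups (markers +1.5 log2 in their phase), G2/M
  fractions 0.60/0.35/0.50 in 2i/a2i/serum;
* 10 of 295 2i cells are 2C-like: 2C markers (near-silent otherwise,
  ln-scale baseline μ=−0.5) multiplied by per-gene folds averaging 50
  (log-sd 0.5 — "at least 10-fold" is the list-inclusion floor of the
  signature, while the genes defining it swing from silence to high
  expression), and a MERVL-like reporter at 200-fold. Per-gene folds
  matter: a uniform fold preserves within-cell marker ranks and is
  invisible to Spearman clustering;
* per-cell mRNA content (log-normal, sd 0.3; ×0.5 in 2i, ×1.4 in G2/M)
  multiplies endogenous means only; sequencing depth (sd 0.25) and the
  per-batch global location effect multiply spikes too, since both are
  library-level; per-gene batch offsets (sd 0.1 log2) and per-batch
  dispersion multipliers (log-sd 0.1) hit endogenous genes only;
* a latent-factor transcription-factor module: one hub (loading 0.9)
  and five members (loading 0.8) share a standard-normal cell score on
  the log2 mean;
* QC metrics on the read scale (100 reads per counted fragment, exon
  fraction ~0.65, lower for 2C-like cells, mitochondrial reads from 13
  mito genes).

All draws flow from one `numpy` generator seeded by `SimulationConfig.seed`,
so a fixed seed reproduces counts bit-for-bit.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: no read-level artifacts (no
alignment error, no UMI structure, no gene-length coverage bias beyond
an optional planted trend), no dropout mechanism beyond what the
negative binomial implies, no continuous differentiation trajectories
(subpopulations are discrete), no doublets, and marker panels that are
cleanly informative rather than partially redundant. Detector
performance on real panels will be worse than the planted-truth numbers.

One subtlety the generator did expose: per-batch dispersion multipliers
are a *genuine* variability difference between conditions once batches
are nested in conditions, and the Friedman test correctly detects them.
The "equal heterogeneity across conditions" quantity reported by
`scripts/acceptance.py` is therefore computed under a design where the
conditions are exchangeable (no batch dispersion effects, matched cell
numbers); the full study-structure p-value is reported alongside and is
expected to be small.

## Problem sizes and numerical choices

The acceptance script and test suite run the estimator checks at 7,000
genes × 300 cells (trend removal, HVG recovery), 2,000 × 500 (size
factors), the study layout at 1,000 genes (population structure,
network), and 200 replicates per null-calibration family with 499
permutations per enrichment call — sizes at which every planted effect
is comfortably detectable and a full run takes seconds. Tolerances:
running-median oracle agreement at 1e-12; batch-mean equality at 1e-8 on
the log scale; BH adjustment never below raw p by construction.

## Known limitations

* The location/scale batch adjustment assumes batch effects are
  per-gene affine on the log scale; nonlinear batch distortions will
  leave residue.
* The 2C caller assumes the rare population is *more* marker-expressing
  than the background; an inverted signature needs `side`-style
  generalization.
* `min_mean=10` discards most of the transcriptome at shallow depth;
  the DM table deliberately reports only genes where CV² is estimable.
* Phase calling is a two-state argmax; cells in transition get forced
  into one of the two groups.
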