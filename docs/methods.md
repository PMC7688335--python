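# Methods

This package reimplements, as tested library code, the computational
procedures used to analyze a murine model of mutant-CALR essential
thrombocythemia: single-cell RNA-seq quality control, reference mapping,
graph abstraction of the stem/progenitor landscape, a kNN-vote
differential-abundance statistic, per-cluster differential expression, and
the statistics applied to single-cell clone assays.  The original mouse data
are not distributed; a synthetic-data generator with known ground truth
stands in for them, so every claim the test suite makes is about recovery of
planted structure, not about the biology of real cells.

## Synthetic landscape generator (`datagen`)

Cells live in a latent space of dimension `latent_dim`.  Each coarse cluster
has a centroid; non-bridge centroids sit on orthogonal axes at distance
`cluster_separation` (in units of the within-cluster latent SD,
`latent_noise_sd`, default 1) from the origin, so any two non-bridge
clusters are `separation * sqrt(2)` apart.  A cluster may be declared a
*bridge* between two named clusters; its centroid is the midpoint of theirs,
placing it `separation / sqrt(2)` from each flank — deliberately closer than
any other pair, which makes it an intermediate population on a trajectory.
Fine subclusters perturb the coarse centroid by `fine_spread_fraction`
(default 0.3) of the separation in a random direction.

Expression: gene means are `softplus(W z + b)` with `W ~ N(0, gene_scale² /
latent_dim)` and `b ~ N(0, 1.5²)`, guaranteeing positivity; means are
rescaled per cell to a log-normal library size (`library_size_mean`, shape
`library_size_sigma = 0.3`), and counts drawn from a negative binomial with
variance `mu + dispersion mu²` (gamma–Poisson mixture).  Mitochondrial genes
get zero latent loading (housekeeping-like) and their baselines are scaled
so the expected mitochondrial fraction is `mito_fraction_target` (default
4%, comfortably under the 10% QC threshold).  Query samples rescale the
coarse-cluster proportions by per-cluster genotype multipliers; planted DE
genes have their means multiplied by `2**log2FC` in mutant cells of the
target cluster before library rescaling (the resulting dilution is
negligible for the few dozen planted genes used here).

Planted DE genes are drawn from the well-expressed tail of the baseline
(`expressed_gene_indices`): a two-fold change on a gene with near-zero
baseline is statistically invisible at any sample size and does not
represent the intended study condition for sensitivity checks.

Spiked artifacts: doublets are element-wise sums of two distinct uniformly
sampled cells (cross-cluster pairs are not forced; parent indices are
recorded in the barcode); low-quality cells are copies of real cells with
either the mitochondrial share forced to 15–60% or the detected-gene count
truncated to 200.

The **demo landscape** used by the recovery benchmarks has 13 coarse
clusters (HSC, MK, a pMKP-like bridge between them, and ten other lineages),
5 fine subclusters each (65 planted fine labels, emulating the ~63-node
reference abstraction), 2,000 genes (50 mitochondrial), separation 5,
dispersion 0.25, library size 2,500, and mutant multipliers 3.0 (bridge) and
1.5 (HSC, MK).  These values were fixed as the package's study conditions:
separation 5 yields clusters that are well resolved but still contiguous
enough for the k = 7 graph to carry bridge–flank edges, which is the regime
the abstraction is designed for.

What the generator does **not** emulate: batch effects and ambient RNA,
gene–gene correlation beyond the low-rank latent structure, realistic
marker-gene identities, zero inflation beyond NB sampling, and cell-cycle or
library-chemistry covariates.  Passing tests therefore demonstrate
correctness of the procedures and recoverability of planted effects under a
clean NB landscape, not robustness to all features of real data.

## Quality control (`qc`)

Doublet scoring is scrublet-style: one synthetic doublet per observed cell
(sum of two distinct random parents), joint total-count normalization to the
median library, log1p, PCA to 30 components, and score = fraction of the
k = 20 nearest neighbors (self excluded) that are synthetic.  The PCA depth
and k are not given by the source experiment and are exposed in the config.
The top 1% (LSK) / 4.5% (LK) of scores per sample × gate are removed,
`ceil(fraction * n)` cells, ties broken by (score desc, barcode asc).

Hard filters: mitochondrial fraction strictly > 0.10; detected genes
strictly < 500; total UMI further than 3 SDs from the mean.  The 3-SD rule
is computed per sample × gate on raw totals, both tails (log-scale and
pooled variants are config options; the source text does not specify).
Cells failing several rules are counted once under the first applicable
rule, in the order doublet → mito → genes → UMI.  Re-filtering is idempotent
when the first pass's UMI statistics are reused.  Normalization scales each
cell to a common target (default: median library of the post-QC samples;
the source states only that totals were equalized).

## Reference mapping (`mapping`)

HVGs: binned normalized dispersion on log1p data (20 equal-frequency mean
bins, z-scored variance/mean per bin), top 2,000 by default; the selection
method is not specified by the source and this is the standard contract.
PCA: HVG submatrix centered and unit-scaled (clipped at ±10; scaling
optional), top 50 components, deterministic sign convention.  Queries are
projected with reference parameters only; HVGs missing from a query are
treated as zero up to a 20% missing cap.  Label transfer: plurality vote of
the 15 nearest reference cells (Euclidean distance in component space).
Strict majority is unattainable with >2 labels, so plurality is used, with
ties broken by summed inverse distance then label order.

## Landscape graph (`graph`)

The cell graph is the union-symmetrized k = 7 nearest-neighbor graph.
Partitions are found by seeded Leiden refinement of Louvain modularity
(RBConfiguration), with coarse resolution 1.0 and fine resolution 8.0 —
the fine default was chosen so the demo reference partitions into ~60–66
nodes, matching the reference granularity the abstraction emulates.  Exact
cluster counts are data properties, not contracts.

Abstracted-graph connectivity between fine clusters i, j:

    w_ij = min(1, e_ij / e_hat_ij),
    e_hat_ij = E_total * n_i * n_j / C(n_cells, 2),

observed inter-cluster edges over their expectation under uniformly random
placement of all `E_total` edges across cell pairs.  This normalization
makes a random graph's weights center on 1 for any partition and gives
weight 0 when no inter-cluster edge exists.  Edges with weight > 0.3 are
displayed/used for layout.  The layout is a simplified ForceAtlas2: linear
attraction along (weighted) edges, degree-scaled repulsion between all node
pairs, decaying step size, seeded initialization; O(n²) per iteration with
no Barnes–Hut approximation, which is adequate below a few thousand nodes.
Layout coordinates are visualization-only; no analysis quantity depends on
them.

## Differential abundance (`abundance`)

Each query cell casts votes to its k = 15 nearest reference cells with the
total votes per sample equalized.  The default *weighted* scheme realizes
this exactly: a cell in sample s casts mass `1/n_s` split evenly over its k
neighbors, so each sample's total is 1 and the signed difference
d = votes(MUT) − votes(WT) sums to zero over reference cells.  An *integer*
scheme (`k_s = round(V/n_s)` unit votes per cell) is retained for fidelity
experiments; it equalizes totals only up to rounding.  The voting k is not
printed by the source; 15 (shared with mapping) is the default.  Node-level
abundance is the arithmetic mean of d over member cells; the top enriched
node is the argmax (ties broken by node size).  A permutation null (sample
labels shuffled over pooled query cells, neighbor structure computed once)
is provided for calibration testing only — the source describes no
significance procedure for abundance, and none is claimed.

## Differential expression (`de`)

Per gene, a two-sided Wilcoxon rank-sum test of mutant vs wild-type cells
within a cluster.  When both groups have ≤ 10 cells the permutation
distribution of the rank sum is computed exactly by dynamic programming over
doubled midranks (tie-aware, equivalent to full enumeration); otherwise the
tie-corrected normal approximation with continuity correction is used (mean
|error| vs exact ≈ 0.005 at group sizes 8–10).  BH adjustment is the
standard step-up (delegated to statsmodels).  Fold change is
`(mean_MUT + ε)/(mean_WT + ε)` on total-count-normalized means with
ε = 0.01; the DE gate is adjusted p < 0.05 and FC > 1.5 (one-sided, as the
source phrases it; a `two_sided_fc` switch adds FC < 1/1.5).  The
pathway-export gate is adjusted p < 0.01 and |log2FC| > 0.3785 (FC ≈ 1.3).
Genes expressed in at least one retained cell are tested; no further
gene-level QC is described by the source.

## Clone statistics (`clones`)

Wells are classified by content of enlarged (presumptive megakaryocyte) and
small cells: exactly one large → "1 MK"; several large only → ">1 MK"; both
→ "mixed"; small only → "proliferation only"; dead wells are tracked
separately.  Consolidations: MK/no-MK (three MK-containing categories vs
proliferation only) and three-way (1 MK / >1 MK / mixed+prolif), both
conserving counts.  `min_divisions(n) = ceil(log2 n)` assumes strictly
binary division and no death — the mathematical minimum — applied to the
maximum cell count over the observation window.  Marker-overlap scores
count CD41/Sca1/cKit agreement out of 3; a 0/3 score is flagged as
out-of-domain rather than rejected.

Summary-statistic tests: the default two-sample test from (mean, SD, n) is
Welch's t with Satterthwaite df.  The source names Student's t, but every
printed p-value that can be recomputed from printed summaries matches the
Welch form and not the pooled form; both variants are provided and the
discrepancy is simply documented.  One printed value (the pMKP bone-marrow
frequency comparison, p = 0.042) is reproduced only to 0.0398 — within the
propagation of the 1-significant-figure rounding of its printed SDs.
Chi-square is Pearson's statistic without continuity correction (with a
low-expected-count warning); Fisher's exact two-sided p uses the
probability-mass convention (sum of margin-fixed tables no likelier than
the observed), matching enumeration oracles exactly; Mann-Whitney U is
exact by enumeration for n+m ≤ 12 and tie-corrected asymptotic otherwise.

## Benchmarks and problem sizes

The recovery benchmarks (`experiments`) use: bridge recovery — demo
landscape, 5,000 reference and 2 × 3,000 query cells, 20 seeds; null
calibration — six-cluster landscape, 1,200 reference and 2 × 600 query
cells, 200 permutations, 50 seeds; doublet AUROC — two clusters of 400
cells, 5% spiked doublets, 10 seeds; DE recovery — 20 planted |log2FC| = 1
genes, ~500 cells per genotype in the tested cluster, 20 seeds.  The
analysis scripts run a smaller narrative instance (3,000 reference / 1,500
query cells) of the same demo.  These sizes were chosen so each benchmark
is statistically decisive at desk scale.

## Known limitations

- The generator's orthogonal-centroid geometry caps the number of non-bridge
  clusters at `latent_dim` and encodes no differentiation continuum beyond
  the bridge construction.
- The abstraction weight is the package's own exactly-testable contract; it
  reproduces the qualitative behavior of partition-based graph abstraction
  but is not bit-compatible with any particular external release.
- The permutation null for abundance is calibrated marginally per node; no
  multiplicity control across nodes is attempted (none is claimed by the
  descriptive statistic).
- Pathway analysis itself (a proprietary tool in the source workflow) is out
  of scope; only the export filter is implemented.
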