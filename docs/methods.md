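# Methods

This note documents the models and procedures implemented in `clonogem`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Quality control and normalization

Filtering is two one-pass steps, genes first: genes detected (count > 0) in
fewer than `min_cells_per_gene` cells (default 4) are removed; then cells are
kept only if their detected-feature count lies in
`[min_features_per_cell, max_features_per_cell]` (defaults 200–2500) and
their mitochondrial UMI fraction is **below** `max_mito_fraction` (default
5%). Two deliberate details:

- The mitochondrial fraction is computed on the **pre-gene-filter** matrix.
  A dying cell's signature should not be rescued because its mt- genes
  happen to be rare in the dataset.
- The feature count is computed on the gene-filtered matrix, matching the
  order in which the standard droplet workflow constructs its object.
- There is no iteration: cell removal can in principle push a gene back
  below the detection threshold, but re-filtering loops are not part of the
  standard recipe, so filtering is one pass and is only idempotent when the
  data is not balanced on a threshold knife-edge. An empty post-QC matrix
  raises `AllCellsFilteredError` rather than returning an empty success.

Mitochondrial genes are recognized by the case-insensitive symbol prefix
`mt-` (mouse convention; configurable).

Normalization is `log(1 + count/cell_total × scale)` with scale 10⁴; the
scaled view z-scores each gene across cells, maps zero-variance genes to 0,
and clips at +10 — the defaults of the workflow this mirrors. Variable genes
are ranked by the variance of trend-standardized counts (lowess of log₁₀
variance on log₁₀ mean; clipped at √n), the variance-stabilizing recipe.

## Clustering

PCA (top 2000 variable genes, 50 components by default) uses a full SVD with
component signs fixed so the largest-magnitude loading is positive —
reproducibility, not mathematics. The SNN graph connects cells whose
k-nearest-neighbor sets (k = 20, self included) overlap, weighted by Jaccard
similarity and pruned below 1/15. Community detection is seeded Leiden
modularity optimization (`RBConfigurationVertexPartition`), default
resolution 1.0 from the commonly used 0.8–1.4 range; labels are relabeled by
decreasing cluster size. The resolution–cluster-count relationship is
checked empirically in the tests as a property of this configuration, not
asserted as a theorem.

The 2-D embedding is pluggable (`embed_2d`): UMAP with a fixed random state,
or the first two PCs. The pipeline defaults to the PCA embedding — it is
deterministic, instantaneous, and sufficient for the density summaries; UMAP
is one config key away. Density maps use a Gaussian KDE per condition on a
shared grid, renormalized to integrate to exactly 1 on the grid.

## Clonotype statistics

Clone identity is the productive TRB V gene + J gene + CDR3 nucleotide
sequence; with several productive TRB contigs in a cell the highest-UMI one
wins, ties broken by lexicographically smallest CDR3. `paired` mode appends
the analogous TRA key. Barcodes without a productive TRB are reported
unassigned, and cells without TCR are **kept** in the expression analysis
(config flag on the pipeline to drop them was considered and rejected as a
silent cell-loss hazard; filtering can be done explicitly upstream).

Clone size is computed within condition across all clusters. This "global
size" is what makes the sharing analysis meaningful: a clone spanning the
exhausted and proliferating compartments counts as expanded in both.
"Expanded" means size ≥ 2, the complement of a singleton clone.
`mean_clone_size` averages over the unique clones present in a cluster (not
over cells, which would weight large clones quadratically); averaging over
within-cluster cell counts instead is available via `size_scope`.

Sharing percentages are computed over **expanded** cells only; the matrix
diagonal is fixed at 100 as a display convention, and a cluster with no
expanded cells scores 0 toward every other cluster.

## Regulons and AUCell

Regulon construction is a declared co-expression heuristic: for each TF,
candidate targets are ranked by absolute Spearman correlation across cells,
the top `n_top_targets` above a correlation floor are kept, and regulons
below 10 genes are dropped. This deliberately replaces motif-based target
pruning, which depends on external motif databases; externally derived
regulon lists can be supplied and scored identically, so the scoring and
testing layers are independent of how regulons were built. Co-expression
alone cannot distinguish direct regulation from shared cluster identity —
a TF active in one cluster will recruit that cluster's markers — so the
planted-recovery test evaluates the heuristic against a homogeneous
background.

AUCell scoring uses `top_fraction` = 0.05 of the ranked genes (the cited
method's convention; the source does not state the value used). Per-cell
ranking ties are broken deterministically by gene index rather than
randomized: determinism was preferred and is documented, at the cost of a
slight systematic preference for lower-index genes among exact ties.
Importance weights do not enter the score; the recovery curve is binary
membership, matching the original statistic.

## The GEM topic model

The tree is fixed: branching (5, 4, 3) below a virtual root, 85 nodes, every
node a GEM. The root is not a GEM and emits nothing — the printed node count
5 + 20 + 60 = 85 excludes it, which is the reading adopted.

Generative model per cell: each internal node has a stop probability
v ~ Beta(1, α_stop) (leaves stop with probability 1; the root never stops)
and a child distribution ~ Dirichlet(α_branch/b·1); a token walks from the
root, stopping or descending, then draws its gene from the stopped node's
Dirichlet(η) distribution. Tokens are individual UMIs — a count of c
contributes c tokens — so the cell-by-GEM count matrix conserves library
sizes exactly.

Inference is collapsed Gibbs over token→node assignments with v, the child
probabilities and the gene distributions integrated out. The per-token
conditional is (path probability under the cell's collapsed stick-breaking
counts) × (collapsed gene probability (η + n_node,gene)/(Gη + n_node)). The
sampler was chosen over variational inference because the bundled generator
uses the identical process, so recovery can be verified directly. Priors
default to η = 0.1, α_stop = α_branch = 1.0; all configurable. The original
work delegates its inference configuration to a reference implementation
without stating priors or iteration counts, so these defaults are declared
here, not reconstructed.

The posterior summary is the final Gibbs sample by default: averaging
post-burn-in samples is available (`average=True`) but opt-in, because a
posterior mean breaks the integer token-count semantics of the cell-by-GEM
matrix. Diagnostics record the collapsed joint log-probability per sweep;
a non-finite value raises with the iteration index. On identifiable
synthetic data the trajectory rises steeply through burn-in — monitored in
tests as a trend, never asserted monotone (Gibbs is stochastic).

Label switching: the tree is symmetric, so the sampler may recover a planted
topic at a different node position than it was generated from. Recovery is
therefore evaluated after an optimal one-to-one node matching (Hungarian
algorithm on pairwise cosine similarity), scoring the pairs whose planted
node sits at depth 1.

## Shared rank-sum kernel

One Wilcoxon rank-sum implementation backs marker detection, differential
regulons and differential GEMs. When both groups have ≤ 10 observations the
two-sided p is exact: the full permutation distribution of the rank sum is
enumerated with midranks, and p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Larger
groups use the tie-corrected normal approximation with continuity
correction; the boundary error is ≤ 0.01 at sizes 9–10. Identical pooled
samples return p = 1. GEM counts are normalized by library size before
testing; marker effect sizes are log₂ ratios of depth-scaled means
(+1-protected); multiple testing uses Benjamini–Hochberg (the source says
"adjusted P value" without naming a method; BH is the field default and is
configurable).

The exact one-proportion z test is z = (k/n − p₀)/√(p₀(1−p₀)/n) with
two-sided normal p.

## Synthetic data: what it emulates, what it does not

The generator emulates: cluster-specific multinomial expression programs
with planted marker folds; log-normal library sizes; a Beta-distributed
per-cell mitochondrial fraction (so QC has true positives); truncated
power-law clone sizes (default exponent 2.5, max 50 — heavy-tailed
repertoires without free parameters the source never states) with
controllable cross-cluster sharing, per-cluster expansion fractions, and
singleton-only clusters; TF→target co-activation via a shared per-cell Gamma
activity factor; and topic-tree token emission identical to the model the
sampler fits.

It does **not** emulate batch effects, ambient RNA, doublets, or
gene-length/GC biases. Passing the recovery tests therefore demonstrates
correctness of the statistics under the stated models, not robustness to
every artifact of real droplet data. Reproducibility is by a single seed
with named substreams per generator, so running stages in a different order
cannot change any stage's output.

## Problem sizes

The test suite and acceptance script run at desk scale by design: oracle
equivalences on fixtures of ≤ 50 cells / ≤ 50 genes (where exhaustive
enumeration is feasible), clonality recovery at 500 + 150 cells, topic
recovery at 500 cells × 300 genes with a (2,2,2) tree and 500 Gibbs sweeps,
null calibration over 20 seeds at 160 cells, and end-to-end determinism at
250 cells. These sizes make every check reproducible in seconds while
keeping the statistical tolerances meaningful (binomial standard errors are
computed from the actual n used).

## Known limitations

- The regulon heuristic conflates co-expression with regulation; it is a
  stand-in interface for externally inferred networks, not a network
  inference method.
- The topic tree is truncated and fixed; no model selection over tree shapes
  is attempted, and deeper or wider trees change the granularity of GEMs.
- The Gibbs sampler is exact in its conditionals but, like all single-site
  samplers, mixes slowly between symmetric modes; recovered node *positions*
  are only identified up to tree symmetry.
- QC idempotence is a property of typical data, not a guarantee (see above).
- `snn_cluster` requires at least k cells and is sensitive to k at very
  small n.
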