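# Methods

## The problem

Drop-out events — expressed genes recorded as zero for technical reasons —
make single-cell RNA-seq count matrices so sparse that standard correlation
coefficients (Pearson, Spearman, Cosine) applied to expression values miss
almost all gene–gene relationships: two genes co-expressed in the same cell
type can show near-zero correlation simply because their technical zeros are
mutually exclusive. `scgrn` infers co-expression by changing variables: each
gene is represented not by its counts but by its vector of signed
differential-expression (DE) Z-scores across all pairs of cell clusters.
Genes that respond in the same way to every cluster contrast are
co-regulated, whether or not they were captured in the same cells.

## Pipeline

### Normalisation and gene filtering

Counts are library-size normalised (each cell scaled to the mean library
size). All-zero and near-silent genes stay in the container but an
"expressed" mask (detected in at least `min_cells_expressed` cells, default
5) excludes them from DE and correlation. The detection threshold is a
package choice; it is exposed in the configuration because the appropriate
value depends on dataset depth.

### Recursive clustering

Cells are clustered hierarchically (Ward linkage on 1 − Pearson correlation
distances over highly variable genes, HVGs), and every resulting cluster is
re-clustered after recomputing its own HVG set — a single global HVG set
describes only the major cell types, so sub-types emerge only under
per-branch re-selection. HVGs are ranked by the excess of their coefficient
of variation over a rolling-median CV-vs-mean trend, scaled by the local
spread of that excess (CV estimates are far noisier at low expression, and an
unscaled excess ranks noisy low-mean genes above genuine markers).

The number of clusters at each step comes from an elbow rule: the dendrogram
is cut at nine levels spaced at 10% intervals of the merge-height range
(q10 near the root, q90 near the leaves), the number of informative clusters
(clusters of at least `min(min_size, n/5)` cells) is recorded at each level,
and the tree is cut at the level just before the first two-in-a-row increase
of that count. If the pattern never occurs the cut falls at the first level
with the maximal informative count. Children below the partition floor are
absorbed into their nearest sibling (centroid correlation).

Recursion terminates when a cluster is smaller than `min_size` (default 50
for datasets under 5000 cells, n/100 above), when it is smaller than
`2*min_size` and not heterogeneous (the chosen cut level below q60), when no
genes show excess variability, when the cut yields no meaningful separation,
or at `max_depth` (default 6). Heterogeneous small clusters split under a
relaxed floor of `min_size/4`, since a cluster below `2*min_size` cannot by
arithmetic split into two parts both above `min_size`.

### The noise model and pairwise DE

Cells with highly similar transcriptomes (greedy groups of 5–10 cells above
the 90th percentile of mutual rank correlation over highly expressed genes)
are treated as biological pseudo-replicates; the absolute log2 fold-changes
between within-group cell pairs, collected into 15 expression bins (quantile
bins of log mean expression), form an empirical null. The p-value of a
change between two expression values is the add-one-smoothed two-sided tail
of the null in the gene's bin: p(0) = 1 exactly, floor 1/(N+1). Datasets too
small to form replicate groups can use a Poisson fallback null.

DE between two clusters compares each cell of one group with each cell of
the other. For every gene the n1 × n2 signed −log10 p values are summed into
a raw score, which is standardised against a null obtained from (default 3)
random re-splits of the pooled cells: the per-gene null sd is a
through-origin regression of reshuffle sds on the gene's effective
comparison count (cell pairs with detection in at least one cell), with two
finite-sample corrections — the c4 unbiasing of an sd estimated from R
samples, and the sqrt(1 + 1/R) inflation from comparing against an estimated
null mean. Without these corrections the null Z-scores are over-dispersed by
~30%. An independent Wilcoxon rank-sum Z (tie-corrected, with continuity
correction below group sizes of 500) is merged with the numerical-model Z as
|Z_final| = sqrt(Z_num² + Z_w²), signed by Z_num (falling back to the
Wilcoxon sign). Merging rewards genes flagged reproducibly by both tests;
the two are complementary because Wilcoxon Z-scores are bounded by group
size while the numerical model is not.

### Correlation and thresholding

With x leaf clusters, genes acquire x(x−1)/2 Z-score coordinates. Pearson,
Spearman and Cosine coefficients are computed between gene vectors (zero
variance genes excluded; at least 3 coordinates required). The combined
coefficient is the worse (smaller-magnitude) of Pearson and Cosine, zero
when they disagree in sign. The network keeps the top 0.1% of candidate
pairs by combined magnitude (`corr_fraction`); the magnitude of the weakest
kept pair is the adaptive threshold rho_thresh, which equalises datasets of
different depth and cell number. Boundary ties are kept. Pairs with
|rho_Spearman| < |rho_thresh − 0.15| are then discarded as unstable.

### Network construction and statistics

Kept pairs become signed weighted edges. Edges with no endpoint annotated as
a regulator of gene expression are removed (GO sub-setting), then isolated
nodes and connected components below 1% of the current node count are pruned
to a fixpoint. Statistics: density (edges/nodes), % negative edges,
% regulator nodes, components, unweighted average shortest path on the
largest component, modularity of a greedy modularity-maximising partition
(absolute modularity values are algorithm-dependent), and a discrete
power-law goodness-of-fit p for the degree sequence (MLE alpha via the
Hurwitz zeta likelihood, xmin by KS minimisation, p from 200 semi-parametric
bootstrap refits with exact inverse-CDF tail sampling); p > 0.01 is read as
consistent with a scale-free topology.

### Centralities and comparison

Degree, betweenness, closeness, PageRank (damping 0.85) and eigenvector
centralities are computed on the unweighted undirected graph — signed
correlation weights have no shortest-path interpretation; |weight|-weighted
variants exist behind a flag. Betweenness is normalised to [0, 1]; closeness
uses the per-component (n_c − 1)/Σd convention; PageRank sums to 1 over the
graph; eigenvector centrality lives on the largest component (zero
elsewhere). Between two conditions, nodes are ranked by the absolute change
of a centrality (top 1000 reported; nodes present in one network get 0 in
the other, flagged), genes shifting with a strict common sign in all five
centralities are called consensus shifts, and gene pairs whose combined
correlation flips sign are inversions, "strong" when |rho_A − rho_B| > 1.

### Validation statistics

Per-edge signature co-occurrence uses the 2×2 table over an experimental
signature collection and the one-sided (greater) Fisher exact p — computed
as the hypergeometric upper tail, which is the same test — plus the fold
enrichment a·S/((a+b)(a+c)) over all evaluable signatures. Hub essentiality
is ES = log2((E_hubs/NE_hubs)/(E_bg/NE_bg)) with an add-one-smoothed
one-tailed permutation p over 10,000 equal-size random draws from the
catalogue (realised as hypergeometric draws of the essential count, which is
equivalent to resampling gene identities and removes the loop over genes),
Benjamini–Hochberg corrected across hub sets. Infinite ES (a zero cell) is
reported as ±inf with a Haldane-corrected (+0.5) companion value. Organ
specificity: top-20% membership per centrality per organ (exclusive =
central in exactly one), and an expression multiplicity from the modified
Z = (organ mean − cross-organ median)/IQR with type-7 (linear interpolation)
quartiles; genes with IQR = 0 get Z = 0 and a flag. The quartile convention
is stated because multiplicities depend on it.

## The synthetic generator

The generator is a Splat-style negative-binomial hierarchy. Gene base means
are Gamma(shape 4, scale 6) — high counts, because the benchmark requires a
near-dense (~3% zeros) reference. Cells belong to `n_clusters` clusters
(default 5, equal proportions); background DE gives each gene, per cluster,
a 4-fold shift with probability 0.1. Planted co-regulation: 12 modules of 10
genes share a per-module cluster profile (fold exponents in {−1, 0, 1}),
scaled per gene by an adherence drawn from U(0.25, 1) — so within-module
correlations form a continuum rather than one crisp level — with 20% of
module genes inverted (negative correlations). Each module also has a
per-cell activity (log-sd 0.5) loading on its genes: co-regulated genes
covary *within* clusters, a component of the true correlation signal that no
cluster-level representation can recover, which keeps benchmark recovery
below the trivial ceiling. Counts are Gamma–Poisson with NB size 10
(moderate overdispersion, typical of UMI fits; heavier noise erases the
|Pearson| > 0.8 truth pairs entirely) and lognormal library factors
(sd 0.15).

Dropout is Bernoulli thinning with probability logistic in log2 mean
(slope 0.7 in log2 units, i.e. the Splatter default shape of 1 on the
natural-log scale; a uniform mode exists for ablations), with the midpoint
calibrated by bisection so the realised zero fraction hits the target within
±1%. Truth = gene pairs with |Pearson| > 0.8 on log1p library-normalised
reference counts, recomputable from the stored reference.

What the generator does not emulate: empirical library-size distributions of
specific protocols, batch effects, doublets, and transcriptional bursting
beyond NB overdispersion. Passing benchmarks on it therefore show that the
pipeline recovers planted cluster-profile co-regulation under calibrated
mean-dependent dropout — not that real-tissue networks are correct.

## Benchmark protocols and problem sizes

The dropout-recovery experiment (scripts/acceptance.py and the acceptance
tests) simulates the reference at 3% sparsity, degrades it to 88% and 97%,
runs the full pipeline and computes the ROC AUC of |combined rho| against
the truth over all evaluable pairs, averaged over 10 seeds. The script runs
800 genes × 1000 cells with 5 clusters: the full cell count is kept because
cluster recovery at extreme sparsity is cell-limited, while the gene
reduction only shrinks the candidate-pair space; this keeps the whole script
around ten minutes on one CPU. A repetition whose degraded matrix supports
no cluster structure at all scores 0.5 (chance — the pipeline recovers
nothing) rather than being dropped. At 97% sparsity individual repetitions
range widely (≈0.49–0.69) for exactly this reason.

The null-FDR experiment permutes cells into clusters of a fixed size
multiset and counts pairs passing the real-data threshold. Chance
correlations shrink with the number of cluster-pair coordinates, so the
experiment is only meaningful with a realistic cluster count (the tests use
8 random clusters, 28 coordinates); with 3 clusters a 3-point correlation
exceeds 0.9 frequently by chance.

## Numerical choices and degenerate inputs

* Empirical p-values use add-one smoothing throughout; p = 0 is impossible.
* Adaptive threshold: k = ceil(fraction · P); ties at the boundary kept.
* Clusters with fewer than 2 cells are merged into the nearest cluster by
  centroid correlation before pairwise DE, with a warning.
* Null sd in Z_num is floored at a configurable epsilon (1e−8); genes with
  zero effective comparisons get Z_num = 0.
* The per-bin noise null falls back to the pooled null when a bin holds
  fewer than 50 samples; per-bin samples are capped at 20,000 (seeded
  subsample).
* Pruning an empty or vanishing network raises rather than returning an
  empty graph.
* All randomness (reshuffles, permutations, simulation, bootstrap) flows
  from explicit integer seeds; re-running with the same configuration and
  inputs is bit-reproducible.

## Known limitations

* The inferred networks are undirected; no causal orientation is attempted.
* Centrality changes between conditions carry no significance estimate.
* Modularity values depend on the community algorithm and should be compared
  only within this package.
* The pseudo-replicate grouping assumes the dataset contains groups of
  transcriptionally near-identical cells; datasets of uniformly distinct
  cells (e.g. a pure continuum) degrade the noise model towards the
  Poisson fallback.
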