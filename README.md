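# scgrn — global gene regulatory networks from single-cell RNA-seq

Single-cell RNA-seq is dominated by drop-out events: expressed genes
recorded as zero for technical reasons. Two genes co-expressed in the same
cell type can land in *different* cells' technical zeros, so standard
correlation coefficients applied to expression counts find almost nothing.
`scgrn` infers gene–gene correlations in a transformed space instead: each
gene is represented by its vector of signed differential-expression
Z-scores across all pairs of recursively defined cell clusters,

    Z_final = sign ⊙ sqrt(Z_num² + Z_wilcoxon²),

where `Z_num` comes from an empirical noise model built from
pseudo-replicate cells and `Z_wilcoxon` from the rank-sum test, computed for
every gene over every one of the x(x−1)/2 cluster-pair contrasts. Pearson,
Spearman and Cosine coefficients between these vectors expose correlations
that dropout conceals in count space. The final coefficient per pair is
min-magnitude(ρ_p, ρ_c) (zero on sign conflict); the top 0.1% of pairs by
magnitude become the signed edges of an undirected network (adaptive
threshold ρ_thresh, typically 0.9–0.99), pruned to edges touching at least
one annotated "regulator of gene expression".

The package is aimed at computational biologists who want to move beyond
cluster-and-DE workflows: build networks per condition, quantify gene
importance with five node centralities (degree, betweenness, closeness,
PageRank with damping 0.85, eigenvector), compare conditions by centrality
changes and correlation inversions, and validate edges and hubs against
signature collections (GMT), essentiality catalogues and organ panels.
A synthetic-data module generates clustered negative-binomial counts with
planted co-regulated modules and calibrated dropout, so every stage is
testable without external data.

## Worked example

```python
import numpy as np
from scgrn import RegulatorAnnotation, RunConfig, infer
from scgrn.synthetic_benchmarks import SimConfig, simulate

expr, truth = simulate(SimConfig(n_genes=300, n_cells=240, n_clusters=3,
                                 n_modules=8, module_size=8, seed=7))
regulators = RegulatorAnnotation(
    {f"G{g:04d}" for g in np.concatenate(truth.module_genes)}
    | {f"G{i:04d}" for i in range(0, 300, 7)})
result = infer(expr, regulators,
               config=RunConfig(seed=7, clustering_min_size=40,
                                corr_fraction=0.002))
print(result.tree.n_leaves, result.table.rho_thresh, result.stats.density)
```

Running `python examples/01_simulate_and_infer_network.py` (the same code
with commentary) prints:

```
simulated 300 genes x 240 cells, sparsity 3.0%, 79 true correlated pairs
clusters found: 3
adaptive correlation threshold: 1.000
network: 57 nodes, 69 edges, density 1.21, modularity 0.10
top hub genes by pagerank:
node
G0225    0.031897
G0277    0.031365
...
```

The three planted cell clusters are recovered exactly; the adaptive
threshold is the magnitude of the weakest kept correlation (at this tiny
scale the top 0.2% of pairs are all near-perfect); density is edges/nodes,
and the PageRank hubs are the genes most embedded in the inferred
regulatory structure. The other example scripts cover the dropout-recovery
benchmark (`02`), condition comparison with centrality deltas, consensus
shifts and correlation inversions (`03`), and edge/hub validation with
signature co-occurrence and essentiality scoring (`04`).

A thin CLI mirrors the library (`scgrn infer`, `compare`, `validate-edges`,
`score-essentiality`, `organ-specificity`, `simulate`, `benchmark`,
`print-config`); exit codes are 0 (ok), 2 (input error), 3 (numerical
failure).

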