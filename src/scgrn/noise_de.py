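"""Numerical noise model and pairwise differential expression in Z-score space.

The central idea: cells with highly similar transcriptomes are treated as
biological pseudo-replicates, and the expression variation *within* such groups
estimates the technical noise of the dataset. The resulting empirical null of
log-fold-changes yields a p-value for any expression change between two cells.
Differential expression between two clusters then compares every cell of one
group against every cell of the other (n1 x n2 comparisons), sums the signed
-log10 p-values into a raw score, adjusts it against a reshuffled-label null,
and merges the resulting Z with an independent Wilcoxon rank-sum Z:

    |Z_final| = sqrt(Z_num^2 + Z_wilcoxon^2)

Repeating this for every pair of clusters gives each gene a vector of signed
Z-scores — the representation over which gene-gene correlations are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_model import ExpressionMatrix

_MAX_NULL_PER_BIN = 20_000
_MIN_NULL_PER_BIN = 50


@dataclass
class NoiseModel:
    """Empirical null of within-replicate log-fold-changes, binned by expression.

    ``bin_edges`` partition genes by log2 mean normalized expression;
    ``null_abs_lfc`` holds, per bin, the sorted absolute log-fold-changes
    observed between pseudo-replicate cells. p-values are empirical two-sided
    tails with add-one smoothing: p = (#{null >= |lfc|} + 1) / (N + 1), so
    p(lfc=0) = 1 and the floor is 1/(N+1).
    """

    bin_edges: np.ndarray
    null_abs_lfc: list = field(default_factory=list)
    pseudocount: float = 1.0
    _nlp_tables: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        pooled = np.sort(np.concatenate([v for v in self.null_abs_lfc if len(v)])
                         if any(len(v) for v in self.null_abs_lfc)
                         else np.array([0.0]))
        self.null_abs_lfc = [
            np.sort(np.asarray(v, dtype=float)) if len(v) >= _MIN_NULL_PER_BIN
            else pooled
            for v in self.null_abs_lfc
        ]
        self._nlp_tables = []
        for v in self.null_abs_lfc:
            n = len(v)
            idx = np.arange(n + 1)
            self._nlp_tables.append(-np.log10((n - idx + 1.0) / (n + 1.0)))

    @property
    def n_bins(self) -> int:
        return len(self.null_abs_lfc)

    def assign_bins(self, mean_expression: np.ndarray) -> np.ndarray:
        """Bin index per gene from its mean normalized expression."""
        logm = np.log2(np.asarray(mean_expression, dtype=float) + self.pseudocount)
        return np.clip(np.searchsorted(self.bin_edges, logm, side="right") - 1,
                       0, self.n_bins - 1)

    def neglog10_p(self, abs_lfc: np.ndarray, bin_idx: int) -> np.ndarray:
        """-log10 p for absolute log-fold-changes, all in one expression bin."""
        null = self.null_abs_lfc[bin_idx]
        pos = np.searchsorted(null, abs_lfc, side="left")
        return self._nlp_tables[bin_idx][pos]

    def p_fn(self, expression_a: float, expression_b: float) -> float:
        """Two-sided p-value of a change between two expression values.

        The bin is taken from the mean of the two values, so the function is
        exactly symmetric in its arguments and p_fn(x, x) = 1.
        """
        pc = self.pseudocount
        lfc = np.log2(expression_a + pc) - np.log2(expression_b + pc)
        b = int(self.assign_bins(np.array([(expression_a + expression_b) / 2.0]))[0])
        return float(10.0 ** (-self.neglog10_p(np.array([abs(lfc)]), b)[0]))


def _pseudo_replicate_groups(expr: ExpressionMatrix, min_group: int,
                             top_q: float, seed: int,
                             max_cells: int, max_group: int):
    """Greedy grouping of mutually most-similar cells by rank correlation."""
    rng = np.random.default_rng(seed)
    n = expr.n_cells
    cell_idx = np.arange(n)
    if n > max_cells:
        cell_idx = np.sort(rng.choice(n, size=max_cells, replace=False))
    X = expr.dense()[:, cell_idx]
    means = X.mean(axis=1)
    top_genes = np.argsort(means)[::-1][: min(200, X.shape[0])]
    ranks = rankdata(X[top_genes], axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks.T)
    corr = np.nan_to_num(corr, nan=-1.0)
    np.fill_diagonal(corr, -np.inf)

    m = len(cell_idx)
    off = corr[np.triu_indices(m, k=1)]
    thresh = np.quantile(off[np.isfinite(off)], top_q) if m > 1 else np.inf

    unassigned = set(range(m))
    groups = []
    work = corr.copy()
    while len(unassigned) >= min_group:
        sub = sorted(unassigned)
        sub_arr = np.array(sub)
        block = work[np.ix_(sub_arr, sub_arr)]
        flat = np.argmax(block)
        i, j = np.unravel_index(flat, block.shape)
        if block[i, j] < thresh:
            break
        group = [sub_arr[i], sub_arr[j]]
        unassigned.discard(group[0])
        unassigned.discard(group[1])
        while len(group) < max_group and unassigned:
            cand = np.array(sorted(unassigned))
            mean_to_group = corr[np.ix_(cand, np.array(group))].mean(axis=1)
            k = int(np.argmax(mean_to_group))
            if mean_to_group[k] < thresh and len(group) >= min_group:
                break
            group.append(cand[k])
            unassigned.discard(cand[k])
        if len(group) >= min_group:
            groups.append(cell_idx[np.array(group)])
    return groups


def fit_noise_model(expr: ExpressionMatrix, n_bins: int = 15,
                    min_group: int = 5, top_q: float = 0.90,
                    seed: int = 0, max_cells: int = 300,
                    max_group: int = 10,
                    min_cells_expressed: int = 5) -> NoiseModel:
    """Fit the empirical noise model from pseudo-replicate cell groups.

    Cells are greedily grouped by mutual rank correlation over highly expressed
    genes (groups of ``min_group``..``max_group`` cells above the ``top_q``
    similarity quantile); absolute log-fold-changes between all within-group
    cell pairs populate the per-bin null distributions.
    """
    if expr.n_cells < 20:
        raise ValueError(
            "need >= 20 cells to form pseudo-replicate groups; for smaller "
            "inputs use fit_poisson_noise_model() as a fallback"
        )
    if not expr.normalized:
        raise ValueError("noise model requires a normalized matrix")

    groups = _pseudo_replicate_groups(expr, min_group, top_q, seed,
                                      max_cells, max_group)
    if not groups:
        raise ValueError(
            "could not form any pseudo-replicate group; use "
            "fit_poisson_noise_model() as a fallback"
        )

    mask = expr.expressed_mask(min_cells_expressed)
    X = expr.dense()[mask]
    pc = expr.pseudocount
    gene_means = X.mean(axis=1)
    logm = np.log2(gene_means + pc)
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    # collapse duplicate edges from heavily tied means
    edges = np.unique(edges)
    if len(edges) < 2:
        edges = np.array([-np.inf, np.inf])
    bins = np.clip(np.searchsorted(edges, logm, side="right") - 1,
                   0, len(edges) - 2)

    rng = np.random.default_rng(seed + 1)
    per_bin = [[] for _ in range(len(edges) - 1)]
    L = np.log2(X + pc)
    for g in groups:
        cols = L[:, g]
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                d = np.abs(cols[:, a] - cols[:, b])
                for bi in range(len(per_bin)):
                    per_bin[bi].append(d[bins == bi])
    null = []
    for bi, chunks in enumerate(per_bin):
        v = np.concatenate(chunks) if chunks else np.array([])
        if len(v) > _MAX_NULL_PER_BIN:
            v = rng.choice(v, size=_MAX_NULL_PER_BIN, replace=False)
        null.append(v)
    return NoiseModel(bin_edges=edges, null_abs_lfc=null, pseudocount=pc)


def fit_poisson_noise_model(expr: ExpressionMatrix, n_bins: int = 15,
                            n_pairs: int = 2000, seed: int = 0) -> NoiseModel:
    """Poisson-like fallback null for inputs too small to form replicate groups.

    Per expression bin, the null log-fold-changes are simulated from pairs of
    Poisson draws at the bin's representative mean.
    """
    pc = expr.pseudocount
    mask = expr.expressed_mask(1)
    means = expr.dense()[mask].mean(axis=1)
    if means.size == 0:
        means = np.array([1.0])
    logm = np.log2(means + pc)
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    edges = np.unique(edges)
    if len(edges) < 2:
        edges = np.array([-np.inf, np.inf])
    rng = np.random.default_rng(seed)
    null = []
    for bi in range(len(edges) - 1):
        sel = means[np.clip(np.searchsorted(edges, logm, "right") - 1,
                            0, len(edges) - 2) == bi]
        m = sel.mean() if sel.size else float(means.mean())
        x = rng.poisson(m, size=n_pairs)
        y = rng.poisson(m, size=n_pairs)
        null.append(np.abs(np.log2(x + pc) - np.log2(y + pc)))
    return NoiseModel(bin_edges=edges, null_abs_lfc=null, pseudocount=pc)


# ---------------------------------------------------------------------------
# pairwise DE scores


def _check_groups(cells_a, cells_b):
    a = np.asarray(cells_a)
    b = np.asarray(cells_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 cells")
    if np.intersect1d(a, b).size:
        raise ValueError("cell groups overlap")
    return a, b


def raw_de_score(expr: ExpressionMatrix, cells_a, cells_b,
                 model: NoiseModel, gene_idx=None,
                 chunk_elements: int = 4_000_000) -> np.ndarray:
    """Per-gene sum of signed -log10 p over all n1 x n2 cell pair comparisons.

    Positive scores mean upregulation in group A. The computation enumerates
    every cell pair exactly (vectorised in chunks of genes sharing a bin).
    """
    a, b = _check_groups(cells_a, cells_b)
    X = expr.dense()
    if gene_idx is None:
        gene_idx = np.arange(expr.n_genes)
    gene_idx = np.asarray(gene_idx)
    pc = expr.pseudocount
    sub = X[gene_idx]
    mean_union = sub[:, np.concatenate([a, b])].mean(axis=1)
    bins = model.assign_bins(mean_union)
    La = np.log2(sub[:, a] + pc)
    Lb = np.log2(sub[:, b] + pc)
    n1, n2 = len(a), len(b)
    out = np.zeros(len(gene_idx))
    per_chunk = max(1, chunk_elements // (n1 * n2))
    for bi in np.unique(bins):
        rows = np.flatnonzero(bins == bi)
        for start in range(0, len(rows), per_chunk):
            r = rows[start:start + per_chunk]
            D = La[r][:, :, None] - Lb[r][:, None, :]
            nlp = model.neglog10_p(np.abs(D).ravel(), int(bi)).reshape(D.shape)
            out[r] = (np.sign(D) * nlp).sum(axis=(1, 2))
    return out


def adjust_raw_score(raw_score: np.ndarray, expr: ExpressionMatrix,
                     cells_a, cells_b, model: NoiseModel,
                     reshuffles: int = 3, seed: int = 0,
                     eps: float = 1e-8, gene_idx=None) -> np.ndarray:
    """Adjust raw DE scores into Z_num against a reshuffled-label null.

    The null mean per gene comes from ``reshuffles`` random permutations of the
    pooled cell labels (cells of the two groups mixed, then re-split at the
    original sizes). The null sd is scaled linearly in the effective number of
    comparisons for the gene — cell pairs where the gene is detected in at
    least one of the two cells — via a through-the-origin regression of the
    per-gene reshuffle sds on the effective pair counts, which pools
    information across genes.
    """
    if reshuffles < 1:
        raise ValueError("reshuffles must be >= 1")
    a, b = _check_groups(cells_a, cells_b)
    if gene_idx is None:
        gene_idx = np.arange(expr.n_genes)
    gene_idx = np.asarray(gene_idx)
    n1, n2 = len(a), len(b)
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty((reshuffles, len(gene_idx)))
    for r in range(reshuffles):
        perm = rng.permutation(pool)
        null[r] = raw_de_score(expr, perm[:n1], perm[n1:], model,
                               gene_idx=gene_idx)
    null_mean = null.mean(axis=0)
    if reshuffles > 1:
        # c4 unbiasing: the ddof=1 sd of R samples underestimates sigma
        from scipy.special import gammaln
        c4 = np.sqrt(2.0 / (reshuffles - 1)) * np.exp(
            gammaln(reshuffles / 2.0) - gammaln((reshuffles - 1) / 2.0))
        s_g = null.std(axis=0, ddof=1) / c4
    else:
        s_g = np.abs(null[0])

    X = expr.dense()[gene_idx]
    za = (X[:, a] == 0).sum(axis=1)
    zb = (X[:, b] == 0).sum(axis=1)
    eff = n1 * n2 - za * zb  # pairs with detection in >= 1 cell
    denom = float((eff.astype(float) ** 2).sum())
    slope = float((s_g * eff).sum() / denom) if denom > 0 else 0.0
    # the observed score is compared to an ESTIMATED null mean of R
    # reshuffles, so the difference has variance sigma^2 * (1 + 1/R)
    null_sd = np.maximum(slope * eff * np.sqrt(1.0 + 1.0 / reshuffles), eps)
    z = (raw_score - null_mean) / null_sd
    z[eff == 0] = 0.0
    return z


def wilcoxon_z(expr: ExpressionMatrix, cells_a, cells_b,
               gene_idx=None, continuity: bool | None = None) -> np.ndarray:
    """Signed Wilcoxon rank-sum Z per gene (normal approximation).

    Positive when group A is stochastically larger. Uses tie-corrected
    variance; the continuity correction is applied by default and dropped for
    very large groups (min(n1, n2) > 500), where its effect is negligible.
    """
    a, b = _check_groups(cells_a, cells_b)
    n1, n2 = len(a), len(b)
    if continuity is None:
        continuity = min(n1, n2) <= 500
    if gene_idx is None:
        gene_idx = np.arange(expr.n_genes)
    X = expr.dense()[np.asarray(gene_idx)]
    vals = np.concatenate([X[:, a], X[:, b]], axis=1)
    ranks = rankdata(vals, axis=1)
    r_a = ranks[:, :n1].sum(axis=1)
    u = r_a - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2

    # tie correction: sum of t^3 - t over tied groups, per gene
    sv = np.sort(vals, axis=1)
    same = np.concatenate(
        [np.zeros((vals.shape[0], 1), bool), sv[:, 1:] == sv[:, :-1]], axis=1
    )
    tie_term = np.empty(vals.shape[0])
    for g in range(vals.shape[0]):
        # run lengths of tied values
        boundaries = np.flatnonzero(~same[g])
        lengths = np.diff(np.append(boundaries, n))
        tie_term[g] = float((lengths.astype(float) ** 3 - lengths).sum())

    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sd = np.sqrt(np.maximum(var, 0.0))
    diff = u - mu
    if continuity:
        diff = diff - 0.5 * np.sign(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, diff / sd, 0.0)
    return z


def merge_z(z_num: np.ndarray, z_wilcoxon: np.ndarray) -> np.ndarray:
    """Merge the two DE Z-scores: magnitude sqrt(Z_num^2 + Z_w^2).

    The sign is taken from Z_num, falling back to the Wilcoxon sign when
    Z_num is exactly zero. Merging rewards genes reproducibly flagged by both
    tests: |Z_final| >= max(|Z_num|, |Z_wilcoxon|).
    """
    z_num = np.asarray(z_num, dtype=float)
    z_wilcoxon = np.asarray(z_wilcoxon, dtype=float)
    if z_num.shape != z_wilcoxon.shape:
        raise ValueError("Z-score vectors have mismatched lengths")
    mag = np.hypot(z_num, z_wilcoxon)
    sign = np.sign(z_num)
    sign = np.where(sign == 0, np.sign(z_wilcoxon), sign)
    return sign * mag


# ---------------------------------------------------------------------------
# the Z-score matrix over all cluster pairs


@dataclass
class ZScoreMatrix:
    """Gene x cluster-pair matrix of final signed DE Z-scores."""

    genes: np.ndarray
    comparisons: list  # list of (cluster_a, cluster_b) with a < b
    Z: np.ndarray

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.genes), len(self.comparisons)):
            raise ValueError("Z shape does not match genes x comparisons")

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def column_names(self) -> list:
        return [f"{a}|{b}" for a, b in self.comparisons]

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.Z, index=self.genes,
                     columns=self.column_names()).to_csv(
            path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "ZScoreMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        comps = [tuple(c.split("|", 1)) for c in df.columns]
        return cls(df.index.to_numpy(), comps, df.to_numpy())


def _merge_tiny_clusters(expr: ExpressionMatrix, assignments: dict,
                         min_cells: int = 2) -> dict:
    """Merge clusters with < min_cells cells into the nearest cluster by
    centroid Pearson distance."""
    labels = sorted(assignments)
    sizes = {c: len(assignments[c]) for c in labels}
    small = [c for c in labels if sizes[c] < min_cells]
    if not small:
        return assignments
    L = np.log2(expr.dense() + expr.pseudocount)
    centroids = {c: L[:, assignments[c]].mean(axis=1) for c in labels}
    out = {c: list(assignments[c]) for c in labels if c not in small}
    for c in small:
        best, best_r = None, -np.inf
        for o in out:
            r = np.corrcoef(centroids[c], centroids[o])[0, 1]
            if r > best_r:
                best, best_r = o, r
        if best is None:
            continue
        warnings.warn(f"cluster {c!r} has < {min_cells} cells; merged into {best!r}")
        out[best] = out[best] + list(assignments[c])
    return {c: np.asarray(v) for c, v in out.items()}


def zscore_matrix(expr: ExpressionMatrix, assignments,
                  model: NoiseModel | None = None,
                  reshuffles: int = 3, seed: int = 0,
                  min_cells_expressed: int = 5) -> ZScoreMatrix:
    """Run DE between all x(x-1)/2 cluster pairs and collect final Z-scores.

    ``assignments`` maps cluster label -> array of cell indices (or is a
    per-cell label vector). Column order is lexicographic over sorted cluster
    labels with a < b. Deterministic given ``seed``.
    """
    if not isinstance(assignments, dict):
        lab = np.asarray(assignments)
        assignments = {c: np.flatnonzero(lab == c) for c in np.unique(lab)}
    if len(assignments) < 2:
        raise ValueError("need >= 2 clusters for pairwise DE")
    assignments = _merge_tiny_clusters(expr, assignments)
    if model is None:
        model = fit_noise_model(expr, seed=seed,
                                min_cells_expressed=min_cells_expressed)
    mask = expr.expressed_mask(min_cells_expressed)
    gene_idx = np.flatnonzero(mask)
    labels = sorted(assignments)
    comps = [(labels[i], labels[j])
             for i in range(len(labels)) for j in range(i + 1, len(labels))]
    Z = np.empty((len(gene_idx), len(comps)))
    for k, (ca, cb) in enumerate(comps):
        a, b = assignments[ca], assignments[cb]
        raw = raw_de_score(expr, a, b, model, gene_idx=gene_idx)
        z_num = adjust_raw_score(raw, expr, a, b, model,
                                 reshuffles=reshuffles,
                                 seed=seed * 100_003 + k, gene_idx=gene_idx)
        z_w = wilcoxon_z(expr, a, b, gene_idx=gene_idx)
        Z[:, k] = merge_z(z_num, z_w)
    return ZScoreMatrix(expr.genes[gene_idx], comps, Z)
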