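"""Recursive Ward clustering with per-branch re-selection of variable genes.

Each cluster is re-clustered after recomputing its own set of highly variable
genes (HVGs): a single global HVG set mostly separates major cell types, so
sub-types and subtle states only emerge once distances are recomputed on the
branch's own variable genes. An elbow-style rule on the dendrogram decides the
cut level at each step, and recursion stops when a cluster is too small or
yields no meaningful further separation; clusters below twice the minimum
partition size are split only when they are very heterogeneous (their
unsupervised cut falls deep in the tree).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_model import ExpressionMatrix

_QUANTILES = np.arange(0.1, 1.0, 0.1)  # q10 .. q90


@dataclass
class ClusterTree:
    """Result of recursive clustering: leaf assignments plus the nested record."""

    assignments: dict  # cell index -> leaf label (e.g. "0.1.2")
    tree: dict
    min_size: int

    def labels(self, n_cells: int) -> np.ndarray:
        out = np.empty(n_cells, dtype=object)
        for cell, lab in self.assignments.items():
            out[cell] = lab
        return out

    @property
    def n_leaves(self) -> int:
        return len(set(self.assignments.values()))

    def leaf_cells(self) -> dict:
        out = {}
        for cell, lab in self.assignments.items():
            out.setdefault(lab, []).append(cell)
        return {k: np.sort(np.asarray(v)) for k, v in out.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"min_size": self.min_size, "tree": self.tree}, fh,
                      indent=1, default=str)

    def assignments_to_tsv(self, path, cells) -> None:
        with open(path, "w") as fh:
            fh.write("cell\tcluster\n")
            for idx in sorted(self.assignments):
                fh.write(f"{cells[idx]}\t{self.assignments[idx]}\n")


def highly_variable_genes(expr: ExpressionMatrix, cells=None,
                          n_hvg: int = 500, min_pass: int = 10,
                          window: int = 101) -> np.ndarray:
    """Rank genes by excess coefficient of variation over the mean-CV trend.

    CV is computed on log-normalised values over the given cells; the trend is
    a rolling median of CV against mean expression, so HVGs are genes whose
    variability exceeds what their expression level predicts. Returns the
    indices of the top ``n_hvg`` genes (or every passing gene if fewer);
    returns an empty array — a termination signal — when fewer than
    ``min_pass`` genes show any excess variability.
    """
    if cells is None:
        cells = np.arange(expr.n_cells)
    cells = np.asarray(cells)
    X = np.log2(expr.dense()[:, cells] + expr.pseudocount)
    mean = X.mean(axis=1)
    sd = X.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)

    order = np.argsort(mean)
    cv_sorted = cv[order]
    k = min(window, len(cv_sorted))
    if k % 2 == 0:
        k = max(1, k - 1)
    trend_sorted = _rolling_median(cv_sorted, k)
    # scale by the local spread: CV estimates are far noisier at low
    # expression, and an unscaled excess would rank noisy low-mean genes
    # above genuine markers
    spread_sorted = _rolling_median(np.abs(cv_sorted - trend_sorted), k)
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    spread = np.empty_like(spread_sorted)
    spread[order] = spread_sorted
    excess = (cv - trend) / (spread + 1e-12)

    passing = np.flatnonzero(excess > 0)
    if len(passing) < min_pass:
        return np.array([], dtype=int)
    ranked = passing[np.argsort(excess[passing])[::-1]]
    return ranked[:n_hvg]


def _rolling_median(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1 or len(x) <= 2:
        return np.full_like(x, np.median(x) if len(x) else 0.0)
    from scipy.ndimage import median_filter
    # mirror boundaries: "nearest" would replicate an outlying edge value
    # into half its own window and absorb it into the trend
    return median_filter(x, size=k, mode="mirror")


def _ward_linkage(expr: ExpressionMatrix, cells: np.ndarray,
                  hvg: np.ndarray) -> np.ndarray:
    """Ward linkage on 1 - Pearson correlation distances over HVGs."""
    X = np.log2(expr.dense()[np.ix_(hvg, cells)] + expr.pseudocount)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return linkage(squareform(dist, checks=False), method="ward")


def choose_cut_index(counts) -> int | None:
    """Apply the two-increases-in-a-row elbow rule to cluster counts at the
    q10..q90 cut levels.

    Finds the first position i where counts[i] > counts[i-1] and
    counts[i+1] > counts[i]; the chosen cut is the level immediately before
    the first of those two increases (index i-1). Returns None when the
    pattern never occurs.
    """
    counts = list(counts)
    for i in range(1, len(counts) - 1):
        if counts[i] > counts[i - 1] and counts[i + 1] > counts[i]:
            return i - 1
    return None


def cut_tree_elbow(link: np.ndarray, n_cells: int,
                   count_min_size: int = 1) -> tuple[np.ndarray, int]:
    """Cut a Ward tree at the elbow over 10th-quantile cut heights.

    Cut heights divide the merge-distance range into 10% intervals, ordered so
    that deeper levels (towards q90) cut nearer the leaves; the cluster count
    evaluated at each level considers only clusters with at least
    ``count_min_size`` cells (fragments below it are absorbed downstream and
    would otherwise swamp the count). Returns (labels, chosen level index
    0..8, 0 meaning q10). When the two-in-a-row pattern never occurs, falls
    back to the first level with the maximal informative-cluster count.
    """
    if n_cells < 2:
        return np.zeros(max(n_cells, 1), dtype=int), 0
    heights = link[:, 2]
    # q10 cuts high in the tree (few clusters), q90 near the leaves
    h_min, h_max = float(heights.min()), float(heights.max())
    cut_heights = h_min + (1.0 - _QUANTILES) * (h_max - h_min)
    all_labels = [fcluster(link, t=h, criterion="distance")
                  for h in cut_heights]
    counts = []
    for lab in all_labels:
        _, sizes = np.unique(lab, return_counts=True)
        counts.append(int((sizes >= count_min_size).sum()))
    idx = choose_cut_index(counts)
    if idx is None:
        idx = int(np.argmax(counts))
    return all_labels[idx] - 1, idx


@dataclass
class _RecursionConfig:
    min_size: int
    max_depth: int
    n_hvg: int
    hetero_cut_index: int  # chosen quantile index >= this counts as heterogeneous


def default_min_size(n_cells: int) -> int:
    """50 cells for datasets below 5000 cells, else ceil(n/100)."""
    return 50 if n_cells < 5000 else int(np.ceil(n_cells / 100))


def recursive_cluster(expr: ExpressionMatrix, min_size: int | None = None,
                      max_depth: int = 6, n_hvg: int = 500,
                      hetero_cut_index: int = 5, seed: int = 0) -> ClusterTree:
    """Recursively segregate cells into the maximum number of informative
    clusters.

    A cluster of at least ``2 * min_size`` cells is re-clustered whenever the
    elbow cut yields a meaningful separation; a smaller cluster (but above
    ``min_size``) is re-clustered only when it is very heterogeneous — its
    unsupervised cut level reaches ``hetero_cut_index`` (default q60).
    Children falling below the partition floor are merged into their nearest
    sibling by centroid correlation. The procedure is deterministic.
    """
    del seed  # deterministic; kept for interface symmetry
    if min_size is None:
        min_size = default_min_size(expr.n_cells)
    cfg = _RecursionConfig(min_size, max_depth, n_hvg, hetero_cut_index)
    assignments: dict[int, str] = {}
    tree = _recurse(expr, np.arange(expr.n_cells), "0", 0, cfg, assignments)
    return ClusterTree(assignments=assignments, tree=tree, min_size=min_size)


def _recurse(expr, cells, label, depth, cfg, assignments) -> dict:
    node = {"label": label, "n_cells": int(len(cells)), "children": []}

    def leaf(reason):
        node["terminated"] = reason
        for c in cells:
            assignments[int(c)] = label
        return node

    if depth >= cfg.max_depth:
        return leaf("max_depth")
    if len(cells) < cfg.min_size or len(cells) < 4:
        return leaf("below_min_size")
    small = len(cells) < 2 * cfg.min_size

    hvg = highly_variable_genes(expr, cells, n_hvg=cfg.n_hvg)
    if hvg.size == 0:
        return leaf("no_variable_genes")
    node["n_hvg"] = int(hvg.size)

    # count only clusters big enough to be informative at this branch size
    count_floor = max(2, min(cfg.min_size, len(cells) // 5))
    link = _ward_linkage(expr, cells, hvg)
    labels, cut_idx = cut_tree_elbow(link, len(cells),
                                     count_min_size=count_floor)
    node["cut_quantile_index"] = int(cut_idx)
    if small and cut_idx < cfg.hetero_cut_index:
        return leaf("small_and_homogeneous")

    # partition floor: min_size normally; relaxed for heterogeneous small
    # clusters, which cannot split into two min_size halves by construction
    floor = cfg.min_size if not small else max(2, cfg.min_size // 4)
    parts = {k: cells[labels == k] for k in np.unique(labels)}
    parts = _absorb_small(expr, parts, floor)
    if len(parts) < 2:
        return leaf("no_meaningful_split")

    for i, k in enumerate(sorted(parts, key=lambda k: -len(parts[k]))):
        child = _recurse(expr, parts[k], f"{label}.{i}", depth + 1, cfg,
                         assignments)
        node["children"].append(child)
    return node


def _absorb_small(expr, parts: dict, floor: int) -> dict:
    """Merge children below the partition floor into their nearest sibling."""
    big = {k: v for k, v in parts.items() if len(v) >= floor}
    small = {k: v for k, v in parts.items() if len(v) < floor}
    if not big:
        return {0: np.concatenate(list(parts.values()))} if parts else {}
    if not small:
        return parts
    L = np.log2(expr.dense() + expr.pseudocount)
    centroids = {k: L[:, v].mean(axis=1) for k, v in parts.items()}
    out = {k: list(v) for k, v in big.items()}
    for k, v in small.items():
        best, best_r = None, -np.inf
        for o in big:
            r = np.corrcoef(centroids[k], centroids[o])[0, 1]
            if r > best_r:
                best, best_r = o, r
        out[best].extend(v)
    return {k: np.sort(np.asarray(v)) for k, v in out.items()}
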