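"""Gene-gene correlations in Z-score space, with adaptive thresholding.

Each gene is represented by its vector of signed DE Z-scores across all
cluster-pair comparisons; Pearson, Spearman and Cosine coefficients are
computed between those vectors. The final coefficient per pair is the worse
(smaller-magnitude) of Pearson and Cosine — Spearman serves as a later
control. Edges are selected by an adaptive threshold retaining the top
fraction (default 0.1%) of candidate pairs by combined magnitude, which
equalises datasets of different depth and cell number, and pairs whose
Spearman magnitude falls below |rho_thresh - 0.15| are discarded as unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .noise_de import ZScoreMatrix


@dataclass
class CorrelationTable:
    """Condensed upper-triangle store of per-pair coefficients.

    ``genes`` are the retained (non-zero-variance) genes; arrays are condensed
    vectors of length G*(G-1)/2 ordered as numpy's squareform (i < j). A pair
    (g1, g2) is stored once with the lower index first.
    """

    genes: np.ndarray
    rho_p: np.ndarray
    rho_s: np.ndarray
    rho_c: np.ndarray
    rho_combined: np.ndarray = field(default=None)
    rho_thresh: float = float("nan")
    kept: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        g = len(self.genes)
        n_pairs = g * (g - 1) // 2
        for name in ("rho_p", "rho_s", "rho_c"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n_pairs:
                raise ValueError(f"{name} has wrong condensed length")

    @property
    def n_pairs(self) -> int:
        return len(self.rho_p)

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        g = len(self.genes)
        return np.triu_indices(g, k=1)

    def pair_index_of(self, g1, g2) -> int:
        g = len(self.genes)
        pos = {name: i for i, name in enumerate(self.genes)}
        i, j = sorted((pos[g1], pos[g2]))
        return g * i - i * (i + 1) // 2 + (j - i - 1)

    def lookup(self, g1, g2, which: str = "rho_combined") -> float:
        return float(getattr(self, which)[self.pair_index_of(g1, g2)])

    def to_dataframe(self, kept_only: bool = False) -> pd.DataFrame:
        ii, jj = self.pair_indices()
        df = pd.DataFrame({
            "gene1": self.genes[ii], "gene2": self.genes[jj],
            "rho_p": self.rho_p, "rho_s": self.rho_s, "rho_c": self.rho_c,
            "rho_combined": self.rho_combined,
            "kept": self.kept if self.kept is not None else False,
        })
        if kept_only:
            df = df[df["kept"]].reset_index(drop=True)
        return df

    def to_tsv(self, path, kept_only: bool = True) -> None:
        self.to_dataframe(kept_only=kept_only).to_csv(path, sep="\t",
                                                      index=False)


def correlate_zspace(Z: ZScoreMatrix, genes_mask=None) -> CorrelationTable:
    """Pearson, Spearman and Cosine coefficients between gene Z-score vectors.

    Requires at least 3 comparison columns; genes with zero variance across
    comparisons are excluded from the candidate pairs.
    """
    if Z.n_comparisons < 3:
        raise ValueError("insufficient cluster structure: need >= 3 "
                         "cluster-pair comparisons")
    M = Z.Z
    genes = Z.genes
    if genes_mask is not None:
        genes_mask = np.asarray(genes_mask)
        M = M[genes_mask]
        genes = genes[genes_mask]
    var = M.var(axis=1)
    keep = var > 0
    M = M[keep]
    genes = genes[keep]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with non-zero Z variance")

    iu = np.triu_indices(len(genes), k=1)
    rho_p = np.clip(np.corrcoef(M), -1, 1)[iu]
    ranks = rankdata(M, axis=1)
    rho_s = np.clip(np.corrcoef(ranks), -1, 1)[iu]
    norms = np.linalg.norm(M, axis=1)
    rho_c = np.clip((M @ M.T) / np.outer(norms, norms), -1, 1)[iu]
    return CorrelationTable(genes=genes, rho_p=rho_p, rho_s=rho_s, rho_c=rho_c)


def combine_worst(rho_p, rho_c):
    """Worst-of combination of Pearson and Cosine.

    Same sign: the coefficient of smaller magnitude (keeping the sign).
    Conflicting signs: 0, the conservative reading of "lowest (worst)".
    """
    rho_p = np.asarray(rho_p, dtype=float)
    rho_c = np.asarray(rho_c, dtype=float)
    same_sign = np.sign(rho_p) * np.sign(rho_c) > 0
    smaller = np.where(np.abs(rho_p) <= np.abs(rho_c), rho_p, rho_c)
    return np.where(same_sign, smaller, 0.0)


def adaptive_threshold(table: CorrelationTable,
                       fraction: float = 0.001) -> CorrelationTable:
    """Keep the top ``fraction`` of candidate pairs by |rho_combined|.

    k = ceil(fraction * P) pairs are retained; rho_thresh is the magnitude of
    the k-th largest, and boundary ties are all kept (inclusive threshold).
    """
    if table.rho_combined is None:
        table.rho_combined = combine_worst(table.rho_p, table.rho_c)
    P = table.n_pairs
    if P == 0:
        raise ValueError("no candidate pairs")
    k = min(P, math.ceil(fraction * P))
    mags = np.abs(table.rho_combined)
    kth = np.partition(mags, P - k)[P - k]
    table.rho_thresh = float(kth)
    table.kept = mags >= kth
    return table


def spearman_control(table: CorrelationTable,
                     margin: float = 0.15) -> CorrelationTable:
    """Null out kept pairs whose |rho_s| falls below |rho_thresh - margin|."""
    if table.kept is None or not np.isfinite(table.rho_thresh):
        raise ValueError("run adaptive_threshold first")
    bound = abs(table.rho_thresh - margin)
    table.kept = table.kept & (np.abs(table.rho_s) >= bound)
    return table


def correlate(Z: ZScoreMatrix, fraction: float = 0.001,
              spearman_margin: float = 0.15,
              genes_mask=None) -> CorrelationTable:
    """Full correlation stage: coefficients, combination, threshold, control."""
    table = correlate_zspace(Z, genes_mask=genes_mask)
    table.rho_combined = combine_worst(table.rho_p, table.rho_c)
    adaptive_threshold(table, fraction=fraction)
    spearman_control(table, margin=spearman_margin)
    return table
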