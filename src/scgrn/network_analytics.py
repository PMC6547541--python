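"""Node centralities, between-condition centrality changes, and correlation
inversions.

Five centralities quantify complementary kinds of biological importance on the
(unweighted, undirected) regulatory network: degree (local connectivity),
betweenness (bottleneck position on shortest paths), closeness (speed of
signal spread), PageRank with damping 0.85 ("popularity" under a damped random
walk), and eigenvector centrality (influence via influential neighbours).
Comparative analysis between two conditions ranks nodes by the absolute change
in a centrality, finds genes shifting consistently in all five measures, and
detects gene pairs whose correlation inverts sign between conditions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .correlation_engine import CorrelationTable

METRICS = ["degree", "betweenness", "closeness", "pagerank", "eigenvector"]


def centralities(net, damping: float = 0.85,
                 use_weights: bool = False) -> pd.DataFrame:
    """Five per-node centralities on the unweighted undirected graph.

    Betweenness and closeness are normalised to [0, 1] (closeness per
    component: (n_c - 1) / sum of distances). PageRank is computed on the full
    graph and sums to 1; eigenvector centrality is computed on the largest
    component, zero elsewhere. ``use_weights`` switches shortest-path metrics
    to |weight| distances (off by default; the inferred edge weights are
    signed correlations, which have no shortest-path interpretation).
    """
    g = net.graph if hasattr(net, "graph") else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    wkey = None
    if use_weights:
        g = g.copy()
        for u, v, d in g.edges(data=True):
            d["absweight"] = abs(d.get("weight", 1.0))
        wkey = "absweight"
    deg = dict(g.degree)
    btw = nx.betweenness_centrality(g, normalized=True, weight=wkey)
    clo = nx.closeness_centrality(g, wf_improved=False, distance=wkey)
    pr = nx.pagerank(g, alpha=damping, weight=wkey, tol=1e-12, max_iter=500)
    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    ev = {n: 0.0 for n in g.nodes}
    if len(largest) > 1:
        sub = g.subgraph(largest)
        ev.update(nx.eigenvector_centrality_numpy(sub, weight=wkey))
    else:
        ev[next(iter(largest))] = 1.0
    nodes = list(g.nodes)
    return pd.DataFrame({
        "degree": [float(deg[n]) for n in nodes],
        "betweenness": [btw[n] for n in nodes],
        "closeness": [clo[n] for n in nodes],
        "pagerank": [pr[n] for n in nodes],
        "eigenvector": [abs(ev[n]) for n in nodes],
    }, index=pd.Index(nodes, name="node"))


def delta_centrality(tab_a: pd.Series | pd.DataFrame,
                     tab_b: pd.Series | pd.DataFrame,
                     metric: str | None = None, top_n: int = 1000,
                     de_pvalues: pd.Series | None = None) -> pd.DataFrame:
    """Rank nodes by the absolute change in one centrality between networks.

    Nodes present in only one network get centrality 0 in the other and are
    flagged via ``in_both``. DE p-values, when supplied, are joined so
    centrality changes can be cross-read against expression changes.
    """
    a = tab_a[metric] if isinstance(tab_a, pd.DataFrame) else tab_a
    b = tab_b[metric] if isinstance(tab_b, pd.DataFrame) else tab_b
    nodes = a.index.union(b.index)
    if a.index.intersection(b.index).empty:
        raise ValueError("the two networks share no nodes")
    c_a = a.reindex(nodes).fillna(0.0)
    c_b = b.reindex(nodes).fillna(0.0)
    out = pd.DataFrame({
        "c_a": c_a, "c_b": c_b, "delta": c_b - c_a,
        "in_both": nodes.isin(a.index) & nodes.isin(b.index),
    })
    if de_pvalues is not None:
        out["de_p"] = de_pvalues.reindex(nodes)
    out = out.loc[out["delta"].abs().sort_values(ascending=False).index]
    return out.head(top_n)


def consensus_shift(tab_a: pd.DataFrame, tab_b: pd.DataFrame,
                    metrics=METRICS) -> dict:
    """Genes whose deltas are non-zero and sign-consistent in ALL metrics.

    Returns {"increased": set, "decreased": set}. A zero delta in any metric
    excludes the gene (strict rule).
    """
    nodes = tab_a.index.union(tab_b.index)
    deltas = pd.DataFrame(index=nodes)
    for m in metrics:
        deltas[m] = (tab_b[m].reindex(nodes).fillna(0.0)
                     - tab_a[m].reindex(nodes).fillna(0.0))
    up = deltas.gt(0).all(axis=1)
    down = deltas.lt(0).all(axis=1)
    return {"increased": set(deltas.index[up]),
            "decreased": set(deltas.index[down])}


def find_inversions(corr_a: CorrelationTable, corr_b: CorrelationTable,
                    strong: float = 1.0) -> pd.DataFrame:
    """Gene pairs whose combined correlation flips sign between conditions.

    Candidate pairs are the union of the kept sets; coefficients are looked up
    in both tables (pairs evaluable in only one are skipped). ``strength`` is
    rho_a - rho_b; an inversion is "strong" when it is a sign flip and
    |strength| exceeds ``strong`` (default 1). Sorted by |strength|.
    """
    genes_a = {g: i for i, g in enumerate(corr_a.genes)}
    genes_b = {g: i for i, g in enumerate(corr_b.genes)}

    def kept_pairs(tab):
        ii, jj = tab.pair_indices()
        sel = np.flatnonzero(tab.kept) if tab.kept is not None else []
        return {(tab.genes[ii[k]], tab.genes[jj[k]]) for k in sel}

    def canon(p):
        return tuple(sorted(p))

    union = {canon(p) for p in kept_pairs(corr_a)} | \
            {canon(p) for p in kept_pairs(corr_b)}
    rows = []
    for g1, g2 in sorted(union):
        if g1 not in genes_a or g2 not in genes_a:
            continue
        if g1 not in genes_b or g2 not in genes_b:
            continue
        ra = corr_a.lookup(g1, g2)
        rb = corr_b.lookup(g1, g2)
        flip = bool(np.sign(ra) * np.sign(rb) < 0)
        strength = ra - rb
        rows.append((g1, g2, ra, rb, strength, flip,
                     flip and abs(strength) > strong))
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "rho_a", "rho_b",
                                     "strength", "is_sign_flip", "strong"])
    return df.sort_values("strength", key=np.abs,
                          ascending=False).reset_index(drop=True)
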