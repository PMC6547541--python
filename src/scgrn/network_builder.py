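"""Regulatory network construction: GO sub-setting, pruning, global statistics.

Kept correlations become the signed, weighted edges of an undirected network.
Edges where neither endpoint is annotated as a "regulator of gene expression"
are discarded (GO sub-setting), so every surviving edge represents a putative
regulatory link. The graph is then cleaned to a fixpoint by removing isolated
nodes and small disconnected components (< 1% of the current node count).
Summary statistics mirror the usual network overview table: density
(edges/nodes), % negative edges, % regulator nodes, connected components,
average shortest path, modularity, and a power-law goodness-of-fit p for the
degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlation_engine import CorrelationTable
from .data_model import RegulatorAnnotation
from .powerlaw_fit import power_law_ks_p


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    pct_negative_edges: float
    pct_regulators: float
    density: float
    n_components: int
    avg_shortest_path: float
    modularity: float
    powerlaw_ks_p: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RegulatoryNetwork:
    """Undirected signed-weighted graph with regulator flags."""

    graph: nx.Graph
    rho_thresh: float = float("nan")
    pruning_log: list = field(default_factory=list)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def regulator_nodes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("regulator", False)}

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tweight\n")
            for u, v, d in self.graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_edge_tsv(cls, path,
                      regulators: RegulatorAnnotation | None = None
                      ) -> "RegulatoryNetwork":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            del header
            for line in fh:
                u, v, w = line.rstrip("\n").split("\t")
                g.add_edge(u, v, weight=float(w))
        if regulators is not None:
            for n in g.nodes:
                g.nodes[n]["regulator"] = n in regulators
        return cls(graph=g)


def edges_from_correlations(table: CorrelationTable) -> nx.Graph:
    """Kept pairs -> undirected graph weighted by the combined coefficient."""
    if table.kept is None:
        raise ValueError("correlation table has no kept flags; threshold first")
    g = nx.Graph()
    ii, jj = table.pair_indices()
    sel = np.flatnonzero(table.kept)
    for k in sel:
        g.add_edge(table.genes[ii[k]], table.genes[jj[k]],
                   weight=float(table.rho_combined[k]))
    return g


def go_subset(graph: nx.Graph, regulators: RegulatorAnnotation) -> nx.Graph:
    """Drop edges where neither endpoint is a regulator of gene expression."""
    if len(regulators) == 0:
        raise ValueError("empty regulator set would delete the whole network")
    out = graph.copy()
    to_drop = [(u, v) for u, v in out.edges
               if u not in regulators and v not in regulators]
    out.remove_edges_from(to_drop)
    for n in out.nodes:
        out.nodes[n]["regulator"] = n in regulators
    return out


def prune(graph: nx.Graph, min_component_frac: float = 0.01,
          rho_thresh: float = float("nan")) -> RegulatoryNetwork:
    """Iteratively remove isolated nodes and tiny components, to a fixpoint.

    At each pass, zero-degree nodes are dropped, then connected components
    smaller than ``min_component_frac`` of the *current* node count. The
    removal order is logged.
    """
    g = graph.copy()
    log = []
    while True:
        isolated = [n for n, d in g.degree if d == 0]
        if isolated:
            g.remove_nodes_from(isolated)
            log.append(("isolated_nodes", len(isolated)))
        n_now = g.number_of_nodes()
        if n_now == 0:
            break
        comps = list(nx.connected_components(g))
        if len(comps) > 1:
            cutoff = min_component_frac * n_now
            small = [c for c in comps if len(c) < cutoff]
        else:
            small = []
        if not isolated and not small:
            break
        if small:
            dropped = set().union(*small)
            g.remove_nodes_from(dropped)
            log.append(("small_components", len(small), len(dropped)))
        if not small and isolated:
            continue
    if g.number_of_nodes() == 0:
        raise ValueError("network vanished during pruning; inspect thresholds")
    return RegulatoryNetwork(graph=g, rho_thresh=rho_thresh, pruning_log=log)


def build_network(table: CorrelationTable,
                  regulators: RegulatorAnnotation) -> RegulatoryNetwork:
    """Correlation table -> GO-subset, pruned regulatory network."""
    g = edges_from_correlations(table)
    g = go_subset(g, regulators)
    return prune(g, rho_thresh=table.rho_thresh)


def network_stats(net: RegulatoryNetwork, powerlaw_bootstrap: int = 200,
                  seed: int = 0, with_powerlaw: bool = False,
                  with_modularity: bool = True,
                  with_paths: bool = True) -> NetworkStats:
    """Global statistics of a pruned network.

    Modularity uses greedy modularity maximisation (deterministic); the
    average shortest path is computed unweighted on the largest component.
    The power-law KS p-value is optional because it is the one expensive
    statistic (bootstrapped refits).
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
    pct_neg = 100.0 * sum(w < 0 for w in weights) / e if e else 0.0
    regs = net.regulator_nodes()
    pct_reg = 100.0 * len(regs) / n
    comps = list(nx.connected_components(g))
    avg_sp = float("nan")
    if with_paths:
        largest = g.subgraph(max(comps, key=len))
        avg_sp = (nx.average_shortest_path_length(largest)
                  if largest.number_of_nodes() > 1 else 0.0)
    modularity = float("nan")
    if with_modularity:
        communities = nx.algorithms.community.greedy_modularity_communities(g)
        modularity = nx.algorithms.community.modularity(g, communities)
    pl_p = float("nan")
    if with_powerlaw:
        degs = [d for _, d in g.degree]
        pl_p = power_law_ks_p(degs, n_bootstrap=powerlaw_bootstrap,
                              seed=seed).p_value
    return NetworkStats(
        n_nodes=n, n_edges=e, pct_negative_edges=pct_neg,
        pct_regulators=pct_reg, density=e / n, n_components=len(comps),
        avg_shortest_path=avg_sp, modularity=modularity, powerlaw_ks_p=pl_p,
    )
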