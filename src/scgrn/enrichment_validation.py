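"""External-evidence statistics for inferred networks.

Three validation layers: (1) per-edge co-occurrence of neighbouring genes in
experimental perturbation signatures (one-sided Fisher exact test on a 2x2
signature-membership table, plus a fold-enrichment ratio), (2) essentiality of
network hubs against an experimentally curated catalogue (log2 odds-ratio
"essentiality score" with a resampling p-value and BH correction across hub
sets), and (3) organ specificity of central genes (top-20% exclusivity per
centrality, and an expression multiplicity based on a modified Z across
organs). A generic hypergeometric gene-set enrichment with Bonferroni
correction rounds out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import EssentialityTable, GeneSetCollection


# ---------------------------------------------------------------------------
# per-edge co-occurrence in signatures


def cooccurrence_p(a: int, S: int, n1: int, n2: int) -> float:
    """One-sided (greater) Fisher p for a 2x2 co-occurrence table.

    Equals the hypergeometric upper tail P(X >= a) with X ~ HG(S, n1, n2).
    """
    return float(hypergeom.sf(a - 1, S, n1, n2))


def edge_cooccurrence(net, sets: GeneSetCollection) -> pd.DataFrame:
    """Fisher co-occurrence test for every edge against a signature collection.

    For an edge (g1, g2) and S evaluable signatures: a = signatures containing
    both genes, b = only g1, c = only g2, d = neither. The one-sided (greater)
    Fisher p equals the hypergeometric upper tail P(X >= a); fold enrichment
    is observed over expected co-occurrence, a*S / ((a+b)*(a+c)). Edges whose
    genes are absent from the collection universe are skipped (counted in the
    returned frame's attrs).
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    g = net.graph if hasattr(net, "graph") else net
    names = list(sets.sets)
    members = [sets.sets[n] for n in names]
    S = len(names)
    universe = sets.universe
    rows, skipped = [], 0
    membership_cache: dict = {}

    def vec(gene):
        if gene not in membership_cache:
            membership_cache[gene] = np.fromiter(
                (gene in m for m in members), dtype=bool, count=S)
        return membership_cache[gene]

    for g1, g2 in g.edges:
        if g1 not in universe or g2 not in universe:
            skipped += 1
            continue
        v1, v2 = vec(g1), vec(g2)
        a = int((v1 & v2).sum())
        n1, n2 = int(v1.sum()), int(v2.sum())
        b, c = n1 - a, n2 - a
        d = S - a - b - c
        fold = a * S / (n1 * n2) if n1 > 0 and n2 > 0 else np.nan
        p = cooccurrence_p(a, S, n1, n2)
        rows.append((g1, g2, a, b, c, d, fold, p))
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "a", "b", "c", "d",
                                     "fold", "p"])
    df.attrs["skipped_edges"] = skipped
    df.attrs["n_signatures"] = S
    return df


def cooccurrence_summary(edge_df: pd.DataFrame, alpha: float = 0.05,
                         occurrence_grid=None) -> dict:
    """Per-network validation summary.

    Returns the fraction of validated edges (p < alpha), the fold
    distribution, and the validated-fraction curve as a function of the
    minimum number of signature occurrences of the less-annotated gene of the
    edge.
    """
    validated = edge_df["p"] < alpha
    occ = np.minimum(edge_df["a"] + edge_df["b"], edge_df["a"] + edge_df["c"])
    if occurrence_grid is None:
        top = int(occ.max()) if len(occ) else 0
        occurrence_grid = np.unique(np.linspace(0, top, 10).astype(int))
    curve = []
    for m in occurrence_grid:
        sel = occ >= m
        frac = float(validated[sel].mean()) if sel.any() else np.nan
        curve.append((int(m), frac, int(sel.sum())))
    return {
        "fraction_validated": float(validated.mean()) if len(edge_df) else np.nan,
        "fold_median": float(np.nanmedian(edge_df["fold"])) if len(edge_df) else np.nan,
        "curve": curve,
    }


# ---------------------------------------------------------------------------
# hub essentiality


@dataclass
class EssentialityResult:
    name: str
    e_hubs: int
    ne_hubs: int
    e_background: int
    ne_background: int
    es: float
    es_haldane: float
    p_empirical: float
    p_adjusted: float = float("nan")
    n_hubs_scored: int = 0


def _es(e_h, ne_h, e_b, ne_b) -> float:
    e_h, ne_h, e_b, ne_b = (np.float64(v) for v in (e_h, ne_h, e_b, ne_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (e_h / ne_h) / (e_b / ne_b)
        return float(np.log2(ratio))


def essentiality_score(hub_sets: dict, ess: EssentialityTable,
                       n_perm: int = 10_000, seed: int = 0) -> list:
    """Essentiality score and permutation p-value for each hub set.

    ES = log2((E_hubs/NE_hubs) / (E_background/NE_background)). The empirical
    p is one-tailed with add-one smoothing over ``n_perm`` random draws of
    equally sized gene sets from the catalogue (realised as hypergeometric
    draws of the essential count, which is equivalent to resampling gene
    identities). p-values are BH-adjusted across the supplied hub sets.
    """
    e_b, ne_b = ess.counts()
    if e_b == 0 or ne_b == 0:
        raise ValueError("background must contain both classes")
    gene_to_ess = dict(zip(ess.genes, ess.essential))
    m_total = e_b + ne_b
    rng = np.random.default_rng(seed)
    results = []
    for name, hubs in hub_sets.items():
        scored = [g for g in hubs if g in gene_to_ess]
        n = len(scored)
        if n == 0:
            raise ValueError(f"hub set {name!r} shares no genes with the "
                             "essentiality table")
        e_h = int(sum(gene_to_ess[g] for g in scored))
        ne_h = n - e_h
        es = _es(e_h, ne_h, e_b, ne_b)
        es_hald = _es(e_h + 0.5, ne_h + 0.5, e_b + 0.5, ne_b + 0.5)
        e_rand = rng.hypergeometric(e_b, ne_b, n, size=n_perm)
        with np.errstate(divide="ignore", invalid="ignore"):
            es_rand = np.log2((e_rand / (n - e_rand)) / (e_b / ne_b))
        obs = es if np.isfinite(es) else es_hald
        comp = np.where(np.isfinite(es_rand), es_rand,
                        np.where(e_rand == n, np.inf, -np.inf))
        p = (float((comp >= obs).sum()) + 1.0) / (n_perm + 1.0)
        results.append(EssentialityResult(
            name=name, e_hubs=e_h, ne_hubs=ne_h, e_background=e_b,
            ne_background=ne_b, es=es, es_haldane=es_hald, p_empirical=p,
            n_hubs_scored=n))
    _, adj, _, _ = multipletests([r.p_empirical for r in results],
                                 method="fdr_bh")
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def centrality_sweep_es(centrality: pd.Series, ess: EssentialityTable,
                        k_grid=None, n_perm: int = 2000,
                        seed: int = 0) -> pd.DataFrame:
    """ES curve over cumulative top-k hub sets ranked by a centrality."""
    ranked = centrality.sort_values(ascending=False).index.to_list()
    if k_grid is None:
        k_grid = np.unique(np.linspace(10, len(ranked), 10).astype(int))
    hub_sets = {f"top_{k}": ranked[:k] for k in k_grid}
    res = essentiality_score(hub_sets, ess, n_perm=n_perm, seed=seed)
    return pd.DataFrame([{
        "k": int(r.name.split("_")[1]), "es": r.es, "es_haldane": r.es_haldane,
        "p": r.p_empirical, "p_adj": r.p_adjusted,
    } for r in res])


# ---------------------------------------------------------------------------
# organ specificity


def specificity(centrality_tables: dict, organ_means: pd.DataFrame,
                metric: str = "pagerank", top_frac: float = 0.2,
                z_cut: float = 2.0) -> pd.DataFrame:
    """Organ specificity of central genes.

    ``centrality_tables`` maps organ -> centrality DataFrame; a gene is
    central in an organ when it ranks in the top ``top_frac`` of the chosen
    metric there, exclusive when central in exactly one organ. The expression
    modified Z per organ is (organ mean - median across organs) / IQR across
    organs (type-7 quartiles); genes with IQR = 0 get z = 0 and are flagged.
    Expression multiplicity counts organs with z > ``z_cut``.
    """
    organs = list(centrality_tables)
    if len(organs) < 2:
        raise ValueError("need >= 2 organs")
    central_in: dict = {}
    for organ in organs:
        tab = centrality_tables[organ]
        col = tab[metric]
        k = max(1, int(np.ceil(top_frac * len(col))))
        top = set(col.sort_values(ascending=False).head(k).index)
        for gene in top:
            central_in.setdefault(gene, []).append(organ)

    med = organ_means.median(axis=1)
    q75 = organ_means.quantile(0.75, axis=1, interpolation="linear")
    q25 = organ_means.quantile(0.25, axis=1, interpolation="linear")
    iqr = q75 - q25
    with np.errstate(divide="ignore", invalid="ignore"):
        z = organ_means.sub(med, axis=0).div(iqr, axis=0)
    iqr_zero = iqr == 0
    z[iqr_zero] = 0.0
    expr_mult = (z > z_cut).sum(axis=1)

    genes = sorted(set(central_in) | set(organ_means.index))
    rows = []
    for gene in genes:
        orgs = central_in.get(gene, [])
        rows.append({
            "gene": gene,
            "central_in": ",".join(sorted(orgs)),
            "centrality_multiplicity": len(orgs),
            "exclusive": len(orgs) == 1,
            "expression_multiplicity": int(expr_mult.get(gene, 0)),
            "iqr_zero": bool(iqr_zero.get(gene, False)),
        })
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# generic hypergeometric enrichment


def hypergeom_enrichment(query_genes, sets: GeneSetCollection,
                         universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per set, Bonferroni-adjusted."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        K = len(members & universe)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, K, k, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df.sort_values("p").reset_index(drop=True)
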