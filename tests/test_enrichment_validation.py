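import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import hypergeom_upper_tail
from scgrn.data_model import EssentialityTable, GeneSetCollection
from scgrn.enrichment_validation import (cooccurrence_p, edge_cooccurrence,
                                         essentiality_score,
                                         hypergeom_enrichment, specificity)
from scgrn.network_builder import RegulatoryNetwork


def collection_from_membership(v1, v2):
    """Signatures realising given membership vectors for genes A and B."""
    sets = {}
    for i, (a, b) in enumerate(zip(v1, v2)):
        members = {"PAD"}  # keeps empty signatures representable
        if a:
            members.add("A")
        if b:
            members.add("B")
        sets[f"sig{i}"] = members
    return GeneSetCollection(sets)


def edge_net():
    return RegulatoryNetwork(graph=nx.Graph([("A", "B")]))


class TestEdgeCooccurrence:
    def test_independence_gives_fold_one(self):
        # S=100, A in 50, B in 50, both in 25
        v1 = [1] * 50 + [0] * 50
        v2 = [1] * 25 + [0] * 25 + [1] * 25 + [0] * 25
        df = edge_cooccurrence(edge_net(), collection_from_membership(v1, v2))
        row = df.iloc[0]
        assert row["a"] == 25
        assert row["fold"] == pytest.approx(1.0)

    def test_full_overlap_fold_two_and_exact_tail(self):
        v = [1] * 50 + [0] * 50
        df = edge_cooccurrence(edge_net(), collection_from_membership(v, v))
        row = df.iloc[0]
        assert row["fold"] == pytest.approx(2.0)
        assert row["p"] == pytest.approx(hypergeom_upper_tail(50, 100, 50, 50),
                                         rel=1e-10)

    def test_zero_overlap_with_positive_margins(self):
        v1 = [1] * 30 + [0] * 70
        v2 = [0] * 30 + [1] * 30 + [0] * 40
        df = edge_cooccurrence(edge_net(), collection_from_membership(v1, v2))
        row = df.iloc[0]
        assert row["fold"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_gene_outside_universe_skipped(self):
        net = RegulatoryNetwork(graph=nx.Graph([("A", "ZZZ")]))
        coll = collection_from_membership([1, 0], [0, 1])
        df = edge_cooccurrence(net, coll)
        assert len(df) == 0
        assert df.attrs["skipped_edges"] == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            edge_cooccurrence(edge_net(), GeneSetCollection({}))

    def test_p_equals_combinatorial_tail(self, rng):
        """Sweep: exhaustive margins at S <= 20 plus random tables S <= 200."""
        for S in (5, 12, 20):
            for n1 in range(0, S + 1, 4):
                for n2 in range(0, S + 1, 5):
                    for a in range(max(0, n1 + n2 - S), min(n1, n2) + 1, 3):
                        want = hypergeom_upper_tail(a, S, n1, n2)
                        assert cooccurrence_p(a, S, n1, n2) == pytest.approx(
                            want, rel=1e-9, abs=1e-12)
        for _ in range(200):
            S = int(rng.integers(2, 201))
            n1 = int(rng.integers(0, S + 1))
            n2 = int(rng.integers(0, S + 1))
            a = int(rng.integers(max(0, n1 + n2 - S), min(n1, n2) + 1))
            want = hypergeom_upper_tail(a, S, n1, n2)
            assert cooccurrence_p(a, S, n1, n2) == pytest.approx(
                want, rel=1e-9, abs=1e-12)


def make_ess(e_bg, ne_bg, seed=0):
    genes = [f"E{i}" for i in range(e_bg)] + [f"N{i}" for i in range(ne_bg)]
    ess = [True] * e_bg + [False] * ne_bg
    return EssentialityTable(pd.DataFrame({"gene": genes, "essential": ess}))


class TestEssentialityScore:
    def test_equal_fractions_es_zero(self):
        ess = make_ess(40, 80)
        hubs = [f"E{i}" for i in range(10)] + [f"N{i}" for i in range(20)]
        res = essentiality_score({"h": hubs}, ess, n_perm=100, seed=0)[0]
        assert res.es == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # E_hubs=30, NE_hubs=10, E_bg=3000, NE_bg=6000 -> log2 6
        ess = make_ess(3000, 6000)
        hubs = [f"E{i}" for i in range(30)] + [f"N{i}" for i in range(10)]
        res = essentiality_score({"h": hubs}, ess, n_perm=200, seed=1)[0]
        assert res.es == pytest.approx(math.log2(6.0))

    def test_whole_background_degenerate(self):
        ess = make_ess(30, 60)
        res = essentiality_score({"all": list(ess.genes)}, ess,
                                 n_perm=500, seed=2)[0]
        assert res.es == pytest.approx(0.0)
        assert res.p_empirical > 0.99

    def test_p_in_valid_range_and_bh_not_below_raw(self):
        ess = make_ess(50, 100, seed=3)
        sets = {"a": [f"E{i}" for i in range(20)],
                "b": [f"N{i}" for i in range(20)]}
        res = essentiality_score(sets, ess, n_perm=1000, seed=3)
        for r in res:
            assert 1 / 1001 <= r.p_empirical <= 1.0
            assert r.p_adjusted >= r.p_empirical - 1e-12

    def test_permutation_p_converges(self):
        ess = make_ess(60, 120)
        hubs = [f"E{i}" for i in range(25)] + [f"N{i}" for i in range(15)]
        p1 = essentiality_score({"h": hubs}, ess, n_perm=2000,
                                seed=5)[0].p_empirical
        p2 = essentiality_score({"h": hubs}, ess, n_perm=4000,
                                seed=6)[0].p_empirical
        se = math.sqrt(p1 * (1 - p1) / 2000 + p2 * (1 - p2) / 4000)
        assert abs(p1 - p2) < 3 * max(se, 1e-4)

    def test_disjoint_hubs_rejected(self):
        ess = make_ess(5, 5)
        with pytest.raises(ValueError, match="no genes"):
            essentiality_score({"h": ["missing"]}, ess, n_perm=10)


class TestSpecificity:
    def make_inputs(self):
        organs = ["brain", "heart"]
        genes = [f"g{i}" for i in range(10)]
        tabs = {}
        rng = np.random.default_rng(1)
        for k, organ in enumerate(organs):
            vals = rng.random(10)
            vals[0] = 10.0 if organ == "brain" else 0.0  # g0 brain-exclusive
            tabs[organ] = pd.DataFrame({"pagerank": vals}, index=genes)
        means = pd.DataFrame(1.0, index=genes,
                             columns=["o1", "o2", "o3", "o4", "o5"])
        return tabs, means

    def test_exclusive_hub(self):
        tabs, means = self.make_inputs()
        out = specificity(tabs, means, metric="pagerank")
        assert out.loc["g0", "centrality_multiplicity"] == 1
        assert bool(out.loc["g0", "exclusive"])

    def test_identical_expression_zero_multiplicity(self):
        tabs, means = self.make_inputs()
        out = specificity(tabs, means)
        assert (out["expression_multiplicity"] == 0).all()
        assert out["iqr_zero"].all()

    def test_modified_z_with_defined_iqr(self):
        tabs, means = self.make_inputs()
        # organ means [10, 1, 2, 1, 3]: median 2, IQR (type-7) = 3 - 1 = 2
        means.loc["g0"] = [10.0, 1.0, 2.0, 1.0, 3.0]
        out = specificity(tabs, means)
        # z in organ o1 = (10 - 2) / 2 = 4 > 2; all other organs below 2
        assert out.loc["g0", "expression_multiplicity"] == 1
        assert not bool(out.loc["g0", "iqr_zero"])

    def test_organ_label_equivariance(self):
        tabs, means = self.make_inputs()
        out1 = specificity(tabs, means)
        renamed = {"x_" + k: v for k, v in tabs.items()}
        out2 = specificity(renamed, means)
        for g in out1.index:
            got = {o[2:] for o in out2.loc[g, "central_in"].split(",") if o}
            want = {o for o in out1.loc[g, "central_in"].split(",") if o}
            assert got == want

    def test_needs_two_organs(self):
        tabs, means = self.make_inputs()
        with pytest.raises(ValueError, match=">= 2 organs"):
            specificity({"brain": tabs["brain"]}, means)


class TestHypergeomEnrichment:
    def test_exact_set_minimal_p(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection({"hit": {f"g{i}" for i in range(5)},
                                  "other": {f"g{i}" for i in range(10, 14)}})
        df = hypergeom_enrichment([f"g{i}" for i in range(5)], sets, universe)
        assert df.iloc[0]["set"] == "hit"

    def test_disjoint_query_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection({"s": {"g0", "g1"}})
        df = hypergeom_enrichment(["g10", "g11"], sets, universe)
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_toy_combinatorial_value(self):
        # universe 20, set 10, query 5, overlap 5 -> C(10,5)/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection({"s": {f"g{i}" for i in range(10)}})
        df = hypergeom_enrichment([f"g{i}" for i in range(5)], sets, universe)
        want = math.comb(10, 5) / math.comb(20, 5)
        assert df.iloc[0]["p"] == pytest.approx(want, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeom_enrichment([], GeneSetCollection({"s": {"a"}}), set())
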