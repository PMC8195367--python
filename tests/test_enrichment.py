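"""Hypergeometric, edge-density, family and network statistics."""

import itertools
from math import comb

import networkx as nx
import numpy as np
import pytest

from tscca.enrichment import (degree_aware_edge_test, edge_enrichment,
                              extract_three_layer_network, family_cooperativity,
                              hypergeometric_enrichment)
from tscca.errors import ValidationError


class TestHypergeometric:
    def test_exact_enumeration_value(self):
        """(N=10, K=4, n=5, x=3): right tail = 66/252 by counting draws."""
        res = hypergeometric_enrichment(
            {f"i{k}" for k in range(5)},
            {f"i{k}" for k in [0, 1, 2, 7]},  # 3 annotated among drawn
            {f"i{k}" for k in range(10)},
        )
        assert res.overlap == 3
        # enumeration oracle over all C(10,5) draws
        pop = list(range(10))
        ann = set([0, 1, 2, 7])
        hits = sum(1 for S in itertools.combinations(pop, 5)
                   if len(ann & set(S)) >= 3)
        assert hits / comb(10, 5) == pytest.approx(66 / 252)
        assert res.p_value == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_right_tail_is_one(self):
        res = hypergeometric_enrichment({"a"}, {"b"}, {"a", "b", "c"})
        assert res.overlap == 0 and res.p_value == pytest.approx(1.0)

    def test_annotation_equals_background(self):
        bg = {f"x{i}" for i in range(8)}
        res = hypergeometric_enrichment(set(list(bg)[:3]), bg, bg)
        assert res.p_value == pytest.approx(1.0)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_member_outside_background_errors(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"zzz"}, {"a"}, {"a", "b"})

    def test_monotone_in_overlap(self):
        bg = {f"x{i}" for i in range(20)}
        ann = {f"x{i}" for i in range(8)}
        ps = []
        for k in range(6):
            members = {f"x{i}" for i in range(k)} | {f"x{i}" for i in range(10, 15 - k + 10 - 5 + 5)}
            members = set(itertools.islice(sorted(ann), k)) | \
                set(itertools.islice(sorted(bg - ann), 5 - k))
            ps.append(hypergeometric_enrichment(members, ann, bg).p_value)
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestEdgeEnrichment:
    def test_complete_subgraph_fold(self):
        bg = [f"n{i}" for i in range(4)]
        # background density 0.5: 3 of 6 possible edges; node set {n0,n1,n2}
        # spans all C(3,2)=3 pairs as edges -> density 1.0, fold 2
        edges = {frozenset(("n0", "n1")), frozenset(("n0", "n2")),
                 frozenset(("n1", "n2"))}
        res = edge_enrichment({"n0", "n1", "n2"}, edges, bg)
        assert res.fold_enrichment == pytest.approx(2.0)

    def test_no_edges_p_one(self):
        bg = [f"n{i}" for i in range(5)]
        edges = {frozenset(("n3", "n4"))}
        res = edge_enrichment({"n0", "n1"}, edges, bg)
        assert res.overlap == 0 and res.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_set_enumeration(self, rng):
        """p equals the exact tail over all C(12,5) node sets."""
        bg = [f"n{i}" for i in range(12)]
        G = nx.gnm_random_graph(12, 18, seed=4)
        edges = {frozenset((f"n{a}", f"n{b}")) for a, b in G.edges}
        nodes = {f"n{i}" for i in [0, 2, 5, 7, 9]}

        def count(S):
            return sum(1 for e in edges if set(e) <= set(S))

        observed = count(nodes)
        tail = sum(1 for S in itertools.combinations(bg, 5)
                   if count(S) >= observed)
        exact = tail / comb(12, 5)
        res = edge_enrichment(nodes, edges, bg)
        # hypergeometric on edge counts is the model, enumeration the
        # truth; they agree closely on homogeneous backgrounds
        assert res.overlap == observed
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_mirna_gene_mode_counts_ordered_pairs(self):
        mirnas, genes = {"m1", "m2"}, {"g1", "g2", "g3"}
        edges = {("m1", "g1"), ("m1", "g2"), ("m2", "g9")}
        res = edge_enrichment(
            (mirnas, genes), edges, {"g1", "g2", "g3", "g9"},
            mode="mirna_gene", mirna_background={"m1", "m2", "m3"})
        assert res.overlap == 2
        assert res.set_size == 6
        assert res.background_size == 12


class TestDegreeAwareEdgeTest:
    def test_regular_graph_matches_plain_permutation(self):
        """On a cycle all degrees are 2, so the binning is vacuous."""
        n = 30
        bg = [f"n{i}" for i in range(n)]
        edges = {frozenset((f"n{i}", f"n{(i + 1) % n}")) for i in range(n)}
        nodes = {f"n{i}" for i in range(6)}  # a path: 5 internal edges
        res = degree_aware_edge_test(nodes, edges, bg, n_perm=600, seed=0)
        # plain uniform-resampling null oracle
        rng = np.random.default_rng(1)
        null = []
        for _ in range(600):
            S = {bg[i] for i in rng.choice(n, size=6, replace=False)}
            null.append(sum(1 for e in edges if set(e) <= S))
        plain_p = (1 + sum(x >= res.observed for x in null)) / 601
        assert res.p_value == pytest.approx(plain_p, abs=0.05)

    def test_hub_module_discounted(self):
        """A hubs-only module looks enriched naively but not degree-aware.

        Background: several star centres wired to leaves; the module is
        the centres plus edges among them.  The naive hypergeometric
        sees far more edges than the average node set; the degree-aware
        null resamples among hubs and finds the count unremarkable.
        """
        G = nx.Graph()
        hubs = [f"h{i}" for i in range(5)]
        for i, h in enumerate(hubs):
            for j in range(12):
                G.add_edge(h, f"leaf{i}_{j}")
        for a, b in itertools.combinations(hubs, 2):
            G.add_edge(a, b)
        bg = list(G.nodes)
        edges = {frozenset(e) for e in G.edges}
        naive = edge_enrichment(set(hubs), edges, bg)
        aware = degree_aware_edge_test(set(hubs), edges, bg, n_perm=400, seed=7)
        assert aware.p_value > naive.p_value * 10

    def test_seed_reproducibility(self):
        bg = [f"n{i}" for i in range(20)]
        G = nx.gnm_random_graph(20, 40, seed=2)
        edges = {frozenset((f"n{a}", f"n{b}")) for a, b in G.edges}
        nodes = {f"n{i}" for i in range(5)}
        r1 = degree_aware_edge_test(nodes, edges, bg, n_perm=100, seed=11)
        r2 = degree_aware_edge_test(nodes, edges, bg, n_perm=100, seed=11)
        assert r1.p_value == r2.p_value and r1.null_mean == r2.null_mean


class TestFamilyCooperativity:
    def test_whole_family_module_hits_floor_p(self):
        fams = {"famA": {f"m{i}" for i in range(5)}}
        universe = {f"m{i}" for i in range(523)}
        res = family_cooperativity({f"m{i}" for i in range(5)}, fams, universe,
                                   n_perm=1000, seed=0)
        assert res.max_shared_family == 5
        assert res.p_value == pytest.approx(1 / 1001)

    def test_singleton_families(self):
        fams = {f"f{i}": {f"m{i}"} for i in range(10)}
        res = family_cooperativity({"m0", "m1"}, fams,
                                   {f"m{i}" for i in range(10)},
                                   n_perm=50, seed=0)
        assert res.max_shared_family == 1
        assert not res.has_cooperative_pair

    def test_universe_smaller_than_module_errors(self):
        with pytest.raises(ValidationError):
            family_cooperativity({"a", "b"}, {}, {"a"}, n_perm=10, seed=0)

    def test_seed_determinism(self):
        fams = {"f": {"m1", "m2", "m3"}}
        uni = {f"m{i}" for i in range(30)}
        r1 = family_cooperativity({"m1", "m2", "m9"}, fams, uni, 200, seed=5)
        r2 = family_cooperativity({"m1", "m2", "m9"}, fams, uni, 200, seed=5)
        assert r1.p_value == r2.p_value


class TestThreeLayerNetwork:
    def test_layers_and_isolated_node(self):
        net = extract_three_layer_network(
            {"g1", "g2", "g3"}, {"m1"},
            {("m1", "g1")}, {frozenset(("g1", "g2"))})
        assert net.mirnas == {"m1"}
        assert net.direct_genes == {"g1"}
        assert net.indirect_genes == {"g2"}
        assert len(net.edges) == 2

    def test_tie_broken_by_smallest_node(self):
        # two 2-node components; the one containing the lexicographically
        # smallest node wins
        net = extract_three_layer_network(
            {"ga", "gb", "gc", "gd"}, set(), set(),
            {frozenset(("gc", "gd")), frozenset(("ga", "gb"))})
        assert net.direct_genes == set()
        assert net.indirect_genes == {"ga", "gb"}

    def test_component_matches_bfs_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        mirnas = [f"m{i}" for i in range(5)]
        mg = {(mirnas[rng.integers(5)], genes[rng.integers(30)])
              for _ in range(12)}
        gg = {frozenset((genes[a], genes[b]))
              for a, b in rng.integers(0, 30, size=(25, 2)) if a != b}
        net = extract_three_layer_network(set(genes), set(mirnas), mg, gg)
        G = nx.Graph()
        G.add_edges_from((a, b) for a, b in mg)
        G.add_edges_from(tuple(e) for e in gg)
        comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
        expected = comps[0]
        got = net.mirnas | net.direct_genes | net.indirect_genes
        assert got == expected

    def test_empty_graph(self):
        net = extract_three_layer_network(set(), set(), set(), set())
        assert net.counts == {"mirnas": 0, "direct_genes": 0,
                              "indirect_genes": 0, "edges": 0}
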