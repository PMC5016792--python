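"""Therapeutic-module network: selection, enrichment, projection."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vesnet.io import GeneSetCollection, export_graphml, import_graphml
from vesnet.modulenet import (ConfigError, annotate_upregulation,
                              enrich_categories, node_table,
                              project_onto_network,
                              select_therapeutic_genes)
from vesnet.modulenet import \
    test_upregulated_enrichment as upregulated_enrichment_of
from vesnet.simulate import gen_annotations, gen_network

CATS = ("angiogenesis", "anti_inflammation", "neurogenesis", "apoptosis")


def collection(**sets):
    base = {c: set() for c in CATS}
    base.update({k: set(v) for k, v in sets.items()})
    return GeneSetCollection(sets=base)


class TestSelection:
    def test_multi_membership_carries_multiple_flags(self):
        cats = collection(neurogenesis={"G1"}, apoptosis={"G1", "G2"})
        sel = select_therapeutic_genes({"G1", "G2", "G3"}, cats)
        assert list(sel.index) == ["G1", "G2"]
        assert sel.loc["G1", "neurogenesis"] and sel.loc["G1", "apoptosis"]
        assert not sel.loc["G2", "neurogenesis"]

    def test_disjoint_proteome_empty_selection(self, caplog):
        cats = collection(angiogenesis={"X1"})
        with caplog.at_level("WARNING", logger="vesnet"):
            sel = select_therapeutic_genes({"G1"}, cats)
        assert sel.empty

    def test_missing_category_named(self):
        cats = GeneSetCollection(sets={"angiogenesis": {"G1"}})
        with pytest.raises(ConfigError, match="neurogenesis"):
            select_therapeutic_genes({"G1"}, cats)

    def test_flags_stable_under_category_order(self):
        sets = {"angiogenesis": {"G1"}, "anti_inflammation": {"G2"},
                "neurogenesis": {"G1", "G3"}, "apoptosis": {"G3"}}
        fwd = GeneSetCollection(sets=dict(sets))
        rev = GeneSetCollection(sets=dict(reversed(list(sets.items()))))
        a = select_therapeutic_genes({"G1", "G2", "G3"}, fwd)
        b = select_therapeutic_genes({"G1", "G2", "G3"}, rev)
        pd.testing.assert_frame_equal(a, b)


class TestCategoryEnrichment:
    def test_exact_designed_overlap_recovered(self):
        universe = {f"G{i:04d}" for i in range(400)}
        query = {f"G{i:04d}" for i in range(200)}
        designs = {c: (100, 25) for c in CATS}
        cats, _ = gen_annotations(universe, designs, query, seed=5)
        rep = enrich_categories(query, cats, background_n=400,
                                category_names=CATS)
        assert (rep.k == 25).all()
        assert (rep.K == 100).all()
        assert (rep.n == 200).all()

    def test_category_equal_to_proteome_maximal(self):
        genes = {f"G{i}" for i in range(30)}
        cats = collection(**{c: genes for c in CATS})
        rep = enrich_categories(genes, cats, background_n=1000,
                                category_names=CATS)
        assert (rep.k == 30).all()
        assert (rep.p < 1e-20).all()

    def test_null_categories_uniformish_p(self):
        rng = np.random.default_rng(4)
        universe = [f"G{i:04d}" for i in range(500)]
        query = set(universe[:100])
        ps = []
        for rep in range(120):
            members = set(rng.choice(universe, size=60, replace=False))
            cats = collection(angiogenesis=members)
            out = enrich_categories(query, cats, background_n=500,
                                    category_names=("angiogenesis",))
            ps.append(out.p.iloc[0])
        assert 0.35 < np.mean(ps) < 0.75

    def test_bh_applied_across_categories(self):
        genes = {f"G{i}" for i in range(20)}
        cats = collection(angiogenesis=set(list(genes)[:10]),
                          anti_inflammation={"X1"}, neurogenesis={"X2"},
                          apoptosis={"X3"})
        rep = enrich_categories(genes, cats, background_n=200,
                                category_names=CATS)
        assert (rep.q >= rep.p - 1e-12).all()


class TestProjection:
    def _selection(self, genes):
        return pd.DataFrame({c: [True] + [False] * (len(CATS) - 1)
                             for c in CATS}, index=pd.Index(sorted(genes)))

    def _selection_all(self, genes):
        df = pd.DataFrame(False, index=pd.Index(sorted(genes)), columns=CATS)
        df["angiogenesis"] = True
        return df

    def test_induced_subgraph_hand_example(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("C", "E")])
        sel = self._selection_all({"A", "B", "C", "X"})
        tnet = project_onto_network(sel, net)
        edges = {tuple(sorted(e)) for e in tnet.graph.edges}
        assert edges == {("A", "B"), ("B", "C")}
        assert tnet.connected_genes() == {"A", "B", "C"}
        assert tnet.largest_component() == {"A", "B", "C"}
        assert tnet.graph.nodes["X"]["component"] is not None
        assert tnet.summary()["genes_connected"] == 3

    def test_empty_selection_empty_network(self):
        sel = pd.DataFrame(columns=list(CATS))
        tnet = project_onto_network(sel, nx.Graph([("A", "B")]))
        assert tnet.n_genes == 0 and tnet.n_links == 0

    def test_every_projected_edge_in_parent(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            net = gen_network(40, "erdos_renyi", 0.1, seed=trial)
            genes = set(rng.choice(sorted(net.nodes), size=15, replace=False))
            tnet = project_onto_network(self._selection_all(genes), net)
            for a, b in tnet.graph.edges:
                assert net.has_edge(a, b)
                assert a in genes and b in genes
            # completeness: every parent edge inside the selection appears
            for a, b in itertools.combinations(sorted(genes), 2):
                if net.has_edge(a, b):
                    assert tnet.graph.has_edge(a, b)

    def test_components_match_bfs_oracle(self):
        def bfs_components(adj, nodes):
            seen, comps = set(), []
            for start in nodes:
                if start in seen:
                    continue
                comp, queue = {start}, [start]
                while queue:
                    v = queue.pop()
                    for w in adj.get(v, ()):
                        if w not in comp:
                            comp.add(w)
                            queue.append(w)
                seen |= comp
                comps.append(frozenset(comp))
            return set(comps)

        for seed in range(8):
            net = gen_network(12, "erdos_renyi", 0.15, seed=seed)
            genes = set(net.nodes)
            tnet = project_onto_network(self._selection_all(genes), net)
            adj = {v: set(tnet.graph.adj[v]) for v in tnet.graph.nodes}
            oracle = bfs_components(adj, sorted(genes))
            got = {}
            for v, a in tnet.graph.nodes(data=True):
                got.setdefault(a["component"], set()).add(v)
            assert {frozenset(c) for c in got.values()} == oracle
            sizes = sorted(tnet.component_sizes.values(), reverse=True)
            assert sizes == sorted((len(c) for c in oracle), reverse=True)

    def test_category_fractions_sum_to_one(self):
        cats = collection(angiogenesis={"G1"}, apoptosis={"G1"},
                          neurogenesis={"G2"})
        sel = select_therapeutic_genes({"G1", "G2"}, cats)
        tnet = project_onto_network(sel, nx.Graph())
        n1 = tnet.graph.nodes["G1"]
        assert n1["frac_angiogenesis"] == pytest.approx(0.5)
        assert n1["frac_apoptosis"] == pytest.approx(0.5)
        assert sum(n1[f"frac_{c}"] for c in CATS) == pytest.approx(1.0)


class TestAnnotation:
    def _net(self, genes):
        sel = pd.DataFrame(True, index=pd.Index(sorted(genes)),
                           columns=["angiogenesis"])
        return project_onto_network(sel, nx.Graph())

    def _deps(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "gene_id", "log2fc",
                                           "lr", "p", "q", "direction"])

    def test_max_abs_fold_change_rule(self):
        tnet = self._net({"G1"})
        deps = self._deps([("P1", "G1", 1.2, 9, 1e-4, 1e-3, "up"),
                           ("P2", "G1", 2.0, 9, 1e-5, 1e-4, "up")])
        tnet = annotate_upregulation(tnet, deps)
        assert tnet.graph.nodes["G1"]["upregulated"]
        assert tnet.graph.nodes["G1"]["fold_change"] == pytest.approx(2.0)

    def test_absent_gene_keeps_null(self):
        tnet = annotate_upregulation(self._net({"G1"}), self._deps([]))
        assert not tnet.graph.nodes["G1"]["upregulated"]
        assert tnet.graph.nodes["G1"]["fold_change"] is None

    def test_exactly_flagged_count(self):
        tnet = self._net({f"G{i}" for i in range(5)})
        deps = self._deps([("P0", "G0", 2.0, 9, 1e-5, 1e-4, "up"),
                           ("P3", "G3", 1.5, 9, 1e-5, 1e-4, "up"),
                           ("P4", "G4", -1.5, 9, 1e-5, 1e-4, "down")])
        tnet = annotate_upregulation(tnet, deps)
        flagged = [v for v in tnet.graph.nodes
                   if tnet.graph.nodes[v]["upregulated"]]
        assert sorted(flagged) == ["G0", "G3"]

    def test_graphml_round_trip_preserves_annotations(self, tmp_path):
        tnet = self._net({"G1", "G2"})
        deps = self._deps([("P1", "G1", 1.7, 9, 1e-5, 1e-4, "up")])
        tnet = annotate_upregulation(tnet, deps)
        path = tmp_path / "mod.graphml"
        export_graphml(tnet, path)
        back = import_graphml(path)
        assert back.nodes["G1"]["fold_change"] == pytest.approx(1.7)
        assert back.nodes["G1"]["upregulated"] is True
        assert back.nodes["G2"]["fold_change"] is None


class TestUpregulatedEnrichment:
    def _tnet(self, net, genes):
        sel = pd.DataFrame(True, index=pd.Index(sorted(genes)),
                           columns=["angiogenesis"])
        return project_onto_network(sel, net)

    def test_maximal_overlap_extreme_p(self):
        net = nx.path_graph(10)
        net = nx.relabel_nodes(net, lambda i: f"G{i}")
        module_genes = {f"G{i}" for i in range(10)}
        proteome = {f"G{i}" for i in range(200)}
        tnet = self._tnet(net, module_genes)
        res = upregulated_enrichment_of(tnet, proteome, module_genes)
        assert res.k == 10 and res.p < 1e-10

    def test_null_upregulated_sets_uniformish(self):
        rng = np.random.default_rng(8)
        net = gen_network(80, "erdos_renyi", 0.08, seed=1)
        proteome = {f"G{i:05d}" for i in range(300)}
        module_genes = set(sorted(net.nodes)[:40])
        tnet = self._tnet(net, module_genes)
        ps = []
        for _ in range(150):
            up = set(rng.choice(sorted(proteome), size=30, replace=False))
            ps.append(upregulated_enrichment_of(tnet, proteome, up).p)
        assert 0.35 < np.mean(ps) < 0.75

    def test_stray_upregulated_genes_intersected_away(self, caplog):
        net = nx.Graph([("G1", "G2")])
        tnet = self._tnet(net, {"G1", "G2"})
        with caplog.at_level("WARNING", logger="vesnet"):
            res = upregulated_enrichment_of(tnet, {"G1", "G2", "G3"},
                                              {"G1", "ALIEN"})
        assert res.K == 1

    def test_empty_network_rejected(self):
        tnet = self._tnet(nx.Graph(), set())
        with pytest.raises(ValueError, match="empty"):
            upregulated_enrichment_of(tnet, {"G1"}, {"G1"})


def test_node_table_sorted_and_complete():
    net = nx.Graph([("G2", "G1")])
    sel = pd.DataFrame(True, index=pd.Index(["G1", "G2"]),
                       columns=["angiogenesis"])
    tnet = project_onto_network(sel, net)
    table = node_table(tnet)
    assert list(table.gene_id) == ["G1", "G2"]
    assert "component" in table.columns
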