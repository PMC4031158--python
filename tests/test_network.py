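import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathwave as pw
from pathwave.network import KGMLParseError, PathwayValidationError


class TestParseKGML:
    def test_two_reactions_share_compound(self, kgml_two_reactions):
        doc = pw.parse_kgml(kgml_two_reactions)
        assert doc.pathway_id == "path:syn00010"
        assert doc.title == "toy metabolism"
        assert len(doc.reactions) == 2
        r1, r2 = doc.reactions
        assert "cpd:M1" in r1.products and "cpd:M1" in r2.substrates
        assert r1.gene_ids == {"gene:G1"}
        assert r2.gene_ids == {"gene:G2", "gene:G3"}

    def test_signaling_document(self, kgml_signaling):
        doc = pw.parse_kgml(kgml_signaling)
        assert doc.reactions == ()
        assert doc.relations == (("1", "2"),)

    def test_truncated_xml_is_a_parse_error(self, kgml_two_reactions):
        with pytest.raises(KGMLParseError, match="line"):
            pw.parse_kgml(kgml_two_reactions[: len(kgml_two_reactions) // 2])

    def test_missing_pathway_id(self):
        with pytest.raises(PathwayValidationError, match="name"):
            pw.parse_kgml("<pathway title='x'/>")

    def test_relation_to_undeclared_entity(self):
        xml = ("<pathway name='p'><entry id='1' name='gene:G1' type='gene'/>"
               "<relation entry1='1' entry2='99'/></pathway>")
        with pytest.raises(PathwayValidationError, match="99"):
            pw.parse_kgml(xml)


def _doc_with_metabolite_usage():
    """Three reactions; M_hub appears in all, M_rare in one."""
    reactions = tuple(
        pw.network.ReactionEntry(
            reaction_id=f"R{i}", gene_ids=frozenset({f"g{i}"}),
            substrates=("M_hub",), products=("M_rare",) if i == 0 else ("M_x",),
        )
        for i in range(3)
    )
    return pw.PathwayDocument(pathway_id="p", title="", reactions=reactions)


class TestFilterMetabolites:
    @pytest.mark.parametrize(
        "degree,whitelisted,expect_removed",
        [(9, False, True),    # above threshold -> removed
         (8, False, False),   # boundary: exactly 8 -> retained
         (20, True, False)],  # whitelisted hub -> retained
    )
    def test_degree_rule(self, degree, whitelisted, expect_removed):
        doc = _doc_with_metabolite_usage()
        policy = pw.MetaboliteFilterPolicy(
            whitelist=frozenset({"M_hub"}) if whitelisted else frozenset()
        )
        degrees = {"M_hub": degree, "M_rare": 1, "M_x": 2}
        out = pw.filter_metabolites(doc, policy, degrees)
        present = any("M_hub" in r.substrates for r in out.reactions)
        assert present != expect_removed

    def test_blacklist_removes_regardless_of_degree(self):
        doc = _doc_with_metabolite_usage()
        policy = pw.MetaboliteFilterPolicy(blacklist=frozenset({"M_rare"}))
        out = pw.filter_metabolites(doc, policy, {"M_hub": 1, "M_rare": 1, "M_x": 1})
        assert all("M_rare" not in r.products for r in out.reactions)

    def test_missing_degree_is_an_error(self):
        doc = _doc_with_metabolite_usage()
        with pytest.raises(ValueError, match="M_x"):
            pw.filter_metabolites(doc, pw.MetaboliteFilterPolicy(), {"M_hub": 1, "M_rare": 1})

    def test_idempotent(self):
        doc = _doc_with_metabolite_usage()
        policy = pw.MetaboliteFilterPolicy(degree_threshold=2)
        degrees = {"M_hub": 3, "M_rare": 1, "M_x": 2}
        once = pw.filter_metabolites(doc, policy, degrees)
        twice = pw.filter_metabolites(once, policy, degrees)
        assert once == twice

    def test_whitelist_blacklist_overlap_rejected(self):
        with pytest.raises(ValueError):
            pw.MetaboliteFilterPolicy(whitelist=frozenset("a"), blacklist=frozenset("a"))


def _chain_doc(n_reactions):
    """R0..R(n-1) chained through distinct intermediate metabolites."""
    reactions = tuple(
        pw.network.ReactionEntry(
            reaction_id=f"R{i}", gene_ids=frozenset(),
            substrates=(f"M{i}",), products=(f"M{i + 1}",),
        )
        for i in range(n_reactions)
    )
    return pw.PathwayDocument(pathway_id="chain", title="", reactions=reactions)


class TestBuildReactionNetwork:
    def test_product_substrate_edge(self, kgml_two_reactions):
        net = pw.build_reaction_network(pw.parse_kgml(kgml_two_reactions))
        assert net.n_nodes == 2 and net.n_edges == 1
        assert int(net.adjacency.sum()) == 2  # one symmetric pair

    def test_nine_reaction_chain_is_a_path_graph(self):
        net = pw.build_reaction_network(_chain_doc(9))
        assert net.n_nodes == 9 and net.n_edges == 8
        degrees = sorted(net.adjacency.sum(axis=0).tolist())
        assert degrees == [1, 1] + [2] * 7

    def test_disjoint_reactions_have_no_edge(self):
        reactions = tuple(
            pw.network.ReactionEntry(f"R{i}", frozenset(), (f"S{i}",), (f"P{i}",))
            for i in range(2)
        )
        doc = pw.PathwayDocument("p", "", reactions)
        assert pw.build_reaction_network(doc).n_edges == 0

    def test_signaling_mode(self, kgml_signaling):
        net = pw.build_reaction_network(pw.parse_kgml(kgml_signaling))
        assert net.kind == "signaling"
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.node_genes["1"] == {"gene:GA"}

    def test_adjacency_invariants_and_oracle(self, rng):
        """Edge set equals a brute-force double loop over reaction pairs."""
        for _ in range(25):
            n = int(rng.integers(2, 8))
            mets = [f"M{i}" for i in range(int(rng.integers(2, 6)))]
            k = min(3, len(mets) + 1)
            reactions = tuple(
                pw.network.ReactionEntry(
                    f"R{i}", frozenset(),
                    tuple(rng.choice(mets, size=rng.integers(0, k), replace=False)),
                    tuple(rng.choice(mets, size=rng.integers(0, k), replace=False)),
                )
                for i in range(n)
            )
            doc = pw.PathwayDocument("p", "", reactions)
            net = pw.build_reaction_network(doc)
            a = net.adjacency
            assert np.array_equal(a, a.T) and not a.diagonal().any()
            for i in range(n):
                for j in range(i + 1, n):
                    expect = bool(
                        set(reactions[i].products) & set(reactions[j].substrates)
                        or set(reactions[j].products) & set(reactions[i].substrates)
                    )
                    assert bool(a[i, j]) == expect


class TestConnectedComponents:
    def test_path_is_one_component(self):
        net = pw.build_reaction_network(_chain_doc(3))
        comps = pw.connected_components(net)
        assert len(comps) == 1 and comps[0].n_nodes == 3

    def test_two_disjoint_edges(self):
        net = pw.read_edge_list_network("a\tb\nc\td\n")
        comps = pw.connected_components(net)
        assert [c.n_nodes for c in comps] == [2, 2]
        assert comps[0].nodes[0] == "a"  # size tie broken by smallest node id

    def test_empty_network(self):
        net = pw.PathwayNetwork("p", [], {}, np.zeros((0, 0)))
        assert pw.connected_components(net) == []


class TestEdgeList:
    def test_annotations_and_singletons(self):
        net = pw.read_edge_list_network("a\tb\n", "a\tg1,g2\nc\tg3\n")
        assert net.nodes == ["a", "b", "c"]
        assert net.node_genes["a"] == {"g1", "g2"}
        assert net.node_genes["b"] == frozenset()

    @given(st.integers(2, 7), st.integers(0, 10**6))
    def test_adjacency_always_symmetric_zero_diagonal(self, n, seed):
        r = np.random.default_rng(seed)
        lines = [
            f"n{int(r.integers(n))}\tn{int(r.integers(n))}"
            for _ in range(int(r.integers(1, 10)))
        ]
        net = pw.read_edge_list_network("\n".join(lines))
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert not net.adjacency.diagonal().any()
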