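"""ceRNA graph construction, couples, shared proteins, and round-trip exports."""

import itertools

import networkx as nx
import pytest

from cerna_weaver.ceweb import (
    build_network,
    cerna_couples,
    export_graph,
    fixture_interactions,
    fixture_pathway_sets,
    import_graph,
    shared_proteins,
)
from cerna_weaver.errors import ValidationError
from cerna_weaver.records import DuplexInteraction

EXPECTED_PSEUDOGENES = {"ENSCING00000011392", "ENSCING00000018651", "ENSCING00000007698"}


@pytest.fixture(scope="module")
def table5_graph():
    return build_network(fixture_interactions(), fixture_pathway_sets())


class TestBuildNetwork:
    def test_empty_interactions_keep_pathway_scaffold(self):
        sets = {"P1": ["g1", "g2"], "P2": ["g2"]}
        g = build_network([], sets)
        kinds = nx.get_node_attributes(g, "kind")
        assert set(kinds.values()) == {"pathway", "gene"}
        assert g.has_edge("g2", "P2")

    def test_table5_sequesters_edge_present(self, table5_graph):
        g = table5_graph
        assert g.has_edge("cin-mir-92c-5p", "ENSCING00000011392")
        assert g.edges["cin-mir-92c-5p", "ENSCING00000011392"]["edge_type"] == "sequesters"

    def test_edge_counts_match_deduplicated_tally(self, table5_graph):
        interactions = fixture_interactions()
        sets = fixture_pathway_sets()
        pathway_genes = {g for genes in sets.values() for g in genes}
        gene_edges = {
            (x.mirna_id, x.target_id)
            for x in interactions
            if x.target_kind == "mRNA" and x.target_id in pathway_genes
        }
        retained = {m for m, _ in gene_edges}
        pseudo_edges = {
            (x.mirna_id, x.target_id)
            for x in interactions
            if x.target_kind == "pseudogene" and x.mirna_id in retained
        }
        member_edges = {(g, p) for p, genes in sets.items() for g in genes}
        assert table5_graph.number_of_edges() == len(gene_edges) + len(pseudo_edges) + len(
            member_edges
        )

    def test_duplicates_collapse_to_min_energy(self):
        sets = {"P": ["g1"]}
        dup = [
            DuplexInteraction("m1", "g1", "mRNA", 1, 7, 0.1, -13.0),
            DuplexInteraction("m1", "g1", "mRNA", 20, 26, 0.1, -18.5),
        ]
        g = build_network(dup, sets)
        assert g.edges["m1", "g1"]["delta_g"] == -18.5

    def test_pseudogene_node_set(self, table5_graph):
        pseudo = {n for n, d in table5_graph.nodes(data=True) if d["kind"] == "pseudogene"}
        assert pseudo == EXPECTED_PSEUDOGENES


class TestCouples:
    def test_no_sequesters_edges_no_couples(self):
        g = build_network(
            [DuplexInteraction("m1", "g1", "mRNA", 1, 7, 0.0, -13.0)], {"P": ["g1"]}
        )
        assert cerna_couples(g) == []

    def test_table5_sfrp_couple(self, table5_graph):
        couples = {(c.mirna_id, c.pseudogene_id): c for c in cerna_couples(table5_graph)}
        c = couples[("cin-mir-153-5p", "ENSCING00000007698")]
        assert "NM_001078496" in c.gene_ids  # secreted frizzled-related protein (Sfrp1/5)
        assert "Wnt" in c.pathways

    def test_couples_match_cubic_enumeration(self, table5_graph):
        g = table5_graph
        nodes = list(g.nodes)
        expected = set()
        for m, p, gene in itertools.product(nodes, nodes, nodes):
            if (
                g.nodes[m]["kind"] == "miRNA"
                and g.nodes[p]["kind"] == "pseudogene"
                and g.nodes[gene]["kind"] == "gene"
                and g.has_edge(m, p)
                and g.edges[m, p]["edge_type"] == "sequesters"
                and g.has_edge(m, gene)
                and g.edges[m, gene]["edge_type"] == "targets"
            ):
                expected.add((m, p))
        assert {(c.mirna_id, c.pseudogene_id) for c in cerna_couples(g)} == expected

    def test_every_couple_mirna_both_roles(self, table5_graph):
        g = table5_graph
        for c in cerna_couples(g):
            types = {d["edge_type"] for _, _, d in g.out_edges(c.mirna_id, data=True)}
            assert {"targets", "sequesters"} <= types


class TestSharedProteins:
    def test_disjoint_sets_share_nothing(self):
        assert shared_proteins({"A": ["g1"], "B": ["g2"]}) == {}

    def test_smad4_shared_by_three_pathways(self):
        shared = shared_proteins(fixture_pathway_sets())
        assert shared["NM_001078476"] == {"Wnt", "FoxO", "Tgf-β"}  # Smad4

    def test_matches_pairwise_intersections(self):
        sets = {k: set(v) for k, v in fixture_pathway_sets().items()}
        expected = set()
        for a, b in itertools.combinations(sets, 2):
            expected |= sets[a] & sets[b]
        assert set(shared_proteins(sets)) == expected


class TestExport:
    def test_empty_graph_exports_header_only(self, tmp_path):
        p = export_graph(nx.DiGraph(), tmp_path / "empty.tsv", "tsv")
        lines = p.read_text().strip().splitlines()
        assert lines == ["source\ttarget\tsource_kind\ttarget_kind\tedge_type\tdelta_g"]

    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_round_trip_preserves_nodes_and_edges(self, table5_graph, tmp_path, fmt):
        path = export_graph(table5_graph, tmp_path / f"net.{fmt}", fmt)
        back = import_graph(path, fmt)
        assert set(back.nodes) == set(table5_graph.nodes)
        assert set(back.edges) == set(table5_graph.edges)
        for n in back.nodes:
            assert back.nodes[n]["kind"] == table5_graph.nodes[n]["kind"]

    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_export_import_export_is_byte_identical(self, table5_graph, tmp_path, fmt):
        p1 = export_graph(table5_graph, tmp_path / f"a.{fmt}", fmt)
        back = import_graph(p1, fmt)
        p2 = export_graph(back, tmp_path / f"b.{fmt}", fmt)
        assert p1.read_bytes() == p2.read_bytes()

    def test_graphml_is_wellformed_xml(self, tmp_path, rng):
        g = nx.DiGraph()
        for i in range(50):
            g.add_node(f"n{i}", kind="gene")
        for _ in range(80):
            a, b = rng.integers(0, 50, size=2)
            g.add_edge(f"n{a}", f"n{b}", edge_type="targets")
        path = export_graph(g, tmp_path / "r.graphml", "graphml")
        from lxml import etree

        root = etree.parse(str(path)).getroot()
        assert root.tag.endswith("graphml")
        assert root.nsmap[None] == "http://graphml.graphdrawing.org/xmlns"

    def test_unknown_format_rejected(self, table5_graph, tmp_path):
        with pytest.raises(ValidationError):
            export_graph(table5_graph, tmp_path / "x.bin", "binary")


def test_couple_count_monotone_under_energy_tightening():
    """Filtering interactions at a stricter deltaG upstream never creates new couples."""
    interactions = [
        DuplexInteraction("m1", "g1", "mRNA", 1, 7, 0.0, -13.0),
        DuplexInteraction("m1", "p1", "pseudogene", 1, 7, 0.0, -20.0),
        DuplexInteraction("m2", "g2", "mRNA", 1, 7, 0.0, -19.0),
        DuplexInteraction("m2", "p2", "pseudogene", 1, 7, 0.0, -14.0),
    ]
    sets = {"P": ["g1", "g2"]}
    loose = cerna_couples(build_network(interactions, sets))
    strict_in = [x for x in interactions if x.delta_g < -15.0]
    strict = cerna_couples(build_network(strict_in, sets))
    loose_keys = {(c.mirna_id, c.pseudogene_id) for c in loose}
    strict_keys = {(c.mirna_id, c.pseudogene_id) for c in strict}
    assert strict_keys <= loose_keys and len(strict) <= len(loose)
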