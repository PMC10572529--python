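import random

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gibbslink import (
    NetworkFormatError,
    PathwayGraph,
    PPINetwork,
    apply_id_mapping,
    merge_networks,
    parse_edge_list,
    parse_kgml,
    read_id_mapping,
    write_edge_list,
)

KGML_TWO_GENES = """<?xml version="1.0"?>
<pathway name="path:hsa00001" org="hsa" title="fixture-two-genes">
  <entry id="1" name="hsa:5925" type="gene"/>
  <entry id="2" name="hsa:595" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""

KGML_MULTIGENE_ENTRY = """<?xml version="1.0"?>
<pathway name="path:hsa00002" org="hsa" title="fixture-multigene">
  <entry id="1" name="hsa:1869 hsa:1870" type="gene"/>
  <entry id="2" name="hsa:595" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel"/>
</pathway>
"""

KGML_NO_RELATIONS = """<?xml version="1.0"?>
<pathway name="path:hsa00003" org="hsa" title="fixture-no-relations">
  <entry id="1" name="hsa:5925" type="gene"/>
  <entry id="2" name="hsa:595" type="gene"/>
  <entry id="3" name="cpd:C00001" type="compound"/>
</pathway>
"""

KGML_GROUP = """<?xml version="1.0"?>
<pathway name="path:hsa00004" org="hsa" title="fixture-group">
  <entry id="1" name="hsa:1111" type="gene"/>
  <entry id="2" name="hsa:2222" type="gene"/>
  <entry id="3" type="group">
    <component id="1"/>
    <component id="2"/>
  </entry>
  <entry id="4" name="hsa:3333" type="gene"/>
  <relation entry1="3" entry2="4" type="PPrel"/>
</pathway>
"""


def pathway_from_edges(name, edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return PathwayGraph(name=name, graph=g, source_format="edgelist")


class TestParseKgml:
    def test_two_gene_entries_one_relation(self):
        p = parse_kgml(KGML_TWO_GENES)
        assert p.nodes == {"hsa:5925", "hsa:595"}
        assert p.edges == {frozenset(("hsa:5925", "hsa:595"))}
        assert p.source_format == "kgml"
        assert p.name == "fixture-two-genes"

    def test_gene_entries_without_relations_give_nodes_only(self):
        p = parse_kgml(KGML_NO_RELATIONS)
        assert p.nodes == {"hsa:5925", "hsa:595"}  # compound entry skipped
        assert p.edges == set()

    def test_multigene_entry_clique_expands_across_entries(self):
        p = parse_kgml(KGML_MULTIGENE_ENTRY)
        assert p.nodes == {"hsa:1869", "hsa:1870", "hsa:595"}
        # edges run entry-to-entry only: no edge between hsa:1869 and hsa:1870
        assert p.edges == {
            frozenset(("hsa:1869", "hsa:595")),
            frozenset(("hsa:1870", "hsa:595")),
        }

    def test_group_entry_expands_to_component_genes(self):
        p = parse_kgml(KGML_GROUP)
        assert p.edges == {
            frozenset(("hsa:1111", "hsa:3333")),
            frozenset(("hsa:2222", "hsa:3333")),
        }

    def test_malformed_xml_raises_with_location(self):
        with pytest.raises(NetworkFormatError, match="line"):
            parse_kgml("<pathway><entry id='1'")

    def test_no_gene_entries_warns_and_returns_empty(self, caplog):
        doc = '<?xml version="1.0"?><pathway name="p"><entry id="1" name="cpd:C1" type="compound"/></pathway>'
        with caplog.at_level("WARNING"):
            p = parse_kgml(doc)
        assert p.nodes == set()
        assert any("empty pathway" in r.message for r in caplog.records)


class TestParseEdgeList:
    @pytest.mark.parametrize(
        "text,dialect,nodes,edges",
        [
            ("A\tB\nB\tC\n", "tsv", 3, 2),
            ("A pp B\nB pp C D\n", "sif", 4, 3),  # SIF multi-target record
            ("A\tB\nA\tB\n", "tsv", 2, 1),  # duplicates collapse
            ("A pp A\n", "sif", 1, 0),  # self-loop dropped, node kept
        ],
    )
    def test_parsing(self, text, dialect, nodes, edges):
        p = parse_edge_list(text, dialect=dialect)
        assert len(p.nodes) == nodes
        assert len(p.edges) == edges

    def test_short_record_raises_with_line_number(self):
        with pytest.raises(NetworkFormatError, match="line 2"):
            parse_edge_list("A\tB\nC\n", dialect="tsv")

    def test_header_flag_skips_first_line(self):
        p = parse_edge_list("source\ttarget\nA\tB\n", dialect="tsv", header=True)
        assert p.nodes == {"A", "B"}

    def test_self_loop_count_logged(self, caplog):
        with caplog.at_level("INFO"):
            parse_edge_list("A\tA\nB\tC\n", dialect="tsv")
        assert any("1 self-loop" in r.message for r in caplog.records)


class TestMerge:
    def test_merge_with_self_is_idempotent(self):
        p = pathway_from_edges("p", [("A", "B"), ("B", "C")])
        net = merge_networks([p, p])
        assert net.nodes == {"A", "B", "C"}
        assert len(net.edges) == 2

    def test_union_of_two_pathways(self):
        net = merge_networks(
            [pathway_from_edges("p1", [("A", "B")]), pathway_from_edges("p2", [("B", "C")])]
        )
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {frozenset("AB"), frozenset("BC")}
        assert net.provenance == ["p1", "p2"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_networks([])

    @given(st.integers(0, 2**31 - 1))
    def test_merge_commutes_and_matches_set_union(self, seed):
        rng = random.Random(seed)
        ps = []
        for k in range(2):
            edges = {
                tuple(sorted((f"N{rng.randint(0, 7)}", f"N{rng.randint(0, 7)}")))
                for _ in range(rng.randint(0, 10))
            }
            edges = {e for e in edges if e[0] != e[1]}
            ps.append(pathway_from_edges(f"p{k}", edges))
        ab = merge_networks([ps[0], ps[1]])
        ba = merge_networks([ps[1], ps[0]])
        assert ab == ba
        assert ab.nodes == ps[0].nodes | ps[1].nodes
        assert ab.edges == ps[0].edges | ps[1].edges
        assert all(len(e) == 2 for e in ab.edges)  # no self-loops survive


class TestIdMapping:
    def test_first_mapping_wins_and_unmapped_kept(self):
        mapping = read_id_mapping("hsa:5925\tRB1\nhsa:5925\tWRONG\nhsa:595\tCCND1\n")
        assert mapping == {"hsa:5925": "RB1", "hsa:595": "CCND1"}
        net = merge_networks(
            [pathway_from_edges("p", [("hsa:5925", "hsa:595"), ("hsa:595", "hsa:999")])]
        )
        mapped = apply_id_mapping(net, mapping)
        assert mapped.nodes == {"RB1", "CCND1", "hsa:999"}
        assert frozenset(("RB1", "CCND1")) in mapped.edges

    def test_collapsing_map_never_leaves_self_loop(self):
        net = merge_networks([pathway_from_edges("p", [("a", "b")])])
        mapped = apply_id_mapping(net, {"a": "X", "b": "X"})
        assert mapped.nodes == {"X"}
        assert mapped.edges == set()


class TestWriteEdgeList:
    def test_two_edge_network_writes_sorted_records(self):
        net = merge_networks([pathway_from_edges("p", [("C", "A"), ("B", "A")])])
        assert write_edge_list(net, dialect="tsv") == "A\tB\nA\tC\n"
        assert write_edge_list(net, dialect="sif") == "A\tpp\tB\nA\tpp\tC\n"

    def test_empty_network_writes_empty_text(self):
        net = PPINetwork(graph=nx.Graph())
        assert write_edge_list(net) == ""

    @pytest.mark.parametrize("dialect", ["tsv", "sif"])
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, dialect, seed):
        rng = random.Random(seed)
        g = nx.gnp_random_graph(rng.randint(2, 12), rng.uniform(0.2, 0.8), seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        if dialect == "tsv":  # TSV cannot carry isolated nodes
            g.remove_nodes_from([n for n, d in dict(g.degree()).items() if d == 0])
        net = PPINetwork(graph=g)
        text = write_edge_list(net, dialect=dialect)
        back = parse_edge_list(text, dialect=dialect)
        assert back.nodes == net.nodes
        assert back.edges == net.edges
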