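"""Gene-list and edge-table parsing, validation and round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from keynet import (
    ScoredEdge,
    ScoredGeneList,
    ScoredNetwork,
    edge_count,
    normalize_symbol,
    read_edge_table,
    read_gene_list,
    write_edge_table,
    write_gene_list,
)

from conftest import complete_graph, net_from_edges


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

class TestGeneList:
    def test_symbols_are_case_normalized_and_unique(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScoredGeneList("X", [("BDNF", 1.0), ("bdnf", 2.0)])
        gl = ScoredGeneList("X", [(" bdnf ", 1.0)])
        assert gl.symbols == ["BDNF"]

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ScoredGeneList("X", [("A", -0.1)])

    def test_read_collapses_duplicates_keeping_max(self, tmp_path, caplog):
        f = tmp_path / "genes.tsv"
        f.write_text("BDNF\t30.9\nbdnf\t1.0\n")
        gl = read_gene_list(f, "X")
        assert len(gl) == 1
        assert gl.score("BDNF") == 30.9

    def test_read_score_range(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("A\t0.8\nB\t5.0\nC\t30.9\n")
        gl = read_gene_list(f, "X")
        scores = [s for _, s in gl.entries]
        assert len(gl) == 3
        assert min(scores) == 0.8 and max(scores) == 30.9

    def test_read_fixture_sized_list(self, tmp_path, fixture_lists):
        pos = fixture_lists[0]
        f = tmp_path / "pos.tsv"
        write_gene_list(pos, f)
        back = read_gene_list(f, "PoS")
        assert len(back) == 36
        assert back.symbol_set == pos.symbol_set

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("symbol\tscore\n")
        with pytest.raises(ValueError, match="empty gene list"):
            read_gene_list(f, "X")

    def test_unparseable_row_names_line(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("A\t1.0\nB\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gene_list(f, "X")

    def test_missing_scores_default_to_zero(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("A\nB\t2.5\n")
        gl = read_gene_list(f, "X")
        assert gl.score("A") == 0.0 and gl.score("B") == 2.5


# ---------------------------------------------------------------------------
# edges and networks
# ---------------------------------------------------------------------------

class TestScoredEdge:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            ScoredEdge("A", "a", 500)

    def test_canonical_pair_order(self):
        assert ScoredEdge("B", "A", 500).pair == ("A", "B")

    @pytest.mark.parametrize("bad", [-1, 1000])
    def test_score_range_enforced(self, bad):
        with pytest.raises(ValueError, match="out of range"):
            ScoredEdge("A", "B", bad)
        with pytest.raises(ValueError, match="out of range"):
            ScoredEdge("A", "B", 500, {"coexpression": bad})


class TestEdgeTable:
    def test_directed_pairs_merge(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text(
            "protein1\tprotein2\tcombined_score\n"
            "A\tB\t950\nB\tA\t950\nB\tC\t905\nC\tD\t999\n"
        )
        net = read_edge_table(f)
        assert net.n_nodes == 4
        assert net.n_edges == 3
        assert edge_count(net, "directed_pairs") == 6

    def test_unit_scale_conversion(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("protein1\tprotein2\tcombined_score\nA\tB\t0.95\n")
        net = read_edge_table(f, score_scale="unit")
        assert net.get_edge("A", "B").combined == 950

    def test_unit_scale_caps_at_999(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("protein1\tprotein2\tcombined_score\nA\tB\t1.0\n")
        assert read_edge_table(f, score_scale="unit").get_edge("A", "B").combined == 999

    def test_conflicting_duplicate_scores_error(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("protein1\tprotein2\tcombined_score\nA\tB\t950\nB\tA\t900\n")
        with pytest.raises(ValueError, match="conflicting"):
            read_edge_table(f)

    def test_self_loop_row_dropped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "edges.tsv"
        f.write_text("protein1\tprotein2\tcombined_score\nA\tA\t950\nA\tB\t900\n")
        with caplog.at_level("WARNING", logger="keynet"):
            net = read_edge_table(f)
        assert net.n_edges == 1
        assert any("self-loop" in r.message for r in caplog.records)

    def test_string_export_space_separated_flavor(self, tmp_path):
        f = tmp_path / "string.txt"
        f.write_text(
            "protein1 protein2 coexpression experimental textmining combined_score\n"
            "BDNF NTRK2 657 629 995 999\n"
        )
        net = read_edge_table(f)
        e = net.get_edge("BDNF", "NTRK2")
        assert e.combined == 999
        assert e.channels == {"coexpression": 657, "experimental": 629, "textmining": 995}

    def test_isolated_nodes_from_node_file(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("protein1\tprotein2\tcombined_score\nA\tB\t950\n")
        nf = tmp_path / "nodes.txt"
        nf.write_text("A\nB\nC\n")
        net = read_edge_table(f, node_file=nf)
        assert net.n_nodes == 3
        assert net.degree("C") == 0


# ---------------------------------------------------------------------------
# edge_count and round-trip properties
# ---------------------------------------------------------------------------

class TestEdgeCount:
    def test_complete_graph_conventions(self):
        k5 = complete_graph(5)
        assert edge_count(k5, "undirected") == 10
        assert edge_count(k5, "directed_pairs") == 20

    def test_empty_network(self):
        net = ScoredNetwork("empty", nodes=["A"])
        assert edge_count(net, "undirected") == 0
        assert edge_count(net, "directed_pairs") == 0


@st.composite
def scored_networks(draw):
    n = draw(st.integers(min_value=2, max_value=10))
    names = [f"G{i}" for i in range(n)]
    pairs = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)]
    chosen = draw(st.lists(st.sampled_from(pairs), min_size=1, max_size=len(pairs), unique=True))
    net = ScoredNetwork("hyp", nodes=names)
    for a, b in chosen:
        cs = draw(st.integers(min_value=0, max_value=999))
        channels = {"coexpression": draw(st.integers(min_value=0, max_value=999))}
        net.add_edge(ScoredEdge(a, b, cs, channels))
    return net


@settings(max_examples=50, derandomize=True)
@given(net=scored_networks())
def test_edge_table_roundtrip(tmp_path_factory, net):
    """Writing and re-reading an edge table preserves nodes, edges and scores."""
    from keynet.netcore import write_node_list

    d = tmp_path_factory.mktemp("rt")
    path, nodes_path = d / "edges.tsv", d / "nodes.txt"
    write_edge_table(net, path)
    write_node_list(net, nodes_path)
    back = read_edge_table(path, node_file=nodes_path)
    assert back.node_set == net.node_set
    assert {e.pair for e in back.edges} == {e.pair for e in net.edges}
    for e in net.edges:
        be = back.get_edge(e.a, e.b)
        assert be.combined == e.combined
        assert be.channels.get("coexpression", 0) == e.channels.get("coexpression", 0)


@settings(max_examples=50, derandomize=True)
@given(net=scored_networks())
def test_directed_pairs_double_undirected(net):
    assert edge_count(net, "directed_pairs") == 2 * edge_count(net, "undirected")


def test_normalize_symbol_strips_and_uppercases():
    assert normalize_symbol("  bdnf\t") == "BDNF"
    with pytest.raises(ValueError):
        normalize_symbol("   ")
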