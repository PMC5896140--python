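import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from spermnet import (
    DirectedNetwork,
    EdgeRecord,
    EmptyNetworkError,
    NetworkParseError,
    connected_components,
    intersect,
    main_component,
    main_component_share,
    percentage,
    read_network,
    union_merge,
    write_network,
)

from conftest import net_from_pairs
from _oracles import union_find_components

node_ids = st.text(alphabet="ABCDEFGH", min_size=1, max_size=3)
edge_lists = st.lists(st.tuples(node_ids, node_ids), min_size=1, max_size=25)


def networks(pairs_list):
    return net_from_pairs(pairs_list)


class TestReadWrite:
    def test_sif_rows_become_directed_edges(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp B\nB pp C\n")
        net = read_network(p, dialect="sif")
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.has_edge("A", "B") and net.has_edge("B", "C")
        assert not net.has_edge("B", "A")

    def test_duplicate_tsv_rows_collapse(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nA\tB\n")
        assert read_network(p, dialect="tsv").n_edges == 1

    def test_four_column_tsv_carries_score(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tpp\tB\t950\n")
        net = read_network(p, dialect="tsv")
        (rec,) = list(net.edges())
        assert rec.score == 950

    def test_duplicate_edges_keep_max_score(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tpp\tB\t300\nA\tpp\tB\t950\nA\tpp\tB\t100\n")
        (rec,) = list(read_network(p, dialect="tsv").edges())
        assert rec.score == 950

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.sif"
        p.write_text("A pp B\nA B\n")
        with pytest.raises(NetworkParseError, match=":2"):
            read_network(p, dialect="sif")

    def test_out_of_range_score_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tpp\tB\t1500\n")
        with pytest.raises(NetworkParseError, match="1500"):
            read_network(p, dialect="tsv")

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.sif"
        p.write_text("")
        with pytest.raises(EmptyNetworkError):
            read_network(p, dialect="sif")

    def test_empty_network_writes_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            write_network(DirectedNetwork(), tmp_path / "e.sif", dialect="sif")

    @pytest.mark.parametrize("dialect", ["sif", "tsv"])
    @settings(
        derandomize=True,
        max_examples=40,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(pairs=edge_lists)
    def test_round_trip_is_identity_on_edges(self, tmp_path, dialect, pairs):
        net = networks(pairs)
        path = tmp_path / f"rt.{dialect}"
        write_network(net, path, dialect=dialect)
        back = read_network(path, dialect=dialect)
        assert back.edge_keys() == net.edge_keys()

    def test_scored_network_round_trips_scores(self, tmp_path):
        net = DirectedNetwork(
            [EdgeRecord("A", "pp", "B", 950), EdgeRecord("B", "pp", "C", None)]
        )
        path = tmp_path / "scored.tsv"
        write_network(net, path, dialect="tsv")
        assert read_network(path, dialect="tsv") == net


class TestComponents:
    def test_two_disjoint_edges_two_components(self):
        decomp = connected_components(net_from_pairs([("A", "B"), ("C", "D")]))
        assert decomp.sizes == [2, 2]
        assert decomp.main == {"A", "B"}  # size tie broken by smallest member

    def test_chain_is_one_component(self, chain):
        assert connected_components(chain).n_components == 1

    def test_direction_is_ignored_for_membership(self):
        # A->C and B->C are weakly connected despite no directed A..B path
        decomp = connected_components(net_from_pairs([("A", "C"), ("B", "C")]))
        assert decomp.n_components == 1

    def test_25_component_fixture_matches_union_find(self):
        rng = np.random.default_rng(42)
        pairs = []
        for comp in range(25):
            size = int(rng.integers(2, 8))
            names = [f"c{comp:02d}x{i}" for i in range(size)]
            pairs += [(names[i], names[i + 1]) for i in range(size - 1)]
        net = net_from_pairs(pairs)
        decomp = connected_components(net)
        oracle = union_find_components(
            sorted(net.nodes), {(s, t) for s, t, _ in net.edge_keys()}
        )
        assert decomp.n_components == 25
        assert [set(c) for c in decomp.components] == oracle

    def test_sizes_partition_node_count(self):
        net = net_from_pairs([("A", "B"), ("C", "D"), ("E", "F"), ("F", "G")])
        decomp = connected_components(net)
        assert sum(decomp.sizes) == net.n_nodes

    def test_empty_network_errors(self):
        with pytest.raises(EmptyNetworkError):
            connected_components(DirectedNetwork())


class TestMainComponent:
    def test_picks_largest_and_reports_share(self):
        net = net_from_pairs([("A", "B"), ("C", "D"), ("C", "E")])
        mc = main_component(net)
        assert mc.nodes == {"C", "D", "E"}
        assert main_component_share(net) == 60.0

    def test_identity_on_connected_network(self, chain):
        assert main_component(chain) == chain

    def test_idempotent(self):
        net = net_from_pairs([("A", "B"), ("C", "D"), ("C", "E")])
        mc = main_component(net)
        assert main_component(mc) == mc

    def test_interactome_share_arithmetic(self):
        assert percentage(7758, 7892) == 98.3


class TestSetAlgebra:
    def test_intersect_with_self_is_identity(self, triangle):
        assert intersect(triangle, triangle) == triangle

    def test_disjoint_networks_intersect_empty(self):
        a = net_from_pairs([("A", "B")])
        b = net_from_pairs([("C", "D")])
        assert intersect(a, b).n_nodes == 0

    def test_intersect_matches_pairwise_membership_oracle(self, ba_small):
        rng = np.random.default_rng(0)
        nodes = sorted(ba_small.nodes)
        keep1 = set(rng.choice(nodes, size=150, replace=False))
        keep2 = set(rng.choice(nodes, size=150, replace=False))
        a, b = ba_small.subnetwork(keep1), ba_small.subnetwork(keep2)
        got = intersect(a, b)
        # oracle: nested loop over edge records
        expected_edges = {
            rec.key
            for rec in a.edges()
            if any(rec.key == other.key for other in b.edges())
        }
        assert got.edge_keys() == expected_edges
        assert got.nodes == a.nodes & b.nodes

    def test_union_of_triangles_sharing_an_edge(self):
        t1 = net_from_pairs([("A", "B"), ("B", "C"), ("C", "A")])
        t2 = net_from_pairs([("B", "C"), ("C", "D"), ("D", "B")])
        merged = union_merge([t1, t2])
        # enumeration: nodes {A,B,C,D}, shared edge B->C counted once
        assert merged.n_nodes == 4
        assert merged.n_edges == 5

    def test_union_single_network_is_identity(self, chain):
        assert union_merge([chain]) == chain

    def test_union_disjoint_sizes_add(self):
        a = net_from_pairs([("A", "B")])
        b = net_from_pairs([("C", "D")])
        merged = union_merge([a, b])
        assert merged.n_nodes == 4 and merged.n_edges == 2

    def test_union_empty_list_errors(self):
        with pytest.raises(ValueError):
            union_merge([])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(p1=edge_lists, p2=edge_lists)
    def test_union_commutes_and_absorbs_intersection(self, p1, p2):
        a, b = networks(p1), networks(p2)
        assert union_merge([a, b]) == union_merge([b, a])
        assert intersect(a, union_merge([a, b])) == a

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(p1=edge_lists, p2=edge_lists, p3=edge_lists)
    def test_union_is_associative(self, p1, p2, p3):
        a, b, c = networks(p1), networks(p2), networks(p3)
        assert union_merge([union_merge([a, b]), c]) == union_merge(
            [a, union_merge([b, c])]
        )


def test_percentage_rounds_half_up():
    assert percentage(1, 16, decimals=1) == 6.3  # 6.25 -> 6.3
    assert percentage(196, 7758) == 2.5


def test_self_loops_are_flagged():
    net = net_from_pairs([("A", "A"), ("A", "B")])
    assert net.self_loops == {"A"}
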