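import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spermnet import (
    DirectedNetwork,
    EdgeRecord,
    bottleneck_scores,
    control_backbone,
    identify_hubs,
    intersect,
    kde_split,
    node_metrics,
    planted_hub_metrics,
    shortest_path_tree,
    top_bottlenecks,
)
from spermnet.controllers import neighborhood_network, root_indicators

from conftest import net_from_pairs
from _oracles import brute_force_bottleneck, random_digraph


def metrics_from_degrees(degrees):
    return pd.DataFrame(
        {"degree": degrees}, index=[f"v{i}" for i in range(len(degrees))]
    )


class TestIdentifyHubs:
    def test_one_sigma_threshold_arithmetic(self):
        # degrees [1,1,1,1,10]: mu=2.8, population sigma=3.6, tau=6.4
        crit, hubs = identify_hubs(metrics_from_degrees([1, 1, 1, 1, 10]))
        assert crit.mean == pytest.approx(2.8)
        assert crit.std == pytest.approx(3.6)
        assert crit.threshold == pytest.approx(6.4)
        assert hubs == ["v4"]

    def test_regular_graph_makes_every_node_a_hub(self):
        with pytest.warns(UserWarning, match="sigma = 0"):
            _crit, hubs = identify_hubs(metrics_from_degrees([3, 3, 3, 3]))
        assert len(hubs) == 4

    def test_hub_order_degree_desc_then_lexicographic(self):
        m = pd.DataFrame({"degree": [9, 9, 1, 1, 1, 1, 1, 1]},
                         index=["b", "a", "c", "d", "e", "f", "g", "h"])
        _crit, hubs = identify_hubs(m)
        assert hubs == ["a", "b"]

    def test_membership_invariant_under_relabeling(self, ba_small_metrics):
        _c1, hubs1 = identify_hubs(ba_small_metrics)
        renamed = ba_small_metrics.rename(index=lambda n: "x" + n)
        _c2, hubs2 = identify_hubs(renamed)
        assert ["x" + h for h in hubs1] == hubs2
        assert len(hubs1) <= len(ba_small_metrics)


class TestKdeSplit:
    def test_unimodal_sample_is_one_subpopulation(self):
        rng = np.random.default_rng(1)
        split = kde_split(rng.normal(0.5, 0.1, size=200))
        assert split.n_subpopulations == 1

    def test_planted_party_date_split(self):
        values, labels = planted_hub_metrics(100, 30, seed=7)
        split = kde_split(values, metric="clustering")
        assert split.n_subpopulations == 2
        assert 0.2 < split.boundaries[0] < 0.7
        # generator labels are the oracle: no cross-assignment
        assert set(split.assignments[labels == 0]) == {0}
        assert set(split.assignments[labels == 1]) == {1}

    def test_two_tight_gaussians_split_with_boundary_between_means(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(0.0, 0.05, 100), rng.normal(0.86, 0.02, 30)]
        )
        split = kde_split(vals)
        assert split.n_subpopulations == 2
        assert 0.2 < split.boundaries[0] < 0.7

    def test_zero_variance_is_degenerate_single_population(self):
        split = kde_split([0.4] * 20)
        assert split.degenerate and split.n_subpopulations == 1

    def test_density_integrates_to_one(self):
        values, _ = planted_hub_metrics(80, 40, seed=3)
        split = kde_split(values)
        assert np.trapezoid(split.density, split.grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            kde_split([0.1, 0.2])


class TestShortestPathTree:
    def test_chain_from_head(self, chain):
        tree = shortest_path_tree(chain, "A")
        assert tree.parent == {"B": "A", "C": "B"}
        assert tree.size == 3

    def test_chain_from_tail_is_singleton(self, chain):
        assert shortest_path_tree(chain, "C").size == 1

    def test_diamond_ties_break_lexicographically(self):
        net = net_from_pairs([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
        tree = shortest_path_tree(net, "A")
        assert tree.parent["D"] == "B"

    def test_tree_paths_are_shortest(self):
        rng = np.random.default_rng(2)
        nodes, edges = random_digraph(rng, n_max=12, n_min=5)
        net = net_from_pairs(edges) if edges else None
        if net is None:
            pytest.skip("degenerate draw")
        from _oracles import floyd_warshall

        dist = floyd_warshall(sorted(nodes), {(s, t) for s, t in edges})
        root = sorted(net.nodes)[0]
        tree = shortest_path_tree(net, root)
        for v in tree.parent:
            depth, node = 0, v
            while node != root:
                node = tree.parent[node]
                depth += 1
            assert depth == dist[(root, v)]


class TestBottleneckScores:
    def test_chain_scores(self, chain):
        assert bottleneck_scores(chain).scores == {"A": 0, "B": 1, "C": 2}

    def test_isolated_node_scores_zero(self):
        net = DirectedNetwork(nodes=["A", "B"])
        assert bottleneck_scores(net).scores == {"A": 0, "B": 0}

    def test_root_excluded_from_its_own_tree(self, chain):
        assert root_indicators(chain, "A")["A"] == 0

    def test_matches_path_walking_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            nodes, edges = random_digraph(rng, n_max=15, n_min=3)
            net = net_from_pairs(edges) if edges else DirectedNetwork(nodes=nodes)
            for n in nodes:
                net.add_node(n)
            assert bottleneck_scores(net).scores == brute_force_bottleneck(nodes, edges)


class TestTopBottlenecks:
    def test_chain_top_is_sink(self, chain):
        scores = bottleneck_scores(chain)
        assert top_bottlenecks(scores, 1) == ["C"]

    def test_k_equal_n_ranks_all(self, chain):
        assert len(top_bottlenecks(bottleneck_scores(chain), 3)) == 3

    def test_k_beyond_n_truncates_with_warning(self, chain):
        with pytest.warns(UserWarning, match="exceeds"):
            ranked = top_bottlenecks(bottleneck_scores(chain), 10)
        assert len(ranked) == 3

    def test_stable_under_node_order_permutation(self, ba_small):
        scores = bottleneck_scores(ba_small)
        shuffled = dict(sorted(scores.scores.items(), key=lambda kv: hash(kv[0])))
        from spermnet import BottleneckScores

        assert top_bottlenecks(BottleneckScores(shuffled), 10) == top_bottlenecks(
            scores, 10
        )


class TestControlBackbone:
    def test_identical_controller_sets_give_their_neighborhood(self, ba_small):
        seeds = sorted(ba_small.nodes)[:10]
        expected = neighborhood_network(ba_small, seeds)
        assert control_backbone(ba_small, seeds, seeds) == expected

    def test_disjoint_neighborhoods_yield_empty_network(self):
        net = net_from_pairs([("A", "B"), ("C", "D")])
        with pytest.warns(UserWarning, match="overlap"):
            bb = control_backbone(net, ["A"], ["C"])
        assert bb.n_nodes == 0

    def test_matches_set_algebra_oracle(self, ba_small, ba_small_metrics):
        _crit, hubs = identify_hubs(ba_small_metrics)
        scores = bottleneck_scores(ba_small)
        top_bn = top_bottlenecks(
            scores, len(hubs), degrees=ba_small_metrics["degree"].to_dict()
        )
        bb = control_backbone(ba_small, hubs, top_bn)
        oracle = intersect(
            neighborhood_network(ba_small, hubs),
            neighborhood_network(ba_small, top_bn),
        )
        assert bb == oracle

    def test_empty_controller_list_rejected(self, chain):
        with pytest.raises(ValueError):
            control_backbone(chain, [], ["A"])


def test_bottleneck_correlates_with_betweenness(ba_small, ba_small_metrics):
    """The two control notions agree in rank on a scale-free network."""
    scores = bottleneck_scores(ba_small)
    nodes = sorted(ba_small.nodes)
    rho, _p = stats.spearmanr(
        [scores.scores[n] for n in nodes],
        [ba_small_metrics.loc[n, "betweenness"] for n in nodes],
    )
    assert rho > 0
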