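"""nlBC core: BFS structure, restricted accumulation, oracle, limits."""

import math

import numpy as np
import pytest

from nlbc import (
    InputGeneSet,
    bfs_shortest_paths,
    brute_force_nlbc,
    compute_nlbc,
    read_gene_list,
    standard_bc,
)

from conftest import net_from_edges, random_connected_net, random_inputs


class TestInputGeneSet:
    def test_requires_two_mapped_nodes(self, path3):
        with pytest.raises(ValueError, match="at least 2"):
            InputGeneSet({"s": 1.0})

    def test_rejects_non_positive_weights(self):
        with pytest.raises(ValueError, match="non-positive"):
            InputGeneSet({"s": 1.0, "t": 0.0})

    def test_unmapped_symbols_dropped_with_record(self, path3):
        inputs = InputGeneSet.from_weights(
            path3, {"s": 1.0, "t": 2.0, "NOT_THERE": 1.0}
        )
        assert inputs.weights == {"s": 1.0, "t": 2.0}
        assert inputs.dropped == ["NOT_THERE"]

    def test_gene_list_file_defaults_missing_weight_to_one(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("EGFR\t2.5\nGRB2\n# comment\nSOS1\t\n")
        assert read_gene_list(path) == {"EGFR": 2.5, "GRB2": 1.0, "SOS1": 1.0}


class TestBfsShortestPaths:
    def test_four_cycle_has_two_paths_to_opposite(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        dag = bfs_shortest_paths(net, "A")
        assert dag.dist["C"] == 2
        assert dag.sigma["C"] == 2
        assert sorted(dag.preds["C"]) == ["B", "D"]

    def test_path_counts(self, path3):
        dag = bfs_shortest_paths(path3, "s")
        assert dag.sigma["t"] == 1 and dag.dist["t"] == 2

    def test_complete_graph_all_at_distance_one(self):
        net = net_from_edges(
            [(a, b) for a in "WXYZ" for b in "WXYZ" if a < b]
        )
        dag = bfs_shortest_paths(net, "W")
        assert all(dag.dist[v] == 1 and dag.sigma[v] == 1 for v in "XYZ")

    def test_sigma_is_sum_over_predecessors(self):
        rng = np.random.default_rng(42)
        net = random_connected_net(rng)
        src = sorted(net.nodes)[0]
        dag = bfs_shortest_paths(net, src)
        for v in dag.dist:
            if v == src:
                assert dag.sigma[v] == 1 and dag.preds[v] == []
                continue
            assert dag.sigma[v] == sum(dag.sigma[p] for p in dag.preds[v])
            assert all(dag.dist[p] == dag.dist[v] - 1 for p in dag.preds[v])

    def test_unknown_source_raises_with_symbol(self, path3):
        with pytest.raises(KeyError, match="GHOST"):
            bfs_shortest_paths(path3, "GHOST")


class TestComputeNlbc:
    def test_single_path_interior_scores_one(self, path3):
        ct = compute_nlbc(path3, InputGeneSet({"s": 1.0, "t": 1.0}))
        assert ct.values["v"] == pytest.approx(1.0)
        assert ct.values["s"] == ct.values["t"] == 0.0

    def test_diamond_splits_evenly(self, diamond):
        ct = compute_nlbc(diamond, InputGeneSet({"s": 1.0, "t": 1.0}))
        assert ct.values["a"] == pytest.approx(0.5)
        assert ct.values["b"] == pytest.approx(0.5)

    def test_asymmetric_bridge_weighted(self, asymmetric_bridge, bridge_inputs):
        ct = compute_nlbc(asymmetric_bridge, bridge_inputs)
        assert ct.normalizer == pytest.approx(8.0)
        assert ct.values["b1"] == pytest.approx(0.75)
        assert ct.values["b2"] == pytest.approx(0.625)
        assert ct.values["t"] == pytest.approx(0.375)
        assert ct.values["s1"] == ct.values["s2"] == 0.0

    def test_adjacent_pair_has_no_interior(self, path3):
        ct = compute_nlbc(path3, InputGeneSet({"s": 1.0, "v": 1.0}))
        assert all(v == 0.0 for v in ct.values.values())

    def test_input_node_not_in_network_raises(self, path3):
        with pytest.raises(KeyError):
            compute_nlbc(path3, InputGeneSet({"s": 1.0, "zz": 1.0}))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            net = random_connected_net(rng)
            inputs = random_inputs(rng, net)
            fast = compute_nlbc(net, inputs)
            slow = brute_force_nlbc(net, inputs)
            assert fast.normalizer == pytest.approx(slow.normalizer)
            for v in net.nodes:
                assert fast.values[v] == pytest.approx(
                    slow.values[v], abs=1e-9
                ), f"mismatch at {v}"

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_connected_net(rng)
            ct = compute_nlbc(net, random_inputs(rng, net))
            assert all(-1e-12 <= v <= 1 + 1e-12 for v in ct.values.values())

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(11)
        net = random_connected_net(rng)
        inputs = random_inputs(rng, net)
        scaled = InputGeneSet({g: 37.5 * w for g, w in inputs.weights.items()})
        a = compute_nlbc(net, inputs)
        b = compute_nlbc(net, scaled)
        for v in net.nodes:
            assert a.values[v] == pytest.approx(b.values[v], abs=1e-12)

    def test_uniform_weights_reduce_to_pair_average(self):
        rng = np.random.default_rng(13)
        net = random_connected_net(rng)
        nodes = sorted(net.nodes)
        chosen = [str(g) for g in rng.choice(nodes, size=5, replace=False)]
        inputs = InputGeneSet({g: 1.0 for g in chosen})
        ct = compute_nlbc(net, inputs)
        n_pairs = math.comb(len(chosen), 2)
        for v in net.nodes:
            expected = 0.0
            for i, s in enumerate(chosen):
                dag = bfs_shortest_paths(net, s)
                for t in chosen[i + 1 :]:
                    dag_v = _sigma_through(net, s, t, v)
                    expected += dag_v / dag.sigma[t]
            assert ct.values[v] == pytest.approx(
                expected / n_pairs, abs=1e-9
            )

    def test_disconnected_pair_contributes_zero_but_counts_in_w(self):
        net = net_from_edges([("s", "v"), ("v", "t"), ("p", "q")])
        inputs = InputGeneSet({"s": 1.0, "t": 1.0, "p": 1.0})
        ct = compute_nlbc(net, inputs)
        # w counts all three pairs even though two are disconnected
        assert ct.normalizer == pytest.approx(6.0)
        assert ct.values["v"] == pytest.approx(2.0 / 6.0)


def _sigma_through(net, s, t, v):
    """Number of shortest s-t paths with v strictly interior."""
    if v in (s, t):
        return 0
    dag_s = bfs_shortest_paths(net, s)
    if t not in dag_s.dist or v not in dag_s.dist:
        return 0
    dag_v = bfs_shortest_paths(net, v)
    if t not in dag_v.dist:
        return 0
    if dag_s.dist[v] + dag_v.dist[t] != dag_s.dist[t]:
        return 0
    return dag_s.sigma[v] * dag_v.sigma[t]


class TestStandardBc:
    def test_path_middle(self, path3):
        bc = standard_bc(path3)
        assert bc["v"] == pytest.approx(1.0)
        assert bc["s"] == bc["t"] == 0.0

    def test_star_center_closed_form(self):
        k = 6
        net = net_from_edges([("hub", f"leaf{i}") for i in range(k)])
        assert standard_bc(net)["hub"] == pytest.approx(math.comb(k, 2))

    def test_four_cycle_half_everywhere(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert all(
            v == pytest.approx(0.5) for v in standard_bc(net).values()
        )


class TestLimits:
    def test_global_limit_recovers_standard_bc(self):
        rng = np.random.default_rng(17)
        net = random_connected_net(rng, max_nodes=20)
        inputs = InputGeneSet({g: 1.0 for g in net.nodes})
        ct = compute_nlbc(net, inputs)
        bc = standard_bc(net)
        n_pairs = math.comb(net.n_nodes, 2)
        for v in net.nodes:
            assert ct.values[v] == pytest.approx(
                bc[v] / n_pairs, abs=1e-9
            )

    def test_large_weight_limit_is_single_source_dependency_average(self):
        rng = np.random.default_rng(19)
        net = random_connected_net(rng, max_nodes=20)
        inputs = random_inputs(rng, net, max_size=6)
        genes = inputs.nodes
        favored = genes[0]
        boosted = dict(inputs.weights)
        boosted[favored] = 1e6
        ct = compute_nlbc(net, InputGeneSet(boosted))
        others = [g for g in genes if g != favored]
        for v in net.nodes:
            expected = sum(
                _sigma_through(net, favored, t, v)
                / bfs_shortest_paths(net, favored).sigma[t]
                if t in bfs_shortest_paths(net, favored).dist
                else 0.0
                for t in others
            ) / len(others)
            assert ct.values[v] == pytest.approx(expected, abs=1e-4)


class TestBruteForceGuard:
    def test_rejects_large_networks(self):
        net = net_from_edges([(f"n{i}", f"n{i+1}") for i in range(300)])
        with pytest.raises(ValueError, match="oracle"):
            brute_force_nlbc(net, InputGeneSet({"n0": 1.0, "n5": 1.0}))
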