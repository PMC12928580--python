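"""Driver-directed network expansion and intrinsic-extrinsic shortest paths."""

import random

import networkx as nx
import pytest

from ccclink.errors import ValidationError
from ccclink.iepath import distance_to_signature, expand_to_driver, export_ie, ie_paths
from ccclink.io import intracellular_from_pairs
from ccclink.mining import gspan_mine
from ccclink.network import MCTCNetwork, read_network
from oracles import bfs_distances


def base_net():
    net = MCTCNetwork("s1")
    net.add_edge(("L", "TC"), ("R", "Mac"))
    net.add_edge(("R", "Mac"), ("X", "Mac"))
    return net


class TestExpansion:
    def test_driver_already_present_is_fixed_point(self):
        net = base_net()
        net.add_edge(("DRV", "TC"), ("L", "TC"))
        intra = intracellular_from_pairs([("DRV", "L")])
        res = expand_to_driver(net, "DRV", "TC", intra)
        assert res.rounds == 0 and res.reached
        assert res.network == net

    def test_single_round_adds_exact_frontier(self):
        net = base_net()
        intra = intracellular_from_pairs([("DRV", "L"), ("L", "Y")])
        res = expand_to_driver(net, "DRV", "TC", intra)
        assert res.rounds == 1 and res.reached
        assert res.network.nodes == net.nodes | {("DRV", "TC"), ("Y", "TC")}

    def test_two_round_chain_matches_bfs_ball(self):
        net = base_net()
        intra = intracellular_from_pairs([("DRV", "W"), ("W", "L")])
        res = expand_to_driver(net, "DRV", "TC", intra)
        assert res.rounds == 2 and res.reached
        # oracle: BFS ball of radius 2 in the intracellular graph seeded at
        # the cancer-cell genes of the original network
        dist = bfs_distances(intra.graph, "L")
        expected_new = {(g, "TC") for g, d in dist.items() if 0 < d <= 2}
        assert res.network.nodes == net.nodes | expected_new

    def test_expansion_monotone_and_stopping_round_minimal(self):
        rng = random.Random(4)
        for _ in range(10):
            net = MCTCNetwork("s")
            genes = [f"g{i}" for i in range(12)]
            net.add_edge((genes[0], "TC"), (genes[1], "Mac"))
            intra = intracellular_from_pairs(
                [tuple(rng.sample(genes, 2)) for _ in range(15)]
            )
            driver = "g9"
            if driver not in intra.genes:
                continue
            prev_nodes = set(net.nodes)
            reached_at = None
            for k in range(1, 7):
                res = expand_to_driver(net, driver, "TC", intra, max_rounds=k)
                assert prev_nodes <= res.network.nodes
                prev_nodes = res.network.nodes
                if res.reached and reached_at is None:
                    reached_at = res.rounds
            full = expand_to_driver(net, driver, "TC", intra, max_rounds=6)
            if full.reached:
                dist = bfs_distances(intra.graph, genes[0])
                assert reached_at == dist[driver]

    def test_unknown_driver_rejected(self):
        intra = intracellular_from_pairs([("A", "B")])
        with pytest.raises(ValidationError):
            expand_to_driver(base_net(), "MISSING", "TC", intra)

    def test_unreachable_flagged(self):
        intra = intracellular_from_pairs([("DRV", "ISOLATED")])
        res = expand_to_driver(base_net(), "DRV", "TC", intra)
        assert not res.reached


def _signature_from(nets):
    return gspan_mine(nets, min_support=2)[0]


class TestIEPaths:
    def _setup(self):
        net = base_net()
        net.add_edge(("DRV", "TC"), ("L", "TC"))
        sig_nets = []
        for i in range(2):
            n = MCTCNetwork(f"m{i}")
            n.add_edge(("L", "TC"), ("R", "Mac"))
            sig_nets.append(n)
        return net, _signature_from(sig_nets)

    def test_adjacent_target_length_one(self):
        net, sig = self._setup()
        paths = ie_paths(net, ("DRV", "TC"), sig)
        by_target = {p.target_node: p for p in paths}
        assert by_target[("L", "TC")].length == 1
        assert by_target[("R", "Mac")].length == 2
        assert distance_to_signature(paths) == 1

    def test_all_shortest_returns_every_route(self):
        net, sig = self._setup()
        net.add_edge(("DRV", "TC"), ("Z", "TC"))
        net.add_edge(("Z", "TC"), ("R", "Mac"))  # second 2-hop route to R@Mac
        paths = [p for p in ie_paths(net, ("DRV", "TC"), sig) if p.target_node == ("R", "Mac")]
        assert len(paths) == 2
        one = [p for p in ie_paths(net, ("DRV", "TC"), sig, mode="one") if p.target_node == ("R", "Mac")]
        assert len(one) == 1
        # lexicographically smallest label sequence chosen
        assert one[0].nodes == min((p.nodes for p in paths),
                                   key=lambda ns: tuple(f"{g}@{t}" for g, t in ns))

    def test_lengths_match_bfs_oracle_on_random_graphs(self):
        rng = random.Random(21)
        for _ in range(10):
            net = MCTCNetwork("s")
            genes = [f"g{i}" for i in range(10)]
            for _ in range(18):
                a, b = rng.sample([(g, t) for g in genes for t in ("TC", "Mac")], 2)
                net.add_edge(a, b)
            source = next(iter(sorted(net.nodes)))
            dist = bfs_distances(net.graph, source)
            sig_nets = []
            target = sorted(net.nodes)[-1]
            for i in range(2):
                n = MCTCNetwork(f"m{i}")
                n.add_edge(target, (target[0] + "x", "CTL") if target[1] != "CTL" else (target[0] + "x", "TC"))
                sig_nets.append(n)
            sig = _signature_from(sig_nets)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                paths = ie_paths(net, source, sig)
            for p in paths:
                if p.target_node in dist:
                    assert p.length == dist[p.target_node]
                else:
                    assert p.length is None and p.nodes == ()

    def test_unreachable_target_warns_not_fails(self):
        net, sig = self._setup()
        net.graph.remove_edge(("R", "Mac"), ("X", "Mac"))
        net.graph.remove_edge(("L", "TC"), ("R", "Mac"))
        with pytest.warns(UserWarning, match="unreachable"):
            paths = ie_paths(net, ("DRV", "TC"), sig)
        assert any(p.length is None for p in paths)

    def test_missing_driver_node_rejected(self):
        net, sig = self._setup()
        with pytest.raises(ValidationError):
            ie_paths(net, ("NOPE", "TC"), sig)


class TestExport:
    def _paths(self):
        net, sig = TestIEPaths()._setup()
        return ie_paths(net, ("DRV", "TC"), sig)

    def test_sif_edge_count(self, tmp_path):
        paths = self._paths()
        out = tmp_path / "ie.sif"
        export_ie(paths, out, fmt="SIF")
        lines = [l for l in out.read_text().splitlines() if l]
        # union of a 2-node and a 3-node path sharing edges: 2 unique edges
        assert len(lines) == 2

    def test_empty_paths_valid_file(self, tmp_path):
        out = tmp_path / "ie.tsv"
        export_ie([], out, fmt="TSV")
        assert out.read_text().startswith("source\ttarget")

    def test_graphml_roundtrip(self, tmp_path):
        import networkx as nx

        paths = self._paths()
        out = tmp_path / "ie.graphml"
        export_ie(paths, out, fmt="GraphML")
        g = nx.read_graphml(out)
        labels = {f"{a[0]}@{a[1]}" for p in paths for a in p.nodes}
        assert set(g.nodes) == labels
        edges = {tuple(sorted(e)) for p in paths for e in zip(p.nodes, p.nodes[1:])}
        assert g.number_of_edges() == len(edges)
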