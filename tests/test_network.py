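"""Graph construction and path deduction against exhaustive oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pbsnet import (
    bottleneck_path,
    build_network,
    k_shortest_paths,
    shortest_path,
    terminal_emitter_report,
)
from pbsnet.errors import ConfigurationError, UnknownNodeError
from pbsnet.fixtures import plant_path
from pbsnet.network import edge_weight
from pbsnet.regions import Role

from conftest import build_fixture, point_chromophore, random_positions


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the library's search code)
# ---------------------------------------------------------------------------

def enumerate_simple_paths(edges: dict, source: str, sink: str):
    """Yield every simple path as a node tuple (DFS over an edge dict)."""
    adjacency: dict[str, set] = {}
    for (u, v) in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)

    def walk(path):
        node = path[-1]
        if node == sink:
            yield tuple(path)
            return
        for nbr in adjacency.get(node, ()):  # order irrelevant: we sort later
            if nbr not in path:
                yield from walk(path + [nbr])

    if source in adjacency:
        yield from walk([source])


def oracle_rankings(edges: dict, source: str, sink: str, weight_mode: str):
    """All simple paths sorted by (total weight, node sequence)."""
    scored = []
    for path in enumerate_simple_paths(edges, source, sink):
        steps = [edges[tuple(sorted(p))] for p in zip(path, path[1:])]
        weight = sum(edge_weight(d, weight_mode) for d in steps)
        scored.append((weight, list(path), max(steps)))
    scored.sort(key=lambda s: (s[0], s[1]))
    return scored


def network_from_points(positions, cutoff, weight_mode="distance"):
    labels = [f"N{i:02d}" for i in range(len(positions))]
    chromos = [point_chromophore(lbl, p) for lbl, p in zip(labels, positions)]
    net = build_network(chromos, cutoff=cutoff, weight_mode=weight_mode)
    edges = {(u, v): d for u, v, d, _ in net.edges}
    return net, edges, labels


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_cutoff_excludes_far_pairs(self):
        net, edges, _ = network_from_points([(0, 0, 0), (50, 0, 0)], cutoff=40)
        assert len(edges) == 0

    def test_edges_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        positions = random_positions(rng, 5, scale=50)
        cutoff = 30.0
        net, edges, labels = network_from_points(positions, cutoff)
        expected = set()
        for i, j in itertools.combinations(range(5), 2):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d <= cutoff:
                expected.add(tuple(sorted((labels[i], labels[j]))))
        assert set(edges) == expected

    def test_weight_modes(self):
        net, edges, labels = network_from_points([(0, 0, 0), (10, 0, 0)], 40,
                                                 weight_mode="distance_power6")
        (u, v, d, w), = net.edges
        assert w == pytest.approx(d**6)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            build_network([], cutoff=40)
        with pytest.raises(ConfigurationError):
            build_network([point_chromophore("A", (0, 0, 0))], cutoff=-1)

    def test_terminal_emitter_flags(self):
        chromos = [
            point_chromophore("A", (0, 0, 0), Role.CPCB),
            point_chromophore("B", (10, 0, 0), Role.APCD),
            point_chromophore("C", (20, 0, 0), Role.APCE),
        ]
        net = build_network(chromos, cutoff=40)
        assert net.terminal_emitters() == ["B/301/TBL", "C/301/TBL"]
        assert net.terminal_emitters(Role.APCD) == ["B/301/TBL"]


# ---------------------------------------------------------------------------
# path search vs oracle
# ---------------------------------------------------------------------------

class TestPathsAgainstOracle:
    @pytest.mark.parametrize("weight_mode", ["distance", "distance_power6"])
    def test_shortest_and_bottleneck_on_random_graphs(self, weight_mode):
        """On 6-node random geometric graphs all searches match enumeration."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            positions = random_positions(rng, 6, scale=45)
            net, edges, labels = network_from_points(positions, cutoff=30,
                                                     weight_mode=weight_mode)
            source, sink = labels[0] + "/301/TBL", labels[-1] + "/301/TBL"
            edge_ids = {tuple(sorted((u, v))): d for (u, v), d in edges.items()}
            ranked = oracle_rankings(edge_ids, source, sink, weight_mode)
            got = shortest_path(net, source, sink)
            if not ranked:
                assert got is None
                assert bottleneck_path(net, source, sink) is None
                assert k_shortest_paths(net, source, sink, 3) == []
                continue
            assert got.nodes == ranked[0][1]
            assert got.total_weight == pytest.approx(ranked[0][0])
            # k-shortest agree with the oracle's top-k
            k = min(5, len(ranked))
            got_k = k_shortest_paths(net, source, sink, k)
            assert [p.nodes for p in got_k] == [r[1] for r in ranked[:k]]
            # bottleneck: min over paths of max edge, ties by weight then order
            best_b = sorted(ranked, key=lambda s: (s[2], s[0], s[1]))[0]
            got_b = bottleneck_path(net, source, sink)
            assert got_b.bottleneck == pytest.approx(best_b[2])

    def test_k1_equals_shortest(self):
        rng = np.random.default_rng(7)
        net, _, labels = network_from_points(random_positions(rng, 6, 40), cutoff=35)
        s, t = labels[0] + "/301/TBL", labels[3] + "/301/TBL"
        sp = shortest_path(net, s, t)
        if sp is not None:
            assert k_shortest_paths(net, s, t, 1)[0].nodes == sp.nodes

    def test_source_equals_sink(self):
        net, _, labels = network_from_points([(0, 0, 0), (10, 0, 0)], 40)
        node = labels[0] + "/301/TBL"
        res = shortest_path(net, node, node)
        assert res.nodes == [node]
        assert res.total_weight == 0.0
        assert bottleneck_path(net, node, node).bottleneck == 0.0

    def test_disconnected_returns_none(self):
        net, _, labels = network_from_points([(0, 0, 0), (500, 0, 0)], 40)
        a, b = (lbl + "/301/TBL" for lbl in labels)
        assert shortest_path(net, a, b) is None
        assert bottleneck_path(net, a, b) is None
        assert k_shortest_paths(net, a, b, 4) == []

    def test_unknown_node_raises(self):
        net, _, _ = network_from_points([(0, 0, 0), (10, 0, 0)], 40)
        with pytest.raises(UnknownNodeError, match="nope"):
            shortest_path(net, "nope", "N00/301/TBL")

    def test_bottleneck_prefers_two_short_hops(self):
        """Direct 30 Å edge loses to an 18+18 Å relay under the minimax rule."""
        positions = [(0, 0, 0), (15, 9.95, 0), (30, 0, 0)]
        net, edges, labels = network_from_points(positions, cutoff=31)
        a, c = labels[0] + "/301/TBL", labels[2] + "/301/TBL"
        direct = net.edge_distance(a, c)
        res = bottleneck_path(net, a, c)
        assert len(res.nodes) == 3
        assert res.bottleneck < direct

    def test_weight_power6_prefers_nearest_neighbour_stepping(self):
        """d⁶ weighting picks two hops when both are below d·2^(-1/6)."""
        d = 30.0
        hop = d * 2 ** (-1 / 6) * 0.98  # just under the break-even hop length
        y = np.sqrt(hop**2 - (d / 2) ** 2)
        net, _, labels = network_from_points(
            [(0, 0, 0), (d / 2, y, 0), (d, 0, 0)], cutoff=d + 1,
            weight_mode="distance_power6",
        )
        res = shortest_path(net, labels[0] + "/301/TBL", labels[2] + "/301/TBL")
        assert len(res.nodes) == 3

    def test_adding_edge_never_increases_shortest_weight(self):
        """Monotonicity: raising the cutoff only adds edges, never worse paths."""
        rng = np.random.default_rng(13)
        positions = random_positions(rng, 7, scale=55)
        for mode in ("distance", "distance_power6"):
            net_small, _, labels = network_from_points(positions, cutoff=25, weight_mode=mode)
            net_big, _, _ = network_from_points(positions, cutoff=45, weight_mode=mode)
            for i, j in itertools.combinations(range(7), 2):
                a = labels[i] + "/301/TBL"
                b = labels[j] + "/301/TBL"
                small = shortest_path(net_small, a, b)
                big = shortest_path(net_big, a, b)
                if small is not None:
                    assert big is not None
                    assert big.total_weight <= small.total_weight + 1e-9


# ---------------------------------------------------------------------------
# planted paths and emitter reporting
# ---------------------------------------------------------------------------

class TestPlantedRecovery:
    def test_recovers_planted_chain(self, tmp_path):
        for seed in range(5):
            spec, expected = plant_path(6, step=25, cutoff=40, seed=seed)
            _, model, chromos = build_fixture(tmp_path, spec, f"pp{seed}")
            net = build_network(chromos, cutoff=40)
            res = shortest_path(net, expected[0], expected[-1])
            assert res.nodes == expected

    def test_terminal_emitter_report_trace(self, tmp_path):
        """The region trace follows the planted rod -> core layout."""
        spec, expected = plant_path(5, step=25, cutoff=40, seed=3)
        _, model, chromos = build_fixture(tmp_path, spec, "trace")
        net = build_network(chromos, cutoff=40)
        report = terminal_emitter_report(net)
        row = report.loc[report["source"] == expected[0]].iloc[0]
        assert row["apcd_path"] == ">".join(expected)
        trace = row["apcd_region_trace"].split(">")
        assert trace[:-1] == ["rod/R1"] * (len(expected) - 1)
        assert trace[-1] == "core/A4"

    def test_apcf_on_route_flag(self):
        """ApcF flagged when it is the unique sub-cutoff step toward ApcE."""
        chromos = [
            point_chromophore("A", (0, 0, 0), Role.CPCB),
            point_chromophore("B", (20, 0, 0), Role.APCF),
            point_chromophore("C", (40, 0, 0), Role.APCE),
        ]
        net = build_network(chromos, cutoff=25)
        report = terminal_emitter_report(net, sources=["A/301/TBL"])
        assert bool(report.iloc[0]["apcf_on_apce_route"]) is True

    def test_no_emitters_raises(self):
        net, _, _ = network_from_points([(0, 0, 0), (10, 0, 0)], 40)
        with pytest.raises(ConfigurationError):
            terminal_emitter_report(net)
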