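"""Distance-weighted chromophore graphs and energy-transfer path deduction.

Excitation migrating through a phycobilisome hops between bilins with a
Förster-type efficiency that falls off steeply (∝ R⁻⁶) with distance, so
published transfer routes are deduced from pairwise bilin proximity.  The
network built here is undirected, with edges between chromophore pairs
closer than a cutoff (default 40 Å — the separation still treated as
permissive for inter-complex transfer).  "Most probable path" is
operationalised three ways:

* additive distance (``weight_mode="distance"``): literal shortest path;
* additive d⁶ (``weight_mode="distance_power6"``, the default): penalises
  long hops the way a Förster-type rate would, so the optimum follows
  nearest-neighbour stepping;
* bottleneck (:func:`bottleneck_path`): minimise the longest single hop.

All tie-breaking is deterministic: among equal-weight optima the
lexicographically smallest node-id sequence wins.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chromophore import Chromophore, DEFAULT_METRIC, DistanceMetric, chromophore_distance
from .errors import ConfigurationError, UnknownNodeError
from .regions import Role, TERMINAL_EMITTER_ROLES

DEFAULT_CUTOFF = 40.0  # Å
WEIGHT_MODES = ("distance", "distance_power6")


@dataclass
class PathResult:
    """One path through the chromophore graph."""

    nodes: list[str]
    step_distances: list[float]
    total_weight: float
    bottleneck: float

    @property
    def n_steps(self) -> int:
        return len(self.step_distances)

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "step_distances": list(self.step_distances),
            "total_weight": self.total_weight,
            "bottleneck": self.bottleneck,
        }


@dataclass
class EETNetwork:
    """Undirected chromophore graph with distance-derived edge weights."""

    graph: nx.Graph
    cutoff: float
    metric: DistanceMetric
    weight_mode: str
    chromophores: dict[str, Chromophore] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, data["distance"], data["weight"]))
        return sorted(out)

    def terminal_emitters(self, role: Optional[Role] = None) -> list[str]:
        """Node ids flagged as terminal emitters, optionally of one role."""
        out = []
        for node, data in self.graph.nodes(data=True):
            if not data.get("is_terminal_emitter"):
                continue
            if role is not None and data.get("role") != role.value:
                continue
            out.append(node)
        return sorted(out)

    def node_role(self, node: str) -> str:
        return self.graph.nodes[node].get("role", Role.OTHER.value)

    def node_region(self, node: str) -> str:
        return self.graph.nodes[node].get("region", "unplaced")

    def _check_node(self, node: str) -> None:
        if node not in self.graph:
            raise UnknownNodeError(f"unknown chromophore id {node!r}")

    def edge_distance(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["distance"])

    def path_result(self, nodes: Sequence[str]) -> PathResult:
        steps = [self.edge_distance(u, v) for u, v in zip(nodes, nodes[1:])]
        weights = [self.graph.edges[u, v]["weight"] for u, v in zip(nodes, nodes[1:])]
        return PathResult(
            nodes=list(nodes),
            step_distances=steps,
            total_weight=float(sum(weights)),
            bottleneck=float(max(steps)) if steps else 0.0,
        )


def edge_weight(distance: float, weight_mode: str) -> float:
    if weight_mode == "distance":
        return float(distance)
    if weight_mode == "distance_power6":
        return float(distance) ** 6
    raise ConfigurationError(
        f"unknown weight_mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
    )


def build_network(
    chromophores: Sequence[Chromophore],
    cutoff: float = DEFAULT_CUTOFF,
    metric: DistanceMetric = DEFAULT_METRIC,
    weight_mode: str = "distance_power6",
) -> EETNetwork:
    """All-pairs distance graph with edges at ``distance <= cutoff``.

    Terminal-emitter flags are set on bilins whose parent role is ApcD or
    ApcE (the two exits toward the photosystems).  Node ordering and edge
    enumeration are deterministic.
    """
    if len(chromophores) < 1:
        raise ConfigurationError("build_network needs at least one chromophore")
    if cutoff <= 0:
        raise ConfigurationError(f"cutoff must be positive, got {cutoff}")
    if weight_mode not in WEIGHT_MODES:
        raise ConfigurationError(
            f"unknown weight_mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
        )
    ordered = sorted(chromophores, key=lambda c: c.label)
    g = nx.Graph()
    for c in ordered:
        g.add_node(
            c.label,
            role=c.parent_role.value,
            region=c.region.label,
            is_terminal_emitter=c.parent_role in TERMINAL_EMITTER_ROLES,
        )
    for c1, c2 in itertools.combinations(ordered, 2):
        d = chromophore_distance(c1, c2, metric)
        if d <= cutoff:
            g.add_edge(c1.label, c2.label, distance=d, weight=edge_weight(d, weight_mode))
    return EETNetwork(
        graph=g,
        cutoff=cutoff,
        metric=metric,
        weight_mode=weight_mode,
        chromophores={c.label: c for c in ordered},
    )


# ---------------------------------------------------------------------------
# path search
# ---------------------------------------------------------------------------

def _dijkstra_lexi(
    network: EETNetwork,
    source: str,
    sink: str,
    extend: Callable[[tuple, float, float], tuple],
    start_key: tuple,
) -> Optional[list[str]]:
    """Generic label-setting search with composite, lexicographic keys.

    ``extend(key, edge_weight, edge_distance)`` must be monotone: the
    extended key never compares smaller than the key it extends.  The path
    node sequence is the last component of the key, which makes equal-cost
    ties resolve to the lexicographically smallest sequence.
    """
    heap: list[tuple] = [start_key + ((source,),)]
    done: set[str] = set()
    while heap:
        entry = heapq.heappop(heap)
        key, path = entry[:-1], entry[-1]
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == sink:
            return list(path)
        for nbr in network.graph.neighbors(node):
            if nbr in done:
                continue
            data = network.graph.edges[node, nbr]
            new_key = extend(key, data["weight"], data["distance"])
            heapq.heappush(heap, new_key + (path + (nbr,),))
    return None


def shortest_path(network: EETNetwork, source: str, sink: str) -> Optional[PathResult]:
    """Minimum-total-weight path under the network's weight mode.

    Returns ``None`` when source and sink are disconnected.  Among
    equal-weight optima the lexicographically smallest node sequence is
    returned.
    """
    network._check_node(source)
    network._check_node(sink)
    if source == sink:
        return PathResult(nodes=[source], step_distances=[], total_weight=0.0, bottleneck=0.0)
    path = _dijkstra_lexi(
        network,
        source,
        sink,
        extend=lambda key, w, d: (key[0] + w,),
        start_key=(0.0,),
    )
    return network.path_result(path) if path else None


def k_shortest_paths(
    network: EETNetwork, source: str, sink: str, k: int
) -> list[PathResult]:
    """The ``k`` best loopless paths in non-decreasing total weight.

    Yen-style enumeration (via networkx) with deterministic re-sorting:
    ties in total weight are ordered by node sequence.  Fewer than ``k``
    results are returned when fewer simple paths exist.
    """
    network._check_node(source)
    network._check_node(sink)
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if source == sink:
        return [shortest_path(network, source, sink)]
    if not nx.has_path(network.graph, source, sink):
        return []
    collected: list[PathResult] = []
    gen = nx.shortest_simple_paths(network.graph, source, sink, weight="weight")
    # Yen's algorithm yields non-decreasing weights; keep pulling while a
    # later path could still tie with the current k-th best.
    for nodes in gen:
        res = network.path_result(nodes)
        if len(collected) >= k and res.total_weight > collected[k - 1].total_weight + 1e-12:
            break
        collected.append(res)
        collected.sort(key=lambda r: (r.total_weight, r.nodes))
    return collected[:k]


def bottleneck_path(network: EETNetwork, source: str, sink: str) -> Optional[PathResult]:
    """Path minimising the longest hop; ties by total weight, then node order."""
    network._check_node(source)
    network._check_node(sink)
    if source == sink:
        return PathResult(nodes=[source], step_distances=[], total_weight=0.0, bottleneck=0.0)
    path = _dijkstra_lexi(
        network,
        source,
        sink,
        extend=lambda key, w, d: (max(key[0], d), key[1] + w),
        start_key=(0.0, 0.0),
    )
    return network.path_result(path) if path else None


# ---------------------------------------------------------------------------
# terminal-emitter reporting
# ---------------------------------------------------------------------------

def _best_path_to_role(
    network: EETNetwork, source: str, role: Role
) -> Optional[PathResult]:
    best: Optional[PathResult] = None
    for target in network.terminal_emitters(role):
        res = shortest_path(network, source, target)
        if res is None:
            continue
        if best is None or (res.total_weight, res.nodes) < (best.total_weight, best.nodes):
            best = res
    return best


def region_trace(network: EETNetwork, path: PathResult) -> list[str]:
    """Ordered region labels along a path (consecutive duplicates kept)."""
    return [network.node_region(n) for n in path.nodes]


def terminal_emitter_report(
    network: EETNetwork,
    sources: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Best route from each source bilin to each terminal-emitter class.

    ``sources`` defaults to every rod bilin (nodes whose region compartment
    is ``rod``).  For each source the minimum-weight route to the nearest
    ApcD bilin and to the nearest ApcE (α-LCM) bilin is reported, along with
    the ordered region trace and whether the ApcF bilin lies on the ApcE
    route (the conserved hand-off into the membrane-facing emitter).
    """
    if not network.terminal_emitters():
        raise ConfigurationError(
            "network has no terminal emitters (no ApcD/ApcE-parented bilins)"
        )
    if sources is None:
        sources = [
            n for n in network.nodes if network.node_region(n).startswith("rod")
        ]
    else:
        sources = list(sources)
        for s in sources:
            network._check_node(s)

    rows = []
    for source in sorted(sources):
        row: dict = {"source": source, "source_region": network.node_region(source)}
        for role, tag in ((Role.APCD, "apcd"), (Role.APCE, "apce")):
            res = _best_path_to_role(network, source, role)
            if res is None:
                row[f"{tag}_target"] = None
                row[f"{tag}_path"] = None
                row[f"{tag}_total_weight"] = np.nan
                row[f"{tag}_bottleneck"] = np.nan
                row[f"{tag}_region_trace"] = None
            else:
                row[f"{tag}_target"] = res.nodes[-1]
                row[f"{tag}_path"] = ">".join(res.nodes)
                row[f"{tag}_total_weight"] = res.total_weight
                row[f"{tag}_bottleneck"] = res.bottleneck
                row[f"{tag}_region_trace"] = ">".join(region_trace(network, res))
            if tag == "apce":
                row["apcf_on_apce_route"] = bool(
                    res is not None
                    and any(
                        network.node_role(n) == Role.APCF.value for n in res.nodes[1:-1]
                    )
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def to_graphml(network: EETNetwork, path) -> None:
    """Write the network as GraphML (role/region/emitter flag on nodes)."""
    g = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        g.add_node(
            node,
            role=data.get("role", ""),
            region=data.get("region", ""),
            is_terminal_emitter=bool(data.get("is_terminal_emitter", False)),
        )
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(u, v, distance=float(data["distance"]), weight=float(data["weight"]))
    nx.write_graphml(g, str(path))


def edge_table(network: EETNetwork) -> pd.DataFrame:
    rows = [
        {"id1": u, "id2": v, "distance": d, "weight": w}
        for u, v, d, w in network.edges
    ]
    return pd.DataFrame(rows, columns=["id1", "id2", "distance", "weight"])
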