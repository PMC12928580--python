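"""Intrinsic-extrinsic (IE) signaling paths.

A communication network is centered on ligand-receptor pairs, so a cancer
driver gene need not appear in it.  To connect the driver to its associated
CCC signatures, the network is first *expanded*: in breadth-first rounds,
each node's first-order neighbors from the intracellular gene-interaction
network are incorporated (within the cancer cell type by default) until the
driver node enters the node set.  IE paths are then the shortest paths from
the driver node to each node of a signature in the expanded network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .errors import ParameterError, ValidationError
from .io import IntracellularNetwork
from .mining import FrequentSubnetwork
from .network import INTRA, MCTCNetwork, Node, node_label

__all__ = ["IEPath", "ExpansionResult", "expand_to_driver", "ie_paths", "export_ie"]


@dataclass(frozen=True)
class IEPath:
    """An ordered shortest path from the driver node to a signature node.

    ``nodes`` is empty (and ``length`` None) when the target is absent from
    or unreachable in the expanded network.
    """

    driver_node: Node
    target_node: Node
    nodes: tuple[Node, ...]
    length: int | None

    @property
    def found(self) -> bool:
        return self.length is not None


@dataclass
class ExpansionResult:
    network: MCTCNetwork
    rounds: int
    reached: bool


def expand_to_driver(
    net: MCTCNetwork,
    driver: str,
    cancer_type: str,
    intra: IntracellularNetwork,
    max_rounds: int = 6,
    all_types: bool = False,
) -> ExpansionResult:
    """Grow the network with intracellular neighbors until the driver appears.

    Round k adds, for every node present after round k-1 (restricted to the
    cancer cell type unless ``all_types``), its first-order neighbors in the
    intracellular network, as intracellular edges within that node's cell
    type.  Expansion stops at the first round whose node set contains
    ``(driver, cancer_type)``; if the driver is not reached within
    ``max_rounds`` the fully expanded network is returned flagged
    unreachable.
    """
    if max_rounds < 1:
        raise ParameterError(f"max_rounds must be >= 1, got {max_rounds}")
    if driver not in intra.genes:
        raise ValidationError(f"driver {driver!r} absent from the intracellular network")
    target: Node = (driver, cancer_type)
    expanded = MCTCNetwork(net.sample_id, net.graph.copy())
    if target in expanded.graph:
        return ExpansionResult(expanded, rounds=0, reached=True)
    for rnd in range(1, max_rounds + 1):
        current = list(expanded.graph.nodes)
        grew = False
        for gene, ctype in current:
            if not all_types and ctype != cancer_type:
                continue
            for nb in sorted(intra.neighbors(gene)):
                if not expanded.graph.has_edge((gene, ctype), (nb, ctype)):
                    expanded.add_edge((gene, ctype), (nb, ctype), INTRA)
                    grew = True
        if target in expanded.graph:
            return ExpansionResult(expanded, rounds=rnd, reached=True)
        if not grew:  # fixed point short of the driver
            return ExpansionResult(expanded, rounds=rnd, reached=False)
    return ExpansionResult(expanded, rounds=max_rounds, reached=False)


def ie_paths(
    expanded: MCTCNetwork,
    driver_node: Node,
    signature: FrequentSubnetwork,
    mode: str = "all_shortest",
) -> list[IEPath]:
    """Shortest path(s) from the driver node to every signature node.

    ``mode='all_shortest'`` returns every minimal path per target;
    ``mode='one'`` returns the lexicographically smallest (by node-label
    sequence) minimal path per target.  Absent or unreachable targets are
    reported with an empty path and a warning rather than an error.
    """
    if mode not in ("all_shortest", "one"):
        raise ParameterError(f"unknown mode {mode!r}")
    if driver_node not in expanded.graph:
        raise ValidationError(f"driver node {driver_node} not in expanded network")
    out: list[IEPath] = []
    for target in signature.nodes():
        if target not in expanded.graph or not nx.has_path(expanded.graph, driver_node, target):
            warnings.warn(
                f"signature node {node_label(target)} absent or unreachable", stacklevel=2
            )
            out.append(IEPath(driver_node, target, (), None))
            continue
        paths = [
            tuple(p) for p in nx.all_shortest_paths(expanded.graph, driver_node, target)
        ]
        paths.sort(key=lambda p: tuple(node_label(n) for n in p))
        if mode == "one":
            paths = paths[:1]
        for p in paths:
            out.append(IEPath(driver_node, target, p, len(p) - 1))
    return out


def distance_to_signature(paths: list[IEPath]) -> int | None:
    """Summary distance: minimum path length over reachable signature nodes."""
    lengths = [p.length for p in paths if p.length is not None]
    return min(lengths) if lengths else None


def export_ie(paths: list[IEPath], path: str, fmt: str = "SIF") -> None:
    """Write the union-of-paths subnetwork for visualization.

    Node attributes record gene, cell type, and whether the node is a
    signature endpoint.  Overlapping paths are deduplicated.  An empty path
    list yields an empty but valid file.
    """
    if fmt not in ("SIF", "GraphML", "TSV"):
        raise ParameterError(f"unknown export format {fmt!r}")
    g = nx.Graph()
    targets = {p.target_node for p in paths}
    for p in paths:
        for node in p.nodes:
            g.add_node(
                node_label(node),
                gene=node[0],
                cell_type=node[1],
                on_signature=node in targets,
            )
        for a, b in zip(p.nodes, p.nodes[1:]):
            g.add_edge(node_label(a), node_label(b))
    if fmt == "GraphML":
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        if fmt == "TSV":
            fh.write("source\ttarget\n")
        for a, b in sorted(map(sorted, g.edges())):
            if fmt == "SIF":
                fh.write(f"{a}\tie\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
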