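"""Multi-cell-type communication (MCTC) networks.

An MCTC network describes one (pseudo-)sample's inferred signaling among a
set of cell types.  Nodes are (gene, cell type) pairs; edges are undirected
and typed ``intracellular`` (same cell type) or ``intercellular`` (different
cell types).  Node prizes and edge weights from upstream inference tools are
deliberately discarded: downstream frequent-subnetwork mining operates on
unweighted labeled graphs.

Per-cell-type-pair networks come from a pluggable backend:

* :class:`ExternalBackend` ingests precomputed edge lists (e.g. from a
  dedicated signal-transduction inference tool run outside this package);
* :class:`LiteBackend` builds a simple co-expression network from a
  ligand-receptor pair table and an intracellular interaction network.

The per-pair networks are then unioned into one MCTC network per sample.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InputFormatError, ParameterError, ValidationError
from .io import AnnotatedCohort, IntracellularNetwork, LigandReceptorTable
from .pseudosample import PseudoSample

__all__ = [
    "Node",
    "MCTCNetwork",
    "read_network",
    "write_network",
    "union_networks",
    "lite_pairwise_network",
    "NetworkBackend",
    "LiteBackend",
    "ExternalBackend",
]

Node = tuple[str, str]  # (gene symbol, cell type)

INTRA = "intracellular"
INTER = "intercellular"


def node_label(node: Node) -> str:
    """Canonical string label ``gene@celltype`` used for mining and display."""
    return f"{node[0]}@{node[1]}"


def parse_label(label: str) -> Node:
    gene, _, ctype = label.rpartition("@")
    return gene, ctype


def _edge_kind(a: Node, b: Node) -> str:
    return INTRA if a[1] == b[1] else INTER


@dataclass
class MCTCNetwork:
    """One sample's unweighted multi-cell-type communication network."""

    sample_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, a: Node, b: Node, kind: str | None = None) -> None:
        if a == b:
            raise ValidationError(f"self-loop on node {a}")
        expected = _edge_kind(a, b)
        if kind is None:
            kind = expected
        elif kind != expected:
            raise ValidationError(
                f"edge {a}–{b} tagged {kind!r} but cell types imply {expected!r}"
            )
        prev = self.graph.get_edge_data(a, b)
        if prev is not None and prev["kind"] != kind:
            raise ValidationError(f"edge {a}–{b} has conflicting kinds")
        self.graph.add_edge(a, b, kind=kind)

    @property
    def nodes(self) -> set[Node]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[Node, Node, str]]:
        """Edges as (node, node, kind) with endpoints in sorted order."""
        return {
            (*sorted((a, b)), data["kind"]) for a, b, data in self.graph.edges(data=True)
        }

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MCTCNetwork):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


# ----------------------------------------------------------------------
# file formats


def read_network(path: str | Path, sample_id: str) -> MCTCNetwork:
    """Read an edge-list TSV: geneA, typeA, geneB, typeB[, kind[, weight...]].

    The kind column is validated against cell-type equality when present and
    inferred from it when absent; any trailing weight columns are discarded.
    """
    net = MCTCNetwork(sample_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("geneA", "gene_a"):  # header
                continue
            if len(parts) < 4:
                raise InputFormatError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
            a = (parts[0].strip(), parts[1].strip())
            b = (parts[2].strip(), parts[3].strip())
            kind = parts[4].strip() if len(parts) >= 5 and parts[4].strip() else None
            if kind is not None and kind not in (INTRA, INTER):
                raise InputFormatError(f"{path}:{lineno}: unknown edge kind {kind!r}")
            try:
                net.add_edge(a, b, kind)
            except ValidationError as exc:
                raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_network(net: MCTCNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\ttypeA\tgeneB\ttypeB\tkind\n")
        for a, b, kind in sorted(net.edges):
            fh.write(f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{kind}\n")


def write_sif(net: MCTCNetwork, path: str | Path) -> None:
    """SIF export (``source<TAB>kind<TAB>target``) for Cytoscape."""
    with open(path, "w") as fh:
        for a, b, kind in sorted(net.edges):
            fh.write(f"{node_label(a)}\t{kind}\t{node_label(b)}\n")


def write_graphml(net: MCTCNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node_label(node), gene=node[0], cell_type=node[1])
    for a, b, kind in net.edges:
        g.add_edge(node_label(a), node_label(b), kind=kind)
    nx.write_graphml(g, path)


# ----------------------------------------------------------------------
# construction


def union_networks(nets: Sequence[MCTCNetwork], sample_id: str | None = None) -> MCTCNetwork:
    """Union of per-cell-type-pair networks into one MCTC network.

    Node and edge sets are unioned with set semantics; an edge occurring in
    several inputs with conflicting kind tags is an error.
    """
    if not nets:
        raise ParameterError("cannot union an empty list of networks")
    ids = {n.sample_id for n in nets}
    if sample_id is None:
        if len(ids) > 1:
            raise ValidationError(f"networks belong to different samples: {sorted(ids)}")
        sample_id = nets[0].sample_id
    out = MCTCNetwork(sample_id)
    for net in nets:
        out.graph.add_nodes_from(net.graph.nodes)
        for a, b, data in net.graph.edges(data=True):
            out.add_edge(a, b, data["kind"])
    return out


def _expressed_fraction(
    expr: pd.DataFrame, gene: str, cells: Sequence[str]
) -> float:
    """Fraction of a cell multiset (with multiplicity) expressing a gene."""
    if gene not in expr.index or len(cells) == 0:
        return 0.0
    vals = expr.loc[gene, list(cells)]
    return float((vals.to_numpy() > 0).mean())


def lite_pairwise_network(
    ps: PseudoSample,
    cohort: AnnotatedCohort,
    lr_table: LigandReceptorTable,
    intra: IntracellularNetwork,
    type_a: str,
    type_b: str,
    expr_frac_threshold: float = 0.1,
    hop_radius: int = 1,
) -> MCTCNetwork:
    """Expression-threshold communication network for one cell-type pair.

    An intercellular edge (L@A)–(R@B) is added for every ligand-receptor
    pair with the ligand expressed in at least ``expr_frac_threshold`` of
    type-A cells of the pseudo-sample and the receptor likewise in type-B
    cells (and symmetrically with the roles of A and B swapped).  Both genes
    must have passed the per-type retention filter.  Around the ligands and
    receptors actually used within each type, intracellular edges from
    ``intra`` between retained genes are added up to ``hop_radius`` hops.

    This is a deliberately simple backend: it captures co-expression of
    annotated ligand-receptor pairs, not information-theoretic signaling
    evidence, and exists so the full pipeline runs self-contained.
    """
    if type_a == type_b:
        raise ParameterError("pairwise network requires two distinct cell types")
    if len(lr_table) == 0:
        raise ParameterError("empty ligand-receptor table")
    net = MCTCNetwork(ps.sample_id)
    cells = {t: ps.cells_by_type.get(t, ()) for t in (type_a, type_b)}

    def ok(gene: str, ctype: str) -> bool:
        return (
            cohort.is_retained(gene, ctype)
            and _expressed_fraction(cohort.expr, gene, cells[ctype]) >= expr_frac_threshold
        )

    used: dict[str, set[str]] = {type_a: set(), type_b: set()}
    for lig, rec in lr_table.pairs:
        for sender, receiver in ((type_a, type_b), (type_b, type_a)):
            if ok(lig, sender) and ok(rec, receiver):
                net.add_edge((lig, sender), (rec, receiver), INTER)
                used[sender].add(lig)
                used[receiver].add(rec)

    # intracellular neighborhoods of the used ligands/receptors
    for ctype, seeds in used.items():
        ball = dict.fromkeys(seeds)  # gene -> hop distance (ordered)
        frontier = set(seeds)
        dist = {g: 0 for g in seeds}
        for hop in range(1, hop_radius + 1):
            nxt = set()
            for g in frontier:
                for nb in intra.neighbors(g):
                    if cohort.is_retained(nb, ctype) and nb not in dist:
                        dist[nb] = hop
                        nxt.add(nb)
            frontier = nxt
        for a, b in intra.graph.edges:
            if a in dist and b in dist:
                net.add_edge((a, ctype), (b, ctype), INTRA)
    return net


# ----------------------------------------------------------------------
# backends


class NetworkBackend(abc.ABC):
    """Contract: produce one MCTC network per pseudo-sample."""

    @abc.abstractmethod
    def network_for(self, ps: PseudoSample) -> MCTCNetwork: ...

    def networks(self, samples: Iterable[PseudoSample]) -> list[MCTCNetwork]:
        return [self.network_for(ps) for ps in samples]


class LiteBackend(NetworkBackend):
    """Build MCTC networks from the built-in co-expression rule."""

    def __init__(
        self,
        cohort: AnnotatedCohort,
        lr_table: LigandReceptorTable,
        intra: IntracellularNetwork,
        focal_types: Sequence[str],
        expr_frac_threshold: float = 0.1,
        hop_radius: int = 1,
    ) -> None:
        self.cohort = cohort
        self.lr_table = lr_table
        self.intra = intra
        self.focal_types = list(focal_types)
        self.expr_frac_threshold = expr_frac_threshold
        self.hop_radius = hop_radius

    def network_for(self, ps: PseudoSample) -> MCTCNetwork:
        pair_nets = [
            lite_pairwise_network(
                ps,
                self.cohort,
                self.lr_table,
                self.intra,
                a,
                b,
                self.expr_frac_threshold,
                self.hop_radius,
            )
            for i, a in enumerate(self.focal_types)
            for b in self.focal_types[i + 1 :]
        ]
        return union_networks(pair_nets, sample_id=ps.sample_id)


class ExternalBackend(NetworkBackend):
    """Ingest precomputed per-sample networks from edge-list files."""

    def __init__(self, paths: Mapping[str, str | Path]) -> None:
        self.paths = dict(paths)

    def network_for(self, ps: PseudoSample) -> MCTCNetwork:
        if ps.sample_id not in self.paths:
            raise InputFormatError(f"no precomputed network for sample {ps.sample_id!r}")
        return read_network(self.paths[ps.sample_id], ps.sample_id)
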