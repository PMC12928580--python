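"""Frequent connected subnetwork mining over MCTC networks (gSpan).

Candidate cell-cell communication signatures are the connected labeled
subgraphs that recur across the cohort's per-sample communication networks.
Mining follows gSpan: patterns are grown depth-first by rightmost-path
extension, each growth step is represented as a DFS-code edge
``(i, j, label_i, edge_kind, label_j)`` over DFS discovery indices, and a
branch is pruned unless its DFS code is the *minimum* code of the pattern it
encodes, which guarantees each isomorphism class is enumerated exactly once.

Node labels are ``gene@celltype`` strings; edge labels are the
intracellular/intercellular kind tags.  Containment is label-preserving
subgraph isomorphism (occurrences need not be induced).  Support is the
number of distinct (pseudo-)samples whose network contains the pattern; the
exact support set is tracked through embedding lists.

The mined patterns are one-hot encoded into a binary occurrence matrix F
(pseudo-samples x patterns, ``f_ij = 1`` iff sample i's network contains
pattern j), the extrinsic feature matrix consumed by association testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import ParameterError, ValidationError
from .network import MCTCNetwork, Node, node_label, parse_label

__all__ = [
    "FrequentSubnetwork",
    "gspan_mine",
    "encode_occurrence",
    "choose_support",
]

# A DFS-code edge: (i, j, label_i, edge_label, label_j); forward iff i < j.
CodeEdge = tuple[int, int, str, str, str]
Code = tuple[CodeEdge, ...]


@dataclass(frozen=True)
class FrequentSubnetwork:
    """A frequent connected labeled subgraph with its exact support set.

    ``canonical_code`` is the minimum DFS code; ``node_labels[k]`` is the
    label of DFS vertex k; ``edge_list`` holds (i, j, kind) index triples.
    """

    pattern_id: int
    canonical_code: Code
    node_labels: tuple[str, ...]
    edge_list: tuple[tuple[int, int, str], ...]
    support_set: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.support_set)

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def nodes(self) -> tuple[Node, ...]:
        return tuple(parse_label(lbl) for lbl in self.node_labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, lbl in enumerate(self.node_labels):
            g.add_node(k, label=lbl)
        for i, j, kind in self.edge_list:
            g.add_edge(i, j, kind=kind)
        return g

    def signature(self) -> str:
        """Field notation, e.g. ``HGF(Mph) – MET(TC)``."""
        parts = []
        for i, j, _ in self.edge_list:
            gi, ti = parse_label(self.node_labels[i])
            gj, tj = parse_label(self.node_labels[j])
            parts.append(f"{gi}({ti}) – {gj}({tj})")
        return "; ".join(parts)


# ----------------------------------------------------------------------
# DFS-code machinery


def _ext_key(t: CodeEdge) -> tuple:
    """Order of candidate extensions of one shared code prefix.

    Backward edges (j < i) precede forward edges; backward edges sort by
    increasing target index; forward edges sort by decreasing source depth
    (deeper on the rightmost path first); label triples break remaining ties.
    """
    i, j, li, le, lj = t
    if j < i:  # backward
        return (0, j, le, lj)
    return (1, -i, li, le, lj)


def _rightmost_path(code: Code) -> list[int]:
    path = [0, 1]
    for i, j, *_ in code[1:]:
        if i < j:  # forward
            path = path[: path.index(i) + 1] + [j]
    return path


def _node_labels_of(code: Code) -> list[str]:
    labels: dict[int, str] = {}
    for i, j, li, _, lj in code:
        labels.setdefault(i, li)
        labels.setdefault(j, lj)
    return [labels[k] for k in range(len(labels))]


class _PatternGraph:
    """Adjacency view of the graph a DFS code encodes."""

    def __init__(self, code: Code) -> None:
        self.labels = _node_labels_of(code)
        self.adj: dict[int, list[tuple[int, str]]] = {k: [] for k in range(len(self.labels))}
        self.edges: set[frozenset[int]] = set()
        for i, j, _, le, _ in code:
            self.adj[i].append((j, le))
            self.adj[j].append((i, le))
            self.edges.add(frozenset((i, j)))


def _min_code(pat: _PatternGraph) -> Code:
    """Minimum DFS code of a small labeled graph.

    Runs the canonical greedy search: keep every partial DFS traversal whose
    code equals the minimal prefix, extend all of them, append the globally
    minimal next edge, repeat until all edges are consumed.
    """
    n = len(pat.labels)
    m = len(pat.edges)
    # states: (map: dfs index -> graph vertex, rmpath over dfs indices, used pattern edges)
    first: CodeEdge | None = None
    states: list[tuple[list[int], list[int], set[frozenset[int]]]] = []
    for u in range(n):
        for v, le in pat.adj[u]:
            t: CodeEdge = (0, 1, pat.labels[u], le, pat.labels[v])
            if first is None or t < first:
                first, states = t, []
            if t == first:
                states.append(([u, v], [0, 1], {frozenset((u, v))}))
    assert first is not None
    code: list[CodeEdge] = [first]
    while len(code) < m:
        best: CodeEdge | None = None
        nxt: list[tuple[list[int], list[int], set[frozenset[int]]]] = []
        for vmap, rmpath, used in states:
            pos = {g: k for k, g in enumerate(vmap)}
            rm = rmpath[-1]
            # backward extensions from the rightmost vertex
            for v, le in pat.adj[vmap[rm]]:
                k = pos.get(v)
                if k is None or k not in rmpath[:-1]:
                    continue
                if frozenset((vmap[rm], v)) in used:
                    continue
                t = (rm, k, pat.labels[vmap[rm]], le, pat.labels[v])
                cand = (vmap, rmpath, used | {frozenset((vmap[rm], v))})
                if best is None or _ext_key(t) < _ext_key(best):
                    best, nxt = t, [cand]
                elif t == best:
                    nxt.append(cand)
            # forward extensions from the rightmost path
            for k in rmpath:
                for v, le in pat.adj[vmap[k]]:
                    if v in pos:
                        continue
                    t = (k, len(vmap), pat.labels[vmap[k]], le, pat.labels[v])
                    cand = (
                        vmap + [v],
                        rmpath[: rmpath.index(k) + 1] + [len(vmap)],
                        used | {frozenset((vmap[k], v))},
                    )
                    if best is None or _ext_key(t) < _ext_key(best):
                        best, nxt = t, [cand]
                    elif t == best:
                        nxt.append(cand)
        assert best is not None, "DFS enumeration dead-ended (should be impossible)"
        code.append(best)
        states = nxt
    return tuple(code)


def _is_min(code: Code) -> bool:
    return _min_code(_PatternGraph(code)) == code


# ----------------------------------------------------------------------
# database graphs and embeddings


class _DBGraph:
    def __init__(self, net: MCTCNetwork) -> None:
        nodes = sorted(net.graph.nodes, key=node_label)
        self.index = {nd: k for k, nd in enumerate(nodes)}
        self.labels = [node_label(nd) for nd in nodes]
        self.adj: dict[int, list[tuple[int, str]]] = {k: [] for k in range(len(nodes))}
        for a, b, data in net.graph.edges(data=True):
            ia, ib = self.index[a], self.index[b]
            self.adj[ia].append((ib, data["kind"]))
            self.adj[ib].append((ia, data["kind"]))


def gspan_mine(
    networks: Sequence[MCTCNetwork],
    min_support: int,
    max_edges: int = 5,
) -> list[FrequentSubnetwork]:
    """Mine all frequent connected subgraphs with at most ``max_edges`` edges.

    Returns exactly the label-preserving-isomorphism-distinct connected
    patterns (with at least one edge) contained in at least ``min_support``
    of the input networks, each with its exact support set.  The result is
    deterministic and independent of the input network order: patterns are
    emitted in minimum-DFS-code order.
    """
    if not networks:
        raise ParameterError("empty network list")
    if min_support < 2:
        raise ParameterError(f"min_support must be >= 2, got {min_support}")
    if max_edges < 1:
        raise ParameterError(f"max_edges must be >= 1, got {max_edges}")
    ids = [net.sample_id for net in networks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_ids among networks")
    db = [_DBGraph(net) for net in networks]

    found: list[tuple[Code, frozenset[str]]] = []

    def recurse(code: Code, embeddings: list[tuple[int, tuple[int, ...]]]) -> None:
        if not _is_min(code):
            return
        support_set = frozenset(ids[gid] for gid, _ in embeddings)
        found.append((code, support_set))
        if len(code) >= max_edges:
            return
        rmpath = _rightmost_path(code)
        rm = rmpath[-1]
        nnodes = len(_node_labels_of(code))
        code_edges = {frozenset((i, j)) for i, j, *_ in code}
        ext: dict[CodeEdge, list[tuple[int, tuple[int, ...]]]] = {}
        for gid, vmap in embeddings:
            g = db[gid]
            mapped = set(vmap)
            # backward
            for k in rmpath[:-1]:
                if frozenset((rm, k)) in code_edges:
                    continue
                for v, le in g.adj[vmap[rm]]:
                    if v == vmap[k]:
                        t = (rm, k, g.labels[vmap[rm]], le, g.labels[v])
                        ext.setdefault(t, []).append((gid, vmap))
            # forward
            for k in rmpath:
                for v, le in g.adj[vmap[k]]:
                    if v in mapped:
                        continue
                    t = (k, nnodes, g.labels[vmap[k]], le, g.labels[v])
                    ext.setdefault(t, []).append((gid, vmap + (v,)))
        for t in sorted(ext, key=_ext_key):
            embs = ext[t]
            if len({gid for gid, _ in embs}) >= min_support:
                recurse(code + (t,), embs)

    # frequent single edges, in canonical orientation (smaller label first)
    singles: dict[CodeEdge, list[tuple[int, tuple[int, ...]]]] = {}
    for gid, g in enumerate(db):
        for u in range(len(g.labels)):
            for v, le in g.adj[u]:
                if g.labels[u] > g.labels[v] or (g.labels[u] == g.labels[v] and u > v):
                    continue
                t: CodeEdge = (0, 1, g.labels[u], le, g.labels[v])
                singles.setdefault(t, []).append((gid, (u, v)))
                if g.labels[u] == g.labels[v]:
                    singles[t].append((gid, (v, u)))
    for t in sorted(singles):
        embs = singles[t]
        if len({gid for gid, _ in embs}) >= min_support:
            recurse((t,), embs)

    found.sort(key=lambda item: item[0])
    patterns = []
    for pid, (code, support_set) in enumerate(found):
        labels = tuple(_node_labels_of(code))
        edge_list = tuple((min(i, j), max(i, j), le) for i, j, _, le, _ in code)
        patterns.append(
            FrequentSubnetwork(
                pattern_id=pid,
                canonical_code=code,
                node_labels=labels,
                edge_list=edge_list,
                support_set=support_set,
            )
        )
    return patterns


def encode_occurrence(
    patterns: Sequence[FrequentSubnetwork],
    networks: Sequence[MCTCNetwork],
) -> pd.DataFrame:
    """One-hot occurrence matrix F (samples x patterns) from support sets."""
    ids = [net.sample_id for net in networks]
    id_set = set(ids)
    for pat in patterns:
        stray = pat.support_set - id_set
        if stray:
            raise ValidationError(
                f"pattern {pat.pattern_id} supported by unknown samples: {sorted(stray)}"
            )
    data = {
        pat.pattern_id: [1 if sid in pat.support_set else 0 for sid in ids]
        for pat in patterns
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"), dtype=int)


def choose_support(
    networks: Sequence[MCTCNetwork],
    target_driver_prevalence: float,
) -> tuple[int, int]:
    """Suggest a support threshold from the driver prevalence of interest.

    Returns ``(ceil(prevalence * n_samples), n_frequent_edges)`` where the
    second element counts the distinct single-edge patterns meeting the
    suggested threshold — a cheap lower bound on the pattern count, advisory
    only.
    """
    if not (0 < target_driver_prevalence <= 1):
        raise ParameterError("prevalence must be in (0, 1]")
    suggestion = math.ceil(target_driver_prevalence * len(networks))
    edge_support: dict[tuple[str, str, str], set[str]] = {}
    for net in networks:
        for a, b, kind in net.edges:
            la, lb = sorted((node_label(a), node_label(b)))
            edge_support.setdefault((la, kind, lb), set()).add(net.sample_id)
    n_freq = sum(1 for s in edge_support.values() if len(s) >= suggestion)
    return suggestion, n_freq


def write_patterns(
    patterns: Sequence[FrequentSubnetwork], path: str
) -> pd.DataFrame:
    """Pattern table TSV: id, canonical code, nodes, edges, support."""
    rows = [
        {
            "pattern_id": p.pattern_id,
            "canonical_code": repr(p.canonical_code),
            "nodes": ";".join(p.node_labels),
            "edges": ";".join(f"{i}-{j}:{k}" for i, j, k in p.edge_list),
            "signature": p.signature(),
            "support": p.support,
            "support_set": ",".join(sorted(p.support_set)),
        }
        for p in patterns
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
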