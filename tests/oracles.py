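"""Independent brute-force oracles used to validate the implementation.

Everything in here is deliberately naive and shares no code with the
package's algorithmic paths: pattern enumeration by exhaustive edge-subset
search with permutation-canonical forms, Fisher tails by explicit
combinatorial enumeration, shortest paths by a hand-rolled BFS, and a
textbook two-group log-rank statistic.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np


# ----------------------------------------------------------------------
# labeled-subgraph enumeration


def perm_canonical(nodes: list[str], edges: list[tuple[int, int, str]]) -> tuple:
    """Canonical form of a small labeled graph by brute-force permutation."""
    n = len(nodes)
    best = None
    for perm in itertools.permutations(range(n)):
        relabeled_nodes = tuple(nodes[j] for j in sorted(range(n), key=lambda k: perm[k]))
        # perm[k] = new index of original node k
        relabeled_edges = tuple(
            sorted((min(perm[i], perm[j]), max(perm[i], perm[j]), lab) for i, j, lab in edges)
        )
        cand = (relabeled_nodes, relabeled_edges)
        if best is None or cand < best:
            best = cand
    return best


def _connected(edges: list[tuple]) -> bool:
    nodes = {e[0] for e in edges} | {e[1] for e in edges}
    adj = {v: set() for v in nodes}
    for a, b, _ in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v] - seen)
    return seen == nodes


def enumerate_frequent(graphs, min_support: int, max_edges: int) -> dict:
    """All connected labeled patterns with <= max_edges edges and their supports.

    ``graphs`` is a list of (sample_id, networkx Graph with node attr
    ``label`` and edge attr ``kind``).  Returns {canonical form: support set}.
    """
    per_graph: list[tuple[str, set]] = []
    for sid, g in graphs:
        found = set()
        edge_list = list(g.edges(data="kind"))
        for k in range(1, max_edges + 1):
            for subset in itertools.combinations(edge_list, k):
                if not _connected(list(subset)):
                    continue
                nodes = sorted({v for a, b, _ in subset for v in (a, b)})
                idx = {v: i for i, v in enumerate(nodes)}
                labels = [g.nodes[v]["label"] for v in nodes]
                edges = [(idx[a], idx[b], kind) for a, b, kind in subset]
                found.add(perm_canonical(labels, edges))
        per_graph.append((sid, found))
    support: dict = {}
    for sid, found in per_graph:
        for form in found:
            support.setdefault(form, set()).add(sid)
    return {form: sids for form, sids in support.items() if len(sids) >= min_support}


# ----------------------------------------------------------------------
# Fisher one-sided tail


def fisher_greater_enumeration(n: int, n_driver: int, n_pattern: int, a_obs: int) -> float:
    """P(overlap >= a_obs) by enumerating all placements of pattern-positives."""
    samples = range(n)
    driver = set(range(n_driver))
    total = 0
    hits = 0
    for subset in itertools.combinations(samples, n_pattern):
        total += 1
        if len(driver & set(subset)) >= a_obs:
            hits += 1
    return hits / total


# ----------------------------------------------------------------------
# shortest paths


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


# ----------------------------------------------------------------------
# two-group log-rank


def logrank_two_group(time, event, group) -> float:
    """Textbook two-group log-rank chi-square statistic."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    assert len(levels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = ((time == t) & (event == 1)).sum()
        n = at_risk.sum()
        n1 = (at_risk & (group == levels[0])).sum()
        d1 = ((time == t) & (event == 1) & (group == levels[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
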