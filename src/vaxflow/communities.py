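"""Hierarchical community detection with a modularity-guided windowed cut.

The dendrogram is built with the Paris agglomerative algorithm: cluster
distance is the inverse of the node-pair sampling ratio,
d(a, b) = s_a * s_b / (W * w_ab), where s are cluster strengths, w_ab the
inter-cluster weight and W the total strength. The distance is reducible, so
a nearest-neighbor chain produces the exact dendrogram in near-quadratic
time. The goal of the windowed cut is a small number of large, balanced
communities: candidate partitions with 2-5 communities are compared by
modularity; if the best still traps >90% of nodes in one community, the next
five community counts (6-10, 11-15, ...) are tried, and so on.

Louvain and fixed-k cuts are provided as robustness alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities
from networkx.algorithms.community import modularity as _nx_modularity


class DisconnectedGraphError(ValueError):
    """Raised when clustering is attempted on a disconnected graph."""


def symmetrize(graph: nx.Graph | nx.DiGraph) -> nx.Graph:
    """Undirected view of a weighted digraph: w_uv = w(u->v) + w(v->u)."""
    if not graph.is_directed():
        return graph
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v, w in graph.edges(data="weight", default=1):
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy-linkage layout.

    `nodes[i]` is the leaf with id i; row t of `merges` is
    (left, right, height, size) creating cluster id n + t. Heights are
    non-decreasing along every root path.
    """

    nodes: list
    merges: np.ndarray  # shape (n - 1, 4)

    @property
    def n_leaves(self) -> int:
        return len(self.nodes)


@dataclass
class Partition:
    """Flat community assignment with contiguous ids from 0."""

    membership: dict  # node -> community id

    def __post_init__(self) -> None:
        ids = sorted(set(self.membership.values()))
        if ids and ids != list(range(len(ids))):
            remap = {old: new for new, old in enumerate(ids)}
            self.membership = {n: remap[c] for n, c in self.membership.items()}

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable]) -> "Partition":
        return cls({n: i for i, comm in enumerate(communities) for n in comm})

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return [out[c] for c in sorted(out)]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]

    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def largest_share(self) -> float:
        if not self.membership:
            return 0.0
        return max(self.sizes()) / len(self.membership)

    def __len__(self) -> int:
        return len(self.membership)


def paris_dendrogram(graph: nx.Graph | nx.DiGraph) -> Dendrogram:
    """Full Paris dendrogram of a connected weighted graph.

    Directed input is symmetrized by summing reciprocal weights. Deterministic
    for a fixed node ordering: nodes are processed in sorted order and ties in
    the nearest-neighbor search break toward the smaller cluster id.
    """
    g = symmetrize(graph)
    n = g.number_of_nodes()
    if n == 0:
        return Dendrogram([], np.empty((0, 4)))
    if n > 1 and not nx.is_connected(g):
        raise DisconnectedGraphError(
            "graph is disconnected; extract the giant component first"
        )
    nodes = sorted(g.nodes, key=str)
    index = {node: i for i, node in enumerate(nodes)}

    neighbors: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    strength = np.zeros(2 * n - 1)
    size = np.ones(2 * n - 1, dtype=int)
    for u, v, w in g.edges(data="weight", default=1):
        if u == v:
            continue
        i, j = index[u], index[v]
        neighbors[i][j] = neighbors[i].get(j, 0.0) + float(w)
        neighbors[j][i] = neighbors[j].get(i, 0.0) + float(w)
        strength[i] += w
        strength[j] += w
    total = float(strength[:n].sum())

    def dist(a: int, b: int) -> float:
        w_ab = neighbors[a].get(b, 0.0)
        if w_ab <= 0:
            return np.inf
        return strength[a] * strength[b] / (total * w_ab)

    active = set(range(n))
    chain: list[int] = []
    raw_merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        if not chain:
            chain.append(min(active))
        a = chain[-1]
        # nearest neighbor of a (smallest distance, ties to smaller id)
        best, best_d = -1, np.inf
        for b in neighbors[a]:
            d = dist(a, b)
            if d < best_d or (d == best_d and b < best):
                best, best_d = b, d
        if best < 0:
            raise DisconnectedGraphError(
                "graph is disconnected; extract the giant component first"
            )
        if len(chain) >= 2 and chain[-2] == best:
            chain.pop()
            chain.pop()
            b = best
            c = next_id
            next_id += 1
            raw_merges.append((a, b, best_d, int(size[a] + size[b])))
            merged: dict[int, float] = {}
            for x, w in neighbors[a].items():
                if x != b:
                    merged[x] = merged.get(x, 0.0) + w
            for x, w in neighbors[b].items():
                if x != a:
                    merged[x] = merged.get(x, 0.0) + w
            for x, w in merged.items():
                neighbors[x].pop(a, None)
                neighbors[x].pop(b, None)
                neighbors[x][c] = w
            del neighbors[a], neighbors[b]
            neighbors[c] = merged
            strength[c] = strength[a] + strength[b]
            size[c] = size[a] + size[b]
            active.discard(a)
            active.discard(b)
            active.add(c)
        else:
            chain.append(best)

    # Reorder merges by height (stable, so children keep preceding parents —
    # reducibility guarantees child height <= parent height).
    order = sorted(range(len(raw_merges)), key=lambda t: (raw_merges[t][2], t))
    new_id = {}
    for new_pos, old_pos in enumerate(order):
        new_id[n + old_pos] = n + new_pos
    merges = np.zeros((len(raw_merges), 4))
    for new_pos, old_pos in enumerate(order):
        left, right, h, sz = raw_merges[old_pos]
        left = new_id.get(left, left)
        right = new_id.get(right, right)
        merges[new_pos] = (min(left, right), max(left, right), h, sz)
    return Dendrogram(nodes, merges)


def cut_at_k(dendrogram: Dendrogram, k: int) -> Partition:
    """Partition with exactly k communities: the k - 1 highest merges removed."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        left, right = int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1])
        c = n + t
        parent[find(left)] = c
        parent[find(right)] = c
    roots: dict[int, int] = {}
    membership = {}
    for i, node in enumerate(dendrogram.nodes):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        membership[node] = roots[r]
    return Partition(membership)


def modularity(graph: nx.Graph | nx.DiGraph, partition: Partition) -> float:
    """Weighted Newman-Girvan modularity on the symmetrized graph."""
    g = symmetrize(graph)
    missing = set(g.nodes) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    if g.number_of_edges() == 0:
        return 0.0
    comms = [c & set(g.nodes) for c in partition.communities()]
    comms = [c for c in comms if c]
    return float(_nx_modularity(g, comms, weight="weight"))


@dataclass
class CutInfo:
    window: int
    k: int
    modularity: float
    largest_share: float
    terminated_by: str  # "size_condition" | "exhausted" | "trivial"


def _window_ks(window: int, n: int) -> list[int]:
    if window == 0:
        ks = range(2, 6)
    else:
        lo = 6 + 5 * (window - 1)
        ks = range(lo, lo + 5)
    return [k for k in ks if k <= n]


def cut_dendrogram(
    dendrogram: Dendrogram,
    graph: nx.Graph | nx.DiGraph,
    max_share: float = 0.9,
    return_info: bool = False,
):
    """Windowed maximum-modularity cut of a Paris dendrogram.

    Within the current window of candidate community counts ({2..5}, then
    {6..10}, {11..15}, ...) the maximum-modularity partition is selected
    (ties to fewer communities). If its largest community holds more than
    `max_share` of the nodes, the next window is tried; the procedure stops
    when the condition fails or candidates are exhausted (returning the last
    window's best).
    """
    n = dendrogram.n_leaves
    if n < 2:
        part = Partition({node: 0 for node in dendrogram.nodes})
        if return_info:
            return part, CutInfo(0, 1, 0.0, 1.0 if n else 0.0, "trivial")
        return part
    window = 0
    best_part: Partition | None = None
    best_info: CutInfo | None = None
    while True:
        ks = _window_ks(window, n)
        if not ks:
            assert best_part is not None and best_info is not None
            best_info.terminated_by = "exhausted"
            return (best_part, best_info) if return_info else best_part
        best_mod = -np.inf
        window_best: Partition | None = None
        window_k = -1
        for k in ks:
            part = cut_at_k(dendrogram, k)
            q = modularity(graph, part)
            if q > best_mod:
                best_mod, window_best, window_k = q, part, k
        assert window_best is not None
        share = window_best.largest_share()
        best_part = window_best
        best_info = CutInfo(window, window_k, best_mod, share, "size_condition")
        if share <= max_share:
            return (best_part, best_info) if return_info else best_part
        window += 1


def louvain(graph: nx.Graph | nx.DiGraph, seed: int = 0) -> Partition:
    """Louvain partition of the symmetrized weighted graph (robustness
    alternative); the seed fixes tie-breaking order."""
    g = symmetrize(graph)
    comms = louvain_communities(g, weight="weight", seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), sorted(str(x) for x in c)))
    return Partition.from_communities(comms)


def binary_group_accuracy(
    groups_ref: Mapping[Hashable, str], groups_alt: Mapping[Hashable, str]
) -> float:
    """Fraction of users given the same binary (no-vax / other) group by two
    methods, computed on the intersection of their user sets."""
    common = set(groups_ref) & set(groups_alt)
    if not common:
        raise ValueError("no common users between the two groupings")
    agree = sum(1 for u in common if groups_ref[u] == groups_alt[u])
    return agree / len(common)
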