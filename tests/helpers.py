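"""Independent oracles and small generators shared across tests.

Everything here is deliberately naive: the betweenness oracle enumerates
every shortest path explicitly, and the density-only detector re-derives
the growth loop with no bottleneck machinery at all, so they can vouch
for the package's implementations without sharing code with them.
"""

from __future__ import annotations

import math
import random

import networkx as nx


def bfs_distances(adj: dict[str, list[str]], s: str) -> dict[str, int]:
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(net: nx.Graph) -> dict[str, float]:
    """Betweenness by explicit enumeration of all shortest paths.

    For each unordered connected pair, every shortest path is listed by
    walking distance labels backwards from the target; each path credits
    its interior nodes with 1/(number of shortest paths).
    """
    nodes = sorted(net.nodes)
    adj = {n: sorted(net[n]) for n in nodes}
    score = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t not in dist or t == s:
                continue
            paths: list[list[str]] = []

            def extend(path: list[str]) -> None:
                u = path[-1]
                if u == s:
                    paths.append(path)
                    return
                for v in adj[u]:
                    if dist.get(v) == dist[u] - 1:
                        extend(path + [v])

            extend([t])
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


def random_graph(seed: int, n_max: int = 12, p: float | None = None) -> nx.Graph:
    """A seeded G(n, p) graph with string node names (possibly disconnected)."""
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    if p is None:
        p = rng.uniform(0.1, 0.7)
    g = nx.Graph()
    names = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g


def density(net: nx.Graph, members: set[str]) -> float:
    n = len(members)
    if n < 2:
        return 1.0
    e = sum(1 for u, v in net.edges(members) if u in members and v in members)
    return 2.0 * e / (n * (n - 1))


def density_only_detect(net: nx.Graph, cc: float, k: float, min_size: int) -> list[frozenset[str]]:
    """Pure density-gated seed-and-grow: the bottleneck-free reference.

    No bottleneck set, no close-bottleneck index, no termination rule —
    candidates come from every member and the score is the density term
    alone.  Seeds are ordered by betweenness descending (the seed
    ordering is not part of the ablation), identifier ascending on ties.
    """
    if net.number_of_nodes() == 0:
        return []
    ct = nx.betweenness_centrality(net, normalized=False)
    queue = sorted(net.nodes, key=lambda x: (-ct[x], x))
    queued = set(queue)
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for seed in queue:
        if seed not in queued:
            continue
        members = {seed}
        for _ in range(net.number_of_nodes()):
            cands = {nbr for m in members for nbr in net[m]} - members
            eligible = [(density(net, members | {c}), c)
                        for c in cands if density(net, members | {c}) >= cc]
            if not eligible:
                break
            eligible.sort(key=lambda sc: (-sc[0], sc[1]))
            m = max(1, math.ceil(k / 100.0 * len(eligible)))
            members.update(c for _, c in eligible[:m])
        fs = frozenset(members)
        if len(fs) >= min_size:
            queued -= fs
            if fs not in seen:
                seen.add(fs)
                out.append(fs)
        else:
            queued.discard(seed)
    return out
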