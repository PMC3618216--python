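"""Bottleneck proteins: betweenness centrality, the top-BC% cut, and each
node's close-bottleneck index.

Bottlenecks are the nodes through which many shortest paths run — in PPI
networks these tend to be essential connector proteins between functional
modules, so dense sub-graphs whose boundaries are bottlenecks are good
protein-complex candidates.  A node's *close bottlenecks* are the
bottlenecks within shortest-path distance 2 of it (a bottleneck is close
to itself, distance 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

__all__ = [
    "BottleneckIndex",
    "betweenness",
    "select_bottlenecks",
    "bfs_ball",
    "compute_close_bottlenecks",
    "build_index",
    "write_centrality",
]


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness centrality.

    For node v: sum over unordered pairs {s, t} (s ≠ t ≠ v) of the
    fraction of shortest s–t paths that pass through v.  Endpoints are
    excluded; pairs in different components contribute nothing.  Degree-1
    and isolated nodes score 0.
    """
    return nx.betweenness_centrality(net, normalized=False)


def select_bottlenecks(ct: Mapping[str, float], bc_percent: float) -> frozenset[str]:
    """The top ``ceil(bc_percent/100 × |nodes|)`` nodes by betweenness.

    Ranking is (score descending, identifier ascending) so the cut is
    deterministic under ties.  ``bc_percent = 0`` returns the empty set —
    the no-bottleneck ablation where growth is gated by density alone.
    """
    if not 0.0 <= bc_percent <= 100.0:
        raise ValueError(f"bc_percent must be in [0, 100], got {bc_percent}")
    if not ct:
        raise ValueError("centrality table is empty")
    if bc_percent == 0.0:
        return frozenset()
    m = math.ceil(bc_percent / 100.0 * len(ct))
    ranked = sorted(ct, key=lambda n: (-ct[n], n))
    return frozenset(ranked[:m])


def bfs_ball(net: nx.Graph, n: str, radius: int) -> frozenset[str]:
    """All nodes within shortest-path distance ``radius`` of n, n included."""
    if n not in net:
        raise KeyError(f"node {n!r} not in network")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return frozenset(nx.single_source_shortest_path_length(net, n, cutoff=radius))


@dataclass(frozen=True)
class BottleneckIndex:
    """The bottleneck set plus every node's close bottlenecks (distance ≤ 2)."""

    bottlenecks: frozenset[str]
    close: dict[str, frozenset[str]] = field(hash=False)
    bc_percent: float = float("nan")


def compute_close_bottlenecks(net: nx.Graph, bottlenecks: frozenset[str] | set[str],
                              bc_percent: float = float("nan")) -> BottleneckIndex:
    """Index close(n) = {b ∈ bottlenecks : dist(n, b) ≤ 2} for every node.

    Computed by radius-2 BFS from each bottleneck (cheaper than from each
    node when bottlenecks are the top few percent).
    """
    bottlenecks = frozenset(bottlenecks)
    if not bottlenecks <= set(net.nodes):
        raise ValueError("bottlenecks must be a subset of the network's nodes")
    close: dict[str, set[str]] = {n: set() for n in net.nodes}
    for b in bottlenecks:
        for n in nx.single_source_shortest_path_length(net, b, cutoff=2):
            close[n].add(b)
    return BottleneckIndex(
        bottlenecks=bottlenecks,
        close={n: frozenset(s) for n, s in close.items()},
        bc_percent=bc_percent,
    )


def build_index(net: nx.Graph, bc_percent: float,
                ct: Mapping[str, float] | None = None) -> BottleneckIndex:
    """Convenience: centrality → top-BC% cut → close-bottleneck index."""
    if ct is None:
        ct = betweenness(net)
    bots = select_bottlenecks(ct, bc_percent)
    return compute_close_bottlenecks(net, bots, bc_percent)


def write_centrality(ct: Mapping[str, float], path: str | Path) -> None:
    """Dump the centrality table as TSV (node, score), score descending."""
    with open(path, "w") as fh:
        for n in sorted(ct, key=lambda n: (-ct[n], n)):
            fh.write(f"{n}\t{ct[n]:.10g}\n")
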