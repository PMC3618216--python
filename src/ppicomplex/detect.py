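"""Bottleneck-guided seed-and-grow detection of overlapping protein complexes.

The detector grows one candidate cluster per seed, seeds taken in order
of decreasing betweenness centrality.  A neighbouring node n of the
cluster is eligible if adding it keeps the cluster's edge density at or
above the CC threshold, and eligible candidates are ranked by

    score(n) = density(members ∪ {n}) × |B| / |S| × |B| / |Cn|

where S is the cluster's shared bottlenecks (the intersection of the
members' close-bottleneck sets, initialized to the seed's), Cn is n's
close bottlenecks and B = S ∩ Cn.  The top k% of eligible candidates
join per iteration.  Bottleneck members never contribute new
candidates — the search ends at bottlenecks, so bottlenecks become the
boundaries of complexes and neighbouring complexes naturally overlap on
them.  Clusters of at least ``min_size`` members are reported; their
members are removed from the seed queue (but may still be absorbed into
later clusters, which is what permits overlap).

With ``bc_percent = 0`` there are no bottlenecks and the score
degenerates to the density term alone — the CC-only ablation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .bottleneck import BottleneckIndex, betweenness, build_index, compute_close_bottlenecks
from .graph_io import ComplexSet

__all__ = [
    "DetectParams",
    "Cluster",
    "cluster_density",
    "candidate_score",
    "grow_cluster",
    "detect_complexes",
]


@dataclass(frozen=True)
class DetectParams:
    """Tunable parameters of the detector.

    bc_percent
        Top percentage of nodes (by betweenness) declared bottlenecks.
        0 disables bottlenecks entirely (density-only ablation).
    cc_threshold
        Minimum cluster edge density 2E/(n(n−1)) a candidate must
        preserve to be eligible.
    k_percent
        Percentage of eligible candidates admitted per growth iteration;
        at least one is always admitted when any is eligible.
    min_size
        Minimum member count for a cluster to be reported as a complex.
    max_iter
        Safety cap on growth iterations per seed (default: node count).
    tie_admission
        If True, admit every candidate tied at the best score instead of
        the top-k% batch — the simplified walkthrough mode; default off.
    """

    bc_percent: float = 1.0
    cc_threshold: float = 0.6
    k_percent: float = 5.0
    min_size: int = 3
    max_iter: Optional[int] = None
    tie_admission: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.bc_percent <= 100.0:
            raise ValueError(f"bc_percent must be in [0, 100], got {self.bc_percent}")
        if not 0.0 <= self.cc_threshold <= 1.0:
            raise ValueError(f"cc_threshold must be in [0, 1], got {self.cc_threshold}")
        if not 0.0 < self.k_percent <= 100.0:
            raise ValueError(f"k_percent must be in (0, 100], got {self.k_percent}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")


@dataclass
class Cluster:
    """A grown candidate complex.

    ``shared_bottlenecks`` is the intersection of the members' close
    sets; ``active`` are the non-bottleneck members whose neighbours may
    still be explored (the seed counts as active while the cluster is
    the initial singleton).  ``trace`` records membership after each
    growth iteration, starting with the singleton.
    """

    seed: str
    members: frozenset[str]
    shared_bottlenecks: frozenset[str]
    active: frozenset[str]
    trace: list[frozenset[str]] = field(default_factory=list)


def cluster_density(net: nx.Graph, members: Iterable[str]) -> float:
    """Edge density 2E/(n(n−1)) of the induced subgraph; 1.0 below 2 nodes.

    This is the "clustering coefficient" that gates growth: the fraction
    of possible member pairs that actually interact.
    """
    ms = set(members)
    n = len(ms)
    if n < 2:
        return 1.0
    e = sum(1 for u, v in net.edges(ms) if u in ms and v in ms)
    return 2.0 * e / (n * (n - 1))


def candidate_score(net: nx.Graph, members: Iterable[str], shared: frozenset[str],
                    n: str, idx: BottleneckIndex) -> float:
    """Growth score of candidate n against the current cluster.

    density(members ∪ {n}) × |S∩Cn|/|S| × |S∩Cn|/|Cn|, with S the
    cluster's shared bottlenecks and Cn the candidate's close
    bottlenecks.  When no bottlenecks exist at all the ratio terms are
    dropped and the score is the density alone; when S or Cn is empty
    (but bottlenecks exist) the score is 0.
    """
    ms = set(members)
    if n in ms:
        raise ValueError(f"candidate {n!r} is already a member")
    density = cluster_density(net, ms | {n})
    if not idx.bottlenecks:
        return density
    cn = idx.close.get(n, frozenset())
    if not shared or not cn:
        return 0.0
    b = len(shared & cn)
    return density * (b / len(shared)) * (b / len(cn))


def _admit(scored: list[tuple[float, str]], k_percent: float, tie_admission: bool) -> list[str]:
    """Pick the admission batch from (score, node) pairs.

    Ranking is score descending, identifier ascending.  Default batch
    size is max(1, ceil(k% of eligible)); tie_admission instead takes
    every node tied at the best score.
    """
    scored.sort(key=lambda sn: (-sn[0], sn[1]))
    if tie_admission:
        best = scored[0][0]
        return [n for s, n in scored if s == best]
    m = max(1, math.ceil(k_percent / 100.0 * len(scored)))
    return [n for _, n in scored[:m]]


def grow_cluster(net: nx.Graph, seed: str, idx: BottleneckIndex, p: DetectParams) -> Cluster:
    """Grow a cluster from ``seed`` until no candidate passes the CC gate.

    The initial singleton's shared-bottleneck set is the seed's close
    set, and the seed generates candidates even if it is itself a
    bottleneck; from the first admission on, only non-bottleneck members
    do.  Each iteration scores every density-eligible neighbour of the
    active members against the pre-batch cluster and admits a batch.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    members: set[str] = {seed}
    shared = idx.close.get(seed, frozenset())
    active: set[str] = {seed}
    trace = [frozenset(members)]
    max_iter = p.max_iter if p.max_iter is not None else net.number_of_nodes()
    for _ in range(max_iter):
        candidates = {nbr for m in active for nbr in net[m]} - members
        scored = [
            (candidate_score(net, members, shared, c, idx), c)
            for c in candidates
            if cluster_density(net, members | {c}) >= p.cc_threshold
        ]
        if not scored:
            break
        batch = _admit(scored, p.k_percent, p.tie_admission)
        members.update(batch)
        shared = frozenset.intersection(
            *(idx.close.get(m, frozenset()) for m in members)
        ) if members else frozenset()
        active = members - idx.bottlenecks
        trace.append(frozenset(members))
    return Cluster(
        seed=seed,
        members=frozenset(members),
        shared_bottlenecks=shared,
        active=frozenset(active),
        trace=trace,
    )


def detect_complexes(net: nx.Graph, p: DetectParams = DetectParams(),
                     bottlenecks: Optional[frozenset[str]] = None) -> ComplexSet:
    """Run the full detector and return the (possibly overlapping) complexes.

    Seeds are all nodes sorted by betweenness descending (identifier
    ascending on ties).  Each reported complex removes its members from
    the seed queue; a sub-``min_size`` cluster consumes only its seed.
    Removal blocks seeding, not later absorption, so complexes may
    overlap — typically on the bottlenecks at their boundaries.
    Duplicate member sets are reported once.

    ``bottlenecks`` overrides the top-BC% cut with an explicit set
    (useful for reproducing hand-worked configurations).
    """
    result = ComplexSet()
    if net.number_of_nodes() == 0:
        return result
    ct = betweenness(net)
    if bottlenecks is None:
        idx = build_index(net, p.bc_percent, ct)
    else:
        idx = compute_close_bottlenecks(net, bottlenecks, p.bc_percent)
    queue = sorted(net.nodes, key=lambda n: (-ct[n], n))
    queued = set(queue)
    seen: set[frozenset[str]] = set()
    for seed in queue:
        if seed not in queued:
            continue
        cluster = grow_cluster(net, seed, idx, p)
        if len(cluster.members) >= p.min_size:
            queued -= cluster.members
            if cluster.members not in seen:
                seen.add(cluster.members)
                result.append(cluster.members)
        else:
            queued.discard(seed)
    return result
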