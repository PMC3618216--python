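"""Synthetic PPI networks: a fixed worked-example fixture and a seeded
planted-complex generator.

The planted generator emulates the structure the detector targets:
disjoint dense modules (the "complexes"), bridged by dedicated connector
nodes that carry all inter-module shortest paths — so connectors become
high-betweenness bottlenecks — plus uniform noise edges standing in for
false-positive interactions.  The fixed toy fixture is an 11-node graph
constructed to satisfy every printed constraint of the hand-worked
growth example (it is a consistency model of that example, not a
reconstruction of an original dataset figure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_io import ComplexSet

__all__ = ["SyntheticSpec", "toy_network", "planted_network", "TOY_EDGES"]

# Three triangle "hub" nodes C, G, H each bridge the dense core {C,D,E,G,H}
# to a peripheral triangle; they carry the inter-module paths, so they are
# the three top-betweenness nodes and the natural bottlenecks.
TOY_EDGES: tuple[tuple[str, str], ...] = (
    ("G", "D"), ("G", "E"), ("D", "E"),
    ("C", "D"), ("C", "E"),
    ("H", "D"), ("H", "E"),
    ("C", "A"), ("C", "B"), ("A", "B"),
    ("H", "I"), ("H", "J"), ("I", "J"),
    ("G", "L"), ("G", "M"), ("L", "M"),
)


def toy_network() -> tuple[nx.Graph, frozenset[str], ComplexSet]:
    """The fixed 11-node worked-example network.

    Returns (network, bottlenecks {C, G, H}, expected complexes).  The
    graph satisfies the worked example's printed facts: G's neighbours
    are D, E, L and M; close(D) = close(G) = {G, C, H}; the cluster
    {D, G} has edge density 1; growth from G reaches {C, D, E, G, H} and
    ends at the bottlenecks C and H.  The expected detection output is
    four overlapping complexes whose pairwise overlaps are exactly the
    bottlenecks.
    """
    net = nx.Graph()
    net.add_edges_from(TOY_EDGES)
    expected = ComplexSet([
        frozenset("CDEGH"),
        frozenset("ABC"),
        frozenset("HIJ"),
        frozenset("GLM"),
    ])
    return net, frozenset("CGH"), expected


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-complex network.

    n_complexes
        Number of disjoint dense modules planted (default 20).
    size_range
        Inclusive (min, max) module sizes, min ≥ 3 (default 5–10).
    within_density
        Probability of each within-module edge; a module is resampled
        until connected (default 0.9).
    n_connectors
        Bridge nodes between each pair of consecutive modules; each
        links to 2 nodes of both modules (default 1).
    noise_p
        Probability of a uniform extra edge per remaining node pair
        (default 0.01).
    rng_seed
        Single seed governing all randomness.
    """

    n_complexes: int = 20
    size_range: tuple[int, int] = (5, 10)
    within_density: float = 0.9
    n_connectors: int = 1
    noise_p: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if lo < 3 or hi < lo:
            raise ValueError(f"size_range must satisfy 3 <= min <= max, got {self.size_range}")
        if not 0.0 < self.within_density <= 1.0:
            raise ValueError(f"within_density must be in (0, 1], got {self.within_density}")
        if not 0.0 <= self.noise_p < 1.0:
            raise ValueError(f"noise_p must be in [0, 1), got {self.noise_p}")
        if self.n_connectors < 0:
            raise ValueError("n_connectors must be >= 0")


def _sample_module(rng: np.random.Generator, names: list[str],
                   density: float) -> list[tuple[str, str]]:
    """Edges of one dense module, resampled until connected."""
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    while True:
        mask = rng.random(len(pairs)) < density
        edges = [p for p, keep in zip(pairs, mask) if keep]
        g = nx.Graph(edges)
        g.add_nodes_from(names)
        if nx.is_connected(g):
            return edges


def planted_network(spec: SyntheticSpec) -> tuple[nx.Graph, ComplexSet]:
    """Generate a planted-complex network and its ground truth.

    Consecutive modules i and i+1 are bridged by ``n_connectors``
    dedicated connector nodes, each wired to 2 members of both modules;
    the last module also bridges back to the first, closing a ring so
    every junction carries comparable inter-module traffic and all
    connectors acquire high betweenness (with two modules there is a
    single junction).  Noise edges are then added independently over all
    node pairs not yet connected.  Truth complexes are the planted
    member sets; connectors are not members of any truth complex.  Fully
    determined by ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.size_range
    net = nx.Graph()
    truth = ComplexSet()
    modules: list[list[str]] = []
    for i in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        names = [f"M{i:03d}N{j:02d}" for j in range(size)]
        net.add_nodes_from(names)
        net.add_edges_from(_sample_module(rng, names, spec.within_density))
        modules.append(names)
        truth.append(names, label=f"module{i:03d}")
    n_junctions = spec.n_complexes if spec.n_complexes > 2 else spec.n_complexes - 1
    for i in range(n_junctions):
        for c in range(spec.n_connectors):
            bridge = f"B{i:03d}C{c:02d}"
            nxt = (i + 1) % spec.n_complexes
            left = rng.choice(len(modules[i]), size=2, replace=False)
            right = rng.choice(len(modules[nxt]), size=2, replace=False)
            for j in left:
                net.add_edge(bridge, modules[i][j])
            for j in right:
                net.add_edge(bridge, modules[nxt][j])
    if spec.noise_p > 0.0:
        nodes = sorted(net.nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if not net.has_edge(nodes[i], nodes[j]) and rng.random() < spec.noise_p:
                    net.add_edge(nodes[i], nodes[j])
    return net, truth
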