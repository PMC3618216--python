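"""Flat-file I/O for PPI networks and protein-complex sets.

PPI networks are undirected simple graphs: nodes are opaque protein
identifiers, edges are physical interactions.  Input files are bare edge
lists — the two-column TSV that DIP/BioGRID-style exports reduce to once
the user extracts the identifier columns — or Cytoscape SIF.  Complex sets
(both references such as MIPS/CYC2008 flat lists and our own output) are
one complex per line, members tab-separated.

Networks are held in :class:`networkx.Graph`; readers normalize on the
way in (self-loop rows dropped, duplicate and reversed rows collapsed).
Identifiers are case-sensitive and never translated: the algorithm
consumes topology only, identifier mapping is dataset policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

log = logging.getLogger("ppicomplex")

__all__ = [
    "ComplexSet",
    "FormatError",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "read_complexes",
    "write_complexes",
]


class FormatError(ValueError):
    """An input file yielded no usable records."""


@dataclass
class ComplexSet:
    """An ordered collection of (possibly overlapping) protein complexes.

    Each complex is a frozenset of member identifiers with an optional
    label.  Member sets may overlap between complexes; two complexes with
    identical member sets are collapsed to one on write.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if not self.labels:
            self.labels = [None] * len(self.complexes)
        if len(self.labels) != len(self.complexes):
            raise ValueError("labels and complexes must have equal length")

    def append(self, members: Iterable[str], label: Optional[str] = None) -> None:
        self.complexes.append(frozenset(members))
        self.labels.append(label)

    def filter_min_size(self, min_size: int) -> "ComplexSet":
        """Complexes with at least ``min_size`` members, order preserved."""
        keep = [(c, l) for c, l in zip(self.complexes, self.labels) if len(c) >= min_size]
        return ComplexSet([c for c, _ in keep], [l for _, l in keep])

    def deduplicated(self) -> "ComplexSet":
        """First occurrence of each distinct member set, order preserved."""
        seen: set[frozenset[str]] = set()
        out = ComplexSet()
        for c, l in zip(self.complexes, self.labels):
            if c not in seen:
                seen.add(c)
                out.append(c, l)
        return out

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __contains__(self, members: object) -> bool:
        return frozenset(members) in set(self.complexes)  # type: ignore[arg-type]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self.complexes == other.complexes


def _iter_edge_rows(lines: Iterable[str], fmt: str) -> Iterator[tuple[int, str, list[tuple[str, str]]]]:
    """Yield (line number, raw line, endpoint pairs) for each non-blank row."""
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fmt == "tsv":
            if len(fields) < 2:
                yield lineno, raw.rstrip("\n"), []
                continue
            yield lineno, raw.rstrip("\n"), [(fields[0], fields[1])]
        elif fmt == "sif":
            # SIF: source relation target [target ...]; extra targets fan out.
            if len(fields) < 3:
                yield lineno, raw.rstrip("\n"), []
                continue
            src = fields[0]
            yield lineno, raw.rstrip("\n"), [(src, t) for t in fields[2:]]
        else:
            raise ValueError(f"unknown edge-list format: {fmt!r}")


def read_ppi_edgelist(path: str | Path, fmt: str = "tsv") -> nx.Graph:
    """Read a PPI network from a flat edge list.

    Parameters
    ----------
    path
        File with one interaction per row.  ``tsv``: first two
        whitespace-separated fields are the endpoints, extra columns are
        ignored.  ``sif``: ``source relation target [target ...]``.
    fmt
        ``"tsv"`` (default) or ``"sif"``.

    Returns
    -------
    networkx.Graph
        Undirected simple graph.  Self-loop rows are dropped entirely (a
        node survives only through some other edge), duplicate and
        reversed rows collapse to one edge.

    Raises
    ------
    FormatError
        If no edges could be parsed; the message names the first
        malformed line if one was seen.
    OSError
        If the file cannot be read.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    net = nx.Graph()
    n_selfloop = n_duplicate = n_malformed = 0
    first_bad: Optional[tuple[int, str]] = None
    with open(path) as fh:
        for lineno, raw, pairs in _iter_edge_rows(fh, fmt):
            if not pairs:
                n_malformed += 1
                if first_bad is None:
                    first_bad = (lineno, raw)
                continue
            for u, v in pairs:
                if u == v:
                    n_selfloop += 1
                elif net.has_edge(u, v):
                    n_duplicate += 1
                else:
                    net.add_edge(u, v)
    if net.number_of_edges() == 0:
        if first_bad is not None:
            raise FormatError(
                f"{path}: no edges parsed as {fmt}; first malformed line "
                f"{first_bad[0]}: {first_bad[1]!r}"
            )
        raise FormatError(f"{path}: no edges parsed as {fmt}")
    if n_selfloop or n_duplicate or n_malformed:
        log.info(
            "%s: dropped %d self-loop, %d duplicate, %d malformed row(s)",
            path, n_selfloop, n_duplicate, n_malformed,
        )
    log.info("%s: %d nodes, %d edges", path, net.number_of_nodes(), net.number_of_edges())
    return net


def write_ppi_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a two-column TSV, rows and endpoints sorted."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_complexes(path: str | Path) -> ComplexSet:
    """Read a flat complex list: one complex per line, members tab- or
    space-separated.  Blank lines are ignored; duplicate members within a
    line collapse."""
    cs = ComplexSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            members = raw.split()
            if not members:
                continue
            unique = frozenset(members)
            if len(unique) < 1:
                log.warning("%s: line %d has no members, skipped", path, lineno)
                continue
            cs.append(unique)
    return cs


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members tab-separated and sorted
    lexicographically; identical member sets are written once."""
    with open(path, "w") as fh:
        for members in cs.deduplicated():
            fh.write("\t".join(sorted(members)) + "\n")
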