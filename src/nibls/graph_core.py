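"""Proximity graph over aligned sRNA reads and its clustering coefficients.

Reads are vertices; an undirected edge joins two reads on the same chromosome
whenever the nucleotide gap between their intervals is strictly smaller than
the minimum inclusion distance ``M``.  For intervals sorted so that
``start_a <= start_b`` the gap is ``start_b - end_a - 1`` — the number of
intervening nucleotides — so overlapping or abutting reads have gap <= 0 and
connect for any ``M >= 1``; at ``M = 0`` only strictly overlapping reads
connect.  Once an edge exists the distance is discarded: the graph is simple
and unweighted, with no self-loops.

The per-vertex clustering coefficient (Watts–Strogatz) is the fraction of
possible edges among a vertex's neighbours that actually exist; a component's
coefficient is the mean over its member vertices.  Vertices of degree <= 1
have an ill-defined ratio (0/0); by default they contribute 0 to the mean,
with an ``exclude`` convention available that drops them from the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

from .gff_io import AlignedRead

__all__ = [
    "ProximityGraph",
    "Component",
    "interval_gap",
    "build_graph",
    "connected_components",
    "vertex_clustering",
    "component_clustering",
]

Degree1Convention = Literal["zero", "exclude"]


@dataclass(frozen=True, slots=True)
class Component:
    """A maximal connected set of vertices ('vertex-island') on one chromosome."""

    members: frozenset[int]
    chrom: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a component must have at least one member")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProximityGraph:
    """Simple undirected graph over the reads of one dataset.

    Vertex ``v`` is the index of ``reads[v]``; vertex indexing follows input
    order, so runs are reproducible.  ``adjacency[v]`` is the neighbour set of
    ``v``; adjacency is kept symmetric and self-loop free by construction.
    """

    reads: Sequence[AlignedRead]
    adjacency: list[set[int]]
    min_inclusion_distance: int

    @property
    def n_vertices(self) -> int:
        return len(self.reads)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency) // 2

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def neighbors(self, v: int) -> set[int]:
        return self.adjacency[v]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each edge once as (u, v) with u < v."""
        for u, nbrs in enumerate(self.adjacency):
            for v in nbrs:
                if u < v:
                    yield (u, v)


def interval_gap(a: AlignedRead, b: AlignedRead) -> int:
    """Number of nucleotides strictly between two same-chromosome reads.

    Negative when the intervals overlap, 0 when they abut.  For reads ordered
    so that ``a.start <= b.start`` this is ``b.start - a.end - 1``.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap is only defined for reads on the same chromosome")
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end - 1


def build_graph(reads: Sequence[AlignedRead], M: int) -> ProximityGraph:
    """Build the proximity graph at minimum inclusion distance ``M``.

    For every unordered pair of same-chromosome reads an edge exists iff
    ``interval_gap(a, b) < M`` (strict).  Uses a sort-and-sweep within each
    chromosome: reads are processed in start order and a read ``a`` stays a
    live edge candidate only while ``a.end >= current_start - M``; once it
    drops below that bound it can never connect to a later read, because
    starts are non-decreasing.  The edge set is identical to brute-force
    all-pairs evaluation.
    """
    if M < 0:
        raise ValueError(f"minimum inclusion distance must be >= 0, got {M}")
    adjacency: list[set[int]] = [set() for _ in reads]

    by_chrom: dict[str, list[int]] = {}
    for idx, r in enumerate(reads):
        by_chrom.setdefault(r.chrom, []).append(idx)

    for indices in by_chrom.values():
        order = sorted(indices, key=lambda i: (reads[i].start, reads[i].end, i))
        active: list[int] = []  # candidate partners, pruned by end coordinate
        for b in order:
            start_b = reads[b].start
            cutoff = start_b - M
            still_live: list[int] = []
            for a in active:
                if reads[a].end >= cutoff:
                    still_live.append(a)
                    # gap = start_b - end_a - 1 < M  <=>  end_a >= start_b - M
                    adjacency[a].add(b)
                    adjacency[b].add(a)
            still_live.append(b)
            active = still_live
    return ProximityGraph(reads=reads, adjacency=adjacency, min_inclusion_distance=M)


def connected_components(graph: ProximityGraph) -> list[Component]:
    """Partition all vertices into maximal connected sets.

    Output order is deterministic: by chromosome, then smallest member start
    coordinate, then smallest member index.
    """
    seen = [False] * graph.n_vertices
    comps: list[Component] = []
    for root in range(graph.n_vertices):
        if seen[root]:
            continue
        stack = [root]
        seen[root] = True
        members = []
        while stack:
            v = stack.pop()
            members.append(v)
            for u in graph.adjacency[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(Component(frozenset(members), graph.reads[root].chrom))

    def sort_key(c: Component) -> tuple[str, int, int]:
        return (
            c.chrom,
            min(graph.reads[v].start for v in c.members),
            min(c.members),
        )

    return sorted(comps, key=sort_key)


def vertex_clustering(graph: ProximityGraph, v: int) -> float:
    """Watts–Strogatz local clustering coefficient of vertex ``v``.

    With ``k = degree(v)`` and ``t`` the number of edges among the neighbours
    of ``v``: returns ``t / (k (k - 1) / 2)`` for ``k >= 2`` and 0.0 for
    ``k <= 1`` (the ratio 0/0 is fixed to zero by convention).
    """
    if v < 0 or v >= graph.n_vertices:
        raise ValueError(f"vertex {v} not in graph of {graph.n_vertices} vertices")
    nbrs = graph.adjacency[v]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(len(graph.adjacency[u] & nbrs) for u in nbrs) // 2
    return links / (k * (k - 1) / 2)


def component_clustering(
    graph: ProximityGraph,
    component: Component,
    degree1: Degree1Convention = "zero",
) -> float:
    """Clustering coefficient gamma of a component: the mean over its vertices.

    ``degree1='zero'`` (default): degree-<=1 vertices contribute 0 to the
    mean, so a two-read component has gamma 0.  ``degree1='exclude'``: such
    vertices are dropped from the average; if none remain, gamma is 0.
    """
    if not component.members:
        raise ValueError("cannot compute clustering of an empty component")
    if degree1 == "zero":
        vals = [vertex_clustering(graph, v) for v in component.members]
    elif degree1 == "exclude":
        vals = [
            vertex_clustering(graph, v)
            for v in component.members
            if graph.degree(v) >= 2
        ]
        if not vals:
            return 0.0
    else:
        raise ValueError(f"unknown degree-1 convention {degree1!r}")
    return sum(vals) / len(vals)
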