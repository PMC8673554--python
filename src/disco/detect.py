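"""Cluster the breakpoint graph into events and emit consensus junction calls.

An event cluster is a maximal set of edges connected through shared or
within-window breakends with compatible orientation; distinct events
(different chromosome pairs, incompatible retained sides, or beyond the
window) are never joined. Within a cluster, splice-like edges sharing a
breakend are grouped as splice isoforms of one event.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .graph import BreakpointGraph, Edge, GraphParams
from .model import SPLICE_LIKE, BreakEnd, JunctionCall


@dataclass
class EventCluster:
    """A connected set of edges belonging to one rearrangement event."""

    edges: list[Edge]
    total_score: float = 0.0
    # indices into ``edges`` forming splice-isoform families (filled by
    # splice_variant_correction); edges not in any family are singletons
    variant_groups: list[list[int]] = field(default_factory=list)

    @property
    def span_key(self) -> tuple:
        first = min(e.breakendA.sort_key for e in self.edges)
        return first


def _sides_compatible(a: BreakEnd, b: BreakEnd) -> bool:
    return (
        a.chrom == b.chrom
        and a.retained_side == b.retained_side
        and (a.strand == b.strand or "." in (a.strand, b.strand))
    )


def edges_linked(e: Edge, f: Edge, window: int) -> bool:
    """Linkage predicate: same head-to-tail status and chromosome pair,
    compatible orientation per side, and either an exactly shared
    breakend on one side or both sides within the window."""
    if e.head_to_tail != f.head_to_tail:
        return False
    if not (_sides_compatible(e.breakendA, f.breakendA) and _sides_compatible(e.breakendB, f.breakendB)):
        return False
    dA = abs(e.breakendA.pos - f.breakendA.pos)
    dB = abs(e.breakendB.pos - f.breakendB.pos)
    sharedA = e.breakendA.key == f.breakendA.key
    sharedB = e.breakendB.key == f.breakendB.key
    return sharedA or sharedB or (dA < window and dB < window)


def extract_clusters(graph: BreakpointGraph) -> list[EventCluster]:
    """Connected components of the edge linkage relation.

    Output is sorted by descending total score, then genomic order, so
    event ids are deterministic.
    """
    params = graph.params
    edges = sorted(graph.edges.values(), key=lambda e: e.key)
    g = nx.Graph()
    g.add_nodes_from(range(len(edges)))
    # bucket by chromosome pair to avoid the full quadratic sweep
    buckets: dict[tuple, list[int]] = {}
    for i, e in enumerate(edges):
        buckets.setdefault((e.breakendA.chrom, e.breakendB.chrom, e.head_to_tail), []).append(i)
    for idxs in buckets.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                if edges_linked(edges[i], edges[j], params.merge_window_nt):
                    g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        comp_edges = [edges[i] for i in sorted(comp)]
        total = sum(e.score(params) for e in comp_edges)
        clusters.append(EventCluster(edges=comp_edges, total_score=total))
    clusters.sort(key=lambda c: (-c.total_score, c.span_key))
    return clusters


def splice_variant_correction(clusters: list[EventCluster]) -> list[EventCluster]:
    """Group splice-like edges that share a breakend into isoform families.

    Mirrors multiple exonic junctions of one fusion event (alternative
    acceptor/donor exons) being reported under a single event. Evidence
    counts stay attached to their own edges; nothing is double-assigned.
    """
    for cluster in clusters:
        parent = list(range(len(cluster.edges)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        splice_idx = [
            i for i, e in enumerate(cluster.edges) if e.provisional_type == SPLICE_LIKE
        ]
        for ii, i in enumerate(splice_idx):
            for j in splice_idx[ii + 1 :]:
                ei, ej = cluster.edges[i], cluster.edges[j]
                if ei.breakendA.key == ej.breakendA.key or ei.breakendB.key == ej.breakendB.key:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in splice_idx:
            groups.setdefault(find(i), []).append(i)
        cluster.variant_groups = sorted(
            (sorted(v) for v in groups.values() if len(v) > 1), key=lambda v: v[0]
        )
    return clusters


def _consensus_groups(cluster: EventCluster, params: GraphParams) -> list[list[int]]:
    """Partition a cluster's edges into consensus junction groups.

    Base-precise edges group by single-linkage within a small jitter
    window on both sides (same type); imprecise (spanning-only) edges
    attach within the full merge window. Distinct isoforms, whose
    breakends differ by more than the jitter on one side, stay separate.
    """
    edges = cluster.edges
    n = len(edges)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    def compatible(ei: Edge, ej: Edge) -> bool:
        return (
            ei.head_to_tail == ej.head_to_tail
            and _sides_compatible(ei.breakendA, ej.breakendA)
            and _sides_compatible(ei.breakendB, ej.breakendB)
        )

    precise = [i for i in range(n) if edges[i].n_precise > 0]
    imprecise = [i for i in range(n) if edges[i].n_precise == 0]
    # base-precise edges: single linkage within the jitter window, same type
    for ii, i in enumerate(precise):
        for j in precise[ii + 1 :]:
            ei, ej = edges[i], edges[j]
            if not compatible(ei, ej) or ei.provisional_type != ej.provisional_type:
                continue
            dA = abs(ei.breakendA.pos - ej.breakendA.pos)
            dB = abs(ei.breakendB.pos - ej.breakendB.pos)
            if dA <= params.consensus_jitter_nt and dB <= params.consensus_jitter_nt:
                union(i, j)
    # imprecise (spanning-only) edges attach to the nearest precise edge
    # within the merge window; they never bridge two precise groups
    leftovers = []
    for i in imprecise:
        best = None
        for j in precise:
            ei, ej = edges[i], edges[j]
            if not compatible(ei, ej):
                continue
            dA = abs(ei.breakendA.pos - ej.breakendA.pos)
            dB = abs(ei.breakendB.pos - ej.breakendB.pos)
            if dA < params.merge_window_nt and dB < params.merge_window_nt:
                if best is None or dA + dB < best[0]:
                    best = (dA + dB, j)
        if best is not None:
            union(i, best[1])
        else:
            leftovers.append(i)
    for ii, i in enumerate(leftovers):
        for j in leftovers[ii + 1 :]:
            ei, ej = edges[i], edges[j]
            if not compatible(ei, ej):
                continue
            dA = abs(ei.breakendA.pos - ej.breakendA.pos)
            dB = abs(ei.breakendB.pos - ej.breakendB.pos)
            if dA < params.merge_window_nt and dB < params.merge_window_nt:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(v) for v in groups.values()), key=lambda v: v[0])


def _merged_interval(ends: list[BreakEnd]) -> tuple[int, int]:
    los = [bk.interval[0] for bk in ends if bk.interval]
    his = [bk.interval[1] for bk in ends if bk.interval]
    if not los:
        p = ends[0].pos
        return (p, p + 1)
    lo, hi = max(los), min(his)
    if lo >= hi:  # disjoint: fall back to the union
        lo, hi = min(los), max(his)
    return lo, hi


def call_junctions(
    clusters: list[EventCluster], params: Optional[GraphParams] = None
) -> list[JunctionCall]:
    """One consensus call per junction group of each event cluster.

    The consensus position is the modal base-precise split-read pair
    (ties to the smallest coordinates); spanning-only groups report the
    midpoint of their merged uncertainty interval with its width.
    """
    params = params or GraphParams()
    calls: list[JunctionCall] = []
    for event_id, cluster in enumerate(clusters):
        variant_of = {}
        for gid, grp in enumerate(cluster.variant_groups, start=1):
            for i in grp:
                variant_of[i] = gid
        for group in _consensus_groups(cluster, params):
            edges = [cluster.edges[i] for i in group]
            pos_counts: Counter = Counter()
            for e in edges:
                pos_counts.update(e.pos_counts)
            n_split = sum(e.n_precise for e in edges)
            n_spanning = sum(e.n_spanning for e in edges)
            score = sum(e.score(params) for e in edges)
            startsA = set().union(*(e.startsA for e in edges))
            startsB = set().union(*(e.startsB for e in edges))
            ref = edges[0]
            if pos_counts:
                best = max(pos_counts.values())
                posA, posB = min(p for p, c in pos_counts.items() if c == best)
                bkA = ref.breakendA.moved_to(posA)
                bkB = ref.breakendB.moved_to(posB)
                uncertainty = 0
            else:
                loA, hiA = _merged_interval([e.breakendA for e in edges])
                loB, hiB = _merged_interval([e.breakendB for e in edges])
                bkA = ref.breakendA.moved_to((loA + hiA) // 2, precise=False)
                bkB = ref.breakendB.moved_to((loB + hiB) // 2, precise=False)
                uncertainty = max(hiA - loA, hiB - loB)
            if bkB.sort_key < bkA.sort_key:
                bkA, bkB = bkB, bkA
                startsA, startsB = startsB, startsA
            calls.append(
                JunctionCall(
                    breakendA=bkA,
                    breakendB=bkB,
                    n_split=n_split,
                    n_spanning=n_spanning,
                    score=score,
                    event_id=event_id,
                    variant_group=variant_of.get(group[0], 0),
                    uncertainty_nt=uncertainty,
                    startsA=tuple(sorted(startsA)),
                    startsB=tuple(sorted(startsB)),
                    circ_flag=edges[0].head_to_tail,
                )
            )
    calls.sort(key=lambda c: (c.event_id, c.breakendA.sort_key, c.breakendB.sort_key))
    return calls


def detect(graph: BreakpointGraph) -> list[JunctionCall]:
    """merge → cluster → splice-variant correction → consensus calls."""
    from .graph import merge_nearby_breakends

    merged = merge_nearby_breakends(graph)
    clusters = splice_variant_correction(extract_clusters(merged))
    return call_junctions(clusters, merged.params)
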