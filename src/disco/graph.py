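"""Breakpoint graph: breakend nodes with typed, weighted evidence edges.

Edges derived from splice-like and genomic evidence between the same
positions are kept separate; head-to-tail (back-splice-like) edges are
tagged and never merge with non-head-to-tail edges.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    GENOMIC,
    HEAD_TO_TAIL_SPLIT,
    SPANNING_PAIR,
    SPLICE_LIKE,
    SPLIT_READ,
    BreakEnd,
    ReadEvidence,
)


@dataclass
class GraphParams:
    """Thresholds and evidence weights.

    ``merge_window_nt`` mirrors the library insert size: spanning-pair
    breakends closer than this (strictly) to a base-precise split-read
    breakend are absorbed into it. Split reads are up-weighted because
    they pin the junction to the base. ``min_reads`` >= 2 enforces the
    more-than-one-read calling rule.
    """

    merge_window_nt: int = 450
    w_split: float = 3.0
    w_spanning: float = 1.0
    min_score: float = 6.0
    min_reads: int = 2
    consensus_jitter_nt: int = 10

    def __post_init__(self) -> None:
        if self.merge_window_nt <= 0:
            raise ValueError("merge_window_nt must be > 0")
        if self.min_reads < 2:
            raise ValueError("min_reads must be >= 2")


@dataclass
class Edge:
    """Aggregated evidence between one canonical breakend pair."""

    breakendA: BreakEnd
    breakendB: BreakEnd
    provisional_type: str  # SPLICE_LIKE or GENOMIC (mixed never occurs here)
    head_to_tail: bool = False
    n_split: int = 0
    n_spanning: int = 0
    n_head_to_tail: int = 0
    # joint counter of base-precise (posA, posB) observations
    pos_counts: Counter = field(default_factory=Counter)
    startsA: set = field(default_factory=set)
    startsB: set = field(default_factory=set)

    @property
    def n_precise(self) -> int:
        return self.n_split + self.n_head_to_tail

    @property
    def n_total(self) -> int:
        return self.n_split + self.n_spanning + self.n_head_to_tail

    def score(self, params: GraphParams) -> float:
        return params.w_split * self.n_precise + params.w_spanning * self.n_spanning

    @property
    def key(self) -> tuple:
        return (
            self.breakendA.key,
            self.breakendB.key,
            self.provisional_type,
            self.head_to_tail,
        )

    def absorb(self, other: "Edge") -> None:
        self.n_split += other.n_split
        self.n_spanning += other.n_spanning
        self.n_head_to_tail += other.n_head_to_tail
        self.pos_counts.update(other.pos_counts)
        self.startsA |= other.startsA
        self.startsB |= other.startsB


class BreakpointGraph:
    """Multigraph over breakends, keyed by (pair, type, head-to-tail)."""

    def __init__(self, params: Optional[GraphParams] = None):
        self.params = params or GraphParams()
        self.edges: dict[tuple, Edge] = {}
        self.n_evidence = 0

    @property
    def nodes(self) -> set[tuple]:
        out = set()
        for e in self.edges.values():
            out.add(e.breakendA.key)
            out.add(e.breakendB.key)
        return out

    def add_evidence(self, ev: ReadEvidence) -> None:
        if ev.breakendA is None or ev.category is None:
            raise ValueError("evidence must be classified with breakends inferred")
        h2t = ev.category == HEAD_TO_TAIL_SPLIT
        ptype = ev.provisional_type or GENOMIC
        key = (ev.breakendA.key, ev.breakendB.key, ptype, h2t)
        edge = self.edges.get(key)
        if edge is None:
            edge = Edge(ev.breakendA, ev.breakendB, ptype, head_to_tail=h2t)
            self.edges[key] = edge
        if ev.category == SPLIT_READ:
            edge.n_split += 1
        elif ev.category == HEAD_TO_TAIL_SPLIT:
            edge.n_head_to_tail += 1
        else:
            edge.n_spanning += 1
        if ev.category in (SPLIT_READ, HEAD_TO_TAIL_SPLIT):
            edge.pos_counts[(ev.breakendA.pos, ev.breakendB.pos)] += 1
        edge.startsA.add(ev.armA.start)
        edge.startsB.add(ev.armB.start)
        self.n_evidence += 1


def build_graph(
    evidence: Iterable[ReadEvidence], params: Optional[GraphParams] = None
) -> BreakpointGraph:
    """Insert classified evidence into a fresh breakpoint graph."""
    graph = BreakpointGraph(params)
    for ev in evidence:
        graph.add_evidence(ev)
    return graph


def _compatible_strand(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def merge_nearby_breakends(graph: BreakpointGraph) -> BreakpointGraph:
    """Absorb imprecise (spanning) breakends into nearby split-read nodes.

    An imprecise node moves to the nearest base-precise node strictly
    within ``merge_window_nt`` that shares chrom, retained side and a
    compatible strand (and head-to-tail status). Base-precise nodes are
    never moved. When both sides of a spanning edge land on a pair that
    already has split support, its counts are summed into that edge; the
    operation is idempotent and conserves all evidence counts.
    """
    w = graph.params.merge_window_nt
    # precise nodes grouped by (chrom, retained_side, h2t)
    precise: dict[tuple, list[BreakEnd]] = {}
    for e in graph.edges.values():
        if e.n_precise > 0:
            for bk in (e.breakendA, e.breakendB):
                precise.setdefault((bk.chrom, bk.retained_side, e.head_to_tail), []).append(bk)
    for lst in precise.values():
        lst.sort(key=lambda bk: (bk.pos, bk.strand))

    def target_for(bk: BreakEnd, h2t: bool) -> Optional[BreakEnd]:
        cands = precise.get((bk.chrom, bk.retained_side, h2t), [])
        best = None
        best_d = w
        for cand in cands:
            if not _compatible_strand(bk.strand, cand.strand):
                continue
            d = abs(cand.pos - bk.pos)
            if d < best_d or (d == best_d and best is not None and cand.pos < best.pos):
                best, best_d = cand, d
        return best

    new_edges: dict[tuple, Edge] = {}
    for e in sorted(graph.edges.values(), key=lambda e: (-e.n_precise, e.key)):
        bkA, bkB = e.breakendA, e.breakendB
        if e.n_precise == 0:
            tA = target_for(bkA, e.head_to_tail)
            tB = target_for(bkB, e.head_to_tail)
            if tA is not None:
                bkA = tA
            if tB is not None:
                bkB = tB
            if bkB.sort_key < bkA.sort_key:
                bkA, bkB = bkB, bkA
                e = Edge(
                    bkA,
                    bkB,
                    e.provisional_type,
                    e.head_to_tail,
                    e.n_split,
                    e.n_spanning,
                    e.n_head_to_tail,
                    Counter({(pb, pa): c for (pa, pb), c in e.pos_counts.items()}),
                    set(e.startsB),
                    set(e.startsA),
                )
        # choose a host edge at this pair: prefer one with split support
        host = None
        if e.n_precise == 0:
            for ptype in (SPLICE_LIKE, GENOMIC):
                for h2t in (e.head_to_tail,):
                    k = (bkA.key, bkB.key, ptype, h2t)
                    cand = new_edges.get(k)
                    if cand is not None and cand.n_precise > 0:
                        host = cand
                        break
                if host is not None:
                    break
        if host is not None:
            host.absorb(e)
            continue
        k = (bkA.key, bkB.key, e.provisional_type, e.head_to_tail)
        existing = new_edges.get(k)
        if existing is not None:
            existing.absorb(e)
        else:
            new_edges[k] = Edge(
                bkA,
                bkB,
                e.provisional_type,
                e.head_to_tail,
                e.n_split,
                e.n_spanning,
                e.n_head_to_tail,
                Counter(e.pos_counts),
                set(e.startsA),
                set(e.startsB),
            )
    merged = BreakpointGraph(graph.params)
    merged.edges = new_edges
    merged.n_evidence = graph.n_evidence
    return merged


def graph_summary(graph: BreakpointGraph) -> dict:
    """Serializable counters: nodes, edges by type, evidence totals."""
    by_type: dict[str, int] = {}
    n_split = n_spanning = n_h2t = 0
    for e in graph.edges.values():
        label = ("head_to_tail_" if e.head_to_tail else "") + e.provisional_type
        by_type[label] = by_type.get(label, 0) + 1
        n_split += e.n_split
        n_spanning += e.n_spanning
        n_h2t += e.n_head_to_tail
    return {
        "n_nodes": len(graph.nodes),
        "n_edges": len(graph.edges),
        "edges_by_type": dict(sorted(by_type.items())),
        "n_split": n_split,
        "n_spanning": n_spanning,
        "n_head_to_tail": n_h2t,
        "total_evidence": n_split + n_spanning + n_h2t,
    }
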