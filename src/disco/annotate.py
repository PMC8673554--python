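"""Filtering, exonic/intronic labelling, gene annotation and circRNA flagging.

The exonic/intronic label encodes mechanism, not location: exonic means
the junction was produced by splicing (both breakends at annotated —
or, via splice motifs, cryptic — exon boundaries); intronic means the
junction spans the genomic breakpoint itself, as seen in pre-mRNA reads.
A genomic breakpoint that happens to fall inside an exon therefore still
gets the intronic (genomic) label.
"""
from __future__ import annotations

import csv
import logging
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from . import motifs
from .model import LEFT, RIGHT, BreakEnd, JunctionCall

logger = logging.getLogger("disco")

EXONIC = "exonic"
INTRONIC = "intronic"

_NONSTANDARD = re.compile(r"(_alt$|_random$|_decoy$|^chrUn|^HLA-)")


@dataclass
class GeneModel:
    """Transcript-union gene model: sorted, non-overlapping exon intervals."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s1 >= e1 or s2 < e1:
                raise ValueError(f"exons of {self.gene_id} must be sorted and non-overlapping")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class FilterParams:
    min_reads: int = 2
    min_split: int = 1
    min_arm_entropy: float = 0.5  # fraction of distinct read start positions
    exclude_nonstandard_contigs: bool = True
    exon_boundary_tolerance_nt: int = 2

    def __post_init__(self) -> None:
        if self.min_reads < 2:
            raise ValueError("min_reads must be >= 2 (junctions need more than one read)")


class GeneIndex:
    """Interval index over gene spans plus sorted exon-boundary arrays."""

    def __init__(self, models: Iterable[GeneModel], tolerance_nt: int = 2):
        self.models = list(models)
        self.tolerance_nt = tolerance_nt
        self._trees: dict[str, IntervalTree] = {}
        self._exon_starts: dict[str, list[int]] = {}
        self._exon_ends: dict[str, list[int]] = {}  # position of last exon base
        for m in self.models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.start, m.end, m)
            for s, e in m.exons:
                self._exon_starts.setdefault(m.chrom, []).append(s)
                self._exon_ends.setdefault(m.chrom, []).append(e - 1)
        for d in (self._exon_starts, self._exon_ends):
            for v in d.values():
                v.sort()

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def genes_at(self, chrom: str, pos: int, strand: Optional[str] = None) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        if strand in ("+", "-"):
            hits = [m for m in hits if m.strand == strand]
        return sorted(hits, key=lambda m: (m.gene_name, m.gene_id))

    def _near(self, arr: list[int], pos: int, tol: int) -> bool:
        i = bisect_left(arr, pos - tol)
        return i < len(arr) and arr[i] <= pos + tol

    def breakend_at_boundary(self, bk: BreakEnd, tol: Optional[int] = None) -> bool:
        """Splice-consistent boundary: a left-retained breakend must sit at
        an exon end, a right-retained one at an exon start."""
        tol = self.tolerance_nt if tol is None else tol
        if bk.retained_side == LEFT:
            return self._near(self._exon_ends.get(bk.chrom, []), bk.pos, tol)
        return self._near(self._exon_starts.get(bk.chrom, []), bk.pos, tol)

    def junction_at_boundaries(self, bkA: BreakEnd, bkB: BreakEnd, tol: Optional[int] = None) -> bool:
        return self.breakend_at_boundary(bkA, tol) and self.breakend_at_boundary(bkB, tol)


def read_gtf(path: str) -> list[GeneModel]:
    """Load gene models from GTF exon features (gene_id/gene_name attributes).

    Exons are unioned per gene into a non-overlapping transcript-union model.
    """
    genes: dict[str, dict] = {}
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(attr_re.findall(f[8]))
            gid = attrs.get("gene_id")
            if not gid:
                continue
            g = genes.setdefault(
                gid,
                {"name": attrs.get("gene_name", gid), "chrom": f[0], "strand": f[6], "exons": []},
            )
            g["exons"].append((int(f[3]) - 1, int(f[4])))  # GTF is 1-based inclusive
    out = []
    for gid, g in sorted(genes.items()):
        exons = sorted(g["exons"])
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out.append(GeneModel(gid, g["name"], g["chrom"], g["strand"], merged))
    return out


def write_gtf(models: Iterable[GeneModel], path: str, source: str = "disco") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; gene_name "{m.gene_name}";'
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")


def is_nonstandard_contig(chrom: str) -> bool:
    return bool(_NONSTANDARD.search(chrom))


def apply_filters(call: JunctionCall, params: Optional[FilterParams] = None) -> JunctionCall:
    """Evaluate all filter rules; every firing reason is reported."""
    params = params or FilterParams()
    reasons = []
    if call.n_reads < params.min_reads:
        reasons.append("insufficient_reads")
    if params.min_split > 0 and call.n_split < params.min_split:
        reasons.append("no_split_support")
    if call.n_reads > 0:
        frac = max(len(set(call.startsA)), len(set(call.startsB))) / call.n_reads
        if frac < params.min_arm_entropy:
            reasons.append("low_start_diversity")
    if params.exclude_nonstandard_contigs and (
        is_nonstandard_contig(call.breakendA.chrom) or is_nonstandard_contig(call.breakendB.chrom)
    ):
        reasons.append("nonstandard_contig")
    call.filter_reasons = tuple(reasons)
    call.filter_status = "failed" if reasons else "passed"
    return call


def classify_junction(
    call: JunctionCall,
    gene_index: Optional[GeneIndex] = None,
    reference=None,
    strict_motifs: bool = False,
) -> str:
    """Assign the exonic (splice fusion) vs intronic (genomic breakpoint) label.

    Exonic iff both breakends sit at annotated exon boundaries with
    splice-consistent orientation, or — in motif mode — both junction
    flanks match a canonical splice context (cryptic exons, possibly
    intergenic). Everything else is intronic.
    """
    bkA, bkB = call.breakendA, call.breakendB
    known = False
    label = INTRONIC
    if gene_index is not None and (gene_index.has_chrom(bkA.chrom) or gene_index.has_chrom(bkB.chrom)):
        known = True
        if gene_index.junction_at_boundaries(bkA, bkB):
            label = EXONIC
    if label == INTRONIC and reference is not None:

        def covered(bk: BreakEnd) -> bool:
            return motifs.fetch(reference, bk.chrom, bk.pos, bk.pos + 1) != ""

        if covered(bkA) and covered(bkB):
            known = True
            if motifs.junction_has_splice_motif(reference, bkA, bkB, strict=strict_motifs):
                label = EXONIC
    if not known and (gene_index is not None or reference is not None):
        logger.warning(
            "breakends %s/%s on contigs absent from annotation and reference; labelled intronic",
            bkA.chrom,
            bkB.chrom,
        )
    call.classification = label
    return label


def annotate_genes(
    call: JunctionCall, gene_index: GeneIndex, stranded: bool = False
) -> JunctionCall:
    """Record overlapping genes per breakend and the intergenic status."""

    def genes_for(bk: BreakEnd) -> tuple[str, ...]:
        strand = bk.strand if (stranded and bk.strand in "+-") else None
        return tuple(m.gene_name for m in gene_index.genes_at(bk.chrom, bk.pos, strand))

    call.genesA = genes_for(call.breakendA)
    call.genesB = genes_for(call.breakendB)
    n_in = sum(1 for g in (call.genesA, call.genesB) if g)
    call.intergenic_status = {2: "both_in_gene", 1: "one_intergenic", 0: "both_intergenic"}[n_in]
    return call


def read_circ_catalogue(path: str) -> set[tuple]:
    """Back-splice catalogue: TSV chrom/start/end/strand, 0-based half-open."""
    entries: set[tuple] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError):
                logger.warning("skipping malformed catalogue line %d: %r", ln, line.strip())
                continue
            strand = f[3] if len(f) > 3 and f[3] in "+-" else "."
            entries.add((chrom, start, end, strand))
    return entries


def flag_head_to_tail(
    call: JunctionCall, circ_catalogue: Optional[set] = None
) -> JunctionCall:
    """Head-to-tail geometry: same chrom and strand, acceptor upstream of
    donor (canonical first breakend right-retained, second left-retained).
    Catalogue matching demands exact (0-nt) agreement with a back-splice
    exon-junction entry."""
    a, b = call.breakendA, call.breakendB
    call.circ_flag = (
        a.chrom == b.chrom
        and (a.strand == b.strand or "." in (a.strand, b.strand))
        and a.retained_side == RIGHT
        and b.retained_side == LEFT
    )
    call.catalogue_match = False
    if call.circ_flag and circ_catalogue:
        for chrom, start, end, strand in circ_catalogue:
            if chrom != a.chrom or a.pos != start or b.pos != end - 1:
                continue
            if strand != "." and a.strand in "+-" and strand != a.strand:
                continue
            call.catalogue_match = True
            break
    return call


def classify_and_annotate(
    calls: list[JunctionCall],
    gene_index: Optional[GeneIndex] = None,
    reference=None,
    filter_params: Optional[FilterParams] = None,
    circ_catalogue: Optional[set] = None,
    stranded: bool = False,
    strict_motifs: bool = False,
) -> list[JunctionCall]:
    """Run filters, labelling, gene annotation and circRNA flagging in order."""
    for call in calls:
        apply_filters(call, filter_params)
        classify_junction(call, gene_index, reference, strict_motifs)
        if gene_index is not None:
            annotate_genes(call, gene_index, stranded=stranded)
        flag_head_to_tail(call, circ_catalogue)
    return calls


# ---------------------------------------------------------------------------
# junction table serialisation (1-based inclusive on disk)

_COLUMNS = [
    "chromA", "posA", "strandA", "retainedA",
    "chromB", "posB", "strandB", "retainedB",
    "n_split", "n_spanning", "distinct_startsA", "distinct_startsB",
    "score", "uncertainty_nt",
    "event_id", "variant_group", "classification",
    "filter_status", "filter_reasons", "circ_flag", "catalogue_match",
    "genesA", "genesB", "intergenic_status",
]

_HEADER_COMMENT = (
    "# coordinates are 1-based inclusive; a breakend is the last retained aligned base\n"
)


def write_junctions(calls: Iterable[JunctionCall], path: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for c in calls:
            w.writerow(
                [
                    c.breakendA.chrom, c.breakendA.pos + 1, c.breakendA.strand, c.breakendA.retained_side,
                    c.breakendB.chrom, c.breakendB.pos + 1, c.breakendB.strand, c.breakendB.retained_side,
                    c.n_split, c.n_spanning, len(set(c.startsA)), len(set(c.startsB)),
                    f"{c.score:g}", c.uncertainty_nt,
                    c.event_id, c.variant_group, c.classification or "",
                    c.filter_status, ",".join(c.filter_reasons), int(c.circ_flag), int(c.catalogue_match),
                    ",".join(c.genesA), ",".join(c.genesB), c.intergenic_status or "",
                ]
            )


def read_junctions(path: str) -> list[JunctionCall]:
    calls = []
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    rd = csv.DictReader(rows, delimiter="\t")
    for r in rd:
        calls.append(
            JunctionCall(
                breakendA=BreakEnd(r["chromA"], int(r["posA"]) - 1, r["retainedA"], r["strandA"]),
                breakendB=BreakEnd(r["chromB"], int(r["posB"]) - 1, r["retainedB"], r["strandB"]),
                n_split=int(r["n_split"]),
                n_spanning=int(r["n_spanning"]),
                # distinct-start counts round-trip as surrogate positions
                startsA=tuple(range(int(r["distinct_startsA"]))),
                startsB=tuple(range(int(r["distinct_startsB"]))),
                score=float(r["score"]),
                uncertainty_nt=int(r["uncertainty_nt"]),
                event_id=int(r["event_id"]),
                variant_group=int(r["variant_group"]),
                classification=r["classification"] or None,
                filter_status=r["filter_status"],
                filter_reasons=tuple(x for x in r["filter_reasons"].split(",") if x),
                circ_flag=bool(int(r["circ_flag"])),
                catalogue_match=bool(int(r["catalogue_match"])),
                genesA=tuple(x for x in r["genesA"].split(",") if x),
                genesB=tuple(x for x in r["genesB"].split(",") if x),
                intergenic_status=r["intergenic_status"] or None,
            )
        )
    return calls


def write_bedpe(calls: Iterable[JunctionCall], path: str) -> None:
    """BEDPE export (0-based half-open single-base intervals per breakend)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            a, b = c.breakendA, c.breakendB
            fh.write(
                f"{a.chrom}\t{a.pos}\t{a.pos + 1}\t{b.chrom}\t{b.pos}\t{b.pos + 1}\t"
                f"junction_{i}\t{c.score:g}\t{a.strand}\t{b.strand}\n"
            )
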