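"""Reading chimeric/discordant alignments and reconstructing fragment evidence.

Accepts either a standalone chimeric SAM/BAM or chimeric records embedded
in a main BAM as supplementary alignments. Split alignments of one read
must be linked by an SA-style cross-reference tag; mate pairs use the
standard paired flags.
"""
from __future__ import annotations

import json
import logging
import sys
from collections import defaultdict
from typing import Iterable, Iterator, Optional

import pysam

from . import motifs
from .model import (
    GENOMIC,
    HEAD_TO_TAIL_SPLIT,
    LEFT,
    RIGHT,
    SPANNING_PAIR,
    SPLICE_LIKE,
    SPLIT_READ,
    AlignmentArm,
    BreakEnd,
    LibraryLayout,
    ReadEvidence,
)

logger = logging.getLogger("disco")

DEFAULT_MIN_ARM_NT = 20


def _is_discordant(rec: pysam.AlignedSegment, insert_max: int) -> bool:
    if rec.is_unmapped or rec.is_secondary or rec.is_qcfail or rec.is_duplicate:
        return False
    if rec.is_supplementary or rec.has_tag("SA"):
        return True
    if rec.is_paired and not rec.mate_is_unmapped:
        if rec.reference_id != rec.next_reference_id:
            return True
        if rec.is_reverse == rec.mate_is_reverse:  # same-orientation mates
            return True
        if rec.template_length and abs(rec.template_length) > insert_max:
            return True
    return False


def read_chimeric_records(
    path: str,
    region: Optional[tuple[str, int, int]] = None,
    layout: Optional[LibraryLayout] = None,
) -> Iterator[pysam.AlignedSegment]:
    """Stream records flagged chimeric/supplementary or mate-discordant.

    Concordant records are skipped. With ``region`` the file must be
    coordinate-sorted and indexed.
    """
    layout = layout or LibraryLayout()
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        if region is not None:
            if not af.has_index():
                raise IOError(
                    f"region query needs an index: missing {path}.bai (or .csi); "
                    f"run `disco fix` first"
                )
            it: Iterable[pysam.AlignedSegment] = af.fetch(*region)
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if _is_discordant(rec, layout.expected_insert_max_nt):
                yield rec


def arm_from_record(rec: pysam.AlignedSegment) -> AlignmentArm:
    """Build an AlignmentArm (reference orientation) from an aligned record."""
    cig = rec.cigartuples or []
    clip_left = sum(n for op, n in cig[:1] if op in (4, 5))
    if len(cig) > 1 and cig[1][0] in (4, 5) and cig[0][0] in (4, 5):
        clip_left += cig[1][1]
    clip_right = sum(n for op, n in cig[-1:] if op in (4, 5))
    strand = "-" if rec.is_reverse else "+"
    # read bases preceding this arm in original read orientation
    read_offset = clip_right if rec.is_reverse else clip_left
    return AlignmentArm(
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand=strand,
        clip_left_nt=clip_left,
        clip_right_nt=clip_right,
        read_offset=read_offset,
    )


def _read_number(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired:
        return 0
    return 1 if rec.is_read1 else 2


def pair_read_fragments(
    records: Iterable[pysam.AlignedSegment],
    layout: Optional[LibraryLayout] = None,
    min_arm_nt: int = DEFAULT_MIN_ARM_NT,
    counters: Optional[dict] = None,
) -> list[ReadEvidence]:
    """Reconstruct per-fragment evidence (arm pairs) from chimeric records.

    A read with supplementary alignments yields split evidence from arms
    adjacent in read order; a mate pair without split evidence yields one
    spanning evidence. Fragments with an absent partner arm are dropped
    and counted as orphans; name collisions are dropped as malformed.
    Output is deterministically sorted by canonical breakend pair then
    fragment id (breakends are inferred downstream; the sort here uses
    arm coordinates, which determine them).
    """
    layout = layout or LibraryLayout()
    if counters is None:
        counters = {}
    counters.setdefault("total_fragments", 0)
    counters.setdefault("emitted", 0)
    counters.setdefault("orphaned", 0)
    counters.setdefault("malformed", 0)
    counters.setdefault("dropped_short_arm", 0)
    counters.setdefault("dropped", 0)
    counters.setdefault("multi_segment_fragments", 0)

    by_fragment: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for rec in records:
        by_fragment[rec.query_name].append(rec)

    out: list[ReadEvidence] = []
    for name in sorted(by_fragment):
        recs = by_fragment[name]
        counters["total_fragments"] += 1
        # name collision: two primaries for the same read number
        primaries: dict[int, pysam.AlignedSegment] = {}
        malformed = False
        for r in recs:
            if not r.is_supplementary:
                rn = _read_number(r)
                if rn in primaries:
                    malformed = True
                primaries[rn] = r
        if malformed:
            counters["malformed"] += 1
            continue

        emitted_any = False
        split_seen = False
        for rn in sorted({_read_number(r) for r in recs}):
            segs = [r for r in recs if _read_number(r) == rn]
            if len(segs) < 2:
                continue
            split_seen = True
            arms = sorted((arm_from_record(r) for r in segs), key=lambda a: a.read_offset)
            if len(arms) > 2:
                counters["multi_segment_fragments"] += 1
                logger.debug("fragment %s has %d chimeric segments", name, len(arms))
            for a, b in zip(arms, arms[1:]):
                if min(a.length, b.length) < min_arm_nt:
                    counters["dropped_short_arm"] += 1
                    continue
                out.append(ReadEvidence(fragment_id=name, armA=a, armB=b, from_same_read=True))
                emitted_any = True

        orphan = False
        if not split_seen:
            if 1 in primaries and 2 in primaries:
                a = arm_from_record(primaries[1])
                b = arm_from_record(primaries[2])
                out.append(ReadEvidence(fragment_id=name, armA=a, armB=b, from_same_read=False))
                emitted_any = True
            elif any(r.is_paired for r in recs):
                orphan = True
        if emitted_any:
            counters["emitted"] += 1
        elif orphan:
            counters["orphaned"] += 1
        else:
            counters["dropped"] += 1

    return out


def classify_evidence(
    ev: ReadEvidence,
    layout: Optional[LibraryLayout] = None,
    reference=None,
    exon_boundary_index=None,
    strict_motifs: bool = False,
) -> ReadEvidence:
    """Assign the evidence category and provisional edge type.

    Head-to-tail: both arms on one chrom+strand with the later-in-read
    arm mapping upstream of (or overlapping) the earlier one — the
    back-splice / small tandem duplication signature. Split boundaries
    at a canonical splice context (or annotated exon boundary when an
    index is supplied) are provisionally splice_like; everything else,
    including all spanning pairs, is provisionally genomic.
    """
    layout = layout or LibraryLayout()
    a, b = ev.armA, ev.armB
    if ev.from_same_read:
        earlier, later = (a, b) if a.read_offset <= b.read_offset else (b, a)
        if (
            a.chrom == b.chrom
            and a.strand == b.strand
            and later.start < earlier.end
        ):
            ev.category = HEAD_TO_TAIL_SPLIT
        else:
            ev.category = SPLIT_READ
    else:
        ev.category = SPANNING_PAIR

    infer_breakends(ev, layout)

    ev.provisional_type = GENOMIC
    if ev.category in (SPLIT_READ, HEAD_TO_TAIL_SPLIT):
        if exon_boundary_index is not None and exon_boundary_index.junction_at_boundaries(
            ev.breakendA, ev.breakendB
        ):
            ev.provisional_type = SPLICE_LIKE
        elif reference is not None and motifs.junction_has_splice_motif(
            reference, ev.breakendA, ev.breakendB, strict=strict_motifs
        ):
            ev.provisional_type = SPLICE_LIKE
    return ev


def _arm_breakend(
    arm: AlignmentArm,
    junction_right: bool,
    precise: bool,
    layout: LibraryLayout,
) -> BreakEnd:
    # mate-pair transcript strand is protocol-dependent (read2 maps opposite);
    # imprecise breakends rely on retained-side geometry only
    strand = arm.strand if (layout.stranded and precise) else "."
    w = layout.expected_insert_max_nt
    if junction_right:
        pos = arm.end - 1
        interval = None if precise else (pos, pos + w)
        return BreakEnd(arm.chrom, pos, LEFT, strand, precise=precise, interval=interval)
    pos = arm.start
    interval = None if precise else (max(0, pos - w + 1), pos + 1)
    return BreakEnd(arm.chrom, pos, RIGHT, strand, precise=precise, interval=interval)


def infer_breakends(ev: ReadEvidence, layout: Optional[LibraryLayout] = None) -> ReadEvidence:
    """Derive the two oriented breakends from the arm pair.

    Split-read breakends are base-precise at the last retained aligned
    base (junction side = the more heavily clipped arm side); spanning
    breakends sit at the arm's junction-facing bound with an uncertainty
    interval of at most the expected insert size.
    """
    layout = layout or LibraryLayout()
    precise = ev.from_same_read
    ends = []
    for arm in (ev.armA, ev.armB):
        if precise:
            if arm.clip_right_nt != arm.clip_left_nt:
                junction_right = arm.clip_right_nt > arm.clip_left_nt
            else:  # symmetric clips: fall back to read-order rule
                earlier = arm.read_offset <= min(ev.armA.read_offset, ev.armB.read_offset)
                junction_right = earlier == (arm.strand == "+")
        else:
            junction_right = arm.strand == "+"
        ends.append(_arm_breakend(arm, junction_right, precise, layout))
    ev.breakendA, ev.breakendB = ends
    ev.canonicalise()
    return ev


def collect_evidence(
    path: str,
    layout: Optional[LibraryLayout] = None,
    reference=None,
    exon_boundary_index=None,
    min_arm_nt: int = DEFAULT_MIN_ARM_NT,
    strict_motifs: bool = False,
    counters: Optional[dict] = None,
) -> list[ReadEvidence]:
    """File-to-evidence convenience: read, pair, classify, infer, sort."""
    layout = layout or LibraryLayout()
    if counters is None:
        counters = {}
    evidence = pair_read_fragments(
        read_chimeric_records(path, layout=layout),
        layout=layout,
        min_arm_nt=min_arm_nt,
        counters=counters,
    )
    for ev in evidence:
        classify_evidence(
            ev,
            layout,
            reference=reference,
            exon_boundary_index=exon_boundary_index,
            strict_motifs=strict_motifs,
        )
    evidence.sort(key=lambda e: e.sort_key)
    return evidence


def fix_alignment(in_path: str, out_path: str, threads: int = 1) -> dict:
    """Normalise a chimeric SAM/BAM to a coordinate-sorted, indexed BAM."""
    pysam.sort("-@", str(threads), "-o", out_path, in_path)  # type: ignore[attr-defined]
    pysam.index(out_path)  # type: ignore[attr-defined]
    counters: dict = {"total_records": 0, "chimeric_records": 0}
    layout = LibraryLayout()
    with pysam.AlignmentFile(out_path) as af:
        for rec in af.fetch(until_eof=True):
            counters["total_records"] += 1
            if _is_discordant(rec, layout.expected_insert_max_nt):
                counters["chimeric_records"] += 1
    return counters


def write_run_report(counters: dict, path: Optional[str] = None) -> None:
    """Emit per-file counters to stderr and optionally a JSON report."""
    for k, v in sorted(counters.items()):
        print(f"[disco] {k}: {v}", file=sys.stderr)
    if path:
        with open(path, "w") as fh:
            json.dump(counters, fh, indent=2, sort_keys=True)
            fh.write("\n")
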