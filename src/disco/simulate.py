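"""Synthetic genomes, gene models, planted rearrangements and chimeric reads.

Emulates the alignment-level signal of rRNA-minus (pre-mRNA rich) and
poly(A)+ (spliced-only) paired-end libraries: spliced fusion split reads
at exon boundaries, genomic-breakpoint split reads inside introns,
inverted/large-insert spanning pairs, back-splice (head-to-tail) reads,
and uniform random noise chimeras. Everything is deterministic under the
spec seed, so every pipeline stage is testable without external data.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from . import motifs
from .annotate import GeneModel, write_gtf
from .model import LEFT, RIGHT, BreakEnd

EVENT_TYPES = ("deletion", "inversion", "translocation", "tandem_duplication", "back_splice")

_MIN_ARM_NT = 20


@dataclass
class SimSpec:
    """Study conditions for one simulated library.

    Defaults mirror a 126-nt stranded paired-end library with a 300-600 nt
    fragment peak; 20 planted events with 30 split + 20 spanning reads
    each and 200 noise chimeras. ``pre_mrna_fraction`` is the chance a
    supporting read derives from unspliced pre-mRNA and therefore spans
    the genomic breakpoint instead of the fusion splice junction
    (~0.35 emulates rRNA-minus, ~0.02 poly(A)+ selection).
    """

    n_contigs: int = 4
    contig_length_nt: int = 300_000
    n_genes: int = 40
    exons_per_gene: int = 6
    exon_length_nt: int = 200
    intron_length_nt: int = 300
    n_events: int = 20
    event_mix: dict = field(
        default_factory=lambda: {
            "deletion": 0.30,
            "inversion": 0.20,
            "translocation": 0.30,
            "tandem_duplication": 0.10,
            "back_splice": 0.10,
        }
    )
    reads_per_event_split: int = 30
    reads_per_event_spanning: int = 20
    pre_mrna_fraction: float = 0.0
    read_length_nt: int = 126
    insert_mean_nt: int = 450
    insert_sd_nt: int = 50
    stranded: bool = True
    noise_reads: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.event_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_mix proportions must sum to 1, got {total}")
        if set(self.event_mix) - set(EVENT_TYPES):
            raise ValueError(f"unknown event types: {set(self.event_mix) - set(EVENT_TYPES)}")
        if self.read_length_nt < 2 * _MIN_ARM_NT:
            raise ValueError("read_length_nt must fit two minimum-length arms")
        if not 0.0 <= self.pre_mrna_fraction <= 1.0:
            raise ValueError("pre_mrna_fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per pipeline stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class FusionTruth:
    """Ground truth for one planted event.

    ``breakpointA/B`` are the genomic breakpoints (canonically ordered);
    ``exonic_pair`` is the fusion splice junction produced by the
    expressed transcript (absent only for events without one);
    ``splice_chain`` lists the exons of the expressed derivative.
    """

    event_id: int
    event_type: str
    breakpointA: BreakEnd
    breakpointB: BreakEnd
    expressed: bool = True
    splice_chain: tuple = ()
    exonic_pair: Optional[tuple[BreakEnd, BreakEnd]] = None
    expected_label: str = "exonic"  # exonic / intronic / both
    n_spliced_reads: int = 0
    n_genomic_reads: int = 0

    @property
    def has_genomic_junction(self) -> bool:
        return self.event_type != "back_splice"

    def expected_pairs(self) -> list[tuple[str, BreakEnd, BreakEnd]]:
        """(kind, bkA, bkB) for every junction this event's reads cover."""
        pairs = []
        if self.exonic_pair is not None and self.n_spliced_reads > 0:
            pairs.append(("exonic", *self.exonic_pair))
        if self.has_genomic_junction and self.n_genomic_reads > 0:
            pairs.append(("intronic", self.breakpointA, self.breakpointB))
        return pairs


# ---------------------------------------------------------------------------
# reference + annotation


def _gene_layout(spec: SimSpec) -> list[GeneModel]:
    """Deterministic non-overlapping gene placement (all forward strand)."""
    span = spec.exons_per_gene * spec.exon_length_nt + (spec.exons_per_gene - 1) * spec.intron_length_nt
    stride = span + 4000
    per_contig = -(-spec.n_genes // spec.n_contigs)
    if 5000 + per_contig * stride > spec.contig_length_nt:
        raise ValueError("contig_length_nt too small for the requested gene layout")
    models = []
    for g in range(spec.n_genes):
        contig = f"chr{g // per_contig + 1}"
        start = 5000 + (g % per_contig) * stride
        exons = []
        pos = start
        for _ in range(spec.exons_per_gene):
            exons.append((pos, pos + spec.exon_length_nt))
            pos += spec.exon_length_nt + spec.intron_length_nt
        models.append(GeneModel(f"SIMG{g + 1:04d}", f"SIMG{g + 1:04d}", contig, "+", exons))
    return models


def generate_reference(spec: SimSpec) -> tuple[dict[str, str], dict[str, int]]:
    """Random reference with canonical GT..AG motifs at every intron."""
    rng = spec.rng(1)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for i in range(spec.n_contigs):
        arr = rng.integers(0, 4, size=spec.contig_length_nt)
        seqs[f"chr{i + 1}"] = bases[arr].tobytes().decode()
    # embed splice motifs at generated exon boundaries
    for m in _gene_layout(spec):
        s = list(seqs[m.chrom])
        for (_, e1), (s2, _) in zip(m.exons, m.exons[1:]):
            s[e1], s[e1 + 1] = "G", "T"
            s[s2 - 2], s[s2 - 1] = "A", "G"
        seqs[m.chrom] = "".join(s)
    lengths = {c: len(s) for c, s in seqs.items()}
    return seqs, lengths


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def generate_annotation(spec: SimSpec, gtf_path: Optional[str] = None) -> list[GeneModel]:
    """Gene models matching the generated reference; optionally written as GTF."""
    models = _gene_layout(spec)
    if gtf_path:
        write_gtf(models, gtf_path)
    return models


# ---------------------------------------------------------------------------
# rearrangement planting


def _nudge_off_motif(reference: dict, bk: BreakEnd) -> BreakEnd:
    """Shift a planted genomic breakend off any canonical splice context."""
    pos = bk.pos
    for _ in range(10):
        cand = dataclasses.replace(bk, pos=pos)
        if not motifs.breakend_has_splice_motif(reference, cand):
            return cand
        pos += 1
    return dataclasses.replace(bk, pos=pos)


def plant_rearrangements(
    spec: SimSpec,
    reference: dict[str, str],
    models: Optional[list[GeneModel]] = None,
) -> list[FusionTruth]:
    """Plant ``n_events`` rearrangements over distinct genes.

    Genomic breakpoints land 30-280 nt inside the introns flanking the
    fusion exon boundaries (within the insert-size window, as expected
    for co-clustering of pre-mRNA and spliced evidence) and are nudged
    off canonical splice motifs.
    """
    models = models or _gene_layout(spec)
    rng = spec.rng(2)
    types = sorted(spec.event_mix)
    probs = np.array([spec.event_mix[t] for t in types])
    counts = np.floor(probs * spec.n_events).astype(int)
    while counts.sum() < spec.n_events:  # largest-remainder top-up
        frac = probs * spec.n_events - counts
        counts[int(np.argmax(frac))] += 1
    chosen: list[str] = []
    for t, c in zip(types, counts):
        chosen.extend([t] * int(c))
    rng.shuffle(chosen)

    by_contig: dict[str, list[GeneModel]] = {}
    order = rng.permutation(len(models))
    for i in order:
        by_contig.setdefault(models[i].chrom, []).append(models[i])
    pool = [models[i] for i in order]

    def take_pair(same_contig: bool) -> tuple[GeneModel, GeneModel]:
        for i in range(len(pool)):
            for j in range(len(pool)):
                if i == j:
                    continue
                a, b = pool[i], pool[j]
                same = a.chrom == b.chrom
                if same != same_contig:
                    continue
                if same and a.start >= b.start:
                    continue
                for k in sorted((i, j), reverse=True):
                    pool.pop(k)
                return a, b
        raise ValueError("gene pool exhausted; increase n_genes or n_contigs")

    def take_one() -> GeneModel:
        return pool.pop(0)

    truths = []
    for event_id, etype in enumerate(chosen):
        dA = int(rng.integers(30, 280))
        dB = int(rng.integers(30, 280))
        if etype in ("deletion", "translocation", "inversion"):
            gA, gB = take_pair(same_contig=etype != "translocation")
            iA = int(rng.integers(1, spec.exons_per_gene - 1))
            iB = int(rng.integers(1, spec.exons_per_gene - 1))
            donor = BreakEnd(gA.chrom, gA.exons[iA][1] - 1, LEFT, "+")
            if etype == "inversion":
                acceptor = BreakEnd(gB.chrom, gB.exons[iB][1] - 1, LEFT, "-")
                gbB = _nudge_off_motif(
                    reference, BreakEnd(gB.chrom, gB.exons[iB][1] - 1 + dB, LEFT, "-")
                )
            else:
                acceptor = BreakEnd(gB.chrom, gB.exons[iB][0], RIGHT, "+")
                gbB = _nudge_off_motif(
                    reference, BreakEnd(gB.chrom, gB.exons[iB][0] - dB, RIGHT, "+")
                )
            gbA = _nudge_off_motif(reference, BreakEnd(gA.chrom, gA.exons[iA][1] - 1 + dA, LEFT, "+"))
            chain = tuple((gA.chrom,) + e for e in gA.exons[: iA + 1]) + tuple(
                (gB.chrom,) + e for e in gB.exons[iB:]
            )
            truths.append(
                FusionTruth(event_id, etype, gbA, gbB, splice_chain=chain, exonic_pair=(donor, acceptor))
            )
        elif etype == "tandem_duplication":
            g = take_one()
            i = int(rng.integers(0, spec.exons_per_gene - 2))
            j = int(rng.integers(i + 1, spec.exons_per_gene - 1))
            # spliced duplication junction: exon j end back to exon i start
            donor = BreakEnd(g.chrom, g.exons[j][1] - 1, LEFT, "+")
            acceptor = BreakEnd(g.chrom, g.exons[i][0], RIGHT, "+")
            gbE = _nudge_off_motif(reference, BreakEnd(g.chrom, g.exons[j][1] - 1 + dA, LEFT, "+"))
            gbS = _nudge_off_motif(reference, BreakEnd(g.chrom, g.exons[i][0] - dB, RIGHT, "+"))
            truths.append(
                FusionTruth(
                    event_id,
                    etype,
                    gbS,
                    gbE,
                    splice_chain=tuple((g.chrom,) + e for e in g.exons[i : j + 1]),
                    exonic_pair=(acceptor, donor),
                )
            )
        else:  # back_splice
            g = take_one()
            i = int(rng.integers(0, spec.exons_per_gene - 2))
            j = int(rng.integers(i + 1, spec.exons_per_gene - 1))
            acceptor = BreakEnd(g.chrom, g.exons[i][0], RIGHT, "+")
            donor = BreakEnd(g.chrom, g.exons[j][1] - 1, LEFT, "+")
            truths.append(
                FusionTruth(
                    event_id,
                    "back_splice",
                    acceptor,
                    donor,
                    splice_chain=tuple((g.chrom,) + e for e in g.exons[i : j + 1]),
                    exonic_pair=(acceptor, donor),
                )
            )
    # canonical ordering of genomic pairs
    for t in truths:
        if t.breakpointB.sort_key < t.breakpointA.sort_key:
            t.breakpointA, t.breakpointB = t.breakpointB, t.breakpointA
        if t.exonic_pair is not None:
            a, b = t.exonic_pair
            if b.sort_key < a.sort_key:
                t.exonic_pair = (b, a)
    return truths


def circ_catalogue_from_truths(truths: list[FusionTruth]) -> set[tuple]:
    """Back-splice exon-junction entries (chrom, start, end, strand), half-open."""
    out = set()
    for t in truths:
        if t.event_type == "back_splice" and t.exonic_pair is not None:
            a, b = t.exonic_pair  # a: acceptor (right-retained), b: donor (left-retained)
            out.add((a.chrom, a.pos, b.pos + 1, "+"))
    return out


# ---------------------------------------------------------------------------
# read simulation


def _revcomp(s: str) -> str:
    return motifs.revcomp(s)


def _arm_seq(reference: dict, chrom: str, start: int, end: int, strand: str) -> str:
    s = reference[chrom][start:end]
    return _revcomp(s) if strand == "-" else s


class _SamBuilder:
    def __init__(self, contig_lengths: dict[str, int]):
        self.header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": c, "LN": contig_lengths[c]} for c in sorted(contig_lengths)],
            }
        )
        self.records: list[pysam.AlignedSegment] = []

    def _base(self, name: str, chrom: str, start: int, flag: int, cigar: str, seq: str) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(self.header)
        a.query_name = name
        a.flag = flag
        a.reference_id = self.header.get_tid(chrom)
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = seq
        return a

    def split_read(
        self,
        name: str,
        reference: dict,
        arm1: tuple[str, int, int, str],  # chrom, start, end, strand; earlier in read
        arm2: tuple[str, int, int, str],
    ) -> None:
        c1, s1, e1, st1 = arm1
        c2, s2, e2, st2 = arm2
        l1, l2 = e1 - s1, e2 - s2
        seq1 = _arm_seq(reference, c1, s1, e1, st1)
        seq2 = _arm_seq(reference, c2, s2, e2, st2)
        read_seq = seq1 + seq2
        # cigars in reference orientation; the other arm's bases are clipped
        cig1 = f"{l1}M{l2}S" if st1 == "+" else f"{l2}S{l1}M"
        cig2 = f"{l1}S{l2}M" if st2 == "+" else f"{l2}M{l1}S"
        sa1 = f"{c1},{s1 + 1},{st1},{cig1},60,0;"
        sa2 = f"{c2},{s2 + 1},{st2},{cig2},60,0;"
        f1 = 16 if st1 == "-" else 0
        f2 = 2048 | (16 if st2 == "-" else 0)
        r1 = self._base(name, c1, s1, f1, cig1, read_seq if st1 == "+" else _revcomp(read_seq))
        r1.set_tag("SA", sa2)
        r2 = self._base(name, c2, s2, f2, cig2, read_seq if st2 == "+" else _revcomp(read_seq))
        r2.set_tag("SA", sa1)
        self.records.extend([r1, r2])

    def mate_pair(
        self,
        name: str,
        reference: dict,
        arm1: tuple[str, int, int, str],
        arm2: tuple[str, int, int, str],
    ) -> None:
        c1, s1, e1, st1 = arm1
        c2, s2, e2, st2 = arm2
        l1, l2 = e1 - s1, e2 - s2
        f1 = 1 | 64 | (16 if st1 == "-" else 0) | (32 if st2 == "-" else 0)
        f2 = 1 | 128 | (16 if st2 == "-" else 0) | (32 if st1 == "-" else 0)
        r1 = self._base(name, c1, s1, f1, f"{l1}M", _arm_seq(reference, c1, s1, e1, st1))
        r2 = self._base(name, c2, s2, f2, f"{l2}M", _arm_seq(reference, c2, s2, e2, st2))
        for r, (oc, os) in ((r1, (c2, s2)), (r2, (c1, s1))):
            r.next_reference_id = self.header.get_tid(oc)
            r.next_reference_start = os
        if c1 == c2:
            span = max(e1, e2) - min(s1, s2)
            r1.template_length = span if s1 <= s2 else -span
            r2.template_length = -r1.template_length
        self.records.extend([r1, r2])

    def write(self, path: str) -> None:
        with pysam.AlignmentFile(path, "wh", header=self.header) as fh:
            for r in self.records:
                fh.write(r)


def _split_arms_for_pair(
    bk1: BreakEnd, bk2: BreakEnd, f: int, total: int
) -> tuple[tuple, tuple]:
    """Arm coordinates for a split read with f bases on the bk1 flank."""

    def arm(bk: BreakEnd, length: int) -> tuple[str, int, int, str]:
        strand = bk.strand if bk.strand in "+-" else "+"
        if bk.retained_side == LEFT:
            return (bk.chrom, bk.pos - length + 1, bk.pos + 1, strand)
        return (bk.chrom, bk.pos, bk.pos + length, strand)

    return arm(bk1, f), arm(bk2, total - f)


def _spanning_arms_for_pair(
    bk1: BreakEnd, bk2: BreakEnd, g1: int, g2: int, read_len: int
) -> tuple[tuple, tuple]:
    def arm(bk: BreakEnd, gap: int) -> tuple[str, int, int, str]:
        if bk.retained_side == LEFT:
            end = bk.pos - gap + 1
            return (bk.chrom, end - read_len, end, "+")
        start = bk.pos + gap
        return (bk.chrom, start, start + read_len, "-")

    return arm(bk1, g1), arm(bk2, g2)


def simulate_alignments(
    truths: list[FusionTruth],
    spec: SimSpec,
    reference: dict[str, str],
    sam_path: str,
) -> list[FusionTruth]:
    """Emit spec-conformant chimeric SAM records for the planted events.

    Spliced reads cross the fusion splice junction; with probability
    ``pre_mrna_fraction`` a read instead derives from pre-mRNA and spans
    the genomic breakpoint. Spanning pairs are only emitted for
    junctions without head-to-tail geometry (fragments within a circle
    or small duplication mostly look concordant). Noise reads are
    uniform random arm chimeras. Byte-identical output under one seed.
    """
    rng = spec.rng(3)
    lengths = {c: len(s) for c, s in reference.items()}
    sam = _SamBuilder(lengths)
    L = spec.read_length_nt
    min_f, max_f = _MIN_ARM_NT, L - _MIN_ARM_NT
    for t in truths:
        t.n_spliced_reads = 0
        t.n_genomic_reads = 0
        # split reads
        for i in range(spec.reads_per_event_split):
            genomic = t.has_genomic_junction and rng.random() < spec.pre_mrna_fraction
            if genomic:
                bk1, bk2 = t.breakpointA, t.breakpointB
                t.n_genomic_reads += 1
            else:
                bk1, bk2 = t.exonic_pair
                t.n_spliced_reads += 1
            f = int(rng.integers(min_f, max_f + 1))
            # read traverses the left-retained flank first where there is one
            if bk1.retained_side != LEFT and bk2.retained_side == LEFT:
                bk1, bk2 = bk2, bk1
            a1, a2 = _split_arms_for_pair(bk1, bk2, f, L)
            sam.split_read(f"sim_e{t.event_id:03d}_s{i:04d}", reference, a1, a2)
        # spanning pairs (non-head-to-tail junctions only)
        for i in range(spec.reads_per_event_spanning):
            genomic = t.has_genomic_junction and rng.random() < spec.pre_mrna_fraction
            pair = (t.breakpointA, t.breakpointB) if genomic else t.exonic_pair
            if pair is None:
                continue
            bk1, bk2 = pair
            if bk1.chrom == bk2.chrom and bk1.retained_side == RIGHT and bk2.retained_side == LEFT:
                continue  # head-to-tail geometry: skip pair emission
            insert = int(np.clip(rng.normal(spec.insert_mean_nt, spec.insert_sd_nt), 2 * L + 10, spec.insert_mean_nt + 3 * spec.insert_sd_nt))
            gsum = max(insert - 2 * L, 2)
            g1 = int(rng.integers(1, gsum))
            g2 = gsum - g1
            if genomic:
                t.n_genomic_reads += 1
            else:
                t.n_spliced_reads += 1
            a1, a2 = _spanning_arms_for_pair(bk1, bk2, g1, g2, L)
            sam.mate_pair(f"sim_e{t.event_id:03d}_p{i:04d}", reference, a1, a2)
    # noise chimeras: uniform random arm pairs
    contigs = sorted(lengths)
    for i in range(spec.noise_reads):
        f = int(rng.integers(min_f, max_f + 1))
        arms = []
        for length in (f, L - f):
            c = contigs[int(rng.integers(len(contigs)))]
            pos = int(rng.integers(1000, lengths[c] - 1000))
            strand = "+" if rng.random() < 0.5 else "-"
            arms.append((c, pos, pos + length, strand))
        sam.split_read(f"sim_noise_{i:05d}", reference, arms[0], arms[1])
    sam.write(sam_path)
    return truths


# ---------------------------------------------------------------------------
# truth serialisation + scoring


def write_truths(truths: list[FusionTruth], path: str) -> None:
    cols = [
        "event_id", "event_type",
        "chromA", "posA", "retainedA", "strandA",
        "chromB", "posB", "retainedB", "strandB",
        "exonic_chromA", "exonic_posA", "exonic_retainedA", "exonic_strandA",
        "exonic_chromB", "exonic_posB", "exonic_retainedB", "exonic_strandB",
        "expressed", "expected_label", "n_spliced_reads", "n_genomic_reads",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            ex = t.exonic_pair
            row = [
                t.event_id, t.event_type,
                t.breakpointA.chrom, t.breakpointA.pos + 1, t.breakpointA.retained_side, t.breakpointA.strand,
                t.breakpointB.chrom, t.breakpointB.pos + 1, t.breakpointB.retained_side, t.breakpointB.strand,
            ]
            if ex:
                row += [ex[0].chrom, ex[0].pos + 1, ex[0].retained_side, ex[0].strand,
                        ex[1].chrom, ex[1].pos + 1, ex[1].retained_side, ex[1].strand]
            else:
                row += [""] * 8
            row += [int(t.expressed), t.expected_label, t.n_spliced_reads, t.n_genomic_reads]
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    classification_accuracy: float
    exact_fraction: float
    n_calls: int
    n_truths: int
    n_true_positive_calls: int
    both_label_fraction: float  # of truths covered by both read kinds

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def score_against_truth(
    calls, truths: list[FusionTruth], window_nt: int = 40, passing_only: bool = True
) -> RecoveryScore:
    """Precision/recall/label accuracy of calls against planted truth.

    A call is a true positive iff both its breakends are within
    ``window_nt`` of a junction its truth's reads actually covered.
    Classification accuracy compares the call label against the covered
    junction's kind (splice junction -> exonic, genomic breakpoint ->
    intronic) over matched calls.
    """
    if passing_only:
        calls = [c for c in calls if c.passed]
    expected = []  # (truth_idx, kind, bkA, bkB)
    for ti, t in enumerate(truths):
        for kind, a, b in t.expected_pairs():
            expected.append((ti, kind, a, b))
    n_tp = 0
    n_correct = 0
    recovered: set[int] = set()
    matched_events_labels: dict[int, set[str]] = {}
    for c in calls:
        best = None
        for ti, kind, a, b in expected:
            if c.breakendA.chrom != a.chrom or c.breakendB.chrom != b.chrom:
                continue
            dA = abs(c.breakendA.pos - a.pos)
            dB = abs(c.breakendB.pos - b.pos)
            if dA <= window_nt and dB <= window_nt:
                d = dA + dB
                if best is None or d < best[0]:
                    best = (d, ti, kind)
        if best is not None:
            n_tp += 1
            _, ti, kind = best
            recovered.add(ti)
            if c.classification == kind:
                n_correct += 1
            matched_events_labels.setdefault(ti, set()).add(c.classification)
    n_exact = 0
    n_split_tp = 0
    for c in calls:
        if c.n_split == 0:
            continue
        best = None
        for ti, kind, a, b in expected:
            if c.breakendA.chrom != a.chrom or c.breakendB.chrom != b.chrom:
                continue
            dA = abs(c.breakendA.pos - a.pos)
            dB = abs(c.breakendB.pos - b.pos)
            if dA <= window_nt and dB <= window_nt and (best is None or dA + dB < best):
                best = dA + dB
        if best is not None:
            n_split_tp += 1
            if best == 0:
                n_exact += 1
    covered = {ti for ti, t in enumerate(truths) if t.expected_pairs()}
    both_kind = [
        ti for ti, t in enumerate(truths) if t.n_spliced_reads > 0 and t.n_genomic_reads > 0 and t.has_genomic_junction
    ]
    n_both = sum(
        1 for ti in both_kind if {"exonic", "intronic"} <= matched_events_labels.get(ti, set())
    )
    return RecoveryScore(
        precision=n_tp / len(calls) if calls else float("nan"),
        recall=len(recovered) / len(covered) if covered else float("nan"),
        classification_accuracy=n_correct / n_tp if n_tp else float("nan"),
        exact_fraction=n_exact / n_split_tp if n_split_tp else float("nan"),
        n_calls=len(calls),
        n_truths=len(truths),
        n_true_positive_calls=n_tp,
        both_label_fraction=n_both / len(both_kind) if both_kind else float("nan"),
    )


# ---------------------------------------------------------------------------
# one-call dataset convenience


@dataclass
class SimulatedDataset:
    spec: SimSpec
    reference: dict[str, str]
    contig_lengths: dict[str, int]
    models: list[GeneModel]
    truths: list[FusionTruth]
    sam_path: str
    circ_catalogue: set


def simulate_dataset(spec: SimSpec, outdir: str) -> SimulatedDataset:
    """Generate reference, annotation, events and chimeric SAM under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    reference, lengths = generate_reference(spec)
    write_fasta(reference, os.path.join(outdir, "reference.fa"))
    models = generate_annotation(spec, os.path.join(outdir, "annotation.gtf"))
    truths = plant_rearrangements(spec, reference, models)
    sam_path = os.path.join(outdir, "chimeric.sam")
    simulate_alignments(truths, spec, reference, sam_path)
    write_truths(truths, os.path.join(outdir, "truth.tsv"))
    return SimulatedDataset(
        spec=spec,
        reference=reference,
        contig_lengths=lengths,
        models=models,
        truths=truths,
        sam_path=sam_path,
        circ_catalogue=circ_catalogue_from_truths(truths),
    )
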