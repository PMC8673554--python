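"""Core domain types shared across the detection pipeline.

Coordinate convention: all positions are 0-based internally; half-open
intervals for ranges. Report output is converted to 1-based inclusive.
A breakend records the position of the *last retained aligned base* of
its flank, never the first lost base.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

# retained_side values: which genomic flank of the break survives in the
# derivative allele.
LEFT = "left_of_break"
RIGHT = "right_of_break"

# evidence categories
SPLIT_READ = "split_read"
SPANNING_PAIR = "spanning_pair"
HEAD_TO_TAIL_SPLIT = "head_to_tail_split"

# provisional edge types
SPLICE_LIKE = "splice_like"
GENOMIC = "genomic"

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """An oriented single-base genomic coordinate (0-based)."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class BreakEnd:
    """One oriented side of a junction.

    ``pos`` is the last retained aligned base. ``precise`` is True for
    split-read (base-precise) breakends; spanning-pair breakends are
    imprecise and carry a half-open ``interval`` of candidate positions
    whose width is bounded by the library insert size.
    """

    chrom: str
    pos: int
    retained_side: str  # LEFT or RIGHT
    strand: str = "."
    precise: bool = True
    interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.retained_side not in (LEFT, RIGHT):
            raise ValueError(f"bad retained_side {self.retained_side!r}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.interval is not None and self.interval[0] >= self.interval[1]:
            raise ValueError("interval must be non-empty half-open")

    @property
    def position(self) -> GenomicPosition:
        return GenomicPosition(self.chrom, self.pos, self.strand)

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.retained_side, self.strand)

    @property
    def key(self) -> tuple:
        """Identity used for graph node lookup (ignores precision metadata)."""
        return (self.chrom, self.pos, self.strand, self.retained_side)

    def moved_to(self, pos: int, precise: bool = True) -> "BreakEnd":
        return replace(self, pos=pos, precise=precise, interval=None)


def order_breakends(a: BreakEnd, b: BreakEnd) -> tuple[BreakEnd, BreakEnd, bool]:
    """Canonical (lexicographic) ordering; returns (first, second, swapped)."""
    if b.sort_key < a.sort_key:
        return b, a, True
    return a, b, False


@dataclass(frozen=True)
class AlignmentArm:
    """One aligned segment of a discordant fragment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    clip_left_nt: int = 0
    clip_right_nt: int = 0
    read_offset: int = 0  # read bases preceding this arm, in read order

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("arm must have start < end")
        if min(self.clip_left_nt, self.clip_right_nt) < 0:
            raise ValueError("clip counts must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadEvidence:
    """One fragment's discordant signal, decomposed into two arms.

    ``from_same_read`` distinguishes split alignments of a single read
    from mate pairs; it drives the split/spanning categorisation.
    """

    fragment_id: str
    armA: AlignmentArm
    armB: AlignmentArm
    from_same_read: bool
    category: Optional[str] = None  # SPLIT_READ / SPANNING_PAIR / HEAD_TO_TAIL_SPLIT
    provisional_type: Optional[str] = None  # SPLICE_LIKE / GENOMIC
    breakendA: Optional[BreakEnd] = None
    breakendB: Optional[BreakEnd] = None

    def canonicalise(self) -> None:
        """Order breakends (and matching arms) lexicographically."""
        if self.breakendA is None or self.breakendB is None:
            raise ValueError("breakends not yet inferred")
        if self.breakendB.sort_key < self.breakendA.sort_key:
            self.breakendA, self.breakendB = self.breakendB, self.breakendA
            self.armA, self.armB = self.armB, self.armA

    @property
    def sort_key(self) -> tuple:
        return (self.breakendA.sort_key, self.breakendB.sort_key, self.fragment_id)


@dataclass
class LibraryLayout:
    """Sequencing-library properties that drive discordance calls.

    ``expected_insert_max_nt`` doubles as the breakend merge window: read
    pairs cannot constrain a breakpoint more tightly than the insert size.
    """

    stranded: bool = True
    strand_protocol: str = "forward"  # forward / reverse / none
    expected_insert_max_nt: int = 450
    read_length_nt: int = 126

    def __post_init__(self) -> None:
        if self.expected_insert_max_nt <= 0:
            raise ValueError("expected_insert_max_nt must be > 0")
        if self.read_length_nt <= 0:
            raise ValueError("read_length_nt must be > 0")
        if not self.stranded:
            self.strand_protocol = "none"


@dataclass
class JunctionCall:
    """A detected junction: two consensus breakends plus evidence and labels."""

    breakendA: BreakEnd
    breakendB: BreakEnd
    n_split: int = 0
    n_spanning: int = 0
    score: float = 0.0
    event_id: int = -1
    variant_group: int = 0
    uncertainty_nt: int = 0
    startsA: tuple[int, ...] = ()
    startsB: tuple[int, ...] = ()
    classification: Optional[str] = None  # "exonic" / "intronic"
    filter_status: str = "unfiltered"  # "passed" / "failed"
    filter_reasons: tuple[str, ...] = ()
    circ_flag: bool = False
    catalogue_match: bool = False
    genesA: tuple[str, ...] = ()
    genesB: tuple[str, ...] = ()
    intergenic_status: Optional[str] = None

    @property
    def n_reads(self) -> int:
        return self.n_split + self.n_spanning

    @property
    def interchromosomal(self) -> bool:
        return self.breakendA.chrom != self.breakendB.chrom

    @property
    def passed(self) -> bool:
        return self.filter_status == "passed"
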