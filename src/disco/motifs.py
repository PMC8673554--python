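"""Canonical splice-site dinucleotide checks against a reference sequence."""
from __future__ import annotations

from .model import LEFT, RIGHT, BreakEnd

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _donor_acceptor_sets(strict: bool) -> tuple[set[str], set[str]]:
    if strict:
        return {"GT"}, {"AG"}
    # GT-AG plus the minor GC-AG and AT-AC spliceosomal classes
    return {"GT", "GC", "AT"}, {"AG", "AC"}


def fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice a reference (pyfaidx.Fasta or dict of strings), uppercased."""
    if start < 0:
        return ""
    try:
        seq = reference[chrom][start:end]
    except KeyError:
        return ""
    return str(seq).upper()


def breakend_has_splice_motif(reference, breakend: BreakEnd, strict: bool = False) -> bool:
    """True if the intron-side dinucleotide at this breakend is splice-consistent.

    A left-retained breakend abuts an intron starting at pos+1 (donor in
    forward transcription, acceptor read in reverse); a right-retained
    breakend abuts an intron ending at pos-1. Either transcription
    direction is accepted.
    """
    donors, acceptors = _donor_acceptor_sets(strict)
    if breakend.retained_side == LEFT:
        s = fetch(reference, breakend.chrom, breakend.pos + 1, breakend.pos + 3)
        ok = donors | {revcomp(a) for a in acceptors}
    else:
        s = fetch(reference, breakend.chrom, breakend.pos - 2, breakend.pos)
        ok = acceptors | {revcomp(d) for d in donors}
    return len(s) == 2 and s in ok


def junction_has_splice_motif(reference, bkA: BreakEnd, bkB: BreakEnd, strict: bool = False) -> bool:
    """Both sides of the junction carry a canonical splice context."""
    return breakend_has_splice_motif(reference, bkA, strict) and breakend_has_splice_motif(
        reference, bkB, strict
    )
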