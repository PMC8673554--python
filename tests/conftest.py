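"""Shared fixtures: hand-built SAM files and evidence factories."""
from __future__ import annotations

import pytest

from disco.model import (
    GENOMIC,
    LEFT,
    RIGHT,
    SPANNING_PAIR,
    SPLIT_READ,
    AlignmentArm,
    BreakEnd,
    ReadEvidence,
)

CONTIGS = {
    "chr1": 1_000_000,
    "chr2": 1_000_000,
    "chr3": 2_000_000,
    "chr4": 1_000_000,
    "chr5": 1_000_000,
    "chr7": 1_000_000,
    "chr8": 1_000_000,
    "chr11_KI270721v1_random": 100_000,
}


def sam_text(records: list[str], contigs: dict[str, int] = CONTIGS) -> str:
    head = ["@HD\tVN:1.6\tSO:unsorted"]
    head += [f"@SQ\tSN:{c}\tLN:{l}" for c, l in contigs.items()]
    return "\n".join(head + records) + "\n"


def write_sam(path, records: list[str], contigs: dict[str, int] = CONTIGS) -> str:
    path.write_text(sam_text(records, contigs))
    return str(path)


def sam_record(
    name: str,
    flag: int,
    chrom: str,
    pos1: int,
    cigar: str,
    seq_len: int,
    rnext: str = "*",
    pnext1: int = 0,
    tlen: int = 0,
    tags: str = "",
) -> str:
    fields = [
        name, str(flag), chrom, str(pos1), "60", cigar,
        rnext, str(pnext1), str(tlen), "A" * seq_len, "*",
    ]
    if tags:
        fields.append(tags)
    return "\t".join(fields)


def make_split_evidence(
    frag: str,
    chromA: str,
    posA: int,
    sideA: str,
    chromB: str,
    posB: int,
    sideB: str,
    strandA: str = "+",
    strandB: str = "+",
    ptype: str = GENOMIC,
    category: str = SPLIT_READ,
    startA: int | None = None,
    startB: int | None = None,
) -> ReadEvidence:
    """Directly assembled base-precise evidence (bypasses SAM parsing)."""
    sA = startA if startA is not None else max(0, posA - 50)
    sB = startB if startB is not None else max(0, posB - 50)
    ev = ReadEvidence(
        fragment_id=frag,
        armA=AlignmentArm(chromA, sA, sA + 60, strandA),
        armB=AlignmentArm(chromB, sB, sB + 60, strandB),
        from_same_read=True,
        category=category,
        provisional_type=ptype,
        breakendA=BreakEnd(chromA, posA, sideA, strandA),
        breakendB=BreakEnd(chromB, posB, sideB, strandB),
    )
    ev.canonicalise()
    return ev


def make_spanning_evidence(
    frag: str,
    chromA: str,
    posA: int,
    sideA: str,
    chromB: str,
    posB: int,
    sideB: str,
    window: int = 450,
    startA: int | None = None,
    startB: int | None = None,
) -> ReadEvidence:
    def bk(chrom: str, pos: int, side: str) -> BreakEnd:
        if side == LEFT:
            iv = (pos, pos + window)
        else:
            iv = (max(0, pos - window + 1), pos + 1)
        return BreakEnd(chrom, pos, side, ".", precise=False, interval=iv)

    sA = startA if startA is not None else max(0, posA - 80)
    sB = startB if startB is not None else max(0, posB - 80)
    ev = ReadEvidence(
        fragment_id=frag,
        armA=AlignmentArm(chromA, sA, sA + 60, "+"),
        armB=AlignmentArm(chromB, sB, sB + 60, "-"),
        from_same_read=False,
        category=SPANNING_PAIR,
        provisional_type=GENOMIC,
        breakendA=bk(chromA, posA, sideA),
        breakendB=bk(chromB, posB, sideB),
    )
    ev.canonicalise()
    return ev


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default study-condition simulation, shared across tests."""
    from disco.simulate import SimSpec, simulate_dataset

    outdir = tmp_path_factory.mktemp("sim_default")
    return simulate_dataset(SimSpec(seed=11), str(outdir))


@pytest.fixture(scope="session")
def default_calls(default_dataset):
    from disco.pipeline import run_pipeline

    ds = default_dataset
    return run_pipeline(
        ds.sam_path,
        gene_models=ds.models,
        reference=ds.reference,
        circ_catalogue=ds.circ_catalogue,
    )
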