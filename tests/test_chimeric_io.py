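"""Discordance predicates, fragment pairing and breakend inference."""
from __future__ import annotations

import pytest

from disco.chimeric_io import (
    classify_evidence,
    collect_evidence,
    infer_breakends,
    pair_read_fragments,
    read_chimeric_records,
)
from disco.model import (
    HEAD_TO_TAIL_SPLIT,
    LEFT,
    RIGHT,
    SPANNING_PAIR,
    SPLICE_LIKE,
    SPLIT_READ,
    AlignmentArm,
    LibraryLayout,
    ReadEvidence,
)

from conftest import sam_record, write_sam


def _six_record_sam(tmp_path):
    """Two concordant, two interchromosomal-mate, two split-read records."""
    records = [
        # concordant FR pair, insert 300 (skipped)
        sam_record("frag1", 99, "chr1", 1001, "100M", 100, "=", 1201, 300),
        sam_record("frag1", 147, "chr1", 1201, "100M", 100, "=", 1001, -300),
        # mates on chr1 and chr7 (both yielded)
        sam_record("frag2", 65, "chr1", 2001, "100M", 100, "chr7", 501),
        sam_record("frag2", 129, "chr7", 501, "100M", 100, "chr1", 2001),
        # split read: 75 nt on chr1 + 51 nt on chr8 linked by SA
        sam_record("frag3", 0, "chr1", 101, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
        sam_record("frag3", 2048, "chr8", 501, "75S51M", 126, tags="SA:Z:chr1,101,+,75M51S,60,0;"),
    ]
    return write_sam(tmp_path / "six.sam", records)


def test_discordance_predicates_on_six_record_fixture(tmp_path):
    path = _six_record_sam(tmp_path)
    recs = list(read_chimeric_records(path))
    names = sorted((r.query_name, r.is_supplementary) for r in recs)
    assert names == [("frag2", False), ("frag2", False), ("frag3", False), ("frag3", True)]


def test_empty_file_yields_empty_stream(tmp_path):
    path = write_sam(tmp_path / "empty.sam", [])
    assert list(read_chimeric_records(path)) == []


def test_unreadable_file_is_fatal(tmp_path):
    with pytest.raises(IOError):
        list(read_chimeric_records(str(tmp_path / "missing.sam")))


def test_region_query_without_index_names_the_index(tmp_path):
    path = _six_record_sam(tmp_path)
    with pytest.raises(IOError, match="index"):
        list(read_chimeric_records(path, region=("chr1", 0, 10_000)))


def test_split_read_pairs_into_one_evidence(tmp_path):
    path = _six_record_sam(tmp_path)
    counters: dict = {}
    evidence = pair_read_fragments(read_chimeric_records(path), counters=counters)
    by_frag = {ev.fragment_id: ev for ev in evidence}
    assert set(by_frag) == {"frag2", "frag3"}
    assert by_frag["frag3"].from_same_read
    assert not by_frag["frag2"].from_same_read
    assert counters["emitted"] == 2


def test_orphan_mate_counted_not_emitted(tmp_path):
    path = write_sam(
        tmp_path / "orphan.sam",
        [sam_record("frag4", 65, "chr2", 5001, "100M", 100, "chr7", 901)],
    )
    counters: dict = {}
    evidence = pair_read_fragments(read_chimeric_records(path), counters=counters)
    assert evidence == []
    assert counters["orphaned"] == 1


def test_name_collision_dropped_as_malformed(tmp_path):
    records = [
        sam_record("frag5", 0, "chr1", 101, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
        sam_record("frag5", 0, "chr3", 9001, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
    ]
    path = write_sam(tmp_path / "collide.sam", records)
    counters: dict = {}
    evidence = pair_read_fragments(read_chimeric_records(path), counters=counters)
    assert evidence == []
    assert counters["malformed"] == 1


def test_fragment_conservation_counters(tmp_path):
    records = [
        sam_record("frag1", 99, "chr1", 1001, "100M", 100, "=", 1201, 300),
        sam_record("frag1", 147, "chr1", 1201, "100M", 100, "=", 1001, -300),
        sam_record("frag2", 65, "chr1", 2001, "100M", 100, "chr7", 501),
        sam_record("frag2", 129, "chr7", 501, "100M", 100, "chr1", 2001),
        sam_record("frag3", 0, "chr1", 101, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
        sam_record("frag3", 2048, "chr8", 501, "75S51M", 126, tags="SA:Z:chr1,101,+,75M51S,60,0;"),
        sam_record("frag4", 65, "chr2", 5001, "100M", 100, "chr7", 901),
        sam_record("frag5", 0, "chr1", 101, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
        sam_record("frag5", 0, "chr3", 9001, "75M51S", 126, tags="SA:Z:chr8,501,+,75S51M,60,0;"),
    ]
    path = write_sam(tmp_path / "mix.sam", records)
    counters: dict = {}
    evidence = pair_read_fragments(read_chimeric_records(path), counters=counters)
    assert len(evidence) <= counters["total_fragments"]
    assert (
        counters["emitted"] + counters["orphaned"] + counters["malformed"] + counters["dropped"]
        == counters["total_fragments"]
    )


def _split_ev(armA: AlignmentArm, armB: AlignmentArm, frag="r1") -> ReadEvidence:
    return ReadEvidence(fragment_id=frag, armA=armA, armB=armB, from_same_read=True)


def test_head_to_tail_category():
    # second-in-read arm starts 2,000 nt upstream of the first arm's end
    a = AlignmentArm("chr5", 10_000, 10_075, "+", clip_right_nt=51, read_offset=0)
    b = AlignmentArm("chr5", 8_000, 8_051, "+", clip_left_nt=75, read_offset=75)
    ev = classify_evidence(_split_ev(a, b))
    assert ev.category == HEAD_TO_TAIL_SPLIT


def test_head_to_tail_invariant_under_arm_swap():
    a = AlignmentArm("chr5", 10_000, 10_075, "+", clip_right_nt=51, read_offset=0)
    b = AlignmentArm("chr5", 8_000, 8_051, "+", clip_left_nt=75, read_offset=75)
    ev1 = classify_evidence(_split_ev(a, b))
    ev2 = classify_evidence(_split_ev(b, a))
    assert ev1.category == ev2.category == HEAD_TO_TAIL_SPLIT
    assert (ev1.breakendA, ev1.breakendB) == (ev2.breakendA, ev2.breakendB)


def test_inverted_mates_are_spanning_pair():
    a = AlignmentArm("chr3", 10_000, 10_100, "+")
    b = AlignmentArm("chr3", 1_010_000, 1_010_100, "+")
    ev = ReadEvidence("p1", a, b, from_same_read=False)
    assert classify_evidence(ev).category == SPANNING_PAIR


def test_canonical_splice_context_marks_splice_like():
    # junction flanks read GT..AG on the reference by construction
    ref = {"chr1": "A" * 175 + "GT" + "A" * 100, "chr8": "A" * 498 + "AG" + "C" * 100}
    a = AlignmentArm("chr1", 100, 175, "+", clip_right_nt=51, read_offset=0)
    b = AlignmentArm("chr8", 500, 551, "+", clip_left_nt=75, read_offset=75)
    ev = classify_evidence(_split_ev(a, b), reference=ref)
    assert ev.category == SPLIT_READ
    assert ev.provisional_type == SPLICE_LIKE


def test_breakends_from_clip_structure():
    a = AlignmentArm("chr1", 100, 175, "+", clip_right_nt=51, read_offset=0)
    b = AlignmentArm("chr8", 500, 551, "+", clip_left_nt=75, read_offset=75)
    ev = infer_breakends(_split_ev(a, b))
    assert (ev.breakendA.chrom, ev.breakendA.pos, ev.breakendA.retained_side) == ("chr1", 174, LEFT)
    assert (ev.breakendB.chrom, ev.breakendB.pos, ev.breakendB.retained_side) == ("chr8", 500, RIGHT)
    assert ev.breakendA.precise and ev.breakendB.precise


def test_breakend_inference_is_pure():
    a = AlignmentArm("chr1", 100, 175, "+", clip_right_nt=51, read_offset=0)
    b = AlignmentArm("chr8", 500, 551, "+", clip_left_nt=75, read_offset=75)
    ev1 = infer_breakends(_split_ev(a, b))
    ev2 = infer_breakends(_split_ev(a, b))
    assert (ev1.breakendA, ev1.breakendB) == (ev2.breakendA, ev2.breakendB)


def test_spanning_breakend_interval_bounded_by_insert():
    layout = LibraryLayout(expected_insert_max_nt=450)
    a = AlignmentArm("chr2", 10, 85, "+")
    b = AlignmentArm("chr2", 900, 975, "+")
    ev = classify_evidence(ReadEvidence("p2", a, b, from_same_read=False), layout)
    for bk in (ev.breakendA, ev.breakendB):
        assert not bk.precise
        lo, hi = bk.interval
        assert hi - lo <= 450
        assert lo <= bk.pos < hi


def test_evidence_stream_deterministic_order(default_dataset):
    ds = default_dataset
    ev1 = collect_evidence(ds.sam_path, reference=ds.reference)
    ev2 = collect_evidence(ds.sam_path, reference=ds.reference)
    key = lambda e: (e.sort_key, e.category)
    assert [key(e) for e in ev1] == [key(e) for e in ev2]
    assert [e.sort_key for e in ev1] == sorted(e.sort_key for e in ev1)


def test_planted_split_junctions_recovered_exactly(default_dataset):
    """Every planted junction with split reads yields evidence at the
    exact planted coordinates."""
    ds = default_dataset
    ev = collect_evidence(ds.sam_path, reference=ds.reference)
    seen = {(e.breakendA.chrom, e.breakendA.pos, e.breakendB.chrom, e.breakendB.pos) for e in ev}
    for t in ds.truths:
        if t.n_spliced_reads > 0:
            a, b = t.exonic_pair
            assert (a.chrom, a.pos, b.chrom, b.pos) in seen
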