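"""Filters, exonic/intronic labelling, gene annotation and circRNA flags."""
from __future__ import annotations

import pytest

from disco.annotate import (
    EXONIC,
    INTRONIC,
    FilterParams,
    GeneIndex,
    GeneModel,
    annotate_genes,
    apply_filters,
    classify_junction,
    flag_head_to_tail,
    read_circ_catalogue,
    read_gtf,
    read_junctions,
    write_gtf,
    write_junctions,
)
from disco.model import LEFT, RIGHT, BreakEnd, JunctionCall


def make_call(
    chromA="chr1",
    posA=1000,
    sideA=LEFT,
    chromB="chr2",
    posB=5000,
    sideB=RIGHT,
    strandA="+",
    strandB="+",
    n_split=5,
    n_spanning=3,
    startsA=None,
    startsB=None,
):
    n = n_split + n_spanning
    return JunctionCall(
        breakendA=BreakEnd(chromA, posA, sideA, strandA),
        breakendB=BreakEnd(chromB, posB, sideB, strandB),
        n_split=n_split,
        n_spanning=n_spanning,
        startsA=tuple(startsA if startsA is not None else range(n)),
        startsB=tuple(startsB if startsB is not None else range(n)),
    )


# --- filters ---------------------------------------------------------------


def test_single_read_always_fails_insufficient_reads():
    call = apply_filters(make_call(n_split=1, n_spanning=0))
    assert call.filter_status == "failed"
    assert "insufficient_reads" in call.filter_reasons


def test_two_reads_pass_at_defaults():
    call = apply_filters(make_call(n_split=2, n_spanning=0))
    assert call.passed


def test_spanning_only_call_fails_no_split_support():
    call = apply_filters(make_call(n_split=0, n_spanning=6))
    assert "no_split_support" in call.filter_reasons


def test_nonstandard_contig_filtered():
    call = apply_filters(make_call(chromA="chr11_KI270721v1_random"))
    assert "nonstandard_contig" in call.filter_reasons


def test_start_diversity_fraction():
    bad = apply_filters(make_call(n_split=10, n_spanning=0, startsA=[7], startsB=[9]))
    assert "low_start_diversity" in bad.filter_reasons
    good = apply_filters(make_call(n_split=10, n_spanning=0))
    assert good.passed


def test_all_firing_reasons_reported():
    call = apply_filters(
        make_call(chromA="chrUn_GL000195v1", n_split=0, n_spanning=1, startsA=[1], startsB=[1])
    )
    assert set(call.filter_reasons) == {
        "insufficient_reads",
        "no_split_support",
        "nonstandard_contig",
    }


def test_filters_monotone_in_split_count():
    for n in range(1, 8):
        call = apply_filters(make_call(n_split=n, n_spanning=0))
        if n >= 2:
            assert "insufficient_reads" not in call.filter_reasons


def test_min_reads_floor():
    with pytest.raises(ValueError):
        FilterParams(min_reads=1)


# --- classification --------------------------------------------------------


@pytest.fixture
def two_gene_index():
    models = [
        GeneModel("G1", "GENEA", "chr1", "+", [(100, 300), (500, 700), (900, 1100)]),
        GeneModel("G2", "GENEB", "chr2", "+", [(4000, 4200), (4500, 4700), (5000, 5200)]),
    ]
    return models, GeneIndex(models, tolerance_nt=2)


def test_exon_boundary_junction_is_exonic(two_gene_index):
    _, index = two_gene_index
    # donor at exon end of G1, acceptor at exon start of G2
    call = make_call(posA=299, sideA=LEFT, posB=4500, sideB=RIGHT, chromB="chr2")
    assert classify_junction(call, index) == EXONIC


def test_mid_intron_junction_is_intronic(two_gene_index):
    _, index = two_gene_index
    call = make_call(posA=400, sideA=LEFT, posB=4850, sideB=RIGHT, chromB="chr2")
    assert classify_junction(call, index) == INTRONIC


def test_cryptic_intergenic_donor_with_annotated_acceptor_is_exonic(two_gene_index):
    _, index = two_gene_index
    # intergenic donor with GT context + annotated acceptor boundary
    ref = {"chr1": "A" * 2001 + "GT" + "A" * 500, "chr2": "C" * 6000}
    call = make_call(posA=2000, sideA=LEFT, posB=4500, sideB=RIGHT, chromB="chr2")
    # boundary rule alone says intronic; motif rule on both sides:
    ref["chr2"] = "C" * 4498 + "AG" + "C" * 2000
    assert classify_junction(call, index, reference=ref) == EXONIC


def test_in_exon_genomic_breakpoint_labelled_intronic(two_gene_index):
    """A breakpoint inside an exon without splice context encodes breakage,
    not splicing, and keeps the genomic (intronic) label."""
    _, index = two_gene_index
    ref = {"chr1": "A" * 3000, "chr2": "C" * 7000}
    call = make_call(posA=200, sideA=LEFT, posB=5100, sideB=RIGHT, chromB="chr2")
    assert classify_junction(call, index, reference=ref) == INTRONIC


def test_every_call_gets_exactly_one_label(two_gene_index):
    _, index = two_gene_index
    calls = [
        make_call(posA=p, sideA=s) for p in (0, 299, 400) for s in (LEFT, RIGHT)
    ]
    for c in calls:
        assert classify_junction(c, index) in (EXONIC, INTRONIC)
        assert c.classification in (EXONIC, INTRONIC)


# --- gene annotation -------------------------------------------------------


def test_intergenic_status_levels(two_gene_index):
    _, index = two_gene_index
    both = annotate_genes(make_call(posA=200, posB=4600, chromB="chr2"), index)
    assert both.intergenic_status == "both_in_gene"
    assert both.genesA == ("GENEA",) and both.genesB == ("GENEB",)
    one = annotate_genes(make_call(posA=200, posB=50_000, chromB="chr2"), index)
    assert one.intergenic_status == "one_intergenic"
    neither = annotate_genes(make_call(posA=50_000, posB=60_000, chromB="chr2"), index)
    assert neither.intergenic_status == "both_intergenic"


def test_unstranded_membership_ignores_gene_strand(two_gene_index):
    _, index = two_gene_index
    call = make_call(posA=200, strandA="-", posB=4600, chromB="chr2")
    stranded = annotate_genes(call, index, stranded=True)
    assert stranded.genesA == ()  # antisense breakend excluded
    unstranded = annotate_genes(call, index, stranded=False)
    assert unstranded.genesA == ("GENEA",)


# --- head-to-tail / circRNA -----------------------------------------------


def test_head_to_tail_orientation_flags_circ():
    call = make_call(
        chromA="chr4", posA=1000, sideA=RIGHT, chromB="chr4", posB=2000, sideB=LEFT
    )
    assert flag_head_to_tail(call).circ_flag


def test_interchromosomal_never_circ():
    call = make_call(chromA="chr4", posA=1000, sideA=RIGHT, chromB="chr5", posB=2000, sideB=LEFT)
    assert not flag_head_to_tail(call).circ_flag


def test_ordinary_orientation_not_circ():
    call = make_call(chromA="chr4", posA=1000, sideA=LEFT, chromB="chr4", posB=2000, sideB=RIGHT)
    assert not flag_head_to_tail(call).circ_flag


def test_catalogue_match_requires_exactness():
    catalogue = {("chr4", 1000, 2001, "+")}
    exact = flag_head_to_tail(
        make_call(chromA="chr4", posA=1000, sideA=RIGHT, chromB="chr4", posB=2000, sideB=LEFT),
        catalogue,
    )
    assert exact.circ_flag and exact.catalogue_match
    off_by_one = flag_head_to_tail(
        make_call(chromA="chr4", posA=1001, sideA=RIGHT, chromB="chr4", posB=2000, sideB=LEFT),
        catalogue,
    )
    assert off_by_one.circ_flag and not off_by_one.catalogue_match


def test_malformed_catalogue_lines_skipped(tmp_path):
    path = tmp_path / "circ.tsv"
    path.write_text("chr1\t100\t900\t+\nbroken line\nchr2\tnotanumber\t5\t-\n")
    assert read_circ_catalogue(str(path)) == {("chr1", 100, 900, "+")}


# --- IO round trips --------------------------------------------------------


def test_gtf_round_trip(tmp_path, two_gene_index):
    models, _ = two_gene_index
    path = tmp_path / "genes.gtf"
    write_gtf(models, str(path))
    back = read_gtf(str(path))
    assert [(m.gene_id, m.chrom, m.strand, m.exons) for m in back] == [
        (m.gene_id, m.chrom, m.strand, m.exons) for m in models
    ]


def test_junction_table_round_trip(tmp_path):
    calls = [
        apply_filters(make_call()),
        apply_filters(make_call(chromA="chr4", posA=1000, sideA=RIGHT, chromB="chr4", posB=2000, sideB=LEFT, n_split=1, n_spanning=0)),
    ]
    for c in calls:
        c.classification = INTRONIC
    path = tmp_path / "junctions.tsv"
    write_junctions(calls, str(path))
    back = read_junctions(str(path))
    assert len(back) == 2
    for orig, rt in zip(calls, back):
        assert rt.breakendA.key == orig.breakendA.key
        assert rt.breakendB.key == orig.breakendB.key
        assert (rt.n_split, rt.n_spanning, rt.filter_status, rt.filter_reasons) == (
            orig.n_split, orig.n_spanning, orig.filter_status, orig.filter_reasons
        )
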