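"""Match an RNA-derived junction set against a second assay's breakpoints.

Cross-assay comparison (e.g. RNA-seq junctions vs WGS breakpoints) uses
a two-sided window: both sides of a junction must lie within 40 genomic
nucleotides of the partner's sides. Head-to-tail junctions and
alternate-locus contigs are excluded first; each junction matches at
most once, nearest pair first.
"""
from disco.cohort import MatchParams, match_junction_sets
from disco.model import LEFT, RIGHT, BreakEnd, JunctionCall


def jc(chromA, posA, chromB, posB):
    return JunctionCall(
        breakendA=BreakEnd(chromA, posA, LEFT, "+"),
        breakendB=BreakEnd(chromB, posB, RIGHT, "+"),
        n_split=4,
    )


rna = [
    jc("chr1", 10_000, "chr5", 40_000),   # exact WGS partner
    jc("chr2", 20_000, "chr6", 50_000),   # partner shifted 38/12 nt -> match
    jc("chr3", 30_000, "chr7", 60_000),   # partner shifted 41 nt -> no match
    jc("chr4", 35_000, "chr8", 70_000),   # private to RNA
]
wgs = [
    jc("chr1", 10_000, "chr5", 40_000),
    jc("chr2", 20_038, "chr6", 50_012),
    jc("chr3", 30_041, "chr7", 60_000),
    jc("chr9", 1_000, "chr10", 2_000),    # private to WGS
]

res = match_junction_sets(rna, wgs, MatchParams(window_nt=40))
print(f"matched: {res.n_matched}, RNA-only: {len(res.only_a)}, WGS-only: {len(res.only_b)}")
for x, y in res.matched:
    d = abs(x.breakendA.pos - y.breakendA.pos) + abs(x.breakendB.pos - y.breakendB.pos)
    print(f"  {x.breakendA.chrom}:{x.breakendA.pos} ~ {y.breakendA.pos} (total offset {d} nt)")
print("a 41-nt offset on either side is outside the window and stays unmatched")
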