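# Methods

## Evidence model

A discordant fragment contributes one of three evidence categories:

- **split read** — one sequencing read aligned in two parts (primary +
  supplementary record linked by an SA tag). Base-precise: each arm's
  junction side is the side carrying the larger soft/hard clip, and the
  breakend is the last aligned base on the retained side.
- **spanning pair** — mates flanking a junction without crossing it
  (different chromosomes, same-orientation mates, or insert above the
  expected maximum). Interval-precise: the breakend sits at the arm's
  junction-facing bound and carries a half-open uncertainty interval of at
  most the expected insert size (default 450 nt).
- **head-to-tail split** — a split read whose later-in-read arm maps
  upstream of (or overlapping) the earlier arm on the same chromosome and
  strand; the signature of back-splicing (circRNA) or a small tandem
  duplication. Detection is invariant under arm order.

Breakends record `retained_side` ∈ {left_of_break, right_of_break}: which
genomic flank survives on the derivative allele. A collinear joint
(deletion, translocation) has opposite retained sides; an inverted joint
has equal sides. Pairs are kept in lexicographic canonical order.

Mate-pair breakends carry unknown strand even in stranded libraries: the
transcript strand of the second mate depends on the library protocol, and
retained-side geometry already encodes the orientation that matters for
merging and clustering. In unstranded libraries all breakend strands are
unknown and strand checks degrade to orientation-consistency checks.

Fragments with more than two chimeric segments decompose into
adjacent-in-read arm pairs, preserving chained multi-breakpoint structures
without inventing long-range joins. Arms shorter than 20 aligned nt
(configurable) are dropped: very short alignments are the dominant source
of spurious junctions. Fragment accounting is conserved:
emitted + orphaned + malformed + dropped = total.

## Provisional typing and the breakpoint graph

Split boundaries are provisionally **splice_like** when both breakends lie
at annotated exon boundaries (tolerance below) or, given a reference, when
both junction flanks match a canonical splice context — GT–AG, plus GC–AG
and AT–AC unless `--strict-motifs`. The motif check accepts either
transcription direction independently per side (a deliberately permissive
rule; direction consistency is not enforced because inverted joints mix
orientations). Everything else, including all spanning pairs, is
provisionally **genomic**. The two edge types are stored separately at the
same coordinates — this separation is what lets one event report both its
fusion-mRNA junction and its genomic breakpoint.

Edges aggregate counts per (breakend pair, type, head-to-tail flag) with
score `w_split·(n_split + n_head_to_tail) + w_spanning·n_spanning`.
Defaults `w_split = 3, w_spanning = 1, min_score = 6, min_reads = 2`: split
reads pin the junction to the base and are up-weighted; the floor of two
reads is a hard calling rule. Head-to-tail splits take the split weight
(they are base-precise split observations) but head-to-tail edges never
merge or cluster with non-head-to-tail edges, so back-splices cannot
contaminate linear fusion calls.

**Merging.** An imprecise (spanning-only) breakend strictly within the
merge window (default 450 nt, or the library's expected insert when given)
of a base-precise breakend with the same chromosome, retained side and a
compatible strand is absorbed into it; the nearest candidate wins, ties to
the smaller coordinate. Base-precise breakends never move. When both sides
of a spanning edge land on a pair that already has split support, its
counts join that edge — read-pair support thereby accrues to whichever
splice-like or genomic junction it corroborates. Merging conserves all
counts, is idempotent, and the final graph is independent of evidence
insertion order.

## Clustering and consensus

Two edges belong to the same event when their head-to-tail status and
chromosome pair match, retained sides and strands are compatible per side,
and either they share a breakend exactly on one side (links splice isoforms
with a common donor/acceptor) or both sides fall within the merge window
(links a genomic breakpoint to the exonic junction of the same derivative
allele, since in-gene breakpoints sit in the introns adjacent to the fused
exons). Events are maximal connected components of this relation, computed
independently per component; hot-spot regions do not collapse into one
mega-event because linkage always requires per-side proximity or identity.

Within a cluster, consensus junctions are formed by single-linkage over
base-precise edges of the same type within a 10-nt jitter window per side
(absorbs aligner wobble at homologous junction ends while keeping isoform
acceptors, which lie at least an intron apart, separate). Spanning-only
edges then attach to the nearest precise group within the merge window —
attachment, not linkage, so an imprecise edge can never bridge two precise
groups (e.g. an exonic junction and its nearby genomic breakpoint).
Remaining spanning-only edges group among themselves. The consensus
position is the modal split-read pair (ties to the smallest coordinates);
spanning-only groups report their merged interval midpoint with the
interval width as uncertainty. Splice-like edges sharing a breakend are
additionally marked as one isoform family (`variant_group`); evidence is
never double-assigned.

## Filtering, labelling, annotation

Filters report every firing reason, not just the first:

- `insufficient_reads` — fewer than `min_reads = 2` total supporting reads.
- `no_split_support` — no base-precise read (`min_split = 1`).
- `low_start_diversity` — fraction of distinct read start positions below
  0.5, taken as the max over the two sides (PCR-duplicate stacks; with two
  reads the fraction is ≥ 0.5, so duplicate pairs still pass the read floor).
- `nonstandard_contig` — unplaced/unlocalized (chrUn\*, \*_random),
  alternate-locus (\*_alt) and decoy contigs, on by default.

Filters are monotone in evidence: added support never turns a passing call
into `insufficient_reads`.

The **exonic/intronic label encodes mechanism, not location**: exonic means
produced by splicing — both breakends at annotated exon boundaries with
splice-consistent orientation (left-retained at an exon end, right-retained
at an exon start; tolerance 2 nt for aligner jitter) or, in motif mode,
both flanks at canonical splice contexts (admits cryptic, including
intergenic, exons). Everything else is intronic, including genomic
breakpoints that happen to fall inside exons; the gene annotation still
records the exon. Breakends on contigs absent from both annotation and
reference are labelled intronic with a warning.

Gene annotation assigns each breakend the genes whose span (first to last
exon) contains it — strand-aware only for stranded libraries — and an
intergenic status (both_in_gene / one_intergenic / both_intergenic).
Head-to-tail flagging is purely geometric; catalogue matching requires
exact (0-nt) agreement with a back-splice exon junction, so small tandem
duplications, which share the geometry but not the annotated exon pair,
stay unmatched.

## Cohort utilities

**Junction-set matching** (cross-assay, e.g. RNA vs WGS): both sides must
lie within the window (default 40 nt, boundary inclusive — "within 40"
read inclusively, declared and tested) on the same contigs after canonical
ordering. Head-to-tail junctions and alternate-locus contigs are excluded
before matching; optional interchromosomal restriction avoids artefacts
from read-throughs, circRNAs and small indels. Assignment is greedy by
nearest pair (deterministic, adequate at realistic junction densities);
each junction matches at most once. Disjoint contig name sets raise a hard
error (mixed genome builds). **Density binning** adds both endpoints of
each non-head-to-tail junction to fixed-size bins and reports Pearson
correlation between two tracks over matched bins.

**Locus-conditioned DE.** A sample is mutant iff it has ≥ 1 passing
junction with a breakend inside the locus. Genes on the locus's chromosome
are tested mutant vs wild type on raw counts with a self-contained engine
re-specifying the standard contract (log₂FC + BH q-values): median-of-ratios
size factors (robust to composition bias from truly differential genes,
which total-count scaling is not); tagwise NB dispersions by moments,
shrunk toward the common median with 20 prior degrees of freedom; a
conditional exact-style test on normalized group sums (the sum of n
NB(μ, φ) counts is NB(nμ, φ/n); the two-sided p-value is the mass of all
splits of the total at most as likely as the observed one); log₂FC from
group means with a prior count of 0.5. Both groups need ≥ 2 samples. The
output table is ordered by the gene's genomic centre ((start+end)/2) with
an up/down/ns direction column at the chosen q threshold. The engine tracks
edgeR's exact test closely (log FC correlation > 0.99 in the cross-check
test) while being slightly anticonservative at very small sample sizes.

## Simulator

The generator's defaults are the study conditions used throughout the
tests: 4 contigs × 300 kb; 40 forward-strand genes (6 × 200-nt exons,
300-nt introns, GT..AG embedded at every intron) laid out deterministically;
20 events mixed 30% deletion / 20% inversion / 30% translocation /
10% tandem duplication / 10% back-splice over distinct genes; 30 split +
20 spanning reads per event plus 200 uniform noise chimeras; 126-nt
stranded reads, fragment size 300–600 nt (mean 450, sd 50). Genomic
breakpoints land 30–280 nt inside the introns flanking the fused exon
boundaries — within the insert window, as expected for in-gene breakpoints
— and are nudged off canonical splice contexts so mechanism labelling is
well-posed. `pre_mrna_fraction` (0 by default; 0.35 emulates rRNA-minus,
0.02 poly(A)+, mirroring typical intronic read fractions of 30–40% vs
5–10%) is the per-read probability of deriving from pre-mRNA and hence
covering the genomic breakpoint instead of the splice junction. All
randomness flows through per-stage substreams of the spec seed; outputs are
byte-identical across runs.

Deliberate idealizations — what passing tests do *not* show about real
data: alignments are error-free with correct clip structure (noise is
modelled at the alignment level as random arm chimeras, the operative
confounder for a detector that consumes alignments, rather than as base
errors); all genes are forward-strand; every intron is canonical; no
quality scores, duplicates, expression gradients or FFPE degradation;
spanning pairs are not emitted for head-to-tail junctions (circle-internal
fragments mostly look concordant). Real libraries will show lower precision
and recall than the simulation's.

## Numerical and design choices

- Coordinates: 0-based half-open internally; 1-based inclusive in report
  output (stated in the table header). Breakend = last retained aligned
  base, fixed once and declared.
- Merge window strictly `< 450` nt; matching window `≤ 40` nt — both as
  declared boundary semantics, exercised at 449/450 and 40/41 in tests.
- Consensus ties break to the smallest coordinate; cluster and call
  ordering is deterministic (score-descending, then genomic order).
- Silent partner mates (one mate spans the junction, the other does not)
  count as spanning support only.
- Hard thresholds, no q-values, in junction calling: the detector is a
  filter cascade by design; multiple-testing correction applies only in the
  cohort DE module.
- Degenerate inputs: empty alignment files yield empty call sets; an empty
  call set scores recall 0 with undefined (NaN) precision; zero-total genes
  get p = 1 in DE.

## Limitations

- No top-level reconstruction of multi-breakpoint ("poly-fusion") alleles;
  chained events appear as separate adjacent junction calls.
- Junctions supported only by shifts in concordant coverage are invisible:
  the detector consumes discordant alignments exclusively.
- The permissive per-side motif rule can, rarely, label a genomic
  breakpoint exonic when both flanks coincide with splice-like
  dinucleotides by chance (~0.4% per junction for GT/AG alone).
- Greedy (not optimal bipartite) junction matching can differ from the
  optimum in pathological tie configurations.
- The DE exact test assumes equal effective library sizes after
  normalization and a common dispersion within a gene across groups.
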