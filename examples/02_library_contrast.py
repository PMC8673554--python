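"""Compare genomic-breakpoint yield between library preparations.

rRNA-minus libraries retain unspliced pre-mRNA, so a sizeable fraction
of reads covering a rearranged locus span the genomic breakpoint itself
(intronic junctions). Poly(A)+ selection removes pre-mRNA, leaving
almost only spliced fusion junctions. The same 20 planted events are
sequenced under both emulations; only the pre-mRNA read fraction
differs (0.35 vs 0.02).
"""
import tempfile

from disco import run_pipeline
from disco.simulate import SimSpec, simulate_dataset

for label, frac in (("rRNA-minus", 0.35), ("poly(A)+", 0.02)):
    with tempfile.TemporaryDirectory() as workdir:
        spec = SimSpec(seed=42, pre_mrna_fraction=frac)
        ds = simulate_dataset(spec, workdir)
        calls = [c for c in run_pipeline(
            ds.sam_path, gene_models=ds.models, reference=ds.reference,
            circ_catalogue=ds.circ_catalogue,
        ) if c.passed]
    exonic = sum(1 for c in calls if c.classification == "exonic")
    intronic = sum(1 for c in calls if c.classification == "intronic")
    print(f"{label:<11} pre-mRNA fraction {frac:.2f}: "
          f"{exonic} exonic (splice fusion) and {intronic} intronic (genomic breakpoint) junctions")

print("\nexonic yield is nearly identical; the intronic (breakpoint) yield is what "
      "the pre-mRNA content buys")
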