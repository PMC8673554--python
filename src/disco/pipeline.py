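"""End-to-end orchestration: alignment file in, junction table out."""
from __future__ import annotations

from typing import Optional

from .annotate import FilterParams, GeneIndex, GeneModel, classify_and_annotate
from .chimeric_io import collect_evidence
from .detect import call_junctions, extract_clusters, splice_variant_correction
from .graph import BreakpointGraph, GraphParams, build_graph, graph_summary, merge_nearby_breakends
from .model import JunctionCall, LibraryLayout


def run_pipeline(
    sam_path: str,
    gene_models: Optional[list[GeneModel]] = None,
    reference=None,
    layout: Optional[LibraryLayout] = None,
    graph_params: Optional[GraphParams] = None,
    filter_params: Optional[FilterParams] = None,
    circ_catalogue: Optional[set] = None,
    strict_motifs: bool = False,
    counters: Optional[dict] = None,
) -> list[JunctionCall]:
    """Evidence → graph → merge → clusters → calls → filters → labels.

    ``reference`` (FASTA-like mapping) enables splice-motif checks;
    ``gene_models`` enables exon-boundary classification and gene
    annotation. Either may be omitted.
    """
    layout = layout or LibraryLayout()
    graph_params = graph_params or GraphParams(merge_window_nt=layout.expected_insert_max_nt)
    filter_params = filter_params or FilterParams()
    index = (
        GeneIndex(gene_models, tolerance_nt=filter_params.exon_boundary_tolerance_nt)
        if gene_models is not None
        else None
    )
    if counters is None:
        counters = {}
    evidence = collect_evidence(
        sam_path,
        layout=layout,
        reference=reference,
        exon_boundary_index=index,
        strict_motifs=strict_motifs,
        counters=counters,
    )
    graph = build_graph(evidence, graph_params)
    counters["graph"] = graph_summary(graph)
    merged = merge_nearby_breakends(graph)
    clusters = splice_variant_correction(extract_clusters(merged))
    calls = call_junctions(clusters, graph_params)
    classify_and_annotate(
        calls,
        gene_index=index,
        reference=reference,
        filter_params=filter_params,
        circ_catalogue=circ_catalogue,
        stranded=layout.stranded,
        strict_motifs=strict_motifs,
    )
    counters["n_calls"] = len(calls)
    counters["n_passed"] = sum(1 for c in calls if c.passed)
    return calls
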