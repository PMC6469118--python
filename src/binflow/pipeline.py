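"""End-to-end assembly: alignments in, quantified transcript models out.

Per locus (and per strand where junctions disagree): cluster splice sites,
build exon ranges and bins, construct the bin graph, denoise coverage
(pre-correction, optional guide correction, convex-cost min-cost flow),
simplify, resolve ambiguous nodes with phasing evidence, filter noise edges
and retained introns, and decompose the remaining flow into transcripts.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import aux_graph as ag
from . import exon_binning as eb
from . import io_alignments as io
from .bin_graph import annotate_coverage, build_bin_graph
from .flow import find_guide_path, guided_correct, precorrect_coverage, solve_bin_graph_flow
from .gtf_io import GtfTranscript, read_gtf, write_gtf
from .resolution import (
    IR_FRACTION,
    MIN_EDGE_FRACTION,
    NO_EVIDENCE_FRACTION,
    Transcript,
    collect_evidence,
    drop_contained_transcripts,
    extract_transcripts,
    filter_edges,
    filter_intron_retention,
    guided_abundance_filter,
    resolve_all,
    simplify,
    stub_evidence_ids,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bam: str
    out: Optional[str] = None
    guide: Optional[str] = None
    trust: float = 60.0
    bandwidth: int = eb.DEFAULT_BANDWIDTH
    min_edge_fraction: float = MIN_EDGE_FRACTION
    no_evidence_fraction: float = NO_EVIDENCE_FRACTION
    ir_fraction: float = IR_FRACTION
    min_transcript_coverage: Optional[float] = None  # disabled by default
    single_exon: bool = True
    drop_contained: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_edge_fraction", "no_evidence_fraction", "ir_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.trust <= 100.0:
            raise ValueError("trust must be in [0, 100]")


@dataclass
class LocusReport:
    chrom: str
    start: int
    end: int
    strand: str
    n_fragments: int = 0
    n_bins: int = 0
    n_rejected: int = 0
    n_nodes: int = 0
    n_exon_ranges: int = 0
    unresolved: List[int] = field(default_factory=list)
    transcripts: List[Transcript] = field(default_factory=list)


def _chain_to_intervals(chain, exons) -> Tuple[Tuple[int, int], ...]:
    out: List[List[int]] = []
    for idx in chain:
        x = exons[idx]
        if out and out[-1][1] == x.start:
            out[-1][1] = x.end
        else:
            out.append([x.start, x.end])
    return tuple((s, e) for s, e in out)


def _with_intervals(transcripts, exons, locus, strand):
    for t in transcripts:
        t.chrom = locus.chrom
        t.strand = strand
        t.exons = _chain_to_intervals(t.chain, exons)
    return transcripts


def map_guide_to_chain(
    guide: GtfTranscript, exons: List[eb.ExonRange]
) -> Optional[Tuple[int, ...]]:
    """Convert a guide's genomic exons to an exon-range chain, or None.

    Internal splice boundaries must coincide exactly with range boundaries;
    terminal ends may extend past the covered region. Ranges within one guide
    exon must tile it without gaps.
    """
    chain: List[int] = []
    n = len(guide.exons)
    for k, (gs, ge) in enumerate(guide.exons):
        ranges = [x for x in exons if x.start < ge and x.end > gs]
        if not ranges:
            return None
        for a, b in zip(ranges, ranges[1:]):
            if a.end != b.start:
                return None
        if k > 0 and ranges[0].start != gs:
            return None
        if k < n - 1 and ranges[-1].end != ge:
            return None
        chain.extend(x.index for x in ranges)
    if any(b <= a for a, b in zip(chain, chain[1:])):
        return None
    return tuple(chain)


def assemble_locus(
    locus: io.Locus,
    strand: str,
    fragments: Sequence[io.AlignedFragment],
    junctions: List[io.Junction],
    coverage: io.CoverageDeltas,
    config: RunConfig,
    guides: Sequence[GtfTranscript] = (),
) -> LocusReport:
    """Run all assembly stages for one locus and strand."""
    report = LocusReport(locus.chrom, locus.start, locus.end, strand)
    report.n_fragments = len(fragments)

    clustered = eb.cluster_splice_sites(junctions, config.bandwidth)
    clustered = eb.filter_low_support(clustered)
    exons = eb.build_exon_ranges(clustered, coverage, locus)
    report.n_exon_ranges = len(exons)
    if not exons:
        return report
    canonical = {(j.donor, j.acceptor) for j in clustered}
    store = eb.assign_fragments(fragments, exons, canonical)
    report.n_rejected = store.rejected
    bins = store.sorted_bins()
    report.n_bins = len(bins)
    if not bins:
        return report
    links = store.paired_links()

    # the aux stage merges and absorbs counts in place: give it copies so the
    # original bins keep per-read counts for coverage and phasing evidence
    aux_bins = [
        eb.Bin(exons=b.exons, count=b.count, bases=b.bases) for b in bins
    ]
    aux = ag.build_aux_edges(aux_bins)
    ag.strip_and_reduce(aux)
    ag.merge_unique_chains(aux)
    g = build_bin_graph(aux)
    report.n_nodes = len(g.node_labels)
    annotate_coverage(g, exons, coverage, bins)
    precorrect_coverage(g)

    guide_chains: List[Tuple[int, ...]] = []
    if guides:
        for gt in guides:
            ch = map_guide_to_chain(gt, exons)
            if ch is not None:
                guide_chains.append(ch)
            else:
                logger.info(
                    "guide %s incompatible with locus %s:%d-%d",
                    gt.transcript_id, locus.chrom, locus.start, locus.end,
                )
        if guide_chains:
            guided_correct(g, guide_chains, config.trust / 100.0)

    solve_bin_graph_flow(g)

    def evidenced_ids() -> Set[int]:
        ids: Set[int] = set(stub_evidence_ids(g))
        for ev in collect_evidence(g, bins, links).values():
            for c in ev.connections:
                ids.add(id(c.tail))
                ids.add(id(c.head))
        # an edge whose whole chain is attested by one read bin carries
        # direct phasing through its region
        chains = {b.exons for b in bins}
        for e in g.exon_edges():
            n = len(e.chain)
            if any(
                any(c[k: k + n] == e.chain for k in range(len(c) - n + 1))
                for c in chains
            ):
                ids.add(id(e))
        return ids

    # noise filters on the full graph; flow re-balanced when edges fall and
    # the filter re-applied once, since re-balancing can regrow weak slack
    removed = filter_edges(
        g, evidenced_ids(), config.min_edge_fraction, config.no_evidence_fraction
    )
    removed += filter_intron_retention(g, exons, coverage, config.ir_fraction)
    if removed:
        solve_bin_graph_flow(g)
        if filter_edges(
            g, evidenced_ids(), config.min_edge_fraction, config.no_evidence_fraction
        ):
            solve_bin_graph_flow(g)

    transcripts: List[Transcript] = []
    for ch in sorted(set(guide_chains)):
        path = find_guide_path(g, ch)
        if path is None:
            continue
        # include the boundary stubs so conservation survives the subtraction
        s_arc = [
            e for e in g.ins[ch[0]]
            if e.source == "s" and len(e.chain) <= 1
        ]
        t_arc = [
            e for e in g.outs[ch[-1]]
            if e.target == "t" and len(e.chain) <= 1
        ]
        full = s_arc + list(path) + t_arc
        flow = min(e.flow for e in full)
        if flow < 1.0:
            continue
        for e in full:
            e.flow -= flow
        transcripts.append(
            Transcript(chain=ch, strand=strand, abundance=flow, guided=True)
        )

    report.unresolved = simplify(g)
    evidence = collect_evidence(g, bins, links)
    ev_ids: Set[int] = set()
    for ev in evidence.values():
        for c in ev.connections:
            ev_ids.add(id(c.tail))
            ev_ids.add(id(c.head))
    filter_edges(g, ev_ids, config.min_edge_fraction, config.no_evidence_fraction)
    resolve_all(g, evidence, ev_ids, bins, links)
    filter_edges(g, ev_ids, config.min_edge_fraction, config.no_evidence_fraction)
    assembled = extract_transcripts(
        g, evidenced=ev_ids, min_fraction=config.min_edge_fraction
    )
    if config.drop_contained:
        assembled = drop_contained_transcripts(
            _with_intervals(assembled, exons, locus, strand)
        )
    transcripts.extend(assembled)
    if guide_chains:
        transcripts = guided_abundance_filter(transcripts, config.trust)

    final: List[Transcript] = []
    for t in transcripts:
        ivals = _chain_to_intervals(t.chain, exons)
        if not config.single_exon and len(ivals) == 1:
            continue
        if (
            config.min_transcript_coverage is not None
            and t.abundance < config.min_transcript_coverage
        ):
            continue
        t.chrom = locus.chrom
        t.strand = strand
        t.exons = ivals
        final.append(t)
    report.transcripts = final
    return report


def run_pipeline(config: RunConfig) -> Tuple[List[Transcript], List[LocusReport]]:
    """Assemble a whole alignment file; returns transcripts and reports."""
    fragments = list(io.stream_fragments(config.bam))
    coverage = io.CoverageDeltas()
    total_templates = 0
    for f in fragments:
        coverage.add_fragment(f)
        if f.is_first_mate:
            total_templates += 1
    junctions = io.collect_junctions(fragments)
    loci = io.partition_loci(coverage, junctions)
    guides = read_gtf(config.guide) if config.guide else []

    frag_by_chrom: Dict[str, List[io.AlignedFragment]] = defaultdict(list)
    for f in fragments:
        frag_by_chrom[f.chrom].append(f)
    junc_by_chrom: Dict[str, List[io.Junction]] = defaultdict(list)
    for j in junctions:
        junc_by_chrom[j.chrom].append(j)

    all_transcripts: List[Transcript] = []
    reports: List[LocusReport] = []
    for locus in loci:
        lf = [
            f for f in frag_by_chrom[locus.chrom]
            if f.start < locus.end and f.end > locus.start
        ]
        lj = [
            j for j in junc_by_chrom[locus.chrom]
            if locus.start <= j.donor and j.acceptor <= locus.end
        ]
        strands = sorted({j.strand for j in lj if j.strand in "+-"})
        if not strands:
            strands = ["."]
        both = len(strands) > 1
        for strand in strands:
            sj = [j for j in lj if j.strand == strand or (not both and j.strand == ".")]
            sf = [f for f in lf if f.strand == strand or f.strand == "."]
            lg = [
                t for t in guides
                if t.chrom == locus.chrom
                and (t.strand == strand or strand == ".")
                and t.exons[0][0] < locus.end
                and t.exons[-1][1] > locus.start
            ]
            rep = assemble_locus(locus, strand, sf, sj, coverage, config, lg)
            logger.info(
                "locus %s:%d-%d[%s]: %d fragments, %d bins, %d nodes, "
                "%d unresolved, %d transcripts",
                rep.chrom, rep.start, rep.end, rep.strand,
                rep.n_fragments, rep.n_bins, rep.n_nodes,
                len(rep.unresolved), len(rep.transcripts),
            )
            reports.append(rep)
            all_transcripts.extend(rep.transcripts)

    # FPKM: flow units * 1e9 / (transcript length * total fragments)
    denom = max(total_templates, 1)
    for t in all_transcripts:
        t.fpkm = t.abundance * 1e9 / (max(t.length, 1) * denom)
    if config.out:
        write_gtf(all_transcripts, config.out)
    return all_transcripts, reports
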