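import pytest

from binflow import aux_graph as ag
from binflow import exon_binning as eb
from binflow import io_alignments as io
from binflow.fixtures import emit, figure_example_locus


@pytest.fixture(scope="session")
def figure_locus_sam(tmp_path_factory):
    """Curated worked-example locus written as SAM + truth GTF."""
    locus, frags = figure_example_locus()
    d = tmp_path_factory.mktemp("fig")
    sam = str(d / "fig.sam")
    gtf = str(d / "truth.gtf")
    emit([locus], [frags], sam, gtf)
    return locus, sam, gtf


def build_locus_graph(sam_path, bandwidth=3):
    """Run the front half of the pipeline on a one-locus SAM.

    Returns (exon ranges, bin store, aux graph, bin graph, coverage store).
    """
    from binflow.bin_graph import annotate_coverage, build_bin_graph

    frags = list(io.stream_fragments(sam_path))
    cov = io.CoverageDeltas()
    for f in frags:
        cov.add_fragment(f)
    junctions = io.collect_junctions(frags)
    loci = io.partition_loci(cov, junctions)
    assert len(loci) == 1
    clustered = eb.filter_low_support(eb.cluster_splice_sites(junctions, bandwidth))
    exons = eb.build_exon_ranges(clustered, cov, loci[0])
    store = eb.assign_fragments(
        frags, exons, {(j.donor, j.acceptor) for j in clustered}
    )
    bins = store.sorted_bins()
    aux_bins = [eb.Bin(exons=b.exons, count=b.count, bases=b.bases) for b in bins]
    aux = ag.build_aux_edges(aux_bins)
    ag.strip_and_reduce(aux)
    ag.merge_unique_chains(aux)
    g = build_bin_graph(aux)
    annotate_coverage(g, exons, cov, bins)
    return exons, store, aux, g, cov


def random_bin_chains(seed):
    """Random read-like bin chains over a few isoforms (graph stress inputs)."""
    import numpy as np

    r = np.random.default_rng(seed)
    n_exons = int(r.integers(3, 9))
    n_iso = int(r.integers(1, 5))
    isoforms = set()
    for _ in range(20):
        keep = tuple(i for i in range(n_exons) if r.random() < 0.7)
        if len(keep) >= 2:
            isoforms.add(keep)
        if len(isoforms) >= n_iso:
            break
    chains = set()
    for iso in isoforms:
        L = len(iso)
        for _ in range(int(r.integers(3, 10))):
            a = int(r.integers(0, L))
            b = int(r.integers(a + 1, L + 1))
            chains.add(iso[a:b])
        chains.add(iso)
    return n_exons, sorted(chains)
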