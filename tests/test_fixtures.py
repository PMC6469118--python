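"""Synthetic-data generator: determinism, coverage, noise knobs."""

import math

import numpy as np
import pytest

from binflow import exon_binning as eb
from binflow import io_alignments as io
from binflow.fixtures import (
    LocusSpec,
    emit,
    make_locus,
    random_locus_spec,
    sample_reads,
    transcript_to_blocks,
)
from binflow.gtf_io import read_gtf


def test_make_locus_validates_isoforms():
    with pytest.raises(ValueError):
        make_locus(LocusSpec(isoforms=((0, 2, 1),), abundances=(1.0,)))
    with pytest.raises(ValueError):
        # shorter than the mean fragment length
        make_locus(
            LocusSpec(exon_lengths=(60, 60), intron_lengths=(100,),
                      isoforms=((0, 1),), abundances=(1.0,))
        )


def test_transcript_to_blocks_merges_adjacent_exons():
    spec = LocusSpec(exon_lengths=(100, 100, 100), intron_lengths=(0, 150),
                     isoforms=((0, 1, 2),), abundances=(1.0,))
    locus = make_locus(spec)
    blocks = transcript_to_blocks(locus, 0, 50, 250)
    # exons 0 and 1 are genomically adjacent: one block, then a gap
    assert blocks[0] == (locus.exons[0][0] + 50, locus.exons[1][1])
    assert len(blocks) == 2


def test_same_seed_identical_sam_bytes(tmp_path):
    spec = random_locus_spec(42)
    locus = make_locus(spec)
    paths = []
    for k in range(2):
        sam = tmp_path / f"run{k}.sam"
        frags = sample_reads(locus, depth=12.0, seed=9)
        emit([locus], [frags], str(sam))
        paths.append(sam.read_bytes())
    assert paths[0] == paths[1]


def test_junction_support_near_expectation(tmp_path):
    spec = LocusSpec(isoforms=((0, 1, 2, 3, 4, 5, 6),), abundances=(1.0,))
    locus = make_locus(spec)
    depth = 20.0
    frags = sample_reads(locus, depth=depth, seed=4)
    sam = tmp_path / "x.sam"
    emit([locus], [frags], str(sam))
    reads = list(io.stream_fragments(str(sam)))
    junctions = io.collect_junctions(reads)
    # crossing count at a junction ~ Poisson(mate depth); allow 5 sigma
    for j in junctions:
        assert abs(j.support - depth) < 5 * math.sqrt(depth) + 3


def test_jitter_recovered_by_clustering(tmp_path):
    spec = LocusSpec(isoforms=((0, 1, 2, 3, 4, 5, 6),), abundances=(1.0,))
    locus = make_locus(spec)
    frags = sample_reads(locus, depth=25.0, seed=6, jitter_rate=0.15, jitter_bp=2)
    sam = tmp_path / "x.sam"
    emit([locus], [frags], str(sam))
    reads = list(io.stream_fragments(str(sam)))
    raw = io.collect_junctions(reads)
    true_junctions = {
        (locus.exons[a][1], locus.exons[b][0])
        for a, b in zip(locus.isoforms[0], locus.isoforms[0][1:])
    }
    assert {(j.donor, j.acceptor) for j in raw} != true_junctions  # jitter hit
    clustered = eb.cluster_splice_sites(raw, bandwidth=3)
    clustered = eb.filter_low_support(clustered)
    assert {(j.donor, j.acceptor) for j in clustered} == true_junctions


def test_coverage_trend_skews_start_positions():
    spec = LocusSpec(isoforms=((0, 1, 2, 3, 4, 5, 6),), abundances=(1.0,))
    locus = make_locus(spec)
    flat = sample_reads(locus, depth=30.0, seed=3)
    skew = sample_reads(locus, depth=30.0, seed=3, coverage_trend=0.8)
    mid = (locus.start + locus.end) / 2
    frac_flat = np.mean([f.blocks1[0][0] > mid for f in flat])
    frac_skew = np.mean([f.blocks1[0][0] > mid for f in skew])
    assert frac_skew > frac_flat + 0.05


def test_drop_rate_reduces_fragments():
    spec = LocusSpec(isoforms=((0, 1, 2, 3, 4, 5, 6),), abundances=(1.0,))
    locus = make_locus(spec)
    full = sample_reads(locus, depth=30.0, seed=3)
    dropped = sample_reads(locus, depth=30.0, seed=3, drop_rate=0.5)
    assert len(dropped) < 0.7 * len(full)


def test_random_locus_spec_isoforms_distinguishable():
    """No isoform's intron chain is an infix of another's."""
    def introns(chain):
        return tuple(zip(chain, chain[1:]))

    for seed in range(30):
        spec = random_locus_spec(seed)
        for a in spec.isoforms:
            for b in spec.isoforms:
                if a == b:
                    continue
                ia, ib = introns(a), introns(b)
                if len(ia) <= len(ib):
                    assert not any(
                        ib[k: k + len(ia)] == ia
                        for k in range(len(ib) - len(ia) + 1)
                    ), (seed, a, b)


def test_truth_gtf_round_trip(tmp_path, figure_locus_sam):
    locus, sam, gtf = figure_locus_sam
    models = read_gtf(gtf)
    assert len(models) == len(locus.isoforms)
    by_start = sorted(models, key=lambda t: t.exons[0][0])
    for t in models:
        assert t.chrom == locus.chrom
        assert t.strand == locus.strand
    # intervals match the merged exon chains of the isoforms
    from binflow.gtf_io import _merged_intervals
    truth = sorted(tuple(_merged_intervals(locus, c)) for c in locus.isoforms)
    assert sorted(tuple(t.exons) for t in models) == truth
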