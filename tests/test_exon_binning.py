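"""Splice-site clustering, exon ranges, bin assignment and mate merging."""

import pytest
from hypothesis import given, settings, strategies as st

from binflow import exon_binning as eb
from binflow import io_alignments as io


def J(donor, acceptor, support=1, strand="+", chrom="c"):
    return io.Junction(chrom=chrom, strand=strand, donor=donor,
                       acceptor=acceptor, support=support)


class TestClusterSpliceSites:
    def test_nearby_donors_merge_to_strongest(self):
        out = eb.cluster_splice_sites(
            [J(1000, 5000, 50), J(1002, 5000, 1)], bandwidth=3
        )
        assert len(out) == 1
        assert out[0].donor == 1000
        assert out[0].support == 51

    def test_distant_sites_unchanged(self):
        out = eb.cluster_splice_sites([J(1000, 5000), J(2000, 5000)], 3)
        assert sorted(j.donor for j in out) == [1000, 2000]

    def test_empty(self):
        assert eb.cluster_splice_sites([], 3) == []

    def test_tie_breaks_leftmost(self):
        out = eb.cluster_splice_sites([J(1000, 5000, 5), J(1002, 5000, 5)], 3)
        assert out[0].donor == 1000


def test_low_support_filter_drops_dominated_singletons():
    out = eb.filter_low_support([J(1000, 5000, 1), J(1000, 6000, 30)])
    assert [(j.donor, j.acceptor) for j in out] == [(1000, 6000)]
    kept = eb.filter_low_support([J(1000, 5000, 1), J(2000, 6000, 30)])
    assert len(kept) == 2


class TestBuildExonRanges:
    def make_cov(self, intervals):
        cov = io.CoverageDeltas()
        for s, e in intervals:
            cov.add_block("c", s, e)
        return cov

    def test_single_junction_splits_covered_region(self):
        cov = self.make_cov([(0, 100), (200, 300)])
        exons = eb.build_exon_ranges([J(100, 200)], cov, io.Locus("c", 0, 300))
        assert [(x.start, x.end) for x in exons] == [(0, 100), (200, 300)]

    def test_overlapping_junctions_enumerate_boundaries(self):
        # full coverage on [0,300) with cuts at 100, 150, 200, 250
        cov = self.make_cov([(0, 300)])
        exons = eb.build_exon_ranges(
            [J(100, 200), J(150, 250)], cov, io.Locus("c", 0, 300)
        )
        assert [(x.start, x.end) for x in exons] == [
            (0, 100), (100, 150), (150, 200), (200, 250), (250, 300)
        ]

    def test_junction_outside_coverage_dropped(self):
        cov = self.make_cov([(0, 100)])
        exons = eb.build_exon_ranges([J(500, 600)], cov, io.Locus("c", 0, 100))
        assert [(x.start, x.end) for x in exons] == [(0, 100)]

    def test_ranges_tile_covered_region_without_straddling(self):
        cov = self.make_cov([(0, 300), (400, 600)])
        exons = eb.build_exon_ranges(
            [J(150, 450)], cov, io.Locus("c", 0, 600)
        )
        for x in exons:
            assert not (x.start < 150 < x.end)
            assert not (x.start < 450 < x.end)
        total = sum(x.length for x in exons)
        assert total == 300 + 200


def frag(blocks, chrom="c", strand="+"):
    return io.AlignedFragment(
        chrom=chrom, strand=strand, blocks=tuple(blocks), mate_key="q"
    )


class TestBinOfFragment:
    exons = [
        eb.ExonRange(0, "c", 0, 100),
        eb.ExonRange(1, "c", 100, 200),
        eb.ExonRange(2, "c", 300, 400),
    ]
    canonical = {(200, 300)}

    def test_contiguous_blocks(self):
        assert eb.bin_of_fragment(frag([(50, 150)]), self.exons, set()) == (0, 1)

    def test_spliced_fragment_skips_exon(self):
        f = frag([(50, 100), (300, 350)])
        assert eb.bin_of_fragment(f, self.exons, {(100, 300)}) == (0, 2)

    def test_non_canonical_junction_rejected(self):
        f = frag([(50, 120), (320, 380)])  # junction 120->320 not canonical
        assert eb.bin_of_fragment(f, self.exons, self.canonical) is None

    def test_three_exon_multi_splice(self):
        f = frag([(50, 200), (300, 350)])
        assert eb.bin_of_fragment(f, self.exons, self.canonical) == (0, 1, 2)


class TestCombineMates:
    @pytest.mark.parametrize(
        "r1,r2,kind,payload",
        [
            ((1, 2, 3), (3, 4), "merged", (1, 2, 3, 4)),
            ((1, 2), (3, 4), "merged", (1, 2, 3, 4)),
            ((1, 2), (4, 5), "link", ((1, 2), (4, 5))),
            ((1, 2, 3), (2, 4), "rejected", None),
        ],
    )
    def test_contract(self, r1, r2, kind, payload):
        got_kind, got = eb.combine_mates(r1, r2)
        assert got_kind == kind
        assert got == payload

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=5, unique=True),
        st.lists(st.integers(0, 9), min_size=1, max_size=5, unique=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_mate_order(self, a, b):
        r1, r2 = tuple(sorted(a)), tuple(sorted(b))
        assert eb.combine_mates(r1, r2) == eb.combine_mates(r2, r1)


def test_assign_fragments_conserves_counts(figure_locus_sam):
    locus, sam, _ = figure_locus_sam
    frags = list(io.stream_fragments(sam))
    cov = io.CoverageDeltas()
    for f in frags:
        cov.add_fragment(f)
    junctions = io.collect_junctions(frags)
    clustered = eb.cluster_splice_sites(junctions, 3)
    loci = io.partition_loci(cov, junctions)
    exons = eb.build_exon_ranges(clustered, cov, loci[0])
    store = eb.assign_fragments(
        frags, exons, {(j.donor, j.acceptor) for j in clustered}
    )
    n_templates = len({f.mate_key for f in frags})
    assert store.total_count + store.rejected == n_templates


def test_cov_mean_depth():
    cov = io.CoverageDeltas()
    for _ in range(10):
        cov.add_block("c", 0, 100)
    x = eb.ExonRange(0, "c", 0, 100)
    assert eb.cov(x, cov) == pytest.approx(10.0)
    assert eb.boundary_cov(x, cov) == (10, 10, 10)
    with pytest.raises(ValueError):
        cov.depth_stats("c", 50, 50)
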