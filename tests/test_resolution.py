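"""Simplification, phasing LP, noise filters and flow decomposition."""

import math

import numpy as np
import pytest

from binflow.bin_graph import SINK, SOURCE, BinGraph
from binflow.exon_binning import Bin, ExonRange, PairedLink
from binflow.io_alignments import CoverageDeltas
from binflow.oracles import brute_force_resolve
from binflow.resolution import (
    ConservationError,
    Transcript,
    check_conservation,
    collect_evidence,
    drop_contained_transcripts,
    extract_transcripts,
    filter_edges,
    filter_intron_retention,
    guided_abundance_filter,
    guided_abundance_fraction,
    resolve_node,
    simplify,
)


def G(nodes, edges):
    """Graph from (source, target, chain, flow) tuples."""
    g = BinGraph()
    for lab in nodes:
        g.ensure_node(lab)
    out = []
    for u, v, chain, flow in edges:
        e = g.new_edge(u, v, tuple(chain))
        e.flow = float(flow)
        out.append(e)
    return g, out


class TestSimplify:
    def test_linear_chain_contracts_to_single_edge(self):
        g, _ = G([0, 1, 2], [
            (SOURCE, 0, (0,), 10), (0, 1, (0, 1), 10),
            (1, 2, (1, 2), 10), (2, SINK, (2,), 10),
        ])
        assert simplify(g) == []
        live = g.live_edges()
        assert len(live) == 1
        assert live[0].chain == (0, 1, 2)
        assert live[0].flow == 10

    def test_tree_node_contracted_out_edges_reanchored(self):
        g, _ = G([0, 1, 2, 3], [
            (SOURCE, 0, (0,), 9), (0, 1, (0, 1), 9),
            (1, 2, (1, 2), 4), (1, 3, (1, 3), 5),
            (2, SINK, (2,), 4), (3, SINK, (3,), 5),
        ])
        simplify(g)
        chains = sorted(e.chain for e in g.live_edges())
        assert chains == [(0, 1, 2), (0, 1, 3)]

    def test_ambiguous_node_kept_and_reported(self):
        g, _ = G([0, 1, 2, 3, 4], [
            (SOURCE, 0, (0,), 5), (SOURCE, 1, (1,), 5),
            (0, 2, (0, 2), 5), (1, 2, (1, 2), 5),
            (2, 3, (2, 3), 5), (2, 4, (2, 4), 5),
            (3, SINK, (3,), 5), (4, SINK, (4,), 5),
        ])
        assert simplify(g) == [2]

    def test_conservation_violation_raises(self):
        g, _ = G([0, 1], [
            (SOURCE, 0, (0,), 10), (0, 1, (0, 1), 3), (1, SINK, (1,), 3),
        ])
        with pytest.raises(ConservationError):
            check_conservation(g)


class TestResolveNode:
    def test_perfect_phasing(self):
        x, o1, o2 = resolve_node(
            ["e1", "e2"], ["f1", "f2"],
            [(0, 0), (1, 1)], [8.0, 8.0], [8.0, 8.0], [8.0, 8.0],
        )
        assert list(x) == [8.0, 8.0]
        assert o1 == 0.0 and o2 == 0.0

    def test_partial_evidence_leaves_flow(self):
        # evidence covers only one in-edge: the other's flow stays unexplained
        x, o1, o2 = resolve_node(
            ["e1", "e2"], ["f1"],
            [(0, 0)], [5.0], [5.0, 7.0], [12.0],
        )
        assert o2 == pytest.approx(7.0 + 7.0)  # e2 and f1's uncovered part

    def test_matches_integer_grid_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            nS = int(rng.integers(1, 4))
            nT = int(rng.integers(1, 4))
            pairs = [(i, j) for i in range(nS) for j in range(nT)]
            rng.shuffle(pairs)
            E = sorted(pairs[: int(rng.integers(1, min(5, len(pairs)) + 1))])
            n = [float(rng.integers(0, 13)) for _ in E]
            fl_S = [float(rng.integers(1, 13)) for _ in range(nS)]
            fl_T = [float(rng.integers(1, 13)) for _ in range(nT)]
            x, o1, o2 = resolve_node(range(nS), range(nT), E, n, fl_S, fl_T)
            b1, b2 = brute_force_resolve(E, n, fl_S, fl_T)
            assert math.isclose(o1, b1, abs_tol=1e-6), trial
            assert math.isclose(o2, b2, abs_tol=1e-6), trial


def evidence_graph():
    """2-in 2-out node with spanning bins that phase it exactly."""
    g, edges = G([0, 1, 2, 3, 4], [
        (SOURCE, 0, (0,), 10), (SOURCE, 1, (1,), 10),
        (0, 2, (0, 2), 10), (1, 2, (1, 2), 10),
        (2, 3, (2, 3), 10), (2, 4, (2, 4), 10),
        (3, SINK, (3,), 10), (4, SINK, (4,), 10),
    ])
    bins = [
        Bin(exons=(0, 2, 3), count=9),
        Bin(exons=(1, 2, 4), count=8),
        Bin(exons=(2, 3), count=4),  # sub-bin of a spanning bin: dropped
    ]
    return g, bins


class TestCollectEvidence:
    def test_spanning_bins_give_specific_connections(self):
        g, bins = evidence_graph()
        ev = collect_evidence(g, bins, [])
        conns = {(c.tail.chain, c.head.chain): c for c in ev[2].connections}
        assert ((0, 2), (2, 3)) in conns
        assert ((1, 2), (2, 4)) in conns
        assert conns[((0, 2), (2, 3))].count == 9

    def test_subset_bins_dropped(self):
        g, bins = evidence_graph()
        ev = collect_evidence(g, bins, [])
        # the (2,3) sub-bin may not add a second connection's worth of count
        conns = {(c.tail.chain, c.head.chain): c for c in ev[2].connections}
        assert len(conns) == 2

    def test_paired_link_beyond_node_is_informative(self):
        g, _ = evidence_graph()
        links = [PairedLink(left=(0, 2), right=(4,), count=6)]
        ev = collect_evidence(g, [], links)
        conns = {(c.tail.chain, c.head.chain): c for c in ev[2].connections}
        assert conns[((0, 2), (2, 4))].count == 6
        assert not conns[((0, 2), (2, 4))].specific

    def test_paired_link_ending_at_node_is_ignored(self):
        g, _ = evidence_graph()
        # the right mate reaches only the node's exon: no continuation info
        links = [PairedLink(left=(0,), right=(2,), count=6)]
        ev = collect_evidence(g, [], links)
        assert 2 not in ev


class TestFilterEdges:
    def build(self):
        g, edges = G([0, 1, 2], [
            (SOURCE, 0, (0,), 120), (0, 1, (0, 1), 100), (0, 2, (0, 2), 20),
            (1, SINK, (1,), 100), (2, SINK, (2,), 20),
        ])
        return g, edges

    def test_weak_unevidenced_edge_removed(self):
        g, edges = self.build()
        removed = filter_edges(g, evidenced=set(), min_fraction=0.30)
        # 20 < 0.30 * 100 at node 0 -> removed (75% rule may remove more)
        assert all(e.chain != (0, 2) for e in g.live_edges())
        assert removed >= 1

    def test_edge_at_threshold_kept(self):
        g, edges = G([0, 1, 2], [
            (SOURCE, 0, (0,), 140), (0, 1, (0, 1), 100), (0, 2, (0, 2), 40),
            (1, SINK, (1,), 100), (2, SINK, (2,), 40),
        ])
        filter_edges(g, evidenced={id(e) for e in edges}, min_fraction=0.30)
        assert any(e.chain == (0, 2) for e in g.live_edges())

    def test_evidenced_edge_immune(self):
        g, edges = self.build()
        weak = [e for e in edges if e.chain == (0, 2)][0]
        filter_edges(g, evidenced={id(weak)}, min_fraction=0.30)
        assert any(e.chain == (0, 2) for e in g.live_edges())

    def test_idempotent(self):
        g, edges = self.build()
        filter_edges(g, evidenced=set(), min_fraction=0.30)
        first = sorted(e.chain for e in g.live_edges())
        again = filter_edges(g, evidenced=set(), min_fraction=0.30)
        assert again == 0
        assert sorted(e.chain for e in g.live_edges()) == first

    def test_rollback_when_disconnecting(self):
        g, edges = G([0, 1], [
            (SOURCE, 0, (0,), 100), (0, 1, (0, 1), 10), (1, SINK, (1,), 10),
        ])
        filter_edges(g, evidenced=set(), min_fraction=0.30)
        # removing the only path would disconnect source from sink
        assert any(e.chain == (0, 1) for e in g.live_edges())


class TestIntronRetention:
    def build(self, intron_depth, flank_depth=50):
        exons = [
            ExonRange(0, "c", 0, 100),
            ExonRange(1, "c", 100, 200),   # the retained intron material
            ExonRange(2, "c", 200, 300),
        ]
        exons[0].right_kind = "splice"
        exons[2].left_kind = "splice"
        cov = CoverageDeltas()
        for _ in range(flank_depth):
            cov.add_block("c", 0, 100)
            cov.add_block("c", 200, 300)
        for _ in range(intron_depth):
            cov.add_block("c", 100, 200)
        g, edges = G([0, 2], [
            (SOURCE, 0, (0,), 50),
            (0, 2, (0, 2), 40),          # spliced form
            (0, 2, (0, 1, 2), 10),       # reads through the intron
            (2, SINK, (2,), 50),
        ])
        return g, exons, cov

    def test_low_coverage_retention_removed(self):
        g, exons, cov = self.build(intron_depth=1)
        removed = filter_intron_retention(g, exons, cov, ir_fraction=0.10)
        assert removed == 1
        assert all(e.chain != (0, 1, 2) for e in g.live_edges())

    def test_supported_retention_kept(self):
        g, exons, cov = self.build(intron_depth=40)
        removed = filter_intron_retention(g, exons, cov, ir_fraction=0.10)
        assert removed == 0

    def test_no_candidates_noop(self):
        g, _ = G([0, 1], [
            (SOURCE, 0, (0,), 10), (0, 1, (0, 1), 10), (1, SINK, (1,), 10),
        ])
        exons = [ExonRange(0, "c", 0, 100), ExonRange(1, "c", 200, 300)]
        assert filter_intron_retention(g, exons, CoverageDeltas(), 0.10) == 0


class TestExtractTranscripts:
    def test_single_path(self):
        g, _ = G([0, 1], [
            (SOURCE, 0, (0,), 10), (0, 1, (0, 1), 10), (1, SINK, (1,), 10),
        ])
        ts = extract_transcripts(g)
        assert [(t.chain, t.abundance) for t in ts] == [((0, 1), 10.0)]

    def test_two_disjoint_paths(self):
        g, _ = G([0, 1, 2, 3], [
            (SOURCE, 0, (0,), 7), (0, 1, (0, 1), 7), (1, SINK, (1,), 7),
            (SOURCE, 2, (2,), 3), (2, 3, (2, 3), 3), (3, SINK, (3,), 3),
        ])
        ts = extract_transcripts(g)
        assert sorted((t.chain, t.abundance) for t in ts) == [
            ((0, 1), 7.0), ((2, 3), 3.0)
        ]

    def test_longest_first_differs_from_heaviest(self):
        # heaviest path is short; the longest path is removed first
        g, _ = G([0, 1, 2, 3], [
            (SOURCE, 0, (0,), 12),
            (0, 1, (0, 1), 4), (1, 2, (1, 2), 4), (2, 3, (2, 3), 4),
            (0, 3, (0, 3), 8),
            (3, SINK, (3,), 12),
        ])
        ts = extract_transcripts(g)
        assert ts[0].chain == (0, 1, 2, 3)
        assert ts[0].abundance == 4.0
        assert ts[1].chain == (0, 3)

    def test_decomposition_completeness(self):
        g, edges = G([0, 1, 2], [
            (SOURCE, 0, (0,), 10),
            (0, 1, (0, 1), 6), (0, 2, (0, 2), 4),
            (1, SINK, (1,), 6), (2, SINK, (2,), 4),
        ])
        total_out = sum(e.flow for e in g.outs[SOURCE])
        ts = extract_transcripts(g)
        assert sum(t.abundance for t in ts) == pytest.approx(total_out)


class TestGuidedAbundance:
    def test_trust_mapping_endpoints(self):
        assert guided_abundance_fraction(0) == 0.0
        assert guided_abundance_fraction(100) == pytest.approx(0.25)
        assert guided_abundance_fraction(60) == pytest.approx(0.09)

    def test_full_trust_drops_rare_unannotated(self):
        ts = [Transcript(chain=(0,), strand="+", abundance=100.0),
              Transcript(chain=(1,), strand="+", abundance=1.0)]
        kept = guided_abundance_filter(ts, trust=100)
        assert len(kept) == 1 and kept[0].abundance == 100.0

    def test_zero_trust_keeps_all(self):
        ts = [Transcript(chain=(0,), strand="+", abundance=100.0),
              Transcript(chain=(1,), strand="+", abundance=1.0)]
        assert len(guided_abundance_filter(ts, trust=0)) == 2

    def test_single_transcript_kept_at_any_trust(self):
        ts = [Transcript(chain=(0,), strand="+", abundance=5.0)]
        assert len(guided_abundance_filter(ts, trust=100)) == 1


def test_drop_contained_prefers_stronger_member():
    big = Transcript(chain=(0, 1, 2, 3), strand="+", abundance=30.0,
                     chrom="c", exons=((0, 10), (20, 30), (40, 50), (60, 70)))
    nested_weak = Transcript(chain=(1, 2), strand="+", abundance=4.0,
                             chrom="c", exons=((20, 30), (40, 50)))
    kept = drop_contained_transcripts([big, nested_weak])
    assert kept == [big]
    # a weak extension of a strong call loses to the contained call
    weak_ext = Transcript(chain=(0, 1, 2, 3), strand="+", abundance=3.0,
                          chrom="c", exons=((0, 10), (20, 30), (40, 50), (60, 70)))
    strong_core = Transcript(chain=(1, 2, 3), strand="+", abundance=28.0,
                             chrom="c", exons=((20, 30), (40, 50), (60, 70)))
    kept = drop_contained_transcripts([weak_ext, strong_core])
    assert kept == [strong_core]
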