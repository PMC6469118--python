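"""Overlap/containment graph construction, reduction and chain merging."""

import numpy as np

from binflow import aux_graph as ag
from binflow.exon_binning import Bin


def bins_of(*chains, count=1):
    return [Bin(exons=tuple(c), count=count, bases=10) for c in chains]


def edge_chains(g):
    ov = {(v.exons, w.exons) for v, w in g.overlap_edges()}
    ct = {(v.exons, w.exons) for v, w in g.contained_edges()}
    return ov, ct


class TestBuildAuxEdges:
    def test_suffix_prefix_overlap(self):
        g = ag.build_aux_edges(bins_of((1, 2, 3), (2, 3, 4)))
        ov, ct = edge_chains(g)
        assert ((1, 2, 3), (2, 3, 4)) in ov
        assert not ct

    def test_infix_containment(self):
        g = ag.build_aux_edges(bins_of((2, 3), (1, 2, 3, 4)))
        ov, ct = edge_chains(g)
        assert ((2, 3), (1, 2, 3, 4)) in ct

    def test_non_contiguous_subset_is_not_contained(self):
        g = ag.build_aux_edges(bins_of((1, 3), (1, 2, 3)))
        _, ct = edge_chains(g)
        assert ((1, 3), (1, 2, 3)) not in ct


class TestStripAndReduce:
    def test_transitive_overlap_removed(self):
        g = ag.build_aux_edges(bins_of((1, 2), (2, 3), (1, 2, 3)))
        # (1,2)->(1,2,3) is containment-ish; build a clean chain instead
        g = ag.build_aux_edges(bins_of((1, 2, 3), (2, 3, 4), (3, 4, 5)))
        ag.strip_and_reduce(g)
        ov, _ = edge_chains(g)
        assert ((1, 2, 3), (3, 4, 5)) not in ov
        assert ((1, 2, 3), (2, 3, 4)) in ov
        assert ((2, 3, 4), (3, 4, 5)) in ov

    def test_contained_node_loses_overlap_edges(self):
        g = ag.build_aux_edges(bins_of((2, 3), (1, 2, 3, 4), (3, 4, 5)))
        ag.strip_and_reduce(g)
        ov, _ = edge_chains(g)
        assert all(v != (2, 3) and w != (2, 3) for v, w in ov)

    def test_no_transitive_edges_unchanged(self):
        g = ag.build_aux_edges(bins_of((1, 2, 3), (2, 3, 4)))
        before = edge_chains(g)
        ag.strip_and_reduce(g)
        assert edge_chains(g) == before

    def test_matches_brute_force_transitive_reduction(self):
        """Random bin sets: reduced overlap edges equal the path-based oracle."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            chains = set()
            while len(chains) < int(rng.integers(4, 12)):
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, n + 1))
                chains.add(tuple(range(a, b)))
            bins = bins_of(*sorted(chains))
            g = ag.build_aux_edges(bins)
            # oracle: all overlap edges among non-contained nodes, then
            # remove every edge with an alternative directed path
            contained = {
                b.exons for b in g.nodes if g.contained_in[b]
            }
            raw = {
                (v.exons, w.exons)
                for v, w in g.overlap_edges()
                if v.exons not in contained and w.exons not in contained
            }
            def reachable(src, dst, edges, skip):
                stack = [src]
                seen = set()
                while stack:
                    u = stack.pop()
                    for a, b in edges:
                        if a == u and (a, b) != skip and b not in seen:
                            if b == dst:
                                return True
                            seen.add(b)
                            stack.append(b)
                return False
            expected = {
                (v, w) for v, w in raw if not reachable(v, w, raw, (v, w))
            }
            ag.strip_and_reduce(g)
            got, _ = edge_chains(g)
            assert got == expected, (trial, sorted(chains))


class TestMergeUniqueChains:
    def test_unique_overlap_pair_merges(self):
        g = ag.build_aux_edges(bins_of((1, 2), (2, 3)))
        ag.strip_and_reduce(g)
        ag.merge_unique_chains(g)
        assert sorted(b.exons for b in g.nodes) == [(1, 2, 3)]
        assert g.nodes[0].count == 2

    def test_converging_overlaps_not_merged(self):
        # b->d and c->d both overlap d: neither pair is unique at d
        g = ag.build_aux_edges(
            bins_of((1, 3, 4), (2, 3, 4), (3, 4, 5))
        )
        ag.strip_and_reduce(g)
        ag.merge_unique_chains(g)
        chains = sorted(b.exons for b in g.nodes)
        assert chains == [(1, 3, 4), (2, 3, 4), (3, 4, 5)]

    def test_unique_subset_absorbed_with_count(self):
        g = ag.build_aux_edges(bins_of((2, 3), (1, 2, 3, 4)))
        ag.strip_and_reduce(g)
        ag.merge_unique_chains(g)
        assert [b.exons for b in g.nodes] == [(1, 2, 3, 4)]
        assert g.nodes[0].count == 2

    def test_total_count_conserved(self):
        chains = [(0, 1), (1, 2), (2, 3), (1, 2, 3), (0, 1, 2, 3), (2,)]
        bins = bins_of(*chains, count=3)
        total = sum(b.count for b in bins)
        g = ag.build_aux_edges(bins)
        ag.strip_and_reduce(g)
        ag.merge_unique_chains(g)
        assert sum(b.count for b in g.nodes) == total

    def test_remaining_overlaps_mark_ambiguity(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(4, 8))
            chains = set()
            while len(chains) < 8:
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, n + 1))
                chains.add(tuple(range(a, b)))
            g = ag.build_aux_edges(bins_of(*sorted(chains)))
            ag.strip_and_reduce(g)
            ag.merge_unique_chains(g)
            for v, w in g.overlap_edges():
                assert len(g.overlap_out[v]) >= 2 or len(g.overlap_in[w]) >= 2
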