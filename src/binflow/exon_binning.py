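"""Exon-range identification and read binning.

Splice sites are clustered to absorb small alignment errors, the covered part
of a locus is partitioned into the minimal set of exon ranges explaining every
splice site, and each fragment is assigned to a *bin*: the ordered chain of
exon ranges it overlaps. Mate pairs that overlap or abut are merged into one
bin; distant mates are kept as paired links for the phasing stage.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .io_alignments import AlignedFragment, CoverageDeltas, Junction, Locus

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 3


@dataclass
class ExonRange:
    """Atomic exon fragment: maximal interval between consecutive boundaries."""

    index: int
    chrom: str
    start: int
    end: int
    left_kind: str = "coverage_edge"   # 'splice' or 'coverage_edge'
    right_kind: str = "coverage_edge"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(eq=False)
class Bin:
    """Ordered chain of exon-range indices with read support.

    ``bases`` accumulates the aligned base count of supporting reads so that
    per-base edge coverage can be derived later; start/end positions are kept
    as compressed multisets.
    """

    exons: Tuple[int, ...]
    count: int = 0
    bases: int = 0
    left_starts: Counter = field(default_factory=Counter)
    right_ends: Counter = field(default_factory=Counter)
    #: reads (mates) crossing each consecutive exon pair of the chain; kept at
    #: mate level so edge coverage stays commensurable with base depth
    pair_cross: Counter = field(default_factory=Counter)

    def add(
        self,
        count: int,
        bases: int,
        start: int,
        end: int,
        mate_chains: Sequence[Tuple[int, ...]] = (),
    ) -> None:
        self.count += count
        self.bases += bases
        self.left_starts[start] += count
        self.right_ends[end] += count
        for mc in mate_chains:
            for pair in zip(mc, mc[1:]):
                self.pair_cross[pair] += 1

    def absorb(self, other: "Bin") -> None:
        self.count += other.count
        self.bases += other.bases
        self.left_starts.update(other.left_starts)
        self.right_ends.update(other.right_ends)
        self.pair_cross.update(other.pair_cross)

    def crossings(self) -> Counter:
        """Per-pair crossing counts; falls back to the fragment count for
        bins built without mate detail."""
        if self.pair_cross:
            return self.pair_cross
        return Counter(
            {pair: self.count for pair in zip(self.exons, self.exons[1:])}
        )


@dataclass
class PairedLink:
    left: Tuple[int, ...]
    right: Tuple[int, ...]
    count: int = 1


def cluster_splice_sites(
    junctions: List[Junction], bandwidth: int = DEFAULT_BANDWIDTH
) -> List[Junction]:
    """Merge splice-site coordinates within ``bandwidth`` by 1D clustering.

    Donors and acceptors are clustered independently per (chrom, strand) by
    single linkage; each cluster collapses onto the member with maximal total
    support (ties: leftmost). Junction support is re-aggregated on the
    canonical coordinates.
    """
    if not junctions:
        return []

    def canonical_map(coords: Dict[int, int]) -> Dict[int, int]:
        out: Dict[int, int] = {}
        cluster: List[int] = []
        for p in sorted(coords):
            if cluster and p - cluster[-1] > bandwidth:
                rep = max(cluster, key=lambda q: (coords[q], -q))
                for q in cluster:
                    out[q] = rep
                cluster = []
            cluster.append(p)
        if cluster:
            rep = max(cluster, key=lambda q: (coords[q], -q))
            for q in cluster:
                out[q] = rep
        return out

    grouped: Dict[Tuple[str, str], List[Junction]] = defaultdict(list)
    for j in junctions:
        grouped[(j.chrom, j.strand)].append(j)
    merged: Dict[Tuple[str, str, int, int], int] = defaultdict(int)
    for (chrom, strand), js in grouped.items():
        donors: Dict[int, int] = defaultdict(int)
        acceptors: Dict[int, int] = defaultdict(int)
        for j in js:
            donors[j.donor] += j.support
            acceptors[j.acceptor] += j.support
        dmap = canonical_map(donors)
        amap = canonical_map(acceptors)
        for j in js:
            merged[(chrom, strand, dmap[j.donor], amap[j.acceptor])] += j.support
    return [
        Junction(chrom=c, strand=s, donor=d, acceptor=a, support=n)
        for (c, s, d, a), n in sorted(merged.items())
    ]


def filter_low_support(junctions: List[Junction], ratio: int = 10) -> List[Junction]:
    """Drop support-1 junctions dominated by a parallel junction.

    A support-1 junction is removed when another junction sharing its donor or
    acceptor has at least ``ratio``-fold its support.
    """
    by_donor: Dict[Tuple[str, str, int], int] = defaultdict(int)
    by_acceptor: Dict[Tuple[str, str, int], int] = defaultdict(int)
    for j in junctions:
        by_donor[(j.chrom, j.strand, j.donor)] = max(
            by_donor[(j.chrom, j.strand, j.donor)], j.support
        )
        by_acceptor[(j.chrom, j.strand, j.acceptor)] = max(
            by_acceptor[(j.chrom, j.strand, j.acceptor)], j.support
        )
    out = []
    for j in junctions:
        if j.support == 1 and (
            by_donor[(j.chrom, j.strand, j.donor)] >= ratio
            or by_acceptor[(j.chrom, j.strand, j.acceptor)] >= ratio
        ):
            continue
        out.append(j)
    return out


def build_exon_ranges(
    junctions: List[Junction],
    coverage: CoverageDeltas,
    locus: Locus,
) -> List[ExonRange]:
    """Partition the covered part of a locus into the minimal exon-range set.

    Boundaries are the coverage edges plus every canonical donor/acceptor
    site; ranges are maximal covered intervals between consecutive boundaries.
    Junctions with an endpoint outside the covered region are dropped with a
    warning (noise).
    """
    ivals = [
        (s, e)
        for s, e in coverage.covered_intervals(locus.chrom)
        if e > locus.start and s < locus.end
    ]
    if not ivals:
        return []
    splice_cuts: Set[int] = set()
    starts = [s for s, _ in ivals]

    def covered_cut(p: int) -> bool:
        """A cut position is valid if it splits or borders a covered interval."""
        from bisect import bisect_right

        i = bisect_right(starts, p) - 1
        if i >= 0 and ivals[i][0] <= p <= ivals[i][1]:
            return True
        return i + 1 < len(ivals) and ivals[i + 1][0] == p

    for j in junctions:
        ok = covered_cut(j.donor) and covered_cut(j.acceptor)
        if not ok:
            logger.warning(
                "junction %s:%d-%d outside covered region; dropped",
                j.chrom, j.donor, j.acceptor,
            )
            continue
        splice_cuts.add(j.donor)
        splice_cuts.add(j.acceptor)

    ranges: List[ExonRange] = []
    for s, e in ivals:
        cuts = sorted({s, e} | {p for p in splice_cuts if s < p < e})
        for a, b in zip(cuts, cuts[1:]):
            ranges.append(
                ExonRange(
                    index=len(ranges),
                    chrom=locus.chrom,
                    start=a,
                    end=b,
                    left_kind="splice" if a in splice_cuts else "coverage_edge",
                    right_kind="splice" if b in splice_cuts else "coverage_edge",
                )
            )
    return ranges


def bin_of_fragment(
    fragment: AlignedFragment,
    exons: List[ExonRange],
    canonical_junctions: Set[Tuple[int, int]],
) -> Optional[Tuple[int, ...]]:
    """Exon-index chain of the ranges a fragment overlaps, or None if rejected.

    A fragment is rejected when one of its splice junctions does not coincide
    with a canonical (clustered) junction between exon-range boundaries.
    """
    for d, a in fragment.junctions():
        if (d, a) not in canonical_junctions:
            return None
    chain: List[int] = []
    for bs, be in fragment.blocks:
        for x in exons:
            if x.end <= bs or x.start >= be:
                continue
            if not chain or chain[-1] != x.index:
                chain.append(x.index)
    if not chain:
        return None
    if any(b <= a for a, b in zip(chain, chain[1:])):
        return None
    return tuple(chain)


def combine_mates(
    r1: Tuple[int, ...], r2: Tuple[int, ...]
) -> Tuple[str, Optional[Tuple]]:
    """Merge two mate bin chains, link them, or reject them.

    Returns ('merged', chain), ('link', (left, right)) or ('rejected', None).
    Mates overlapping (last exon of the upstream chain >= first of the
    downstream) must agree exactly on the overlap; adjacent chains are
    concatenated; otherwise a paired link is kept. Symmetric in mate order.
    """
    a, b = sorted((tuple(r1), tuple(r2)), key=lambda c: (c[0], c[-1]))
    if a[-1] >= b[0]:
        # overlap: suffix of a from b's first exon must equal prefix of b
        try:
            k = a.index(b[0])
        except ValueError:
            return "rejected", None
        overlap = a[k:]
        if b[: len(overlap)] != overlap:
            return "rejected", None
        return "merged", a + b[len(overlap):]
    if a[-1] + 1 == b[0]:
        return "merged", a + b
    return "link", (a, b)


class BinStore:
    """Deduplicated bins plus paired links for one locus."""

    def __init__(self) -> None:
        self.bins: Dict[Tuple[int, ...], Bin] = {}
        self.links: Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], int] = defaultdict(int)
        self.rejected = 0

    def add_chain(
        self,
        chain: Tuple[int, ...],
        bases: int,
        start: int,
        end: int,
        mate_chains: Sequence[Tuple[int, ...]] = (),
    ) -> None:
        b = self.bins.get(chain)
        if b is None:
            b = self.bins[chain] = Bin(exons=chain)
        b.add(1, bases, start, end, mate_chains or (chain,))

    def add_link(self, left: Tuple[int, ...], right: Tuple[int, ...]) -> None:
        self.links[(left, right)] += 1

    def sorted_bins(self) -> List[Bin]:
        return [self.bins[k] for k in sorted(self.bins)]

    def paired_links(self) -> List[PairedLink]:
        return [PairedLink(l, r, n) for (l, r), n in sorted(self.links.items())]

    @property
    def total_count(self) -> int:
        return sum(b.count for b in self.bins.values())


def assign_fragments(
    fragments: Sequence[AlignedFragment],
    exons: List[ExonRange],
    canonical_junctions: Set[Tuple[int, int]],
) -> BinStore:
    """Bin all fragments of a locus, merging mates where possible.

    Fragments sharing a mate key are paired; the pair is merged into a single
    bin when their chains overlap consistently or abut, stored as a paired
    link otherwise. Inconsistent overlaps reject both mates.
    """
    store = BinStore()
    by_key: Dict[str, List[AlignedFragment]] = defaultdict(list)
    for f in fragments:
        by_key[f.mate_key].append(f)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda f: (f.start, f.end))
        chains = []
        ok = True
        for f in group:
            c = bin_of_fragment(f, exons, canonical_junctions)
            if c is None:
                ok = False
                break
            chains.append((c, f))
        if not ok:
            store.rejected += len(group)
            continue
        if len(chains) == 1:
            c, f = chains[0]
            store.add_chain(c, f.aligned_length, f.start, f.end)
        elif len(chains) == 2:
            (c1, f1), (c2, f2) = chains
            kind, payload = combine_mates(c1, c2)
            bases = f1.aligned_length + f2.aligned_length
            start = min(f1.start, f2.start)
            end = max(f1.end, f2.end)
            if kind == "merged":
                store.add_chain(payload, bases, start, end, mate_chains=(c1, c2))
            elif kind == "link":
                left, right = payload
                store.add_chain(left, f1.aligned_length, f1.start, f1.end)
                store.add_chain(right, f2.aligned_length, f2.start, f2.end)
                store.add_link(left, right)
            else:
                store.rejected += 2
        else:  # >2 records with one name: ambiguous, reject
            store.rejected += len(group)
    return store


def cov(exon: ExonRange, coverage: CoverageDeltas) -> float:
    """Mean per-base depth over an exon range."""
    mean, _, _, _ = coverage.depth_stats(exon.chrom, exon.start, exon.end)
    return mean


def boundary_cov(exon: ExonRange, coverage: CoverageDeltas) -> Tuple[int, int, int]:
    """(leftmost-base, rightmost-base, max) depth over an exon range."""
    _, left, right, mx = coverage.depth_stats(exon.chrom, exon.start, exon.end)
    return left, right, mx
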