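"""Streaming of spliced paired-end alignments into genomic blocks and junctions.

Alignments are decomposed into maximal reference-consuming blocks; gaps of at
least the minimum intron length are splice junctions. Coverage is accumulated
as sparse per-base gain/loss events so that whole chromosomes can be processed
in one pass with a small memory footprint.

All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pysam

#: gaps in the alignment shorter than this are deletions, not introns (bp)
MIN_INTRON_LENGTH = 30

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S = 0, 1, 2, 3, 4
_CIGAR_EQ, _CIGAR_X = 7, 8
_REF_CONSUMING_BLOCK = {_CIGAR_M, _CIGAR_D, _CIGAR_EQ, _CIGAR_X}


class UnsortedInputError(RuntimeError):
    """Raised when the alignment stream is not coordinate-sorted."""


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned read (a single mate), decomposed into genomic blocks."""

    chrom: str
    strand: str  # '+', '-' or '.' (unknown)
    blocks: Tuple[Tuple[int, int], ...]
    mate_key: str
    is_first_mate: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junctions(self) -> List[Tuple[int, int]]:
        """(donor, acceptor) pairs: intron start / end, half-open sense."""
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class Junction:
    """A splice junction: intron [donor, acceptor) with read support."""

    chrom: str
    strand: str
    donor: int
    acceptor: int
    support: int = 1

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")


class CoverageDeltas:
    """Sparse per-chromosome coverage as signed gain/loss events per base.

    ``add_block`` records +1 at the block start and -1 at its end; depth at any
    base is the prefix sum of the deltas. The sum of all deltas per chromosome
    is zero and every prefix sum is nonnegative.
    """

    def __init__(self) -> None:
        self._deltas: Dict[str, Dict[int, int]] = defaultdict(lambda: defaultdict(int))
        self._finalized: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    def add_block(self, chrom: str, start: int, end: int, weight: int = 1) -> None:
        if end <= start:
            raise ValueError("empty block")
        d = self._deltas[chrom]
        d[start] += weight
        d[end] -= weight
        self._finalized.pop(chrom, None)

    def add_fragment(self, frag: AlignedFragment) -> None:
        for s, e in frag.blocks:
            self.add_block(frag.chrom, s, e)

    def chroms(self) -> List[str]:
        return sorted(self._deltas)

    def _arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted positions and cumulative depth *starting at* each position."""
        if chrom not in self._finalized:
            d = self._deltas.get(chrom, {})
            pos = np.array(sorted(p for p, v in d.items() if v != 0), dtype=np.int64)
            dl = np.array([d[p] for p in pos], dtype=np.int64)
            self._finalized[chrom] = (pos, np.cumsum(dl))
        return self._finalized[chrom]

    def depth_at(self, chrom: str, position: int) -> int:
        pos, cum = self._arrays(chrom)
        i = np.searchsorted(pos, position, side="right") - 1
        return int(cum[i]) if i >= 0 else 0

    def depth_stats(self, chrom: str, start: int, end: int) -> Tuple[float, int, int, int]:
        """(mean, leftmost, rightmost, max) depth over [start, end)."""
        if end <= start:
            raise ValueError("zero-length coverage query")
        pos, cum = self._arrays(chrom)
        if len(pos) == 0:
            return 0.0, 0, 0, 0
        i0 = int(np.searchsorted(pos, start, side="right")) - 1
        i1 = int(np.searchsorted(pos, end, side="left"))
        left = int(cum[i0]) if i0 >= 0 else 0
        # breakpoints inside the interval
        inner = pos[max(i0 + 1, 0):i1]
        depths = [left] + [int(cum[j]) for j in range(max(i0 + 1, 0), i1)]
        bounds = [start] + [int(p) for p in inner] + [end]
        total = sum(d * (bounds[k + 1] - bounds[k]) for k, d in enumerate(depths))
        return total / (end - start), depths[0], depths[-1], max(depths)

    def median_depth(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted median depth over [start, end)."""
        if end <= start:
            raise ValueError("zero-length coverage query")
        pos, cum = self._arrays(chrom)
        i0 = int(np.searchsorted(pos, start, side="right")) - 1
        i1 = int(np.searchsorted(pos, end, side="left"))
        left = int(cum[i0]) if i0 >= 0 else 0
        inner = pos[max(i0 + 1, 0):i1]
        depths = [left] + [int(cum[j]) for j in range(max(i0 + 1, 0), i1)]
        bounds = [start] + [int(p) for p in inner] + [end]
        pairs = sorted(
            (d, bounds[k + 1] - bounds[k]) for k, d in enumerate(depths)
        )
        half = (end - start) / 2.0
        acc = 0
        for d, ln in pairs:
            acc += ln
            if acc >= half:
                return float(d)
        return float(pairs[-1][0])

    def median_depth_multi(
        self, chrom: str, intervals: List[Tuple[int, int]]
    ) -> float:
        """Length-weighted median depth over a union of intervals."""
        pairs: List[Tuple[int, int]] = []  # (depth, length)
        total = 0
        for start, end in intervals:
            if end <= start:
                continue
            pos, cum = self._arrays(chrom)
            i0 = int(np.searchsorted(pos, start, side="right")) - 1
            i1 = int(np.searchsorted(pos, end, side="left"))
            left = int(cum[i0]) if i0 >= 0 else 0
            inner = pos[max(i0 + 1, 0):i1]
            depths = [left] + [int(cum[j]) for j in range(max(i0 + 1, 0), i1)]
            bounds = [start] + [int(p) for p in inner] + [end]
            for k, d in enumerate(depths):
                ln = bounds[k + 1] - bounds[k]
                pairs.append((d, ln))
                total += ln
        if not pairs:
            return 0.0
        pairs.sort()
        half = total / 2.0
        acc = 0
        for d, ln in pairs:
            acc += ln
            if acc >= half:
                return float(d)
        return float(pairs[-1][0])

    def covered_intervals(self, chrom: str) -> List[Tuple[int, int]]:
        """Maximal intervals of strictly positive depth."""
        pos, cum = self._arrays(chrom)
        out: List[Tuple[int, int]] = []
        open_at: Optional[int] = None
        for p, c in zip(pos, cum):
            if c > 0 and open_at is None:
                open_at = int(p)
            elif c <= 0 and open_at is not None:
                out.append((open_at, int(p)))
                open_at = None
        if open_at is not None:  # cannot happen for balanced deltas
            out.append((open_at, int(pos[-1])))
        return out


def _blocks_from_cigar(pos: int, cigartuples, min_intron: int) -> Tuple[Tuple[int, int], ...]:
    """Decompose a CIGAR into reference blocks, splitting at N >= min_intron.

    M/=/X/D consume reference into the current block; N splits (or, if shorter
    than the minimum intron length, is merged like a deletion); I/S consume
    no reference.
    """
    blocks: List[List[int]] = []
    cur: Optional[List[int]] = None
    at = pos
    for op, ln in cigartuples:
        if op in _REF_CONSUMING_BLOCK:
            if cur is None:
                cur = [at, at + ln]
            else:
                cur[1] += ln
            at += ln
        elif op == _CIGAR_N:
            if ln >= min_intron:
                if cur is not None:
                    blocks.append(cur)
                    cur = None
            elif cur is not None:  # short gap: treat as deletion
                cur[1] += ln
            at += ln
        # I, S, H, P: no reference consumed
    if cur is not None:
        blocks.append(cur)
    return tuple((s, e) for s, e in blocks if e > s)


def stream_fragments(
    alignment_file: str,
    region: Optional[Tuple[str, int, int]] = None,
    min_intron: int = MIN_INTRON_LENGTH,
) -> Iterator[AlignedFragment]:
    """Yield AlignedFragments from a coordinate-sorted SAM/BAM file.

    Secondary and supplementary records are skipped. The strand of a spliced
    read is taken from its XS tag; spliced reads without one get strand '.'.
    Raises UnsortedInputError if records go backwards in coordinate order.
    """
    mode = "rb" if alignment_file.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_file, mode, check_sq=False) as fh:
        it = fh.fetch(region[0], region[1], region[2]) if region else fh
        last: Tuple[str, int] = ("", -1)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if region is None:
                key = (chrom, rec.reference_start)
                if chrom == last[0] and rec.reference_start < last[1]:
                    raise UnsortedInputError(
                        f"input not coordinate-sorted: {rec.query_name} at "
                        f"{chrom}:{rec.reference_start} after {last[0]}:{last[1]}"
                    )
                last = key
            blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples or [], min_intron)
            if not blocks:
                continue
            spliced = len(blocks) > 1
            if spliced:
                try:
                    strand = rec.get_tag("XS")
                except KeyError:
                    strand = "."
            else:
                strand = "."
            yield AlignedFragment(
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                mate_key=rec.query_name,
                is_first_mate=not rec.is_read2,
            )


def collect_junctions(fragments) -> List[Junction]:
    """Aggregate junction support over an iterable of fragments."""
    counts: Dict[Tuple[str, str, int, int], int] = defaultdict(int)
    for f in fragments:
        for donor, acceptor in f.junctions():
            counts[(f.chrom, f.strand, donor, acceptor)] += 1
    return [
        Junction(chrom=c, strand=s, donor=d, acceptor=a, support=n)
        for (c, s, d, a), n in sorted(counts.items())
    ]


@dataclass
class Locus:
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, p: int) -> bool:
        return chrom == self.chrom and self.start <= p < self.end


def partition_loci(coverage: CoverageDeltas, junctions: List[Junction]) -> List[Locus]:
    """Maximal covered intervals, merged across junctions spanning gaps.

    Returns disjoint, sorted loci. A junction whose donor and acceptor fall in
    different covered intervals bridges them into one locus.
    """
    loci: List[Locus] = []
    by_chrom: Dict[str, List[Junction]] = defaultdict(list)
    for j in junctions:
        by_chrom[j.chrom].append(j)
    for chrom in coverage.chroms():
        ivals = coverage.covered_intervals(chrom)
        if not ivals:
            continue
        starts = [s for s, _ in ivals]
        # union-find over interval indices
        parent = list(range(len(ivals)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def locate(p: int) -> Optional[int]:
            i = bisect_right(starts, p) - 1
            if i >= 0 and ivals[i][0] <= p < ivals[i][1]:
                return i
            return None

        for j in by_chrom.get(chrom, []):
            # donor is the first intronic base; the exonic base is donor-1
            a = locate(j.donor - 1)
            b = locate(j.acceptor)
            if a is not None and b is not None and find(a) != find(b):
                parent[find(b)] = find(a)
        groups: Dict[int, List[Tuple[int, int]]] = defaultdict(list)
        for i, iv in enumerate(ivals):
            groups[find(i)].append(iv)
        for members in groups.values():
            s = min(m[0] for m in members)
            e = max(m[1] for m in members)
            loci.append(Locus(chrom, s, e))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci
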