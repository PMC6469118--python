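"""Deterministic synthetic loci: transcript structures, paired-end reads, SAM.

The generator emulates systematic benchmark data for spliced assembly:
artificial multi-isoform genes with uniform coverage per isoform, paired-end
reads sampled uniformly along each transcript, fragment lengths from a
truncated normal, and optional noise knobs (junction jitter, a linear
coverage trend along the transcript, random fragment drop-out). Alignments
are generated directly — the method consumes alignments, not bases — so read
sequences are omitted and splice junctions are exact unless jittered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

DEFAULT_READ_LENGTH = 100
DEFAULT_FRAG_MEAN = 250
DEFAULT_FRAG_SD = 25
DEFAULT_DEPTH = 30.0


@dataclass
class SyntheticLocus:
    """Exon layout and isoform set of one artificial gene."""

    chrom: str
    exons: List[Tuple[int, int]]  # absolute genomic half-open intervals
    isoforms: List[Tuple[int, ...]]  # chains of exon indices
    abundances: List[float]  # relative coverage per isoform
    strand: str = "+"
    read_length: int = DEFAULT_READ_LENGTH
    frag_mean: float = DEFAULT_FRAG_MEAN
    frag_sd: float = DEFAULT_FRAG_SD

    def transcript_length(self, iso: int) -> int:
        return sum(self.exons[i][1] - self.exons[i][0] for i in self.isoforms[iso])

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class LocusSpec:
    """Generative parameters; realised into a SyntheticLocus by make_locus."""

    chrom: str = "chrS"
    offset: int = 1000
    exon_lengths: Sequence[int] = (150, 120, 100, 90, 140, 110, 130)
    intron_lengths: Sequence[int] = (200,) * 6
    isoforms: Sequence[Tuple[int, ...]] = ((0, 1, 2, 3, 4, 5, 6),)
    abundances: Sequence[float] = (1.0,)
    strand: str = "+"
    read_length: int = DEFAULT_READ_LENGTH
    frag_mean: float = DEFAULT_FRAG_MEAN
    frag_sd: float = DEFAULT_FRAG_SD


def make_locus(spec: LocusSpec) -> SyntheticLocus:
    """Realise a locus; isoforms shorter than the fragment length are invalid."""
    if len(spec.intron_lengths) != len(spec.exon_lengths) - 1:
        raise ValueError("need one intron length between consecutive exons")
    exons: List[Tuple[int, int]] = []
    at = spec.offset
    for i, ln in enumerate(spec.exon_lengths):
        exons.append((at, at + ln))
        at += ln
        if i < len(spec.intron_lengths):
            at += spec.intron_lengths[i]
    if len(set(spec.isoforms)) != len(spec.isoforms):
        raise ValueError("duplicate isoforms")
    loc = SyntheticLocus(
        chrom=spec.chrom,
        exons=exons,
        isoforms=[tuple(c) for c in spec.isoforms],
        abundances=list(spec.abundances),
        strand=spec.strand,
        read_length=spec.read_length,
        frag_mean=spec.frag_mean,
        frag_sd=spec.frag_sd,
    )
    for k, chain in enumerate(loc.isoforms):
        if any(b <= a for a, b in zip(chain, chain[1:])):
            raise ValueError(f"isoform {chain} not increasing")
        if loc.transcript_length(k) < spec.frag_mean:
            raise ValueError(
                f"isoform {chain} shorter than the mean fragment length"
            )
    return loc


def transcript_to_blocks(
    locus: SyntheticLocus, iso: int, t_start: int, t_end: int
) -> List[Tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic blocks (merge adjacency)."""
    chain = locus.isoforms[iso]
    blocks: List[List[int]] = []
    at = 0
    for idx in chain:
        s, e = locus.exons[idx]
        ln = e - s
        lo, hi = max(t_start, at), min(t_end, at + ln)
        if lo < hi:
            gs, ge = s + (lo - at), s + (hi - at)
            if blocks and blocks[-1][1] == gs:
                blocks[-1][1] = ge
            else:
                blocks.append([gs, ge])
        at += ln
    return [(s, e) for s, e in blocks]


@dataclass
class SimulatedFragment:
    name: str
    iso: int
    blocks1: List[Tuple[int, int]]
    blocks2: Optional[List[Tuple[int, int]]]


def sample_reads(
    locus: SyntheticLocus,
    depth: float,
    seed: int,
    jitter_rate: float = 0.0,
    jitter_bp: int = 2,
    coverage_trend: float = 0.0,
    drop_rate: float = 0.0,
    paired: bool = True,
) -> List[SimulatedFragment]:
    """Sample paired-end fragments uniformly along each isoform.

    ``depth`` is the target per-base coverage of each isoform, scaled by its
    relative abundance. ``coverage_trend`` in [0,1) ramps the sampling weight
    linearly from (1 - trend) at the 5' end to (1 + trend) at the 3' end.
    ``jitter_rate`` shifts a read's splice junction by up to ``jitter_bp``
    (donor and acceptor together, emulating alignment slippage).
    """
    rng = np.random.default_rng(seed)
    frags: List[SimulatedFragment] = []
    serial = 0
    for iso, chain in enumerate(locus.isoforms):
        tlen = locus.transcript_length(iso)
        weight = locus.abundances[iso]
        r = locus.read_length
        bases_per_frag = 2 * r if paired else r
        n = max(1, round(depth * weight * tlen / bases_per_frag))
        for _ in range(n):
            if drop_rate > 0 and rng.random() < drop_rate:
                continue
            flen = int(round(rng.normal(locus.frag_mean, locus.frag_sd)))
            flen = max(r if not paired else r + 10, min(flen, tlen))

            def anchor(span: int) -> int:
                """Uniform anchor along the transcript, optionally ramped."""
                width = tlen - span
                if width <= 0:
                    return 0
                if coverage_trend > 0:
                    u = rng.random()
                    a = min(coverage_trend, 0.999)
                    pos = (math.sqrt((1 - a) ** 2 + 4 * a * u) - (1 - a)) / (2 * a)
                    return int(pos * width)
                return int(rng.integers(0, width + 1))

            serial += 1
            name = f"frag{serial:07d}"
            if paired:
                # anchor one mate uniformly and clip the insert at the
                # transcript bounds, so read coverage stays flat along the
                # whole transcript (fragmentation covers the ends too)
                if rng.random() < 0.5:
                    s1 = anchor(r)
                    end = min(tlen, s1 + flen)
                    b1 = transcript_to_blocks(locus, iso, s1, s1 + r)
                    b2 = transcript_to_blocks(locus, iso, end - r, end)
                else:
                    e2 = anchor(r) + r
                    start = max(0, e2 - flen)
                    b1 = transcript_to_blocks(locus, iso, start, start + r)
                    b2 = transcript_to_blocks(locus, iso, e2 - r, e2)
            else:
                start = anchor(flen)
                b1 = transcript_to_blocks(locus, iso, start, start + flen)
                b2 = None
            if jitter_rate > 0:
                b1 = _jitter(b1, rng, jitter_rate, jitter_bp)
                if b2 is not None:
                    b2 = _jitter(b2, rng, jitter_rate, jitter_bp)
            frags.append(SimulatedFragment(name, iso, b1, b2))
    return frags


def _jitter(
    blocks: List[Tuple[int, int]], rng, rate: float, bp: int
) -> List[Tuple[int, int]]:
    if len(blocks) < 2:
        return blocks
    out = [list(b) for b in blocks]
    for i in range(len(out) - 1):
        if rng.random() < rate:
            d = int(rng.integers(1, bp + 1)) * (1 if rng.random() < 0.5 else -1)
            if out[i][1] + d > out[i][0] and out[i + 1][0] + d < out[i + 1][1]:
                out[i][1] += d
                out[i + 1][0] += d
    return [(s, e) for s, e in out]


# ----------------------------------------------------------------------
# emission


def _cigar(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ops = []
    for k, (s, e) in enumerate(blocks):
        if k > 0:
            ops.append((3, s - blocks[k - 1][1]))  # N
        ops.append((0, e - s))  # M
    return ops


def emit(
    loci: Sequence[SyntheticLocus],
    fragments_per_locus: Sequence[List[SimulatedFragment]],
    sam_path: str,
    gtf_path: Optional[str] = None,
    chrom_length: Optional[int] = None,
) -> None:
    """Write reads as a coordinate-sorted SAM plus the truth annotation."""
    chroms: Dict[str, int] = {}
    for loc in loci:
        need = loc.end + 1000
        chroms[loc.chrom] = max(chroms.get(loc.chrom, 0), need)
    if chrom_length:
        chroms = {c: max(v, chrom_length) for c, v in chroms.items()}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chroms.items())],
    }
    records = []
    for loc, frags in zip(loci, fragments_per_locus):
        tid_of = {c: i for i, (c, _) in enumerate(sorted(chroms.items()))}
        tid = tid_of[loc.chrom]
        for f in frags:
            paired = f.blocks2 is not None
            mates = [(f.blocks1, True)]
            if paired:
                mates.append((f.blocks2, False))
            for blocks, first in mates:
                a = pysam.AlignedSegment()
                a.query_name = f.name
                a.reference_id = tid
                a.reference_start = blocks[0][0]
                a.cigartuples = _cigar(blocks)
                a.mapping_quality = 60
                flag = 0
                if paired:
                    flag |= 0x1 | 0x2
                    flag |= 0x40 if first else 0x80
                    other = f.blocks2 if first else f.blocks1
                    a.next_reference_id = tid
                    a.next_reference_start = other[0][0]
                    if other[0][0] >= blocks[0][0]:
                        flag |= 0x20  # mate reverse (FR layout)
                    else:
                        flag |= 0x10
                a.flag = flag
                if len(blocks) > 1:
                    a.set_tag("XS", loc.strand)
                records.append((loc.chrom, a.reference_start, a))
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for _, _, a in records:
            out.write(a)
    if gtf_path:
        from .gtf_io import write_truth_gtf

        write_truth_gtf(loci, gtf_path)


# ----------------------------------------------------------------------
# random locus generation (systematic benchmark style)


def random_locus_spec(
    seed: int,
    n_exons: Optional[int] = None,
    n_isoforms: Optional[int] = None,
    chrom: str = "chrS",
    offset: int = 1000,
    equal_abundance: bool = True,
    shared_termini: bool = True,
) -> LocusSpec:
    """A random multi-isoform gene: distinguishable spliceforms on one exon chain.

    Exon lengths 80-180 bp, introns 80-300 bp; isoforms are distinct
    subchains, each with at least three exons so transcripts exceed the
    fragment length. In the systematic-benchmark style, isoforms of a gene
    share the first and last exon and differ by exon skipping
    (``shared_termini``); alternative termini can be requested for fixtures
    exercising start/end placement. Isoform sets are additionally
    constrained to carry distinguishing splice evidence: no isoform's intron
    chain may be a contiguous subsequence of another's, and every shared run
    of exons must be bridgeable by a fragment of an isoform for which the
    run is internal — a transcript whose junctions cannot be phased to a
    distinguishing context is unidentifiable from splice data alone at
    uniform coverage.
    """
    rng = np.random.default_rng(seed)
    if n_exons is None:
        n_exons = int(rng.integers(4, 9))
    if n_isoforms is None:
        n_isoforms = int(rng.integers(1, 9))
    # internal exons are short (most reads span junctions); terminal exons
    # are long, as real first and last exons with UTRs are, which also keeps
    # every junction a fragment length away from the transcript ends
    exon_lengths = [int(rng.integers(80, 181)) for _ in range(n_exons)]
    exon_lengths[0] = int(rng.integers(300, 401))
    exon_lengths[-1] = int(rng.integers(300, 401))
    intron_lengths = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]

    def introns_of(chain: Tuple[int, ...]) -> Tuple[Tuple[int, int], ...]:
        return tuple((a, b) for a, b in zip(chain, chain[1:]))

    def infix(a, b) -> bool:
        if len(a) > len(b):
            return False
        return any(b[k: k + len(a)] == a for k in range(len(b) - len(a) + 1))

    bridge = DEFAULT_FRAG_MEAN - 50  # span a bridging fragment can cover

    def compatible(a: Tuple[int, ...], b: Tuple[int, ...]) -> bool:
        """Pairwise identifiability from fragments of bounded length.

        Every maximal run of exons shared by both isoforms must be phased to
        the distinguishing context around it by a single fragment of the
        isoform for which the run is internal; a run that is terminal for
        one isoform and terminal on the opposite side (or both sides) for
        the other leaves no anchoring junction at all and is rejected.
        """
        runs = []
        for i in range(len(a)):
            for j in range(len(b)):
                if a[i] != b[j] or (i > 0 and j > 0 and a[i - 1] == b[j - 1]):
                    continue
                k = 0
                while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                    k += 1
                runs.append((i, j, k))
        for i, j, k in runs:
            pa, sa = i == 0, i + k == len(a)
            pb, sb = j == 0, j + k == len(b)
            content = sum(exon_lengths[x] for x in a[i: i + k]) + 2
            if (pa or sa) and (pb or sb):
                if pa and pb and not (sa or sb):
                    continue  # shared start: divergence is right-anchored
                if sa and sb and not (pa or pb):
                    continue  # shared end
                return False  # start of one against end of the other
            # the isoform for which the run is internal must bridge it
            if content > bridge:
                return False
        return True

    isoforms: List[Tuple[int, ...]] = []
    tries = 0
    while len(isoforms) < n_isoforms and tries < 400:
        tries += 1
        keep = [
            i for i in range(n_exons)
            if (shared_termini and i in (0, n_exons - 1)) or rng.random() < 0.75
        ]
        if len(keep) < 3:
            continue
        chain = tuple(keep)
        if chain in isoforms:
            continue
        if sum(exon_lengths[i] for i in chain) < DEFAULT_FRAG_MEAN + 30:
            continue
        ic = introns_of(chain)
        if any(
            infix(ic, introns_of(o)) or infix(introns_of(o), ic) for o in isoforms
        ):
            continue
        if not all(compatible(chain, o) for o in isoforms):
            continue
        isoforms.append(chain)
    if not isoforms:
        isoforms = [tuple(range(n_exons))]
    isoforms.sort()
    if equal_abundance:
        abundances = [1.0] * len(isoforms)
    else:
        # geometric separation: ranks are unambiguous relative to counting
        # noise, which is what a rank-recovery benchmark must guarantee
        weights = [1.6 ** k for k in range(len(isoforms))]
        order = rng.permutation(len(isoforms))
        abundances = [float(weights[order[i]]) for i in range(len(isoforms))]
    return LocusSpec(
        chrom=chrom,
        offset=offset,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        isoforms=isoforms,
        abundances=abundances,
    )


def figure_example_locus(offset: int = 1000) -> Tuple[SyntheticLocus, List[SimulatedFragment]]:
    """Curated worked-example locus with hand-placed reads.

    Seven exons A..G (indices 0..6). Three isoforms: two share the chain
    D,F,G after distinct starts (A resp. B), the third reads through
    A,C,D,E,F,G. Short internal exons make multi-splice reads spanning
    C+D (|C|+|D| < read length) possible. Reads are placed so that each
    isoform yields its full-chain bin via mate merging, plus reads spanning
    only D,F — the ambiguous bin that could belong to either short isoform
    and forces exon D to become a node, while E and F stay inside edges.
    """
    spec = LocusSpec(
        chrom="chrF",
        offset=offset,
        exon_lengths=(80, 90, 40, 30, 70, 60, 120),  # A..G
        intron_lengths=(150, 160, 170, 180, 190, 200),
        isoforms=((0, 2, 3, 4, 5, 6), (0, 3, 5, 6), (1, 3, 5, 6)),
        abundances=(1.0, 1.0, 1.0),
    )
    locus = make_locus(spec)
    frags: List[SimulatedFragment] = []
    serial = 0

    def add(iso: int, s1: int, e1: int, s2: Optional[int] = None, e2: Optional[int] = None, copies: int = 12):
        nonlocal serial
        for k in range(copies):
            serial += 1
            b1 = transcript_to_blocks(locus, iso, s1 + k % 3, e1 + k % 3)
            b2 = (
                transcript_to_blocks(locus, iso, s2 + k % 3, e2 + k % 3)
                if s2 is not None
                else None
            )
            frags.append(SimulatedFragment(f"fig{serial:05d}", iso, b1, b2))

    # T1 = A C D E F G (len 400): mates (A,C,D) + (E,F,G) are chain-adjacent
    add(0, 0, 130, 150, 300)
    # T2 = A D F G (len 290): read1 spans A,D,F; read2 overlaps F,G
    add(1, 40, 140, 120, 220)
    # T3 = B D F G (len 300): read1 spans B,D,F; read2 overlaps F,G
    add(2, 50, 150, 130, 230)
    # unpaired reads spanning only D,F from both short isoforms
    add(1, 82, 166, copies=8)
    add(2, 92, 176, copies=8)
    return locus, frags
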