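"""Minimal GTF2.2 reading and writing for transcript models.

Internally all coordinates are 0-based half-open; GTF is 1-based closed.
Only ``transcript`` and ``exon`` features are consumed or produced.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple


@dataclass
class GtfTranscript:
    chrom: str
    strand: str
    transcript_id: str
    gene_id: str
    exons: List[Tuple[int, int]]  # 0-based half-open, sorted
    attributes: Dict[str, str] = field(default_factory=dict)


def _parse_attributes(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str) -> List[GtfTranscript]:
    """Read transcripts with their exons; exon-only files are accepted."""
    exons: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    meta: Dict[str, Tuple[str, str, str, Dict[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attr_text = f[:9]
            if feature not in ("exon", "transcript"):
                continue
            attrs = _parse_attributes(attr_text)
            tid = attrs.get("transcript_id", "")
            gid = attrs.get("gene_id", tid)
            if tid not in meta:
                meta[tid] = (chrom, strand, gid, attrs)
            if feature == "exon":
                exons[tid].append((int(start) - 1, int(end)))
    out = []
    for tid, (chrom, strand, gid, attrs) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        out.append(
            GtfTranscript(
                chrom=chrom,
                strand=strand,
                transcript_id=tid,
                gene_id=gid,
                exons=ex,
                attributes=attrs,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id))
    return out


def write_gtf(transcripts: Sequence, path: str, source: str = "binflow") -> None:
    """Write assembled transcripts as GTF (transcript + exon features).

    Accepts resolution.Transcript objects carrying chrom/strand/exons/
    abundance/fpkm; ordering is deterministic (chrom, start, transcript_id).
    """
    rows = []
    for t in transcripts:
        rows.append(t)
    rows.sort(key=lambda t: (t.chrom, t.exons[0][0] if t.exons else 0))
    with open(path, "w") as fh:
        fh.write("##description: assembled transcripts\n")
        for k, t in enumerate(rows, start=1):
            gid = f"BINFLOW.{k}"
            tid = f"{gid}.1"
            start = t.exons[0][0] + 1
            end = t.exons[-1][1]
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'cov "{t.abundance:.4f}"; FPKM "{t.fpkm:.4f}";'
                + (' guided "1";' if t.guided else "")
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{start}\t{end}\t1000\t{t.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t1000\t{t.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def write_truth_gtf(loci: Sequence, path: str) -> None:
    """Truth annotation for synthetic loci, with simulated abundances."""
    with open(path, "w") as fh:
        fh.write("##description: synthetic truth\n")
        for li, loc in enumerate(loci, start=1):
            for k, chain in enumerate(loc.isoforms, start=1):
                gid = f"SYN.{li}"
                tid = f"{gid}.{k}"
                ivals = _merged_intervals(loc, chain)
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'abundance "{loc.abundances[k - 1]:.4f}";'
                )
                fh.write(
                    f"{loc.chrom}\tsim\ttranscript\t{ivals[0][0] + 1}\t{ivals[-1][1]}"
                    f"\t1000\t{loc.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(ivals, start=1):
                    fh.write(
                        f"{loc.chrom}\tsim\texon\t{s + 1}\t{e}\t1000\t{loc.strand}\t.\t"
                        f'{attrs} exon_number "{i}";\n'
                    )


def _merged_intervals(loc, chain) -> List[Tuple[int, int]]:
    out: List[List[int]] = []
    for idx in chain:
        s, e = loc.exons[idx]
        if out and out[-1][1] == s:
            out[-1][1] = e
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def splice_chain(exons: Sequence[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Ordered introns of a transcript: the identity used for matching."""
    return tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
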