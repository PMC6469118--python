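"""Transcript-level evaluation against a truth annotation.

A prediction is correct when every splice junction matches a truth transcript
exactly (same intron chain, same chrom and strand, same exon count); this is
the standard strict criterion for simulated benchmarks. Single-exon
transcripts are matched by reciprocal overlap instead, since they carry no
splice signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from scipy.stats import spearmanr


@dataclass
class MatchResult:
    recall: float
    precision: float
    n_truth: int
    n_predicted: int
    matched_pairs: List[Tuple[int, int]]  # (truth index, predicted index)


def _signature(chrom: str, strand: str, exons: Sequence[Tuple[int, int]]):
    introns = tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))
    return chrom, strand, introns


def _single_exon_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def match_transcripts(
    truth: Sequence, predicted: Sequence, min_single_exon_overlap: float = 0.5
) -> MatchResult:
    """Match by exact splice chains (multi-exon) or overlap (single-exon).

    ``truth`` and ``predicted`` carry .chrom, .strand and .exons (sorted
    genomic intervals). Strand '.' on a prediction matches either strand.
    """
    used_pred = set()
    pairs: List[Tuple[int, int]] = []
    pred_multi: Dict[Tuple, List[int]] = {}
    for j, p in enumerate(predicted):
        if len(p.exons) > 1:
            pred_multi.setdefault(_signature(p.chrom, p.strand, p.exons), []).append(j)
    for i, t in enumerate(truth):
        if len(t.exons) > 1:
            for strand in (t.strand, "."):
                sig = _signature(t.chrom, strand, t.exons)
                hits = [j for j in pred_multi.get(sig, []) if j not in used_pred]
                if hits:
                    used_pred.add(hits[0])
                    pairs.append((i, hits[0]))
                    break
        else:
            for j, p in enumerate(predicted):
                if j in used_pred or len(p.exons) != 1:
                    continue
                if p.chrom == t.chrom and p.strand in (t.strand, ".") and (
                    _single_exon_overlap(t.exons[0], p.exons[0])
                    >= min_single_exon_overlap
                ):
                    used_pred.add(j)
                    pairs.append((i, j))
                    break
    n_t, n_p = len(truth), len(predicted)
    return MatchResult(
        recall=len(pairs) / n_t if n_t else 1.0,
        precision=len(pairs) / n_p if n_p else 1.0,
        n_truth=n_t,
        n_predicted=n_p,
        matched_pairs=pairs,
    )


def abundance_rank_correlation(
    truth: Sequence, predicted: Sequence, pairs: List[Tuple[int, int]]
) -> float:
    """Spearman rank correlation of true vs estimated abundance on matches."""
    if len(pairs) < 2:
        return 1.0
    t_vals = [truth[i].abundance for i, _ in pairs]
    p_vals = [predicted[j].abundance for _, j in pairs]
    rho = spearmanr(t_vals, p_vals).statistic
    return float(rho)
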