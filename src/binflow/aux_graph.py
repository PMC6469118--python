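"""Auxiliary overlap/containment graph over bins.

The graph guides construction of the final bin graph: *overlap* edges connect
bins whose chains dovetail (a proper suffix of one equals a proper prefix of
the other), *contained* edges connect a bin to every bin whose chain includes
it as a contiguous infix. Containment is infix containment: bins encode
co-linear splice chains, so a non-contiguous subset would contradict the
splice structure.

After construction, overlap edges owned by contained bins are stripped,
transitive edges of both kinds are removed (string-graph reduction in the
style of Myers), and bins connected by unique overlap paths are merged.
"""

from __future__ import annotations

import json
from collections import defaultdict
from typing import Dict, List, Optional, Set, Tuple

from .exon_binning import Bin


def _overlap_length(a: Tuple[int, ...], b: Tuple[int, ...]) -> Optional[int]:
    """Length of the proper-suffix-of-a = proper-prefix-of-b match, if any.

    Chains are strictly increasing, so b's first exon occurs at most once in a
    and the candidate match is unique.
    """
    if b[0] not in a:
        return None
    k = a.index(b[0])
    if k == 0:
        return None  # not a *proper* suffix
    n = len(a) - k
    if n >= len(b):
        return None  # not a *proper* prefix
    return n if a[k:] == b[:n] else None


def _is_infix(a: Tuple[int, ...], b: Tuple[int, ...]) -> bool:
    """True if chain ``a`` is a contiguous infix of chain ``b`` (a != b)."""
    if len(a) >= len(b) or a[0] not in b:
        return False
    k = b.index(a[0])
    return b[k: k + len(a)] == a


class AuxGraph:
    """Bins as nodes; overlap and contained edges as adjacency maps."""

    def __init__(self, bins: List[Bin]) -> None:
        self.nodes: List[Bin] = list(bins)
        self.overlap_out: Dict[Bin, Set[Bin]] = defaultdict(set)
        self.overlap_in: Dict[Bin, Set[Bin]] = defaultdict(set)
        self.contained_in: Dict[Bin, Set[Bin]] = defaultdict(set)  # v -> containers
        self.contains: Dict[Bin, Set[Bin]] = defaultdict(set)      # w -> contained bins

    # -- edge bookkeeping ---------------------------------------------------
    def add_overlap(self, v: Bin, w: Bin) -> None:
        self.overlap_out[v].add(w)
        self.overlap_in[w].add(v)

    def remove_overlap(self, v: Bin, w: Bin) -> None:
        self.overlap_out[v].discard(w)
        self.overlap_in[w].discard(v)

    def add_contained(self, v: Bin, w: Bin) -> None:
        self.contained_in[v].add(w)
        self.contains[w].add(v)

    def remove_contained(self, v: Bin, w: Bin) -> None:
        self.contained_in[v].discard(w)
        self.contains[w].discard(v)

    def overlap_edges(self) -> List[Tuple[Bin, Bin]]:
        return [(v, w) for v in self.nodes for w in sorted(self.overlap_out[v], key=lambda b: b.exons)]

    def contained_edges(self) -> List[Tuple[Bin, Bin]]:
        return [(v, w) for v in self.nodes for w in sorted(self.contained_in[v], key=lambda b: b.exons)]

    def is_contained(self, v: Bin) -> bool:
        return bool(self.contained_in[v])

    def to_json(self) -> str:
        """Debug export: nodes with chains and counts, edges by kind."""
        idx = {id(b): i for i, b in enumerate(self.nodes)}
        return json.dumps(
            {
                "nodes": [
                    {"id": i, "exons": list(b.exons), "count": b.count}
                    for i, b in enumerate(self.nodes)
                ],
                "overlap": [[idx[id(v)], idx[id(w)]] for v, w in self.overlap_edges()],
                "contained": [[idx[id(v)], idx[id(w)]] for v, w in self.contained_edges()],
            },
            indent=1,
        )


def build_aux_edges(bins: List[Bin]) -> AuxGraph:
    """All overlap and contained edges over deduplicated, sorted bins.

    Proper suffix/prefix matches are found through a hash index of chain
    prefixes, giving near-linear behaviour in the total chain length.
    """
    bins = sorted(bins, key=lambda b: (b.exons[0], -len(b.exons), b.exons))
    g = AuxGraph(bins)
    by_chain: Dict[Tuple[int, ...], Bin] = {b.exons: b for b in bins}
    # index: proper prefix -> bins having it
    prefix_index: Dict[Tuple[int, ...], List[Bin]] = defaultdict(list)
    for b in bins:
        for n in range(1, len(b.exons)):
            prefix_index[b.exons[:n]].append(b)
    for v in bins:
        # overlap: proper suffixes of v that are proper prefixes of others
        for k in range(1, len(v.exons)):
            for w in prefix_index.get(v.exons[k:], ()):
                if w is not v:
                    g.add_overlap(v, w)
        # contained: v an infix of some other chain — scan longer bins' infixes
    for w in bins:
        chain = w.exons
        for i in range(len(chain)):
            for j in range(i + 1, len(chain) + 1):
                if j - i == len(chain):
                    continue
                v = by_chain.get(chain[i:j])
                if v is not None and v is not w:
                    g.add_contained(v, w)
    return g


def strip_and_reduce(g: AuxGraph) -> AuxGraph:
    """Strip overlap edges at contained nodes; remove transitive edges.

    A contained bin may not own overlap edges (in either direction). Then
    overlap and contained edge sets are independently transitively reduced:
    an edge is dropped when its endpoints stay connected by a longer path of
    the same kind.
    """
    for v in list(g.nodes):
        if g.is_contained(v):
            for w in list(g.overlap_out[v]):
                g.remove_overlap(v, w)
            for u in list(g.overlap_in[v]):
                g.remove_overlap(u, v)
    _transitive_reduce(g.nodes, g.overlap_out, g.remove_overlap)
    _transitive_reduce(g.nodes, g.contained_in, g.remove_contained)
    return g


def _transitive_reduce(nodes, out_adj, remove) -> None:
    """Remove edges (u,w) with an alternative u->...->w path (same kind)."""
    order = {id(b): i for i, b in enumerate(nodes)}
    for u in nodes:
        direct = sorted(out_adj[u], key=lambda b: order[id(b)])
        if len(direct) < 2 and not any(out_adj[v] for v in direct):
            continue
        targets = set(map(id, direct))
        # DFS from each direct neighbour; reachable direct targets are transitive
        for v in direct:
            stack = [v]
            seen: Set[int] = set()
            while stack:
                x = stack.pop()
                for y in out_adj[x]:
                    if id(y) in seen:
                        continue
                    seen.add(id(y))
                    stack.append(y)
            for w in direct:
                if id(w) in seen and id(w) in targets and w is not v:
                    remove(u, w)
                    targets.discard(id(w))


def merge_unique_chains(g: AuxGraph) -> AuxGraph:
    """Merge bins joined by unambiguous overlap edges; absorb unique subsets.

    An overlap edge a->b with out-degree(a) = in-degree(b) = 1 is an
    unambiguous join: the two bins are concatenated along their overlap into a
    single bin. Afterwards a contained bin whose containers collapse to a
    single bin is absorbed into it (its count added), leaving contained edges
    only where containment is genuinely ambiguous.
    """
    changed = True
    while changed:
        changed = False
        for a in list(g.nodes):
            outs = g.overlap_out[a]
            if len(outs) != 1:
                continue
            b = next(iter(outs))
            if len(g.overlap_in[b]) != 1 or a is b:
                continue
            _merge_pair(g, a, b)
            changed = True
            break
    # absorb contained bins with a unique (deduplicated) container
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            containers = g.contained_in[v]
            if len(containers) == 1:
                (w,) = containers
                w.absorb(v)
                _drop_node(g, v, into=w)
                changed = True
    return g


def _merge_pair(g: AuxGraph, a: Bin, b: Bin) -> None:
    n = _overlap_length(a.exons, b.exons)
    assert n is not None, "merge on non-overlapping pair"
    merged = Bin(exons=a.exons + b.exons[n:])
    merged.absorb(a)
    merged.absorb(b)
    g.nodes[g.nodes.index(a)] = merged
    g.nodes.remove(b)
    for u in list(g.overlap_in[a]):
        g.remove_overlap(u, a)
        g.add_overlap(u, merged)
    for w in list(g.overlap_out[b]):
        g.remove_overlap(b, w)
        g.add_overlap(merged, w)
    g.remove_overlap(a, b)
    # re-target containment: bins contained in a or b are contained in merged
    for kid in set(g.contains[a]) | set(g.contains[b]):
        g.remove_contained(kid, a)
        g.remove_contained(kid, b)
        if _is_infix(kid.exons, merged.exons):
            g.add_contained(kid, merged)
    for cont in set(g.contained_in[a]) | set(g.contained_in[b]):
        g.remove_contained(a, cont)
        g.remove_contained(b, cont)
        if _is_infix(merged.exons, cont.exons):
            g.add_contained(merged, cont)
    g.overlap_out.pop(a, None)
    g.overlap_in.pop(a, None)
    g.overlap_out.pop(b, None)
    g.overlap_in.pop(b, None)


def _drop_node(g: AuxGraph, v: Bin, into: Bin) -> None:
    g.nodes.remove(v)
    for w in list(g.contained_in[v]):
        g.remove_contained(v, w)
    for kid in list(g.contains[v]):
        g.remove_contained(kid, v)
        if _is_infix(kid.exons, into.exons):
            g.add_contained(kid, into)
    for u in list(g.overlap_in[v]):
        g.remove_overlap(u, v)
    for w in list(g.overlap_out[v]):
        g.remove_overlap(v, w)
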