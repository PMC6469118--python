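"""Generalized splice graph over exon bins.

Nodes carry injective exon labels (plus artificial source/sink); edges carry
ordered exon chains. The graph satisfies four structural conditions:

(i)   every source-sink path spells a unique well-formed transcript,
(ii)  every retained bin maps to a unique path whose end nodes are labeled
      with the bin's first and last exon,
(iii) the node count is minimal among graphs satisfying (i) and (ii),
(iv)  edge chains are maximal (exons stay inside edges wherever no ambiguity
      forces a node).

Construction walks maximal bins in genomic order, splitting and joining the
paths of previously placed bins exactly where overlaps mark genuine
ambiguity. Edges double as shared interval markers: splitting an edge turns
it into an inner node of a binary forest whose leaves are the current live
edges, so a split propagates to every bin holding the edge in O(1) — the
device that keeps total construction work linear in total bin length.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .aux_graph import AuxGraph
from .exon_binning import Bin, ExonRange

logger = logging.getLogger(__name__)

SOURCE = "s"
SINK = "t"


@dataclass(eq=False)
class Edge:
    """Graph edge and, at the same time, an interval-marker node.

    A live edge has neither ``children`` nor ``alias``. Splitting sets
    ``children`` (the edge becomes an inner marker node); merging parallel
    duplicates sets ``alias``. Bins hold marker roots; expanding the roots
    through children/alias links yields the bin's current live path.
    """

    source: object  # exon label (int) or SOURCE
    target: object  # exon label (int) or SINK
    chain: Tuple[int, ...]  # includes endpoint exon labels; () for s/t arcs
    children: Optional[Tuple["Edge", "Edge"]] = None
    alias: Optional["Edge"] = None
    flow: float = 0.0

    @property
    def is_artificial(self) -> bool:
        return self.source == SOURCE or self.target == SINK

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Edge({self.source}->{self.target} {self.chain})"


def _resolve(e: Edge) -> Edge:
    while e.alias is not None:
        e = e.alias
    return e


def expand(edges: Iterable[Edge]) -> List[Edge]:
    """Live edges of a marker-root list, in path order."""
    out: List[Edge] = []

    def rec(e: Edge) -> None:
        e = _resolve(e)
        if e.children is not None:
            rec(e.children[0])
            rec(e.children[1])
        else:
            out.append(e)

    for e in edges:
        rec(e)
    return out


class IncompatibleBinError(RuntimeError):
    """A bin contradicts splits already established in the graph (noise)."""


class BinGraph:
    """DAG with injectively exon-labeled nodes and chain-labeled edges."""

    def __init__(self) -> None:
        self.ins: Dict[object, List[Edge]] = defaultdict(list)
        self.outs: Dict[object, List[Edge]] = defaultdict(list)
        self.node_labels: Set[int] = set()
        self.bin_paths: Dict[Bin, List[Edge]] = {}
        self.contained_paths: Dict[Bin, List[Edge]] = {}
        self.single_exon_bins: List[Bin] = []
        self.node_cov: Dict[int, float] = {}
        self.node_bounds: Dict[int, Tuple[int, int, int]] = {}
        self.node_bypass: Dict[int, float] = {}  # depth carried past the node
        self.edge_cov: Dict[int, float] = {}  # id(edge) -> coverage
        self.dropped_bins: int = 0

    # ------------------------------------------------------------------
    def ensure_node(self, label: int) -> None:
        if label not in self.node_labels:
            self.node_labels.add(label)

    def new_edge(self, u, v, chain: Tuple[int, ...]) -> Edge:
        e = Edge(source=u, target=v, chain=chain)
        self.outs[u].append(e)
        self.ins[v].append(e)
        return e

    def _unlink(self, e: Edge) -> None:
        self.outs[e.source].remove(e)
        self.ins[e.target].remove(e)

    def live_edges(self) -> List[Edge]:
        seen: List[Edge] = []
        for u in sorted(self.node_labels) + [SOURCE]:
            seen.extend(self.outs[u])
        return seen

    def exon_edges(self) -> List[Edge]:
        return [e for e in self.live_edges() if not e.is_artificial]

    # -- interval-marker operations -------------------------------------
    def split_edge(self, e: Edge, at_exon: int) -> Tuple[Edge, Edge]:
        """Split a live edge at an interior exon, creating a node there.

        The split propagates to every bin whose path holds this edge, through
        the shared marker reference.
        """
        e = _resolve(e)
        if e.children is not None:
            raise ValueError("cannot split an already-split edge")
        i = e.chain.index(at_exon)
        if i == 0 or i == len(e.chain) - 1:
            raise ValueError(f"exon {at_exon} not interior to {e.chain}")
        self.ensure_node(at_exon)
        left = self.new_edge(e.source, at_exon, e.chain[: i + 1])
        right = self.new_edge(at_exon, e.target, e.chain[i:])
        self._unlink(e)
        e.children = (left, right)
        return left, right

    def merge_parallel(self, keep: Edge, dup: Edge) -> None:
        """Alias ``dup`` onto ``keep``; both must carry identical chains."""
        keep, dup = _resolve(keep), _resolve(dup)
        if keep is dup:
            return
        if (keep.source, keep.target, keep.chain) != (dup.source, dup.target, dup.chain):
            raise IncompatibleBinError(
                f"cannot merge {dup.chain} into {keep.chain}"
            )
        self._unlink(dup)
        dup.alias = keep

    def path_live(self, b: Bin) -> List[Edge]:
        roots = self.bin_paths.get(b) or self.contained_paths.get(b) or []
        return expand(roots)

    def split_path_at(self, b: Bin, at_exon: int) -> None:
        """Ensure a node exists at ``at_exon`` along bin ``b``'s path."""
        for e in self.path_live(b):
            if at_exon == e.chain[0] or at_exon == e.chain[-1]:
                return  # already a node on the path
            if at_exon in e.chain:
                self.split_edge(e, at_exon)
                return
        raise ValueError(f"exon {at_exon} not on path of bin {b.exons}")

    def path_tail(self, b: Bin, from_label: int) -> List[Edge]:
        edges = self.path_live(b)
        for k, e in enumerate(edges):
            if e.chain[0] == from_label:
                return edges[k:]
        raise ValueError(f"no node {from_label} on path of bin {b.exons}")

    # -- output ----------------------------------------------------------
    def to_json(self) -> str:
        edges = self.exon_edges()
        return json.dumps(
            {
                "nodes": sorted(self.node_labels),
                "edges": [
                    {
                        "source": e.source,
                        "target": e.target,
                        "chain": list(e.chain),
                        "cov": self.edge_cov.get(id(e), 0.0),
                        "flow": e.flow,
                    }
                    for e in edges
                ],
            },
            indent=1,
        )

    def to_dot(self) -> str:
        lines = ["digraph bingraph {"]
        for e in self.live_edges():
            ch = ",".join(map(str, e.chain)) if e.chain else ""
            lines.append(f'  "{e.source}" -> "{e.target}" [label="{ch}"];')
        lines.append("}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# construction


def _unify_tails(
    g: BinGraph,
    tail_owners: List[Tuple[Bin, Tuple[int, ...]]],
    start_label: int,
) -> List[Edge]:
    """Split and merge the paths of several bins over a shared chain region.

    ``tail_owners`` lists (bin, region-chain) pairs: for each bin, the suffix
    of its path starting at ``start_label`` covers the given chain (a prefix
    of the longest region). Nodes present on any tail become split points on
    every tail spanning them; parallel edges between consecutive split points
    are merged. Returns the unified edge sequence over the longest region.
    """
    region = max((chain for _, chain in tail_owners), key=len)
    pos = {x: i for i, x in enumerate(region)}

    # collect split points: every node boundary on any tail, within region
    cutpoints: Set[int] = {start_label}
    for b, chain in tail_owners:
        for e in g.path_tail(b, start_label):
            for lab in (e.chain[0], e.chain[-1]):
                if lab in pos and pos[lab] < len(chain):
                    cutpoints.add(lab)
            if pos.get(e.chain[-1], len(region)) >= len(chain) - 1:
                break

    # phase 1: split every tail at every cutpoint interior to one of its edges
    for b, chain in tail_owners:
        changed = True
        while changed:
            changed = False
            span = 0
            for e in g.path_tail(b, start_label):
                inner = [
                    x for x in e.chain[1:-1]
                    if x in cutpoints and pos.get(x, 10**9) < len(chain)
                ]
                if inner:
                    g.split_edge(e, inner[0])
                    changed = True
                    break
                span += len(e.chain) - 1
                if span >= len(chain) - 1:
                    break

    # phase 2: merge parallel edges between consecutive cutpoints
    unified: List[Edge] = []
    ordered_cuts = sorted(cutpoints, key=lambda x: pos[x])
    for c0, c1 in zip(ordered_cuts, ordered_cuts[1:]):
        group: List[Edge] = []
        for b, chain in tail_owners:
            if pos[c1] > len(chain) - 1:
                continue
            for e in g.path_tail(b, start_label):
                if e.chain[0] == c0:
                    group.append(e)
                    break
        uniq: List[Edge] = []
        for e in group:
            e = _resolve(e)
            if all(e is not u for u in uniq):
                uniq.append(e)
        if not uniq:
            continue
        keep = uniq[0]
        for dup in uniq[1:]:
            g.merge_parallel(keep, dup)
        unified.append(keep)
    return unified


def build_bin_graph(aux: AuxGraph, strict: bool = False) -> BinGraph:
    """Build the bin graph guided by the reduced auxiliary graph.

    Step (a) places maximal bins in genomic order, creating end nodes,
    splitting the paths of incoming-overlap bins at the new bin's first exon,
    joining them over the shared prefix and appending the residual chain from
    the rightmost pre-existing node. Step (b) joins the containing paths of
    each multiply-contained bin along that bin's chain.

    Bins that contradict established splits are dropped with a warning (or
    re-raised when ``strict``).
    """
    g = BinGraph()
    maximal = sorted(
        (b for b in aux.nodes if not aux.is_contained(b)),
        key=lambda b: (b.exons[0], -len(b.exons), b.exons),
    )
    placed: Set[int] = set()
    for b in maximal:
        try:
            _place_maximal(g, aux, b, placed)
            placed.add(id(b))
        except IncompatibleBinError as err:
            g.dropped_bins += 1
            if strict:
                raise
            logger.warning("bin %s dropped: %s", b.exons, err)

    contained = sorted(
        (b for b in aux.nodes if aux.is_contained(b)),
        key=lambda b: (-len(b.exons), b.exons),
    )
    for c in contained:
        try:
            _join_contained(g, c)
        except IncompatibleBinError as err:
            g.dropped_bins += 1
            if strict:
                raise
            logger.warning("contained bin %s dropped: %s", c.exons, err)
        _dedup_parallel(g)

    _dedup_parallel(g)
    placed_maximal = [b for b in maximal if id(b) in placed]
    _repair_ambiguities(g, placed_maximal, contained, strict)
    _minimize_nodes(g, placed_maximal, contained)
    _rebuild_paths(g, placed_maximal, contained)
    _finalize(g)
    return g


def _conditions_hold(g: BinGraph, maximal: List[Bin], contained: List[Bin]) -> bool:
    for b in maximal:
        if len(b.exons) >= 2 and len(route_between_nodes(g, b.exons)) != 1:
            return False
    for c in contained:
        if len(route_infix(g, c.exons)) != 1:
            return False
    try:
        return not _duplicate_transcripts(g)
    except RuntimeError:  # pragma: no cover - too large to verify
        return False


class _Surgery:
    """Journaled graph edits (plain link/unlink) with full rollback.

    Used by the node-elimination sweep, which runs after construction when
    the interval markers are no longer needed; edits therefore bypass the
    marker bookkeeping entirely.
    """

    def __init__(self, g: BinGraph) -> None:
        self.g = g
        self.journal: List[Tuple[str, object]] = []

    def link(self, e: Edge) -> Edge:
        self.g.outs[e.source].append(e)
        self.g.ins[e.target].append(e)
        self.journal.append(("link", e))
        return e

    def unlink(self, e: Edge) -> None:
        self.g._unlink(e)
        self.journal.append(("unlink", e))

    def drop_node(self, v: int) -> None:
        self.g.node_labels.discard(v)
        self.journal.append(("nodedel", v))

    def undo(self) -> None:
        for op, x in reversed(self.journal):
            if op == "link":
                self.g._unlink(x)
            elif op == "unlink":
                self.g.outs[x.source].append(x)
                self.g.ins[x.target].append(x)
            else:
                self.g.node_labels.add(x)
        self.journal.clear()

    # -- composite moves -------------------------------------------------
    def dedup_at(self, u: object) -> None:
        seen: Dict[Tuple[object, Tuple[int, ...]], Edge] = {}
        for e in list(self.g.outs[u]):
            key = (e.target, e.chain)
            if key in seen:
                self.unlink(e)
            else:
                seen[key] = e

    def contract(self, v: int) -> bool:
        """Fuse the single in-edge (or out-edge) of ``v`` through the node."""
        ins, outs = self.g.ins[v], self.g.outs[v]
        if not ins or not outs:
            return False
        if len(ins) == 1:
            pairs = [(ins[0], o) for o in list(outs)]
        elif len(outs) == 1:
            pairs = [(i, outs[0]) for i in list(ins)]
        else:
            return False
        sources = {e0.source for e0, _ in pairs}
        for e in list(ins) + list(outs):
            self.unlink(e)
        for e0, e1 in pairs:
            self.link(Edge(source=e0.source, target=e1.target, chain=e0.chain + e1.chain[1:]))
        self.drop_node(v)
        for u in sources:
            self.dedup_at(u)
        return True

    def split_skipping(self, v: int) -> bool:
        """Split edges adjacent to ``v`` at interior labels that are nodes.

        Condition (iv) keeps exons inside edges even where nodes exist; this
        move temporarily reverses that where re-routing through the existing
        nodes lets ``v`` be contracted away (net node-count win), relying on
        the caller to roll back otherwise.
        """
        candidates = list(self.g.ins[v]) + list(self.g.outs[v])
        did = False
        for e in candidates:
            inner = [x for x in e.chain[1:-1] if x in self.g.node_labels]
            if not inner:
                continue
            cuts = [e.chain.index(x) for x in inner]
            bounds = [0] + cuts + [len(e.chain) - 1]
            self.unlink(e)
            for a, b in zip(bounds, bounds[1:]):
                self.link(
                    Edge(source=e.chain[a], target=e.chain[b], chain=e.chain[a: b + 1])
                )
            did = True
        if not did:
            return False
        for u in {v} | {e.source for e in candidates}:
            self.dedup_at(u)
        return True


def _minimize_nodes(g: BinGraph, maximal: List[Bin], contained: List[Bin]) -> None:
    """Greedy node-elimination sweep enforcing conditions (iii) and (iv).

    A node that no retained bin needs as an endpoint and that has a single
    in-edge (or single out-edge) is tentatively contracted — its edges fused
    into maximal chains; where plain contraction fails, adjacent edges are
    first split at labels that are already nodes (re-routing through them)
    and the contraction retried. A move is kept only when every retained bin
    still routes uniquely, every subset bin keeps a unique placement and no
    two paths spell the same transcript; otherwise it is rolled back. This
    removes join split points whose position turned out not to carry any
    ambiguity once the rest of the locus was built.
    """
    required: Set[int] = set()
    for b in maximal:
        required.add(b.exons[0])
        required.add(b.exons[-1])
    changed = True
    while changed:
        changed = False
        for v in sorted(g.node_labels):
            if v in required:
                continue
            accepted = False
            for variant in ("plain", "split"):
                s = _Surgery(g)
                ok = s.split_skipping(v) if variant == "split" else True
                if ok:
                    ok = s.contract(v)
                if ok and _conditions_hold(g, maximal, contained):
                    accepted = True
                    break
                s.undo()
            if accepted:
                changed = True
                break


def _rebuild_paths(g: BinGraph, maximal: List[Bin], contained: List[Bin]) -> None:
    """Re-materialise bin paths by routing, after repair and minimisation."""
    for b in maximal:
        if len(b.exons) == 1:
            g.bin_paths[b] = []
            continue
        routes = route_between_nodes(g, b.exons)
        g.bin_paths[b] = list(routes[0]) if routes else []
    for c in contained:
        routes = route_infix(g, c.exons)
        g.contained_paths[c] = list(routes[0]) if routes else []


def _repair_ambiguities(
    g: BinGraph, maximal: List[Bin], contained: List[Bin], strict: bool
) -> None:
    """Fixpoint joins for residual condition (i)/(ii) violations.

    Joins performed for one bin can re-introduce ambiguity for another
    (a retained bin routing two ways, or two distinct paths spelling the
    same transcript); both are resolved by the same window join until stable.
    """
    for _ in range(20):
        changed = False
        for b in maximal:
            if len(b.exons) < 2:
                continue
            if len(route_between_nodes(g, b.exons)) > 1:
                try:
                    _join_chain(g, b.exons)
                    changed = True
                except IncompatibleBinError as err:
                    if strict:
                        raise
                    logger.warning("repair of bin %s failed: %s", b.exons, err)
        for c in contained:
            if len(route_infix(g, c.exons)) > 1:
                try:
                    routes = _join_chain(g, c.exons)
                    if routes:
                        g.contained_paths[c] = list(routes[0])
                    changed = True
                except IncompatibleBinError as err:
                    if strict:
                        raise
                    logger.warning("repair of subset %s failed: %s", c.exons, err)
        # duplicate spelled transcripts across maximal paths
        try:
            dupes = _duplicate_transcripts(g)
        except RuntimeError:  # pragma: no cover - too many paths to check
            dupes = []
        for t in dupes:
            try:
                _join_chain(g, t)
                changed = True
            except IncompatibleBinError as err:
                if strict:
                    raise
                logger.warning("repair of duplicate %s failed: %s", t, err)
        _dedup_parallel(g)
        if not changed:
            return


def _duplicate_transcripts(g: BinGraph, limit: int = 4000) -> List[Tuple[int, ...]]:
    starts = [lab for lab in sorted(g.node_labels) if not g.ins[lab]]
    seen: Dict[Tuple[int, ...], int] = {}
    count = 0

    def rec(at: int, acc: List[Edge]) -> None:
        nonlocal count
        if not g.outs[at]:
            count += 1
            if count > limit:
                raise RuntimeError("too many paths")
            t = assemble_transcript(acc)
            seen[t] = seen.get(t, 0) + 1
            return
        for e in g.outs[at]:
            acc.append(e)
            rec(e.target, acc)
            acc.pop()

    for s0 in starts:
        rec(s0, [])
    return [t for t, k in seen.items() if k > 1]


def _place_maximal(g: BinGraph, aux: AuxGraph, b: Bin, placed: Set[int]) -> None:
    chain = b.exons
    if len(chain) == 1:
        g.ensure_node(chain[0])
        g.single_exon_bins.append(b)
        g.bin_paths[b] = []
        return
    v_i, v_j = chain[0], chain[-1]
    g.ensure_node(v_i)
    g.ensure_node(v_j)
    incoming = [a for a in aux.overlap_in[b] if id(a) in placed]
    if not incoming:
        e = g.new_edge(v_i, v_j, chain)
        g.bin_paths[b] = [e]
        return
    # split every incoming-overlap path at v_i, join over the shared prefix
    tails: List[Tuple[Bin, Tuple[int, ...]]] = []
    for a in sorted(incoming, key=lambda x: x.exons):
        k = a.exons.index(v_i)
        overlap = a.exons[k:]
        if chain[: len(overlap)] != overlap:
            raise IncompatibleBinError(
                f"overlap of {a.exons} disagrees with {chain}"
            )
        g.split_path_at(a, v_i)
        if len(overlap) > 1:  # single-exon overlaps only share the node
            tails.append((a, overlap))
    unified = _unify_tails(g, tails, v_i) if tails else []
    # rightmost pre-existing node on the joined path, strictly before v_j
    v_x = unified[-1].chain[-1] if unified else v_i
    residual = chain[chain.index(v_x):]
    e = g.new_edge(v_x, v_j, residual)
    g.bin_paths[b] = unified + [e]


def _join_contained(g: BinGraph, c: Bin) -> None:
    """Make bin ``c``'s placement unique by joining paths (step b).

    One placement: the bin is recorded on it (partial count, exempt from the
    endpoint-node requirement). Several: the placements are merged over the
    maximal window around the bin on which they all agree, so no node appears
    where bins uniquely define their connections. Single-exon bins count as
    uniquely placed whenever their exon is a node.
    """
    routes = _join_chain(g, c.exons)
    if not routes:
        raise IncompatibleBinError(f"contained bin {c.exons} has no placement")
    g.contained_paths[c] = list(routes[0])


def _join_chain(g: BinGraph, chain: Tuple[int, ...]) -> List[Tuple[Edge, ...]]:
    """Collapse all placements of ``chain`` into one shared path.

    The placements' spelled chains are aligned on the chain's first exon and
    the agreement window is extended in both directions as far as every
    placement spells the same labels; edges are split at the window bounds
    and at every node boundary inside it, and the resulting parallel edges
    (identical chains between identical nodes) are merged. Splitting only
    within the agreement window keeps every spelled transcript intact while
    making the covered region shared, which is what minimality requires.
    """
    routes = route_infix(g, chain)
    if len(routes) <= 1:
        return routes
    if len(chain) == 1:
        # several interior placements: establish the node, collapsing them
        for r in routes:
            e = _resolve(r[0])
            if chain[0] in e.chain[1:-1]:
                g.split_edge(e, chain[0])
        return route_infix(g, chain)
    guard = 0
    while len(routes) > 1:
        guard += 1
        if guard > 500:  # pragma: no cover - defensive
            raise IncompatibleBinError(f"join of {chain} did not converge")
        spelled = [assemble_transcript(r) for r in routes]
        offs = [s.index(chain[0]) for s in spelled]
        back = 0
        while all(o - back - 1 >= 0 for o in offs) and len(
            {s[o - back - 1] for s, o in zip(spelled, offs)}
        ) == 1:
            back += 1
        fwd = 0
        while all(o + fwd + 1 < len(s) for s, o in zip(spelled, offs)) and len(
            {s[o + fwd + 1] for s, o in zip(spelled, offs)}
        ) == 1:
            fwd += 1
        region = spelled[0][offs[0] - back: offs[0] + fwd + 1]
        if fwd + 1 < len(chain):
            raise IncompatibleBinError(
                f"placements of {chain} disagree inside the chain"
            )
        if len(region) == 1:
            # no shared context at all: make the lone label a node
            for r in routes:
                e = _resolve(r[0])
                if chain[0] in e.chain[1:-1]:
                    g.split_edge(e, chain[0])
            routes = route_infix(g, chain)
            continue
        pos = {x: i for i, x in enumerate(region)}
        # split points: window bounds plus node boundaries inside the window
        cuts: Set[int] = {region[0], region[-1]}
        for r in routes:
            for e in r:
                for lab in (e.chain[0], e.chain[-1]):
                    if lab in pos:
                        cuts.add(lab)
        progressed = False
        for r in routes:
            for e in r:
                e = _resolve(e)
                inner = [x for x in e.chain[1:-1] if x in cuts]
                if inner:
                    g.split_edge(e, inner[0])
                    progressed = True
                    break
            if progressed:
                break
        if progressed:
            routes = route_infix(g, chain)
            continue
        # boundaries aligned: merge parallel edges between consecutive cuts
        ordered = sorted(cuts, key=lambda x: pos[x])
        merged_any = False
        for c0, c1 in zip(ordered, ordered[1:]):
            group: List[Edge] = []
            for r in routes:
                for e in r:
                    e = _resolve(e)
                    if e.chain and e.chain[0] == c0 and e.chain[-1] == c1:
                        if all(e is not u for u in group):
                            group.append(e)
            for dup in group[1:]:
                g.merge_parallel(group[0], dup)
                merged_any = True
        if not merged_any:  # pragma: no cover - defensive
            raise IncompatibleBinError(f"join of {chain} stalled")
        routes = route_infix(g, chain)
    return routes


def _dedup_parallel(g: BinGraph) -> None:
    """Merge edges with identical endpoints and chains.

    Splits and single-label joins can leave indistinguishable parallel edges
    behind; condition (i) requires them to be one edge, and merging them is
    exactly the path join the ambiguity calls for.
    """
    for u in [SOURCE] + sorted(g.node_labels):
        by_key: Dict[Tuple[object, Tuple[int, ...]], Edge] = {}
        for e in list(g.outs[u]):
            key = (e.target, e.chain)
            keep = by_key.get(key)
            if keep is None:
                by_key[key] = e
            else:
                g.merge_parallel(keep, e)


def _finalize(g: BinGraph) -> None:
    """Connect source and sink to every node.

    Boundary nodes are where transcripts must start or end, but transcripts
    may also start or end at internal nodes (alternative promoters or
    terminators on shared exons). Free source/sink arcs at every node let the
    flow solution place such starts wherever conservation demands surplus;
    unused arcs carry no flow and no cost. The arcs carry the node's exon as
    a single-label chain so that path assembly spells single-exon
    transcripts too.
    """
    for lab in sorted(g.node_labels):
        g.new_edge(SOURCE, lab, (lab,))
        g.new_edge(lab, SINK, (lab,))


# ----------------------------------------------------------------------
# coverage annotation


def genomic_length(chain: Sequence[int], exons: List[ExonRange]) -> int:
    return sum(exons[x].length for x in chain)


def annotate_coverage(
    g: BinGraph, exons: List[ExonRange], coverage, bins: Sequence[Bin]
) -> None:
    """Node coverage from base depth; edge coverage from crossing support.

    A node's coverage is the mean per-base depth over its exon. An edge's
    coverage is estimated from the reads that demonstrably traverse it: for
    every consecutive exon pair inside the edge's chain, the summed count of
    bins containing that pair (each such read crosses the pair's boundary, so
    the count is the per-base depth of traversing reads at that boundary);
    the edge value is the mean over its pairs. Both scales then estimate the
    summed abundance of the transcripts using the feature, which is what the
    flow reconciles. Bins are routed to their unique placement; pairs that
    straddle a node belong to the node arc and are skipped.
    """
    from .exon_binning import boundary_cov, cov as exon_cov

    for lab in sorted(g.node_labels):
        g.node_cov[lab] = exon_cov(exons[lab], coverage)
        g.node_bounds[lab] = boundary_cov(exons[lab], coverage)

    crossing: Dict[int, Dict[Tuple[int, int], float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for b in bins:
        if len(b.exons) < 2:
            continue
        routes = route_infix(g, b.exons)
        if not routes:
            continue  # dropped noise survivor
        # ambiguous placements share the mass equally: dropping them would
        # deflate parallel edges and fabricate source/sink slack
        weight = 1.0 / len(routes)
        for route in routes:
            pair_to_edge: Dict[Tuple[int, int], Edge] = {}
            for e in route:
                for pair in zip(e.chain, e.chain[1:]):
                    pair_to_edge[pair] = e
            for pair, count in b.crossings().items():
                e = pair_to_edge.get(pair)
                if e is not None:
                    crossing[id(e)][pair] += count * weight
    for e in g.exon_edges():
        pairs = list(zip(e.chain, e.chain[1:]))
        vals = [crossing[id(e)].get(p, 0.0) for p in pairs]
        g.edge_cov[id(e)] = float(sum(vals) / len(vals)) if vals else 0.0

    # a node's flow arc carries only the paths routed through the node; depth
    # explained by edges holding the exon inside their chains (condition iv)
    # is subtracted, or the solver would conjure that flow from the source
    for lab in sorted(g.node_labels):
        bypass = sum(
            g.edge_cov[id(e)]
            for e in g.exon_edges()
            if lab in e.chain[1:-1]
        )
        g.node_bypass[lab] = bypass
        g.node_cov[lab] = max(0.0, g.node_cov[lab] - bypass)


# ----------------------------------------------------------------------
# condition checking and exhaustive oracle


def assemble_transcript(path_edges: Sequence[Edge]) -> Tuple[int, ...]:
    """Union of edge chains along a path, as one exon chain."""
    out: List[int] = []
    for e in path_edges:
        for x in e.chain:
            if not out or x > out[-1]:
                out.append(x)
            elif x != out[-1]:
                raise ValueError("path spells a non-increasing chain")
    return tuple(out)


def enumerate_st_paths(g: BinGraph, limit: int = 100000) -> List[List[Edge]]:
    paths: List[List[Edge]] = []

    def rec(at, acc: List[Edge]) -> None:
        if at == SINK:
            paths.append(list(acc))
            if len(paths) > limit:
                raise RuntimeError("path enumeration limit exceeded")
            return
        for e in g.outs[at]:
            acc.append(e)
            rec(e.target, acc)
            acc.pop()

    rec(SOURCE, [])
    return paths


def route_between_nodes(g: BinGraph, chain: Tuple[int, ...]) -> List[List[Edge]]:
    """All node-to-node edge paths spelling exactly ``chain``.

    The chain's first and last exon must be node labels; interior exons may
    be consumed inside edge chains.
    """
    if chain[0] not in g.node_labels or chain[-1] not in g.node_labels:
        return []
    if len(chain) == 1:
        return [[]]
    results: List[List[Edge]] = []

    def rec(at: int, remaining: Tuple[int, ...], acc: List[Edge]) -> None:
        if len(remaining) == 1:
            if at == remaining[0]:
                results.append(list(acc))
            return
        for e in g.outs[at]:
            if e.is_artificial or e.chain[0] != remaining[0]:
                continue
            n = len(e.chain)
            if n <= len(remaining) and e.chain == remaining[:n]:
                acc.append(e)
                rec(e.target, remaining[n - 1:], acc)
                acc.pop()

    rec(chain[0], chain, [])
    return results


def route_infix(g: BinGraph, chain: Tuple[int, ...]) -> List[Tuple[Edge, ...]]:
    """All minimal edge paths containing ``chain`` as an infix.

    Unlike route_between_nodes, the match may start and end inside edge
    chains; used to check that a multiply-contained bin has a unique
    placement after path joining. Matches that would begin or end on a pure
    node label (the endpoint of an adjacent edge) are canonicalised to avoid
    double counting.
    """
    results: List[Tuple[Edge, ...]] = []

    def extend(at: int, remaining: Tuple[int, ...], acc: List[Edge]) -> None:
        if len(remaining) == 1:
            if at == remaining[0]:
                results.append(tuple(acc))
            return
        for e in g.outs[at]:
            if e.is_artificial or e.chain[0] != remaining[0]:
                continue
            n = len(e.chain)
            if n >= len(remaining):
                if e.chain[: len(remaining)] == remaining:
                    results.append(tuple(acc + [e]))
            elif e.chain == remaining[:n]:
                extend(e.target, remaining[n - 1:], acc + [e])

    if len(chain) == 1:
        if chain[0] in g.node_labels:
            return [()]
        return [
            (e,) for e in g.exon_edges() if chain[0] in e.chain[1:-1]
        ]
    for e in g.exon_edges():
        if chain[0] not in e.chain:
            continue
        i = e.chain.index(chain[0])
        if i == len(e.chain) - 1:
            continue  # pure endpoint: the continuation from the node covers it
        m = min(len(e.chain) - i, len(chain))
        if e.chain[i: i + m] != chain[:m]:
            continue
        if m == len(chain):
            results.append((e,))
        else:
            extend(e.target, chain[m - 1:], [e])
    return results


def retained_bins(aux: AuxGraph) -> List[Bin]:
    """Bins subject to condition (ii): maximal (merged) bins only."""
    return [b for b in aux.nodes if not aux.is_contained(b)]


def check_conditions(g: BinGraph, bins: List[Bin]) -> Dict[str, List[str]]:
    """Verify conditions (i) and (ii); returns per-condition violations."""
    report: Dict[str, List[str]] = {"i": [], "ii": []}
    try:
        paths = enumerate_st_paths(g)
    except RuntimeError as err:  # pragma: no cover
        report["i"].append(str(err))
        return report
    seen: Dict[Tuple[int, ...], int] = {}
    for p in paths:
        try:
            t = assemble_transcript(p)
        except ValueError as err:
            report["i"].append(str(err))
            continue
        seen[t] = seen.get(t, 0) + 1
    for t, k in seen.items():
        if k > 1:
            report["i"].append(f"{k} distinct paths spell transcript {t}")
    for b in bins:
        routes = route_between_nodes(g, b.exons)
        if len(routes) != 1:
            report["ii"].append(
                f"bin {b.exons} maps to {len(routes)} paths (expected 1)"
            )
    return report


def minimal_node_count(
    bins: List[Tuple[int, ...]],
    n_exons: int,
    contained: Sequence[Tuple[int, ...]] = (),
) -> Optional[int]:
    """Exhaustive minimum node count over graphs satisfying (i) and (ii).

    Brute-force oracle for small instances: tries every subset of exon labels
    as the node set, builds the canonical graph (each maximal bin contributes
    edges between its consecutive member nodes) and checks condition (i),
    condition (ii) for the maximal bins and unique placement for each
    multiply-contained bin.
    """
    required: Set[int] = set()
    for b in bins:
        required.add(b[0])
        required.add(b[-1])
    optional = [x for x in range(n_exons) if x not in required]
    for extra in range(len(optional) + 1):
        for combo in combinations(optional, extra):
            nodeset = required | set(combo)
            g = _candidate_graph(bins, nodeset)
            if g is None:
                continue
            rep = check_conditions(g, [Bin(exons=b) for b in bins])
            if rep["i"] or rep["ii"]:
                continue
            if all(len(route_infix(g, c)) == 1 for c in contained):
                return len(nodeset)
    return None


def _candidate_graph(bins: List[Tuple[int, ...]], nodeset: Set[int]) -> Optional[BinGraph]:
    g = BinGraph()
    for lab in nodeset:
        g.ensure_node(lab)
    edges_seen: Set[Tuple[object, object, Tuple[int, ...]]] = set()
    for b in bins:
        marks = [i for i, x in enumerate(b) if x in nodeset]
        if not marks or b[0] not in nodeset or b[-1] not in nodeset:
            return None
        for i, j in zip(marks, marks[1:]):
            key = (b[i], b[j], b[i: j + 1])
            if key not in edges_seen:
                edges_seen.add(key)
                g.new_edge(b[i], b[j], b[i: j + 1])
    _finalize(g)
    return g
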