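"""Coverage denoising by convex-cost minimum-cost network flow.

Every graph feature (exon node and bin edge) becomes a flow constraint: nodes
are split into in/out halves joined by an arc of observed coverage, edges map
to arcs directly. The objective charges each arc the convex cost of deviating
from its observed coverage,

    node arc:  c_v(x)  = x^2 / cov(v)
    edge arc:  c_vu(x) = x^2 * (|l(uv)| - 1) / cov(uv)

so that the optimal circulation is the coverage assignment explaining the
observations with minimal total squared relative error (the unannotated
transcript expression cover objective). Convex costs are expanded into
parallel arcs with increasing marginal costs — exact at unit granularity up
to a breakpoint, geometric blocks beyond — and solved with the network
simplex algorithm.

A data-driven pre-correction runs first: per-node forward/reverse overheads
(max coverage minus boundary-base coverage) are propagated along the DAG to
lift coverage dips along long transcripts before the flow is solved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .bin_graph import SINK, SOURCE, BinGraph, Edge

DEFAULT_UNIT_BREAKS = 64
DEFAULT_DEV_CAP = 4  # deviations allowed up to dev_cap * observed value
_MAX_EXACT_SCALE = 10**12


@dataclass(eq=False)
class FlowArc:
    """One cost-bearing or free arc of the expanded network."""

    tail: object
    head: object
    cov: float
    kind: str  # 'node' | 'edge' | 'free'
    chain_len: int = 2
    ref: object = None  # Edge for edge arcs, exon label for node arcs
    flow: float = 0.0

    @property
    def cost_factor(self) -> float:
        """alpha in cost(x) = alpha * x^2; None-like inf for cov == 0."""
        if self.kind == "node":
            return 1.0 / self.cov if self.cov > 0 else math.inf
        if self.kind == "edge":
            return (self.chain_len - 1) / self.cov if self.cov > 0 else math.inf
        return 0.0

    def cost(self, flow: float) -> float:
        """Exact convex deviation cost at the given flow value."""
        if self.kind == "free":
            return 0.0
        d = abs(self.cov - flow)
        a = self.cost_factor
        return a * d * d if math.isfinite(a) else 0.0


class FlowNetwork:
    """Node-split flow network over a bin graph (or built directly in tests)."""

    def __init__(self, arcs: List[FlowArc], source=SOURCE, sink=SINK) -> None:
        self.arcs = arcs
        self.source = source
        self.sink = sink

    @classmethod
    def from_bin_graph(cls, g: BinGraph) -> "FlowNetwork":
        arcs: List[FlowArc] = []
        for lab in sorted(g.node_labels):
            arcs.append(
                FlowArc(
                    tail=("in", lab),
                    head=("out", lab),
                    cov=g.node_cov.get(lab, 0.0),
                    kind="node",
                    ref=lab,
                )
            )

        def endpoint(side: str, lab) -> object:
            if lab == SOURCE:
                return SOURCE
            if lab == SINK:
                return SINK
            return (side, lab)

        for e in g.live_edges():
            if e.is_artificial:
                arcs.append(
                    FlowArc(
                        tail=endpoint("out", e.source),
                        head=endpoint("in", e.target),
                        cov=0.0,
                        kind="free",
                        ref=e,
                    )
                )
            else:
                arcs.append(
                    FlowArc(
                        tail=("out", e.source),
                        head=("in", e.target),
                        cov=g.edge_cov.get(id(e), 0.0),
                        kind="edge",
                        chain_len=len(e.chain),
                        ref=e,
                    )
                )
        return cls(arcs)

    def objective(self) -> float:
        return sum(a.cost(a.flow) for a in self.arcs)


def _marginal_blocks(
    c: int, max_dev: int, unit_breaks: int
) -> List[Tuple[int, float]]:
    """(capacity, mean marginal cost/alpha) blocks for deviations 1..max_dev.

    Marginal cost of the k-th deviation unit is alpha*(2k-1); units up to
    ``unit_breaks`` get their own arc (exact), beyond that geometric blocks
    carry the mean marginal over their range (convexity keeps means ordered).
    """
    blocks: List[Tuple[int, float]] = []
    k = 1
    width = 1
    while k <= max_dev:
        if k <= unit_breaks:
            blocks.append((1, float(2 * k - 1)))
            k += 1
        else:
            w = min(width, max_dev - k + 1)
            lo, hi = k, k + w - 1
            # mean of alpha*(2j-1) over j in [lo, hi] is alpha*(lo+hi-1)
            blocks.append((w, float(lo + hi - 1)))
            k += w
            width *= 2
    return blocks


def _lcm_cap(values: Sequence[int]) -> Optional[int]:
    acc = 1
    for v in values:
        acc = acc * v // math.gcd(acc, v)
        if acc > _MAX_EXACT_SCALE:
            return None
    return acc


def solve_utec(
    net: FlowNetwork,
    unit_breaks: int = DEFAULT_UNIT_BREAKS,
    dev_cap: int = DEFAULT_DEV_CAP,
) -> float:
    """Solve the convex-cost min-cost flow; returns the exact objective.

    Observed coverages are rounded to integers (>= 1 where positive); each
    cost-bearing arc is expanded into baseline mandatory flow plus forward and
    backward deviation arcs with increasing integral marginal costs. Arcs with
    zero observed coverage get a flat marginal equal to the network's median
    per-unit cost. Flow values are written back onto the arcs (and onto the
    bin-graph edges they reference).
    """
    cost_arcs = [a for a in net.arcs if a.kind != "free"]
    cov_int: Dict[int, int] = {}
    for a in cost_arcs:
        cov_int[id(a)] = max(1, round(a.cov)) if a.cov > 0 else 0

    # integer cost scaling: exact when an lcm of denominators is affordable
    denoms = sorted({cov_int[id(a)] for a in cost_arcs if cov_int[id(a)] > 0})
    scale = _lcm_cap(denoms)
    approx_scale = 10**6
    max_cov = max([cov_int[id(a)] for a in cost_arcs], default=1)

    def alpha(a: FlowArc) -> float:
        c = cov_int[id(a)]
        if a.kind == "node":
            return 1.0 / c
        return (a.chain_len - 1) / c

    def int_cost(a: FlowArc, mean_marginal_over_alpha: float) -> int:
        c = cov_int[id(a)]
        factor = 1 if a.kind == "node" else (a.chain_len - 1)
        if scale is not None:
            # exact: scale/c is integral, marginal/alpha is integral
            return int(mean_marginal_over_alpha) * factor * (scale // c)
        return round(mean_marginal_over_alpha * factor / c * approx_scale)

    unit_costs = sorted(
        int_cost(a, 1.0) for a in cost_arcs if cov_int[id(a)] > 0
    )
    median_unit = unit_costs[len(unit_costs) // 2] if unit_costs else 1

    G = nx.MultiDiGraph()
    demand: Dict[object, int] = {}
    arc_units: Dict[Tuple, Tuple[FlowArc, int]] = {}  # (u,v,key) -> (arc, sign)

    def bump(node, d):
        demand[node] = demand.get(node, 0) + d

    key_counter = [0]

    def add_unit_arc(u, v, capacity: int, weight: int, arc: FlowArc, sign: int):
        k = key_counter[0]
        key_counter[0] += 1
        G.add_edge(u, v, key=k, capacity=capacity, weight=weight)
        arc_units[(u, v, k)] = (arc, sign)

    for a in net.arcs:
        G.add_node(a.tail)
        G.add_node(a.head)
        if a.kind == "free":
            add_unit_arc(a.tail, a.head, 10**9, 0, a, +1)
            continue
        c = cov_int[id(a)]
        a.flow = float(c)  # baseline; updated with deviations below
        if c > 0:
            # mandatory baseline flow c: shift demands
            bump(a.tail, +c)
            bump(a.head, -c)
            for cap, mm in _marginal_blocks(c, (dev_cap - 1) * c, unit_breaks):
                add_unit_arc(a.tail, a.head, cap, int_cost(a, mm), a, +1)
            for cap, mm in _marginal_blocks(c, c, unit_breaks):
                add_unit_arc(a.head, a.tail, cap, int_cost(a, mm), a, -1)
        else:
            # zero-coverage arc (created by joins): flat median marginal
            add_unit_arc(a.tail, a.head, dev_cap * max_cov, median_unit, a, +1)

    # circulation closure
    G.add_edge(net.sink, net.source, key="circ", capacity=10**9, weight=0)
    for node, d in demand.items():
        G.nodes[node]["demand"] = d

    try:
        _, flowdict = nx.network_simplex(G)
    except nx.NetworkXUnfeasible as err:  # pragma: no cover - construction bug
        raise RuntimeError(f"infeasible flow network: {err}") from err

    deltas: Dict[int, int] = {id(a): 0 for a in net.arcs}
    for u, targets in flowdict.items():
        for v, keyed in targets.items():
            for k, f in keyed.items():
                if f and (u, v, k) in arc_units:
                    arc, sign = arc_units[(u, v, k)]
                    deltas[id(arc)] += sign * f

    for a in net.arcs:
        base = cov_int[id(a)] if a.kind != "free" else 0
        a.flow = float(base + deltas[id(a)])
        if isinstance(a.ref, Edge):
            a.ref.flow = a.flow
    return net.objective()


def solve_bin_graph_flow(
    g: BinGraph,
    unit_breaks: int = DEFAULT_UNIT_BREAKS,
    dev_cap: int = DEFAULT_DEV_CAP,
) -> Tuple[float, Dict[int, float]]:
    """Solve the coverage flow on a bin graph; edge flows set in place.

    Returns (objective, node flow by exon label).
    """
    net = FlowNetwork.from_bin_graph(g)
    obj = solve_utec(net, unit_breaks=unit_breaks, dev_cap=dev_cap)
    node_flow = {a.ref: a.flow for a in net.arcs if a.kind == "node"}
    return obj, node_flow


# ----------------------------------------------------------------------
# coverage pre-correction


def overheads(g: BinGraph) -> Dict[int, Tuple[float, float]]:
    """Per node: (b+, b-) = max coverage minus right/left boundary coverage."""
    out: Dict[int, Tuple[float, float]] = {}
    for lab in g.node_labels:
        left, right, mx = g.node_bounds.get(lab, (0, 0, 0))
        out[lab] = (float(mx - right), float(mx - left))
    return out


def precorrect_coverage(g: BinGraph) -> None:
    """Lift coverage along the DAG using forward/reverse overheads.

    Forward pass (topological order): a node's corrected inflow is the
    overhead-augmented corrected coverage of its predecessors apportioned by
    relative edge coverage, less the node's own left overhead (floored at
    zero); edge corrections redistribute the node correction by relative
    outgoing coverage. The reverse pass mirrors this right-to-left. Each
    feature's coverage is increased by the larger of its two corrections;
    perfectly uniform coverage (all overheads zero) is left unchanged.
    """
    ov = overheads(g)
    labels = sorted(g.node_labels)  # chains increase genomically: topological

    def exon_in(lab):
        return [e for e in g.ins[lab] if not e.is_artificial]

    def exon_out(lab):
        return [e for e in g.outs[lab] if not e.is_artificial]

    cov_e = {id(e): g.edge_cov.get(id(e), 0.0) for e in g.exon_edges()}

    def cap(lab: int, value: float) -> float:
        # a node's correction may restore the dip between boundary and
        # plateau, never push coverage past the exon's maximal depth (less
        # the share carried by edges bypassing the node); uncapped
        # propagation would compound the read-length ramps at transcript
        # starts/ends into arbitrarily large lifts downstream
        plateau = g.node_bounds.get(lab, (0, 0, 0))[2] - g.node_bypass.get(lab, 0.0)
        return min(max(0.0, value), max(0.0, plateau - g.node_cov.get(lab, 0.0)))

    covf_node: Dict[int, float] = {}
    covf_edge: Dict[int, float] = {}
    for v in labels:
        ins = exon_in(v)
        denom = sum(cov_e[id(e)] for e in ins)
        gain = 0.0
        if denom > 0:
            gain = sum(
                (covf_node[e.source] + ov[e.source][0]) * cov_e[id(e)] / denom
                for e in ins
            )
        covf_node[v] = cap(v, gain - ov[v][1])
        outs = exon_out(v)
        odenom = sum(cov_e[id(e)] for e in outs)
        for e in outs:
            # edges carry the node's correction plus the overhead pushed
            # onward: that is the mass the next node's update receives
            covf_edge[id(e)] = (
                (covf_node[v] + ov[v][0]) * cov_e[id(e)] / odenom
                if odenom > 0
                else 0.0
            )

    covr_node: Dict[int, float] = {}
    covr_edge: Dict[int, float] = {}
    for v in reversed(labels):
        outs = exon_out(v)
        denom = sum(cov_e[id(e)] for e in outs)
        gain = 0.0
        if denom > 0:
            gain = sum(
                (covr_node[e.target] + ov[e.target][1]) * cov_e[id(e)] / denom
                for e in outs
            )
        covr_node[v] = cap(v, gain - ov[v][0])
        ins = exon_in(v)
        idenom = sum(cov_e[id(e)] for e in ins)
        for e in ins:
            covr_edge[id(e)] = (
                (covr_node[v] + ov[v][1]) * cov_e[id(e)] / idenom
                if idenom > 0
                else 0.0
            )

    for v in labels:
        g.node_cov[v] = g.node_cov.get(v, 0.0) + max(covf_node[v], covr_node[v])
    for e in g.exon_edges():
        g.edge_cov[id(e)] = cov_e[id(e)] + max(
            covf_edge.get(id(e), 0.0), covr_edge.get(id(e), 0.0)
        )


# ----------------------------------------------------------------------
# guided correction


def find_guide_path(g: BinGraph, chain: Tuple[int, ...]) -> Optional[List[Edge]]:
    """Map a guide exon chain to its unique s-t path, or None if incompatible."""
    from .bin_graph import route_between_nodes

    if chain[0] not in g.node_labels or chain[-1] not in g.node_labels:
        return None
    if any(e.source == SOURCE for e in g.ins[chain[0]]) is False:
        return None
    if any(e.target == SINK for e in g.outs[chain[-1]]) is False:
        return None
    routes = route_between_nodes(g, chain)
    if len(routes) != 1:
        return None
    return routes[0]


def guided_correct(
    g: BinGraph,
    guides: Sequence[Tuple[int, ...]],
    trust_threshold: float,
) -> Tuple[float, Dict[Tuple[int, ...], float]]:
    """Adjust coverage toward annotation-explained values.

    Each guide is mapped to its path (incompatible guides are dropped). Per
    node, the bias factor is outgoing over incoming edge coverage; each guide
    is assigned the largest coverage propagatable along its path (multiplying
    bias factors) without exceeding remaining feature coverage. Guides are
    processed in deterministic chain order against remaining coverage. With F
    the length-weighted fraction of total coverage explained: if F reaches
    the trust threshold, coverage is replaced by the guide sums; otherwise it
    is raised toward them in proportion to F.

    Returns (F, allocation per guide chain).
    """
    remaining_node = dict(g.node_cov)
    remaining_edge = dict(g.edge_cov)
    guide_sum_node: Dict[int, float] = {lab: 0.0 for lab in g.node_labels}
    guide_sum_edge: Dict[int, float] = {id(e): 0.0 for e in g.exon_edges()}
    alloc: Dict[Tuple[int, ...], float] = {}

    def bias(lab: int) -> float:
        outs = [e for e in g.outs[lab] if not e.is_artificial]
        ins = [e for e in g.ins[lab] if not e.is_artificial]
        num = sum(g.edge_cov.get(id(e), 0.0) for e in outs)
        den = sum(g.edge_cov.get(id(e), 0.0) for e in ins)
        return num / den if den > 0 and num > 0 else 1.0

    for chain in sorted(set(guides)):
        path = find_guide_path(g, chain)
        if path is None:
            alloc[chain] = 0.0
            continue
        # features along the path with cumulative bias scaling
        feats: List[Tuple[str, object, float]] = []
        scalef = 1.0
        feats.append(("node", path[0].source if path else chain[0], scalef))
        for e in path:
            feats.append(("edge", e, scalef))
            scalef *= bias(e.target)
            feats.append(("node", e.target, scalef))
        if not path:
            feats = [("node", chain[0], 1.0)]
        c0 = math.inf
        for kind, ref, sc in feats:
            avail = (
                remaining_node.get(ref, 0.0)
                if kind == "node"
                else remaining_edge.get(id(ref), 0.0)
            )
            c0 = min(c0, avail / sc if sc > 0 else math.inf)
        c0 = max(0.0, 0.0 if math.isinf(c0) else c0)
        alloc[chain] = c0
        for kind, ref, sc in feats:
            take = c0 * sc
            if kind == "node":
                remaining_node[ref] = max(0.0, remaining_node.get(ref, 0.0) - take)
                guide_sum_node[ref] += take
            else:
                remaining_edge[id(ref)] = max(
                    0.0, remaining_edge.get(id(ref), 0.0) - take
                )
                guide_sum_edge[id(ref)] += take

    total = sum(g.node_cov.values()) + sum(
        g.edge_cov.get(id(e), 0.0) for e in g.exon_edges()
    )
    explained = sum(guide_sum_node.values()) + sum(guide_sum_edge.values())
    F = explained / total if total > 0 else 0.0

    if F > 0 and F >= trust_threshold:
        for lab in g.node_labels:
            g.node_cov[lab] = guide_sum_node[lab]
        for e in g.exon_edges():
            g.edge_cov[id(e)] = guide_sum_edge[id(e)]
    elif F > 0:
        for lab in g.node_labels:
            lift = max(0.0, guide_sum_node[lab] - g.node_cov[lab])
            g.node_cov[lab] += lift * F
        for e in g.exon_edges():
            cur = g.edge_cov.get(id(e), 0.0)
            lift = max(0.0, guide_sum_edge[id(e)] - cur)
            g.edge_cov[id(e)] = cur + lift * F
    return F, alloc
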