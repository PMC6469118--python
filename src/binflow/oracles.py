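"""Independent brute-force oracles for validating the optimization steps.

These enumerate the full discrete solution space and are deliberately
independent of the production code paths: the flow oracle walks every
integral conserving flow; the resolution oracle scans integer grids of
connection values. Exponential, therefore only usable on tiny instances.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

from .flow import FlowArc, FlowNetwork


def _topo_vertices(net: FlowNetwork) -> List[object]:
    verts = {net.source, net.sink}
    for a in net.arcs:
        verts.add(a.tail)
        verts.add(a.head)
    indeg = {v: 0 for v in verts}
    for a in net.arcs:
        indeg[a.head] += 1
    order: List[object] = []
    ready = sorted((v for v in verts if indeg[v] == 0), key=str)
    while ready:
        v = ready.pop(0)
        order.append(v)
        for a in net.arcs:
            if a.tail == v:
                indeg[a.head] -= 1
                if indeg[a.head] == 0:
                    ready.append(a.head)
        ready.sort(key=str)
    if len(order) != len(verts):
        raise ValueError("flow network is not acyclic")
    return order


def _compositions(total: int, caps: Sequence[int]):
    """Nonnegative integer vectors summing to ``total`` under per-slot caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for first in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


def brute_force_min_cost_flow(
    net: FlowNetwork, dev_cap: int = 4
) -> Tuple[float, Dict[int, int]]:
    """Minimum UTEC objective over all integral conserving flows.

    Per-arc flow is bounded by ``dev_cap`` times its observed coverage (the
    same feasible box the solver uses). Enumeration walks vertices in
    topological order, composing each internal vertex's inflow over its
    outgoing arcs, with branch-and-bound pruning on the accumulated cost.
    Returns (objective, flow per arc id).
    """
    order = _topo_vertices(net)
    outs: Dict[object, List[FlowArc]] = {v: [] for v in order}
    for a in net.arcs:
        outs[a.tail].append(a)
    caps = {
        id(a): max(1, int(round(a.cov)) * dev_cap) if a.cov > 0 else dev_cap * 20
        for a in net.arcs
    }
    best: List[object] = [math.inf, None]
    flows: Dict[int, int] = {}

    def rec(vi: int, inflow: Dict[object, int], cost: float) -> None:
        if cost >= best[0] - 1e-12:
            return
        if vi == len(order):
            best[0] = cost
            best[1] = dict(flows)
            return
        v = order[vi]
        arcs = outs[v]
        if not arcs:
            rec(vi + 1, inflow, cost)
            return
        if v == net.source:
            # source outflow unconstrained: enumerate arcs independently
            def src(ai: int, c: float) -> None:
                if c >= best[0] - 1e-12:
                    return
                if ai == len(arcs):
                    rec(vi + 1, inflow, c)
                    return
                a = arcs[ai]
                for f in range(caps[id(a)] + 1):
                    flows[id(a)] = f
                    old = inflow.get(a.head, 0)
                    inflow[a.head] = old + f
                    src(ai + 1, c + a.cost(f))
                    inflow[a.head] = old

            src(0, cost)
            return
        total = inflow.get(v, 0)
        for combo in _compositions(total, [caps[id(a)] for a in arcs]):
            c2 = cost
            for a, f in zip(arcs, combo):
                flows[id(a)] = f
                c2 += a.cost(f)
            if c2 >= best[0] - 1e-12:
                continue
            olds = [inflow.get(a.head, 0) for a in arcs]
            for a, f in zip(arcs, combo):
                inflow[a.head] = inflow.get(a.head, 0) + f
            rec(vi + 1, inflow, c2)
            for a, old in zip(arcs, olds):
                inflow[a.head] = old

    rec(0, {}, 0.0)
    return best[0], best[1] or {}


def brute_force_resolve(
    E: Sequence[Tuple[int, int]],
    n: Sequence[float],
    fl_S: Sequence[float],
    fl_T: Sequence[float],
    max_x: Optional[int] = None,
) -> Tuple[float, float]:
    """Exhaustive two-step optimum over integer connection grids.

    Step 1: minimal sum |n - x| subject to per-edge budgets. Step 2: minimal
    unexplained flow sum y over budget-feasible x dominating some step-1
    optimum — i.e. with sum max(0, n - x) not exceeding the step-1 optimum
    (lowering components of x to min(n, x) recovers a step-1 candidate).
    Returns (step1 objective, step2 objective).
    """
    nS, nT = len(fl_S), len(fl_T)
    if max_x is None:
        max_x = int(max(list(fl_S) + list(fl_T) + [0]))

    def feasible(xs) -> bool:
        for i in range(nS):
            if sum(x for (a, _), x in zip(E, xs) if a == i) > fl_S[i] + 1e-9:
                return False
        for j in range(nT):
            if sum(x for (_, b), x in zip(E, xs) if b == j) > fl_T[j] + 1e-9:
                return False
        return True

    best1 = math.inf
    for xs in itertools.product(range(max_x + 1), repeat=len(E)):
        if not feasible(xs):
            continue
        obj = sum(abs(a - b) for a, b in zip(n, xs))
        best1 = min(best1, obj)

    best2 = math.inf
    for xs in itertools.product(range(max_x + 1), repeat=len(E)):
        if not feasible(xs):
            continue
        if sum(max(0.0, a - b) for a, b in zip(n, xs)) > best1 + 1e-9:
            continue
        y = 0.0
        for i in range(nS):
            y += max(0.0, fl_S[i] - sum(x for (a, _), x in zip(E, xs) if a == i))
        for j in range(nT):
            y += max(0.0, fl_T[j] - sum(x for (_, b), x in zip(E, xs) if b == j))
        best2 = min(best2, y)
    return best1, best2


def random_flow_network(seed: int, max_arcs: int = 6, max_cov: int = 20) -> FlowNetwork:
    """Small random series-parallel-ish network for oracle comparison."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n_mid = int(rng.integers(1, 3))
    mids = [f"m{i}" for i in range(n_mid)]
    nodes = ["s"] + mids + ["t"]
    arcs: List[FlowArc] = []
    # ensure s -> ... -> t connectivity
    chain = ["s"] + mids + ["t"]
    for u, v in zip(chain, chain[1:]):
        arcs.append(
            FlowArc(u, v, float(rng.integers(1, max_cov + 1)), "node", ref=None)
        )
    while len(arcs) < max_arcs and rng.random() < 0.7:
        i = int(rng.integers(0, len(nodes) - 1))
        j = int(rng.integers(i + 1, len(nodes)))
        kind = "edge" if rng.random() < 0.5 else "node"
        arcs.append(
            FlowArc(
                nodes[i],
                nodes[j],
                float(rng.integers(1, max_cov + 1)),
                kind,
                chain_len=int(rng.integers(2, 5)),
            )
        )
    return FlowNetwork(arcs, source="s", sink="t")
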