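"""Convex-cost flow: solver vs enumeration oracle, pre-correction, guides."""

import math

import pytest

from binflow.bin_graph import BinGraph
from binflow.flow import (
    FlowArc,
    FlowNetwork,
    guided_correct,
    precorrect_coverage,
    solve_utec,
)
from binflow.oracles import brute_force_min_cost_flow, random_flow_network


def test_single_path_exact_coverage_zero_objective():
    net = FlowNetwork(
        [
            FlowArc("s", "a", 10.0, "node"),
            FlowArc("a", "t", 10.0, "edge", chain_len=3),
        ],
        source="s",
        sink="t",
    )
    obj = solve_utec(net)
    assert obj == pytest.approx(0.0)
    assert all(a.flow == 10.0 for a in net.arcs)


def test_y_graph_matches_enumeration():
    net = FlowNetwork(
        [
            FlowArc("s", "a", 10.0, "node"),
            FlowArc("a", "b", 6.0, "edge", chain_len=2),
            FlowArc("a", "c", 3.0, "edge", chain_len=2),
            FlowArc("b", "t", 6.0, "node"),
            FlowArc("c", "t", 3.0, "node"),
        ],
        source="s",
        sink="t",
    )
    obj = solve_utec(net)
    expected, _ = brute_force_min_cost_flow(net)
    assert obj == pytest.approx(expected, abs=1e-9)


def test_solver_equals_oracle_on_random_networks():
    for seed in range(25):
        net = random_flow_network(seed)
        obj = solve_utec(net)
        expected, _ = brute_force_min_cost_flow(net)
        assert math.isclose(obj, expected, rel_tol=1e-9, abs_tol=1e-9), seed
        # conservation at internal vertices
        verts = {a.tail for a in net.arcs} | {a.head for a in net.arcs}
        for v in verts - {"s", "t"}:
            fin = sum(a.flow for a in net.arcs if a.head == v)
            fout = sum(a.flow for a in net.arcs if a.tail == v)
            assert fin == pytest.approx(fout)


def test_cost_homogeneity_identity():
    """c(kx; kc) = k * c(x; c) for both node and edge cost functions, and the
    scaled optimal flow prices at exactly k times the optimum."""
    a_node = FlowArc("u", "v", 7.0, "node")
    a_edge = FlowArc("u", "v", 7.0, "edge", chain_len=4)
    k = 5
    for a in (a_node, a_edge):
        scaled = FlowArc("u", "v", a.cov * k, a.kind, chain_len=a.chain_len)
        for f in range(0, 20):
            assert scaled.cost(k * f) == pytest.approx(k * a.cost(f))
    for seed in range(8):
        net = random_flow_network(seed)
        obj = solve_utec(net)
        flows = [a.flow for a in net.arcs]
        scaled = FlowNetwork(
            [FlowArc(a.tail, a.head, a.cov * k, a.kind, a.chain_len) for a in net.arcs],
            source="s", sink="t",
        )
        priced = sum(
            sa.cost(k * f) for sa, f in zip(scaled.arcs, flows)
        )
        assert priced == pytest.approx(k * obj, abs=1e-9)
        assert solve_utec(scaled) <= k * obj + 1e-9


def _uniform_graph():
    """Two-exon chain with perfectly flat coverage everywhere."""
    g = BinGraph()
    g.ensure_node(0)
    g.ensure_node(1)
    e = g.new_edge(0, 1, (0, 1))
    g.new_edge("s", 0, (0,))
    g.new_edge(1, "t", (1,))
    g.node_cov = {0: 10.0, 1: 10.0}
    g.node_bounds = {0: (10, 10, 10), 1: (10, 10, 10)}
    g.node_bypass = {0: 0.0, 1: 0.0}
    g.edge_cov = {id(e): 10.0}
    return g, e


def test_precorrect_noop_on_uniform_coverage():
    g, e = _uniform_graph()
    precorrect_coverage(g)
    assert g.node_cov == {0: 10.0, 1: 10.0}
    assert g.edge_cov[id(e)] == 10.0


def test_precorrect_lifts_boundary_dip():
    """A node whose left boundary dips below the plateau is lifted toward it,
    by the overhead carried through its in-edge (hand evaluation of the
    update recurrences)."""
    g = BinGraph()
    for lab in (0, 1):
        g.ensure_node(lab)
    e = g.new_edge(0, 1, (0, 1))
    g.new_edge("s", 0, (0,))
    g.new_edge(1, "t", (1,))
    # node 0 flat at 10 with right-boundary overhead 2 (max 12);
    # node 1 dips at its left boundary (left 8, max 12, mean 10)
    g.node_cov = {0: 10.0, 1: 10.0}
    g.node_bounds = {0: (10, 10, 12), 1: (8, 12, 12)}
    g.node_bypass = {0: 0.0, 1: 0.0}
    g.edge_cov = {id(e): 9.0}
    precorrect_coverage(g)
    # forward: cov_f(0) = 0; edge gets (cov_f(0) + b0+) = 2;
    # cov_f(1) = (0 + 2) - b1- (=4), floored at 0 -> node 1 unchanged forward.
    # reverse: cov_r(1) = 0; edge reverse gets (0 + b1- = 4);
    # cov_r(0) = (0 + 4) - b0+ (=2) = 2, capped at max-cov = 2.
    assert g.node_cov[0] == pytest.approx(12.0)
    assert g.node_cov[1] == pytest.approx(10.0)
    assert g.edge_cov[id(e)] == pytest.approx(9.0 + 4.0)


def test_precorrect_never_decreases_coverage():
    g, e = _uniform_graph()
    g.node_bounds = {0: (4, 10, 14), 1: (2, 12, 13)}
    before_nodes = dict(g.node_cov)
    before_edge = g.edge_cov[id(e)]
    precorrect_coverage(g)
    assert all(g.node_cov[k] >= before_nodes[k] for k in before_nodes)
    assert g.edge_cov[id(e)] >= before_edge


def _guide_graph():
    g = BinGraph()
    for lab in (0, 1, 2):
        g.ensure_node(lab)
    e01 = g.new_edge(0, 1, (0, 1))
    e12 = g.new_edge(1, 2, (1, 2))
    g.new_edge("s", 0, (0,))
    g.new_edge(2, "t", (2,))
    g.node_cov = {0: 10.0, 1: 10.0, 2: 10.0}
    g.node_bounds = {k: (10, 10, 10) for k in (0, 1, 2)}
    g.node_bypass = {k: 0.0 for k in (0, 1, 2)}
    g.edge_cov = {id(e01): 10.0, id(e12): 10.0}
    return g, e01, e12


def test_guided_correct_exact_guide_leaves_coverage():
    g, e01, e12 = _guide_graph()
    F, alloc = guided_correct(g, [(0, 1, 2)], trust_threshold=0.5)
    assert F == pytest.approx(1.0)
    assert alloc[(0, 1, 2)] == pytest.approx(10.0)
    assert g.node_cov == {0: 10.0, 1: 10.0, 2: 10.0}


def test_guided_correct_empty_guides_noop():
    g, e01, e12 = _guide_graph()
    F, alloc = guided_correct(g, [], trust_threshold=0.0)
    assert F == 0.0
    assert g.node_cov[1] == 10.0


def test_guided_correct_incompatible_guide_dropped():
    g, e01, e12 = _guide_graph()
    F, alloc = guided_correct(g, [(0, 2)], trust_threshold=0.9)
    assert alloc[(0, 2)] == 0.0


def test_zero_coverage_arc_usable():
    """Arcs created by joins carry no observed coverage but stay routable."""
    net = FlowNetwork(
        [
            FlowArc("s", "a", 10.0, "node"),
            FlowArc("a", "b", 0.0, "edge", chain_len=2),
            FlowArc("b", "t", 10.0, "node"),
        ],
        source="s",
        sink="t",
    )
    solve_utec(net)
    flows = {(a.tail, a.head): a.flow for a in net.arcs}
    assert flows[("a", "b")] > 0
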