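"""Exact solver for convex-coverage-cost matching via min-cost integer flow.

The reduction builds a five-layer network ``s -> C^X -> X -> Y -> C^Y -> t``:

* ``E1`` source edges ``(s, c^X_i)``: infinite capacity, zero cost;
* ``E2`` edges ``(c^X_i, x)`` for ``1 <= i <= d_x``: unit capacity, cost
  ``w_c(x, i) - w_c(x, i-1)``;
* ``E3`` edges ``(x, y)`` for each finite pair cost: unit capacity, cost
  ``w_m(x, y)``;
* ``E4`` edges ``(y, c^Y_i)`` for ``1 <= i <= d_y``: unit capacity, cost
  ``w_c(y, i) - w_c(y, i-1)``;
* ``E5`` sink edges ``(c^Y_i, t)``: infinite capacity, zero cost.

Convexity makes each element's difference costs non-decreasing in ``i``, so
a min-cost flow saturates coverage edges greedily from ``i = 1`` upward and
the flow cost equals the matching cost minus the empty-matching constant
``delta``.  Edges whose difference cost would be +inf (coverage beyond the
finite table) are omitted, preserving exactness.

The flow value is free (not prescribed): we solve the LP

    min  cost . f   s.t.  conservation at every node but s, t;  0 <= f <= cap

whose constraint matrix is a node-arc incidence matrix, hence totally
unimodular; the basic optimum returned by the HiGHS simplex is integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from sagescore.csm_core import (
    ConvexityError,
    Matching,
    MatchingInstance,
    is_convex,
    matching_cost,
)

INF = math.inf

_SOURCE = ("s", 0)
_SINK = ("t", 0)

# absolute tolerances for flow integrality and the post-solve identity check
_INTEGRALITY_ATOL = 1e-6
_SELF_CHECK_ATOL = 1e-6


class InternalConsistencyError(RuntimeError):
    """Solver self-check failure: flow cost + delta deviates from the
    recomputed matching cost."""


@dataclass(frozen=True)
class FlowEdge:
    tail: tuple[str, object]
    head: tuple[str, object]
    capacity: float  # positive integer or math.inf
    cost: float
    layer: str  # one of E1..E5


@dataclass(frozen=True)
class FlowNetwork:
    """Layered flow network for one matching instance."""

    nodes: tuple[tuple[str, object], ...]
    edges: tuple[FlowEdge, ...]
    delta: float

    def edges_in_layer(self, layer: str) -> list[FlowEdge]:
        return [e for e in self.edges if e.layer == layer]


@dataclass(frozen=True)
class IntegerFlow:
    """An integral flow given as one value per network edge (same order)."""

    flow: tuple[int, ...]
    value: int
    cost: float


def _effective_degree(instance: MatchingInstance, z: str, d: int) -> int:
    # coverage of z can exceed neither its degree nor its finite table
    return min(d, instance.coverage_costs[z].max_finite_coverage)


def build_network(instance: MatchingInstance) -> FlowNetwork:
    """Construct the layered network; raises :class:`ConvexityError` if any
    coverage table fails the midpoint condition.

    The number of ``C^X`` nodes is the maximum over reads of the effective
    degree ``min(d_x, max finite coverage of x)``; symmetric for ``C^Y``.
    """
    for z in instance.X + instance.Y:
        table = instance.coverage_costs[z]
        if not is_convex(table):
            c = table.costs
            bad = next(
                i
                for i in range(1, len(c) - 1)
                if c[i] > (c[i - 1] + c[i + 1]) / 2.0 + 1e-12
            )
            raise ConvexityError(z, bad)

    dx = {x: 0 for x in instance.X}
    dy = {y: 0 for y in instance.Y}
    for x, y in instance.matching_costs:
        dx[x] += 1
        dy[y] += 1
    eff_x = {x: _effective_degree(instance, x, dx[x]) for x in instance.X}
    eff_y = {y: _effective_degree(instance, y, dy[y]) for y in instance.Y}
    d_X = max(eff_x.values(), default=0)
    d_Y = max(eff_y.values(), default=0)

    nodes: list[tuple[str, object]] = [_SOURCE]
    nodes += [("cx", i) for i in range(1, d_X + 1)]
    nodes += [("x", x) for x in instance.X]
    nodes += [("y", y) for y in instance.Y]
    nodes += [("cy", i) for i in range(1, d_Y + 1)]
    nodes.append(_SINK)

    edges: list[FlowEdge] = []
    for i in range(1, d_X + 1):
        edges.append(FlowEdge(_SOURCE, ("cx", i), INF, 0.0, "E1"))
    for x in instance.X:
        costs = instance.coverage_costs[x].costs
        prev = None
        for i in range(1, eff_x[x] + 1):
            diff = costs[i] - costs[i - 1]
            if prev is not None and diff < prev - 1e-9:
                raise ConvexityError(x, i)  # Observation-1 monotonicity guard
            prev = diff
            edges.append(FlowEdge(("cx", i), ("x", x), 1, diff, "E2"))
    for x, y in sorted(instance.matching_costs):
        edges.append(
            FlowEdge(("x", x), ("y", y), 1, instance.matching_costs[(x, y)], "E3")
        )
    for y in instance.Y:
        costs = instance.coverage_costs[y].costs
        prev = None
        for i in range(1, eff_y[y] + 1):
            diff = costs[i] - costs[i - 1]
            if prev is not None and diff < prev - 1e-9:
                raise ConvexityError(y, i)
            prev = diff
            edges.append(FlowEdge(("y", y), ("cy", i), 1, diff, "E4"))
    for i in range(1, d_Y + 1):
        edges.append(FlowEdge(("cy", i), _SINK, INF, 0.0, "E5"))

    return FlowNetwork(tuple(nodes), tuple(edges), instance.delta())


def min_cost_free_flow(network: FlowNetwork) -> IntegerFlow:
    """Minimum-cost integer flow over *all* feasible flow values.

    Solved as an LP without a prescribed value: conservation holds at every
    node except the source and sink, and the objective drives flow along
    negative-cost augmenting structure.  Zero flow is always feasible, so
    the optimal cost is <= 0.
    """
    edges = network.edges
    if not edges:
        return IntegerFlow((), 0, 0.0)

    node_index = {node: k for k, node in enumerate(network.nodes)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, e in enumerate(edges):
        for node, sign in ((e.tail, -1.0), (e.head, 1.0)):
            if node in (_SOURCE, _SINK):
                continue
            rows.append(node_index[node])
            cols.append(j)
            vals.append(sign)

    n_nodes = len(network.nodes)
    A = coo_matrix((vals, (rows, cols)), shape=(n_nodes, len(edges))).tocsr()
    costs = np.array([e.cost for e in edges])
    bounds = [(0, None if math.isinf(e.capacity) else e.capacity) for e in edges]

    res = linprog(
        costs,
        A_eq=A,
        b_eq=np.zeros(n_nodes),
        bounds=bounds,
        method="highs",
    )
    if not res.success:  # pragma: no cover - defensive; zero flow is feasible
        raise InternalConsistencyError(f"LP solver failed: {res.message}")

    raw = res.x
    flow = np.rint(raw).astype(int)
    if np.max(np.abs(raw - flow)) > _INTEGRALITY_ATOL:
        # fall back to the pure dual simplex, which returns a basic solution
        res = linprog(
            costs, A_eq=A, b_eq=np.zeros(n_nodes), bounds=bounds, method="highs-ds"
        )
        raw = res.x
        flow = np.rint(raw).astype(int)
        if np.max(np.abs(raw - flow)) > _INTEGRALITY_ATOL:
            raise InternalConsistencyError("LP optimum is not integral")

    value = sum(int(flow[j]) for j, e in enumerate(edges) if e.tail == _SOURCE)
    cost = float(np.dot(flow, costs))
    return IntegerFlow(tuple(int(v) for v in flow), value, cost)


def extract_matching(flow: IntegerFlow, network: FlowNetwork) -> Matching:
    """Matching induced by a flow: the saturated read-segment edges."""
    pairs = {
        (e.tail[1], e.head[1])
        for e, f in zip(network.edges, flow.flow)
        if e.layer == "E3" and f == 1
    }
    return Matching(frozenset(pairs))


def canonical_flow(network: FlowNetwork, matching: Matching) -> IntegerFlow:
    """The canonical flow of a matching: saturate each matched pair's edge and
    the first ``c_M(z)`` coverage edges of every element.

    Used by the correctness proofs (and the test suite): its cost equals the
    matching cost minus ``delta``.
    """
    cov = matching.coverages()
    flow = []
    for e in network.edges:
        if e.layer == "E3":
            flow.append(1 if (e.tail[1], e.head[1]) in matching.pairs else 0)
        elif e.layer == "E2":
            i, x = e.tail[1], e.head[1]
            flow.append(1 if i <= cov.get(x, 0) else 0)
        elif e.layer == "E4":
            y, i = e.tail[1], e.head[1]
            flow.append(1 if i <= cov.get(y, 0) else 0)
        else:
            flow.append(0)
    # route source/sink edges to satisfy conservation at the C layers
    for j, e in enumerate(network.edges):
        if e.layer == "E1":
            i = e.head[1]
            flow[j] = sum(
                f
                for f, e2 in zip(flow, network.edges)
                if e2.layer == "E2" and e2.tail[1] == i
            )
        elif e.layer == "E5":
            i = e.tail[1]
            flow[j] = sum(
                f
                for f, e2 in zip(flow, network.edges)
                if e2.layer == "E4" and e2.head[1] == i
            )
    cost = float(sum(f * e.cost for f, e in zip(flow, network.edges)))
    value = sum(f for f, e in zip(flow, network.edges) if e.tail == _SOURCE)
    return IntegerFlow(tuple(flow), value, cost)


def solve_csm(instance: MatchingInstance) -> tuple[Matching, float]:
    """Solve a convex-coverage-cost instance exactly.

    Returns the optimal matching and its cost (flow cost plus the
    empty-matching constant).  A post-solve identity check recomputes the
    matching cost from first principles and raises
    :class:`InternalConsistencyError` on disagreement beyond 1e-6.
    """
    network = build_network(instance)
    flow = min_cost_free_flow(network)
    matching = extract_matching(flow, network)
    via_flow = flow.cost + network.delta
    exact = matching_cost(instance, matching)
    if abs(via_flow - exact) > _SELF_CHECK_ATOL * max(1.0, abs(exact)):
        raise InternalConsistencyError(
            f"flow cost + delta = {via_flow} but matching evaluates to {exact}"
        )
    return matching, exact


def network_to_tsv(network: FlowNetwork) -> str:
    """Debug dump: one TSV row per edge (layer, tail, head, capacity, cost)."""
    lines = ["layer\ttail\thead\tcapacity\tcost"]
    for e in network.edges:
        cap = "inf" if math.isinf(e.capacity) else str(int(e.capacity))
        lines.append(f"{e.layer}\t{e.tail}\t{e.head}\t{cap}\t{e.cost:g}")
    return "\n".join(lines) + "\n"
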