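"""Coverage-sensitive many-to-many matching: problem types, cost evaluation,
convexity checks, special-case encoders and a brute-force oracle.

A matching instance consists of two disjoint element sets ``X`` (reads) and
``Y`` (segments), a sparse table of finite pair costs (absent pairs cost
+inf), and one coverage-cost table per element giving the penalty for each
element as a function of how many matching pairs touch it.  The cost of a
matching ``M`` is::

    w(M) = sum over (x, y) in M of w_m(x, y)
         + sum over z in X u Y of w_c(z, c_M(z))

where ``c_M(z)`` counts the pairs of ``M`` incident to ``z``.  The global
problem is to minimise ``w(M)`` over all subsets of X x Y.  It is NP-hard in
general; :mod:`sagescore.flow_solver` solves the convex-coverage-cost case
exactly, and :func:`brute_force_csm` here enumerates small instances as an
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

INF = math.inf

# Relative slack for the midpoint convexity comparison; guards against
# rounding in tables generated from fractional expected coverages.
_CONVEXITY_RTOL = 1e-9


class InstanceError(ValueError):
    """Raised for malformed instances or matchings referencing unknown elements."""


class ConvexityError(ValueError):
    """Raised when an operation requiring convex coverage costs meets a
    non-convex table; carries the offending element id."""

    def __init__(self, element_id: str, index: int):
        self.element_id = element_id
        self.index = index
        super().__init__(
            f"coverage cost table of element {element_id!r} violates the "
            f"midpoint convexity condition at coverage {index}"
        )


class BruteForceSizeError(ValueError):
    """Raised when an instance is too large for exhaustive enumeration."""


@dataclass(frozen=True)
class CoverageCostTable:
    """Per-element coverage costs with finite contiguous support.

    ``costs[i]`` is the cost of the element having coverage ``i``; coverages
    beyond ``max_finite_coverage`` implicitly cost +inf.

    Parameters
    ----------
    element_id:
        Opaque identifier of the element the table belongs to.
    costs:
        Finite costs for coverages ``0 .. len(costs) - 1``.
    """

    element_id: str
    costs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.costs:
            raise InstanceError(
                f"coverage table of {self.element_id!r} must define cost at coverage 0"
            )
        object.__setattr__(self, "costs", tuple(float(c) for c in self.costs))
        for i, c in enumerate(self.costs):
            if not math.isfinite(c):
                raise InstanceError(
                    f"coverage table of {self.element_id!r} has non-finite entry at {i}; "
                    "trim the table instead (beyond the last entry is implicitly +inf)"
                )

    @property
    def max_finite_coverage(self) -> int:
        return len(self.costs) - 1

    def cost(self, coverage: int) -> float:
        """Cost at the given coverage; +inf beyond the finite support."""
        if coverage < 0:
            raise InstanceError("coverage must be nonnegative")
        if coverage > self.max_finite_coverage:
            return INF
        return self.costs[coverage]


def is_convex(table: CoverageCostTable) -> bool:
    """True iff ``costs[i] <= (costs[i-1] + costs[i+1]) / 2`` at every interior
    index, with entries beyond the finite support treated as +inf.

    The +inf tail can only relax the condition, so only indices with a finite
    right neighbour need checking.
    """
    c = table.costs
    for i in range(1, len(c) - 1):
        mid = (c[i - 1] + c[i + 1]) / 2.0
        slack = _CONVEXITY_RTOL * max(1.0, abs(c[i - 1]), abs(c[i]), abs(c[i + 1]))
        if c[i] > mid + slack:
            return False
    return True


@dataclass(frozen=True)
class MatchingInstance:
    """A coverage-sensitive matching instance (X, Y, w).

    ``matching_costs`` is sparse: pairs absent from the map have cost +inf
    and can never belong to a finite-cost matching.  Every element of
    ``X`` and ``Y`` must own a coverage-cost table.
    """

    X: tuple[str, ...]
    Y: tuple[str, ...]
    matching_costs: Mapping[tuple[str, str], float]
    coverage_costs: Mapping[str, CoverageCostTable]

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", tuple(self.X))
        object.__setattr__(self, "Y", tuple(self.Y))
        xs, ys = set(self.X), set(self.Y)
        if len(xs) != len(self.X) or len(ys) != len(self.Y):
            raise InstanceError("duplicate element ids within a shore")
        if xs & ys:
            raise InstanceError(f"X and Y must be disjoint; shared: {sorted(xs & ys)}")
        for (x, y), cost in self.matching_costs.items():
            if x not in xs or y not in ys:
                raise InstanceError(f"matching cost references unknown pair ({x!r}, {y!r})")
            if not math.isfinite(cost):
                raise InstanceError(
                    f"matching cost for ({x!r}, {y!r}) must be finite; omit the pair instead"
                )
        for z in self.X + self.Y:
            if z not in self.coverage_costs:
                raise InstanceError(f"element {z!r} lacks a coverage cost table")

    def finite_pairs(self) -> list[tuple[str, str]]:
        """Finite-cost pairs in lexicographic order."""
        return sorted(self.matching_costs)

    def d_x(self, x: str) -> int:
        """Number of segments with finite matching cost to read ``x``."""
        return sum(1 for (a, _b) in self.matching_costs if a == x)

    def d_y(self, y: str) -> int:
        """Number of reads with finite matching cost to segment ``y``."""
        return sum(1 for (_a, b) in self.matching_costs if b == y)

    def delta(self) -> float:
        """Cost of the empty matching: sum of all zero-coverage costs."""
        return sum(t.costs[0] for t in (self.coverage_costs[z] for z in self.X + self.Y))


@dataclass(frozen=True)
class Matching:
    """A many-to-many matching: a set of (x, y) pairs."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def coverage(self, z: str) -> int:
        """Number of pairs incident to element ``z`` (either side)."""
        return sum(1 for (x, y) in self.pairs if x == z or y == z)

    def coverages(self) -> dict[str, int]:
        cov: dict[str, int] = {}
        for x, y in self.pairs:
            cov[x] = cov.get(x, 0) + 1
            cov[y] = cov.get(y, 0) + 1
        return cov


def matching_cost(instance: MatchingInstance, m: Matching) -> float:
    """Evaluate the matching cost: pair costs plus per-element coverage costs.

    Returns +inf if any pair is absent from the sparse cost map or any
    element's coverage exceeds its finite table.
    """
    xs, ys = set(instance.X), set(instance.Y)
    for x, y in m.pairs:
        if x not in xs or y not in ys:
            raise InstanceError(f"matching pair ({x!r}, {y!r}) references unknown elements")

    total = 0.0
    for pair in m.pairs:
        cost = instance.matching_costs.get(pair)
        if cost is None:
            return INF
        total += cost
    cov = m.coverages()
    for z in instance.X + instance.Y:
        c = instance.coverage_costs[z].cost(cov.get(z, 0))
        if not math.isfinite(c):
            return INF
        total += c
    return total


def brute_force_csm(
    instance: MatchingInstance, max_pairs: int = 20
) -> tuple[Matching, float]:
    """Exact minimum by enumerating all subsets of the finite-cost pairs.

    Ties are broken by lexicographic order of the sorted pair tuple so the
    result is deterministic.  Refuses instances with more than ``max_pairs``
    finite pairs (enumeration is 2**n).
    """
    pairs = instance.finite_pairs()
    n = len(pairs)
    if n > max_pairs:
        raise BruteForceSizeError(
            f"instance has {n} finite pairs, above the enumeration bound {max_pairs}"
        )

    pair_costs = [instance.matching_costs[p] for p in pairs]
    elements = list(instance.X) + list(instance.Y)
    elem_index = {z: k for k, z in enumerate(elements)}
    tables = [instance.coverage_costs[z] for z in elements]
    incident = [(elem_index[x], elem_index[y]) for x, y in pairs]

    best_cost = INF
    best_subset: tuple[tuple[str, str], ...] | None = None
    n_elem = len(elements)
    for mask in range(1 << n):
        cov = [0] * n_elem
        total = 0.0
        k = mask
        i = 0
        while k:
            if k & 1:
                total += pair_costs[i]
                xi, yi = incident[i]
                cov[xi] += 1
                cov[yi] += 1
            k >>= 1
            i += 1
        ok = True
        for zi in range(n_elem):
            c = tables[zi].cost(cov[zi])
            if not math.isfinite(c):
                ok = False
                break
            total += c
        if not ok:
            continue
        if total < best_cost:
            best_cost = total
            best_subset = tuple(pairs[i] for i in range(n) if mask >> i & 1)
        elif total == best_cost and best_subset is not None:
            subset = tuple(pairs[i] for i in range(n) if mask >> i & 1)
            if subset < best_subset:
                best_subset = subset

    assert best_subset is not None  # empty matching is always finite? not if w_c(z,0)=inf
    return Matching(frozenset(best_subset)), best_cost


def encode_bipartite_matching(edges: Iterable[tuple[str, str]]) -> MatchingInstance:
    """Encode maximum-cardinality one-to-one bipartite matching as an instance
    whose optimum equals minus the maximum matching size.

    Every edge gets matching cost -1; every element gets coverage costs
    0 at coverages 0 and 1 and +inf beyond, capping each element at one pair.
    """
    edge_list = sorted(set(edges))
    if not edge_list:
        raise InstanceError("edge set must be nonempty")
    X = tuple(sorted({x for x, _ in edge_list}))
    Y = tuple(sorted({y for _, y in edge_list}))
    if set(X) & set(Y):
        raise InstanceError("bipartite shores must use disjoint vertex names")
    tables = {z: CoverageCostTable(z, (0.0, 0.0)) for z in X + Y}
    costs = {e: -1.0 for e in edge_list}
    return MatchingInstance(X, Y, costs, tables)


# ---------------------------------------------------------------------------
# plain-text instance serialization (fixture + oracle CLI format)
# ---------------------------------------------------------------------------

def write_instance(instance: MatchingInstance, path: str) -> None:
    """Serialize an instance to a plain-text file.

    Format: one ``elem <side> <id>`` line per element (preserving order),
    one ``cov <id> <c0> <c1> ...`` line per coverage table, and one
    ``pair <x> <y> <cost>`` line per finite pair.
    """
    with open(path, "w") as fh:
        for x in instance.X:
            fh.write(f"elem X {x}\n")
        for y in instance.Y:
            fh.write(f"elem Y {y}\n")
        for z in instance.X + instance.Y:
            t = instance.coverage_costs[z]
            fh.write("cov " + z + " " + " ".join(repr(c) for c in t.costs) + "\n")
        for (x, y) in instance.finite_pairs():
            fh.write(f"pair {x} {y} {instance.matching_costs[(x, y)]!r}\n")


def read_instance(path: str) -> MatchingInstance:
    """Parse an instance written by :func:`write_instance`."""
    X: list[str] = []
    Y: list[str] = []
    tables: dict[str, CoverageCostTable] = {}
    costs: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            kind = fields[0]
            if kind == "elem":
                (X if fields[1] == "X" else Y).append(fields[2])
            elif kind == "cov":
                tables[fields[1]] = CoverageCostTable(
                    fields[1], tuple(float(v) for v in fields[2:])
                )
            elif kind == "pair":
                costs[(fields[1], fields[2])] = float(fields[3])
            else:
                raise InstanceError(f"{path}:{lineno}: unknown record {kind!r}")
    return MatchingInstance(tuple(X), tuple(Y), costs, tables)
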