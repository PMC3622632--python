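import numpy as np
import pytest

from sagescore.csm_core import CoverageCostTable, MatchingInstance
from sagescore.instance_builder import ScoringParams


@pytest.fixture
def instance_a():
    """Two reads, one segment; coverage terms reward matching both reads."""
    tables = {
        "x1": CoverageCostTable("x1", (10.0, 0.0)),
        "x2": CoverageCostTable("x2", (10.0, 0.0)),
        "y1": CoverageCostTable("y1", tuple(float((2 - i) ** 2) for i in range(3))),
    }
    return MatchingInstance(
        ("x1", "x2"),
        ("y1",),
        {("x1", "y1"): 1.0, ("x2", "y1"): 2.0},
        tables,
    )


def _instance_b(cost_x2_y2: float) -> MatchingInstance:
    tables = {z: CoverageCostTable(z, (10.0, 0.0)) for z in ("x1", "x2")}
    tables.update(
        {
            z: CoverageCostTable(z, tuple(float((1 - i) ** 2) for i in range(3)))
            for z in ("y1", "y2")
        }
    )
    return MatchingInstance(
        ("x1", "x2"),
        ("y1", "y2"),
        {("x1", "y1"): 0.0, ("x2", "y1"): 0.0, ("x2", "y2"): cost_x2_y2},
        tables,
    )


@pytest.fixture
def instance_b():
    """Coverage penalty makes splitting reads across segments optimal."""
    return _instance_b(1.0)


@pytest.fixture
def instance_b_prime():
    """Same topology, but the alternative placement is too costly."""
    return _instance_b(5.0)


@pytest.fixture
def default_params():
    return ScoringParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# independent oracles used across test modules
# ---------------------------------------------------------------------------

def max_bipartite_matching(edges):
    """Maximum-cardinality bipartite matching by augmenting paths (Kuhn's
    algorithm); independent of the package's flow machinery."""
    adj = {}
    for x, y in edges:
        adj.setdefault(x, []).append(y)
    match_y = {}

    def augment(x, seen):
        for y in adj.get(x, ()):
            if y in seen:
                continue
            seen.add(y)
            if y not in match_y or augment(match_y[y], seen):
                match_y[y] = x
                return True
        return False

    size = 0
    for x in sorted(adj):
        if augment(x, set()):
            size += 1
    return size


def random_matching(rng, instance, max_pairs=6):
    """A uniformly random subset of the instance's finite pairs."""
    from sagescore.csm_core import Matching

    pairs = instance.finite_pairs()
    if not pairs:
        return Matching(frozenset())
    k = int(rng.integers(0, min(max_pairs, len(pairs)) + 1))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    return Matching(frozenset(pairs[int(i)] for i in chosen))
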