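import numpy as np
import pytest

from agmtp.conditional_error import StagePlan
from agmtp.graphs import HypothesisGraph, derive_weights, validate_graph
from agmtp.trial_sim import second_stage_graph, two_treatment_hierarchy

# Worked example: two treatments vs control, hierarchical endpoints.
# Interim z-scores and second-stage p-values of the multi-arm trial in which
# treatment arm 2 is dropped after the interim analysis.
Z1 = np.array([1.66, 1.42, 1.90, 0.79])
Z2_CONTINUED = {0: 1.56, 2: 1.87}
Q = np.array([0.059, 1.0, 0.031, 1.0])

# Frozen reference table for the worked example: per subset (as a frozenset
# of 0-based indices) the graph weights, partial conditional errors (3 dp)
# and their sum (3 dp).  None marks hypotheses outside the subset.
CASE_TABLE = {
    frozenset({0, 1, 2, 3}): ([0.5, 0.5, 0, 0], [0.066, 0.040, 0, 0], 0.106),
    frozenset({0, 1, 2}): ([0.5, 0.5, 0, None], [0.066, 0.040, 0, None], 0.106),
    frozenset({0, 1, 3}): ([0.5, 0.5, None, 0], [0.066, 0.040, None, 0], 0.106),
    frozenset({0, 2, 3}): ([0.5, None, 0, 0.5], [0.066, None, 0, 0.009], 0.074),
    frozenset({1, 2, 3}): ([None, 0.5, 0.5, 0], [None, 0.040, 0.102, 0], 0.142),
    frozenset({0, 1}): ([0.5, 0.5, None, None], [0.066, 0.040, None, None], 0.106),
    frozenset({0, 2}): ([1.0, None, 0, None], [0.133, None, 0, None], 0.133),
    frozenset({0, 3}): ([0.5, None, None, 0.5], [0.066, None, None, 0.009], 0.074),
    frozenset({1, 2}): ([None, 0.5, 0.5, None], [None, 0.040, 0.102, None], 0.142),
    frozenset({1, 3}): ([None, 1.0, None, 0], [None, 0.088, None, 0], 0.088),
    frozenset({2, 3}): ([None, None, 0.5, 0.5], [None, None, 0.102, 0.009], 0.111),
    frozenset({0}): ([1.0, None, None, None], [0.133, None, None, None], 0.133),
    frozenset({1}): ([None, 1.0, None, None], [None, 0.088, None, None], 0.088),
    frozenset({2}): ([None, None, 1.0, None], [None, None, 0.192, None], 0.192),
    frozenset({3}): ([None, None, None, 1.0], [None, None, None, 0.024], 0.024),
}


@pytest.fixture(scope="session")
def case_graph() -> HypothesisGraph:
    return two_treatment_hierarchy()


@pytest.fixture(scope="session")
def case_graph2(case_graph) -> HypothesisGraph:
    return second_stage_graph(case_graph, 0)


@pytest.fixture(scope="session")
def case_weights(case_graph):
    return derive_weights(case_graph)


@pytest.fixture(scope="session")
def case_plan() -> StagePlan:
    return StagePlan(alpha=0.025, n=116, n1=58)


def random_graph(rng: np.random.Generator, m: int) -> HypothesisGraph:
    """A random valid hypothesis graph: node weights on a sub-simplex and
    transition rows with random total mass."""
    w = rng.dirichlet(np.ones(m)) * rng.uniform(0.3, 1.0)
    G = np.zeros((m, m))
    for i in range(m):
        row = rng.dirichlet(np.ones(m - 1)) * rng.uniform(0.0, 1.0)
        G[i, [j for j in range(m) if j != i]] = row
    return validate_graph(w, G)


def mask_of(subset, m=4) -> int:
    out = 0
    for i in subset:
        out |= 1 << i
    return out
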