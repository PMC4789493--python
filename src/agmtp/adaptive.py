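"""Adaptive graph-based closed testing (agMTP) and the gPA comparator.

After the interim analysis each intersection hypothesis ``H_J`` is retested
with an independent second-stage weighted Bonferroni test at conditional
level ``B_J`` (the sum of partial conditional errors):

    reject H_J  iff  B_J >= 1,  or some  q_j < v_{j,J} * B_J,

with strict comparison as defined for the adapted test (a measure-zero
difference from the preplanned non-strict rule for continuous statistics).
The allocation fractions ``v_{j,J}`` translate a possibly modified
second-stage weighting strategy ``w~_J`` into fractions of ``B_J``: the
adjusted level ``gamma_J`` solves

    sum_{j in J} A_{j,J}(w~_{j,J} * gamma_J) = B_J,

and ``v_{j,J} = A_{j,J}(w~_{j,J} gamma_J) / B_J``.  If the weights are
unchanged the solution is ``gamma_J = alpha`` and the adapted test uses the
preplanned conditional levels.  The adapted closure is in general not
consonant, so all ``2^m - 1`` intersections are evaluated explicitly.

The simple comparator (saMTP, equivalently the graph-based partitioning
algorithm gPA) sets the p-values of dropped hypotheses to one and runs the
preplanned sequentially rejective graph test on inverse-normal combination
p-values.  On matched inputs every gPA rejection is an agMTP rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .closed_test import sequentially_rejective
from .conditional_error import (
    ConditionalErrorFn,
    PCETable,
    StagePlan,
    inverse_normal_pvalue,
    ztest_pce,
)
from .graphs import (
    HypothesisGraph,
    SubsetWeights,
    derive_weights,
    subset_label,
    subset_members,
)

#: absolute tolerance on the conditional-error sum when solving for gamma
GAMMA_TOL = 1e-10

ALLOCATION_STRATEGIES = ("eq8", "equal_recycling", "direct")


def solve_gamma(
    z1,
    w2_J,
    B_J: float,
    plan: StagePlan,
    pce_fn: ConditionalErrorFn = ztest_pce,
) -> float:
    """Adjusted level ``gamma_J`` for modified second-stage weights.

    Solves ``sum_j A(z1_j, w~_{j,J} gamma, t) = B_J`` by bracketed bisection
    on ``gamma in [0, 1/max_j w~_{j,J}]``; the sum is continuous and
    nondecreasing and reaches at least 1 at the upper bracket, so a solution
    exists for ``B_J < 1``.  If the conditional-error function is not
    continuous (discrete test statistics) the largest bracketed ``gamma``
    with sum ``<= B_J`` is returned.
    """
    z1 = np.asarray(z1, dtype=float)
    w2 = np.asarray(w2_J, dtype=float)
    wmax = w2.max(initial=0.0)
    if wmax <= 0:
        raise ValueError("all second-stage weights are zero; gamma undefined")
    if not 0 <= B_J < 1:
        raise ValueError(f"solve_gamma requires 0 <= B_J < 1, got {B_J}")
    pos = w2 > 0

    def total(gamma: float) -> float:
        return float(
            np.sum(pce_fn(z1[pos], np.minimum(w2[pos] * gamma, 1.0), plan.t))
        )

    lo, hi = 0.0, 1.0 / wmax
    if total(hi) < B_J:  # cannot happen for exact conditional errors
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if total(mid) <= B_J:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-16 * max(1.0, hi):
            break
    # lo is the largest bracketed gamma with sum <= B_J; for continuous A
    # the sum at lo matches B_J to well below GAMMA_TOL
    return lo


def allocation_fractions(
    z1,
    w2_J,
    B_J: float,
    plan: StagePlan,
    pce_fn: ConditionalErrorFn = ztest_pce,
) -> np.ndarray:
    """Conditional error allocation fractions from modified weights.

    ``v_{j,J} = A(z1_j, w~_{j,J} gamma_J, t) / B_J`` for positive
    second-stage weights, 0 otherwise; the fractions sum to one whenever
    the defining equation for ``gamma_J`` has a solution.
    """
    z1 = np.asarray(z1, dtype=float)
    w2 = np.asarray(w2_J, dtype=float)
    if B_J <= 0:
        return np.zeros_like(w2)
    gamma = solve_gamma(z1, w2, B_J, plan, pce_fn)
    v = np.zeros_like(w2)
    pos = w2 > 0
    v[pos] = np.asarray(
        pce_fn(z1[pos], np.minimum(w2[pos] * gamma, 1.0), plan.t)
    ) / B_J
    return v


def equal_recycling_fractions(A_J, continued: Iterable[int], B_J: float) -> np.ndarray:
    """Fractions that recycle dropped hypotheses' errors equally.

    For continued ``j``: ``v_{j,J} = (A_{j,J} + sum_{dropped i} A_{i,J} /
    #continued) / B_J``; zero for dropped hypotheses.  Guarantees
    ``v_{j,J} B_J >= A_{j,J}``, with strict gain when a dropped hypothesis
    carried positive first-stage weight.
    """
    A = np.asarray(A_J, dtype=float)
    cont = np.zeros(A.shape[0], dtype=bool)
    cont[list(continued)] = True
    k = int(cont.sum())
    if k == 0 or B_J <= 0:
        raise ValueError("need a continued hypothesis and B_J > 0")
    spare = A[~cont].sum() / k
    v = np.where(cont, (A + spare) / B_J, 0.0)
    return v


def adapted_intersection_decision(q, v_J, B_J: float) -> int:
    """Second-stage decision for one intersection: 1 iff ``B_J >= 1`` or
    some ``q_j < v_{j,J} * B_J`` (strict)."""
    if B_J >= 1.0:
        return 1
    q = np.asarray(q, dtype=float)
    v = np.asarray(v_J, dtype=float)
    return int(np.any(q < v * B_J))


@dataclass(frozen=True)
class AdaptedDesign:
    """Second-stage design: adapted weights and allocation fractions.

    Holds, for every nonempty subset ``J`` of the original index set, the
    second-stage weights ``w~_J`` derived from the adapted graph, the
    adjusted level ``gamma_J`` (``nan`` for degenerate or interim-rejected
    subsets) and the allocation fractions ``v_J``.  Dropped hypotheses carry
    zero weight and zero fraction everywhere.
    """

    continued: frozenset[int]
    weights2: SubsetWeights
    gamma: Mapping[int, float]
    v: Mapping[int, np.ndarray]

    @property
    def m(self) -> int:
        return self.weights2.m

    def to_frame(self, pce: PCETable) -> pd.DataFrame:
        """Per-subset table of w~, gamma, v and B."""
        names = self.weights2.names
        rows = sorted(self.v, key=lambda s: (-bin(s).count("1"), s))
        data: dict = {"subset": [subset_label(s, self.m) for s in rows]}
        for i, name in enumerate(names):
            data[f"w2_{name}"] = [
                self.weights2.table[s][i] if s >> i & 1 else np.nan for s in rows
            ]
            data[f"v_{name}"] = [
                self.v[s][i] if s >> i & 1 else np.nan for s in rows
            ]
        data["gamma"] = [self.gamma[s] for s in rows]
        data["B"] = [pce.B[s] for s in rows]
        return pd.DataFrame(data)


def adapt_design(
    graph2: HypothesisGraph,
    pce: PCETable,
    plan: StagePlan,
    z1=None,
    strategy: str = "eq8",
    continued: Iterable[int] | None = None,
    pce_fn: ConditionalErrorFn = ztest_pce,
) -> AdaptedDesign:
    """Build the adapted second-stage design from an adapted graph.

    ``graph2`` is the second-stage graph chosen at interim (dropped
    hypotheses must carry zero node and edge weights).  ``strategy`` selects
    the allocation fractions: ``"eq8"`` (level-calibrated via ``gamma_J``,
    default, requires ``z1``), ``"equal_recycling"`` (requires ``continued``)
    or ``"direct"`` (``v = w~``; valid but not level-preserving).
    """
    if strategy not in ALLOCATION_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    weights2 = derive_weights(graph2)
    if weights2.names != pce.names:
        raise ValueError("second-stage graph and PCE table name mismatch")
    m = weights2.m
    if continued is None:
        continued = [i for i in range(m) if graph2.weights[i] > 0 or graph2.transitions[:, i].sum() > 0 or graph2.transitions[i, :].sum() > 0]
    continued = frozenset(int(i) for i in continued)
    gamma: dict[int, float] = {}
    v: dict[int, np.ndarray] = {}
    for mask in weights2.subsets():
        w2 = weights2.table[mask]
        B = pce.B[mask]
        if not np.any(w2 > 0) or B <= 0 or B >= 1:
            # degenerate subset, nothing to allocate, or rejected at interim
            gamma[mask] = float("nan")
            v[mask] = np.zeros(m)
            continue
        if strategy == "eq8":
            if z1 is None:
                raise ValueError("strategy 'eq8' requires first-stage z-scores")
            gamma[mask] = solve_gamma(z1, w2, B, plan, pce_fn)
            v[mask] = allocation_fractions(z1, w2, B, plan, pce_fn)
        elif strategy == "equal_recycling":
            gamma[mask] = float("nan")
            v[mask] = equal_recycling_fractions(
                pce.A[mask], continued & set(subset_members(mask)), B
            )
        else:  # direct
            gamma[mask] = float("nan")
            v[mask] = w2.copy()
        v[mask].setflags(write=False)
    return AdaptedDesign(continued=continued, weights2=weights2, gamma=gamma, v=v)


def agmtp_closed_test(q, pce: PCETable, design: AdaptedDesign) -> np.ndarray:
    """Adapted closed test: full closure over all ``2^m - 1`` subsets.

    The adapted procedure is in general not consonant, so no sequentially
    rejective shortcut exists; every intersection is evaluated.  Subsets
    whose second-stage weights are all zero reject iff ``B_J >= 1``.
    """
    m = design.m
    q = np.asarray(q, dtype=float)
    if q.shape != (m,):
        raise ValueError(f"expected {m} second-stage p-values, got {q.shape}")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("second-stage p-values must lie in [0, 1]")
    psi = np.ones(m, dtype=int)
    for mask in range(1, 1 << m):
        if mask not in pce.B:
            raise ValueError(f"PCE table is missing subset {mask}")
        if not adapted_intersection_decision(q, design.v[mask], pce.B[mask]):
            for i in subset_members(mask):
                psi[i] = 0
    return psi


def drop_hypotheses(graph: HypothesisGraph, dropped: Iterable[int]) -> HypothesisGraph:
    """Zero the node and edge weights of dropped hypotheses.

    The remaining sub-graph is unchanged; this is the canonical second-stage
    graph when hypotheses are dropped without otherwise modifying the
    strategy (note it does not renormalize weights among survivors).
    """
    dropped = set(int(i) for i in dropped)
    w = graph.weights.copy()
    G = graph.transitions.copy()
    for i in dropped:
        w[i] = 0.0
        G[i, :] = 0.0
        G[:, i] = 0.0
    return HypothesisGraph(names=graph.names, weights=w, transitions=G)


def samtp_gpa(
    q1,
    q,
    graph: HypothesisGraph,
    dropped: Iterable[int],
    plan: StagePlan,
) -> np.ndarray:
    """Simple adaptive comparator (saMTP / gPA).

    Combines stagewise p-values with the inverse-normal method at the
    preplanned information fraction, sets dropped hypotheses' p-values to
    one, and runs the preplanned sequentially rejective graph test.
    """
    q1 = np.asarray(q1, dtype=float)
    q = np.asarray(q, dtype=float)
    p = np.asarray(inverse_normal_pvalue(q1, q, plan.t), dtype=float)
    for i in dropped:
        p[int(i)] = 1.0
    return sequentially_rejective(p, graph, plan.alpha)


def stagewise_pvalues(z) -> np.ndarray:
    """One-sided stagewise p-values ``1 - Phi(z)`` from stage z-scores."""
    return norm.sf(np.asarray(z, dtype=float))
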