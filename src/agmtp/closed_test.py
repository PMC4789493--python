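"""Fixed-sample closed weighted-Bonferroni test and its graph shortcut.

The closed test rejects elementary hypothesis ``H_i`` iff every intersection
``H_J`` with ``i in J`` is rejected by its local weighted Bonferroni test
(some ``p_j <= w_{j,J} * alpha``).  For weights generated by a hypothesis
graph this closure is equivalent to the sequentially rejective shortcut:
reject any hypothesis whose p-value meets its current local level, pass the
level along the graph edges, repeat.
"""

from __future__ import annotations

import numpy as np

from .graphs import (
    HypothesisGraph,
    SubsetWeights,
    derive_weights,
    remove_node,
    subset_members,
)


def _check_pvalues(p, m: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (m,):
        raise ValueError(f"expected {m} p-values, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_alpha(alpha: float) -> float:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(alpha)


def intersection_decision(p, w_J, alpha: float) -> int:
    """Weighted Bonferroni decision for one intersection hypothesis.

    Returns 1 iff ``p_j <= w_{j,J} * alpha`` for some ``j`` with positive
    weight (non-strict comparison; zero-weight entries can never trigger).
    """
    alpha = _check_alpha(alpha)
    w = np.asarray(w_J, dtype=float)
    p = _check_pvalues(p, w.shape[0])
    pos = w > 0
    return int(np.any(p[pos] <= w[pos] * alpha))


def closed_test(p, weights: SubsetWeights, alpha: float) -> np.ndarray:
    """Full closure: ``psi_i = min_{J: i in J} phi_J(p, alpha)``."""
    alpha = _check_alpha(alpha)
    m = weights.m
    p = _check_pvalues(p, m)
    expected = (1 << m) - 1
    subsets = weights.subsets()
    if len(subsets) != expected:
        raise ValueError(
            f"weight table has {len(subsets)} subsets, expected {expected}"
        )
    psi = np.ones(m, dtype=int)
    for mask in subsets:
        if intersection_decision(p, weights.table[mask], alpha):
            continue
        for i in subset_members(mask):
            psi[i] = 0
    return psi


def sequentially_rejective(p, graph: HypothesisGraph, alpha: float) -> np.ndarray:
    """Graph shortcut of the closed test.

    Repeatedly rejects every hypothesis whose p-value is at or below its
    current local level ``w_i * alpha``, removing rejected nodes one at a
    time (order-invariant) and reallocating their levels, until no further
    rejection is possible.  Identical to :func:`closed_test` on the
    graph-derived weight table.
    """
    alpha = _check_alpha(alpha)
    m = graph.m
    p = _check_pvalues(p, m)
    w = graph.weights.copy()
    G = graph.transitions.copy()
    active = np.ones(m, dtype=bool)
    psi = np.zeros(m, dtype=int)
    while True:
        hit = active & (w > 0) & (p <= w * alpha)
        if not hit.any():
            return psi
        for i in np.where(hit)[0]:
            psi[i] = 1
            if active.sum() == 1:
                active[i] = False
                break
            w, G, active = remove_node(w, G, int(i), active)


def graph_test(p, graph: HypothesisGraph, alpha: float) -> np.ndarray:
    """Convenience: derive weights and run the full closed test."""
    return closed_test(p, derive_weights(graph), alpha)
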