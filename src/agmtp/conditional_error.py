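"""Partial conditional error rates for two-stage adaptive designs.

At an unblinded interim analysis the partial conditional error rate
``A_{j,J}(w_{j,J} alpha)`` is the probability, given the first-stage data,
that the preplanned test of ``H_j`` inside intersection ``H_J`` would reject.
For a one-sided z-test with information fraction ``t = n1 / n``,

    A = P(Z_j > c_{1-level} | z1_j)
      = 1 - Phi((c_{1-level} - z1_j * sqrt(t)) / sqrt(1 - t)),

where ``Z_j = sqrt(t) z1_j + sqrt(1-t) z2_j`` is the full-data statistic.
``B_J`` sums the partial conditional errors over ``J`` and acts as the
conditional level available to any independent second-stage test of ``H_J``;
it may exceed 1, in which case ``H_J`` is rejected at interim already.

The same machinery covers preplanned inverse-normal combination tests: the
critical boundary for the second-stage p-value (:func:`combination_boundary`)
coincides with the z-test conditional error when the stage weights are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .graphs import SubsetWeights, subset_label, subset_members

#: levels below this are treated as exactly 0 to avoid quantile overflow
LEVEL_FLOOR = 1e-15

#: signature of a marginal conditional-error function: (z1, level, t) -> prob
ConditionalErrorFn = Callable[[np.ndarray, np.ndarray, float], np.ndarray]


@dataclass(frozen=True)
class StagePlan:
    """Preplanned two-stage design: level and per-group sample sizes.

    ``alpha`` is the one-sided familywise level, ``n`` the preplanned total
    and ``n1`` the first-stage per-group sample size (subjects); the
    information fraction is ``t = n1 / n``.
    """

    alpha: float
    n: float
    n1: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.n1 < self.n:
            raise ValueError(
                f"need 0 < n1 < n, got n1={self.n1}, n={self.n}"
            )

    @property
    def t(self) -> float:
        """Information fraction ``n1 / n``."""
        return self.n1 / self.n


def _check_t(t: float) -> float:
    if not 0 < t < 1:
        raise ValueError(f"information fraction must be in (0, 1), got {t}")
    return float(t)


def ztest_pce(z1, level, t: float):
    """Partial conditional error of the preplanned one-sided z-test.

    Vectorized over ``z1`` and ``level``; returns 0 at level 0 and 1 at
    level 1 (the continuous limits).
    """
    t = _check_t(t)
    z1 = np.asarray(z1, dtype=float)
    level = np.asarray(level, dtype=float)
    if np.any(level < 0) or np.any(level > 1):
        raise ValueError("level must lie in [0, 1]")
    lo = level <= LEVEL_FLOOR
    hi = level >= 1.0
    safe = np.where(lo | hi, 0.5, level)
    c = norm.isf(safe)
    out = norm.sf((c - z1 * np.sqrt(t)) / np.sqrt(1.0 - t))
    out = np.where(lo, 0.0, np.where(hi, 1.0, out))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PCETable:
    """Partial conditional errors ``A_{j,J}`` and sums ``B_J`` per subset."""

    names: tuple[str, ...]
    A: Mapping[int, np.ndarray]
    B: Mapping[int, float]

    @property
    def m(self) -> int:
        return len(self.names)

    def subsets(self) -> list[int]:
        return sorted(self.A)

    def min_B(self, include: int, exclude: int = 0) -> float:
        """Smallest ``B_J`` over subsets containing ``include`` members and
        disjoint from ``exclude`` (both bitmasks)."""
        vals = [
            b
            for mask, b in self.B.items()
            if (mask & include) == include and not mask & exclude
        ]
        if not vals:
            raise ValueError("no subset matches the constraints")
        return min(vals)

    def to_frame(self, weights: SubsetWeights | None = None) -> pd.DataFrame:
        """Per-subset table of weights (optional), ``A`` values and ``B``."""
        rows = sorted(self.A, key=lambda s: (-bin(s).count("1"), s))
        data: dict = {"subset": [subset_label(s, self.m) for s in rows]}
        for i, name in enumerate(self.names):
            if weights is not None:
                data[f"w_{name}"] = [
                    weights.table[s][i] if s >> i & 1 else np.nan for s in rows
                ]
            data[f"A_{name}"] = [
                self.A[s][i] if s >> i & 1 else np.nan for s in rows
            ]
        data["B"] = [self.B[s] for s in rows]
        return pd.DataFrame(data)


def pce_table(
    z1,
    weights: SubsetWeights,
    plan: StagePlan,
    pce_fn: ConditionalErrorFn = ztest_pce,
) -> PCETable:
    """Evaluate ``A_{j,J} = A(z1_j, w_{j,J} alpha, t)`` for every subset.

    ``pce_fn`` defaults to the z-test conditional error; any monotone
    marginal conditional-error function with the same signature may be
    supplied (e.g. for preplanned inverse-normal combination tests).
    """
    m = weights.m
    z1 = np.asarray(z1, dtype=float)
    if z1.shape != (m,):
        raise ValueError(f"expected {m} first-stage z-scores, got {z1.shape}")
    if not np.all(np.isfinite(z1)):
        raise ValueError("first-stage z-scores must be finite")
    A: dict[int, np.ndarray] = {}
    B: dict[int, float] = {}
    for mask in weights.subsets():
        w = weights.table[mask]
        a = np.zeros(m)
        for j in subset_members(mask):
            if w[j] > 0:
                a[j] = pce_fn(z1[j], w[j] * plan.alpha, plan.t)
        a.setflags(write=False)
        A[mask] = a
        B[mask] = float(a.sum())
    return PCETable(names=weights.names, A=A, B=B)


def inverse_normal_pvalue(q1, q2, t: float):
    """Inverse-normal combination of stagewise p-values.

    ``p = 1 - Phi(sqrt(t) c_{1-q1} + sqrt(1-t) c_{1-q2})`` with the limit
    conventions: any input exactly 0 gives 0; otherwise any input exactly 1
    gives 1.  Vectorized.
    """
    t = _check_t(t)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    if np.any((q1 < 0) | (q1 > 1)) or np.any((q2 < 0) | (q2 > 1)):
        raise ValueError("stagewise p-values must lie in [0, 1]")
    zero = (q1 == 0) | (q2 == 0)
    one = ~zero & ((q1 == 1) | (q2 == 1))
    s1 = np.where(zero | one, 0.5, q1)
    s2 = np.where(zero | one, 0.5, q2)
    out = norm.sf(np.sqrt(t) * norm.isf(s1) + np.sqrt(1.0 - t) * norm.isf(s2))
    out = np.where(zero, 0.0, np.where(one, 1.0, out))
    return out if out.ndim else float(out)


def combination_boundary(q1, level, plan: StagePlan):
    """Critical value for the second-stage p-value of an inverse-normal test.

    Returns the largest ``q`` with ``inverse_normal_pvalue(q1, q, t) <=
    level``:

        1 - Phi( sqrt(n/(n-n1)) c_{1-level} - sqrt(n1/(n-n1)) c_{1-q1} ).

    This is the partial conditional error of a preplanned inverse-normal
    combination test; for ``n1 = n/2`` it coincides with
    ``ztest_pce(c_{1-q1}, level, 1/2)``.
    """
    q1 = np.asarray(q1, dtype=float)
    level = np.asarray(level, dtype=float)
    if np.any((q1 < 0) | (q1 > 1)):
        raise ValueError("first-stage p-value must lie in [0, 1]")
    if np.any((level < 0) | (level > 1)):
        raise ValueError("level must lie in [0, 1]")
    n, n1 = plan.n, plan.n1
    lo = level <= LEVEL_FLOOR
    safe = np.where(lo, 0.5, level)
    out = norm.sf(
        np.sqrt(n / (n - n1)) * norm.isf(safe)
        - np.sqrt(n1 / (n - n1)) * norm.isf(np.clip(q1, LEVEL_FLOOR, 1 - 1e-16))
    )
    out = np.where(lo, 0.0, out)
    return out if out.ndim else float(out)


def inverse_normal_pce(plan: StagePlan) -> ConditionalErrorFn:
    """Conditional-error function of a preplanned inverse-normal test.

    Adapts :func:`combination_boundary` to the ``(z1, level, t)`` signature
    used by :func:`pce_table`: the first-stage z-score is translated to its
    stagewise p-value ``q1 = 1 - Phi(z1)``.
    """

    def fn(z1, level, t):
        del t  # stage split is fixed by the plan
        return combination_boundary(norm.sf(np.asarray(z1, dtype=float)), level, plan)

    return fn
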