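"""Synthetic two-stage trial generator and Monte-Carlo engine.

Emulates a three-armed trial (two treatments vs a common control) with a
primary and a secondary endpoint per treatment plus a toxicity marker per
treatment arm.  The six standardized treatment-control statistics
``(z1, z2, z3, z4, t1, t2)`` are multivariate normal with mean

    sqrt(n_s / 2) * (d1/s1, d2/s2, d1/s1, d2/s2, 0, kappa/s_t)

at per-group stage sample size ``n_s`` and a correlation matrix in which
statistics sharing an endpoint correlate at 1/2 (balanced groups, common
control), endpoints within an arm at ``rho``, and toxicity with its arm's
primary endpoint at ``zeta`` (products for the crossed entries).
Hypotheses map to components as H1/H3 = treatment 1 primary/secondary,
H2/H4 = treatment 2.

An interim analysis after ``n1`` of ``n`` per-group subjects applies one of
four adaptation rules (PP: continue as planned; SB: keep the arm with the
larger interim primary z; FF: keep an arm chosen by a fair coin; SF: drop
any arm whose toxicity score exceeds a threshold ``s``).  Continued trials
are evaluated with the preplanned graph test (nothing dropped), the adaptive
graph-based closed test (agMTP, z-test conditional errors) or the simple
inverse-normal comparator (gPA).  Stage-one and stage-two score vectors are
independent draws; full-data statistics are the sqrt(t)-weighted
combination, which is distributionally equivalent to patientwise simulation
for z-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .closed_test import sequentially_rejective
from .conditional_error import StagePlan, pce_table
from .graphs import HypothesisGraph, SubsetWeights, derive_weights, validate_graph
from .adaptive import adapt_design, agmtp_closed_test, samtp_gpa

RULES = ("PP", "SB", "FF", "SF")
PROCEDURES = ("gMCP", "agMTP", "gPA")

#: component indices: z-statistics of H1..H4, then toxicity of arms 1, 2
Z_COMPONENTS = (0, 1, 2, 3)
TOX_COMPONENTS = (4, 5)
#: hypotheses belonging to each treatment arm (primary, secondary)
ARM_HYPOTHESES = ((0, 2), (1, 3))


def two_treatment_hierarchy(names=("H1", "H2", "H3", "H4")) -> HypothesisGraph:
    """Preplanned graph: symmetric in the two treatments, primary endpoints
    split alpha equally, each secondary gated behind its primary, and a
    fully rejected arm passes its level to the other arm's primary."""
    w = [0.5, 0.5, 0.0, 0.0]
    G = np.zeros((4, 4))
    G[0, 2] = 1.0  # H1 -> H3
    G[1, 3] = 1.0  # H2 -> H4
    G[2, 1] = 1.0  # H3 -> H2
    G[3, 0] = 1.0  # H4 -> H1
    return validate_graph(w, G, names)


def second_stage_graph(
    graph: HypothesisGraph, continued_arm: int
) -> HypothesisGraph:
    """Adapted graph after dropping one arm: the dropped arm's nodes and
    edges are zeroed and the continued arm keeps its full hierarchy
    (primary weight 1, primary -> secondary edge 1)."""
    cp, cs = ARM_HYPOTHESES[continued_arm]
    w = np.zeros(4)
    w[cp] = 1.0
    G = np.zeros((4, 4))
    G[cp, cs] = 1.0
    return HypothesisGraph(names=graph.names, weights=w, transitions=G)


@dataclass(frozen=True)
class TrialScenario:
    """Simulation scenario: effects, dependence, sizes and adaptation rule.

    Effect sizes are in outcome units; ``s`` is the toxicity drop threshold
    on the z scale.  ``n2_reallocated`` is the per-group second-stage size
    of the continued groups after an arm is dropped with reallocation.
    """

    delta1: float = 0.0
    delta2: float = 0.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    sigma_t: float = 1.0
    rho: float = 0.3
    zeta: float = 0.5
    kappa: float = 0.0
    s: float = 1.645
    n: int = 116
    n1: int = 58
    rule: str = "PP"
    reallocate: bool = False
    n2_reallocated: int = 87
    alpha: float = 0.025
    graph: HypothesisGraph = field(default_factory=two_treatment_hierarchy)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if not 0 < self.n1 < self.n:
            raise ValueError("need 0 < n1 < n")
        np.linalg.cholesky(self.correlation())  # fail fast on non-PSD input

    @property
    def plan(self) -> StagePlan:
        return StagePlan(alpha=self.alpha, n=self.n, n1=self.n1)

    def correlation(self) -> np.ndarray:
        r, z = self.rho, self.zeta
        return np.array(
            [
                [1, 0.5, r, r / 2, z, z / 2],
                [0.5, 1, r / 2, r, z / 2, z],
                [r, r / 2, 1, 0.5, z * r, z * r / 2],
                [r / 2, r, 0.5, 1, z * r / 2, z * r],
                [z, z / 2, z * r, z * r / 2, 1, 0.5],
                [z / 2, z, z * r / 2, z * r, 0.5, 1],
            ]
        )

    def mean(self, n_s: float) -> np.ndarray:
        scale = np.sqrt(n_s / 2.0)
        return scale * np.array(
            [
                self.delta1 / self.sigma1,
                self.delta2 / self.sigma2,
                self.delta1 / self.sigma1,
                self.delta2 / self.sigma2,
                0.0,
                self.kappa / self.sigma_t,
            ]
        )


def simulate_stage_scores(
    scenario: TrialScenario,
    n_s: float,
    rng: np.random.Generator,
    size: int = 1,
    active: Iterable[int] | None = None,
) -> np.ndarray:
    """Draw ``size`` score vectors at per-group stage sample size ``n_s``.

    ``active`` restricts the draw to a subset of the six components
    (indices into ``(z1, z2, z3, z4, t1, t2)``).
    """
    if n_s <= 0:
        raise ValueError("stage sample size must be positive")
    idx = list(range(6)) if active is None else sorted(int(i) for i in active)
    corr = scenario.correlation()[np.ix_(idx, idx)]
    chol = np.linalg.cholesky(corr)
    raw = rng.standard_normal((size, len(idx)))
    return scenario.mean(n_s)[idx] + raw @ chol.T


def apply_rule(
    scenario: TrialScenario,
    interim_scores: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Interim decision: which arms are dropped, per replicate.

    Returns a boolean array of shape ``(reps, 2)``.  SB keeps the arm with
    the larger interim primary z (a tie drops arm 2); FF flips a fair coin
    independent of the data; SF drops every arm whose toxicity score
    exceeds ``s`` (possibly both or neither).
    """
    scores = np.atleast_2d(np.asarray(interim_scores, dtype=float))
    reps = scores.shape[0]
    dropped = np.zeros((reps, 2), dtype=bool)
    if scenario.rule == "PP":
        return dropped
    if scenario.rule == "SB":
        drop1 = scores[:, 0] < scores[:, 1]
        dropped[:, 0] = drop1
        dropped[:, 1] = ~drop1
    elif scenario.rule == "FF":
        drop1 = rng.random(reps) < 0.5
        dropped[:, 0] = drop1
        dropped[:, 1] = ~drop1
    elif scenario.rule == "SF":
        dropped[:, 0] = scores[:, 4] > scenario.s
        dropped[:, 1] = scores[:, 5] > scenario.s
    return dropped


def second_stage_size(scenario: TrialScenario, any_dropped: bool) -> int:
    """Per-group second-stage size of the continued treatment groups."""
    if any_dropped and scenario.reallocate:
        return scenario.n2_reallocated
    return scenario.n - scenario.n1


# ---------------------------------------------------------------------------
# vectorized closure machinery

def _weight_matrix(weights: SubsetWeights) -> tuple[np.ndarray, np.ndarray]:
    """Stack the subset weight table into (S, m) arrays of weights and
    membership, ordered by bitmask."""
    masks = weights.subsets()
    m = weights.m
    W = np.stack([weights.table[s] for s in masks])
    member = np.array([[bool(s >> i & 1) for i in range(m)] for s in masks])
    return W, member


def closure_batch(p: np.ndarray, weights: SubsetWeights, alpha: float) -> np.ndarray:
    """Closed weighted-Bonferroni test applied to a batch of p-vectors.

    ``p`` has shape (reps, m); returns boolean rejections of the same shape.
    """
    W, member = _weight_matrix(weights)
    rej = (
        ((p[:, None, :] <= W[None] * alpha) & (W > 0)[None]).any(axis=2)
    )  # (reps, S)
    return np.stack(
        [rej[:, member[:, i]].all(axis=1) for i in range(weights.m)], axis=1
    )


def _pce_batch(
    z1: np.ndarray, W: np.ndarray, alpha: float, t: float
) -> np.ndarray:
    """Partial conditional errors for a batch: (reps, S, m) from z-scores
    (reps, m) and a subset weight matrix (S, m)."""
    reps, m = z1.shape
    S = W.shape[0]
    A = np.zeros((reps, S, m))
    sqrt_t, sqrt_u = np.sqrt(t), np.sqrt(1.0 - t)
    cache: dict[tuple[int, float], np.ndarray] = {}
    for s in range(S):
        for j in range(m):
            w = W[s, j]
            if w <= 0:
                continue
            key = (j, w)
            if key not in cache:
                c = norm.isf(w * alpha)
                cache[key] = norm.sf((c - z1[:, j] * sqrt_t) / sqrt_u)
            A[:, s, j] = cache[key]
    return A


def _gamma_batch(
    z1: np.ndarray, w2: np.ndarray, B: np.ndarray, t: float, iters: int = 80
) -> np.ndarray:
    """Vectorized bisection for gamma_J over replicates (general w~ with
    several positive weights)."""
    pos = np.where(w2 > 0)[0]
    sqrt_t, sqrt_u = np.sqrt(t), np.sqrt(1.0 - t)
    lo = np.zeros_like(B)
    hi = np.full_like(B, 1.0 / w2[pos].max())

    def total(g: np.ndarray) -> np.ndarray:
        out = np.zeros_like(g)
        for j in pos:
            lvl = np.clip(w2[j] * g, 1e-15, 1.0)
            out += norm.sf((norm.isf(lvl) - z1[:, j] * sqrt_t) / sqrt_u)
        return out

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = total(mid) <= B
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return lo


def agmtp_batch(
    z1: np.ndarray,
    q: np.ndarray,
    weights1: SubsetWeights,
    graph2: HypothesisGraph,
    plan: StagePlan,
) -> np.ndarray:
    """Adaptive closed test for a batch of trials sharing one adapted graph.

    ``z1``: interim z-scores (reps, m); ``q``: second-stage p-values
    (reps, m) with 1 for hypotheses lacking second-stage data.  Uses z-test
    conditional errors and level-calibrated allocation fractions; subsets
    with a single positive second-stage weight shortcut to ``q_j < B_J``.
    """
    W1, member = _weight_matrix(weights1)
    weights2 = derive_weights(graph2)
    W2, _ = _weight_matrix(weights2)
    t = plan.t
    A = _pce_batch(z1, W1, plan.alpha, t)
    B = A.sum(axis=2)  # (reps, S)
    S, m = W1.shape
    dec = np.zeros(B.shape, dtype=bool)
    sqrt_t, sqrt_u = np.sqrt(t), np.sqrt(1.0 - t)
    for s in range(S):
        w2 = W2[s]
        pos = np.where(w2 > 0)[0]
        early = B[:, s] >= 1.0
        if len(pos) == 0:
            dec[:, s] = early
        elif len(pos) == 1:
            # single positive weight: gamma solves A_j(gamma w2_j) = B, so
            # v_j B = B exactly
            dec[:, s] = early | (q[:, pos[0]] < B[:, s])
        else:
            gamma = _gamma_batch(z1, w2, np.where(early, 0.5, B[:, s]), t)
            hit = np.zeros(B.shape[0], dtype=bool)
            for j in pos:
                lvl = np.clip(w2[j] * gamma, 1e-15, 1.0)
                vB = norm.sf((norm.isf(lvl) - z1[:, j] * sqrt_t) / sqrt_u)
                hit |= q[:, j] < vB
            dec[:, s] = early | hit
    return np.stack(
        [dec[:, member[:, i]].all(axis=1) for i in range(m)], axis=1
    )


# ---------------------------------------------------------------------------
# trial engine

def _draw_trial_data(
    scenario: TrialScenario, rng: np.random.Generator, reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized stage draws shared by all procedures: interim scores at
    ``n1`` and zero-mean second-stage scores (the mean is added later at
    the stage size actually used)."""
    chol = np.linalg.cholesky(scenario.correlation())
    stage1 = scenario.mean(scenario.n1) + rng.standard_normal((reps, 6)) @ chol.T
    stage2_raw = rng.standard_normal((reps, 6)) @ chol.T
    return stage1, stage2_raw


def simulate_trials(
    scenario: TrialScenario,
    procedure: str,
    reps: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``reps`` trials; returns (rejections (reps, 4), dropped (reps, 2)).

    With the same scenario, seed and replication count all procedures see
    identical stagewise data, so per-replicate comparisons are meaningful.
    """
    if procedure not in PROCEDURES:
        raise ValueError(f"unknown procedure {procedure!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    stage1, stage2_raw = _draw_trial_data(scenario, rng, reps)
    dropped = apply_rule(scenario, stage1, rng)
    if procedure == "gMCP":
        dropped = np.zeros_like(dropped)  # preplanned test ignores the rule
    plan = scenario.plan
    t = plan.t
    weights1 = derive_weights(scenario.graph)
    rej = np.zeros((reps, 4), dtype=bool)

    none_dropped = ~dropped.any(axis=1)
    if none_dropped.any():
        z2 = stage2_raw[none_dropped, :4] + scenario.mean(scenario.n - scenario.n1)[:4]
        z_full = np.sqrt(t) * stage1[none_dropped, :4] + np.sqrt(1 - t) * z2
        rej[none_dropped] = closure_batch(norm.sf(z_full), weights1, plan.alpha)

    for arm in (0, 1):  # the dropped arm
        sel = dropped[:, arm] & ~dropped[:, 1 - arm]
        if not sel.any():
            continue
        cont = 1 - arm
        n2 = second_stage_size(scenario, any_dropped=True)
        z2 = stage2_raw[sel, :4] + scenario.mean(n2)[:4]
        q = norm.sf(z2)
        q[:, list(ARM_HYPOTHESES[arm])] = 1.0
        if procedure == "agMTP":
            g2 = second_stage_graph(scenario.graph, cont)
            rej[sel] = agmtp_batch(stage1[sel, :4], q, weights1, g2, plan)
        else:  # gPA
            p = norm.sf(np.sqrt(t) * stage1[sel, :4] + np.sqrt(1 - t) * z2)
            p[:, list(ARM_HYPOTHESES[arm])] = 1.0
            rej[sel] = closure_batch(p, weights1, plan.alpha)
    # both arms dropped: no second-stage data, no rejections (rej stays 0)
    return rej, dropped


def run_trial(
    scenario: TrialScenario,
    procedure: str,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one trial through the generic (non-vectorized) machinery.

    Consumes the same random draws as ``simulate_trials(..., reps=1)``, so
    the two paths can be cross-checked replicate by replicate.
    """
    if procedure not in PROCEDURES:
        raise ValueError(f"unknown procedure {procedure!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    stage1, stage2_raw = _draw_trial_data(scenario, rng, 1)
    dropped = apply_rule(scenario, stage1, rng)[0]
    if procedure == "gMCP":
        dropped = np.zeros_like(dropped)
    plan = scenario.plan
    t = plan.t
    graph = scenario.graph
    z1 = stage1[0, :4]

    if not dropped.any():
        z2 = stage2_raw[0, :4] + scenario.mean(scenario.n - scenario.n1)[:4]
        z_full = np.sqrt(t) * z1 + np.sqrt(1 - t) * z2
        return sequentially_rejective(norm.sf(z_full), graph, plan.alpha), dropped
    if dropped.all():
        return np.zeros(4, dtype=int), dropped

    arm = int(np.where(dropped)[0][0])
    cont = 1 - arm
    n2 = second_stage_size(scenario, any_dropped=True)
    z2 = stage2_raw[0, :4] + scenario.mean(n2)[:4]
    q = norm.sf(z2)
    dropped_hyps = list(ARM_HYPOTHESES[arm])
    q[dropped_hyps] = 1.0
    if procedure == "agMTP":
        weights1 = derive_weights(graph)
        pce = pce_table(z1, weights1, plan)
        design = adapt_design(
            second_stage_graph(graph, cont),
            pce,
            plan,
            z1=z1,
            continued=ARM_HYPOTHESES[cont],
        )
        return agmtp_closed_test(q, pce, design), dropped
    return samtp_gpa(norm.sf(z1), q, graph, dropped_hyps, plan), dropped


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics, in percent."""

    pi: float  # probability of at least one rejection
    pi_i: np.ndarray  # per-hypothesis rejection probabilities
    eta_i: np.ndarray  # per-arm drop probabilities
    reps: int
    se_pi: float  # binomial MC standard error of pi, percentage points

    def as_dict(self) -> dict:
        d = {"pi": self.pi}
        d.update({f"pi_{i + 1}": v for i, v in enumerate(self.pi_i)})
        d.update({f"eta_{i + 1}": v for i, v in enumerate(self.eta_i)})
        d.update({"reps": self.reps, "se": self.se_pi})
        return d


def operating_characteristics(
    scenario: TrialScenario,
    procedure: str,
    reps: int,
    seed: int | np.random.Generator,
) -> OperatingCharacteristics:
    """Estimate pi, pi_i and eta_i by Monte Carlo."""
    rej, dropped = simulate_trials(scenario, procedure, reps, seed)
    any_rej = rej.any(axis=1).mean()
    return OperatingCharacteristics(
        pi=100.0 * any_rej,
        pi_i=100.0 * rej.mean(axis=0),
        eta_i=100.0 * dropped.mean(axis=0),
        reps=reps,
        se_pi=100.0 * float(np.sqrt(any_rej * (1 - any_rej) / reps)),
    )


def primary_power(
    n: int,
    base: np.ndarray,
    scenario: TrialScenario,
) -> float:
    """Probability of rejecting a primary hypothesis (H1 or H2) with the
    fixed-sample graph test at per-group size ``n``, using common random
    numbers ``base`` (zero-mean correlated scores, shape (reps, 4))."""
    z = base + scenario.mean(n)[:4]
    rej = closure_batch(norm.sf(z), derive_weights(scenario.graph), scenario.alpha)
    return float(rej[:, :2].any(axis=1).mean())


def find_sample_size(
    target: float,
    delta: float = 0.4,
    sigma: float = 1.0,
    rho: float = 0.3,
    zeta: float = 0.5,
    alpha: float = 0.025,
    divisor: int = 4,
    reps: int = 100_000,
    seed: int = 0,
    n_max: int = 1024,
    return_curve: bool = False,
):
    """Smallest per-group ``n`` divisible by ``divisor`` with at least
    ``target`` simulated power to reject a primary hypothesis.

    One zero-mean score matrix is drawn and shifted by the candidate's mean,
    so the simulated power curve is exactly nondecreasing in ``n`` and plain
    bisection over the divisible candidates applies.
    """
    if not 0 < target < 1:
        raise ValueError("target power must be in (0, 1)")
    scen = TrialScenario(
        delta1=delta, delta2=delta, sigma1=sigma, sigma2=sigma,
        rho=rho, zeta=zeta, alpha=alpha, n=8, n1=4,
    )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(scen.correlation()[:4, :4])
    base = rng.standard_normal((reps, 4)) @ chol.T
    curve: dict[int, float] = {}

    def power(n: int) -> float:
        if n not in curve:
            curve[n] = primary_power(n, base, scen)
        return curve[n]

    hi = divisor
    while power(hi) < target:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power not reached by n = {n_max}")
    lo = hi // 2 if hi > divisor else 0
    # invariant: power(lo) < target <= power(hi), candidates are multiples
    while hi - lo > divisor:
        mid = divisor * ((lo + hi) // (2 * divisor))
        if power(mid) >= target:
            hi = mid
        else:
            lo = mid
    return (hi, dict(sorted(curve.items()))) if return_curve else hi


def make_scenario(**kwargs) -> TrialScenario:
    """Scenario factory accepting plain keyword overrides (CLI/YAML use)."""
    return TrialScenario(**kwargs)
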