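# Methods

## Graphical multiple testing procedures

A testing strategy for m one-sided elementary hypotheses is encoded by node
weights w_I = (w_{1,I}, …, w_{m,I}) with w_i ≥ 0, Σw_i ≤ 1, and a
transition matrix G_I with g_ij ≥ 0, g_ii = 0 and row sums at most 1.
Removing a node ℓ reallocates its weight along its outgoing edges,
w_j ← w_j + w_ℓ g_ℓj, and rewires the remaining edges by

    g'_jk = (g_jk + g_jℓ g_ℓk) / (1 − g_jℓ g_ℓj),

set to 0 when g_jℓ g_ℓj = 1 (a two-cycle carrying all weight; there is no
mass left to route through the removed node).  Applying the removal to all
indices outside a subset J yields the weighted-Bonferroni weights w_J of
the intersection hypothesis H_J; the result is independent of the removal
order, which the test suite verifies against explicitly shuffled removal
sequences.  The closed test built from these intersection tests is
equivalent to the familiar sequentially rejective shortcut (reject at
p_i ≤ w_i α, propagate, repeat), and both paths are implemented and
property-tested against each other.

Subsets are encoded as bitmasks over positions 0…m−1.  Full enumeration is
exponential, so the package enforces m ≤ 16.  Simplex constraints use an
absolute tolerance of 1e-9 (values within tolerance are clamped); derived
weights below 1e-12 are snapped to zero so that "zero weight" is exact.

## Partial conditional error rates

For a preplanned one-sided z-test with information fraction t = n⁽¹⁾/n, the
partial conditional error of H_j inside H_J given the interim z-score is

    A_{j,J}(u) = 1 − Φ( (c_{1−u} − z_j⁽¹⁾ √t) / √(1−t) ),   u = w_{j,J} α,

a continuous, strictly increasing function of both the level u and the
z-score, with A(0) = 0 and A(1) = 1.  Its defining property — the
unconditional expectation under the null equals the level (a martingale
property) — is tested by simulation.  B_J = Σ_{j∈J} A_{j,J} is *not* a
probability: it may exceed 1, in which case H_J is rejected at the interim
analysis.  Levels below 1e-15 are treated as exactly 0 to avoid quantile
overflow; all computations are double precision, and comparisons with the
worked-example table are made at the 3 decimals to which it is printed.

For a preplanned inverse-normal combination test the conditional error of
the elementary test is the critical boundary for the second-stage p-value,

    1 − Φ( √(n/(n−n⁽¹⁾)) c_{1−u} − √(n⁽¹⁾/(n−n⁽¹⁾)) c_{1−q̃} ),

exposed as `combination_boundary` and, adapted to the (z1, level, t)
signature, as `inverse_normal_pce`.  For equal stage sizes this coincides
with the z-test conditional error — an identity asserted numerically over a
grid, since the two routes are implemented independently.

## The adaptive closed test

At the interim analysis any second-stage test of H_J with conditional level
min(B_J, 1) preserves the error rate, provided its statistic uses only
second-stage observations.  The implemented family is the second-stage
weighted Bonferroni test: reject H_J iff B_J ≥ 1 or q_j < v_{j,J} B_J for
some j.  Three allocation-fraction strategies are provided:

- **eq8** (default): v_{j,J} = A_{j,J}(w̃_{j,J} γ_J)/B_J with γ_J solving
  Σ_j A_{j,J}(w̃_{j,J} γ_J) = B_J.  The solver is a bracketed bisection on
  γ ∈ [0, 1/max_j w̃_{j,J}]: the sum is continuous and nondecreasing, 0 at
  the lower and ≥ 1 at the upper bracket, so a solution exists whenever
  B_J < 1; 200 bisection steps drive the bracket far below the 1e-10
  tolerance on the sum.  For discontinuous (discrete-statistic) conditional
  errors the bisection returns the largest bracketed γ with sum ≤ B_J,
  which keeps the test conservative.  If the weights are unchanged the
  solution is γ_J = α exactly; if continued weights are kept and a
  positively weighted hypothesis is dropped, γ_J ≥ α (both are tested).
- **equal_recycling**: v_{j,J} = (A_{j,J} + Σ_{dropped i} A_{i,J}/|J∩I′|)/B_J
  for continued j.  Simple, and sufficient for the dominance result below.
- **direct**: v = w̃.  Valid for FWER control but not level-preserving —
  the conditional levels v_{j,J}B_J then differ from A_{j,J}(w_{j,J}α) even
  without any adaptation; included for completeness.

The comparison q_j < v_{j,J} B_J is strict, whereas the preplanned test
uses p_j ≤ w_{j,J} α; for continuous statistics the difference is a
measure-zero event, and each is implemented as defined.  The adapted
closure is in general **not consonant** (an intersection may be rejected
with no elementary rejection), so the adaptive test always evaluates all
2^m − 1 intersections; degenerate subsets whose second-stage weights are
all zero reject iff B_J ≥ 1.  The per-subset decisions therefore cannot be
shortcut, which bounds practical use to moderate m — the same limit as the
weight enumeration.

The simple comparator (saMTP/gPA) applies the preplanned sequentially
rejective graph test to inverse-normal combination p-values with dropped
hypotheses' p-values set to one.  On matched inputs (same stagewise data,
second-stage weights equal to the preplanned weights zeroed on dropped
hypotheses, conditional errors of the inverse-normal form) every gPA
rejection is an agMTP rejection; the test suite checks this replicate by
replicate and confirms that the improvement is strict in a nonvanishing
fraction of trials.

A known blemish of the worked example's source: the narrative quotes
critical levels 0.075 for q1 and 0.088 for q3, but the exact minima of B_J
over the relevant subset families are 0.074 (= 0.066 + 0.009 before
rounding) and 0.111.  The quoted 0.075 comes from summing already-rounded
summands and 0.088 appears to pick up the wrong subset family; the package
reports the exact minima via `PCETable.min_B` and the final decisions are
unaffected.

## The trial simulator

The simulator emulates a three-armed parallel-group trial (two treatments
vs a common control) with a primary and a secondary endpoint per treatment
and a toxicity marker per arm.  The six standardized statistics
(z1, z2, z3, z4, t1, t2) are multivariate normal with mean
√(n_s/2)·(δ1/σ1, δ2/σ2, δ1/σ1, δ2/σ2, 0, κ/σ_t) at per-group stage size
n_s.  Correlations: ½ between arms on the same endpoint (balanced groups
sharing a control), ρ between endpoints within an arm, ζ between toxicity
and its arm's primary endpoint, with the crossed entries given by the
products ρ/2, ζ/2, ζρ, ζρ/2.  Stage-one and stage-two vectors are
independent draws and full-data statistics are the √t-weighted combination
— distributionally equivalent to patientwise simulation for z-tests and far
cheaper.  The generator does not emulate features of real trials beyond
this model: no non-normal outcomes, no unknown variances, no staggered
recruitment or dropout, no estimation error in the toxicity threshold.
Passing tests therefore demonstrate correctness of the procedures under
the normal model, not robustness to those departures.

Default design (the reference scenario): α = 0.025 one-sided, n = 116 per
group with interim at n⁽¹⁾ = 58 (t = ½), σ = 1, ρ = 0.3, ζ = 0.5, toxicity
threshold s = 1.645 (the 95% normal quantile).  n = 116 is the smallest
multiple of 4 giving ≥ 90% simulated power to reject a primary hypothesis
at δ1 = δ2 = 0.4 with the fixed-sample graph test; the sample-size search
reproduces it.  Adaptation rules: PP (none), SB (keep the arm with the
larger interim primary z; ties — a probability-zero event — drop arm 2),
FF (fair coin, independent of the data), SF (drop any arm whose toxicity
score exceeds s; possibly both, in which case no hypothesis can be rejected
at the final analysis, or neither, in which case the preplanned test is
performed).  Dropping an arm drops both its hypotheses; the second-stage
graph gives the continued arm's primary hypothesis weight 1 with a unit
edge to its secondary.

When an arm is dropped with sample-size reallocation, the continued
treatment and control groups each receive 87 subjects in the second stage:
the dropped arm's 58 preplanned second-stage patients are split equally
between the two remaining groups (58 + 58/2).  This patient-conserving
arithmetic also reproduces the reference operating characteristics
(e.g. overall power 94.4% under SB with both effects 0.4), which a
second-stage size of 82 does not; the value remains configurable via
`TrialScenario.n2_reallocated`.  Without reallocation the second-stage size
is n − n⁽¹⁾ = 58.

In simulations agMTP uses z-test conditional errors with eq8 fractions.
Because every subset of the adapted graph carries a single positive
second-stage weight, γ_J calibration reduces to v_{j,J}B_J = B_J and the
vectorized engine exploits this; a general vectorized bisection handles
adapted graphs with several positive weights per subset.  The engine is
cross-checked replicate-by-replicate against the generic (scalar) closure
machinery, and all procedures consume identical random draws for a given
seed so per-replicate dominance comparisons are exact.  Monte-Carlo sizes:
property and FWER checks use 2·10⁴–4·10⁴ replicates, operating-
characteristic comparisons 1.5·10⁵–4·10⁵, and the sample-size search 10⁶
score vectors shared across candidates; shared draws make the simulated
power curve exactly nondecreasing in n, so the divisible-candidate
bisection is deterministic given the seed.

## Degenerate inputs and tie-breaking

- Several p-values meeting their level in one shortcut pass are rejected
  simultaneously; the reduced graph is rebuilt by removing them one at a
  time (order-invariant).
- B_J = 0 with positive second-stage weights yields v = 0 and no
  second-stage rejection, consistent with the γ → 0 limit.
- Stagewise p-values exactly 0 or 1 follow the limit conventions of the
  inverse-normal combination (0 wins over 1; either alone is absorbing).
- Hypotheses without second-stage data carry q ≡ 1 and zero second-stage
  weight; an efficient design never spends conditional level on them.

## Limitations

One interim analysis only (no multi-stage recursion), no group-sequential
early-rejection boundaries, no addition of new hypotheses at the interim,
and the first-class conditional-error path covers continuous z-tests and
inverse-normal combination tests; other marginal tests can be supplied as a
custom conditional-error function but their validity is the caller's
responsibility.
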