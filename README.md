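# agmtp — adaptive graph-based multiple testing procedures

Confirmatory clinical trials routinely test several hypotheses at once —
multiple treatment arms, hierarchically ordered endpoints, subgroups — and
regulators require strong control of the familywise error rate (FWER).
Graphical multiple testing procedures encode the testing strategy as a
directed weighted graph: node weights give the initial split of the
one-sided level α across hypotheses, and edge weights say where a rejected
hypothesis' level is propagated.  `agmtp` implements these graph tests and
extends them to **adaptive two-stage designs**, in which an unblinded
interim analysis may drop treatment arms, reallocate sample size, or change
the weighting strategy altogether — while preserving strong FWER control
without any assumption on the joint distribution of the test statistics or
prespecification of the adaptation rule.

It is aimed at trial statisticians and methods researchers who want to
plan, analyse, or simulate multi-arm / multi-endpoint adaptive designs.

## The method in brief

A graph with node weights w_I and transition matrix G_I defines
weighted-Bonferroni weights w_J for every nonempty intersection J ⊆ I by
recursive node removal; the closed test rejects H_i iff every H_J with
i ∈ J has some p_j ≤ w_{j,J}·α.  At an interim analysis the **partial
conditional error rate** of H_j inside H_J is, for a preplanned one-sided
z-test with information fraction t = n⁽¹⁾/n,

    A_{j,J}(w_{j,J}α) = P(Z_j > c_{1−w_{j,J}α} | z_j⁽¹⁾)
                      = 1 − Φ( (c_{1−w_{j,J}α} − z_j⁽¹⁾√t) / √(1−t) ),

and B_J = Σ_{j∈J} A_{j,J} is the conditional level available to *any*
independent second-stage test of H_J.  The adapted test rejects H_J if
B_J ≥ 1 (already at interim) or if some second-stage p-value
q_j < v_{j,J}·B_J, where the allocation fractions v_{j,J} are calibrated to
an adapted second-stage graph via the adjusted level γ_J solving
Σ_j A_{j,J}(w̃_{j,J}·γ_J) = B_J.  Closing this family of tests gives the
adaptive graph-based multiple testing procedure (agMTP).  The simple
comparator (saMTP/gPA) instead sets dropped hypotheses' p-values to one and
runs the preplanned graph test on inverse-normal combination p-values;
agMTP rejects everything it rejects, and more.

## Worked example

A three-armed trial (two regimens vs control) with hierarchically ordered
endpoints: H1/H2 are the primary-endpoint comparisons of treatments 1 and
2, H3/H4 the secondary ones.  At the interim analysis (t = ½) arm 2 is
dropped and its planned patients reallocated.

```python
import numpy as np
from agmtp import (StagePlan, adapt_design, agmtp_closed_test, derive_weights,
                   pce_table, second_stage_graph, two_treatment_hierarchy)

graph = two_treatment_hierarchy()            # w = (1/2, 1/2, 0, 0)
plan = StagePlan(alpha=0.025, n=116, n1=58)
z1 = np.array([1.66, 1.42, 1.90, 0.79])      # interim z-scores

weights = derive_weights(graph)
pce = pce_table(z1, weights, plan)
print(pce.to_frame(weights).round(3).head(5).to_string(index=False))

graph2 = second_stage_graph(graph, continued_arm=0)   # drop arm 2
design = adapt_design(graph2, pce, plan, z1=z1, continued=(0, 2))
q = np.array([0.059, 1.0, 0.031, 1.0])       # second-stage p-values
print("rejections:", dict(zip(graph.names, agmtp_closed_test(q, pce, design))))
print("critical level for q1:", round(pce.min_B(0b0001), 3))
```

which prints

```
   subset  w_H1  A_H1  w_H2  A_H2  w_H3  A_H3  w_H4  A_H4     B
{1,2,3,4}   0.5 0.066   0.5  0.04   0.0 0.000   0.0 0.000 0.106
  {1,2,3}   0.5 0.066   0.5  0.04   0.0 0.000   NaN   NaN 0.106
  {1,2,4}   0.5 0.066   0.5  0.04   NaN   NaN   0.0 0.000 0.106
  {1,3,4}   0.5 0.066   NaN   NaN   0.0 0.000   0.5 0.009 0.074
  {2,3,4}   NaN   NaN   0.5  0.04   0.5 0.102   0.0 0.000 0.142
rejections: {'H1': 1, 'H2': 0, 'H3': 1, 'H4': 0}
critical level for q1: 0.074
```

Each row is one intersection hypothesis: its graph weights w, partial
conditional errors A, and their sum B (the conditional level of the adapted
test).  Because every subset here has a single positive second-stage
weight, H1 is rejected since q1 = 0.059 falls below the smallest B_J over
subsets containing it (0.074), and H3 since q3 = 0.031 falls below the
smallest B_J over subsets containing H3 but not H1 (0.111).  H2 and H4 were
dropped and are retained.

The same analyses are available from the shell:

```sh
agmtp make-fixtures --out-dir example
agmtp adapt --graph example/graph.json --graph2 example/graph2.json \
            --z1 example/z1.csv --q example/q.csv
agmtp simulate --scenario example/scenario.yaml --procedure agmtp --reps 100000 --seed 42
```

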