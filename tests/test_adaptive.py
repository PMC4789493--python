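import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from agmtp.adaptive import (
    adapt_design,
    adapted_intersection_decision,
    agmtp_closed_test,
    allocation_fractions,
    drop_hypotheses,
    equal_recycling_fractions,
    samtp_gpa,
    solve_gamma,
    stagewise_pvalues,
)
from agmtp.closed_test import sequentially_rejective
from agmtp.conditional_error import (
    StagePlan,
    inverse_normal_pce,
    pce_table,
    ztest_pce,
)
from agmtp.graphs import derive_weights, subset_members, validate_graph
from conftest import Q, Z1, random_graph


def pce_closed_form(z1, level, t=0.5):
    """Independent transcription of the z-test conditional error."""
    if level <= 0:
        return 0.0
    if level >= 1:
        return 1.0
    return float(norm.sf((norm.isf(level) - z1 * np.sqrt(t)) / np.sqrt(1 - t)))


class TestSolveGamma:
    def test_unmodified_weights_give_alpha(self, case_plan):
        # gamma solves the defining equation at the preplanned level
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(2, 5))
            g = random_graph(rng, m)
            w = derive_weights(g).table[(1 << m) - 1]
            z1 = rng.normal(size=m)
            B = sum(pce_closed_form(z1[j], w[j] * 0.025) for j in range(m))
            if B >= 1:
                continue
            gamma = solve_gamma(z1, w, B, case_plan)
            assert gamma == pytest.approx(0.025, rel=1e-8)

    def test_reversed_fixed_sequence(self, case_plan):
        # order reversal: the new last hypothesis inherits the whole
        # conditional level; cross-check by independent root finding
        z1 = np.array([1.66, 1.42])
        B = pce_closed_form(1.66, 0.025)
        gamma = solve_gamma(z1, np.array([0.0, 1.0]), B, case_plan)
        oracle = brentq(
            lambda g: pce_closed_form(1.42, g) - B, 0.0, 1.0, xtol=1e-12
        )
        assert gamma == pytest.approx(oracle, abs=1e-9)

    def test_holm_adaptation(self, case_plan):
        # switching to an even split: A1(g/2) + A2(g/2) = A1(alpha)
        z1 = np.array([1.66, 1.42])
        B = pce_closed_form(1.66, 0.025)
        gamma = solve_gamma(z1, np.array([0.5, 0.5]), B, case_plan)
        oracle = brentq(
            lambda g: pce_closed_form(1.66, g / 2)
            + pce_closed_form(1.42, g / 2)
            - B,
            0.0,
            2.0,
            xtol=1e-12,
        )
        assert gamma == pytest.approx(oracle, abs=1e-9)
        for z, w in ((1.66, 0.5), (1.42, 0.5)):
            part = pce_closed_form(z, w * gamma)
            assert 0 < part < B

    def test_gamma_at_least_alpha_after_dropping(self, case_plan):
        # dropping a positively weighted hypothesis while keeping the
        # continued weights frees conditional level: gamma >= alpha
        rng = np.random.default_rng(4)
        for _ in range(25):
            m = int(rng.integers(2, 5))
            g = random_graph(rng, m)
            w = derive_weights(g).table[(1 << m) - 1]
            if not np.all(w > 0):
                continue
            z1 = rng.normal(size=m)
            drop = int(rng.integers(m))
            B = sum(pce_closed_form(z1[j], w[j] * 0.025) for j in range(m))
            if B >= 1:
                continue
            w2 = w.copy()
            w2[drop] = 0.0
            gamma = solve_gamma(z1, w2, B, case_plan)
            assert gamma >= 0.025 - 1e-10

    def test_errors(self, case_plan):
        with pytest.raises(ValueError, match="zero"):
            solve_gamma([1.0], np.array([0.0]), 0.5, case_plan)
        with pytest.raises(ValueError, match="B_J"):
            solve_gamma([1.0], np.array([1.0]), 1.2, case_plan)


class TestAllocationFractions:
    def test_fractions_sum_to_one(self, case_plan):
        rng = np.random.default_rng(8)
        for _ in range(25):
            m = int(rng.integers(2, 5))
            w2 = rng.dirichlet(np.ones(m))
            z1 = rng.normal(size=m)
            B = float(rng.uniform(0.01, 0.9))
            v = allocation_fractions(z1, w2, B, case_plan)
            assert v.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(v >= 0)

    def test_zero_weight_gives_zero_fraction(self, case_plan):
        v = allocation_fractions(
            np.array([1.0, 2.0]), np.array([1.0, 0.0]), 0.3, case_plan
        )
        assert v[1] == 0.0
        assert v[0] == pytest.approx(1.0)

    def test_single_positive_weight_recovers_weight_vector(
        self, case_weights, case_graph2, case_plan
    ):
        # every worked-example subset has one positive second-stage weight,
        # so the fractions coincide with the second-stage weights
        pce = pce_table(Z1, case_weights, case_plan)
        w2 = derive_weights(case_graph2)
        for mask in pce.subsets():
            if pce.B[mask] <= 0 or not np.any(w2.table[mask] > 0):
                continue
            v = allocation_fractions(
                Z1, w2.table[mask], pce.B[mask], case_plan
            )
            np.testing.assert_allclose(v, w2.table[mask], atol=1e-8)


class TestEqualRecycling:
    def test_nothing_dropped_reduces_to_proportional(self):
        A = np.array([0.05, 0.1, 0.0, 0.0])
        v = equal_recycling_fractions(A, [0, 1], 0.15)
        np.testing.assert_allclose(v, [1 / 3, 2 / 3, 0, 0])

    def test_recycled_mass_and_normalization(self):
        A = np.array([0.05, 0.1, 0.02, 0.0])
        B = A.sum()
        v = equal_recycling_fractions(A, [0, 2], B)
        assert v[1] == 0.0
        assert v.sum() == pytest.approx(1.0)
        # each continued fraction at least its own conditional error share
        assert np.all(v[[0, 2]] * B >= A[[0, 2]] - 1e-12)
        assert v[0] * B > A[0]  # strict: a weighted hypothesis was dropped

    def test_empty_continuation_rejected(self):
        with pytest.raises(ValueError):
            equal_recycling_fractions(np.array([0.1]), [], 0.1)


class TestAdaptedDecision:
    def test_interim_rejection_when_b_exceeds_one(self):
        assert adapted_intersection_decision(np.ones(3), np.zeros(3), 1.2) == 1

    def test_strict_comparison(self):
        v = np.array([1.0])
        assert adapted_intersection_decision(np.array([0.106]), v, 0.106) == 0
        assert adapted_intersection_decision(np.array([0.1059]), v, 0.106) == 1

    def test_all_q_one_below_one_retains(self):
        assert adapted_intersection_decision(np.ones(2), np.array([0.5, 0.5]), 0.9) == 0


class TestAgmtpClosedTest:
    def test_worked_example_decisions(self, case_weights, case_graph2, case_plan):
        pce = pce_table(Z1, case_weights, case_plan)
        design = adapt_design(
            case_graph2, pce, case_plan, z1=Z1, continued=(0, 2)
        )
        np.testing.assert_array_equal(
            agmtp_closed_test(Q, pce, design), [1, 0, 1, 0]
        )

    def test_second_stage_pvalues_regenerate_from_zscores(
        self, case_weights, case_graph2, case_plan
    ):
        q = np.array([norm.sf(1.56), 1.0, norm.sf(1.87), 1.0])
        np.testing.assert_allclose(q[[0, 2]], [0.059, 0.031], atol=5e-4)
        pce = pce_table(Z1, case_weights, case_plan)
        design = adapt_design(
            case_graph2, pce, case_plan, z1=Z1, continued=(0, 2)
        )
        np.testing.assert_array_equal(
            agmtp_closed_test(q, pce, design), [1, 0, 1, 0]
        )

    def test_all_q_one_no_interim_rejection(self, case_weights, case_graph2, case_plan):
        pce = pce_table(Z1, case_weights, case_plan)
        design = adapt_design(case_graph2, pce, case_plan, z1=Z1)
        assert agmtp_closed_test(np.ones(4), pce, design).sum() == 0

    def test_matches_independent_subset_oracle(self, case_plan):
        # oracle: evaluate the adapted decision per subset from scratch
        rng = np.random.default_rng(12)
        for _ in range(30):
            m = int(rng.integers(2, 5))
            g = random_graph(rng, m)
            weights = derive_weights(g)
            z1 = rng.normal(size=m)
            q = rng.uniform(size=m)
            dropped = [j for j in range(m) if rng.uniform() < 0.3]
            g2 = drop_hypotheses(g, dropped)
            pce = pce_table(z1, weights, case_plan)
            if all(g2.weights == 0):
                continue
            design = adapt_design(g2, pce, case_plan, z1=z1)
            psi = agmtp_closed_test(q, pce, design)
            w2 = derive_weights(g2)
            for i in range(m):
                dec = 1
                for mask in range(1, 1 << m):
                    if not mask >> i & 1:
                        continue
                    B = pce.B[mask]
                    if B >= 1:
                        continue
                    wv = w2.table[mask]
                    if not np.any(wv > 0):
                        dec = 0
                        break
                    gamma = solve_gamma(z1, wv, B, case_plan)
                    hit = any(
                        wv[j] > 0
                        and q[j] < pce_closed_form(z1[j], wv[j] * gamma)
                        for j in subset_members(mask)
                    )
                    if not hit:
                        dec = 0
                        break
                assert psi[i] == dec


class TestSamtpGpa:
    def test_nothing_dropped_equals_pooled_fixed_sample_test(self, case_graph):
        # equal-weight inverse normal of stagewise z-tests is the full-data
        # z-test when stages are balanced
        plan = StagePlan(alpha=0.025, n=100, n1=50)
        rng = np.random.default_rng(21)
        for _ in range(50):
            z1 = rng.normal(size=4)
            z2 = rng.normal(size=4)
            psi = samtp_gpa(
                stagewise_pvalues(z1), stagewise_pvalues(z2), case_graph, [], plan
            )
            pooled = norm.sf(np.sqrt(0.5) * (z1 + z2))
            np.testing.assert_array_equal(
                psi, sequentially_rejective(pooled, case_graph, 0.025)
            )

    def test_all_continued_p_one(self, case_graph, case_plan):
        psi = samtp_gpa(np.ones(4), np.ones(4), case_graph, [1, 3], case_plan)
        assert psi.sum() == 0

    def test_agmtp_dominates_gpa(self, case_plan):
        # matched inputs, inverse-normal conditional errors, second-stage
        # weights = preplanned weights zeroed on dropped hypotheses
        rng = np.random.default_rng(30)
        pce_fn = inverse_normal_pce(case_plan)
        strict = 0
        for _ in range(300):
            m = int(rng.integers(2, 5))
            g = random_graph(rng, m)
            weights = derive_weights(g)
            z1 = rng.normal(size=m) + 1.0
            z2 = rng.normal(size=m) + 1.0
            dropped = [j for j in range(m) if rng.uniform() < 0.35]
            if len(dropped) == m:
                dropped = dropped[:-1]
            q = stagewise_pvalues(z2)
            q[dropped] = 1.0
            gpa = samtp_gpa(
                stagewise_pvalues(z1), q, g, dropped, case_plan
            )
            g2 = drop_hypotheses(g, dropped)
            pce = pce_table(z1, weights, case_plan, pce_fn=pce_fn)
            design = adapt_design(g2, pce, case_plan, z1=z1, pce_fn=pce_fn)
            ag = agmtp_closed_test(q, pce, design)
            assert np.all(ag >= gpa)
            if np.any(ag > gpa) and any(
                weights.table[(1 << m) - 1][j] > 0 for j in dropped
            ):
                strict += 1
        assert strict > 0  # the improvement is realized, not just formal


class TestDropHypotheses:
    def test_zeroes_node_and_edges(self, case_graph):
        g2 = drop_hypotheses(case_graph, [1, 3])
        assert g2.weights[1] == g2.weights[3] == 0.0
        assert g2.transitions[1].sum() == 0.0
        assert g2.transitions[:, 3].sum() == 0.0
        # survivors untouched
        assert g2.weights[0] == 0.5
        assert g2.transitions[0, 2] == 1.0
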