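"""Markov chain estimation, chi-square comparisons, bouts and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from dolphinwatch.markov import (
    BoutEstimate,
    TransitionCounts,
    behavioural_budget,
    bout_length,
    bouts_from_matrix,
    build_counts,
    compare_bout_lengths,
    compare_budget_proportions,
    compare_chains_global,
    compare_transition_cell,
    recovery_times,
    stationary_distribution,
    transition_probabilities,
)
from dolphinwatch.records import OBSERVED_STATES, Condition, TransitionSample


def brute_force_chi2(table):
    """Independent oracle: literal sum over cells of (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    total = 0.0
    grand = table.sum()
    for r in range(table.shape[0]):
        for c in range(table.shape[1]):
            e = table[r].sum() * table[:, c].sum() / grand
            if e > 0:
                total += (table[r, c] - e) ** 2 / e
    return total


def _samples(pairs, condition):
    return [TransitionSample(i, j, condition, "A") for i, j in pairs]


count_tables = hnp.arrays(
    np.int64, (2, 4), elements=st.integers(min_value=0, max_value=60)
)


class TestBuildCounts:
    def test_counts_by_cell(self):
        samples = _samples([("REST", "REST"), ("REST", "TRAV")], Condition.CONTROL)
        counts = build_counts(samples, Condition.CONTROL)
        assert counts.counts[0].tolist() == [1, 1, 0, 0, 0]
        assert counts.row_totals[0] == 2

    def test_other_condition_gives_zeros(self):
        samples = _samples([("REST", "REST")], Condition.CONTROL)
        counts = build_counts(samples, Condition.IMPACT)
        assert counts.total == 0

    def test_transition_condition_never_counted(self):
        samples = _samples([("REST", "SOC")], Condition.TRANSITION)
        with pytest.raises(ValueError):
            build_counts(samples, Condition.TRANSITION)

    def test_empirical_rows_near_truth(self, rng):
        """10,000 draws from a known chain land within 3 binomial SE."""
        P = np.array([
            [0.5, 0.2, 0.1, 0.1, 0.1],
            [0.1, 0.6, 0.1, 0.1, 0.1],
            [0.2, 0.2, 0.4, 0.1, 0.1],
            [0.25, 0.25, 0.25, 0.15, 0.1],
            [0.1, 0.1, 0.1, 0.1, 0.6],
        ])
        n = 10_000
        state = 0
        samples = []
        for _ in range(n):
            nxt = rng.choice(5, p=P[state])
            samples.append(TransitionSample(OBSERVED_STATES[state],
                                            OBSERVED_STATES[nxt],
                                            Condition.IMPACT, "A"))
            state = nxt
        counts = build_counts(samples, Condition.IMPACT)
        mat = transition_probabilities(counts)
        for i in range(5):
            n_i = counts.row_totals[i]
            for j in range(5):
                se = math.sqrt(P[i, j] * (1 - P[i, j]) / n_i)
                assert abs(mat.probabilities[i, j] - P[i, j]) <= 3 * se + 1e-12


class TestTransitionProbabilities:
    def test_row_normalisation(self):
        counts = TransitionCounts(Condition.CONTROL, np.diag([2, 2, 2, 2, 2]) * 0
                                  + np.array([[2, 2, 0, 0, 0]] + [[0] * 5] * 4))
        mat = transition_probabilities(counts)
        assert mat.probabilities[0].tolist() == [0.5, 0.5, 0, 0, 0]
        assert not mat.defined_rows[1]

    def test_identity_counts_give_identity_matrix(self):
        counts = TransitionCounts(Condition.CONTROL, np.eye(5) * 5)
        mat = transition_probabilities(counts)
        assert np.allclose(mat.probabilities, np.eye(5))

    @given(hnp.arrays(np.int64, (5, 5), elements=st.integers(0, 50)))
    def test_defined_rows_sum_to_one(self, counts):
        mat = transition_probabilities(TransitionCounts(Condition.IMPACT, counts))
        sums = mat.probabilities[mat.defined_rows].sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-12)


class TestChainComparison:
    def test_identical_chains_give_zero_statistic(self):
        counts = TransitionCounts(Condition.CONTROL,
                                  np.full((5, 5), 4.0))
        impact = TransitionCounts(Condition.IMPACT, np.full((5, 5), 4.0))
        res = compare_chains_global(counts, impact)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 20

    @given(a=count_tables, b=count_tables)
    def test_rowwise_statistic_matches_brute_force(self, a, b):
        """The summed statistic equals the literal (O-E)^2/E oracle row by
        row, and scipy's uncorrected Pearson test where applicable."""
        c = np.zeros((5, 5)); i = np.zeros((5, 5))
        c[0, :4], c[1, :4] = a
        i[0, :4], i[1, :4] = b
        control = TransitionCounts(Condition.CONTROL, c)
        impact = TransitionCounts(Condition.IMPACT, i)
        expected = 0.0
        for r in range(2):
            t = np.vstack([c[r, :4], i[r, :4]])
            if t.sum() == 0:
                continue
            expected += brute_force_chi2(t)
        res = compare_chains_global(control, impact)
        assert res.statistic == pytest.approx(expected, abs=1e-9)

    def test_df_reduced_by_empty_columns(self):
        c = np.zeros((5, 5)); i = np.zeros((5, 5))
        c[0] = [10, 5, 3, 0, 0]
        i[0] = [4, 8, 2, 0, 0]
        res = compare_chains_global(TransitionCounts(Condition.CONTROL, c),
                                    TransitionCounts(Condition.IMPACT, i))
        assert res.df == 2  # 3 informative columns -> K_used - 1

    def test_scipy_is_equivalent_oracle(self):
        c = np.zeros((5, 5)); i = np.zeros((5, 5))
        c[2] = [3, 9, 14, 2, 1]
        i[2] = [10, 4, 6, 8, 3]
        res = compare_chains_global(TransitionCounts(Condition.CONTROL, c),
                                    TransitionCounts(Condition.IMPACT, i))
        ref = stats.chi2_contingency(np.vstack([c[2], i[2]]), correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.df == ref.dof
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_type_one_error_near_nominal(self, rng):
        """Identical generating chains are rejected at ~5% over 500 reps."""
        q = np.array([0.3, 0.2, 0.2, 0.15, 0.15])
        P = 0.3 * np.eye(5) + 0.7 * np.ones((5, 1)) * q
        n_rep, alpha, n_trans = 500, 0.05, 400
        rejections = 0
        for _ in range(n_rep):
            mats = []
            for _cond in range(2):
                counts = np.zeros((5, 5))
                state = int(rng.choice(5, p=q))
                for _ in range(n_trans):
                    nxt = int(rng.choice(5, p=P[state]))
                    counts[state, nxt] += 1
                    state = nxt
                mats.append(counts)
            res = compare_chains_global(
                TransitionCounts(Condition.CONTROL, mats[0]),
                TransitionCounts(Condition.IMPACT, mats[1]))
            rejections += res.pvalue < alpha
        rate = rejections / n_rep
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * se


class TestTransitionCellComparison:
    def test_identical_rows_give_zero(self):
        c = np.zeros((5, 5)); c[0] = [5, 5, 0, 0, 0]
        res = compare_transition_cell("REST", "TRAV",
                                      TransitionCounts(Condition.CONTROL, c),
                                      TransitionCounts(Condition.IMPACT, c.copy()))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_matches_brute_force_2x2(self):
        c = np.zeros((5, 5)); i = np.zeros((5, 5))
        c[1, 2], c[1, 0] = 5, 5  # TRAV -> SOC vs elsewhere
        i[1, 2], i[1, 0] = 1, 9
        res = compare_transition_cell("TRAV", "SOC",
                                      TransitionCounts(Condition.CONTROL, c),
                                      TransitionCounts(Condition.IMPACT, i))
        oracle = brute_force_chi2(np.array([[5, 5], [1, 9]]))
        assert res.statistic == pytest.approx(oracle, abs=1e-9)

    def test_closed_form_diagonal_table(self):
        """[[10,0],[0,10]] has chi2 = n(ad-bc)^2 / product of margins = 20."""
        c = np.zeros((5, 5)); i = np.zeros((5, 5))
        c[0, 0], i[0, 1] = 10, 10
        res = compare_transition_cell("REST", "REST",
                                      TransitionCounts(Condition.CONTROL, c),
                                      TransitionCounts(Condition.IMPACT, i))
        assert res.statistic == pytest.approx(20.0, abs=1e-9)

    def test_empty_row_in_one_condition_flagged(self):
        c = np.zeros((5, 5)); c[0] = [5, 5, 0, 0, 0]
        res = compare_transition_cell("REST", "TRAV",
                                      TransitionCounts(Condition.CONTROL, c),
                                      TransitionCounts(Condition.IMPACT,
                                                       np.zeros((5, 5))))
        assert not res.reliable


class TestBudget:
    def test_budget_from_succeeding_states(self):
        samples = _samples(
            [("REST", "SOC"), ("SOC", "SOC"), ("SOC", "REST"), ("REST", "MIL")],
            Condition.CONTROL)
        b = behavioural_budget(samples, Condition.CONTROL)
        assert b.proportion("SOC") == 0.5
        assert b.proportion("REST") == 0.25
        assert b.proportion("MIL") == 0.25
        assert b.n == 4

    @given(counts=hnp.arrays(np.int64, 5, elements=st.integers(0, 40)))
    def test_budget_sums_to_one(self, counts):
        if counts.sum() == 0:
            return
        pairs = []
        for j, c in enumerate(counts):
            pairs += [("REST", OBSERVED_STATES[j])] * int(c)
        b = behavioural_budget(_samples(pairs, Condition.IMPACT), Condition.IMPACT)
        assert b.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_budget_errors(self):
        with pytest.raises(ValueError):
            behavioural_budget([], Condition.CONTROL)

    def test_long_sequence_budget_near_stationary(self, rng):
        """Ergodic theorem: empirical budget of a long single-regime sequence
        approaches the chain's stationary distribution."""
        q = np.array([0.42, 0.08, 0.33, 0.10, 0.07])
        P = 0.55 * np.eye(5) + 0.45 * np.ones((5, 1)) * q
        n = 60_000
        state = 0
        samples = []
        for _ in range(n):
            nxt = int(rng.choice(5, p=P[state]))
            samples.append(TransitionSample(OBSERVED_STATES[state],
                                            OBSERVED_STATES[nxt],
                                            Condition.CONTROL, "A"))
            state = nxt
        b = behavioural_budget(samples, Condition.CONTROL)
        # batch-means SE: autocorrelated, so allow a generous 3x iid bound
        for j in range(5):
            se = math.sqrt(q[j] * (1 - q[j]) / n)
            assert abs(b.proportions[j] - q[j]) <= 9 * se

    def test_budget_comparison_matches_oracles(self):
        from dolphinwatch.markov import BudgetTable

        bc = BudgetTable(Condition.CONTROL, np.array([23, 6, 23, 7, 11]))
        bi = BudgetTable(Condition.IMPACT, np.array([73, 63, 27, 22, 87]))
        cmp = compare_budget_proportions(bc, bi)
        table = np.vstack([bc.counts, bi.counts])
        assert cmp.global_test.statistic == pytest.approx(
            brute_force_chi2(table), abs=1e-9)
        assert cmp.global_test.df == 4
        # per-state = uncorrected 2x2 Pearson on (state, not state)
        t = np.array([[23, 70 - 23], [27, 272 - 27]])
        from dolphinwatch.markov import BudgetTable as BT

        bc2 = BT(Condition.CONTROL, np.array([23, 47, 0, 0, 0]))
        bi2 = BT(Condition.IMPACT, np.array([27, 245, 0, 0, 0]))
        cmp2 = compare_budget_proportions(bc2, bi2)
        assert cmp2.per_state["REST"].statistic == pytest.approx(
            brute_force_chi2(t), abs=1e-9)
        ref = stats.chi2_contingency(t, correction=False)
        assert cmp2.per_state["REST"].statistic == pytest.approx(
            ref.statistic, abs=1e-9)

    def test_equal_budgets_give_zero_statistics(self):
        from dolphinwatch.markov import BudgetTable

        b = BudgetTable(Condition.CONTROL, np.array([10, 10, 10, 10, 10]))
        b2 = BudgetTable(Condition.IMPACT, np.array([10, 10, 10, 10, 10]))
        cmp = compare_budget_proportions(b, b2)
        assert cmp.global_test.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(r.statistic == pytest.approx(0.0, abs=1e-12)
                   for r in cmp.per_state.values())


class TestBoutLength:
    @pytest.mark.parametrize(
        "p, expected_minutes, reported",
        [
            (0.95, 60.0, 60),
            (0.58, 3 / 0.42, 7),
            (0.04, 3.125, 3),
            (0.0, 3.0, 3),
        ],
    )
    def test_formula_and_rounding(self, p, expected_minutes, reported):
        est = bout_length(p, n_i=20)
        assert est.mean_minutes == pytest.approx(expected_minutes, rel=1e-9)
        assert est.reported_minutes == reported

    def test_standard_error_formula(self):
        est = bout_length(0.6, n_i=25)
        assert est.se_p == pytest.approx(math.sqrt(0.6 * 0.4 / 25), rel=1e-12)
        assert est.se_minutes == pytest.approx(3 * est.se_p / 0.4**2, rel=1e-12)

    def test_p_one_gives_flagged_infinity(self):
        est = bout_length(1.0, n_i=5)
        assert math.isinf(est.mean_minutes)
        assert not est.finite

    def test_p_outside_unit_interval_errors(self):
        with pytest.raises(ValueError):
            bout_length(1.2, n_i=5)
        with pytest.raises(ValueError):
            bout_length(-0.1, n_i=5)

    @given(st.floats(min_value=0.0, max_value=0.99),
           st.floats(min_value=0.0, max_value=0.99))
    def test_strictly_increasing_in_p(self, p1, p2):
        lo, hi = sorted([p1, p2])
        if hi - lo < 1e-9:  # below float resolution of 1/(1-p)
            return
        assert bout_length(lo, 10).mean_minutes < bout_length(hi, 10).mean_minutes

    def test_mean_run_length_converges_to_bout(self, rng):
        """Observed mean run length in a long sequence matches t_ii within 5%."""
        p_stay = 0.7
        n = 100_000
        seq = rng.random(n) < p_stay  # True = stay in the state
        # run lengths: a bout ends at each 'leave'; mean = 1/(1-p)
        leaves = (~seq).sum()
        mean_run = n / max(leaves, 1)
        assert abs(mean_run - 1 / (1 - p_stay)) / (1 / (1 - p_stay)) < 0.05


class TestCompareBoutLengths:
    def test_identical_estimates(self):
        a = bout_length(0.5, 30)
        res = compare_bout_lengths(a, bout_length(0.5, 30))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.df == 58

    def test_closed_form_t(self):
        a = BoutEstimate("REST", Condition.CONTROL, 0.5, 20, 3, 2.0, 8.0, 0.1, 1.0)
        b = BoutEstimate("REST", Condition.IMPACT, 0.5, 20, 3, 2.0, 6.0, 0.1, 1.0)
        res = compare_bout_lengths(a, b)
        assert res.statistic == pytest.approx(2 / math.sqrt(2), rel=1e-12)

    def test_infinite_bout_skips_test(self):
        res = compare_bout_lengths(bout_length(1.0, 10), bout_length(0.5, 10))
        assert res.skipped
        assert "infinite" in res.flags[0]

    def test_type_one_error_near_nominal(self, rng):
        """Equal self-transition probabilities are rejected at ~5%."""
        p_true, n_i, n_rep, alpha = 0.6, 200, 500, 0.05
        rej = 0
        for _ in range(n_rep):
            p_c = rng.binomial(n_i, p_true) / n_i
            p_i = rng.binomial(n_i, p_true) / n_i
            res = compare_bout_lengths(bout_length(p_c, n_i), bout_length(p_i, n_i))
            if not res.skipped and res.pvalue < alpha:
                rej += 1
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rej / n_rep - alpha) <= 3 * se


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        pi = stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert np.allclose(pi, [0.5, 0.5])

    def test_hand_solved_two_state(self):
        """pi P = pi for P = [[.9,.1],[.2,.8]] solves to (2/3, 1/3)."""
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    @given(hnp.arrays(np.float64, (4, 4),
                      elements=st.floats(min_value=0.05, max_value=1.0)))
    def test_defining_property(self, raw):
        P = raw / raw.sum(axis=1, keepdims=True)
        pi = stationary_distribution(P)
        assert np.linalg.norm(pi @ P - pi) < 1e-10
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_reducible_chain_errors_naming_states(self):
        counts = TransitionCounts(Condition.CONTROL, np.eye(5) * 3)
        mat = transition_probabilities(counts)
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(mat)

    def test_undefined_row_errors_naming_state(self):
        c = np.ones((5, 5)); c[3] = 0
        mat = transition_probabilities(TransitionCounts(Condition.CONTROL, c))
        with pytest.raises(ValueError, match="DIV"):
            stationary_distribution(mat)


class TestRecoveryTimes:
    @pytest.mark.parametrize("pi_j, minutes, reported", [
        (0.33, 3 / 0.33, 9),
        (0.42, 3 / 0.42, 7),
        (1.0, 3.0, 3),
    ])
    def test_formula_and_rounding(self, pi_j, minutes, reported):
        pi = np.array([pi_j, *([round((1 - pi_j) / 4, 10)] * 4)])
        pi = pi / pi.sum()
        table = recovery_times(pi)
        assert table.minutes[0] == pytest.approx(3 / pi[0], rel=1e-9)
        assert table.reported_minutes[0] == reported

    def test_zero_pi_flagged_infinite(self):
        table = recovery_times([0.5, 0.5, 0.0, 0.0, 0.0])
        assert math.isinf(table.minutes[2])

    @given(hnp.arrays(np.float64, 5,
                      elements=st.floats(min_value=0.01, max_value=1.0)))
    def test_antitone_in_pi(self, raw):
        """States with larger steady-state probability recover faster."""
        pi = raw / raw.sum()
        minutes = recovery_times(pi).minutes
        order = np.argsort(pi)
        diffs = np.diff(minutes[order])
        assert np.all(diffs <= 1e-12)


class TestParameterRecovery:
    def test_large_sample_recovery_of_known_chains(self, rng):
        """10^5 transitions recover p_ij within 3 binomial SE and the
        stationary distribution within 0.01."""
        q = np.array([0.42, 0.08, 0.33, 0.10, 0.07])
        P = 0.55 * np.eye(5) + 0.45 * np.ones((5, 1)) * q
        n = 100_000
        states = np.empty(n + 1, dtype=int)
        states[0] = 0
        u = rng.random(n)
        cdf = np.cumsum(P, axis=1)
        for t in range(n):
            states[t + 1] = np.searchsorted(cdf[states[t]], u[t])
        counts = np.zeros((5, 5))
        np.add.at(counts, (states[:-1], states[1:]), 1)
        mat = transition_probabilities(
            TransitionCounts(Condition.CONTROL, counts))
        for i in range(5):
            n_i = counts[i].sum()
            for j in range(5):
                se = math.sqrt(P[i, j] * (1 - P[i, j]) / n_i)
                assert abs(mat.probabilities[i, j] - P[i, j]) <= 3 * se + 1e-12
        pi_hat = stationary_distribution(mat)
        assert np.max(np.abs(pi_hat - q)) < 0.01

    def test_bouts_from_matrix_skips_undefined_rows(self):
        c = np.ones((5, 5)); c[4] = 0
        mat = transition_probabilities(TransitionCounts(Condition.IMPACT, c))
        bouts = bouts_from_matrix(mat)
        assert "MIL" not in bouts
        assert bouts["REST"].p_ii == pytest.approx(0.2)
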