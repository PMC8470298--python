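"""First-order Markov chain analysis of behavioural transitions.

The behavioural sequence of a dolphin group is modelled as a time-discrete
first-order Markov chain over the five observed states, with one chain fitted
per vessel condition (control / impact).  From each chain the module derives:

* transition probabilities ``p_ij = a_ij / sum_j a_ij`` (row-normalised counts),
* behavioural budgets (proportion of time per state),
* mean bout lengths ``t_ii = 1 / (1 - p_ii)`` transition units, with
  ``SE(p_ii) = sqrt(p_ii (1 - p_ii) / n_i)`` propagated to minutes,
* the stationary distribution ``pi`` (``pi P = pi``), and
* expected recovery times ``E(T_j) = 1 / pi_j`` transition units.

Conditions are compared with Pearson chi-square tests (no continuity
correction): a row-wise homogeneity test across the whole chain, per-cell
2x2 tests, budget proportion tests and Student's t-tests on bout lengths.
One transition unit is 3 minutes unless stated otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .records import OBSERVED_STATES, SCAN_INTERVAL_MIN, Condition, TransitionSample

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TransitionCounts:
    """Observed transition counts a_ij for one condition, fixed state order."""

    condition: Condition
    counts: np.ndarray
    state_order: tuple[str, ...] = OBSERVED_STATES
    n_dropped: int = 0  # samples excluded (e.g. FEED) while counting

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.state_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("transition counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        """n_i: number of samples with state i as preceding behaviour."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def index(self, state: str) -> int:
        return self.state_order.index(state)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probability matrix p_ij with provenance."""

    probabilities: np.ndarray
    source: TransitionCounts
    defined_rows: np.ndarray  # boolean mask, False where n_i = 0

    @property
    def state_order(self) -> tuple[str, ...]:
        return self.source.state_order

    def p(self, i: str, j: str) -> float:
        return float(self.probabilities[self.source.index(i), self.source.index(j)])


@dataclass
class BudgetTable:
    """Proportion of time per behavioural state under one condition."""

    condition: Condition
    counts: np.ndarray  # occurrences per state
    state_order: tuple[str, ...] = OBSERVED_STATES
    source: str = "transitions"  # "transitions" (succeeding states) or "scans"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def proportion(self, state: str) -> float:
        return float(self.proportions[self.state_order.index(state)])


@dataclass
class BoutEstimate:
    """Mean bout length t_ii = 1/(1-p_ii) with delta-method SE, in minutes."""

    state: str | None
    condition: Condition | None
    p_ii: float
    n_i: int
    unit_minutes: float
    mean_units: float
    mean_minutes: float
    se_p: float
    se_minutes: float

    @property
    def reported_minutes(self) -> int | float:
        """Minutes rounded to the nearest whole minute (ties to even)."""
        if math.isinf(self.mean_minutes):
            return math.inf
        return round(self.mean_minutes)

    @property
    def finite(self) -> bool:
        return math.isfinite(self.mean_minutes)


@dataclass
class RecoveryTable:
    """Expected return times E(T_j) = unit / pi_j per state, one condition."""

    condition: Condition | None
    pi: np.ndarray
    unit_minutes: float
    state_order: tuple[str, ...] = OBSERVED_STATES
    pi_source: str = "budget"

    @property
    def minutes(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.pi > 0, self.unit_minutes / self.pi, np.inf)

    @property
    def reported_minutes(self) -> list[int | float]:
        return [round(m) if math.isfinite(m) else math.inf for m in self.minutes]

    def minutes_for(self, state: str) -> float:
        return float(self.minutes[self.state_order.index(state)])


@dataclass
class ChiSquareResult:
    """A Pearson chi-square statistic with df, p-value and the cells used."""

    statistic: float
    df: int
    pvalue: float
    cells_used: int
    flags: list[str] = field(default_factory=list)

    @property
    def reliable(self) -> bool:
        return not self.flags


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    flags: list[str] = field(default_factory=list)

    @property
    def skipped(self) -> bool:
        return math.isnan(self.statistic)


@dataclass
class BudgetComparison:
    global_test: ChiSquareResult
    per_state: dict[str, ChiSquareResult]


# ---------------------------------------------------------------------------
# chain estimation
# ---------------------------------------------------------------------------

def build_counts(
    samples: Iterable[TransitionSample],
    condition: Condition,
    state_order: Sequence[str] = OBSERVED_STATES,
) -> TransitionCounts:
    """Tabulate a_ij over the samples of one condition.

    Samples of other conditions — in particular transition-condition pairs —
    are never counted.  Samples involving states outside ``state_order``
    (e.g. FEED under the default 5-state order) are dropped and tallied in
    ``n_dropped``.
    """
    if condition == Condition.TRANSITION:
        raise ValueError("no chain is fitted for the transition condition")
    order = tuple(state_order)
    idx = {s: k for k, s in enumerate(order)}
    counts = np.zeros((len(order), len(order)))
    dropped = 0
    n_cond = 0
    for s in samples:
        if s.condition != condition:
            continue
        n_cond += 1
        if s.preceding not in idx or s.succeeding not in idx:
            dropped += 1
            continue
        counts[idx[s.preceding], idx[s.succeeding]] += 1
    if n_cond == 0:
        logger.warning("no %s samples: all-zero count matrix", condition.value)
    if dropped:
        logger.warning(
            "%d %s sample(s) involve states outside the analysis order and were dropped",
            dropped, condition.value,
        )
    return TransitionCounts(condition=condition, counts=counts,
                            state_order=order, n_dropped=dropped)


def transition_probabilities(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalise counts into p_ij = a_ij / n_i.

    Rows with n_i = 0 have undefined probabilities; they are left as zero and
    flagged through ``defined_rows`` rather than treated as an error.
    """
    totals = counts.row_totals
    defined = totals > 0
    probs = np.zeros_like(counts.counts)
    probs[defined] = counts.counts[defined] / totals[defined, None]
    assert np.all(np.abs(probs[defined].sum(axis=1) - 1.0) < _ROW_SUM_TOL)
    return TransitionMatrix(probabilities=probs, source=counts, defined_rows=defined)


# ---------------------------------------------------------------------------
# chi-square machinery (Pearson, no continuity correction anywhere)
# ---------------------------------------------------------------------------

def _pearson_chi2(table: np.ndarray) -> tuple[float, int, int, list[str]]:
    """Pearson statistic on a 2D table with zero-margin columns dropped.

    Columns whose combined count is zero carry no information and are removed
    (df reduced accordingly).  Cells whose expected count is zero because a
    row margin is zero contribute 0 (their observed count is necessarily 0
    too); such tables are flagged.
    """
    table = np.asarray(table, dtype=float)
    flags: list[str] = []
    keep = table.sum(axis=0) > 0
    if not keep.all():
        flags.append(f"{int((~keep).sum())} empty column(s) dropped")
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 0, int(table.size), flags + ["fewer than 2 informative columns"]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    grand = table.sum()
    expected = row * col / grand
    if (row == 0).any():
        flags.append("zero row margin: test unreliable")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    stat = float(contrib.sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df, int(table.size), flags


def _chi2_result(stat: float, df: int, cells: int, flags: list[str]) -> ChiSquareResult:
    p = float(stats.chi2.sf(stat, df)) if df >= 1 else float("nan")
    return ChiSquareResult(statistic=stat, df=df, pvalue=p, cells_used=cells, flags=flags)


def compare_chains_global(
    control: TransitionCounts,
    impact: TransitionCounts,
    min_expected: float = 1.0,
) -> ChiSquareResult:
    """Row-wise homogeneity test of the two chains.

    For each preceding state i, the 2xK table (condition x succeeding state)
    is tested after dropping succeeding states with zero combined count;
    statistics and degrees of freedom are summed over rows, so
    df = sum_rows (K_used - 1).  Rows empty in both conditions are excluded
    with a warning.  Expected cells below ``min_expected`` only flag the
    result (the asymptotic p-value may be anti-conservative there).
    """
    if control.state_order != impact.state_order:
        raise ValueError("count matrices use different state orders")
    stat_total, df_total, cells_total = 0.0, 0, 0
    flags: list[str] = []
    for i, state in enumerate(control.state_order):
        row_c, row_i = control.counts[i], impact.counts[i]
        if row_c.sum() == 0 and row_i.sum() == 0:
            flags.append(f"row {state} empty in both conditions: excluded")
            logger.warning("row %s empty in both conditions: excluded", state)
            continue
        table = np.vstack([row_c, row_i])
        stat, df, cells, row_flags = _pearson_chi2(table)
        if row_flags and any("zero row margin" in f for f in row_flags):
            flags.append(f"row {state}: observed in one condition only")
        keep = table.sum(axis=0) > 0
        t = table[:, keep]
        if t.shape[1] >= 2:
            expected = t.sum(axis=1, keepdims=True) * t.sum(axis=0, keepdims=True) / t.sum()
            if (expected[expected > 0] < min_expected).any():
                flags.append(f"row {state}: expected cell count below {min_expected}")
        stat_total += stat
        df_total += df
        cells_total += cells
    return _chi2_result(stat_total, df_total, cells_total, flags)


def compare_transition_cell(
    i: str,
    j: str,
    control: TransitionCounts,
    impact: TransitionCounts,
) -> ChiSquareResult:
    """2x2 test of one transition probability p_ij between conditions.

    Among the transitions out of state i, compares "to j" vs "elsewhere"
    across conditions; df = 1, no continuity correction.  If state i was
    never a preceding state in one condition the result is flagged
    unreliable.
    """
    ic, jc = control.index(i), control.index(j)
    row_c, row_i = control.counts[ic], impact.counts[ic]
    if row_c.sum() + row_i.sum() == 0:
        raise ValueError(f"no transitions out of state {i} in either condition")
    table = np.array(
        [
            [row_c[jc], row_c.sum() - row_c[jc]],
            [row_i[jc], row_i.sum() - row_i[jc]],
        ]
    )
    stat, df, cells, flags = _pearson_chi2(table)
    if row_c.sum() == 0 or row_i.sum() == 0:
        flags.append(f"state {i} unobserved as preceding in one condition: unreliable")
    if df == 0:
        # both conditions always went to j (or never): no contrast to test
        flags.append("degenerate 2x2 (constant column)")
        df = 1
        stat = 0.0
    return _chi2_result(stat, df, cells, flags)


# ---------------------------------------------------------------------------
# budgets
# ---------------------------------------------------------------------------

def behavioural_budget(
    samples: Iterable[TransitionSample],
    condition: Condition,
    state_order: Sequence[str] = OBSERVED_STATES,
) -> BudgetTable:
    """Behavioural budget from the succeeding states of a condition's samples.

    Using succeeding states keeps the budget sample size identical to the
    chain's transition count for that condition.  Raises on an empty sample
    set.
    """
    order = tuple(state_order)
    idx = {s: k for k, s in enumerate(order)}
    counts = np.zeros(len(order))
    for s in samples:
        if s.condition == condition and s.succeeding in idx:
            counts[idx[s.succeeding]] += 1
    if counts.sum() == 0:
        raise ValueError(f"no {condition.value} samples: budget undefined")
    return BudgetTable(condition=condition, counts=counts, state_order=order,
                       source="transitions")


def scan_budget(follows, condition: Condition,
                state_order: Sequence[str] = OBSERVED_STATES) -> BudgetTable:
    """Alternative budget counting scans directly by vessel presence.

    A scan is control when no vessels are present, impact otherwise; this
    uses every scan rather than every transition.
    """
    order = tuple(state_order)
    idx = {s: k for k, s in enumerate(order)}
    counts = np.zeros(len(order))
    for f in follows:
        for s in f.scans:
            cond = Condition.IMPACT if s.vessels_present else Condition.CONTROL
            if cond == condition and s.state in idx:
                counts[idx[s.state]] += 1
    if counts.sum() == 0:
        raise ValueError(f"no {condition.value} scans: budget undefined")
    return BudgetTable(condition=condition, counts=counts, state_order=order,
                       source="scans")


def compare_budget_proportions(
    budget_control: BudgetTable,
    budget_impact: BudgetTable,
) -> BudgetComparison:
    """Compare budgets globally and per state.

    Global: Pearson chi-square on the 2xS (condition x state) count table
    (states absent in both conditions dropped, df reduced).  Per state:
    two-sample test for equality of proportions, identical to the 2x2
    Pearson chi-square without continuity correction, df = 1.
    """
    if budget_control.state_order != budget_impact.state_order:
        raise ValueError("budgets use different state orders")
    table = np.vstack([budget_control.counts, budget_impact.counts])
    stat, df, cells, flags = _pearson_chi2(table)
    global_test = _chi2_result(stat, df, cells, flags)

    per_state: dict[str, ChiSquareResult] = {}
    n_c, n_i = budget_control.n, budget_impact.n
    for k, state in enumerate(budget_control.state_order):
        x_c, x_i = budget_control.counts[k], budget_impact.counts[k]
        t = np.array([[x_c, n_c - x_c], [x_i, n_i - x_i]])
        s, d, c, f = _pearson_chi2(t)
        if d == 0:
            f.append("degenerate 2x2 (state in all or no samples)")
            d, s = 1, 0.0
        per_state[state] = _chi2_result(s, d, c, f)
    return BudgetComparison(global_test=global_test, per_state=per_state)


# ---------------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------------

def bout_length(
    p_ii: float,
    n_i: int,
    unit_minutes: float = SCAN_INTERVAL_MIN,
    state: str | None = None,
    condition: Condition | None = None,
) -> BoutEstimate:
    """Mean bout length t_ii = 1/(1 - p_ii) from a self-transition probability.

    The standard error of p_ii is the binomial ``sqrt(p (1-p) / n_i)``; it is
    propagated to the minute scale with the delta method,
    ``SE(t) = unit * SE(p) / (1 - p)^2``.  ``p_ii = 1`` yields a flagged
    infinite bout; values outside [0, 1] are an error.
    """
    if not 0.0 <= p_ii <= 1.0:
        raise ValueError(f"p_ii must be in [0, 1], got {p_ii}")
    if n_i < 1:
        raise ValueError(f"n_i must be >= 1, got {n_i}")
    if unit_minutes <= 0:
        raise ValueError("unit_minutes must be positive")
    se_p = math.sqrt(p_ii * (1.0 - p_ii) / n_i)
    if p_ii == 1.0:
        logger.warning("p_ii = 1: infinite bout length for state %s", state)
        return BoutEstimate(state, condition, p_ii, n_i, unit_minutes,
                            math.inf, math.inf, se_p, math.inf)
    mean_units = 1.0 / (1.0 - p_ii)
    return BoutEstimate(
        state=state,
        condition=condition,
        p_ii=p_ii,
        n_i=n_i,
        unit_minutes=unit_minutes,
        mean_units=mean_units,
        mean_minutes=unit_minutes * mean_units,
        se_p=se_p,
        se_minutes=unit_minutes * se_p / (1.0 - p_ii) ** 2,
    )


def bouts_from_matrix(P: TransitionMatrix,
                      unit_minutes: float = SCAN_INTERVAL_MIN) -> dict[str, BoutEstimate]:
    """Bout estimates for every state with a defined row of the matrix."""
    out: dict[str, BoutEstimate] = {}
    totals = P.source.row_totals
    for k, state in enumerate(P.state_order):
        if not P.defined_rows[k]:
            continue
        out[state] = bout_length(
            float(P.probabilities[k, k]), int(totals[k]), unit_minutes,
            state=state, condition=P.source.condition,
        )
    return out


def compare_bout_lengths(
    est_control: BoutEstimate,
    est_impact: BoutEstimate,
    welch: bool = False,
) -> TTestResult:
    """Student's t-test on two bout-length estimates (minute scale).

    t = (mean_c - mean_i) / sqrt(SE_c^2 + SE_i^2), with pooled
    df = n_c + n_i - 2 (Welch-Satterthwaite df optionally).  An infinite
    bout in either condition skips the test with a flag.
    """
    if not (est_control.finite and est_impact.finite):
        return TTestResult(math.nan, math.nan, math.nan,
                           flags=["infinite bout: test skipped"])
    if est_control.n_i < 2 or est_impact.n_i < 2:
        return TTestResult(math.nan, math.nan, math.nan,
                           flags=["n_i < 2 in one condition: test skipped"])
    v_c, v_i = est_control.se_minutes ** 2, est_impact.se_minutes ** 2
    denom = math.sqrt(v_c + v_i)
    flags: list[str] = []
    if denom == 0:
        if est_control.mean_minutes == est_impact.mean_minutes:
            return TTestResult(0.0, est_control.n_i + est_impact.n_i - 2, 1.0,
                               flags=["zero standard error"])
        return TTestResult(math.inf, math.nan, 0.0, flags=["zero standard error"])
    t = (est_control.mean_minutes - est_impact.mean_minutes) / denom
    if welch:
        df = (v_c + v_i) ** 2 / (
            v_c ** 2 / (est_control.n_i - 1) + v_i ** 2 / (est_impact.n_i - 1)
        )
    else:
        df = est_control.n_i + est_impact.n_i - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(statistic=t, df=df, pvalue=p, flags=flags)


# ---------------------------------------------------------------------------
# stationary distribution and recovery times
# ---------------------------------------------------------------------------

def stationary_distribution(P: TransitionMatrix | np.ndarray,
                            tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi with pi P = pi, sum(pi) = 1.

    Solved as the left eigenvector of P for eigenvalue 1.  Requires every row
    to be defined and the chain to be irreducible (one strongly connected
    component of the positive-transition graph); otherwise raises, naming the
    states outside the recurrent communicating class.
    """
    if isinstance(P, TransitionMatrix):
        states = P.state_order
        if not P.defined_rows.all():
            undefined = [s for s, d in zip(states, P.defined_rows) if not d]
            raise ValueError(
                f"stationary distribution undefined: no transitions observed out "
                f"of state(s) {', '.join(undefined)}"
            )
        mat = P.probabilities
    else:
        mat = np.asarray(P, dtype=float)
        states = tuple(str(i) for i in range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.abs(mat.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("matrix is not row-stochastic")
    n_comp, labels = connected_components(mat > 0, directed=True, connection="strong")
    if n_comp > 1:
        # the recurrent class is a strongly connected component with no exits
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        outside = [s for s, l in zip(states, labels) if l != main]
        raise ValueError(
            "chain is reducible; states outside the largest communicating "
            f"class: {', '.join(outside)}"
        )
    vals, vecs = np.linalg.eig(mat.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.linalg.norm(pi @ mat - pi) >= tol:
        raise ValueError("failed to solve pi P = pi to tolerance")
    return pi


def recovery_times(
    pi: np.ndarray | Sequence[float],
    unit_minutes: float = SCAN_INTERVAL_MIN,
    condition: Condition | None = None,
    state_order: Sequence[str] = OBSERVED_STATES,
    pi_source: str = "budget",
) -> RecoveryTable:
    """Expected return times E(T_j) = unit_minutes / pi_j.

    ``pi`` may come from the fitted chain's stationary distribution or from
    the observed budget proportions (the two coincide for a long single-regime
    sequence).  A zero pi_j yields a flagged infinite recovery time.
    """
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any():
        raise ValueError("pi must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"pi must sum to 1 (got {pi.sum():.6f})")
    if (pi == 0).any():
        logger.warning("pi contains zeros: infinite recovery time for those states")
    return RecoveryTable(condition=condition, pi=pi, unit_minutes=unit_minutes,
                         state_order=tuple(state_order), pi_source=pi_source)
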