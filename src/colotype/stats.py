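"""Exact-statistics layer: Fisher tests, normality-gated comparisons,
gated correlations, and Bonferroni correction.

Two-sided exact p values follow the "sum of all tables at most as probable as
the observed one" definition throughout (the convention behind standard
statistical software), both for the 2x2 Fisher test and for its
Freeman-Halton generalization to r x c tables.  The r x c test enumerates
every table with the observed margins; when the enumeration would exceed a
node budget it falls back to seeded Monte Carlo sampling from the conditional
(multiple hypergeometric) distribution, reporting the standard error and seed.

Two-group location comparisons are gated on normality: Shapiro-Wilk on each
group, Student's t test when both pass, Mann-Whitney U otherwise (exact
enumeration for small tie-free samples, normal approximation with tie and
continuity correction else).  Correlations are gated the same way between
Pearson and Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyResult",
    "GroupComparisonResult",
    "CorrelationResult",
    "fisher_2x2",
    "fisher_rxc",
    "compare_groups",
    "correlate",
    "bonferroni",
]

#: Relative slack when comparing table probabilities to the observed one,
#: absorbing floating-point noise in the log-probability arithmetic.
_PROB_RTOL = 1e-7

MW_EXACT_MAX_N = 20  # exact Mann-Whitney up to this combined n (no ties)
DEFAULT_MC_REPS = 1_000_000
DEFAULT_MAX_TABLES = 2_000_000


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    method: str  # FISHER_2x2 | FISHER_RxC_EXACT | FISHER_RxC_MC
    p_raw: float
    family_size: int | None = None
    p_corrected: float | None = None
    n_tables: int | None = None  # exact: tables enumerated
    mc_reps: int | None = None
    mc_seed: int | None = None
    mc_se: float | None = None


@dataclass(frozen=True)
class GroupComparisonResult:
    n_a: int
    n_b: int
    normality_p: tuple[float | None, float | None]
    test_used: str  # T_TEST | MANN_WHITNEY
    statistic: float
    p_raw: float
    p_corrected: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # PEARSON | SPEARMAN
    r: float
    p_raw: float
    n: int
    degenerate: bool = False  # zero variance in a marginal


def _validate_counts(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        f = np.asarray(table, dtype=float)
        if not np.allclose(f, np.round(f)):
            raise ValueError("contingency table must hold integer counts")
        t = np.round(f).astype(np.int64)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("contingency table is all zero")
    return t.astype(np.int64)


def fisher_2x2(table) -> float:
    """Exact two-sided Fisher p for a 2x2 table."""
    t = _validate_counts(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def _log_table_prob(cells: np.ndarray, log_const: float) -> float:
    return log_const - gammaln(cells + 1.0).sum()


def _enumerate_rxc(rows, cols, p_obs_log, max_tables):
    """Sum probabilities of margin-fixed tables at most as probable as
    observed.  Returns (p, n_tables) or None when the budget is exceeded."""
    r, c = len(rows), len(cols)
    log_const = (
        gammaln(np.asarray(rows) + 1.0).sum()
        + gammaln(np.asarray(cols) + 1.0).sum()
        - gammaln(sum(rows) + 1.0)
    )
    cutoff = p_obs_log + np.log1p(_PROB_RTOL)
    total = 0.0
    count = 0

    def rec_row(i: int, colrem: tuple[int, ...], lg_acc: float):
        nonlocal total, count
        if count > max_tables:
            raise _BudgetExceeded
        if i == r - 1:
            # last row is forced by the remaining column sums
            lg = lg_acc - gammaln(np.asarray(colrem) + 1.0).sum()
            count += 1
            lp = log_const + lg
            if lp <= cutoff:
                total += np.exp(lp)
            return
        # enumerate compositions of rows[i] into c cells bounded by colrem
        cells = [0] * c

        def rec_cell(j: int, rem: int, lg_row: float, colrem2: tuple[int, ...]):
            nonlocal count
            if j == c - 1:
                if rem > colrem2[j]:
                    return
                cells[j] = rem
                new_colrem = tuple(
                    colrem2[k] - cells[k] if k >= j else colrem2[k] for k in range(c)
                )
                rec_row(
                    i + 1,
                    tuple(colrem[k] - cells[k] for k in range(c)),
                    lg_acc + lg_row - gammaln(rem + 1.0),
                )
                return
            for v in range(min(rem, colrem2[j]) + 1):
                cells[j] = v
                rec_cell(j + 1, rem - v, lg_row - gammaln(v + 1.0), colrem2)

        rec_cell(0, rows[i], 0.0, colrem)

    class _BudgetExceeded(Exception):
        pass

    try:
        rec_row(0, tuple(cols), 0.0)
    except _BudgetExceeded:
        return None
    return min(float(total), 1.0), count


def fisher_rxc(
    table,
    method: str = "auto",
    max_tables: int = DEFAULT_MAX_TABLES,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
) -> ContingencyResult:
    """Freeman-Halton exact test for an r x c table, Monte Carlo fallback.

    ``method``: "auto" (exact unless the enumeration exceeds ``max_tables``
    visited tables), "exact", or "mc".  Monte Carlo samples margin-preserving
    tables from the conditional distribution (Patefield's algorithm via
    ``scipy.stats.random_table``) and reports the estimate's standard error
    and the seed used.
    """
    t = _validate_counts(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"table must be at least 2x2, got {t.shape}")
    rows = [int(x) for x in t.sum(axis=1)]
    cols = [int(x) for x in t.sum(axis=0)]
    log_const = (
        gammaln(np.asarray(rows) + 1.0).sum()
        + gammaln(np.asarray(cols) + 1.0).sum()
        - gammaln(t.sum() + 1.0)
    )
    p_obs_log = _log_table_prob(t.ravel().astype(float), log_const)

    if method in ("auto", "exact"):
        res = _enumerate_rxc(rows, cols, p_obs_log, max_tables)
        if res is not None:
            p, n_tables = res
            return ContingencyResult(
                table=t, method="FISHER_RxC_EXACT", p_raw=p, n_tables=n_tables
            )
        if method == "exact":
            raise ValueError(
                f"exact enumeration exceeds the {max_tables}-table budget; "
                "use method='mc'"
            )
    if seed is None:
        seed = 0
    rng = np.random.default_rng(seed)
    dist = sps.random_table(rows, cols, seed=rng)
    hits = 0
    done = 0
    batch = 100_000
    cutoff = p_obs_log + np.log1p(_PROB_RTOL)
    while done < mc_reps:
        k = min(batch, mc_reps - done)
        samples = dist.rvs(k, method="patefield")
        lp = log_const - gammaln(samples + 1.0).sum(axis=(1, 2))
        hits += int((lp <= cutoff).sum())
        done += k
    p = hits / mc_reps
    se = float(np.sqrt(p * (1.0 - p) / mc_reps))
    return ContingencyResult(
        table=t, method="FISHER_RxC_MC", p_raw=p, mc_reps=mc_reps, mc_seed=seed, mc_se=se
    )


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    normal approximation with tie and continuity correction."""
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of a location difference
        return float(len(a) * len(b) / 2.0), 1.0
    ties = len(np.unique(pooled)) < pooled.size
    if not ties and (a.size + b.size) <= MW_EXACT_MAX_N:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a, b, alpha_normality: float = 0.05, method: str = "auto"
) -> GroupComparisonResult:
    """Normality-gated two-group location comparison.

    With ``method='auto'``: Shapiro-Wilk on each group (needs n >= 3 per
    group); Student's t test when both groups pass the gate at
    ``alpha_normality``, Mann-Whitney U otherwise or when either group is too
    small for the gate.  ``method='t'`` / ``'mannwhitney'`` bypass the gate.
    """
    if method not in ("auto", "t", "mannwhitney"):
        raise ValueError(f"unknown method: {method!r}")
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    sw_a = sw_b = None
    gate_ok = method == "t"
    if method == "auto" and a.size >= 3 and b.size >= 3:
        # Shapiro-Wilk is undefined for constant data; treat as non-normal
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            sw_a = float(sps.shapiro(a).pvalue)
            sw_b = float(sps.shapiro(b).pvalue)
            gate_ok = sw_a > alpha_normality and sw_b > alpha_normality
    if gate_ok:
        res = sps.ttest_ind(a, b)
        return GroupComparisonResult(
            n_a=a.size,
            n_b=b.size,
            normality_p=(sw_a, sw_b),
            test_used="T_TEST",
            statistic=float(res.statistic),
            p_raw=float(res.pvalue),
        )
    stat, p = _mannwhitney(a, b)
    return GroupComparisonResult(
        n_a=a.size,
        n_b=b.size,
        normality_p=(sw_a, sw_b),
        test_used="MANN_WHITNEY",
        statistic=stat,
        p_raw=p,
    )


def correlate(x, y, alpha_normality: float = 0.05, method: str | None = None) -> CorrelationResult:
    """Normality-gated correlation of paired values.

    Pearson when both marginals pass the Shapiro-Wilk gate (or
    ``method='pearson'``), Spearman otherwise.  Pairs with any missing value
    are dropped; n >= 3 complete pairs are required.  Zero marginal variance
    yields an undefined r flagged ``degenerate``.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete pairs")
    xv = df["x"].to_numpy(float)
    yv = df["y"].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(
            method=method.upper() if method else "PEARSON",
            r=float("nan"),
            p_raw=float("nan"),
            n=len(df),
            degenerate=True,
        )
    if method is None:
        sw_x = sps.shapiro(xv).pvalue
        sw_y = sps.shapiro(yv).pvalue
        method = "pearson" if (sw_x > alpha_normality and sw_y > alpha_normality) else "spearman"
    method = method.lower()
    if method == "pearson":
        res = sps.pearsonr(xv, yv)
    elif method == "spearman":
        res = sps.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return CorrelationResult(
        method=method.upper(),
        r=float(res.statistic),
        p_raw=float(res.pvalue),
        n=len(df),
    )


def bonferroni(p_raw: float, family_size: int) -> float:
    """Bonferroni-corrected p: min(1, p_raw * family_size)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    return min(1.0, p_raw * family_size)
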