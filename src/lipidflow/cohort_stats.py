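"""Cohort characteristic statistics: exact contingency-table tests,
summary-based Welch t tests, binary-binary correlation, and a
"table one" report.

The R x C exact test is the Freeman-Halton generalization of Fisher's
test: with both margins fixed, the p-value is the total generalized
hypergeometric probability of every table no more probable than the one
observed.  Enumeration is depth-first over the margin-constrained cell
polytope; a permutation Monte-Carlo estimate is available for tables too
large to enumerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "fisher_exact_2x2", "fisher_exact_rxc", "welch_t_from_summary",
    "phi_coefficient", "table_one",
]

#: Relative tolerance when comparing table probabilities to the observed
#: one, so floating-point noise does not drop exactly-tied tables.
_TIE_EPS = 1e-7


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return t


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    Returns ``(p, odds_ratio)`` where the p-value sums the hypergeometric
    probabilities of all same-margin tables at most as probable as the
    observed one, and the odds ratio is the sample cross-product ratio
    ``(a*d)/(b*c)`` (``inf`` when ``b*c == 0`` with a positive numerator,
    ``nan`` for 0/0).  A table with a zero row or column margin carries no
    information; by convention ``p = 1``.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    a, b, c, d = t.ravel()
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        p = 1.0
    else:
        p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = float(a * d) / float(b * c)
    return p, odds


def _log_table_prob(t: np.ndarray, log_fact_margins: float, log_fact_n: float) -> float:
    return log_fact_margins - log_fact_n - gammaln(t + 1.0).sum()


def _count_tables_bound(row_m, col_m) -> float:
    """Crude upper bound on the enumeration size (product of per-cell ranges)."""
    bound = 1.0
    for r in row_m[:-1]:
        for c in col_m[:-1]:
            bound *= min(r, c) + 1
    return bound


def fisher_exact_rxc(table, max_tables: float = 2e7) -> float:
    """Freeman-Halton exact two-sided p for an R x C table.

    Enumerates every table sharing the observed margins via depth-first
    recursion and sums the generalized hypergeometric probabilities of
    those at most as probable as the observed table.  Raises for tables
    whose enumeration would be infeasible, advising
    :func:`fisher_exact_rxc_montecarlo`.
    """
    t = _as_table(table)
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    keep_r = row_m > 0
    keep_c = col_m > 0
    t = t[np.ix_(keep_r, keep_c)]
    row_m, col_m = row_m[keep_r], col_m[keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if _count_tables_bound(row_m, col_m) > max_tables:
        raise ValueError(
            "table too large for exact enumeration; use "
            "fisher_exact_rxc_montecarlo(table, n_draws, seed)")

    n = int(t.sum())
    log_fact_margins = gammaln(row_m + 1.0).sum() + gammaln(col_m + 1.0).sum()
    log_fact_n = float(gammaln(n + 1.0))
    logp_obs = _log_table_prob(t, log_fact_margins, log_fact_n)
    cut = logp_obs + _TIE_EPS

    R, C = t.shape
    p_total = 0.0

    def recurse(row: int, col_rem: np.ndarray, acc_log_fact: float) -> None:
        nonlocal p_total
        if row == R - 1:
            # last row forced by remaining column margins
            logp = (log_fact_margins - log_fact_n - acc_log_fact
                    - gammaln(col_rem + 1.0).sum())
            if logp <= cut:
                p_total += math.exp(logp)
            return
        # fill row `row` cell by cell under margin constraints
        def fill(col: int, rem_row: int, col_rem: np.ndarray, acc: float) -> None:
            if col == C - 1:
                if rem_row <= col_rem[col]:
                    nxt = col_rem.copy()
                    nxt[col] -= rem_row
                    recurse(row + 1, nxt, acc + math.lgamma(rem_row + 1))
                return
            tail = int(col_rem[col + 1:].sum())
            lo = max(0, rem_row - tail)
            hi = min(rem_row, int(col_rem[col]))
            for v in range(lo, hi + 1):
                nxt = col_rem.copy()
                nxt[col] -= v
                fill(col + 1, rem_row - v, nxt, acc + math.lgamma(v + 1))
        fill(0, int(row_m[row]), col_rem, acc_log_fact)

    recurse(0, col_m.astype(np.int64).copy(), 0.0)
    return min(1.0, p_total)


def fisher_exact_rxc_montecarlo(table, n_draws: int = 100_000,
                                seed: int = 0) -> tuple[float, float]:
    """Permutation Monte-Carlo estimate of the Freeman-Halton p.

    Draws same-margin tables by randomly pairing row and column labels;
    returns ``(p_hat, standard_error)``.
    """
    t = _as_table(table)
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    n = int(t.sum())
    log_fact_margins = gammaln(row_m + 1.0).sum() + gammaln(col_m + 1.0).sum()
    log_fact_n = float(gammaln(n + 1.0))
    logp_obs = _log_table_prob(t, log_fact_margins, log_fact_n)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1)
        if _log_table_prob(sim, log_fact_margins, log_fact_n) <= logp_obs + _TIE_EPS:
            hits += 1
    p = hits / n_draws
    return p, math.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws)


@dataclass
class GroupSummary:
    """Mean, SD and size of one group of a continuous variable."""
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch unequal-variance t test from group summaries.

    Returns ``(t, df, p_two_sided)`` with the Welch-Satterthwaite degrees
    of freedom.  Two zero-SD groups with equal means give ``t=0, p=1``.
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0:
        return 0.0, float(a.n + b.n - 2), 1.0
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def phi_coefficient(table) -> float:
    """Phi coefficient of a 2x2 table: the Pearson correlation of the two
    0/1 encodings, ``(ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))``."""
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    a, b, c, d = t.ravel()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("phi undefined: a zero margin")
    return float((a * d - b * c) / math.sqrt(denom))


def table_one(clinical: pd.DataFrame, group_var: str = "status") -> pd.DataFrame:
    """Per-variable group summaries with the appropriate test.

    Continuous variables get a Welch t test; categorical variables get the
    exact Fisher / Freeman-Halton test on the level x group count table.
    Constant variables are summarized with the test skipped.
    """
    if group_var not in clinical.columns:
        raise KeyError(group_var)
    groups = clinical[group_var]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"group variable {group_var!r} must be binary")
    if (groups.value_counts() == 0).any():
        raise ValueError("empty group")
    g0, g1 = levels
    rows = []
    for var in clinical.columns:
        if var == group_var:
            continue
        x = clinical[var]
        is_continuous = pd.api.types.is_numeric_dtype(x) and x.nunique() > 5
        if x.nunique() <= 1:
            rows.append({"variable": var, "test": "skipped (constant)",
                         "statistic": math.nan, "p": math.nan,
                         "summary": f"constant = {x.iloc[0]!r}"})
            continue
        if is_continuous:
            a = GroupSummary(x[groups == g1].mean(), x[groups == g1].std(ddof=1),
                             int((groups == g1).sum()))
            b = GroupSummary(x[groups == g0].mean(), x[groups == g0].std(ddof=1),
                             int((groups == g0).sum()))
            t, df, p = welch_t_from_summary(a, b)
            rows.append({"variable": var, "test": "welch_t", "statistic": t, "p": p,
                         "summary": f"{g1}: {a.mean:.2f} ({a.sd:.2f}); "
                                    f"{g0}: {b.mean:.2f} ({b.sd:.2f})"})
        else:
            ct = pd.crosstab(x, groups)
            tab = ct.to_numpy()
            if tab.shape == (2, 2):
                p, _ = fisher_exact_2x2(tab)
                name = "fisher_exact"
            else:
                p = fisher_exact_rxc(tab)
                name = "freeman_halton"
            rows.append({"variable": var, "test": name, "statistic": math.nan,
                         "p": p, "summary": "; ".join(
                             f"{lvl}: {ct.loc[lvl, g0]}/{ct.loc[lvl, g1]}"
                             for lvl in ct.index)})
    return pd.DataFrame(rows).set_index("variable")
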