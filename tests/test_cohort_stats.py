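"""Exact contingency tests, Welch t from summaries, phi, and table-one."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

from lipidflow import datasets
from lipidflow.cohort_stats import (GroupSummary, fisher_exact_2x2,
                                    fisher_exact_rxc,
                                    fisher_exact_rxc_montecarlo,
                                    phi_coefficient, table_one,
                                    welch_t_from_summary)


def enumerate_fisher_2x2(table):
    """Independent oracle: enumerate every 2x2 table with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def logp(aa):
        bb, cc, dd = r1 - aa, c1 - aa, r2 - (c1 - aa)
        return (gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1)
                + gammaln(n - c1 + 1) - gammaln(n + 1) - gammaln(aa + 1)
                - gammaln(bb + 1) - gammaln(cc + 1) - gammaln(dd + 1))

    lp_obs = logp(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = logp(aa)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


class TestFisher2x2:
    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p, _ = fisher_exact_2x2(t)
            assert p == pytest.approx(enumerate_fisher_2x2(t), rel=1e-9)

    def test_balanced_table_has_no_association(self):
        p, odds = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0
        assert odds == 1.0

    def test_zero_margin_convention(self):
        p, odds = fisher_exact_2x2([[0, 0], [5, 7]])
        assert p == 1.0
        assert math.isnan(odds)

    def test_odds_ratio_infinite_when_offdiagonal_empty(self):
        _, odds = fisher_exact_2x2([[5, 0], [0, 7]])
        assert math.isinf(odds)

    @given(st.integers(1, 15), st.integers(1, 15), st.integers(1, 15),
           st.integers(1, 15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_row_and_column_swaps(self, a, b, c, d):
        t = [[a, b], [c, d]]
        p0, _ = fisher_exact_2x2(t)
        assert 0 < p0 <= 1
        for variant in ([[c, d], [a, b]], [[b, a], [d, c]]):
            assert fisher_exact_2x2(variant)[0] == pytest.approx(p0, rel=1e-12)


class TestFreemanHalton:
    def test_reduces_to_2x2_fisher(self):
        t = [[3, 9], [11, 4]]
        assert fisher_exact_rxc(t) == pytest.approx(fisher_exact_2x2(t)[0],
                                                    rel=1e-9)

    def test_matches_montecarlo_within_3_se(self):
        t = [[4, 9], [7, 2], [3, 8]]
        exact = fisher_exact_rxc(t)
        p_hat, se = fisher_exact_rxc_montecarlo(t, n_draws=100_000, seed=2)
        assert abs(p_hat - exact) < 3 * se

    def test_probabilities_sum_to_one_over_margin_polytope(self):
        # p at an impossible-to-beat threshold = full polytope mass
        t = np.array([[2, 3], [4, 1], [0, 5]])
        import lipidflow.cohort_stats as cs
        old = cs._TIE_EPS
        try:
            cs._TIE_EPS = 1e9   # accept every table
            assert fisher_exact_rxc(t) == pytest.approx(1.0, abs=1e-9)
        finally:
            cs._TIE_EPS = old

    def test_infeasible_table_advises_montecarlo(self):
        big = np.full((6, 6), 40)
        with pytest.raises(ValueError, match="montecarlo"):
            fisher_exact_rxc(big)


class TestWelch:
    def test_matches_vector_based_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1.5, size=rng.integers(5, 40))
            y = rng.normal(0.4, 0.8, size=rng.integers(5, 40))
            t, df, p = welch_t_from_summary(
                GroupSummary(x.mean(), x.std(ddof=1), len(x)),
                GroupSummary(y.mean(), y.std(ddof=1), len(y)))
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_summaries(self):
        s = GroupSummary(5.0, 1.0, 10)
        t, _, p = welch_t_from_summary(s, s)
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance(self):
        t, _, p = welch_t_from_summary(GroupSummary(1.0, 0.0, 5),
                                       GroupSummary(1.0, 0.0, 5))
        assert (t, p) == (0.0, 1.0)


class TestPhi:
    def test_perfect_association(self):
        assert phi_coefficient([[10, 0], [0, 10]]) == 1.0

    def test_equals_pearson_on_expanded_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            x = np.repeat([0, 0, 1, 1], t.ravel())
            y = np.repeat([0, 1, 0, 1], t.ravel())
            assert phi_coefficient(t) == pytest.approx(
                np.corrcoef(x, y)[0, 1], rel=1e-10)

    def test_sign_flips_with_encoding(self):
        t = np.array([[12, 3], [4, 9]])
        assert phi_coefficient(t) == pytest.approx(
            -phi_coefficient(t[:, ::-1]), rel=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            phi_coefficient([[0, 0], [3, 4]])


def reference_clinical_table() -> pd.DataFrame:
    """Deterministic expansion of the published cohort counts into one
    sample-per-row clinical table (continuous columns omitted)."""
    rows = []
    for grp, gi in (("control", 0), ("case", 1)):
        n = datasets.N_CONTROL if grp == "control" else datasets.N_CASE
        block = {"status": [gi] * n}
        for var, levels in datasets.CATEGORICAL.items():
            vals = []
            for level, counts in levels.items():
                vals += [level] * counts[gi]
            block[var] = vals
        rows.append(pd.DataFrame(block))
    out = pd.concat(rows, ignore_index=True)
    out.index = [f"s{i}" for i in range(len(out))]
    return out


class TestTableOne:
    def test_reproduces_published_categorical_pvalues(self):
        report = table_one(reference_clinical_table(), "status")
        expected = {"gestational_diabetes": 0.013, "smoker": 0.088,
                    "chronic_hypertension": 0.085, "abruption": 0.55,
                    "baby_gender": 0.42, "membrane_rupture": 0.25,
                    "parity": 0.017, "ethnicity": 0.22}
        for var, p_ref in expected.items():
            assert report.loc[var, "p"] == pytest.approx(p_ref, abs=0.01), var

    def test_invariant_to_sample_order(self):
        clin = reference_clinical_table()
        shuffled = clin.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(table_one(clin, "status"),
                                      table_one(shuffled, "status"))

    def test_empty_group_rejected(self):
        clin = reference_clinical_table()
        clin["status"] = 1
        with pytest.raises(ValueError):
            table_one(clin, "status")

    def test_constant_variable_skipped(self):
        clin = reference_clinical_table()
        clin["site"] = "honolulu"
        report = table_one(clin, "status")
        assert "constant" in report.loc["site", "test"]
        assert math.isnan(report.loc["site", "p"])
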