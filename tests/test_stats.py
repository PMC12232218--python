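"""Contingency-table inference: chi-square, Fisher exact, logistic ORs.

The Fisher oracle enumerates every margin-consistent table with exact
Fraction arithmetic, independently of the implementation's integer path.
"""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from gccm.cohort import ValidationError
from gccm.stats import (
    ContingencyTable2x2,
    DegenerateTableError,
    TestMethod as StatMethod,
    bivariable_logistic,
    build_table,
    chi2_pearson,
    fisher_exact,
    format_p,
    run_prespecified_associations,
)

# Nine published chi-square worked examples, reconstructed from the printed
# counts and group sizes (rows = exposure yes/no, columns = outcome yes/no).
PRINTED_CHI2_TABLES = {
    "very_high_risk~any_discussion": ([[47, 36], [8, 18]], 5.30),
    "medical_service~any_discussion": ([[74, 16], [9, 10]], 10.49),
    "palliative_consult~high_gcc": ([[19, 24], [9, 57]], 12.73),
    "metastatic_cancer~high_gcc": ([[19, 31], [9, 50]], 7.34),
    "metastatic_cancer~palliative_consult": ([[28, 22], [15, 44]], 10.59),
    "palliative_consult~any_uncertain": ([[26, 17], [59, 7]], 12.69),
    "metastatic_cancer~any_uncertain": ([[34, 16], [51, 8]], 5.36),
    "confident_comfort_vs_life_extension": ([[132, 10], [312, 54]], 5.53),
    "confident_comfort_vs_function": ([[132, 10], [210, 46]], 9.02),
}


def fisher_oracle(a, b, c, d):
    """Small-p rule by full enumeration with exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        p = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestChi2:
    @pytest.mark.parametrize("name,case", PRINTED_CHI2_TABLES.items())
    def test_reproduces_published_statistics_to_2dp(self, name, case):
        table, expected = case
        res = chi2_pearson(ContingencyTable2x2.from_array(table))
        assert round(res.statistic, 2) == expected

    def test_proportional_rows_give_zero_statistic(self):
        res = chi2_pearson(ContingencyTable2x2(10, 20, 20, 40))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi2_pearson(ContingencyTable2x2(5, 0, 7, 0))

    def test_matches_scipy_without_correction(self):
        t = ContingencyTable2x2(12, 7, 3, 21)
        res = chi2_pearson(t)
        ref = scipy.stats.chi2_contingency(t.to_array(), correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_yates_option_matches_scipy_corrected(self):
        t = ContingencyTable2x2(12, 7, 3, 21)
        res = chi2_pearson(t, correction=True)
        ref = scipy.stats.chi2_contingency(t.to_array(), correction=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_invariant_under_transpose_and_row_col_swap(self, cells):
        a, b, c, d = cells
        s0 = chi2_pearson(ContingencyTable2x2(a, b, c, d)).statistic
        assert chi2_pearson(ContingencyTable2x2(a, c, b, d)).statistic == pytest.approx(s0)
        assert chi2_pearson(ContingencyTable2x2(d, c, b, a)).statistic == pytest.approx(s0)


class TestFisher:
    def test_diagonal_five_by_five_example(self):
        res = fisher_exact(ContingencyTable2x2(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252, abs=1e-15)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact(ContingencyTable2x2(3, 3, 3, 3)).p_value == 1.0

    def test_zero_marginal_is_fine_for_fisher(self):
        assert fisher_exact(ContingencyTable2x2(4, 0, 3, 0)).p_value == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            a = 1
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_on_moderate_tables(self):
        for cells in [(8, 2, 1, 9), (5, 5, 5, 5), (10, 0, 2, 8), (1, 7, 6, 2)]:
            mine = fisher_exact(ContingencyTable2x2(*cells)).p_value
            ref = scipy.stats.fisher_exact(np.array(cells).reshape(2, 2)).pvalue
            assert mine == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("cells", [(130, 70, 90, 110), (125, 75, 95, 105),
                                       (600, 400, 500, 500)])
    def test_large_balanced_tables_agree_with_chi2(self, cells):
        t = ContingencyTable2x2(*cells)
        p_chi = chi2_pearson(t).p_value
        p_fish = fisher_exact(t).p_value
        assert abs(p_chi - p_fish) < 0.01


class TestLogistic:
    def test_or_equals_cross_product_ratio(self):
        # table [[19,24],[9,57]] as predictor/outcome vectors
        y = np.r_[np.ones(19), np.zeros(24), np.ones(9), np.zeros(57)]
        x = np.r_[np.ones(43), np.zeros(66)]
        res = bivariable_logistic(y, x)
        expected = (19 * 57) / (24 * 9)
        assert res.odds_ratio == pytest.approx(expected, rel=1e-6)
        assert res.or_ci[0] < expected < res.or_ci[1]

    def test_independent_predictor_gives_or_one(self):
        y = np.r_[np.ones(25), np.zeros(25), np.ones(25), np.zeros(25)]
        x = np.r_[np.ones(50), np.zeros(50)]
        res = bivariable_logistic(y, x)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_zero_cell_flagged_non_estimable(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]  # perfect separation
        res = bivariable_logistic(y, x)
        assert res.estimable is False
        assert "separation_zero_cell" in res.flags

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            bivariable_logistic(np.ones(10), np.r_[np.ones(5), np.zeros(5)])

    @settings(max_examples=20, deadline=None)
    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_binary_or_matches_ad_bc_closed_form(self, cells):
        a, b, c, d = cells
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = bivariable_logistic(y, x)
        assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)


class TestBuildTableAndBatch:
    def _frame(self, n=20):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "palliative_consult": rng.random(n) < 0.4,
            "high_gcc": rng.random(n) < 0.3,
            "always_true": np.ones(n, dtype=bool),
        })

    def test_counts_sum_to_unit_population(self):
        f = self._frame(20)
        t = build_table(f, "palliative_consult", "high_gcc")
        assert t.n == 20

    def test_printed_margins_reconstruct_printed_table(self):
        # 83 patients with a discussion (47 very-high risk) vs 26 without (8)
        f = pd.DataFrame({
            "very_high_risk": [True] * 47 + [False] * 36 + [True] * 8 + [False] * 18,
            "has_any_discussion": [True] * 83 + [False] * 26,
        })
        t = build_table(f, "has_any_discussion", "very_high_risk")
        assert (t.a, t.b, t.c, t.d) == (47, 36, 8, 18)
        assert t.n == 109

    def test_empty_frame_is_configuration_error(self):
        with pytest.raises(ValidationError):
            build_table(pd.DataFrame(), "x", "y")

    def test_missing_covariate_is_configuration_error(self):
        with pytest.raises(ValidationError, match="nope"):
            build_table(self._frame(), "nope", "high_gcc")

    def test_batch_runs_one_row_per_config_item(self):
        f = self._frame(40)
        config = [
            {"exposure": "palliative_consult", "outcome": "high_gcc",
             "unit": "patient", "method": "chi2_pearson"},
            {"exposure": "palliative_consult", "outcome": "high_gcc",
             "unit": "patient", "method": "fisher_exact"},
            {"exposure": "palliative_consult", "outcome": "high_gcc",
             "unit": "patient", "method": "logistic"},
        ]
        out = run_prespecified_associations({"patient": f}, config)
        assert len(out) == 3
        assert set(out["method"]) == {"chi2_pearson", "fisher_exact", "logistic"}

    def test_degenerate_table_falls_back_to_fisher(self):
        f = self._frame(30)
        config = [{"exposure": "always_true", "outcome": "high_gcc",
                   "unit": "patient", "method": "chi2_pearson"}]
        out = run_prespecified_associations({"patient": f}, config)
        assert out.loc[0, "method"] == StatMethod.FISHER_EXACT.value
        assert "fell_back" in out.loc[0, "flags"]

    def test_empty_config_gives_empty_results(self):
        out = run_prespecified_associations({"patient": self._frame()}, [])
        assert out.empty

    def test_journal_p_formatting(self):
        assert format_p(0.0004) == "<.001"
        assert format_p(0.0234) == ".023"
        assert format_p(float("nan")) == "NA"
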