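"""2x2 accuracy metrics, risk ratios, association tests and intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from frailtykit.diagnostics import (
    ContingencyTable2x2,
    association_p,
    crosstab,
    diag_metrics,
    expected_counts,
    risk_ratio,
    rr_ci,
    wilson_ci,
)

tables = (
    st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    .filter(lambda cells: sum(cells) > 0)
    .map(lambda cells: ContingencyTable2x2(*cells))
)


class TestCrosstab:
    def test_single_concordant_pair(self):
        assert crosstab([True], [True]) == ContingencyTable2x2(1, 0, 0, 0)

    def test_perfect_test_has_no_errors(self):
        rng = np.random.default_rng(0)
        cond = rng.random(50) < 0.3
        table = crosstab(cond, cond)
        assert table.fp == table.fn == 0

    def test_expanded_table_round_trips(self):
        from frailtykit.reference import expand_table

        table = ContingencyTable2x2(16, 9, 4, 73)
        test, cond = expand_table(table)
        assert crosstab(test, cond) == table

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crosstab([True, False], [True])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            crosstab([1.0, np.nan], [1.0, 0.0])


class TestDiagMetrics:
    # Printed operating characteristics of two ZFS items vs SEGA frailty.
    @pytest.mark.parametrize(
        "table, se, sp, ppv, npv",
        [
            (ContingencyTable2x2(16, 9, 4, 73), 0.80, 73 / 82, 0.64, 73 / 77),
            (ContingencyTable2x2(17, 38, 3, 44), 0.85, 44 / 82, 17 / 55, 44 / 47),
        ],
    )
    def test_published_item_examples(self, table, se, sp, ppv, npv):
        m = diag_metrics(table)
        assert m.sensitivity == pytest.approx(se, abs=1e-12)
        assert m.specificity == pytest.approx(sp, abs=1e-12)
        assert m.ppv == pytest.approx(ppv, abs=1e-12)
        assert m.npv == pytest.approx(npv, abs=1e-12)
        assert m.youden == pytest.approx(se + sp - 1, abs=1e-12)

    def test_zero_denominator_flagged_not_zeroed(self):
        m = diag_metrics(ContingencyTable2x2(0, 0, 5, 7))
        assert m.sensitivity == 0
        assert m.ppv is None
        assert "ppv" in m.undefined

    @given(table=tables)
    @settings(derandomize=True, max_examples=200)
    def test_metrics_bounded(self, table):
        m = diag_metrics(table)
        for value in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert value is None or 0 <= value <= 1
        if m.youden is not None:
            assert -1 <= m.youden <= 1


class TestRiskRatio:
    def test_aid_at_home_value(self):
        assert risk_ratio(ContingencyTable2x2(16, 9, 4, 73)) == pytest.approx(12.32, abs=0.005)

    def test_weight_loss_value(self):
        assert risk_ratio(ContingencyTable2x2(4, 2, 16, 80)) == pytest.approx(4.00, abs=0.005)

    def test_equal_risks_give_one(self):
        assert risk_ratio(ContingencyTable2x2(3, 7, 6, 14)) == pytest.approx(1.0)

    def test_zero_negative_risk_is_flagged_infinite(self):
        assert math.isinf(risk_ratio(ContingencyTable2x2(3, 2, 0, 10)))

    def test_empty_test_positive_group_undefined(self):
        assert risk_ratio(ContingencyTable2x2(0, 0, 3, 7)) is None

    @given(table=tables)
    @settings(derandomize=True, max_examples=200)
    def test_reciprocal_symmetry(self, table):
        """Swapping test-positive and test-negative rows inverts the risk ratio."""
        rr = risk_ratio(table)
        rr_swapped = risk_ratio(table.swapped_test())
        if rr is None or rr_swapped is None or rr == 0 or math.isinf(rr):
            return
        assert rr * rr_swapped == pytest.approx(1.0, rel=1e-12)


def fisher_two_sided_by_enumeration(table: ContingencyTable2x2) -> float:
    """Independent oracle: exhaustive hypergeometric enumeration (point-probability rule)."""
    row1 = table.tp + table.fp
    col1 = table.tp + table.fn
    n = table.n
    pmf = stats.hypergeom(n, col1, row1).pmf
    observed = pmf(table.tp)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = pmf(k)
        if p <= observed * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestAssociationP:
    def test_weight_loss_fisher(self):
        result = association_p(ContingencyTable2x2(4, 2, 16, 80))
        assert result.method == "fisher_exact"
        assert round(result.p_value, 3) == 0.013

    def test_memory_yates_chi_square(self):
        result = association_p(ContingencyTable2x2(19, 16, 17, 50))
        assert result.method == "chi2_yates"
        assert round(result.p_value, 3) == 0.007

    def test_independent_table(self):
        result = association_p(ContingencyTable2x2(5, 5, 5, 5))
        assert result.p_value == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        result = association_p(ContingencyTable2x2(0, 0, 5, 7))
        assert result.degenerate and result.p_value == 1.0

    def test_method_rule_follows_expected_counts(self):
        small = ContingencyTable2x2(4, 2, 16, 80)
        large = ContingencyTable2x2(19, 16, 17, 50)
        assert expected_counts(small).min() < 5
        assert expected_counts(large).min() >= 5

    @given(table=tables.filter(lambda t: t.n <= 60 and min(t.tp + t.fp, t.fn + t.tn) > 0
                               and min(t.tp + t.fn, t.fp + t.tn) > 0))
    @settings(derandomize=True, max_examples=150)
    def test_fisher_matches_exhaustive_enumeration(self, table):
        """The Fisher p equals the sum of hypergeometric point probabilities <= observed."""
        ours = stats.fisher_exact(table.as_array(), alternative="two-sided").pvalue
        oracle = fisher_two_sided_by_enumeration(table)
        assert ours == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestWilsonCI:
    def test_zero_successes_lower_bound(self):
        lo, hi = wilson_ci(0, 20)
        assert lo == 0.0 and hi > 0

    def test_all_successes_upper_bound(self):
        lo, hi = wilson_ci(20, 20)
        assert hi == 1.0 and lo < 1

    def test_bracketed_by_clopper_pearson(self):
        """Wilson is narrower than (and centred within) the exact binomial interval."""
        k, n, level = 17, 20, 0.95
        lo, hi = wilson_ci(k, n, level)
        alpha = 1 - level
        cp_lo = stats.beta.ppf(alpha / 2, k, n - k + 1)
        cp_hi = stats.beta.isf(alpha / 2, k + 1, n - k)
        assert cp_lo - 0.01 < lo < hi < cp_hi + 0.01
        assert lo < k / n < hi

    @given(k=st.integers(0, 50), extra=st.integers(0, 50))
    @settings(derandomize=True, max_examples=100)
    def test_contains_point_estimate(self, k, extra):
        n = k + extra
        if n == 0:
            return
        lo, hi = wilson_ci(k, n)
        assert 0 <= lo <= k / n <= hi <= 1


class TestRrCI:
    def test_null_table_straddles_one(self):
        lo, hi = rr_ci(ContingencyTable2x2(30, 70, 30, 70))
        assert lo < 1 < hi

    def test_symmetric_minimal_table_is_wide(self):
        lo, hi = rr_ci(ContingencyTable2x2(1, 1, 1, 1))
        assert lo < 1 < hi and hi / lo > 10

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            rr_ci(ContingencyTable2x2(3, 0, 2, 5))

    def test_aid_interval_matches_bootstrap(self):
        """Katz log interval vs a 10^4-resample percentile bootstrap of the same table."""
        table = ContingencyTable2x2(16, 9, 4, 73)
        lo, hi = rr_ci(table)
        assert lo < 12.32 < hi
        rng = np.random.default_rng(20210904)
        probs = np.array([table.tp, table.fp, table.fn, table.tn]) / table.n
        draws = rng.multinomial(table.n, probs, size=10_000)
        tp, fp, fn, tn = draws.T
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (tp / (tp + fp)) / (fn / (fn + tn))
        rr = rr[np.isfinite(rr) & (rr > 0)]
        boot_lo, boot_hi = np.percentile(rr, [2.5, 97.5])
        # agreement on the log scale within ~25%: the bootstrap is itself noisy
        assert math.log(lo) == pytest.approx(math.log(boot_lo), abs=0.25 * abs(math.log(boot_lo)))
        assert math.log(hi) == pytest.approx(math.log(boot_hi), abs=0.25 * abs(math.log(boot_hi)))
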