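"""Fisher exact test, odds ratios, and carrier-fraction summaries."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from xburden import (
    ContingencyTable,
    FilterConfig,
    associate,
    carrier_table,
    fisher_exact_two_sided,
    load_tlr7_case_roster,
    odds_ratio,
    summarize_carriers,
)


def enumeration_oracle(a, b, c, d):
    """Exact rational two-sided p by full enumeration of the hypergeometric
    distribution over all tables with the observed margins."""
    n = a + b + c + d
    row1, col = a + b, b + d
    denom = comb(n, col)
    p_obs = Fraction(comb(row1, b) * comb(n - row1, d), denom)
    total = Fraction(0)
    for k in range(max(0, col - (n - row1)), min(row1, col) + 1):
        pk = Fraction(comb(row1, k) * comb(n - row1, col - k), denom)
        if pk <= p_obs:
            total += pk
    return float(total)


class TestFisher:
    def test_combined_cohort_table(self):
        # 135 severe (6 carriers) vs 104 asymptomatic (0 carriers)
        p = fisher_exact_two_sided([[129, 6], [104, 0]])
        assert round(p, 3) == 0.037
        assert p == pytest.approx(enumeration_oracle(129, 6, 104, 0), abs=1e-12)

    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_five(self):
        assert fisher_exact_two_sided([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert p == pytest.approx(enumeration_oracle(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_invariant_to_simultaneous_row_and_column_swap(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p1 = fisher_exact_two_sided([[a, b], [c, d]])
        p2 = fisher_exact_two_sided([[d, c], [b, a]])
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[0, 0], [0, 0]])


class TestOddsRatio:
    def test_corrected_study_table(self):
        est, corrected = odds_ratio([[129, 6], [104, 0]])
        assert corrected
        assert est == pytest.approx((6.5 / 129.5) / (0.5 / 104.5), rel=1e-12)

    def test_identical_rows_give_unity(self):
        est, corrected = odds_ratio([[10, 5], [10, 5]])
        assert est == pytest.approx(1.0)
        assert not corrected

    def test_degenerate_carrier_column_flagged(self):
        est, corrected = odds_ratio([[10, 0], [10, 0]])
        assert np.isnan(est)
        assert not corrected

    def test_uncorrected_zero_cell_is_infinite(self):
        est, corrected = odds_ratio([[129, 6], [104, 0]], correction=False)
        assert np.isinf(est)


class TestCarrierTable:
    def test_cross_tabulation(self):
        flags = [True] * 6 + [False] * 129 + [False] * 104
        arms = [1] * 135 + [0] * 104
        t = carrier_table(flags, arms)
        assert t.to_array().tolist() == [[129, 6], [104, 0]]

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            carrier_table([], [])

    def test_all_carriers_consistent_margins(self):
        t = carrier_table([True, True, True], [1, 1, 0])
        assert t.severe_noncarrier == 0 and t.asympt_noncarrier == 0
        assert sum(t.counts) == 3

    def test_non_binary_arm_errors(self):
        with pytest.raises(ValueError):
            carrier_table([True, False], ["case", "excluded"])


def test_associate_end_to_end():
    flags = [True] * 6 + [False] * 129 + [False] * 104
    arms = [1] * 135 + [0] * 104
    res = associate(flags, arms)
    assert round(res.p_value, 3) == 0.037
    assert res.carrier_fraction_severe == pytest.approx(6 / 135)
    assert res.carrier_fraction_asympt == 0.0


class TestSummarizeCarriers:
    @pytest.fixture()
    def summary(self):
        return summarize_carriers(load_tlr7_case_roster()).set_index(["stratum", "rule"])

    def test_candidate_rule_young_carriers(self, summary):
        row = summary.loc[("young", "candidate")]
        assert row["carriers"] == 6
        assert row["denominator"] == 135

    def test_functional_young_fraction(self, summary):
        row = summary.loc[("young", "functional")]
        assert row["carriers"] == 3
        assert row["percent"] == "2.2%"

    def test_functional_all_age_fraction(self, summary):
        row = summary.loc[("all_ages", "functional")]
        assert row["carriers"] == 5
        assert row["percent"] == "1.9%"

    def test_shared_variant_counts_patients_once_each(self):
        roster = load_tlr7_case_roster()
        # P7 and P8 share one variant yet count as two carriers
        allages = summarize_carriers(roster).set_index(["stratum", "rule"])
        assert allages.loc[("all_ages", "candidate"), "carriers"] == 8

    def test_unknown_functional_class_errors(self):
        roster = load_tlr7_case_roster()
        roster.loc[0, "function"] = "GAIN"
        with pytest.raises(ValueError, match="unknown functional class"):
            summarize_carriers(roster)

    def test_missing_af_counts_as_rare(self):
        roster = load_tlr7_case_roster()
        # Ser301Pro has no population AF yet qualifies under the default rule
        cfg = FilterConfig(missing_maf_is_rare=False)
        with_na = summarize_carriers(roster).set_index(["stratum", "rule"])
        without_na = summarize_carriers(roster, cfg).set_index(["stratum", "rule"])
        assert (
            with_na.loc[("young", "candidate"), "carriers"]
            == without_na.loc[("young", "candidate"), "carriers"] + 1
        )
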