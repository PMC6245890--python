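"""Diagnostic-accuracy statistics against independent enumeration oracles."""

import math
from fractions import Fraction


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermiperf.exceptions import InputError
from fermiperf.phantom import make_reader_calls
from fermiperf.stats import (ConfusionCounts, accuracy_stats, confusion,
                             group_compare, mcnemar, proportions_test,
                             reference_study_report, round_half_up)


class TestConfusion:
    def test_perfect_calls(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 2)

    def test_inverted_calls(self):
        c = confusion([0, 1, 0, 1], [1, 0, 1, 0])
        assert (c.tp, c.tn) == (0, 0)

    def test_hand_counted_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            confusion([1, 0], [1])


class TestAccuracyStats:
    def test_reference_quantitative_row(self):
        out = accuracy_stats(ConfusionCounts(tp=11, fp=2, tn=33, fn=5))
        assert out["sensitivity_pct"] == 68.8
        assert out["specificity_pct"] == 94.3
        assert out["agreement_pct"] == 86.3

    def test_matches_rational_arithmetic(self):
        # percentages agree with exact Fraction arithmetic before rounding
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 40, size=4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            out = accuracy_stats(c)
            if tp + fn:
                exact = Fraction(100 * int(tp), int(tp + fn))
                assert out["sensitivity_pct"] == round_half_up(float(exact))
            else:
                assert math.isnan(out["sensitivity_pct"])

    def test_clopper_pearson_bounds_bracket_estimate(self):
        out = accuracy_stats(ConfusionCounts(tp=11, fp=2, tn=33, fn=5))
        lo, hi = out["sensitivity_ci_pct"]
        assert lo < 68.8 < hi
        # exact interval for 11/16 from the beta quantile definition
        from scipy.stats import beta
        assert lo == pytest.approx(
            round_half_up(100 * beta.ppf(0.025, 11, 6)), abs=1e-9)
        assert hi == pytest.approx(
            round_half_up(100 * beta.ppf(0.975, 12, 5)), abs=1e-9)


class TestMcNemar:
    def test_symmetric_discordance_capped_at_one(self):
        assert mcnemar(4, 4) == 1.0

    def test_one_sided_discordance(self):
        assert mcnemar(5, 0) == pytest.approx(2 * 0.5 ** 5)

    def test_exact_binomial_example(self):
        assert mcnemar(10, 2) == pytest.approx(158 / 4096)

    def test_matches_enumeration_for_all_small_tables(self):
        # independent oracle: exact binomial tail by direct summation
        for n in range(0, 13):
            for b in range(n + 1):
                c = n - b
                if n == 0:
                    expected = 1.0
                else:
                    m = min(b, c)
                    tail = sum(math.comb(n, i) for i in range(m + 1)) / 2 ** n
                    expected = min(1.0, 2 * tail)
                assert mcnemar(b, c) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 30), st.integers(0, 30))
    def test_symmetry(self, b, c):
        assert mcnemar(b, c) == mcnemar(c, b)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            mcnemar(-1, 2)


class TestGroupCompare:
    def test_identical_groups_give_f_zero(self):
        res = group_compare({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_anova_on_nine_numbers(self):
        groups = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [101, 102, 103]}
        # closed-form one-way ANOVA oracle
        all_vals = np.concatenate([groups[g] for g in groups])
        grand = all_vals.mean()
        ssb = sum(3 * (np.mean(groups[g]) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(groups[g]) - np.mean(groups[g])) ** 2)
                  for g in groups)
        f_oracle = (ssb / 2) / (ssw / 6)
        res = group_compare(groups)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-12)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(size=8) for g in "abc"}
        res = group_compare(groups)
        assert len(res.pairwise) == 3
        for row in res.pairwise.itertuples():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * 3))

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InputError):
            group_compare({"a": [1.0], "b": [1, 2]})


class TestProportions:
    def test_identical_large_proportions(self):
        assert proportions_test(50, 100, 50, 100, "chi2") == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # oracle: two-sided Fisher by summing hypergeometric probabilities
        # not exceeding the observed table's probability
        from scipy.stats import hypergeom

        def fisher_oracle(a, n1, b, n2):
            k = a + b
            rv = hypergeom(n1 + n2, n1, k)
            p_obs = rv.pmf(a)
            support = np.arange(max(0, k - n2), min(k, n1) + 1)
            return float(rv.pmf(support)[rv.pmf(support)
                                         <= p_obs * (1 + 1e-9)].sum())

        cases = [(10, 10, 0, 10), (3, 12, 9, 14), (0, 8, 5, 9), (7, 20, 7, 20)]
        for a, n1, b, n2 in cases:
            assert proportions_test(a, n1, b, n2, "fisher") == \
                pytest.approx(fisher_oracle(a, n1, b, n2), rel=1e-6)

    def test_fisher_extreme_table(self):
        # [[10,0],[0,10]]: 2/C(20,10) mass in the two extreme tables
        assert proportions_test(10, 10, 0, 10, "fisher") == \
            pytest.approx(2 / 184756, rel=1e-9)

    def test_chi2_closed_form(self):
        # [[20,10],[10,20]]: hand-computed statistic 20/3
        from scipy.stats import chi2
        p = proportions_test(20, 30, 10, 30, "chi2")
        assert p == pytest.approx(float(chi2.sf(20 / 3, 1)), rel=1e-12)

    def test_zero_margin_requires_fisher(self):
        with pytest.raises(InputError):
            proportions_test(0, 5, 0, 7, "chi2")
        assert proportions_test(0, 5, 0, 7, "fisher") == pytest.approx(1.0)


class TestReferenceReport:
    def test_all_rows_reproduce_printed_values(self):
        report = reference_study_report()
        assert report["pass"].all()
        vals = dict(zip(report.quantity, report.value_pct))
        assert vals["prevalence_pct"] == 30.2
        assert vals["quant_agreement_pct"] == 86.3
        assert vals["concordance_with_failures_pct"] == 83.0
        assert vals["specificity_with_failures_pct"] == 89.2
        assert vals["two_vessel_share_pct"] == 31.3
        assert vals["rca_lesion_prevalence_pct"] == 24.5

    def test_reader_level_ordering_reproduced(self):
        # simulated reader groups at the three competency levels recover
        # the accuracy ordering level3 > level2 > level1
        nominal = {"level1": (0.865, 0.419), "level2": (0.573, 0.694),
                   "level3": (0.719, 0.887)}
        acc = {}
        for i, (name, (sens, spec)) in enumerate(nominal.items()):
            accs = []
            for rep in range(30):
                df = make_reader_calls(53, 16 / 53, sens, spec,
                                       seed=1000 * i + rep)
                accs.append((df.call == df.truth).mean())
            acc[name] = np.mean(accs)
        assert acc["level3"] > acc["level2"] > acc["level1"]
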