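"""Burden statistics: odds ratios, exact conditional CIs, chi-square,
Fisher exact and t test, checked against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from triowes import (ContingencyTable, build_exposure_table, compute_burden,
                     conditional_mle_or, exact_or_ci, fisher_exact,
                     odds_ratio, pearson_chi_square, two_sample_t,
                     woolf_or_ci)
from triowes.cohort import TrioPedigree
from triowes.stats import TableError


def enum_tail_probability(t: ContingencyTable, psi: float, tail: str) -> float:
    """Enumeration oracle: noncentral hypergeometric tail probability
    computed from exact binomial coefficients."""
    m1, m2, n1 = t.n_cases, t.n_controls, t.a + t.c
    lo, hi = max(0, n1 - m2), min(m1, n1)
    weights = {k: Fraction(math.comb(m1, k) * math.comb(m2, n1 - k))
               * Fraction(psi) ** k
               for k in range(lo, hi + 1)}
    total = sum(weights.values())
    if tail == "ge":
        num = sum(w for k, w in weights.items() if k >= t.a)
    else:
        num = sum(w for k, w in weights.items() if k <= t.a)
    return float(num / total)


class TestOddsRatio:
    @pytest.mark.parametrize("cells, expected", [
        ((5, 5, 1, 9), 9.0),
        ((1, 9, 1, 9), 1.0),
        ((6, 4, 6, 4), 1.0),
        ((1, 9, 5, 5), 1 / 9.0),
    ])
    def test_cross_product(self, cells, expected):
        assert odds_ratio(ContingencyTable(*cells)) == pytest.approx(expected)

    def test_degenerate_cells_flagged(self):
        assert math.isinf(odds_ratio(ContingencyTable(10, 0, 0, 10)))
        assert math.isnan(odds_ratio(ContingencyTable(0, 10, 0, 10)))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_transposition_symmetry(self, cells):
        t = ContingencyTable(*cells)
        assert odds_ratio(t.transpose_groups()) == pytest.approx(
            1.0 / odds_ratio(t))


class TestExactCI:
    def test_primary_table_reproduces_printed_interval(self):
        lo, hi = exact_or_ci(ContingencyTable(5, 5, 1, 9))
        assert lo < 9.0 < hi
        assert round(lo, 1) == 0.6
        assert round(hi) == 472

    def test_null_table_reproduces_printed_interval(self):
        lo, hi = exact_or_ci(ContingencyTable(1, 9, 1, 9))
        assert lo < 1.0 < hi
        assert round(lo, 2) == 0.01
        assert round(hi) == 87

    @pytest.mark.parametrize("cells", [
        (5, 5, 1, 9), (1, 9, 1, 9), (6, 4, 6, 4), (3, 7, 2, 8), (9, 1, 4, 6),
    ])
    def test_plug_back_tails_are_alpha_half(self, cells):
        """Plugging each bound back into the exact tail probability
        recovers 0.025 to 1e-8 (enumeration oracle)."""
        t = ContingencyTable(*cells)
        lo, hi = exact_or_ci(t, 0.95)
        assert enum_tail_probability(t, lo, "ge") == pytest.approx(
            0.025, abs=1e-8)
        assert enum_tail_probability(t, hi, "le") == pytest.approx(
            0.025, abs=1e-8)

    @pytest.mark.parametrize("cells", [
        (5, 5, 1, 9), (1, 9, 1, 9), (3, 7, 2, 8), (8, 2, 5, 5),
    ])
    def test_against_scipy_conditional_interval(self, cells):
        """Independent cross-check against scipy's conditional exact CI."""
        res = sps.contingency.odds_ratio(
            [[cells[0], cells[1]], [cells[2], cells[3]]])
        ci = res.confidence_interval(0.95)
        lo, hi = exact_or_ci(ContingencyTable(*cells))
        assert lo == pytest.approx(ci.low, rel=1e-6)
        assert hi == pytest.approx(ci.high, rel=1e-6)

    def test_edge_cells_give_zero_and_infinite_bounds(self):
        lo, hi = exact_or_ci(ContingencyTable(10, 0, 0, 10))
        assert hi == math.inf and lo > 0
        lo, hi = exact_or_ci(ContingencyTable(0, 10, 10, 0))
        assert lo == 0.0 and hi < math.inf

    def test_empty_margin_rejected(self):
        with pytest.raises(TableError):
            exact_or_ci(ContingencyTable(0, 10, 0, 10))

    def test_mid_p_interval_is_narrower(self):
        t = ContingencyTable(5, 5, 1, 9)
        lo, hi = exact_or_ci(t)
        mlo, mhi = exact_or_ci(t, mid_p=True)
        assert lo < mlo and mhi < hi

    def test_conditional_mle_inside_ci(self):
        t = ContingencyTable(5, 5, 1, 9)
        lo, hi = exact_or_ci(t)
        cmle = conditional_mle_or(t)
        assert lo < cmle < hi
        # conditional MLE differs from the cross-product estimate
        assert cmle != pytest.approx(9.0, rel=1e-3)

    def test_coverage_under_binomial_sampling(self):
        """Exact 95% CI covers the true odds ratio in at least 95% of
        1,000 binomially sampled tables (n = 10 per arm)."""
        psi_true = 9.0
        p_control = 0.3
        odds_case = psi_true * p_control / (1 - p_control)
        p_case = odds_case / (1 + odds_case)
        rng = np.random.default_rng(77)
        covered = 0
        for _ in range(1000):
            a = int(rng.binomial(10, p_case))
            c = int(rng.binomial(10, p_control))
            t = ContingencyTable(a, 10 - a, c, 10 - c)
            try:
                lo, hi = exact_or_ci(t)
            except TableError:  # empty exposure margin: interval is all psi
                covered += 1
                continue
            covered += lo <= psi_true <= hi
        assert covered / 1000 >= 0.95 - 0.02  # Monte-Carlo slack

    def test_woolf_interval_is_not_the_exact_one(self):
        """The large-sample logit interval cannot reproduce the exact
        small-sample bounds."""
        t = ContingencyTable(1, 9, 1, 9)
        wlo, whi = woolf_or_ci(t)
        elo, ehi = exact_or_ci(t)
        assert whi < ehi / 2 and wlo > elo * 2  # exact (0.01, 87) is far wider


class TestChiSquare:
    @pytest.mark.parametrize("cells, stat, p", [
        ((5, 5, 1, 9), 3.810, 0.051),
        ((6, 4, 3, 7), 1.818, 0.178),
        ((6, 4, 8, 2), 0.952, 0.329),
        ((2, 8, 0, 10), 2.222, 0.136),
        ((7, 7, 7, 7), 0.0, 1.0),
    ])
    def test_closed_form_examples(self, cells, stat, p):
        s, pv = pearson_chi_square(ContingencyTable(*cells))
        assert s == pytest.approx(stat, abs=5e-4)
        assert pv == pytest.approx(p, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_closed_form_matches_observed_expected_sum(self, cells):
        t = ContingencyTable(*cells)
        s_closed, _ = pearson_chi_square(t)
        obs = np.array([[t.a, t.b], [t.c, t.d]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        s_general = ((obs - exp) ** 2 / exp).sum()
        assert s_closed == pytest.approx(s_general, abs=1e-12, rel=1e-12)

    def test_two_by_k_table(self):
        # 2x3 covariate-style table, df = 2; agrees with scipy
        obs = [[7, 1, 2], [5, 5, 0]]
        s, p = pearson_chi_square(obs)
        s2, p2, df, _ = sps.chi2_contingency(obs, correction=False)
        assert s == pytest.approx(s2) and p == pytest.approx(p2) and df == 2

    def test_zero_margin_flagged(self):
        s, p = pearson_chi_square(ContingencyTable(0, 0, 3, 7))
        assert math.isnan(s) and math.isnan(p)


class TestFisher:
    def test_examples(self):
        assert fisher_exact(ContingencyTable(1, 9, 1, 9)) == pytest.approx(1.0)
        assert fisher_exact(ContingencyTable(10, 0, 0, 10)) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9)
        assert fisher_exact(ContingencyTable(0, 10, 0, 10)) == pytest.approx(1.0)

    def test_agrees_with_chi_square_at_large_counts(self):
        t = ContingencyTable(505, 495, 495, 505)
        _, p_chi = pearson_chi_square(t)
        p_f = fisher_exact(t)
        assert abs(p_f - p_chi) / p_chi < 0.05


class TestTTest:
    def test_identical_groups(self):
        s, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert s == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        s, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert s == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_shift_invariance(self):
        s1, p1 = two_sample_t([1, 2, 3], [4, 5, 6])
        s2, p2 = two_sample_t([101, 102, 103], [104, 105, 106])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(TableError):
            two_sample_t([1.0], [2.0, 3.0])


class TestBurdenAssembly:
    def test_compute_burden_consistency(self):
        r = compute_burden(ContingencyTable(5, 5, 1, 9, label="demo"))
        assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert 0 <= r.chi2_p <= 1 and 0 <= r.fisher_p <= 1
        assert "Cornfield" in r.method_notes
        d = r.to_dict()
        assert d["label"] == "demo" and d["a"] == 5

    def test_exposure_table_counts_each_proband_once(self):
        trios = [TrioPedigree(f"f{i}", f"p{i}", f"m{i}", f"d{i}",
                              proband_affected="epilepsy" if i < 4
                              else "no_epilepsy")
                 for i in range(10)]
        t = build_exposure_table(trios, lambda tr: tr.family_id in
                                 {"f0", "f5"}, "x")
        assert t.cells == (1, 3, 1, 5)
        assert t.n == 10

    def test_unlabeled_proband_rejected(self):
        trios = [TrioPedigree("f", "p", "m", "d")]
        with pytest.raises(TableError):
            build_exposure_table(trios, lambda tr: False)

    def test_qualifier_always_false(self):
        trios = [TrioPedigree(f"f{i}", f"p{i}", f"m{i}", f"d{i}",
                              proband_affected="epilepsy" if i < 10
                              else "no_epilepsy")
                 for i in range(20)]
        t = build_exposure_table(trios, lambda tr: False)
        assert t.cells == (0, 10, 0, 10)
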