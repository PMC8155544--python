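"""Burden statistics: exact Fisher test, Woolf interval, allele bookkeeping."""

import math

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from haystack import (
    ContingencyTable,
    alleles_from_individuals,
    fisher_two_sided,
    lof_burden_test,
    woolf_logit_interval,
)
from haystack.errors import DataError

# --- independent oracle: exact integer-arithmetic enumeration ----------------

_COMB = [[math.comb(n, k) for k in range(161)] for n in range(161)]


def fisher_oracle(a, b, c, d):
    """Minimum-likelihood two-sided p by exact rational enumeration.

    Point probabilities are integer weights C(r1,k)*C(r2,c1-k); a table is
    included when its weight is at most the observed one times (1 + 1e-7),
    evaluated without any floating point.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    weights = [_COMB[r1][k] * _COMB[r2][c1 - k] for k in range(kmin, kmax + 1)]
    observed = weights[a - kmin]
    numerator = sum(w for w in weights if w * 10**7 <= observed * (10**7 + 1))
    return numerator / _COMB[r1 + r2][c1]


def test_oracle_reproduces_hand_enumerated_table():
    # margins (5,5)/(6,4): weights 5,50,100,50,5; observed (a=2) is 50
    assert fisher_oracle(2, 3, 4, 1) == pytest.approx(110 / 210)
    assert fisher_two_sided(ContingencyTable(2, 3, 4, 1)) == pytest.approx(110 / 210)


@pytest.mark.parametrize(
    "table",
    [(3, 7, 12, 2), (1, 0, 3, 9), (8, 8, 8, 8), (0, 5, 9, 2), (20, 1, 2, 30), (1, 99, 5, 40)],
)
def test_fisher_matches_oracle_and_scipy(table):
    t = ContingencyTable(*table)
    p = fisher_two_sided(t)
    assert p == pytest.approx(fisher_oracle(*table), rel=1e-9)
    _, p_scipy = scipy.stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    assert p == pytest.approx(p_scipy, rel=1e-6)


@pytest.mark.parametrize("table", [(0, 5, 0, 7), (0, 0, 3, 4), (2, 0, 5, 0)])
def test_degenerate_margins_return_one(table):
    assert fisher_two_sided(ContingencyTable(*table)) == 1.0


@settings(derandomize=True, max_examples=300)
@given(st.tuples(*(st.integers(0, 40),) * 4).filter(lambda t: sum(t) > 0))
def test_fisher_invariant_under_row_and_column_swap(cells):
    """Relabeling cohorts, and relabeling outcomes, leaves p unchanged."""
    a, b, c, d = cells
    p = fisher_two_sided(ContingencyTable(a, b, c, d))
    assert fisher_two_sided(ContingencyTable(c, d, a, b)) == pytest.approx(p, rel=1e-9)
    assert fisher_two_sided(ContingencyTable(b, a, d, c)) == pytest.approx(p, rel=1e-9)


def test_p_monotone_in_observed_excess():
    """Within fixed margins, p shrinks as the observed table grows more extreme."""
    r1 = r2 = 20
    c1 = 10
    ps = [
        fisher_two_sided(ContingencyTable(a, r1 - a, c1 - a, r2 - c1 + a))
        for a in range(c1 // 2, c1 + 1)
    ]
    assert all(q <= p + 1e-12 for p, q in zip(ps, ps[1:]))


class TestWoolfInterval:
    def test_balanced_table_closed_form(self):
        odds_ratio, lo, hi, corrected = woolf_logit_interval(ContingencyTable(10, 10, 10, 10))
        se = math.sqrt(0.4)
        z = scipy.stats.norm.ppf(0.975)
        assert odds_ratio == 1.0
        assert not corrected
        assert lo == pytest.approx(math.exp(-z * se), rel=1e-12)
        assert hi == pytest.approx(math.exp(z * se), rel=1e-12)
        assert (lo, hi) == pytest.approx((0.2896, 3.4534), abs=1e-3)

    def test_haldane_correction_iff_zero_cell(self):
        _, _, _, corrected = woolf_logit_interval(ContingencyTable(0, 10, 5, 5))
        assert corrected
        _, _, _, uncorrected = woolf_logit_interval(ContingencyTable(1, 10, 5, 5))
        assert not uncorrected

    def test_haldane_arithmetic(self):
        odds_ratio, _, _, corrected = woolf_logit_interval(ContingencyTable(0, 10, 5, 5))
        assert corrected
        assert odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    @pytest.mark.parametrize("cells", [(10, 3, 7, 25), (1, 40, 2, 9), (5, 5, 5, 5)])
    def test_log_symmetry_around_odds_ratio(self, cells):
        odds_ratio, lo, hi, _ = woolf_logit_interval(ContingencyTable(*cells))
        assert math.log(odds_ratio) - math.log(lo) == pytest.approx(
            math.log(hi) - math.log(odds_ratio), rel=1e-10
        )
        assert lo < odds_ratio < hi

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*(st.integers(0, 50),) * 4).filter(lambda t: sum(t) > 0))
    def test_widening_confidence_widens_interval(self, cells):
        t = ContingencyTable(*cells)
        _, lo90, hi90, _ = woolf_logit_interval(t, 0.90)
        _, lo99, hi99, _ = woolf_logit_interval(t, 0.99)
        assert lo99 < lo90 and hi99 > hi90


class TestAlleleBookkeeping:
    @pytest.mark.parametrize(
        ("n", "het", "hom", "expected"),
        [
            (247, 1, 0, (1, 493)),
            (125748, 1, 0, (1, 251495)),
            (10, 0, 0, (0, 20)),
            (10, 2, 3, (8, 12)),
        ],
    )
    def test_allele_counts(self, n, het, hom, expected):
        assert alleles_from_individuals(n, het, hom) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            alleles_from_individuals(10, -1, 0)
        with pytest.raises(DataError):
            alleles_from_individuals(2, 2, 1)


class TestBurdenTest:
    def test_cohort_vs_reference_pvalues_round_to_published_precision(self):
        sco = lof_burden_test(247, 1, 0, 125748, 1, 0)
        assert round(sco.p_two_sided, 3) == 0.004
        merge = lof_burden_test(908, 1, 0, 125748, 1, 0)
        assert round(merge.p_two_sided, 2) == 0.01

    def test_no_carriers_anywhere_gives_p_one(self):
        result = lof_burden_test(100, 0, 0, 1000, 0, 0)
        assert result.p_two_sided == 1.0

    def test_per_individual_vs_per_allele_robustness(self):
        """Counting individuals instead of alleles barely moves p for these tables."""
        for cohort_n in (247, 908):
            allele = fisher_two_sided(
                ContingencyTable(1, 2 * cohort_n - 1, 1, 2 * 125748 - 1)
            )
            individual = fisher_two_sided(
                ContingencyTable(1, cohort_n - 1, 1, 125748 - 1)
            )
            assert abs(allele - individual) < 5e-5

    def test_reference_allele_number_override(self):
        result = lof_burden_test(
            247, 1, 0, 125748, 1, 0, reference_allele_number=250000
        )
        assert result.table.d == 249999

    def test_ci_brackets_odds_ratio_without_correction(self):
        result = lof_burden_test(100, 5, 1, 1000, 10, 0)
        assert result.ci_low <= result.odds_ratio <= result.ci_high
        assert not result.correction_applied
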