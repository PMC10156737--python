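"""Carrier counting, Fisher's exact test, chi-squared expected counts,
and the two-locus co-occurrence rate."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from famseg import (CarrierCounts, ContingencyTable2x2, GenotypeCall,
                    build_case_vs_reference, carrier_frequency, chi2_expected,
                    cooccurrence_rate, count_carriers,
                    fisher_exact_two_sided, odds_ratio)

G = GenotypeCall


def test_count_carriers_partition():
    counts = count_carriers({"s1": G.HET, "s2": G.HOM_ALT, "s3": G.HOM_REF,
                             "s4": G.MISSING})
    assert (counts.n_het, counts.n_hom, counts.n_noncarrier,
            counts.n_missing) == (1, 1, 1, 1)
    assert counts.carriers == 2 and counts.genotyped == 3
    assert count_carriers({}).carriers == 0


def test_carrier_frequency():
    assert carrier_frequency(CarrierCounts("r", 10, 1, 989)) == pytest.approx(0.011)
    assert carrier_frequency(CarrierCounts("r", 0, 0, 5)) == 0.0
    assert carrier_frequency(CarrierCounts("r", 2, 3, 0)) == 1.0
    with pytest.raises(ValueError):
        carrier_frequency(CarrierCounts("r", 0, 0, 0, n_missing=5))


def test_build_case_vs_reference():
    case = CarrierCounts("case", 3, 0, 2448)
    ref = CarrierCounts("ref", 85, 0, 60621)
    t = build_case_vs_reference(case, ref)
    assert (t.a, t.b, t.c, t.d) == (3, 2448, 85, 60621)
    assert t.row_margins == (2451, 60706)
    # allele-count mode doubles the denominators
    t2 = build_case_vs_reference(case, ref, allele_counts=True)
    assert t2.row_margins == (2 * 2451, 2 * 60706)


def test_fisher_frozen_examples():
    # enumeration over margins (4,4,4,4): qualifying mass 34/70
    assert fisher_exact_two_sided(ContingencyTable2x2(3, 1, 1, 3)) == \
        pytest.approx(34 / 70, rel=1e-12)
    # margins (5,5,5,5): the two extreme tables, 2/252
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 5, 5, 0)) == \
        pytest.approx(2 / 252, rel=1e-12)
    # observed table is the mode: every table qualifies
    assert fisher_exact_two_sided(ContingencyTable2x2(2, 2, 2, 2)) == \
        pytest.approx(1.0, rel=1e-12)


def test_fisher_degenerate_margin_is_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 5, 5)) == 1.0
    assert ContingencyTable2x2(0, 0, 5, 5).is_degenerate


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if a + b + c + d == 0:
            continue
        t = ContingencyTable2x2(a, b, c, d)
        if t.is_degenerate:
            continue
        expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_two_sided(t) == pytest.approx(expected, rel=1e-9)


def test_fisher_large_cohort_scale():
    """Numerically stable at reference-cohort sizes (N > 60k)."""
    t = ContingencyTable2x2(12, 2439, 85, 60621)
    expected = scipy.stats.fisher_exact([[12, 2439], [85, 60621]])[1]
    assert fisher_exact_two_sided(t) == pytest.approx(expected, rel=1e-9)


@given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
       st.integers(0, 15))
def test_fisher_invariant_under_row_and_column_swap(a, b, c, d):
    if a + b + c + d == 0:
        return
    p1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
    p2 = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a))
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_chi2_examples():
    res = chi2_expected(ContingencyTable2x2(10, 10, 10, 10))
    assert res.expected == ((10, 10), (10, 10))
    assert res.statistic == 0 and res.df == 1

    res = chi2_expected(ContingencyTable2x2(20, 0, 0, 20))
    assert res.expected == ((10, 10), (10, 10))
    assert res.statistic == pytest.approx(40)

    # proportional rows: statistic 0
    assert chi2_expected(ContingencyTable2x2(1, 9, 2, 18)).statistic == \
        pytest.approx(0)


def test_chi2_zero_margin_flagged():
    res = chi2_expected(ContingencyTable2x2(0, 10, 0, 10))
    assert res.undefined and math.isnan(res.statistic)
    assert res.expected[0][0] == 0


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
       st.integers(0, 50))
def test_chi2_expected_conserves_margins(a, b, c, d):
    if a + b + c + d == 0:
        return
    t = ContingencyTable2x2(a, b, c, d)
    e = chi2_expected(t).expected
    assert e[0][0] + e[0][1] == pytest.approx(t.row_margins[0])
    assert e[1][0] + e[1][1] == pytest.approx(t.row_margins[1])
    assert e[0][0] + e[1][0] == pytest.approx(t.col_margins[0])


def test_odds_ratio():
    assert odds_ratio(ContingencyTable2x2(3, 2448, 85, 60621)) == \
        pytest.approx(3 * 60621 / (2448 * 85))
    assert odds_ratio(ContingencyTable2x2(1, 0, 1, 1)) == math.inf
    # identical cohorts -> odds ratio 1
    assert odds_ratio(ContingencyTable2x2(5, 95, 5, 95)) == pytest.approx(1.0)


class Patient:
    def __init__(self, risk_hom, c8_carrier, namd, ga):
        self.risk_hom = risk_hom
        self.c8_carrier = c8_carrier
        self.namd = namd
        self.ga = ga


def test_cooccurrence_printed_breakdown():
    """Six risk-allele homozygotes carrying the rare variant: 4 neovascular,
    1 atrophic, 1 both -> 5/6 with any neovascular involvement, 83%."""
    cohort = (
        [Patient(True, True, namd=True, ga=False) for _ in range(4)]
        + [Patient(True, True, namd=False, ga=True)]
        + [Patient(True, True, namd=True, ga=True)]
        + [Patient(False, True, namd=True, ga=False) for _ in range(3)]
        + [Patient(True, False, namd=False, ga=False) for _ in range(2)]
    )
    k, n, pct = cooccurrence_rate(cohort,
                                  lambda p: p.risk_hom,
                                  lambda p: p.c8_carrier,
                                  lambda p: p.namd)
    assert (k, n, pct) == (5, 6, 83)


def test_cooccurrence_extremes_and_empty():
    cohort = [Patient(True, True, False, False) for _ in range(4)]
    assert cooccurrence_rate(cohort, lambda p: p.risk_hom,
                             lambda p: p.c8_carrier,
                             lambda p: p.namd) == (0, 4, 0)
    assert cooccurrence_rate(cohort, lambda p: p.risk_hom,
                             lambda p: p.c8_carrier,
                             lambda p: True) == (4, 4, 100)
    with pytest.raises(ValueError):
        cooccurrence_rate(cohort, lambda p: False, lambda p: True,
                          lambda p: True)


def test_cooccurrence_rounds_half_away_from_zero():
    cohort = [Patient(True, True, i < 1, False) for i in range(8)]
    # 1/8 = 12.5% -> 13
    assert cooccurrence_rate(cohort, lambda p: p.risk_hom,
                             lambda p: p.c8_carrier,
                             lambda p: p.namd)[2] == 13


def test_counts_validation():
    with pytest.raises(ValueError):
        CarrierCounts("x", -1, 0, 0)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)
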