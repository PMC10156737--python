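"""Cohort-level carrier statistics.

Counts heterozygous carriers, homozygous carriers and non-carriers of a
variant; compares a case cohort's carrier tally against a reference cohort
in a 2x2 table with a two-sided Fisher's exact test (probability-ordering
convention, computed by log-factorial accumulation over the hypergeometric
support) and chi-squared expected counts; and computes the two-locus
phenotype co-occurrence rate among individuals selected by a pair of
genotype predicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, TypeVar

import numpy as np
from scipy.special import gammaln

from .io_formats import GenotypeCall

T = TypeVar("T")

#: relative tolerance for the probability-ordering tie rule in Fisher's test
_FISHER_REL_TOL = 1e-12


@dataclass(frozen=True)
class CarrierCounts:
    """Person-level carrier tallies for one cohort. Heterozygous and
    homozygous carriers each count once as carriers."""

    cohort: str
    n_het: int
    n_hom: int
    n_noncarrier: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_het", "n_hom", "n_noncarrier", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def carriers(self) -> int:
        return self.n_het + self.n_hom

    @property
    def genotyped(self) -> int:
        return self.carriers + self.n_noncarrier

    @property
    def allele_count(self) -> int:
        return self.n_het + 2 * self.n_hom


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: case / reference cohort; columns: carrier / non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def is_degenerate(self) -> bool:
        return 0 in self.row_margins or 0 in self.col_margins


def count_carriers(genotypes: Mapping[str, GenotypeCall],
                   cohort: str = "case") -> CarrierCounts:
    """Partition samples into het carriers, hom carriers, non-carriers and
    missing."""
    het = hom = non = miss = 0
    for g in genotypes.values():
        if g == GenotypeCall.HET:
            het += 1
        elif g == GenotypeCall.HOM_ALT:
            hom += 1
        elif g == GenotypeCall.HOM_REF:
            non += 1
        else:
            miss += 1
    return CarrierCounts(cohort, het, hom, non, miss)


def carrier_frequency(counts: CarrierCounts) -> float:
    """Fraction of genotyped individuals carrying at least one variant
    allele; missing genotypes are excluded from the denominator."""
    if counts.genotyped == 0:
        raise ValueError(f"cohort {counts.cohort!r} has no genotyped individuals; "
                         "carrier frequency undefined")
    return counts.carriers / counts.genotyped


def build_case_vs_reference(case: CarrierCounts, ref: CarrierCounts,
                            allele_counts: bool = False) -> ContingencyTable2x2:
    """Assemble the case-vs-reference 2x2 table (person-level carriage by
    default; ``allele_counts`` switches to allele tallies)."""
    if case.genotyped < 1 or ref.genotyped < 1:
        raise ValueError("both cohorts must have at least one genotyped individual")
    if allele_counts:
        return ContingencyTable2x2(case.allele_count,
                                   2 * case.genotyped - case.allele_count,
                                   ref.allele_count,
                                   2 * ref.genotyped - ref.allele_count)
    return ContingencyTable2x2(case.carriers, case.n_noncarrier,
                               ref.carriers, ref.n_noncarrier)


_logfact_cache = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """log(k!) for k = 0..n, cached."""
    global _logfact_cache
    if len(_logfact_cache) <= n:
        _logfact_cache = gammaln(np.arange(max(n + 1, 2 * len(_logfact_cache))) + 1.0)
    return _logfact_cache


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by the probability-ordering rule.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance 1e-12 — two-sided definitions vary between packages;
    this is the convention of mainstream statistics software). A degenerate
    margin (an empty row or column) returns p = 1.
    """
    if t.is_degenerate:
        return 1.0
    r1, r2 = t.row_margins
    c1, _ = t.col_margins
    n = t.total
    lf = _logfact(n)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log P(a) = logC(r1, a) + logC(r2, c1 - a) - logC(n, c1)
    logp = (lf[r1] - lf[support] - lf[r1 - support]
            + lf[r2] - lf[c1 - support] - lf[r2 - (c1 - support)]
            - (lf[n] - lf[c1] - lf[n - c1]))
    obs = logp[t.a - lo]
    p = float(np.exp(logp[logp <= obs + math.log1p(_FISHER_REL_TOL)]).sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class Chi2Result:
    expected: tuple[tuple[float, float], tuple[float, float]]
    statistic: float
    df: int = 1
    undefined: bool = False


def chi2_expected(t: ContingencyTable2x2) -> Chi2Result:
    """Expected counts under independence and the Pearson chi-squared
    statistic (no continuity correction), df = 1.

    The expected counts are the primary output; with a zero margin the
    expected cells in that line are 0 and the statistic is flagged
    undefined (NaN).
    """
    rows, cols, n = t.row_margins, t.col_margins, t.total
    expected = [[rows[i] * cols[j] / n for j in range(2)] for i in range(2)]
    observed = [[t.a, t.b], [t.c, t.d]]
    if t.is_degenerate:
        return Chi2Result(tuple(tuple(row) for row in expected),
                          float("nan"), undefined=True)
    stat = sum((observed[i][j] - expected[i][j]) ** 2 / expected[i][j]
               for i in range(2) for j in range(2))
    return Chi2Result(tuple(tuple(row) for row in expected), stat)


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio (a*d)/(b*c); infinite or NaN on zero cells."""
    if t.b * t.c == 0:
        return float("inf") if t.a * t.d > 0 else float("nan")
    return (t.a * t.d) / (t.b * t.c)


def cooccurrence_rate(individuals: Iterable[T],
                      genotype_predicate_a: Callable[[T], bool],
                      genotype_predicate_b: Callable[[T], bool],
                      outcome_predicate: Callable[[T], bool],
                      ) -> tuple[int, int, int]:
    """Among individuals satisfying both genotype predicates, the fraction
    with the outcome, as (k, n, percentage).

    The percentage is rounded to the nearest integer, half away from zero.
    With no qualifying individual the rate is undefined and a ValueError is
    raised — at such sample sizes no statistical test is attached.
    """
    qualifying = [ind for ind in individuals
                  if genotype_predicate_a(ind) and genotype_predicate_b(ind)]
    n = len(qualifying)
    if n == 0:
        raise ValueError("no individual satisfies both genotype predicates; "
                         "co-occurrence rate undefined")
    k = sum(1 for ind in qualifying if outcome_predicate(ind))
    pct = int(math.floor(100.0 * k / n + 0.5))
    return k, n, pct
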