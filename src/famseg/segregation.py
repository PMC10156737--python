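"""Per-family dominant segregation testing and cross-family gene collapsing.

Under an autosomal-dominant model a carrier is anyone with at least one
variant allele. A variant segregates in a family when every genotyped
affected member carries it, or all but ``tolerance`` of them do (default 1,
accommodating phenocopies in a late-onset, incompletely penetrant disease),
with at least one affected carrier required. Affected members with missing
genotypes shrink the denominator — absence of data is not evidence of
non-carriage — and are reported separately. Passing variants are collapsed
into gene-level hits across families and ranked by family support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .cohort import Affection, Pedigree
from .filters import AnnotationRecord
from .io_formats import GenotypeCall, VariantKey, VariantRecord

logger = logging.getLogger(__name__)

UNANNOTATED = "UNANNOTATED"


def is_carrier(g: GenotypeCall) -> bool:
    """Dominant-model carrier status: het or hom-alt. Missing is not a
    carrier; callers tally missing genotypes separately."""
    return g in (GenotypeCall.HET, GenotypeCall.HOM_ALT)


@dataclass(frozen=True)
class SegregationResult:
    """Evidence for one (family, variant) pair."""

    family_id: str
    key: VariantKey
    n_affected_genotyped: int
    n_affected_carriers: int
    n_affected_missing: int
    passes: bool
    no_genotyped_affected: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_affected_carriers <= self.n_affected_genotyped:
            raise ValueError("carrier count outside [0, n_affected_genotyped]")


def test_family_segregation(ped: Pedigree, record: VariantRecord,
                            tolerance: int = 1,
                            require_absent_in_unaffected: bool = False,
                            ) -> SegregationResult:
    """Apply the dominant segregation rule to one family and one variant.

    Among genotyped affected members with carrier count c out of n, the
    variant passes iff c >= 1 and (n - c) <= tolerance. With no genotyped
    affected member the result fails and is flagged rather than raising.
    The optional strict mode additionally fails the variant when any
    genotyped unaffected member carries it (off by default: the disease is
    late-onset with incomplete penetrance, so unaffected carriers are
    expected).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    n = c = missing = 0
    unaffected_carrier = False
    for m in ped.members:
        g = record.genotypes.get(m.individual_id, GenotypeCall.MISSING)
        if m.affection == Affection.AFFECTED:
            if g == GenotypeCall.MISSING:
                missing += 1
            else:
                n += 1
                if is_carrier(g):
                    c += 1
        elif m.affection == Affection.UNAFFECTED:
            if g != GenotypeCall.MISSING and is_carrier(g):
                unaffected_carrier = True
    if n == 0:
        return SegregationResult(ped.family_id, record.key, 0, 0, missing,
                                 passes=False, no_genotyped_affected=True)
    passes = c >= 1 and (n - c) <= tolerance
    if require_absent_in_unaffected and unaffected_carrier:
        passes = False
    return SegregationResult(ped.family_id, record.key, n, c, missing, passes)


@dataclass(frozen=True)
class GeneHit:
    """Cross-family gene-level evidence: the union of families in which any
    variant of the gene passed segregation."""

    gene: str
    families_passing: frozenset[str]
    variants: frozenset[VariantKey]
    total_affected_carriers: int

    def __post_init__(self) -> None:
        if not self.families_passing:
            raise ValueError("a GeneHit requires at least one passing family")


def collapse_to_genes(results: Iterable[SegregationResult],
                      annotations: Mapping[VariantKey, AnnotationRecord],
                      ) -> list[GeneHit]:
    """Collapse passing per-family variant results into gene-level hits.

    Distinct variants of the same gene, passing in different families, merge
    into a single hit whose family set is the union (so one variant shared by
    three families and a gene with per-family private variants are treated
    alike). Passing variants without an annotation are reported under the
    pseudo-gene ``UNANNOTATED`` and logged, never dropped.
    """
    families: dict[str, set[str]] = {}
    variants: dict[str, set[VariantKey]] = {}
    carriers: dict[str, int] = {}
    for res in results:
        if not res.passes:
            continue
        ann = annotations.get(res.key)
        if ann is None:
            logger.warning("passing variant %s has no annotation; reported as %s",
                           res.key, UNANNOTATED)
            gene = UNANNOTATED
        else:
            gene = ann.gene
        families.setdefault(gene, set()).add(res.family_id)
        variants.setdefault(gene, set()).add(res.key)
        carriers[gene] = carriers.get(gene, 0) + res.n_affected_carriers
    return [GeneHit(gene, frozenset(families[gene]), frozenset(variants[gene]),
                    carriers[gene])
            for gene in families]


def rank_genes(hits: Iterable[GeneHit]) -> list[GeneHit]:
    """Order gene hits by descending family support, then descending total
    affected carriers, then gene symbol — deterministic under input order."""
    return sorted(hits, key=lambda h: (-len(h.families_passing),
                                       -h.total_affected_carriers, h.gene))
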