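"""Orchestration of the discovery and burden analyses.

``run_prioritization`` chains the retention filters (functional category,
CADD, allele frequency) with the per-family dominant segregation test and
cross-family gene collapsing, producing a ranked gene report plus per-stage
record counts; a known-gene screen runs first and is reported separately.
``run_burden`` compares case carrier counts per variant of interest against
a reference cohort with Fisher's exact test and chi-squared expected counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .burden import (CarrierCounts, Chi2Result, build_case_vs_reference,
                     carrier_frequency, chi2_expected, count_carriers,
                     fisher_exact_two_sided, odds_ratio)
from .cohort import Pedigree
from .filters import (DEFAULT_CADD_MIN, DEFAULT_FUNCTIONAL_CATEGORIES,
                      DEFAULT_MAF_MAX, AnnotationRecord, filter_cadd,
                      filter_functional, filter_maf, screen_known_genes)
from .io_formats import (VariantKey, VariantRecord, read_annotation_table,
                         read_ped, read_vcf)
from .segregation import (GeneHit, SegregationResult, collapse_to_genes,
                          rank_genes, test_family_segregation)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options for the discovery pipeline (defaults are the
    analysis defaults: CADD >= 15, AF <= 1%, exonic/splicing, tolerance 1)."""

    cadd_min: float = DEFAULT_CADD_MIN
    maf_max: float = DEFAULT_MAF_MAX
    categories: tuple[str, ...] = DEFAULT_FUNCTIONAL_CATEGORIES
    tolerance: int = 1
    require_absent_in_unaffected: bool = False
    known_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")
        if not 0.0 <= self.maf_max <= 1.0:
            raise ValueError("maf_max must be within [0,1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "known_genes_file" in raw:
            genes = Path(raw.pop("known_genes_file")).read_text().split()
            raw["known_genes"] = tuple(genes)
        for key in ("categories", "known_genes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PrioritizationResult:
    ranked_hits: list[GeneHit]
    known_gene_hits: list[GeneHit]
    stage_counts: dict[str, int]
    segregation_results: list[SegregationResult]
    dropped_samples: list[str]


def _segregate(pedigrees: Mapping[str, Pedigree],
               records: Sequence[VariantRecord],
               cfg: PipelineConfig) -> list[SegregationResult]:
    results = []
    for rec in records:
        for ped in pedigrees.values():
            results.append(test_family_segregation(
                ped, rec, tolerance=cfg.tolerance,
                require_absent_in_unaffected=cfg.require_absent_in_unaffected))
    return results


def run_prioritization(pedigrees: Mapping[str, Pedigree],
                       variants: Sequence[VariantRecord],
                       annotations: Sequence[AnnotationRecord],
                       cfg: Optional[PipelineConfig] = None,
                       ) -> PrioritizationResult:
    """Filter, segregate, collapse and rank — the full discovery analysis.

    VCF samples that match no pedigree member are dropped (and logged);
    having no overlapping sample at all is an error. Variants lacking an
    annotation are excluded from the annotation-driven filters and logged.
    """
    cfg = cfg or PipelineConfig()
    member_ids = {m.individual_id for ped in pedigrees.values()
                  for m in ped.members}
    vcf_samples = set()
    for rec in variants:
        vcf_samples.update(rec.genotypes)
    dropped = sorted(vcf_samples - member_ids)
    if variants and not (vcf_samples & member_ids):
        raise ValueError("no VCF sample matches any pedigree member")
    if dropped:
        logger.info("dropping %d samples with no pedigree entry: %s",
                    len(dropped), ", ".join(dropped[:10]))

    ann_by_key: dict[VariantKey, AnnotationRecord] = {a.key: a
                                                      for a in annotations}
    by_key: dict[VariantKey, VariantRecord] = {r.key: r for r in variants}
    annotated = [ann_by_key[k] for k in by_key if k in ann_by_key]
    n_unannotated = len(by_key) - len(annotated)
    if n_unannotated:
        logger.info("%d variants lack annotation; excluded from "
                    "annotation-driven filters", n_unannotated)

    stage_counts: dict[str, int] = {"variants": len(by_key),
                                    "annotated": len(annotated)}

    known_gene_hits: list[GeneHit] = []
    if cfg.known_genes:
        known = screen_known_genes(annotated, cfg.known_genes)
        known = filter_maf(filter_cadd(filter_functional(known, cfg.categories),
                                       cfg.cadd_min), cfg.maf_max)
        known_results = _segregate(pedigrees, [by_key[a.key] for a in known],
                                   cfg)
        known_gene_hits = rank_genes(collapse_to_genes(known_results,
                                                       ann_by_key))
        stage_counts["known_gene_screen_hits"] = len(known_gene_hits)

    retained = filter_functional(annotated, cfg.categories)
    stage_counts["after_functional"] = len(retained)
    retained = filter_cadd(retained, cfg.cadd_min)
    stage_counts["after_cadd"] = len(retained)
    retained = filter_maf(retained, cfg.maf_max)
    stage_counts["after_maf"] = len(retained)

    results = _segregate(pedigrees, [by_key[a.key] for a in retained], cfg)
    stage_counts["passing_family_variant_pairs"] = sum(
        1 for r in results if r.passes)
    hits = rank_genes(collapse_to_genes(results, ann_by_key))
    stage_counts["genes"] = len(hits)
    for stage, n in stage_counts.items():
        logger.info("stage %s: %d records", stage, n)
    return PrioritizationResult(hits, known_gene_hits, stage_counts, results,
                                dropped)


def run_prioritization_files(vcf_path: str | Path, ped_path: str | Path,
                             annot_path: str | Path,
                             cfg: Optional[PipelineConfig] = None,
                             ) -> PrioritizationResult:
    """File-based wrapper around :func:`run_prioritization`."""
    _, variants = read_vcf(vcf_path)
    pedigrees = read_ped(ped_path)
    annotations = read_annotation_table(annot_path)
    return run_prioritization(pedigrees, variants, annotations, cfg)


@dataclass
class BurdenRow:
    """Per-variant burden comparison of a case cohort against a reference."""

    key: VariantKey
    found: bool
    ref_counts: CarrierCounts
    case_counts: Optional[CarrierCounts] = None
    case_freq: Optional[float] = None
    ref_freq: Optional[float] = None
    odds_ratio: Optional[float] = None
    fisher_p: Optional[float] = None
    chi2: Optional[Chi2Result] = None

    @property
    def chi2_stat(self) -> Optional[float]:
        return self.chi2.statistic if self.chi2 is not None else None


def run_burden(variants: Sequence[VariantRecord],
               reference: CarrierCounts,
               keys_of_interest: Sequence[VariantKey],
               case_sample_ids: Optional[Sequence[str]] = None,
               ) -> list[BurdenRow]:
    """Carrier-burden comparison for each variant of interest.

    ``case_sample_ids`` restricts the counted samples (e.g. to affected
    cases); a variant absent from the call set yields a flagged row rather
    than an error.
    """
    by_key = {r.key: r for r in variants}
    rows: list[BurdenRow] = []
    for key in keys_of_interest:
        rec = by_key.get(key)
        if rec is None:
            logger.warning("variant %s absent from call set", key)
            rows.append(BurdenRow(key, found=False, ref_counts=reference,
                                  ref_freq=carrier_frequency(reference)))
            continue
        genotypes = rec.genotypes
        if case_sample_ids is not None:
            genotypes = {s: g for s, g in genotypes.items()
                         if s in set(case_sample_ids)}
        case = count_carriers(genotypes, cohort="case")
        table = build_case_vs_reference(case, reference)
        rows.append(BurdenRow(
            key, found=True, ref_counts=reference, case_counts=case,
            case_freq=carrier_frequency(case),
            ref_freq=carrier_frequency(reference),
            odds_ratio=odds_ratio(table),
            fisher_p=fisher_exact_two_sided(table),
            chi2=chi2_expected(table)))
    return rows
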