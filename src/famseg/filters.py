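"""Annotation-driven variant retention rules.

Variants are kept for discovery when they are (i) exonic or splicing,
(ii) predicted deleterious (CADD phred >= 15) or unscored, and (iii) rare
(reference-population allele frequency <= 1%) or absent from the reference.
Missing scores and frequencies are deliberately retained so that novel
variants are never silently lost. A known-gene screen restricts a record set
to a curated symbol list and is intended to run before genome-wide discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import VariantKey

DEFAULT_FUNCTIONAL_CATEGORIES = ("exonic", "splicing")
DEFAULT_CADD_MIN = 15.0
DEFAULT_MAF_MAX = 0.01


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant annotation: gene symbol, functional category, CADD phred
    score and reference-population (ExAC-style) allele frequency.

    ``cadd_phred`` and ``exac_all_af`` are ``None`` when the annotation
    source reported "." — a distinguished missing value, never zero.
    """

    key: VariantKey
    gene: str
    category: str
    cadd_phred: Optional[float] = None
    exac_all_af: Optional[float] = None
    clinvar_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.exac_all_af is not None and not 0.0 <= self.exac_all_af <= 1.0:
            raise ValueError(f"allele frequency out of [0,1]: {self.exac_all_af}")


def _category_components(category: str) -> list[str]:
    # ANNOVAR emits composite categories like "exonic;splicing"
    return [c.strip().lower() for c in category.split(";") if c.strip()]


def filter_functional(records: Iterable[AnnotationRecord],
                      categories: Sequence[str] = DEFAULT_FUNCTIONAL_CATEGORIES,
                      ) -> list[AnnotationRecord]:
    """Retain records whose category (any ';'-separated component,
    case-insensitive) is one of ``categories``."""
    wanted = {c.lower() for c in categories}
    return [r for r in records
            if any(c in wanted for c in _category_components(r.category))]


def filter_cadd(records: Iterable[AnnotationRecord],
                threshold: float = DEFAULT_CADD_MIN) -> list[AnnotationRecord]:
    """Retain records with CADD phred >= threshold, or with no CADD score."""
    if threshold < 0:
        raise ValueError("CADD threshold must be >= 0")
    return [r for r in records if r.cadd_phred is None or r.cadd_phred >= threshold]


def filter_maf(records: Iterable[AnnotationRecord],
               max_af: float = DEFAULT_MAF_MAX) -> list[AnnotationRecord]:
    """Retain records with allele frequency <= max_af, or with no frequency."""
    if not 0.0 <= max_af <= 1.0:
        raise ValueError("max_af must be within [0,1]")
    return [r for r in records if r.exac_all_af is None or r.exac_all_af <= max_af]


def screen_known_genes(records: Iterable[AnnotationRecord],
                       gene_list: Iterable[str]) -> list[AnnotationRecord]:
    """Restrict records to a curated gene list (exact symbol match)."""
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene_list must be non-empty")
    return [r for r in records if r.gene in genes]
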