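"""Synthetic study generator: gene-dropping through simulated pedigrees.

Emulates the statistical structure of a multiplex family study of an
autosomal-dominant, incompletely penetrant late-onset disease: a handful of
multigenerational families each segregating a rare causal variant dropped
from a founder, a background of neutral annotated exome variants at
Hardy–Weinberg founder frequencies, and a large reference cohort of carrier
counts. Families are ascertained the way such studies recruit them — a
family enters the cohort only if it contains multiple affected members.

A single seeded :class:`numpy.random.Generator` is threaded through every
operation; a seed fully determines all outputs, including emitted files
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .burden import CarrierCounts
from .cohort import Affection, Individual, Pedigree, Sex
from .filters import AnnotationRecord
from .io_formats import (GenotypeCall, VariantKey, VariantRecord,
                         write_annotation_table, write_carrier_table,
                         write_ped, write_vcf)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Defaults describe the emulated study design: four multigenerational
    families (three generations, mean sibship 3), a dominant causal variant
    with penetrance 0.95 against a 0.01 phenocopy rate, 2,000 neutral
    background variants, and recruitment conditional on at least three
    affected members per family (multiplex ascertainment).
    """

    n_families: int = 4
    n_generations: int = 3
    mean_sibship: float = 3.0
    penetrance: float = 0.95
    phenocopy_rate: float = 0.01
    causal_gene: str = "C8B"
    causal_cadd: float = 25.0
    causal_af: Optional[float] = 0.0014
    distinct_causal_variants: bool = False
    n_background_variants: int = 2000
    background_af_shape: tuple[float, float] = (0.5, 200.0)
    #: (p_damaging, benign_mean, benign_sd, damaging_mean, damaging_sd)
    cadd_mixture: tuple[float, float, float, float, float] = (0.3, 5.0, 4.0, 25.0, 5.0)
    category_weights: dict[str, float] = field(default_factory=lambda: {
        "exonic": 0.45, "splicing": 0.03, "intronic": 0.30,
        "UTR5": 0.05, "UTR3": 0.10, "intergenic": 0.07})
    genotype_missing_rate: float = 0.0
    af_missing_rate: float = 0.02
    min_affected: int = 3
    reference_n: int = 60706
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "genotype_missing_rate",
                     "af_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.penetrance <= self.phenocopy_rate:
            raise ValueError("penetrance must exceed phenocopy_rate for a "
                             "nondegenerate signal")
        if self.n_families < 1 or self.n_generations < 2:
            raise ValueError("need >= 1 family and >= 2 generations")
        if self.mean_sibship <= 0:
            raise ValueError("mean_sibship must be > 0")


def _roman(g: int) -> str:
    return _ROMAN[g - 1] if g <= len(_ROMAN) else str(g)


def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator,
                      family_id: str = "F1") -> Pedigree:
    """Simulate one multigenerational pedigree.

    Generation I is a founder couple; in each later generation every couple
    has a sibship of size 1 + Poisson(mean_sibship - 1), and each child in a
    non-terminal generation marries a founder spouse. Member ids follow the
    field convention ``<family>-<generation roman numeral>-<index>``.
    """
    members: list[Individual] = []
    father0 = Individual(f"{family_id}-I-1", family_id, sex=Sex.MALE)
    mother0 = Individual(f"{family_id}-I-2", family_id, sex=Sex.FEMALE)
    members += [father0, mother0]
    couples = [(father0.individual_id, mother0.individual_id)]
    lam = max(cfg.mean_sibship - 1.0, 0.0)
    for g in range(2, cfg.n_generations + 1):
        next_couples: list[tuple[str, str]] = []
        idx = 0
        for father_id, mother_id in couples:
            sibship = 1 + int(rng.poisson(lam))
            for _ in range(sibship):
                idx += 1
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = Individual(f"{family_id}-{_roman(g)}-{idx}", family_id,
                                   father_id=father_id, mother_id=mother_id,
                                   sex=sex)
                members.append(child)
                if g < cfg.n_generations:
                    idx += 1
                    spouse_sex = Sex.FEMALE if sex == Sex.MALE else Sex.MALE
                    spouse = Individual(f"{family_id}-{_roman(g)}-{idx}",
                                        family_id, sex=spouse_sex)
                    members.append(spouse)
                    if sex == Sex.MALE:
                        next_couples.append((child.individual_id,
                                             spouse.individual_id))
                    else:
                        next_couples.append((spouse.individual_id,
                                             child.individual_id))
        couples = next_couples
    return Pedigree(family_id, members)


def _topo_order(ped: Pedigree) -> list[Individual]:
    """Members ordered parents-before-children (Kahn's algorithm)."""
    remaining = {m.individual_id: m for m in ped.members}
    placed: set[str] = set()
    order: list[Individual] = []
    while remaining:
        progressed = False
        for iid in list(remaining):
            m = remaining[iid]
            deps = [p for p in (m.father_id, m.mother_id)
                    if p is not None and p in remaining]
            if not deps:
                order.append(m)
                placed.add(iid)
                del remaining[iid]
                progressed = True
        if not progressed:
            raise ValueError(f"pedigree {ped.family_id} has a parentage cycle")
    return order


def _drop_dosages(ped: Pedigree, founder_dosage: dict[str, np.ndarray],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised Mendelian gene-drop: per-individual alt-allele dosage
    arrays (one entry per variant), transmitting each parental allele with
    probability dosage/2."""
    dosages: dict[str, np.ndarray] = {}
    for m in _topo_order(ped):
        if m.is_founder:
            dosages[m.individual_id] = founder_dosage[m.individual_id]
        else:
            f = dosages[m.father_id]
            mo = dosages[m.mother_id]
            dosages[m.individual_id] = (
                (rng.random(f.shape) < f / 2.0).astype(np.int8)
                + (rng.random(mo.shape) < mo / 2.0).astype(np.int8))
    return dosages


_DOSAGE_CALLS = {0: GenotypeCall.HOM_REF, 1: GenotypeCall.HET,
                 2: GenotypeCall.HOM_ALT}


def gene_drop(ped: Pedigree, founder_carrier_id: str,
              rng: np.random.Generator) -> dict[str, GenotypeCall]:
    """Drop a single heterozygous founder variant through the pedigree.

    The seed carrier must be a founder; all other founders are hom-ref.
    Each child inherits the variant allele from a heterozygous parent with
    probability 1/2, so output genotypes are Mendelian-consistent by
    construction.
    """
    carrier = ped.get(founder_carrier_id)
    if carrier is None or not carrier.is_founder:
        raise ValueError(f"{founder_carrier_id!r} is not a founder of family "
                         f"{ped.family_id}")
    founder_dosage = {m.individual_id: np.array([1 if m.individual_id ==
                                                 founder_carrier_id else 0],
                                                dtype=np.int8)
                      for m in ped.members if m.is_founder}
    dosages = _drop_dosages(ped, founder_dosage, rng)
    return {iid: _DOSAGE_CALLS[int(d[0])] for iid, d in dosages.items()}


def assign_phenotypes(ped: Pedigree, genotypes: dict[str, GenotypeCall],
                      penetrance: float, phenocopy_rate: float,
                      rng: np.random.Generator) -> dict[str, Affection]:
    """Incomplete-penetrance phenotype model: carriers are affected with
    probability ``penetrance``, non-carriers with ``phenocopy_rate``,
    independently across members."""
    out: dict[str, Affection] = {}
    for m in ped.members:
        carrier = genotypes.get(m.individual_id) in (GenotypeCall.HET,
                                                     GenotypeCall.HOM_ALT)
        p = penetrance if carrier else phenocopy_rate
        out[m.individual_id] = (Affection.AFFECTED if rng.random() < p
                                else Affection.UNAFFECTED)
    return out


def simulate_background_variants(cfg: SimulationConfig,
                                 peds: Sequence[Pedigree],
                                 rng: np.random.Generator,
                                 afs: Optional[np.ndarray] = None,
                                 ) -> tuple[list[VariantRecord],
                                            list[AnnotationRecord]]:
    """Simulate unlinked neutral variants across all pedigrees.

    Per variant: the population allele frequency is drawn from
    Beta(background_af_shape); founders are genotyped under Hardy–Weinberg
    at that frequency and the variant is gene-dropped independently down
    each pedigree. Annotations draw the functional category from
    ``category_weights`` and the CADD score from a two-component
    (benign/damaging) normal mixture; the true frequency is written to the
    record except with probability ``af_missing_rate``, where it becomes the
    missing sentinel (novel-variant simulation). Genes come round-robin from
    a synthetic symbol pool that excludes the causal gene.
    """
    if afs is None:
        a, b = cfg.background_af_shape
        afs = rng.beta(a, b, size=cfg.n_background_variants)
    afs = np.asarray(afs, dtype=float)
    n = len(afs)
    if n == 0:
        return [], []

    pool = [f"GENE{i:04d}" for i in range(max(1, n // 2) + 1)
            ]
    pool = [g for g in pool if g != cfg.causal_gene][:max(1, n // 2)]
    genes = [pool[i % len(pool)] for i in range(n)]

    cats = list(cfg.category_weights)
    weights = np.array([cfg.category_weights[c] for c in cats], dtype=float)
    weights = weights / weights.sum()
    categories = rng.choice(len(cats), size=n, p=weights)

    p_dmg, b_mean, b_sd, d_mean, d_sd = cfg.cadd_mixture
    damaging = rng.random(n) < p_dmg
    cadd = np.where(damaging, rng.normal(d_mean, d_sd, n),
                    rng.normal(b_mean, b_sd, n))
    cadd = np.clip(cadd, 0.0, 99.0)
    af_missing = rng.random(n) < cfg.af_missing_rate

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    # gene-drop every variant through every pedigree (unlinked => independent)
    dosage_by_sample: dict[str, np.ndarray] = {}
    for ped in peds:
        founder_dosage = {m.individual_id: rng.binomial(2, afs).astype(np.int8)
                          for m in ped.members if m.is_founder}
        dosage_by_sample.update(_drop_dosages(ped, founder_dosage, rng))

    records: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    samples = [m.individual_id for ped in peds for m in ped.members]
    for i in range(n):
        key = VariantKey("1", 1_000_000 + 10 * i,
                         str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        calls = {s: _DOSAGE_CALLS[int(dosage_by_sample[s][i])] for s in samples}
        records.append(VariantRecord(key, calls))
        annotations.append(AnnotationRecord(
            key=key, gene=genes[i], category=cats[int(categories[i])],
            cadd_phred=round(float(cadd[i]), 2),
            exac_all_af=None if af_missing[i] else round(float(afs[i]), 6)))
    return records, annotations


def simulate_reference_cohort(n: int, af: float,
                              rng: np.random.Generator,
                              cohort: str = "reference") -> CarrierCounts:
    """Carrier counts for a reference population of size n under
    Hardy–Weinberg at allele frequency af: carrier probability
    1 - (1 - af)^2, homozygous fraction af^2 among genotypes."""
    if n < 1 or not 0.0 <= af <= 1.0:
        raise ValueError("need n >= 1 and af in [0,1]")
    p_carrier = 1.0 - (1.0 - af) ** 2
    carriers = int(rng.binomial(n, p_carrier))
    p_hom_given_carrier = (af ** 2 / p_carrier) if p_carrier > 0 else 0.0
    n_hom = int(rng.binomial(carriers, p_hom_given_carrier))
    return CarrierCounts(cohort, carriers - n_hom, n_hom, n - carriers)


@dataclass
class StudyData:
    """All in-memory products of one simulated study."""

    config: SimulationConfig
    pedigrees: dict[str, Pedigree]
    samples: list[str]
    variants: list[VariantRecord]
    annotations: list[AnnotationRecord]
    reference: dict[str, CarrierCounts]
    truth: dict


def _simulate_family(cfg: SimulationConfig, rng: np.random.Generator,
                     family_id: str) -> tuple[Pedigree, dict[str, GenotypeCall]]:
    """One ascertained family: redraw until >= min_affected affected members
    (multiplex recruitment), then attach affection status and severity
    grades to the pedigree."""
    for _ in range(1000):
        ped = simulate_pedigree(cfg, rng, family_id)
        founders = [f"{family_id}-I-1", f"{family_id}-I-2"]
        founder_carrier = founders[int(rng.integers(0, 2))]
        genotypes = gene_drop(ped, founder_carrier, rng)
        affection = assign_phenotypes(ped, genotypes, cfg.penetrance,
                                      cfg.phenocopy_rate, rng)
        n_affected = sum(1 for a in affection.values()
                         if a == Affection.AFFECTED)
        if n_affected < cfg.min_affected:
            continue
        members = []
        for m in ped.members:
            aff = affection[m.individual_id]
            if aff == Affection.AFFECTED:
                grade = int(rng.choice([4, 5]))
            else:
                grade = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            members.append(dataclasses.replace(m, affection=aff, amd_grade=grade))
        truth_ped = Pedigree(family_id, members)
        truth_ped._founder_carrier = founder_carrier  # type: ignore[attr-defined]
        return truth_ped, genotypes
    raise RuntimeError(f"could not ascertain family {family_id} with "
                       f">= {cfg.min_affected} affected members in 1000 draws")


def simulate_study(cfg: SimulationConfig,
                   seed: Optional[int] = None) -> StudyData:
    """Simulate the full study: ascertained families, the causal variant
    gene-dropped in every family, background variants, and a reference
    cohort."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pedigrees: dict[str, Pedigree] = {}
    causal_genotypes: dict[str, dict[str, GenotypeCall]] = {}
    for i in range(1, cfg.n_families + 1):
        fam = f"F{i}"
        ped, genotypes = _simulate_family(cfg, rng, fam)
        pedigrees[fam] = ped
        causal_genotypes[fam] = genotypes
    samples = [m.individual_id for ped in pedigrees.values()
               for m in ped.members]

    causal_records: list[VariantRecord] = []
    causal_annotations: list[AnnotationRecord] = []
    fams = list(pedigrees)
    if cfg.distinct_causal_variants:
        for j, fam in enumerate(fams):
            key = VariantKey("1", 500_000 + 10 * j, "G", "A")
            calls = {s: GenotypeCall.HOM_REF for s in samples}
            calls.update(causal_genotypes[fam])
            causal_records.append(VariantRecord(key, calls))
            causal_annotations.append(AnnotationRecord(
                key=key, gene=cfg.causal_gene, category="exonic",
                cadd_phred=cfg.causal_cadd, exac_all_af=cfg.causal_af))
    else:
        key = VariantKey("1", 500_000, "G", "A")
        calls = {}
        for fam in fams:
            calls.update(causal_genotypes[fam])
        causal_records.append(VariantRecord(key, calls))
        causal_annotations.append(AnnotationRecord(
            key=key, gene=cfg.causal_gene, category="exonic",
            cadd_phred=cfg.causal_cadd, exac_all_af=cfg.causal_af))

    bg_records, bg_annotations = simulate_background_variants(
        cfg, list(pedigrees.values()), rng)
    variants = causal_records + bg_records
    annotations = causal_annotations + bg_annotations

    if cfg.genotype_missing_rate > 0:
        for rec in variants:
            mask = rng.random(len(samples)) < cfg.genotype_missing_rate
            for s, miss in zip(samples, mask):
                if miss:
                    rec.genotypes[s] = GenotypeCall.MISSING

    ref_af = cfg.causal_af if cfg.causal_af is not None else 0.0014
    reference = {"reference": simulate_reference_cohort(
        cfg.reference_n, ref_af, rng)}

    truth = {
        "causal_gene": cfg.causal_gene,
        "causal_variants": [str(r.key) for r in causal_records],
        "founder_carrier_by_family": {
            fam: getattr(pedigrees[fam], "_founder_carrier") for fam in fams},
        "carriers_by_family": {
            fam: sorted(iid for iid, g in causal_genotypes[fam].items()
                        if g in (GenotypeCall.HET, GenotypeCall.HOM_ALT))
            for fam in fams},
        "affected_by_family": {
            fam: sorted(m.individual_id for m in pedigrees[fam].members
                        if m.affection == Affection.AFFECTED)
            for fam in fams},
    }
    return StudyData(cfg, pedigrees, samples, variants, annotations,
                     reference, truth)


def emit_fixture(cfg: SimulationConfig, out_dir: str | Path,
                 seed: Optional[int] = None) -> dict[str, Path]:
    """Write a complete synthetic fixture (VCF, PED, annotation TSV, carrier
    TSV, truth manifest) to ``out_dir``. Identical seeds give byte-identical
    files."""
    study = simulate_study(cfg, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "study.vcf",
        "ped": out_dir / "study.ped",
        "annotation": out_dir / "annotations.tsv",
        "carriers": out_dir / "carriers.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(study.samples, study.variants, paths["vcf"])
    write_ped(study.pedigrees, paths["ped"])
    write_annotation_table(study.annotations, paths["annotation"])
    write_carrier_table(study.reference, paths["carriers"])
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True)
                              + "\n")
    return paths
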