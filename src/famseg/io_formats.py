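"""Readers and writers for the formats the pipeline touches.

Multi-sample VCF (via pysam), 6-column PED pedigree text, ANNOVAR-style
annotation TSV, reference carrier-count TSV, and the ranked-gene /
burden report. Coordinates are 1-based throughout (VCF convention).
Phase is discarded; all sites are treated as diploid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .cohort import Affection, Individual, Pedigree, Sex

if TYPE_CHECKING:  # pragma: no cover
    from .burden import CarrierCounts
    from .filters import AnnotationRecord
    from .segregation import GeneHit


class FormatError(ValueError):
    """A file violated the expected format."""


class GenotypeCall(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic site: chromosome, 1-based position, ref and single alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if "," in self.alt:
            raise ValueError("alt must be a single allele (post-split)")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample diploid genotype calls."""

    key: VariantKey
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)


@dataclass
class RawVariantRow:
    """A VCF row before multiallelic splitting: alt alleles plus per-sample
    allele-index tuples (``None`` entries denote missing alleles)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[Optional[int], ...]]


def split_multiallelic(raw: RawVariantRow) -> list[VariantRecord]:
    """Split a row with k alt alleles into k biallelic records.

    For alt allele i, a sample's call is determined by its allele-i dosage:
    0 -> hom_ref (even when it carries other alt alleles), 1 -> het,
    2 -> hom_alt. Half-calls, non-diploid calls and "./." map to missing in
    every split record. Per-sample dosage is conserved across the output.
    """
    out: list[VariantRecord] = []
    for i, alt in enumerate(raw.alts, start=1):
        calls: dict[str, GenotypeCall] = {}
        for sample, alleles in raw.genotypes.items():
            if len(alleles) != 2 or any(a is None for a in alleles):
                calls[sample] = GenotypeCall.MISSING
                continue
            dosage = sum(1 for a in alleles if a == i)
            calls[sample] = (GenotypeCall.HOM_REF, GenotypeCall.HET,
                             GenotypeCall.HOM_ALT)[dosage]
        out.append(VariantRecord(VariantKey(raw.chrom, raw.pos, raw.ref, alt), calls))
    return out


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF 4.x file into biallelic variant records.

    Multiallelic rows are split; phased and unphased genotypes normalise to
    the same call; any call that is not a full diploid genotype is missing.
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: no GT FORMAT field declared in header")
        samples = list(vf.header.samples)
        records: list[VariantRecord] = []
        seen: set[VariantKey] = set()
        row_no = 0
        try:
            for rec in vf:
                row_no += 1
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                if not alts:
                    continue
                genotypes = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    genotypes[s] = tuple(gt) if gt is not None else (None, None)
                raw = RawVariantRow(rec.chrom, rec.pos, rec.ref, alts, genotypes)
                for split in split_multiallelic(raw):
                    if split.key in seen:
                        raise FormatError(
                            f"{path}: duplicate variant {split.key} after splitting")
                    seen.add(split.key)
                    records.append(split)
        except FormatError:
            raise
        except Exception as exc:  # pysam parse failure
            raise FormatError(f"{path}: malformed VCF near data row {row_no + 1}: {exc}")
    return samples, records


_GT_STRINGS = {
    GenotypeCall.HOM_REF: "0/0",
    GenotypeCall.HET: "0/1",
    GenotypeCall.HOM_ALT: "1/1",
    GenotypeCall.MISSING: "./.",
}


def write_vcf(samples: Sequence[str], records: Sequence[VariantRecord],
              path: str | Path) -> None:
    """Write biallelic records as a plain-text VCF 4.2 (GT only).

    Output is deterministic: identical inputs give byte-identical files.
    """
    chroms: list[str] = []
    for r in records:
        if r.key.chrom not in chroms:
            chroms.append(r.key.chrom)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for r in sorted(records, key=lambda r: (chroms.index(r.key.chrom), r.key.pos,
                                            r.key.ref, r.key.alt)):
        gts = "\t".join(_GT_STRINGS[r.genotypes.get(s, GenotypeCall.MISSING)]
                        for s in samples)
        lines.append(f"{r.key.chrom}\t{r.key.pos}\t.\t{r.key.ref}\t{r.key.alt}"
                     f"\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Read 6-column whitespace-delimited PED text into pedigrees.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), affection (2=affected, 1=unaffected, 0/-9=unknown); "0"
    denotes an unknown parent.
    """
    families: dict[str, list[Individual]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        fam, iid, fid, mid, sex, aff = parts[:6]
        families.setdefault(fam, []).append(Individual(
            individual_id=iid, family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
            affection=_AFF_CODES.get(aff, Affection.UNKNOWN),
        ))
    return {fam: Pedigree(fam, members) for fam, members in families.items()}


def write_ped(pedigrees: Mapping[str, Pedigree] | Sequence[Pedigree],
              path: str | Path) -> None:
    """Write pedigrees as 6-column PED text (deterministic order)."""
    peds = (list(pedigrees.values()) if isinstance(pedigrees, Mapping)
            else list(pedigrees))
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
               Affection.UNKNOWN: "0"}
    lines = []
    for ped in peds:
        for m in ped.members:
            lines.append("\t".join([ped.family_id, m.individual_id,
                                    m.father_id or "0", m.mother_id or "0",
                                    sex_out[m.sex], aff_out[m.affection]]))
    Path(path).write_text("\n".join(lines) + "\n")


#: logical name -> default ANNOVAR-style column header
DEFAULT_ANNOTATION_COLUMNS = {
    "chrom": "Chr",
    "pos": "Start",
    "ref": "Ref",
    "alt": "Alt",
    "gene": "Gene.refGene",
    "category": "Func.refGene",
    "cadd": "CADD_phred",
    "af": "ExAC_ALL",
}

MISSING_SENTINEL = "."  # the only recognised missing marker (ANNOVAR dialect)


def read_annotation_table(path: str | Path,
                          column_map: Optional[Mapping[str, str]] = None,
                          ) -> list["AnnotationRecord"]:
    """Read a per-variant annotation TSV.

    ``column_map`` maps the logical names (chrom, pos, ref, alt, gene,
    category, cadd, af) to the file's actual headers; unmapped names use the
    ANNOVAR-style defaults. "." in the CADD or AF column parses to a
    distinguished missing value, never zero.
    """
    from .filters import AnnotationRecord

    cols = dict(DEFAULT_ANNOTATION_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical, header in cols.items():
        if header not in df.columns:
            raise FormatError(f"{path}: missing required column {header!r} "
                              f"(for {logical})")

    def _number(text: str, column: str, lineno: int) -> Optional[float]:
        if text == MISSING_SENTINEL or text == "":
            return None
        try:
            return float(text)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: unparseable number {text!r} "
                              f"in column {column!r}")

    records: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        row_d = dict(zip(df.columns, row))
        records.append(AnnotationRecord(
            key=VariantKey(str(row_d[cols["chrom"]]), int(row_d[cols["pos"]]),
                           str(row_d[cols["ref"]]), str(row_d[cols["alt"]])),
            gene=str(row_d[cols["gene"]]),
            category=str(row_d[cols["category"]]),
            cadd_phred=_number(row_d[cols["cadd"]], cols["cadd"], lineno),
            exac_all_af=_number(row_d[cols["af"]], cols["af"], lineno),
        ))
    return records


def write_annotation_table(records: Sequence["AnnotationRecord"],
                           path: str | Path) -> None:
    """Write annotation records as ANNOVAR-style TSV (deterministic)."""
    cols = DEFAULT_ANNOTATION_COLUMNS

    def _fmt(x: Optional[float]) -> str:
        return MISSING_SENTINEL if x is None else format(x, "g")

    lines = ["\t".join(cols[k] for k in
                       ("chrom", "pos", "ref", "alt", "gene", "category", "cadd", "af"))]
    for r in records:
        lines.append("\t".join([r.key.chrom, str(r.key.pos), r.key.ref, r.key.alt,
                                r.gene, r.category, _fmt(r.cadd_phred),
                                _fmt(r.exac_all_af)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_carrier_table(path: str | Path) -> dict[str, "CarrierCounts"]:
    """Read a cohort carrier-count TSV (cohort, n_het, n_hom, n_noncarrier)."""
    from .burden import CarrierCounts

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cohort", "n_het", "n_hom", "n_noncarrier"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: dict[str, CarrierCounts] = {}
    for i, row in df.iterrows():
        label = row["cohort"]
        if label in out:
            raise FormatError(f"{path}: duplicate cohort label {label!r}")
        counts = [int(row[c]) for c in ("n_het", "n_hom", "n_noncarrier")]
        if any(c < 0 for c in counts):
            raise FormatError(f"{path}: negative count for cohort {label!r}")
        out[label] = CarrierCounts(label, *counts)
    return out


def write_carrier_table(counts: Mapping[str, "CarrierCounts"],
                        path: str | Path) -> None:
    lines = ["cohort\tn_het\tn_hom\tn_noncarrier"]
    for label in counts:
        c = counts[label]
        lines.append(f"{label}\t{c.n_het}\t{c.n_hom}\t{c.n_noncarrier}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt_float(x) -> str:
    if x is None:
        return "NA"
    try:
        import math
        if isinstance(x, float) and math.isnan(x):
            return "NA"
    except Exception:  # pragma: no cover
        pass
    return format(x, ".6g")


def write_report(ranked_hits: Sequence["GeneHit"], burden_rows: Sequence,
                 out_dir: str | Path,
                 known_gene_hits: Optional[Sequence["GeneHit"]] = None,
                 stage_counts: Optional[Mapping[str, int]] = None) -> dict[str, Path]:
    """Write the gene-level TSV, optional burden TSV and a human-readable
    summary. Deterministic: identical inputs yield byte-identical files.

    Returns the paths written keyed by section name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gene_lines = ["rank\tgene\tn_families\tfamilies\tn_variants\tvariants"
                  "\ttotal_affected_carriers"]
    for rank, hit in enumerate(ranked_hits, start=1):
        gene_lines.append("\t".join([
            str(rank), hit.gene, str(len(hit.families_passing)),
            ",".join(sorted(hit.families_passing)),
            str(len(hit.variants)),
            ",".join(str(k) for k in sorted(hit.variants)),
            str(hit.total_affected_carriers)]))
    paths["genes"] = out_dir / "genes.tsv"
    paths["genes"].write_text("\n".join(gene_lines) + "\n")

    if burden_rows:
        b_lines = ["variant\tfound\tcase_carriers\tcase_freq\tref_carriers"
                   "\tref_freq\todds_ratio\tfisher_p\tchi2_stat"]
        for row in burden_rows:
            b_lines.append("\t".join([
                str(row.key), str(row.found).lower(),
                str(row.case_counts.carriers) if row.found else "NA",
                _fmt_float(row.case_freq) if row.found else "NA",
                str(row.ref_counts.carriers),
                _fmt_float(row.ref_freq),
                _fmt_float(row.odds_ratio) if row.found else "NA",
                _fmt_float(row.fisher_p) if row.found else "NA",
                _fmt_float(row.chi2_stat) if row.found else "NA"]))
        paths["burden"] = out_dir / "burden.tsv"
        paths["burden"].write_text("\n".join(b_lines) + "\n")

    summary = ["# Family segregation report", ""]
    if stage_counts:
        summary.append("## Stage record counts")
        for stage, n in stage_counts.items():
            summary.append(f"- {stage}: {n}")
        summary.append("")
    summary.append("## Known-gene screen")
    if known_gene_hits:
        for hit in known_gene_hits:
            summary.append(f"- {hit.gene}: {len(hit.families_passing)} families, "
                           f"{len(hit.variants)} variants")
    else:
        summary.append("- no rare segregating variants in the known-gene list")
    summary += ["", "## Ranked genes (discovery)"]
    if ranked_hits:
        for rank, hit in enumerate(ranked_hits, start=1):
            summary.append(f"{rank}. {hit.gene} — {len(hit.families_passing)} families, "
                           f"{len(hit.variants)} variants, "
                           f"{hit.total_affected_carriers} affected carriers")
    else:
        summary.append("(no gene passed the segregation filter)")
    paths["summary"] = out_dir / "summary.md"
    paths["summary"].write_text("\n".join(summary) + "\n")
    return paths
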