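# Methods

## Problem and model

`famseg` implements a family-based rare-variant discovery analysis for a
late-onset, incompletely penetrant disease segregating in multiplex families
under an autosomal-dominant model. The analysis has five stages:

1. **Annotation-driven retention.** A variant is retained when its functional
   category is exonic or splicing (composite ANNOVAR categories such as
   `exonic;splicing` count if any component matches), its CADD phred score is
   at least 15 *or missing*, and its reference-population allele frequency
   (ExAC-style `ExAC_all` column) is at most 1% *or missing*. Missing scores
   and frequencies are retained deliberately: a novel variant has neither, and
   silently dropping it would defeat the purpose of rare-variant discovery.
   Both boundaries are inclusive; thresholds are configurable with these
   defaults.
2. **Per-family dominant segregation.** For one family and one variant, let
   n be the number of genotyped affected members and c the number of those who
   carry at least one alternate allele (het or hom-alt — a dominant model).
   The variant passes iff c ≥ 1 and n − c ≤ tolerance, with tolerance 1 by
   default ("all affected individuals, or all but one"). The c ≥ 1 guard
   prevents a one-affected family from passing with zero carriers under
   tolerance 1. Affected members with missing genotypes are excluded from n
   and reported separately: absence of data is not evidence of non-carriage.
   Unaffected members are ignored by default because the disease is late-onset
   and incompletely penetrant, so unaffected carriers are expected; a strict
   mode (`require_absent_in_unaffected`) is available and off by default.
3. **Gene collapsing and ranking.** Variants passing in any family are
   collapsed per gene; the hit's family set is the union over the gene's
   variants, so one variant shared by three families and three private
   variants in one gene contribute alike. Genes are ranked by descending
   family count, then descending total affected carriers, then symbol —
   deterministic and invariant to input order. No gene-level p-value is
   attached: the evidence unit is the number of supporting families. A
   known-gene screen (same filters restricted to a curated list) runs first
   and is reported separately even when empty.
4. **Carrier burden.** For a variant of interest, case samples are partitioned
   into het carriers, hom carriers, non-carriers and missing; carriers are
   counted at the person level (hom counts once; an allele-count mode exists
   but is off by default). The case-vs-reference 2×2 table is tested with a
   two-sided Fisher's exact test using the probability-ordering rule — sum the
   hypergeometric probabilities of all tables with the observed margins whose
   probability does not exceed the observed table's, within relative tolerance
   1e-12 (two-sided conventions differ between packages; this is the one used
   by mainstream statistics software). Probabilities are accumulated from a
   cached log-factorial table, which is stable at reference-cohort scale
   (N > 60,000). Chi-squared expected counts (row × column / N) are reported
   alongside, without continuity correction; a zero margin flags the statistic
   undefined rather than raising.
5. **Two-locus co-occurrence.** Among individuals satisfying two genotype
   predicates (e.g. homozygous for a common risk allele *and* carrying the
   rare variant), the fraction with an outcome is reported as (k, n, %) with
   the percentage rounded half away from zero. No test is attached — the
   qualifying n is too small for inference by design.

## Co-IP quantification

Band intensities are normalised to the input control (total protein), then
divided by the wild-type condition's mean so WT sits at 1 identically; the
transform is invariant to rescaling all raw intensities. Conditions are
compared with a two-sample Wilcoxon rank-sum test: midranks for ties, the
null distribution enumerated exactly for pooled sizes up to 12 (triplicate
scale), two-sided p by doubling the smaller tail (observed value included)
capped at 1; larger samples use the normal approximation with tie correction
and no continuity correction. When all pooled values are identical the test
is uninformative and p = 1. The "Wilcoxon test" is interpreted as the
two-sample rank-sum because independent transfection conditions are compared;
an exact signed-rank variant is exposed for genuinely paired designs.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

- **Pedigrees.** A founder couple; each couple's sibship is
  1 + Poisson(mean sibship − 1); children in non-terminal generations marry
  founder spouses. Defaults: 4 families, 3 generations, mean sibship 3
  (≈ 17–21 members per family).
- **Ascertainment.** A family is redrawn until it has at least 3 affected
  members (`min_affected`), emulating how multiplex families are recruited
  into such studies. This conditions the joint distribution of genotypes and
  phenotypes exactly as real recruitment does.
- **Causal variant.** One founder of each family is a het carrier; the allele
  is gene-dropped (each parental allele transmitted with probability
  dosage/2). By default all families share one variant in the causal gene; a
  switch gives each family a private variant in the same gene. Carriers are
  affected with probability 0.95 (penetrance), non-carriers with 0.01
  (phenocopy rate).
- **Background variants.** 2,000 unlinked neutral variants; population allele
  frequency ~ Beta(0.5, 200) (mean ≈ 0.25%, long tail crossing the 1% filter
  boundary), founders drawn under Hardy–Weinberg, then gene-dropped. CADD
  scores come from a benign/damaging normal mixture
  (0.7·N(5, 4) + 0.3·N(25, 5), clipped to [0, 99]) so the CADD filter is
  exercised on both sides of 15; categories are drawn from a weight table
  dominated by exonic/intronic; the annotation's AF field is the missing
  sentinel "." with probability 0.02 (novel-variant simulation).
- **Reference cohort.** Carrier counts for N = 60,706 drawn binomially at
  carrier probability 1 − (1 − AF)², split het/hom by Hardy–Weinberg.
- **Phenotype grades.** Affected members get severity grade 4 or 5,
  unaffected 1–3 weighted toward 1 — cosmetic, to exercise grading I/O.
- **Determinism.** One seeded `numpy.random.Generator` is threaded through
  everything; a seed fully determines all outputs, including emitted files
  byte for byte. Genotype missingness defaults to 0 (within analyzed
  pedigrees every contributing member is genotyped); a configurable missing
  rate exists for testing the missing-data rules.

What the generator does *not* model: linkage disequilibrium (variants drop
independently), realistic site-frequency spectra, mutation, age-of-onset
liability, and genotyping error. Passing tests therefore demonstrate the
correctness of the filtering/segregation/collapsing logic and the calibration
of the statistics under idealised inheritance, not robustness to artefacts of
real sequencing data.

## Severity grading

Per eye: grade 1 for no or small drusen (<63 µm), 2 for medium drusen
(63–124 µm), 3 for large or very large drusen (≥125 µm; the two large bins
collapse into one grade). GA or CNV in an eye overrides its drusen grade; an
individual is grade 4 with GA/CNV in exactly one eye and 5 with both (an eye
with both GA and CNV counts once). Otherwise the individual takes the worse
eye's drusen grade. Grading consumes structured findings only; how clinical
history might adjust a photographic grade is out of scope.

## Numerical and design choices

- Fisher tie tolerance 1e-12: for N ≤ 40 distinct integer hypergeometric
  numerators differ relatively by ≥ 1/C(40,20) ≈ 7×10⁻¹², safely above both
  the tolerance and log-gamma rounding (~10⁻¹⁴), so tie classification is
  exact there.
- Problem sizes in the test and acceptance suites — 100 discovery replicates,
  200 null-calibration replicates, exhaustive Fisher checks to N = 40,
  exhaustive segregation configurations to 6 affecteds, 10,000 transmission
  drops — were chosen to give tight Monte-Carlo bounds (3–4 SE) while keeping
  a full run at desk scale.
- Filter order (category → CADD → MAF → segregation) follows the analysis
  narrative; the filters commute, so order affects only per-stage logs.
- Variant keys are (chrom, 1-based pos, ref, single alt) after multiallelic
  splitting; annotation joins are exact on that key; phase is discarded and
  all sites treated diploid (the model is autosomal).
- The rank-sum example {1,2,4} vs {3,5,6} evaluates to p = 0.2 under the
  doubling rule (tail mass 2/20), matching scipy's exact method.

## Known limitations

- The segregation rule operates on whichever genotypes are loaded; it does
  not distinguish discovery (sequenced) from validation (targeted) samples.
- Only one reference AF column is consulted; population-specific frequencies
  are not modelled.
- No multiple-testing correction across genes or variants; burden p-values
  are reported raw with cohort sizes.
- The known-gene screen shares thresholds with discovery; a separate
  threshold set per screen is not implemented.
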