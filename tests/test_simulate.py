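"""Gene-dropping simulator: Mendelian transmission, penetrance model,
Hardy–Weinberg reference cohorts, fixture determinism."""

import json

import numpy as np
import pytest

from famseg import (Affection, GenotypeCall, SimulationConfig, Individual,
                    Pedigree, Sex, assign_phenotypes, emit_fixture, gene_drop,
                    read_annotation_table, read_carrier_table, read_ped,
                    read_vcf, simulate_background_variants, simulate_pedigree,
                    simulate_reference_cohort, simulate_study,
                    validate_pedigree)
from conftest import check_mendelian

G = GenotypeCall


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(penetrance=0.01, phenocopy_rate=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_generations=1)
    with pytest.raises(ValueError):
        SimulationConfig(mean_sibship=0.0)


def test_pedigree_reproducible_under_seed():
    cfg = SimulationConfig()
    p1 = simulate_pedigree(cfg, np.random.default_rng(5), "F1")
    p2 = simulate_pedigree(cfg, np.random.default_rng(5), "F1")
    assert [m.individual_id for m in p1.members] == \
        [m.individual_id for m in p2.members]
    assert validate_pedigree(p1) == []
    founders = p1.founders()
    assert {f.sex for f in founders[:2]} == {Sex.MALE, Sex.FEMALE}


def small_trio():
    return Pedigree("T", [
        Individual("dad", "T", sex=Sex.MALE),
        Individual("mum", "T", sex=Sex.FEMALE),
        Individual("kid", "T", father_id="dad", mother_id="mum"),
    ])


def test_gene_drop_requires_founder_carrier():
    with pytest.raises(ValueError):
        gene_drop(small_trio(), "kid", np.random.default_rng(0))
    with pytest.raises(ValueError):
        gene_drop(small_trio(), "nobody", np.random.default_rng(0))


def test_gene_drop_homref_parents_give_homref_children():
    ped = small_trio()
    rng = np.random.default_rng(0)
    for _ in range(100):
        calls = gene_drop(ped, "dad", rng)
        assert calls["mum"] == G.HOM_REF
        if calls["dad"] == G.HET and calls["kid"] == G.HOM_ALT:
            pytest.fail("child cannot be hom-alt with one het parent")


def test_gene_drop_transmission_is_mendelian():
    """Het x hom-ref transmission ~ 1/2 (3 SE over 2,000 drops here; the
    full 10,000-drop check lives in the acceptance suite)."""
    ped = small_trio()
    rng = np.random.default_rng(1)
    n = 2000
    carried = sum(gene_drop(ped, "dad", rng)["kid"] != G.HOM_REF
                  for _ in range(n))
    se = (0.25 / n) ** 0.5
    assert abs(carried / n - 0.5) < 3 * se


def test_phenotypes_deterministic_extremes():
    ped = small_trio()
    rng = np.random.default_rng(2)
    genotypes = {"dad": G.HET, "mum": G.HOM_REF, "kid": G.HET}
    aff = assign_phenotypes(ped, genotypes, 1.0, 0.0, rng)
    assert aff == {"dad": Affection.AFFECTED, "mum": Affection.UNAFFECTED,
                   "kid": Affection.AFFECTED}
    none = assign_phenotypes(ped, genotypes, 1e-12, 0.0, rng)
    assert Affection.AFFECTED not in none.values()


def test_penetrance_rate_matches_binomial():
    ped = small_trio()
    rng = np.random.default_rng(3)
    genotypes = {"dad": G.HET, "mum": G.HOM_REF, "kid": G.HOM_REF}
    n = 5000
    hits = sum(assign_phenotypes(ped, genotypes, 0.9, 0.0, rng)["dad"]
               == Affection.AFFECTED for _ in range(n))
    se = (0.9 * 0.1 / n) ** 0.5
    assert abs(hits / n - 0.9) < 4 * se


def test_background_af_zero_gives_monomorphic_variant(study, default_cfg):
    rng = np.random.default_rng(4)
    peds = list(study.pedigrees.values())
    records, annotations = simulate_background_variants(
        default_cfg, peds, rng, afs=np.array([0.0, 0.5]))
    assert all(g == G.HOM_REF for g in records[0].genotypes.values())
    assert len(records) == 2 and len(annotations) == 2
    assert annotations[0].gene != default_cfg.causal_gene


def test_background_empty():
    cfg = SimulationConfig(n_background_variants=0)
    rng = np.random.default_rng(0)
    ped = simulate_pedigree(cfg, rng, "F1")
    assert simulate_background_variants(cfg, [ped], rng) == ([], [])


def test_background_founder_af_matches_beta_mean(default_cfg):
    rng = np.random.default_rng(5)
    ped = small_trio()
    n = 5000
    cfg = SimulationConfig(n_background_variants=n)
    records, _ = simulate_background_variants(cfg, [ped], rng)
    alpha, beta = cfg.background_af_shape
    dosage = {G.HOM_REF: 0, G.HET: 1, G.HOM_ALT: 2}
    founder_af = np.mean([(dosage[r.genotypes["dad"]]
                           + dosage[r.genotypes["mum"]]) / 4 for r in records])
    mean = alpha / (alpha + beta)
    var_af = (alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1)))
    # SE combines Beta sampling of p and binomial founder sampling
    se = np.sqrt((var_af + mean * (1 - mean) / 4) / n)
    assert abs(founder_af - mean) < 3 * se


def test_reference_cohort_extremes_and_hwe():
    rng = np.random.default_rng(6)
    zero = simulate_reference_cohort(100, 0.0, rng)
    assert zero.carriers == 0 and zero.n_noncarrier == 100
    full = simulate_reference_cohort(100, 1.0, rng)
    assert full.n_hom == 100 and full.n_noncarrier == 0

    af, n = 0.001, 60706
    counts = simulate_reference_cohort(n, af, rng)
    p = 1 - (1 - af) ** 2
    se = (n * p * (1 - p)) ** 0.5
    assert abs(counts.carriers - n * p) < 4 * se


def test_study_is_mendelian_consistent(study):
    for ped in study.pedigrees.values():
        assert check_mendelian(ped, study.variants) == []


def test_study_ascertainment_and_grades(study):
    for ped in study.pedigrees.values():
        affected = [m for m in ped.members
                    if m.affection == Affection.AFFECTED]
        assert len(affected) >= study.config.min_affected
        assert all(m.amd_grade in (4, 5) for m in affected)
        assert all(m.amd_grade in (1, 2, 3) for m in ped.members
                   if m.affection == Affection.UNAFFECTED)


def test_study_determinism(default_cfg):
    s1 = simulate_study(default_cfg, seed=11)
    s2 = simulate_study(default_cfg, seed=11)
    assert s1.truth == s2.truth
    assert [r.genotypes for r in s1.variants] == \
        [r.genotypes for r in s2.variants]


def test_distinct_causal_variants_mode():
    cfg = SimulationConfig(distinct_causal_variants=True,
                           n_background_variants=10)
    s = simulate_study(cfg, seed=1)
    assert len(s.truth["causal_variants"]) == cfg.n_families
    causal_ann = [a for a in s.annotations if a.gene == cfg.causal_gene]
    assert len(causal_ann) == cfg.n_families


def test_genotype_missing_rate_applied():
    cfg = SimulationConfig(genotype_missing_rate=0.2,
                           n_background_variants=50)
    s = simulate_study(cfg, seed=2)
    calls = [g for r in s.variants for g in r.genotypes.values()]
    frac = sum(g == G.MISSING for g in calls) / len(calls)
    assert 0.1 < frac < 0.3


def test_fixture_files_roundtrip(tmp_path, default_cfg):
    paths = emit_fixture(default_cfg, tmp_path, seed=9)
    samples, variants = read_vcf(paths["vcf"])
    peds = read_ped(paths["ped"])
    annotations = read_annotation_table(paths["annotation"])
    carriers = read_carrier_table(paths["carriers"])
    truth = json.loads(paths["truth"].read_text())

    assert len(peds) == default_cfg.n_families
    assert len(variants) == len(annotations)
    assert set(samples) == {m.individual_id for p in peds.values()
                            for m in p.members}
    assert "reference" in carriers
    causal_genes = {a.gene for a in annotations
                    if str(a.key) in truth["causal_variants"]}
    assert causal_genes == {truth["causal_gene"]}
    # the causal gene labels exactly the causal variants
    assert all(str(a.key) in truth["causal_variants"]
               for a in annotations if a.gene == truth["causal_gene"])
    for ped in peds.values():
        assert validate_pedigree(ped) == []
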