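import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famseg import (Affection, GenotypeCall, Individual, Pedigree, Sex,
                    SimulationConfig, simulate_study)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_trio(affections=(Affection.UNAFFECTED, Affection.UNAFFECTED,
                          Affection.AFFECTED)) -> Pedigree:
    """Father, mother, child."""
    return Pedigree("FAM", [
        Individual("dad", "FAM", sex=Sex.MALE, affection=affections[0]),
        Individual("mum", "FAM", sex=Sex.FEMALE, affection=affections[1]),
        Individual("kid", "FAM", father_id="dad", mother_id="mum",
                   sex=Sex.MALE, affection=affections[2]),
    ])


def make_affected_sibship(n_affected: int, n_unaffected: int = 0) -> Pedigree:
    """Founder couple with a sibship of affected (a1..) and unaffected
    (u1..) children — the minimal shape for segregation truth tables."""
    members = [
        Individual("dad", "FAM", sex=Sex.MALE, affection=Affection.UNKNOWN),
        Individual("mum", "FAM", sex=Sex.FEMALE, affection=Affection.UNKNOWN),
    ]
    for i in range(1, n_affected + 1):
        members.append(Individual(f"a{i}", "FAM", father_id="dad",
                                  mother_id="mum", affection=Affection.AFFECTED))
    for i in range(1, n_unaffected + 1):
        members.append(Individual(f"u{i}", "FAM", father_id="dad",
                                  mother_id="mum",
                                  affection=Affection.UNAFFECTED))
    return Pedigree("FAM", members)


_ALT_GIVERS = {GenotypeCall.HET, GenotypeCall.HOM_ALT}
_REF_GIVERS = {GenotypeCall.HET, GenotypeCall.HOM_REF}


def trio_consistent(child: GenotypeCall, father: GenotypeCall,
                    mother: GenotypeCall) -> bool:
    """Independent Mendelian trio check on genotype states (missing anywhere
    is vacuously consistent)."""
    calls = (child, father, mother)
    if GenotypeCall.MISSING in calls:
        return True
    if child == GenotypeCall.HOM_ALT:
        return father in _ALT_GIVERS and mother in _ALT_GIVERS
    if child == GenotypeCall.HOM_REF:
        return father in _REF_GIVERS and mother in _REF_GIVERS
    # het child: one parent must be able to give alt while the other gives ref
    return ((father in _ALT_GIVERS and mother in _REF_GIVERS)
            or (father in _REF_GIVERS and mother in _ALT_GIVERS))


def check_mendelian(ped: Pedigree, records) -> list[str]:
    """All trio violations across a pedigree and variant records."""
    violations = []
    for rec in records:
        for m in ped.members:
            if m.father_id is None:
                continue
            ok = trio_consistent(
                rec.genotypes.get(m.individual_id, GenotypeCall.MISSING),
                rec.genotypes.get(m.father_id, GenotypeCall.MISSING),
                rec.genotypes.get(m.mother_id, GenotypeCall.MISSING))
            if not ok:
                violations.append(f"{rec.key} trio {m.individual_id}")
    return violations


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def study(default_cfg):
    return simulate_study(default_cfg, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
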