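"""Pedigree and phenotype domain model for familial late-onset macular degeneration.

A study cohort is a set of families, each a :class:`Pedigree` of
:class:`Individual` members with sex, parentage and affection status.
Disease severity is summarised per individual on a five-grade scale derived
from structured ocular findings (drusen size and the presence of geographic
atrophy, GA, or choroidal neovascularisation, CNV, per eye), with the worse
eye determining the individual's phenotype category.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders; otherwise both must
    name members of the same pedigree (validated by :func:`validate_pedigree`).
    ``amd_grade`` is the optional 1..5 severity grade.
    """

    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    amd_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.amd_grade is not None and not 1 <= self.amd_grade <= 5:
            raise ValueError(f"amd_grade must be in 1..5, got {self.amd_grade}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family's parentage graph.

    Members are kept in insertion order; lookup is by ``individual_id``
    (unique within the family — cross-family collisions are legal, keys are
    ``(family_id, individual_id)`` at the cohort level).
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, Individual] = {}
        for m in self.members:
            if m.individual_id in self._index:
                # kept so validate_pedigree can report it; index holds first
                continue
            self._index[m.individual_id] = m

    def get(self, individual_id: str) -> Optional[Individual]:
        return self._index.get(individual_id)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def ids(self) -> set[str]:
        return set(self._index)


@dataclass(frozen=True)
class Eye:
    """Structured findings for one eye."""

    max_drusen_size_um: float = 0.0
    has_ga: bool = False
    has_cnv: bool = False

    def __post_init__(self) -> None:
        if self.max_drusen_size_um < 0:
            raise ValueError("drusen size must be non-negative")

    @property
    def advanced(self) -> bool:
        return self.has_ga or self.has_cnv


@dataclass(frozen=True)
class EyeFindings:
    """Findings for exactly two eyes of one individual."""

    right: Eye
    left: Eye

    @property
    def eyes(self) -> tuple[Eye, Eye]:
        return (self.right, self.left)


GRADE_CATEGORIES = {
    1: "None or small drusen",
    2: "Medium drusen",
    3: "Large or very large drusen",
    4: "Advanced AMD",
    5: "Advanced AMD",
}


def _drusen_grade(size_um: float) -> int:
    # <63 um: none/small; 63-124: medium; >=125 (125-249 and >249 collapse): large
    if size_um < 63:
        return 1
    if size_um < 125:
        return 2
    return 3


def assign_amd_grade(findings: EyeFindings) -> tuple[int, str]:
    """Assign the modified five-level severity grade for one individual.

    Per-eye severity: grade 1 for no or small drusen (<63 µm), 2 for medium
    drusen (63–124 µm), 3 for large or very large drusen (≥125 µm); GA or CNV
    in an eye overrides its drusen grade. The individual is grade 4 when
    exactly one eye shows GA/CNV, grade 5 when both do, otherwise the worse
    eye's drusen grade. Grades 4–5 map to the "Advanced AMD" category.
    """
    n_advanced = sum(1 for eye in findings.eyes if eye.advanced)
    if n_advanced == 2:
        grade = 5
    elif n_advanced == 1:
        grade = 4
    else:
        grade = max(_drusen_grade(eye.max_drusen_size_um) for eye in findings.eyes)
    return grade, GRADE_CATEGORIES[grade]


@dataclass(frozen=True)
class Violation:
    """One pedigree-invariant violation, as data rather than an exception."""

    individual_id: str
    rule: str
    message: str


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check all pedigree invariants; return an empty list iff all hold.

    Rules checked: unique member ids; parents either both unknown or both
    present in the pedigree; named fathers are male-or-unknown and mothers
    female-or-unknown; the parentage graph is acyclic.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for m in ped.members:
        if m.individual_id in seen:
            out.append(Violation(m.individual_id, "duplicate_id",
                                 f"individual id {m.individual_id!r} occurs more than once"))
        seen.add(m.individual_id)

    for m in ped.members:
        if (m.father_id is None) != (m.mother_id is None):
            out.append(Violation(m.individual_id, "half_unknown_parent",
                                 "father and mother must be both unknown or both named"))
        for role, pid in (("father", m.father_id), ("mother", m.mother_id)):
            if pid is None:
                continue
            parent = ped.get(pid)
            if parent is None:
                out.append(Violation(m.individual_id, "missing_parent",
                                     f"{role} {pid!r} is not a member of family {ped.family_id}"))
                continue
            if role == "father" and parent.sex == Sex.FEMALE:
                out.append(Violation(pid, "father_sex",
                                     f"{pid!r} is named as father but has sex female"))
            if role == "mother" and parent.sex == Sex.MALE:
                out.append(Violation(pid, "mother_sex",
                                     f"{pid!r} is named as mother but has sex male"))

    # cycle detection over the child -> parent edges
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {m.individual_id: WHITE for m in ped.members}

    def visit(start: str) -> bool:
        stack = [(start, iter(_parent_ids(ped, start)))]
        color[start] = GRAY
        while stack:
            node, it = stack[-1]
            advanced = False
            for pid in it:
                if pid not in color:
                    continue
                if color[pid] == GRAY:
                    return True
                if color[pid] == WHITE:
                    color[pid] = GRAY
                    stack.append((pid, iter(_parent_ids(ped, pid))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
        return False

    for m in ped.members:
        if color[m.individual_id] == WHITE and visit(m.individual_id):
            out.append(Violation(m.individual_id, "cycle",
                                 f"{m.individual_id!r} is its own ancestor"))
    return out


def _parent_ids(ped: Pedigree, individual_id: str) -> list[str]:
    m = ped.get(individual_id)
    if m is None:
        return []
    return [p for p in (m.father_id, m.mother_id) if p is not None]


def affected_members(ped: Pedigree, genotyped_only: bool = False,
                     sample_ids: Optional[Iterable[str]] = None) -> set[str]:
    """Ids of affected members, optionally restricted to genotyped samples.

    Members with unknown affection are never counted. When ``genotyped_only``
    is set, ``sample_ids`` must be given and the affected set is intersected
    with it.
    """
    affected = {m.individual_id for m in ped.members if m.affection == Affection.AFFECTED}
    if genotyped_only:
        if sample_ids is None:
            raise ValueError("genotyped_only requires sample_ids")
        affected &= set(sample_ids)
    return affected
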