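"""Pedigree containers: individuals, nuclear families, cohorts.

Genotypes are stored as per-SNP risk-allele counts (additive coding): an
int8 array aligned with the panel, with values 0/1/2 and ``MISSING`` (-1)
for an untyped marker. Raw allele pairs exist only at PED I/O time.

Only two-generation nuclear families (two genotyped founders plus their
children) are supported; sex must be known for every individual because the
downstream model is strictly sex-stratified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import SNPPanel

__all__ = ["MISSING", "Individual", "Family", "Cohort", "FOUNDER"]

MISSING: int = -1
#: parent-id sentinel marking a founder in PED files
FOUNDER: str = "0"

_SEXES = ("male", "female")
_AFFECTIONS = ("affected", "unaffected", "unknown")


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: str
    affection: str
    genotypes: np.ndarray  # int8 risk-allele counts, MISSING = -1

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"{self.individual_id}: sex must be male/female, got {self.sex!r}")
        if self.affection not in _AFFECTIONS:
            raise ValueError(f"{self.individual_id}: bad affection {self.affection!r}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{self.individual_id}: genotype counts must be 0/1/2 or missing")

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER

    @property
    def is_affected(self) -> bool:
        return self.affection == "affected"


@dataclass
class Family:
    """A nuclear family: two genotyped founders and >= 1 child."""

    family_id: str
    father: Individual
    mother: Individual
    children: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError(f"family {self.family_id}: needs at least one child")
        if self.father.sex != "male" or self.mother.sex != "female":
            raise ValueError(f"family {self.family_id}: father must be male, mother female")
        if not (self.father.is_founder and self.mother.is_founder):
            raise ValueError(f"family {self.family_id}: parents must be founders")
        for c in self.children:
            if c.father_id != self.father.individual_id or c.mother_id != self.mother.individual_id:
                raise ValueError(
                    f"family {self.family_id}: child {c.individual_id} does not "
                    "reference the two founders"
                )

    @property
    def affected_children(self) -> list[Individual]:
        return [c for c in self.children if c.is_affected]

    @property
    def unaffected_children(self) -> list[Individual]:
        return [c for c in self.children if c.affection == "unaffected"]

    def members(self) -> list[Individual]:
        return [self.father, self.mother, *self.children]


@dataclass
class Cohort:
    families: list[Family]
    panel: SNPPanel

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family_id in cohort")
        width = len(self.panel)
        for fam in self.families:
            for ind in fam.members():
                if ind.genotypes.shape != (width,):
                    raise ValueError(
                        f"{ind.individual_id}: genotype vector length "
                        f"{ind.genotypes.shape} does not match panel size {width}"
                    )

    def __len__(self) -> int:
        return len(self.families)

    def individuals(self) -> list[Individual]:
        return [ind for fam in self.families for ind in fam.members()]

    @property
    def n_affected_children(self) -> int:
        return sum(len(f.affected_children) for f in self.families)
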