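"""Whitespace-delimited 6-column PED reader/writer.

Row layout: family_id, individual_id, father_id, mother_id, sex (1=male,
2=female), affection (2=affected, 1=unaffected, 0=unknown), then two allele
columns per panel SNP in panel order. Allele code "0" (twice) marks a
missing genotype; any allele other than the SNP's risk/other allele or "0"
is rejected.
"""

from __future__ import annotations

from .families import FOUNDER, MISSING, Cohort, Family, Individual
from .panel import SNPPanel

__all__ = ["read_ped", "write_ped", "PedParseError"]

_SEX_IN = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2"}
_AFF_IN = {"2": "affected", "1": "unaffected", "0": "unknown"}
_AFF_OUT = {v: k for k, v in _AFF_IN.items()}


class PedParseError(ValueError):
    """Malformed or inconsistent PED content; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _alleles_to_count(a1: str, a2: str, snp, line: int) -> int:
    if a1 == "0" and a2 == "0":
        return MISSING
    count = 0
    for a in (a1, a2):
        if a == snp.risk_allele:
            count += 1
        elif a == snp.other_allele:
            pass
        else:
            raise PedParseError(
                f"allele {a!r} at {snp.snp_id} not in "
                f"{{{snp.risk_allele}, {snp.other_allele}, 0}}",
                line,
            )
    return count


def read_ped(path, panel: SNPPanel) -> Cohort:
    """Parse a PED file into a :class:`Cohort` of nuclear families.

    Founders are rows whose parent ids are both "0"; every non-founder row
    must reference a genotyped father and mother present in the same family.
    """
    n_cols = 6 + 2 * len(panel)
    rows: list[tuple[int, Individual]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) != n_cols:
                raise PedParseError(
                    f"expected {n_cols} columns (6 + 2 per SNP), got {len(fields)}", lineno
                )
            fam_id, ind_id, fa_id, mo_id, sex_code, aff_code = fields[:6]
            if sex_code not in _SEX_IN:
                raise PedParseError(f"sex code {sex_code!r} not in {{1, 2}}", lineno)
            if aff_code not in _AFF_IN:
                raise PedParseError(f"affection code {aff_code!r} not in {{0, 1, 2}}", lineno)
            if (fa_id == FOUNDER) != (mo_id == FOUNDER):
                raise PedParseError("half-founder rows (one parent id 0) unsupported", lineno)
            counts = [
                _alleles_to_count(fields[6 + 2 * j], fields[7 + 2 * j], snp, lineno)
                for j, snp in enumerate(panel)
            ]
            rows.append(
                (
                    lineno,
                    Individual(
                        family_id=fam_id,
                        individual_id=ind_id,
                        father_id=fa_id,
                        mother_id=mo_id,
                        sex=_SEX_IN[sex_code],
                        affection=_AFF_IN[aff_code],
                        genotypes=counts,
                    ),
                )
            )

    families: list[Family] = []
    by_family: dict[str, list[tuple[int, Individual]]] = {}
    order: list[str] = []
    for lineno, ind in rows:
        if ind.family_id not in by_family:
            order.append(ind.family_id)
        by_family.setdefault(ind.family_id, []).append((lineno, ind))
    for fam_id in order:
        members = by_family[fam_id]
        founders = [(ln, i) for ln, i in members if i.is_founder]
        children = [i for _, i in members if not i.is_founder]
        fathers = [i for _, i in founders if i.sex == "male"]
        mothers = [i for _, i in founders if i.sex == "female"]
        if len(fathers) != 1 or len(mothers) != 1:
            raise PedParseError(
                f"family {fam_id}: needs exactly one male and one female founder",
                members[0][0],
            )
        families.append(Family(fam_id, fathers[0], mothers[0], children))
    return Cohort(families=families, panel=panel)


def _format_genotype(count: int, snp) -> str:
    if count == MISSING:
        return "0 0"
    n_risk = int(count)
    return " ".join([snp.risk_allele] * n_risk + [snp.other_allele] * (2 - n_risk))


def write_ped(cohort: Cohort, path) -> None:
    """Write a cohort as standard PED (inverse of :func:`read_ped`)."""
    with open(path, "w") as fh:
        for fam in cohort.families:
            for ind in fam.members():
                lead = [
                    ind.family_id,
                    ind.individual_id,
                    ind.father_id,
                    ind.mother_id,
                    _SEX_OUT[ind.sex],
                    _AFF_OUT[ind.affection],
                ]
                geno = [_format_genotype(c, snp) for c, snp in zip(ind.genotypes, cohort.panel)]
                fh.write(" ".join(lead + geno) + "\n")
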