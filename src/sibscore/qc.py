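"""Genotype quality control for nuclear-family cohorts.

Three checks, all on risk-allele counts:

* Mendelian consistency — a child's count must be reachable as one paternal
  plus one maternal transmission given the parental counts.
* Hardy-Weinberg equilibrium — conditional exact test on founder genotype
  counts per SNP (two-sided: sum of probabilities of heterozygote counts no
  more probable than the observed one, conditional on the allele counts).
* Missingness — per-SNP missing fraction over all individuals; SNPs above
  the threshold are flagged in the report, never silently dropped, so the
  audit trail survives.

Families with any Mendelian inconsistency are excluded by ``apply_qc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .families import MISSING, Cohort, Family
from .panel import SNPPanel

__all__ = [
    "MendelianInconsistency",
    "QCReport",
    "transmissible_counts",
    "mendelian_check",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass(frozen=True)
class MendelianInconsistency:
    family_id: str
    child_id: str
    snp_id: str


@dataclass
class QCReport:
    missing_fraction: dict[str, float]
    hwe_pvalue: dict[str, float]
    inconsistencies: list[MendelianInconsistency]
    excluded_families: list[str]
    flagged_snps: list[str] = field(default_factory=list)
    max_missing: float = 0.05


# transmissions a parent with count c can make (risk-allele copies passed on)
_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}


def transmissible_counts(father_count: int, mother_count: int) -> frozenset[int]:
    """All child risk-allele counts reachable from the given parental counts."""
    return frozenset(
        tf + tm for tf in _TRANSMIT[father_count] for tm in _TRANSMIT[mother_count]
    )


def mendelian_check(family: Family, panel: SNPPanel) -> list[MendelianInconsistency]:
    """Flag every (child, SNP) whose count is impossible under biallelic
    Mendelian transmission. SNPs with a missing parental genotype are skipped
    for the whole family; missing child genotypes are never flagged."""
    out: list[MendelianInconsistency] = []
    fa, mo = family.father.genotypes, family.mother.genotypes
    for j, snp in enumerate(panel):
        if fa[j] == MISSING or mo[j] == MISSING:
            continue
        possible = transmissible_counts(int(fa[j]), int(mo[j]))
        for child in family.children:
            c = int(child.genotypes[j])
            if c != MISSING and c not in possible:
                out.append(MendelianInconsistency(family.family_id, child.individual_id, snp.snp_id))
    return out


def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count. Monomorphic samples return 1 by convention.
    """
    if min(n_hom_risk, n_het, n_hom_other) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_risk + n_het + n_hom_other
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_risk = 2 * n_hom_risk + n_het  # risk-allele copies
    n_other = 2 * n - n_risk
    if n_risk == 0 or n_other == 0:
        return 1.0

    rare = min(n_risk, n_other)
    hets = np.arange(rare % 2, rare + 1, 2)  # feasible heterozygote counts
    # log P(n_het | allele counts) up to a shared constant:
    #   n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa
    n_aa = (n_risk - hets) // 2
    n_bb = (n_other - hets) // 2
    logp = hets * np.log(2.0) - gammaln(n_aa + 1) - gammaln(hets + 1) - gammaln(n_bb + 1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    # tolerate float noise when comparing "no more probable than observed"
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _founder_hwe(cohort: Cohort) -> dict[str, float]:
    pvals: dict[str, float] = {}
    founders = [ind for fam in cohort.families for ind in (fam.father, fam.mother)]
    geno = np.array([f.genotypes for f in founders]) if founders else np.empty((0, len(cohort.panel)))
    for j, snp in enumerate(cohort.panel):
        col = geno[:, j] if len(founders) else np.array([])
        col = col[col != MISSING]
        if col.size == 0:
            pvals[snp.snp_id] = float("nan")
            continue
        pvals[snp.snp_id] = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return pvals


def apply_qc(cohort: Cohort, max_missing: float = 0.05) -> tuple[Cohort, QCReport]:
    """Remove families with Mendelian inconsistencies and report per-SNP
    missingness and founder HWE p-values. Idempotent on its own output."""
    inconsistencies: list[MendelianInconsistency] = []
    excluded: list[str] = []
    kept: list[Family] = []
    for fam in cohort.families:
        errs = mendelian_check(fam, cohort.panel)
        if errs:
            inconsistencies.extend(errs)
            excluded.append(fam.family_id)
        else:
            kept.append(fam)

    clean = Cohort(families=kept, panel=cohort.panel)
    inds = clean.individuals()
    geno = np.array([i.genotypes for i in inds]) if inds else np.empty((0, len(cohort.panel)))
    missing = {
        snp.snp_id: float((geno[:, j] == MISSING).mean()) if len(inds) else 0.0
        for j, snp in enumerate(cohort.panel)
    }
    flagged = [s for s, frac in missing.items() if frac >= max_missing and frac > 0]
    report = QCReport(
        missing_fraction=missing,
        hwe_pvalue=_founder_hwe(clean),
        inconsistencies=inconsistencies,
        excluded_families=excluded,
        flagged_snps=flagged,
        max_missing=max_missing,
    )
    return clean, report
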