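"""Weighted sex-specific genetic scores.

Three risk scores are defined from the SNP partition: RS_all (markers
reproducible in both sexes), RS_male and RS_female (markers reproducible in
one sex only), each the plain sum of risk-allele counts over its markers.
The genetic score of an individual is

    GS_sex = W_all * RS_all + W_sex * RS_sex

where the weights are the fitted score GRRs rounded to the nearest integer
(minimum 1). A male's GS uses the male-specific score, a female's the
female-specific one; the opposite-sex score is reported only as a
diagnostic and never enters the GS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import MISSING, Cohort, Individual
from .panel import SNPPanel

__all__ = [
    "ScoreModel",
    "GeneticScore",
    "compute_rs",
    "grr_to_weight",
    "build_score_model",
    "compute_gs",
    "score_bounds",
    "score_cohort",
]


class WeightingError(ValueError):
    pass


def grr_to_weight(grr: float) -> int:
    """Integer weight of a score: its GRR rounded to the nearest integer
    (half away from zero), floor 1. GRRs below 1 are rejected — a
    protective or null score should not be in the model."""
    if not np.isfinite(grr) or grr < 1.0:
        raise WeightingError(f"cannot weight a score with GRR {grr} (< 1 or non-finite)")
    return max(1, int(np.floor(grr + 0.5)))


@dataclass
class ScoreModel:
    """Frozen definition of the sex-specific genetic scores."""

    shared_snps: list[str]
    male_snps: list[str]
    female_snps: list[str]
    w_all: int = 1
    w_male: int = 1
    w_female: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in (self.w_all, self.w_male, self.w_female):
            if int(w) != w or w < 1:
                raise ValueError("weights must be integers >= 1")
        lists = [set(self.shared_snps), set(self.male_snps), set(self.female_snps)]
        if sum(len(s) for s in lists) != len(set().union(*lists)):
            raise ValueError("score SNP lists must be disjoint")

    def sex_snps(self, sex: str) -> list[str]:
        return self.male_snps if sex == "male" else self.female_snps

    def sex_weight(self, sex: str) -> int:
        return self.w_male if sex == "male" else self.w_female

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "shared_snps": self.shared_snps,
                    "male_snps": self.male_snps,
                    "female_snps": self.female_snps,
                    "w_all": self.w_all,
                    "w_male": self.w_male,
                    "w_female": self.w_female,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            shared_snps=d["shared_snps"],
            male_snps=d["male_snps"],
            female_snps=d["female_snps"],
            w_all=d["w_all"],
            w_male=d["w_male"],
            w_female=d["w_female"],
            provenance=d.get("provenance", {}),
        )


@dataclass
class GeneticScore:
    individual_id: str
    sex: str
    rs_all: int
    rs_sex: int
    rs_opposite: int  # diagnostic only, never in gs
    gs: int
    complete: bool = True  # False if a required genotype was imputed/missing


def compute_rs(
    genotypes: np.ndarray,
    snps: list[str],
    panel: SNPPanel,
    missing_policy: str = "strict",
) -> tuple[int | None, bool]:
    """Sum of risk-allele counts over ``snps``.

    Returns (value, complete). Under the default ``strict`` policy a missing
    genotype yields (None, False); under ``impute`` it is replaced by the
    panel expectation 2*risk_freq rounded half up, with complete=False.
    """
    total, complete = 0, True
    for snp_id in snps:
        j = panel.index(snp_id)
        c = int(genotypes[j])
        if c == MISSING:
            if missing_policy == "strict":
                return None, False
            c = int(np.floor(2.0 * panel[j].risk_freq + 0.5))
            complete = False
        total += c
    return total, complete


def build_score_model(partition, grr_all, grr_male, grr_female) -> ScoreModel:
    """Turn a SNP partition and its three fitted score GRRs into a frozen
    :class:`ScoreModel`. Any non-converged estimate is an error."""
    for name, est in (("all", grr_all), ("male", grr_male), ("female", grr_female)):
        if est is not None and not est.converged:
            raise ValueError(f"score GRR for RS_{name} did not converge; refusing to weight")
    shared = list(partition.shared)
    male = list(partition.male_specific)
    female = list(partition.female_specific)
    if not shared:
        import warnings

        warnings.warn("score model has no shared SNPs", stacklevel=2)

    def weight(snps, est):
        return grr_to_weight(est.grr) if snps and est is not None else 1

    return ScoreModel(
        shared_snps=shared,
        male_snps=male,
        female_snps=female,
        w_all=weight(shared, grr_all),
        w_male=weight(male, grr_male),
        w_female=weight(female, grr_female),
        provenance={
            "grr_all": getattr(grr_all, "grr", None),
            "grr_male": getattr(grr_male, "grr", None),
            "grr_female": getattr(grr_female, "grr", None),
        },
    )


def compute_gs(
    individual: Individual,
    model: ScoreModel,
    panel: SNPPanel,
    missing_policy: str = "strict",
) -> GeneticScore | None:
    """Sex-specific genetic score of one individual; None if unscoreable
    under the strict missing-genotype policy."""
    geno, sex = individual.genotypes, individual.sex
    rs_all, ok_all = compute_rs(geno, model.shared_snps, panel, missing_policy)
    rs_sex, ok_sex = compute_rs(geno, model.sex_snps(sex), panel, missing_policy)
    opp = "female" if sex == "male" else "male"
    rs_opp, _ = compute_rs(geno, model.sex_snps(opp), panel, missing_policy)
    if rs_all is None or rs_sex is None:
        return None
    return GeneticScore(
        individual_id=individual.individual_id,
        sex=sex,
        rs_all=rs_all,
        rs_sex=rs_sex,
        rs_opposite=rs_opp if rs_opp is not None else -1,
        gs=model.w_all * rs_all + model.sex_weight(sex) * rs_sex,
        complete=ok_all and ok_sex,
    )


def gs_from_counts(counts: np.ndarray, sex: str, model: ScoreModel, panel: SNPPanel) -> int:
    """GS from a bare count vector (used to score pseudocontrols)."""
    rs_all = int(counts[panel.indices(model.shared_snps)].sum()) if model.shared_snps else 0
    sex_snps = model.sex_snps(sex)
    rs_sex = int(counts[panel.indices(sex_snps)].sum()) if sex_snps else 0
    return model.w_all * rs_all + model.sex_weight(sex) * rs_sex


def score_bounds(model: ScoreModel, sex: str) -> tuple[int, int]:
    """Attainable (min, max) of GS_sex: 0 to
    ``2*w_all*|shared| + 2*w_sex*|sex list|``."""
    return 0, 2 * model.w_all * len(model.shared_snps) + 2 * model.sex_weight(sex) * len(
        model.sex_snps(sex)
    )


def score_cohort(
    cohort: Cohort, model: ScoreModel, missing_policy: str = "strict"
) -> pd.DataFrame:
    """Score every child in the cohort; one row per individual with the
    missing-policy outcome flagged."""
    rows = []
    for fam in cohort.families:
        for child in fam.children:
            gs = compute_gs(child, model, cohort.panel, missing_policy)
            rows.append(
                {
                    "family_id": fam.family_id,
                    "individual_id": child.individual_id,
                    "sex": child.sex,
                    "affection": child.affection,
                    "rs_all": gs.rs_all if gs else pd.NA,
                    "rs_sex": gs.rs_sex if gs else pd.NA,
                    "gs": gs.gs if gs else pd.NA,
                    "complete": gs.complete if gs else False,
                }
            )
    return pd.DataFrame(rows)
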