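"""Published reference tables from the original sex-specific genetic-score
study of autism families.

The study's genotype data are not publicly deposited, but its printed
summary tables are sufficient to replay the rule-based stages of the
pipeline — the RI selection gate and the specificity-constrained threshold
choice — and serve as regression fixtures for them. The reported score GRRs
(shared 1.23, male-specific 1.25, female-specific 2.29) are exposed for the
weighting rule.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .evaluation import ThresholdMetrics, _wald_ci
from .reproducibility import RIResult

__all__ = [
    "REFERENCE_GRR",
    "load_reference_ri",
    "load_reference_threshold_table",
]

#: published score GRR point estimates (shared, male-specific, female-specific)
REFERENCE_GRR = {"all": 1.23, "male": 1.25, "female": 2.29}


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("sibscore.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_reference_ri() -> list[RIResult]:
    """The published per-SNP reproducibility indexes (all/male/female)."""
    df = _read("reference_ri.tsv")
    return [
        RIResult(
            snp_id=r.snp_id,
            ri_all=float(r.ri_all),
            ri_male=float(r.ri_male),
            ri_female=float(r.ri_female),
            n_boot=1000,
        )
        for r in df.itertuples()
    ]


def load_reference_threshold_table(sex: str) -> list[ThresholdMetrics]:
    """The published sensitivity/specificity columns for one sex as a
    threshold table (exploratory sample sizes: 664 male / 179 female cases
    and three pseudocontrols each)."""
    df = _read("reference_threshold_table.tsv")
    df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no reference rows for sex {sex!r}")
    n_cases = 664 if sex == "male" else 179
    n_controls = 3 * n_cases
    return [
        ThresholdMetrics(
            threshold=float(r.threshold),
            sensitivity=float(r.sensitivity),
            specificity=float(r.specificity),
            sens_ci=_wald_ci(float(r.sensitivity), n_cases),
            spec_ci=_wald_ci(float(r.specificity), n_controls),
            n_cases=n_cases,
            n_controls=n_controls,
        )
        for r in df.itertuples()
    ]
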