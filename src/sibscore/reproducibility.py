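"""Bootstrap reproducibility index (RI) and SNP-set selection.

The RI of a marker is the fraction of bootstrap *pseudosamples* — the
cohort's families resampled with replacement, a family drawn k times
contributing its affected children k times — in which the risk allele's
estimated relative risk stays above 1.00. It is computed from the
single-SNP conditional-logistic point estimate in all affected children,
in male cases only and in female cases only, all three on the same family
resample.

Selection rule: a SNP must reach the RI threshold (default 0.80) in all
children; survivors are then classified by their sex-specific RIs —
shared if both sexes reach the threshold, male- or female-specific if only
one does, excluded (with a warning) if neither does.

Conventions: a fit that diverges to +infinity counts as "risk above 1", a
fit that diverges to 0 counts as "not above 1", and a pseudosample in
which the SNP is non-informative is removed from that SNP's denominator
and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import Cohort
from .pseudocontrol import build_pseudocontrols, fit_single_patterns

__all__ = ["BootstrapConfig", "RIResult", "SNPPartition", "bootstrap_ri", "select_snps"]


@dataclass
class BootstrapConfig:
    n_boot: int = 1000
    seed: int = 0
    ri_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ri_threshold < 1:
            raise ValueError("ri_threshold must lie in (0, 1)")


@dataclass
class RIResult:
    snp_id: str
    ri_all: float
    ri_male: float
    ri_female: float
    n_boot: int
    n_used: dict[str, int] = field(default_factory=dict)
    n_divergent: dict[str, int] = field(default_factory=dict)

    def ri(self, group: str) -> float:
        return {"all": self.ri_all, "male": self.ri_male, "female": self.ri_female}[group]


@dataclass
class SNPPartition:
    shared: list[str]
    male_specific: list[str]
    female_specific: list[str]
    excluded: list[str]

    def all_selected(self) -> list[str]:
        return self.shared + self.male_specific + self.female_specific


_GROUPS = ("all", "male", "female")


def _precompute_strata(cohort: Cohort):
    """Flatten the cohort to per-stratum transmission patterns per SNP."""
    counts, usable, sexes, fam_idx = [], [], [], []
    for fi, fam in enumerate(cohort.families):
        for case in fam.affected_children:
            pcs = build_pseudocontrols(fam, case)
            counts.append(pcs.counts)
            usable.append(pcs.usable)
            sexes.append(case.sex)
            fam_idx.append(fi)
    if not counts:
        raise ValueError("cohort has no affected children")
    return (
        np.stack(counts),  # (S, 4, L)
        np.stack(usable),  # (S, L)
        np.array(sexes),
        np.array(fam_idx),
    )


def bootstrap_ri(
    cohort: Cohort,
    config: BootstrapConfig,
    return_log: bool = False,
) -> list[RIResult] | tuple[list[RIResult], pd.DataFrame]:
    """Per-SNP reproducibility indexes over ``config.n_boot`` pseudosamples.

    One family-level resample per pseudosample serves all three groups
    (all / male / female cases). The master seed spawns one independent
    RNG substream per pseudosample, so results do not depend on execution
    order. With ``return_log=True`` also returns the per-pseudosample GRR
    audit log (bootstrap index, snp, group, beta, status).
    """
    counts, usable, sexes, fam_idx = _precompute_strata(cohort)
    S, _, L = counts.shape
    n_fam = len(cohort.families)
    is_male = sexes == "male"
    have_sex = {"all": True, "male": bool(is_male.any()), "female": bool((~is_male).any())}
    for g in ("male", "female"):
        if not have_sex[g]:
            warnings.warn(f"no {g} affected children: RI_{g} undefined", stacklevel=2)

    # per SNP: unique 4-count transmission patterns and per-stratum codes
    pattern_tables, codes = [], np.empty((S, L), dtype=np.int64)
    for j in range(L):
        pats, inv = np.unique(counts[:, :, j], axis=0, return_inverse=True)
        pattern_tables.append(pats.astype(float))
        codes[:, j] = inv

    group_masks = {
        "all": np.ones(S, dtype=bool),
        "male": is_male,
        "female": ~is_male,
    }
    above = {g: np.zeros(L, dtype=int) for g in _GROUPS}
    used = {g: np.zeros(L, dtype=int) for g in _GROUPS}
    divergent = {g: np.zeros(L, dtype=int) for g in _GROUPS}
    log_rows: list[dict] = []

    streams = np.random.SeedSequence(config.seed).spawn(config.n_boot)
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mult = np.bincount(rng.integers(0, n_fam, size=n_fam), minlength=n_fam)
        w_strata = mult[fam_idx].astype(float)
        for j in range(L):
            pats = pattern_tables[j]
            for g in _GROUPS:
                if not have_sex[g]:
                    continue
                mask = group_masks[g] & usable[:, j]
                w = w_strata[mask]
                if w.sum() == 0:
                    status = "empty"
                else:
                    pw = np.bincount(codes[mask, j], weights=w, minlength=pats.shape[0])
                    fit = fit_single_patterns(pats, pw)
                    if not fit.informative or not fit.converged:
                        status = "noninformative" if not fit.informative else "failed"
                    else:
                        used[g][j] += 1
                        if fit.diverged_positive:
                            above[g][j] += 1
                            divergent[g][j] += 1
                            status = "diverged_positive"
                        elif fit.diverged_negative:
                            divergent[g][j] += 1
                            status = "diverged_negative"
                        else:
                            if fit.beta > 0:
                                above[g][j] += 1
                            status = "ok"
                if return_log:
                    log_rows.append(
                        {
                            "bootstrap": b,
                            "snp_id": cohort.panel[j].snp_id,
                            "group": g,
                            "beta": fit.beta if status.startswith(("ok", "diverged")) else np.nan,
                            "status": status,
                        }
                    )

    results = []
    for j, snp in enumerate(cohort.panel):
        ris = {}
        for g in _GROUPS:
            if not have_sex[g] or used[g][j] == 0:
                ris[g] = float("nan")
            else:
                ris[g] = above[g][j] / used[g][j]
        results.append(
            RIResult(
                snp_id=snp.snp_id,
                ri_all=ris["all"],
                ri_male=ris["male"],
                ri_female=ris["female"],
                n_boot=config.n_boot,
                n_used={g: int(used[g][j]) for g in _GROUPS},
                n_divergent={g: int(divergent[g][j]) for g in _GROUPS},
            )
        )
    if return_log:
        return results, pd.DataFrame(log_rows)
    return results


def ri_table(results: list[RIResult]) -> pd.DataFrame:
    """RI results as a table (snp, RI all / male / female)."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "ri_all": [r.ri_all for r in results],
            "ri_male": [r.ri_male for r in results],
            "ri_female": [r.ri_female for r in results],
            "n_boot": [r.n_boot for r in results],
        }
    )


def select_snps(
    ri_results: list[RIResult],
    threshold: float = 0.80,
    panel_snp_ids: list[str] | None = None,
) -> SNPPartition:
    """Partition the panel by the RI gate and the per-sex rule.

    A SNP is excluded iff its overall RI falls below the threshold. Among
    survivors: shared if both sex RIs reach the threshold, male-specific if
    only the male RI does, female-specific if only the female RI does; a
    survivor below threshold in both sexes is excluded with a warning.
    """
    by_id = {r.snp_id: r for r in ri_results}
    ids = panel_snp_ids if panel_snp_ids is not None else [r.snp_id for r in ri_results]
    missing = [s for s in ids if s not in by_id]
    if missing:
        raise ValueError(f"missing RI results for panel SNPs: {missing}")
    shared, male, female, excluded = [], [], [], []
    for snp_id in ids:
        r = by_id[snp_id]
        if not r.ri_all >= threshold:  # NaN fails the gate too
            excluded.append(snp_id)
            continue
        m_ok = r.ri_male >= threshold
        f_ok = r.ri_female >= threshold
        if m_ok and f_ok:
            shared.append(snp_id)
        elif m_ok:
            male.append(snp_id)
        elif f_ok:
            female.append(snp_id)
        else:
            warnings.warn(
                f"{snp_id}: overall RI passes but neither sex RI reaches "
                f"{threshold}; excluding",
                stacklevel=2,
            )
            excluded.append(snp_id)
    return SNPPartition(shared, male, female, excluded)
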