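"""Synthetic nuclear-family cohorts for the genetic-score pipeline.

The generator emulates the statistical structure the analysis assumes:
founder genotypes in Hardy-Weinberg equilibrium at the panel's risk-allele
frequencies, independent Mendelian transmission per SNP (linkage
equilibrium — the panel markers sit in distinct genes), and sex-specific
multiplicative per-allele penetrance

    P(affected | counts, sex) = min(1, f0_sex * prod_s g_{s,sex} ** count_s)

with the baseline ``f0_sex`` calibrated so the pre-ascertainment disease
prevalence matches a target. Families are ascertained by rejection
sampling under one of two schemes:

* ``exploratory`` — keep families with >= 1 affected child and drop the
  unaffected children from retained families (multiplex-style sample with
  no unaffected siblings);
* ``replication`` — keep families with >= 1 affected and >= 1 unaffected
  child, all children retained.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .families import MISSING, Cohort, Family, Individual
from .panel import SNPPanel
from .qc import transmissible_counts

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "calibrate_baseline",
    "simulate_cohort",
    "inject_mendelian_errors",
    "fixture_grrs",
]

_ASCERTAINMENTS = ("exploratory", "replication", "none")


def fixture_grrs(panel: SNPPanel) -> tuple[np.ndarray, np.ndarray]:
    """Default per-SNP (male, female) relative risks for the ten-gene panel:
    shared-effect SNPs 1.25 in both sexes, male-specific 1.3/1.0,
    female-specific 1.0/2.3, the remainder null."""
    shared = {"rs7794745", "rs1861972", "rs7766973"}
    male = {"rs2278556", "rs6872664", "rs10951154"}
    female = {"rs12410279", "rs5918"}
    gm, gf = [], []
    for snp in panel:
        if snp.snp_id in shared:
            gm.append(1.25), gf.append(1.25)
        elif snp.snp_id in male:
            gm.append(1.3), gf.append(1.0)
        elif snp.snp_id in female:
            gm.append(1.0), gf.append(2.3)
        else:
            gm.append(1.0), gf.append(1.0)
    return np.array(gm), np.array(gf)


@dataclass
class SimulationConfig:
    """Generator settings; defaults follow the study design the pipeline
    targets: nuclear families of two children who are siblings of affected
    children, so the per-child baseline disease risk is the sibling
    recurrence risk (overall 0.10 at a 4:1 male:female ratio, i.e. 0.16 and
    0.04) rather than the much lower population prevalence."""

    n_families: int
    panel: SNPPanel
    grr_male: np.ndarray
    grr_female: np.ndarray
    target_prevalence_male: float = 0.16
    target_prevalence_female: float = 0.04
    children_per_family: int | dict[int, float] = 2
    prob_male_child: float = 0.5
    ascertainment: str = "exploratory"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grr_male = np.asarray(self.grr_male, dtype=float)
        self.grr_female = np.asarray(self.grr_female, dtype=float)
        L = len(self.panel)
        if self.grr_male.shape != (L,) or self.grr_female.shape != (L,):
            raise ValueError("grr vectors must have one entry per panel SNP")
        if (self.grr_male <= 0).any() or (self.grr_female <= 0).any():
            raise ValueError("relative risks must be positive")
        for p in (self.target_prevalence_male, self.target_prevalence_female):
            if not 0 < p < 1:
                raise ValueError("target prevalences must lie in (0, 1)")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.ascertainment not in _ASCERTAINMENTS:
            raise ValueError(f"ascertainment must be one of {_ASCERTAINMENTS}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def sibship_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        """(sizes, probabilities) of the children-per-family distribution."""
        if isinstance(self.children_per_family, int):
            return np.array([self.children_per_family]), np.array([1.0])
        sizes = np.array(sorted(self.children_per_family), dtype=int)
        probs = np.array([self.children_per_family[int(s)] for s in sizes], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("children_per_family probabilities must sum to 1")
        return sizes, probs


@dataclass
class TruthRecord:
    """Provenance sidecar: calibrated baselines and sampling effort."""

    baseline_male: float
    baseline_female: float
    n_family_draws: int
    n_families: int
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class CalibrationError(ValueError):
    pass


def calibrate_baseline(config: SimulationConfig, sex: str) -> float:
    """Baseline penetrance f0 such that the population mean of
    ``f0 * prod_s g_s**G_s`` equals the sex's target prevalence, with
    genotypes independent and HWE at each SNP.

    Per SNP the genotype-risk expectation is
    ``p^2 g^2 + 2 p (1-p) g + (1-p)^2``; the product over SNPs divides the
    target. Errors if the implied maximum genotype risk exceeds 1.
    """
    g = config.grr_male if sex == "male" else config.grr_female
    target = (
        config.target_prevalence_male if sex == "male" else config.target_prevalence_female
    )
    p = np.array([s.risk_freq for s in config.panel])
    mean_risk = float(np.prod(p**2 * g**2 + 2 * p * (1 - p) * g + (1 - p) ** 2))
    f0 = target / mean_risk
    if f0 * float(np.prod(np.maximum(g, 1.0) ** 2)) > 1.0 + 1e-12:
        raise CalibrationError(
            f"{sex}: baseline {f0:.4g} puts the maximal genotype risk above 1; "
            "lower the target prevalence or the relative risks"
        )
    return f0


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthRecord]:
    """Draw families until ``n_families`` pass the ascertainment filter."""
    rng = np.random.default_rng(config.seed)
    L = len(config.panel)
    p = np.array([s.risk_freq for s in config.panel])
    f0 = {s: calibrate_baseline(config, s) for s in ("male", "female")}
    log_g = {
        "male": np.log(config.grr_male),
        "female": np.log(config.grr_female),
    }
    sizes, size_probs = config.sibship_sizes()

    families: list[Family] = []
    n_draws = 0
    batch = max(256, config.n_families)
    while len(families) < config.n_families:
        n_draws += batch
        # founder genotypes: HWE = two independent allele draws per SNP
        fa_g = (rng.random((batch, L)) < p).astype(np.int8) + (rng.random((batch, L)) < p)
        mo_g = (rng.random((batch, L)) < p).astype(np.int8) + (rng.random((batch, L)) < p)
        n_children = rng.choice(sizes, size=batch, p=size_probs)
        for i in range(batch):
            nc = int(n_children[i])
            # per-child transmissions
            tf = (rng.random((nc, L)) < fa_g[i] / 2.0).astype(np.int8)
            tm = (rng.random((nc, L)) < mo_g[i] / 2.0).astype(np.int8)
            child_g = tf + tm
            child_sex = np.where(rng.random(nc) < config.prob_male_child, "male", "female")
            risk = np.empty(nc)
            for k in range(nc):
                s = child_sex[k]
                risk[k] = min(1.0, f0[s] * np.exp(child_g[k] @ log_g[s]))
            affected = rng.random(nc) < risk

            if config.ascertainment == "exploratory":
                ok = affected.any()
                keep = affected  # unaffected siblings dropped
            elif config.ascertainment == "replication":
                ok = affected.any() and (~affected).any()
                keep = np.ones(nc, dtype=bool)
            else:
                ok = True
                keep = np.ones(nc, dtype=bool)
            if not ok:
                continue

            fid = f"F{len(families) + 1:05d}"
            father = Individual(fid, f"{fid}_1", "0", "0", "male", "unknown", fa_g[i])
            mother = Individual(fid, f"{fid}_2", "0", "0", "female", "unknown", mo_g[i])
            children = [
                Individual(
                    fid,
                    f"{fid}_{3 + k}",
                    father.individual_id,
                    mother.individual_id,
                    str(child_sex[k]),
                    "affected" if affected[k] else "unaffected",
                    child_g[k],
                )
                for k in range(nc)
                if keep[k]
            ]
            families.append(Family(fid, father, mother, children))
            if len(families) == config.n_families:
                break

        if n_draws >= 1_000_000 and len(families) / n_draws < 1e-6:
            raise RuntimeError(
                f"ascertainment acceptance probability < 1e-6 "
                f"({len(families)}/{n_draws} draws); aborting"
            )

    cohort = Cohort(families=families, panel=config.panel)
    if config.missing_rate > 0:
        _inject_missingness(cohort, config.missing_rate, rng)
    truth = TruthRecord(
        baseline_male=f0["male"],
        baseline_female=f0["female"],
        n_family_draws=n_draws,
        n_families=len(families),
        seed=config.seed,
        config={
            "n_families": config.n_families,
            "grr_male": config.grr_male.tolist(),
            "grr_female": config.grr_female.tolist(),
            "target_prevalence_male": config.target_prevalence_male,
            "target_prevalence_female": config.target_prevalence_female,
            "ascertainment": config.ascertainment,
            "missing_rate": config.missing_rate,
            "prob_male_child": config.prob_male_child,
        },
    )
    return cohort, truth


def _inject_missingness(cohort: Cohort, rate: float, rng) -> None:
    """Blank genotypes at ``rate`` uniformly, never both parents at a SNP."""
    for fam in cohort.families:
        for j in range(len(cohort.panel)):
            for ind in fam.children:
                if rng.random() < rate:
                    ind.genotypes[j] = MISSING
            if rng.random() < rate:
                # blank one randomly chosen parent only
                target = fam.father if rng.random() < 0.5 else fam.mother
                target.genotypes[j] = MISSING


def inject_mendelian_errors(
    cohort: Cohort, rate: float, seed: int
) -> tuple[Cohort, list[tuple[str, str, str]]]:
    """Corrupt a random fraction of (child, SNP) slots with a count that is
    impossible given the parents, where such a count exists (e.g. never for
    het x het parents). Returns the corrupted cohort (modified copy) and the
    list of injected (family_id, child_id, snp_id) slots."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    injected: list[tuple[str, str, str]] = []
    out = copy.deepcopy(cohort)
    for fam in out.families:
        fa, mo = fam.father.genotypes, fam.mother.genotypes
        for child in fam.children:
            for j, snp in enumerate(out.panel):
                if rng.random() >= rate:
                    continue
                if MISSING in (fa[j], mo[j], child.genotypes[j]):
                    continue
                impossible = sorted({0, 1, 2} - transmissible_counts(int(fa[j]), int(mo[j])))
                if not impossible:
                    continue
                child.genotypes[j] = impossible[rng.integers(len(impossible))]
                injected.append((fam.family_id, child.individual_id, snp.snp_id))
    return out, injected
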