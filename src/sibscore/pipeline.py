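"""End-to-end orchestration: QC -> pseudocontrols -> bootstrap RI -> SNP
selection -> joint score fit -> weights -> genetic scores -> risk-group
evaluation; plus the replication workflow that applies a frozen score model
to an independent sample, and the synthetic-data workflow.

Discovery evaluates specificity against pseudocontrol scores (the
exploratory design has no unaffected children); replication evaluates
sensitivity on affected siblings with one index case per family excluded
and specificity on unaffected siblings. All randomness flows from the
single config seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    RiskGroupReport,
    ThresholdMetrics,
    ThresholdSelectionError,
    _wald_ci,
    auc,
    ppv,
    select_threshold,
    sens_spec_table,
    split_recurrence,
)
from .families import Cohort
from .panel import SNPPanel, load_default_panel, read_panel
from .ped import read_ped, write_ped
from .pseudocontrol import build_pseudocontrols, fit_joint_score_model
from .qc import apply_qc
from .reproducibility import BootstrapConfig, SNPPartition, bootstrap_ri, ri_table, select_snps
from .scoring import ScoreModel, build_score_model, compute_gs, gs_from_counts, score_cohort
from .simulate import SimulationConfig, fixture_grrs, simulate_cohort

logger = logging.getLogger("sibscore")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "DiscoveryResult",
    "run_discovery",
    "run_replication",
    "run_simulate",
    "discover",
    "replicate",
]


def _derive_seed(seed: int, stream: str) -> int:
    """Stable named substream below 2**31."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """One config object for all subcommands.

    Exactly one of (ped_path, simulation) provides the input cohort.
    """

    seed: int = 0
    ped_path: str | None = None
    panel_path: str | None = None
    simulation: dict | None = None
    n_boot: int = 1000
    ri_threshold: float = 0.80
    max_fpr: float = 0.20
    overall_recurrence: float = 0.10
    sex_ratio: float = 4.0
    prior_male: float | None = None
    prior_female: float | None = None
    missing_policy: str = "strict"
    max_missing: float = 0.05
    output_dir: str = "sibscore_out"

    def __post_init__(self) -> None:
        if (self.ped_path is None) == (self.simulation is None):
            raise ValueError("exactly one of ped_path / simulation must be given")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def priors(self) -> dict[str, float]:
        if self.prior_male is not None and self.prior_female is not None:
            return {"male": self.prior_male, "female": self.prior_female}
        male, female = split_recurrence(self.overall_recurrence, self.sex_ratio)
        return {"male": male, "female": female}

    def panel(self) -> SNPPanel:
        return read_panel(self.panel_path) if self.panel_path else load_default_panel()

    def load_cohort(self) -> Cohort:
        if self.ped_path is not None:
            return read_ped(self.ped_path, self.panel())
        cohort, _ = simulate_cohort(self.simulation_config())
        return cohort

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation or {})
        panel = self.panel()
        gm, gf = fixture_grrs(panel)
        sim.setdefault("grr_male", gm)
        sim.setdefault("grr_female", gf)
        sim.setdefault("seed", _derive_seed(self.seed, "simulation"))
        if sim.get("ascertainment") == "replication":
            # two-child sibships leave no affected sibling once the index
            # case is excluded; replication-style samples need >= 3 children
            sim.setdefault("children_per_family", 3)
        return SimulationConfig(panel=panel, **sim)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "simulation"
        }
        if self.simulation is not None:
            d["simulation"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.simulation.items()
            }
        return d


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    version: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    partition: SNPPartition
    score_model: ScoreModel | None
    reports: dict[str, RiskGroupReport | None]
    ri_results: list
    joint_fit: object | None
    manifest: RunManifest
    tables: dict[str, list[ThresholdMetrics]] = field(default_factory=dict)


def _case_and_control_scores(cohort: Cohort, model: ScoreModel, sex: str):
    """Affected-child GS versus pseudocontrol GS for one sex (discovery)."""
    case_scores, control_scores = [], []
    need = model.shared_snps + model.sex_snps(sex)
    for fam in cohort.families:
        for case in fam.affected_children:
            if case.sex != sex:
                continue
            pcs = build_pseudocontrols(fam, case)
            idx = cohort.panel.indices(need)
            if need and not all(pcs.usable[i] for i in idx):
                continue
            case_scores.append(gs_from_counts(pcs.counts[0], sex, model, cohort.panel))
            for r in range(1, 4):
                control_scores.append(gs_from_counts(pcs.counts[r], sex, model, cohort.panel))
    return np.array(case_scores), np.array(control_scores)


def discover(
    cohort: Cohort,
    config: PipelineConfig,
) -> DiscoveryResult:
    """Run the discovery analysis on an in-memory cohort."""
    manifest = RunManifest(
        stage="discover",
        config_hash=_config_hash(config),
        version=__version__,
        seed=config.seed,
        started=time.time(),
    )
    t0 = time.time()
    clean, qc_report = apply_qc(cohort, config.max_missing)
    manifest.counts.update(
        families_in=len(cohort),
        families_qc=len(clean),
        excluded_families=len(qc_report.excluded_families),
        strata=clean.n_affected_children,
    )
    logger.info("qc: %d/%d families kept (%.2fs)", len(clean), len(cohort), time.time() - t0)

    t0 = time.time()
    boot_cfg = BootstrapConfig(
        n_boot=config.n_boot,
        seed=_derive_seed(config.seed, "bootstrap"),
        ri_threshold=config.ri_threshold,
    )
    ri_results = bootstrap_ri(clean, boot_cfg)
    partition = select_snps(ri_results, config.ri_threshold, clean.panel.snp_ids)
    manifest.counts.update(
        pseudosamples=boot_cfg.n_boot, selected_snps=len(partition.all_selected())
    )
    logger.info(
        "bootstrap RI: %d SNPs selected of %d (%.2fs)",
        len(partition.all_selected()), len(clean.panel), time.time() - t0,
    )

    if not partition.all_selected():
        manifest.warnings.append("no SNP passed the RI gate; empty score model")
        warnings.warn("no SNP passed the RI gate; empty score model", stacklevel=2)
        manifest.finished = time.time()
        return DiscoveryResult(partition, None, {}, ri_results, None, manifest)

    # joint three-score fit; demote scores whose GRR comes out below 1
    joint = fit_joint_score_model(clean, partition)
    for _ in range(3):
        demote = []
        for name, est, snps in (
            ("shared", joint.grr_all, partition.shared),
            ("male_specific", joint.grr_male, partition.male_specific),
            ("female_specific", joint.grr_female, partition.female_specific),
        ):
            if not snps or not est.informative:
                continue
            # a GRR below 1 should not be weighted; a non-finite (separated)
            # estimate cannot be integer-weighted at all
            if est.diverged_positive or est.diverged_negative or est.grr < 1.0:
                demote.append(name)
        if not demote:
            break
        for name in demote:
            snps = getattr(partition, name)
            msg = f"score {name} fitted GRR < 1 or non-finite; demoting its SNPs {snps} to excluded"
            manifest.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            partition.excluded.extend(snps)
            snps.clear()
        if not partition.all_selected():
            manifest.warnings.append("all scores demoted; empty score model")
            manifest.finished = time.time()
            return DiscoveryResult(partition, None, {}, ri_results, joint, manifest)
        joint = fit_joint_score_model(clean, partition)

    model = build_score_model(
        partition,
        joint.grr_all if partition.shared else None,
        joint.grr_male if partition.male_specific else None,
        joint.grr_female if partition.female_specific else None,
    )
    model.provenance["overall_p"] = joint.overall_p

    priors = config.priors()
    reports: dict[str, RiskGroupReport | None] = {}
    tables: dict[str, list[ThresholdMetrics]] = {}
    for sex in ("male", "female"):
        cases, controls = _case_and_control_scores(clean, model, sex)
        if cases.size == 0 or controls.size == 0:
            manifest.warnings.append(f"no scoreable {sex} cases; skipping evaluation")
            reports[sex] = None
            continue
        table = sens_spec_table(cases, controls)
        tables[sex] = table
        roc = auc(cases, controls)
        try:
            thr = select_threshold(table, config.max_fpr)
        except ThresholdSelectionError as exc:
            manifest.warnings.append(f"{sex}: {exc}")
            reports[sex] = None
            continue
        metrics = next(t for t in table if t.threshold == thr)
        reports[sex] = RiskGroupReport(
            sex=sex,
            threshold=thr,
            metrics=metrics,
            prior_risk=priors[sex],
            ppv=ppv(metrics.sensitivity, metrics.specificity, priors[sex]),
            control_source="pseudocontrols",
            roc=roc,
        )
    manifest.finished = time.time()
    return DiscoveryResult(partition, model, reports, ri_results, joint, manifest, tables)


def _write_discovery(result: DiscoveryResult, clean_dir: Path, cohort: Cohort, config) -> None:
    clean_dir.mkdir(parents=True, exist_ok=True)
    ri_table(result.ri_results).to_csv(clean_dir / "ri_table.tsv", sep="\t", index=False)
    if result.score_model is not None:
        result.score_model.to_json(clean_dir / "score_model.json")
        score_cohort(cohort, result.score_model, config.missing_policy).to_csv(
            clean_dir / "scores.tsv", sep="\t", index=False
        )
        for sex, table in result.tables.items():
            rows = [
                {
                    "threshold": t.threshold,
                    "sensitivity": t.sensitivity,
                    "sens_lo": t.sens_ci[0],
                    "sens_hi": t.sens_ci[1],
                    "specificity": t.specificity,
                    "spec_lo": t.spec_ci[0],
                    "spec_hi": t.spec_ci[1],
                }
                for t in table
            ]
            pd.DataFrame(rows).to_csv(clean_dir / f"sens_spec_{sex}.tsv", sep="\t", index=False)
    report = {
        "partition": result.partition.__dict__,
        "risk_groups": {
            sex: (r.to_dict() if r else None) for sex, r in result.reports.items()
        },
        "overall_p": getattr(result.joint_fit, "overall_p", None),
    }
    with open(clean_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    result.manifest.write(clean_dir / "manifest.json")


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Discovery pipeline from config (PED file or simulation), artifacts
    written to ``config.output_dir``."""
    cohort = config.load_cohort()
    result = discover(cohort, config)
    _write_discovery(result, Path(config.output_dir), cohort, config)
    return result


def replicate(
    cohort: Cohort,
    model: ScoreModel,
    thresholds: dict[str, float],
    priors: dict[str, float],
    max_missing: float = 0.05,
    manifest: RunManifest | None = None,
) -> dict[str, RiskGroupReport | None]:
    """Apply a frozen score model to a replication cohort.

    Sensitivity is estimated on affected siblings with one index case per
    family excluded (the first affected child by individual id);
    specificity on unaffected siblings of the same sex.
    """
    clean, _ = apply_qc(cohort, max_missing)
    if not any(f.unaffected_children for f in clean.families):
        raise ValueError("replication cohort has no unaffected siblings")
    reports: dict[str, RiskGroupReport | None] = {}
    for sex in ("male", "female"):
        case_scores, control_scores = [], []
        for fam in clean.families:
            affected = sorted(fam.affected_children, key=lambda c: c.individual_id)
            for child in affected[1:]:  # index case excluded
                if child.sex != sex:
                    continue
                gs = compute_gs(child, model, clean.panel)
                if gs is not None:
                    case_scores.append(gs.gs)
            for child in fam.unaffected_children:
                if child.sex != sex:
                    continue
                gs = compute_gs(child, model, clean.panel)
                if gs is not None:
                    control_scores.append(gs.gs)
        if manifest is not None:
            manifest.counts[f"{sex}_cases"] = len(case_scores)
            manifest.counts[f"{sex}_controls"] = len(control_scores)
        if not case_scores or not control_scores:
            if manifest is not None:
                manifest.warnings.append(f"{sex}: no scoreable cases or controls")
            reports[sex] = None
            continue
        cases = np.array(case_scores, dtype=float)
        controls = np.array(control_scores, dtype=float)
        t = thresholds[sex]
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        if sens == 0.0 and manifest is not None:
            manifest.warnings.append(f"{sex}: sensitivity 0 at threshold {t}")
        metrics = ThresholdMetrics(
            threshold=t,
            sensitivity=sens,
            specificity=spec,
            sens_ci=_wald_ci(sens, cases.size),
            spec_ci=_wald_ci(spec, controls.size),
            n_cases=cases.size,
            n_controls=controls.size,
        )
        try:
            group_ppv = ppv(sens, spec, priors[sex])
        except ValueError:
            # nothing classified positive at this threshold
            group_ppv = float("nan")
            if manifest is not None:
                manifest.warnings.append(f"{sex}: PPV undefined at threshold {t}")
        reports[sex] = RiskGroupReport(
            sex=sex,
            threshold=t,
            metrics=metrics,
            prior_risk=priors[sex],
            ppv=group_ppv,
            control_source="unaffected siblings",
        )
    return reports


def run_replication(
    config: PipelineConfig, model: ScoreModel, thresholds: dict[str, float]
) -> tuple[dict[str, RiskGroupReport | None], RunManifest]:
    cohort = config.load_cohort()
    manifest = RunManifest(
        stage="replicate",
        config_hash=_config_hash(config),
        version=__version__,
        seed=config.seed,
        started=time.time(),
    )
    manifest.counts["families_in"] = len(cohort)
    reports = replicate(
        cohort, model, thresholds, config.priors(), config.max_missing, manifest
    )
    manifest.finished = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {sex: (r.to_dict() if r else None) for sex, r in reports.items()}, fh, indent=2
        )
    manifest.write(outdir / "manifest.json")
    return reports, manifest


def run_simulate(config: PipelineConfig) -> Path:
    """Write PED + panel + truth sidecar for a simulated cohort."""
    sim_cfg = config.simulation_config()
    cohort, truth = simulate_cohort(sim_cfg)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ped(cohort, outdir / "cohort.ped")
    sim_cfg.panel.write(outdir / "panel.tsv")
    truth.to_json(outdir / "truth.json")
    return outdir
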