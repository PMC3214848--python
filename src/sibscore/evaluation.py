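"""Classifier evaluation of the genetic scores.

Sensitivity/specificity tables over integer score thresholds (rule:
score >= threshold -> high risk), Wald binomial confidence intervals,
rank-sum AUC with a placement-variance (DeLong-style) test against 0.5,
specificity-constrained threshold selection, positive predictive value
under a prior sibling recurrence risk, and the sex-split of an overall
recurrence risk given a male:female risk ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ThresholdMetrics",
    "ROCResult",
    "RiskGroupReport",
    "metrics_at",
    "sens_spec_table",
    "auc",
    "select_threshold",
    "ppv",
    "split_recurrence",
]

_Z = 1.959963984540054


@dataclass
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    n_cases: int
    n_controls: int


@dataclass
class ROCResult:
    auc: float
    se: float
    p_vs_half: float
    n_cases: int
    n_controls: int


@dataclass
class RiskGroupReport:
    """High-risk classification summary at the chosen score threshold."""

    sex: str
    threshold: float
    metrics: ThresholdMetrics
    prior_risk: float
    ppv: float
    control_source: str  # "pseudocontrols" or "unaffected siblings"
    roc: ROCResult | None = None

    def to_dict(self) -> dict:
        d = {
            "sex": self.sex,
            "threshold": self.threshold,
            "sensitivity": self.metrics.sensitivity,
            "sensitivity_ci": list(self.metrics.sens_ci),
            "specificity": self.metrics.specificity,
            "specificity_ci": list(self.metrics.spec_ci),
            "n_cases": self.metrics.n_cases,
            "n_controls": self.metrics.n_controls,
            "prior_risk": self.prior_risk,
            "ppv": self.ppv,
            "control_source": self.control_source,
        }
        if self.roc is not None:
            d["auc"] = self.roc.auc
            d["auc_se"] = self.roc.se
            d["auc_p_vs_half"] = self.roc.p_vs_half
        return d


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    half = _Z * np.sqrt(p * (1 - p) / n) if n > 0 else np.inf
    return (max(0.0, p - half), min(1.0, p + half))


def metrics_at(case_scores, control_scores, threshold: float, method: str = "wald") -> ThresholdMetrics:
    """Sensitivity (cases >= t) and specificity (controls < t) at one
    threshold, with 95% binomial CIs (Wald by default, Wilson optional)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control score")
    sens = float((cases >= threshold).mean())
    spec = float((controls < threshold).mean())
    if method == "wald":
        s_ci, c_ci = _wald_ci(sens, cases.size), _wald_ci(spec, controls.size)
    elif method == "wilson":
        s_ci = tuple(
            stats.binomtest(int(round(sens * cases.size)), cases.size).proportion_ci(
                method="wilson"
            )
        )
        c_ci = tuple(
            stats.binomtest(int(round(spec * controls.size)), controls.size).proportion_ci(
                method="wilson"
            )
        )
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ThresholdMetrics(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        sens_ci=s_ci,
        spec_ci=c_ci,
        n_cases=cases.size,
        n_controls=controls.size,
    )


def sens_spec_table(case_scores, control_scores, method: str = "wald") -> list[ThresholdMetrics]:
    """:func:`metrics_at` for every integer threshold from the minimum to
    the maximum observed score."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control score")
    lo = int(np.floor(min(cases.min(), controls.min())))
    hi = int(np.ceil(max(cases.max(), controls.max())))
    return [metrics_at(cases, controls, t, method) for t in range(lo, hi + 1)]


def auc(case_scores, control_scores) -> ROCResult:
    """Rank-sum AUC (ties count 1/2) with a placement-variance standard
    error and a normal test against the 0.5 null."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control score")
    m, n = cases.size, controls.size
    # placements: V10[i] = P(case_i beats a control), V01[j] = P(control_j loses)
    wins = (cases[:, None] > controls[None, :]).astype(float)
    wins += 0.5 * (cases[:, None] == controls[None, :])
    v10 = wins.mean(axis=1)
    v01 = wins.mean(axis=0)
    a = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:
        var = 0.0
    se = float(np.sqrt(var))
    if se == 0.0:
        p = 1.0 if a == 0.5 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    return ROCResult(auc=a, se=se, p_vs_half=p, n_cases=m, n_controls=n)


class ThresholdSelectionError(ValueError):
    pass


def select_threshold(table: list[ThresholdMetrics], max_fpr: float = 0.20) -> float:
    """Among thresholds with false-positive rate strictly below ``max_fpr``
    (specificity strictly above 1 - max_fpr), the one with maximal
    sensitivity; ties break toward the lower threshold."""
    if not table:
        raise ThresholdSelectionError("empty threshold table")
    eligible = [t for t in table if t.specificity > 1.0 - max_fpr]
    if not eligible:
        raise ThresholdSelectionError(
            f"no threshold achieves specificity above {1.0 - max_fpr:.2f}"
        )
    best = max(eligible, key=lambda t: (t.sensitivity, -t.threshold))
    return best.threshold


def ppv(sensitivity: float, specificity: float, prior: float) -> float:
    """Positive predictive value under a prior disease risk:
    ``sens*prior / (sens*prior + (1-spec)*(1-prior))``."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prior", prior)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sensitivity * prior
    denom = num + (1.0 - specificity) * (1.0 - prior)
    if denom == 0.0:
        raise ValueError("PPV undefined: no individual is classified positive")
    return num / denom


def split_recurrence(overall: float, male_to_female_ratio: float) -> tuple[float, float]:
    """Split an overall sibling recurrence risk into per-sex risks assuming
    equal numbers of male and female siblings and a fixed male:female risk
    ratio. The equal-weight mean of the two risks equals the overall risk:
    female = 2*overall/(1+ratio), male = ratio*female."""
    if not 0.0 < overall < 1.0:
        raise ValueError("overall risk must lie in (0, 1)")
    if male_to_female_ratio <= 0:
        raise ValueError("ratio must be positive")
    female = 2.0 * overall / (1.0 + male_to_female_ratio)
    male = male_to_female_ratio * female
    if male > 1.0:
        raise ValueError(f"implied male risk {male:.3f} exceeds 1")
    return male, female
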