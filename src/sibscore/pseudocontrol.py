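"""Case-pseudocontrol construction and conditional logistic estimation.

For each affected child ("case") the four possible parental transmission
outcomes at a SNP are enumerated: (father transmitted, mother transmitted),
(T, U), (U, T) and (U, U). The case occupies the (T, T) slot; the other
three slots are the *pseudocontrols* — hypothetical siblings built from the
non-transmitted parental alleles. Risk-allele effects are then estimated by
conditional logistic regression on the resulting 1:3 matched strata, which
is robust to population stratification and to ascertainment of families
through affected children.

Multilocus handling: the three pseudocontrols are aligned across SNPs by
transmission-pattern index — slot (T, U) at every SNP, etc. — rather than
enumerating the full 4^L - 1 genotype set. This is valid when the panel
SNPs are in linkage equilibrium (here, markers in distinct genes) and keeps
every stratum at fixed 1:3 size.

The model API follows the statsmodels convention: ``ConditionalLogit`` is
built from a :class:`MatchedDesign`; ``.fit()`` returns a
:class:`ConditionalLogitResults` with coefficients, standard errors,
confidence intervals, Wald and likelihood-ratio tests and a ``summary()``
table. ``fit_conditional_logistic`` and ``fit_joint_score_model`` are thin
functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import MISSING, Cohort, Family, Individual
from .panel import SNPPanel
from .qc import transmissible_counts

__all__ = [
    "PseudocontrolSet",
    "Predictor",
    "SNPPredictor",
    "ScorePredictor",
    "MatchedDesign",
    "GRREstimate",
    "ConditionalLogit",
    "ConditionalLogitResults",
    "build_pseudocontrols",
    "build_design",
    "fit_conditional_logistic",
    "fit_joint_score_model",
    "JointScoreFit",
]

_GRAD_TOL = 1e-8
_MAX_NEWTON = 50


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


# ---------------------------------------------------------------------------
# pseudocontrol construction


@dataclass
class PseudocontrolSet:
    """One matched stratum: an affected child plus its 3 pseudocontrols.

    ``counts`` is a (4, L) risk-allele count matrix whose rows are the
    (T,T) case, (T,U), (U,T) and (U,U) slots; ``usable`` marks SNPs where
    parents and case were all genotyped.
    """

    family_id: str
    case_id: str
    case_sex: str
    counts: np.ndarray
    usable: np.ndarray
    stratum_id: int = 0


class MendelianError(ValueError):
    """Case genotype impossible given the parents (QC should catch first)."""


def build_pseudocontrols(family: Family, case: Individual) -> PseudocontrolSet:
    """Enumerate the four transmission outcomes per SNP for one case.

    When both parents are heterozygous and the case is too, which parent
    transmitted the risk allele is ambiguous; the father is assigned it.
    At the count level the four-outcome multiset is the same either way, so
    downstream estimates are unaffected.
    """
    L = family.father.genotypes.size
    counts = np.zeros((4, L), dtype=np.int8)
    usable = np.ones(L, dtype=bool)
    fa, mo, ch = family.father.genotypes, family.mother.genotypes, case.genotypes
    for j in range(L):
        f, m, c = int(fa[j]), int(mo[j]), int(ch[j])
        if MISSING in (f, m, c):
            usable[j] = False
            continue
        if c not in transmissible_counts(f, m):
            raise MendelianError(
                f"family {family.family_id}, case {case.individual_id}: genotype {c} "
                f"at SNP index {j} inconsistent with parents ({f}, {m})"
            )
        # transmitted risk-allele copies from father/mother; tie -> father
        pairs = [
            (tf, c - tf)
            for tf in ((0,) if f == 0 else (1,) if f == 2 else (0, 1))
            if (c - tf) in ((0,) if m == 0 else (1,) if m == 2 else (0, 1))
        ]
        tf, tm = max(pairs)  # prefers tf = 1 on ambiguity
        uf, um = f - tf, m - tm
        counts[0, j] = tf + tm  # case: (T, T)
        counts[1, j] = tf + um  # (T, U)
        counts[2, j] = uf + tm  # (U, T)
        counts[3, j] = uf + um  # (U, U)
    return PseudocontrolSet(
        family_id=family.family_id,
        case_id=case.individual_id,
        case_sex=case.sex,
        counts=counts,
        usable=usable,
    )


# ---------------------------------------------------------------------------
# predictors and designs


class Predictor:
    """Linear functional of the per-SNP risk-allele counts.

    ``sex`` restricts the predictor to strata of that sex: elsewhere it
    contributes a structural zero (used by the joint sex-specific score
    model) and its genotypes are not required.
    """

    def __init__(self, name: str, weights: dict[str, float], sex: str | None = None):
        if not weights:
            raise ValueError(f"predictor {name}: needs at least one SNP weight")
        self.name = name
        self.weights = dict(weights)
        self.sex = sex

    def required_snps(self) -> list[str]:
        return [s for s, w in self.weights.items() if w != 0]

    def column(self, pcs: PseudocontrolSet, panel: SNPPanel) -> np.ndarray | None:
        """(4,) predictor values for a stratum, or None if unusable."""
        if self.sex is not None and pcs.case_sex != self.sex:
            return np.zeros(4)
        idx = panel.indices(self.required_snps())
        if not all(pcs.usable[i] for i in idx):
            return None
        w = np.array([self.weights[panel[i].snp_id] for i in idx])
        return pcs.counts[:, idx].astype(float) @ w


def SNPPredictor(snp_id: str) -> Predictor:
    """Single-SNP additive predictor (risk-allele count)."""
    return Predictor(snp_id, {snp_id: 1.0})


def ScorePredictor(name: str, snp_ids, weight: float = 1.0, sex: str | None = None) -> Predictor:
    """Unweighted (or uniformly weighted) sum of risk-allele counts."""
    return Predictor(name, {s: weight for s in snp_ids}, sex=sex)


@dataclass
class MatchedDesign:
    """1:3 matched strata with predictor columns, ready to fit.

    ``exog`` has shape (n_strata, 4, k); row 0 of each stratum is the case.
    """

    exog: np.ndarray
    predictor_names: list[str]
    case_sex: np.ndarray  # (n_strata,) of "male"/"female"
    family_ids: list[str]
    case_ids: list[str]
    sex_filter: str = "all"
    n_dropped: int = 0

    @property
    def n_strata(self) -> int:
        return self.exog.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long format (stratum, member_role, predictors) for external checks."""
        roles = ["case", "pseudo1", "pseudo2", "pseudo3"]
        records = []
        for s in range(self.n_strata):
            for r, role in enumerate(roles):
                rec = {
                    "stratum": s,
                    "family_id": self.family_ids[s],
                    "case_id": self.case_ids[s],
                    "member_role": role,
                    "is_case": int(r == 0),
                }
                rec.update(dict(zip(self.predictor_names, self.exog[s, r])))
                records.append(rec)
        return pd.DataFrame(records)


class DesignError(ValueError):
    pass


def build_design(
    cohort: Cohort,
    predictors: list[Predictor],
    sex_filter: str = "all",
) -> MatchedDesign:
    """One stratum per affected child passing the sex filter.

    Strata whose predictors are constant across the four members are
    retained (zero likelihood contribution but counted); strata with a
    required genotype missing are dropped and counted in ``n_dropped``.
    """
    if sex_filter not in ("all", "male", "female"):
        raise DesignError(f"sex_filter must be all/male/female, got {sex_filter!r}")
    rows, sexes, fam_ids, case_ids = [], [], [], []
    n_dropped = 0
    for fam in cohort.families:
        for case in fam.affected_children:
            if sex_filter != "all" and case.sex != sex_filter:
                continue
            pcs = build_pseudocontrols(fam, case)
            cols = [p.column(pcs, cohort.panel) for p in predictors]
            if any(c is None for c in cols):
                n_dropped += 1
                continue
            rows.append(np.column_stack(cols))
            sexes.append(case.sex)
            fam_ids.append(fam.family_id)
            case_ids.append(case.individual_id)
    if not rows:
        raise DesignError(
            f"no usable strata (sex_filter={sex_filter!r}, {n_dropped} dropped)"
        )
    return MatchedDesign(
        exog=np.stack(rows),
        predictor_names=[p.name for p in predictors],
        case_sex=np.array(sexes),
        family_ids=fam_ids,
        case_ids=case_ids,
        sex_filter=sex_filter,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# estimates


@dataclass
class GRREstimate:
    """Per-predictor genetic relative risk from a conditional-logistic fit."""

    name: str
    beta: float
    grr: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    converged: bool
    informative: bool = True
    diverged_positive: bool = False
    diverged_negative: bool = False
    n_informative_strata: int = 0

    @property
    def risk_above_one(self) -> bool:
        """Whether the point estimate exceeds GRR = 1 (positive infinity
        counts as above; negative divergence and the null do not)."""
        return self.beta > 0 or self.diverged_positive


# ---------------------------------------------------------------------------
# scalar (single-predictor) conditional likelihood on aggregated patterns


def _aggregate_patterns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse (S, 4) predictor strata to unique rows with multiplicities."""
    patterns, inverse = np.unique(np.asarray(x, dtype=float), axis=0, return_inverse=True)
    weights = np.bincount(inverse, minlength=patterns.shape[0]).astype(float)
    return patterns, weights


@dataclass
class _ScalarFit:
    beta: float
    se: float
    llf: float
    llnull: float
    converged: bool
    informative: bool
    diverged_positive: bool
    diverged_negative: bool
    n_informative: int


def _scalar_loglik_parts(beta: float, pat: np.ndarray, w: np.ndarray):
    eta = beta * pat
    m = eta.max(axis=1, keepdims=True)
    ex = np.exp(eta - m)
    denom = ex.sum(axis=1)
    pi = ex / denom[:, None]
    ll = float(np.sum(w * (eta[:, 0] - (np.log(denom) + m[:, 0]))))
    mean = (pi * pat).sum(axis=1)
    var = (pi * pat**2).sum(axis=1) - mean**2
    grad = float(np.sum(w * (pat[:, 0] - mean)))
    info = float(np.sum(w * var))
    return ll, grad, info


def fit_single_patterns(patterns: np.ndarray, weights: np.ndarray) -> _ScalarFit:
    """Maximise the 1:3 conditional likelihood for one predictor given
    unique stratum patterns and multiplicities.

    Newton with step-halving; bisection (Brent) fallback on the score
    function. Complete separation (case value extreme in every informative
    stratum) is detected combinatorially and reported as a diverged fit
    with the limiting log-likelihood.
    """
    pat = np.asarray(patterns, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    pat, w = pat[keep], w[keep]
    llnull = float(-np.log(4.0) * w.sum())
    info_rows = np.ptp(pat, axis=1) > 0
    n_info = int(w[info_rows].sum())
    if not info_rows.any():
        return _ScalarFit(0.0, float("inf"), llnull, llnull, True, False, False, False, 0)

    ipat, iw = pat[info_rows], w[info_rows]
    at_max = ipat[:, 0] >= ipat.max(axis=1) - 1e-12
    at_min = ipat[:, 0] <= ipat.min(axis=1) + 1e-12
    if at_max.all() or at_min.all():
        # limiting likelihood: each stratum -> -log(#members tied with the case)
        tied = (
            np.abs(ipat - ipat[:, [0]]) < 1e-12
        ).sum(axis=1)
        ll_lim = float(-np.sum(iw * np.log(tied)) - np.log(4.0) * (w.sum() - iw.sum()))
        sign_pos = bool(at_max.all())
        return _ScalarFit(
            math.inf if sign_pos else -math.inf,
            math.inf,
            ll_lim,
            llnull,
            True,
            True,
            sign_pos,
            not sign_pos,
            n_info,
        )

    beta = 0.0
    ll, grad, info = _scalar_loglik_parts(beta, pat, w)
    converged = False
    for _ in range(_MAX_NEWTON):
        if abs(grad) < _GRAD_TOL:
            converged = True
            break
        step = grad / max(info, 1e-12)
        new_beta = beta + step
        new_ll, new_grad, new_info = _scalar_loglik_parts(new_beta, pat, w)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _scalar_loglik_parts(new_beta, pat, w)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
    if not converged and abs(grad) >= _GRAD_TOL:
        # concave scalar likelihood: fall back to root-finding on the score
        def score(b):
            return _scalar_loglik_parts(b, pat, w)[1]

        lo, hi = -40.0, 40.0
        if score(lo) > 0 > score(hi):
            beta = float(optimize.brentq(score, lo, hi, xtol=1e-12))
            ll, grad, info = _scalar_loglik_parts(beta, pat, w)
            converged = True
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    return _ScalarFit(beta, se, ll, llnull, converged, True, False, False, n_info)


def _scalar_fit_to_estimate(name: str, fit: _ScalarFit) -> GRREstimate:
    if not fit.informative:
        return GRREstimate(
            name, 0.0, 1.0, float("inf"), (0.0, float("inf")), 1.0,
            converged=True, informative=False, n_informative_strata=0,
        )
    if fit.diverged_positive or fit.diverged_negative:
        lr = 2.0 * (fit.llf - fit.llnull)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        grr = float("inf") if fit.diverged_positive else 0.0
        return GRREstimate(
            name, fit.beta, grr, float("inf"),
            (0.0, float("inf")), p, converged=True, informative=True,
            diverged_positive=fit.diverged_positive,
            diverged_negative=fit.diverged_negative,
            n_informative_strata=fit.n_informative,
        )
    z = fit.beta / fit.se if fit.se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * fit.se
    return GRREstimate(
        name, fit.beta, math.exp(fit.beta), fit.se,
        (math.exp(fit.beta - half), math.exp(fit.beta + half)),
        p, converged=fit.converged, informative=True,
        n_informative_strata=fit.n_informative,
    )


# ---------------------------------------------------------------------------
# the model / results pair


class ConditionalLogit:
    """Conditional logistic regression on 1:3 matched case-pseudocontrol strata.

    Maximises ``sum_s [eta_case - log sum_j exp(eta_j)]`` with
    ``eta = X beta`` by Newton-Raphson with step-halving (gradient norm
    tolerance 1e-8). Single-predictor designs use an aggregated-pattern
    scalar path with combinatorial separation detection and a bisection
    fallback.
    """

    def __init__(self, design: MatchedDesign):
        self.design = design
        self.exog = np.asarray(design.exog, dtype=float)
        self.k = self.exog.shape[2]

    def _loglik_parts(self, beta: np.ndarray):
        eta = self.exog @ beta  # (S, 4)
        m = eta.max(axis=1, keepdims=True)
        ex = np.exp(eta - m)
        denom = ex.sum(axis=1)
        pi = ex / denom[:, None]  # (S, 4)
        ll = float(np.sum(eta[:, 0] - (np.log(denom) + m[:, 0])))
        mean = np.einsum("sj,sjk->sk", pi, self.exog)
        grad = self.exog[:, 0, :].sum(axis=0) - mean.sum(axis=0)
        sec = np.einsum("sj,sjk,sjl->kl", pi, self.exog, self.exog)
        hess = -(sec - mean.T @ mean)
        return ll, grad, hess

    def loglike(self, beta) -> float:
        return self._loglik_parts(np.asarray(beta, dtype=float))[0]

    def fit(self) -> "ConditionalLogitResults":
        names = self.design.predictor_names
        S = self.exog.shape[0]
        llnull = float(-np.log(4.0) * S)
        # columns with no within-stratum variation anywhere are inestimable
        active = [
            j for j in range(self.k)
            if np.ptp(self.exog[:, :, j], axis=1).max(initial=0.0) > 0
        ]
        estimates: list[GRREstimate | None] = [None] * self.k

        if len(active) == 1 or (self.k == 1 and active):
            j = active[0]
            pat, w = _aggregate_patterns(self.exog[:, :, j])
            sf = fit_single_patterns(pat, w)
            estimates[j] = _scalar_fit_to_estimate(names[j], sf)
            beta = np.zeros(self.k)
            beta[j] = sf.beta if np.isfinite(sf.beta) else 0.0
            cov = np.full((self.k, self.k), np.nan)
            cov[j, j] = sf.se**2
            llf, lr_df = sf.llf, 1
            converged = sf.converged
        elif active:
            Xa = self.exog[:, :, active]
            beta_a, cov_a, llf, converged = _newton_multi(Xa)
            beta = np.zeros(self.k)
            cov = np.full((self.k, self.k), np.nan)
            for ai, j in enumerate(active):
                beta[j] = beta_a[ai]
                for bi, l in enumerate(active):
                    cov[j, l] = cov_a[ai, bi]
            lr_df = len(active)
            for ai, j in enumerate(active):
                se = math.sqrt(max(cov_a[ai, ai], 0.0)) if np.isfinite(cov_a[ai, ai]) else math.inf
                n_info = int((np.ptp(Xa[:, :, ai], axis=1) > 0).sum())
                col = Xa[:, :, ai]
                info_rows = np.ptp(col, axis=1) > 0
                div_pos = bool(info_rows.any()) and bool(
                    (col[info_rows, 0] >= col[info_rows].max(axis=1) - 1e-12).all()
                )
                div_neg = bool(info_rows.any()) and bool(
                    (col[info_rows, 0] <= col[info_rows].min(axis=1) + 1e-12).all()
                )
                if div_pos or div_neg:
                    estimates[j] = GRREstimate(
                        names[j], math.inf if div_pos else -math.inf,
                        math.inf if div_pos else 0.0, math.inf,
                        (0.0, math.inf), float("nan"), converged=True,
                        diverged_positive=div_pos, diverged_negative=div_neg,
                        n_informative_strata=n_info,
                    )
                    continue
                z = beta_a[ai] / se if 0 < se < math.inf else 0.0
                half = 1.959963984540054 * se
                estimates[j] = GRREstimate(
                    names[j], float(beta_a[ai]), _safe_exp(beta_a[ai]), se,
                    (_safe_exp(beta_a[ai] - half), _safe_exp(beta_a[ai] + half)),
                    float(2.0 * stats.norm.sf(abs(z))),
                    converged=converged, n_informative_strata=n_info,
                )
        else:
            beta = np.zeros(self.k)
            cov = np.full((self.k, self.k), np.nan)
            llf, lr_df, converged = llnull, 0, True

        for j in range(self.k):
            if estimates[j] is None:
                estimates[j] = GRREstimate(
                    names[j], 0.0, 1.0, float("inf"), (0.0, float("inf")), 1.0,
                    converged=True, informative=False,
                )
        lr_stat = max(2.0 * (llf - llnull), 0.0)
        lr_p = float(stats.chi2.sf(lr_stat, df=lr_df)) if lr_df else 1.0
        return ConditionalLogitResults(
            model=self,
            params=beta,
            cov_params=cov,
            estimates=estimates,  # type: ignore[arg-type]
            llf=llf,
            llnull=llnull,
            lr_stat=lr_stat,
            lr_df=lr_df,
            lr_pvalue=lr_p,
            converged=converged,
        )


def _newton_multi(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson with step-halving for a k-column matched design."""
    S, _, k = X.shape

    def parts(beta):
        eta = X @ beta
        m = eta.max(axis=1, keepdims=True)
        ex = np.exp(eta - m)
        denom = ex.sum(axis=1)
        pi = ex / denom[:, None]
        ll = float(np.sum(eta[:, 0] - (np.log(denom) + m[:, 0])))
        mean = np.einsum("sj,sjk->sk", pi, X)
        grad = X[:, 0, :].sum(axis=0) - mean.sum(axis=0)
        sec = np.einsum("sj,sjk,sjl->kl", pi, X, X)
        hess = -(sec - np.einsum("sk,sl->kl", mean, mean))
        return ll, grad, hess

    beta = np.zeros(k)
    ll, grad, hess = parts(beta)
    converged = False
    for _ in range(_MAX_NEWTON):
        if np.linalg.norm(grad) < _GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(k), -grad)
        except np.linalg.LinAlgError:
            step = grad
        new_beta = beta + step
        new = parts(new_beta)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = parts(new_beta)
            halvings += 1
        beta, (ll, grad, hess) = new_beta, new
    if not converged:
        converged = bool(np.linalg.norm(grad) < 1e-6)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, ll, converged


@dataclass
class ConditionalLogitResults:
    """Fitted conditional-logistic model with Wald and LR inference."""

    model: ConditionalLogit
    params: np.ndarray
    cov_params: np.ndarray
    estimates: list[GRREstimate]
    llf: float
    llnull: float
    lr_stat: float
    lr_df: int
    lr_pvalue: float
    converged: bool

    @property
    def bse(self) -> np.ndarray:
        return np.array([e.se for e in self.estimates])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([e.p_value for e in self.estimates])

    @property
    def grr(self) -> np.ndarray:
        return np.array([e.grr for e in self.estimates])

    def conf_int(self) -> np.ndarray:
        return np.array([e.ci95 for e in self.estimates])

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "predictor": [e.name for e in self.estimates],
                "beta": [e.beta for e in self.estimates],
                "GRR": [e.grr for e in self.estimates],
                "se(beta)": [e.se for e in self.estimates],
                "GRR 2.5%": [e.ci95[0] for e in self.estimates],
                "GRR 97.5%": [e.ci95[1] for e in self.estimates],
                "p": [e.p_value for e in self.estimates],
                "informative": [e.informative for e in self.estimates],
            }
        )
        df.attrs["n_strata"] = self.model.design.n_strata
        df.attrs["lr_stat"] = self.lr_stat
        df.attrs["lr_pvalue"] = self.lr_pvalue
        return df


def fit_conditional_logistic(design: MatchedDesign) -> list[GRREstimate]:
    """Fit the design and return one :class:`GRREstimate` per predictor."""
    return ConditionalLogit(design).fit().estimates


@dataclass
class JointScoreFit:
    """Three-score joint fit: shared, male-specific and female-specific
    risk-score GRRs with the overall likelihood-ratio p-value."""

    grr_all: GRREstimate
    grr_male: GRREstimate
    grr_female: GRREstimate
    overall_p: float
    results: ConditionalLogitResults = field(repr=False, default=None)


def fit_joint_score_model(cohort: Cohort, partition) -> JointScoreFit:
    """Single conditional likelihood over all affected children: male strata
    contribute ``b_all*RS_all + b_male*RS_male``, female strata
    ``b_all*RS_all + b_female*RS_female``. The overall p-value is the
    likelihood-ratio test against all coefficients zero (df = number of
    estimable scores).

    ``partition`` may be a :class:`~sibscore.reproducibility.SNPPartition`
    or anything exposing shared/male/female SNP-id lists.
    """
    shared = list(getattr(partition, "shared", getattr(partition, "shared_snps", [])))
    male = list(getattr(partition, "male_specific", getattr(partition, "male_snps", [])))
    female = list(getattr(partition, "female_specific", getattr(partition, "female_snps", [])))
    predictors = []
    # empty lists get a placeholder constant-zero predictor via sex gating
    predictors.append(
        ScorePredictor("RS_all", shared) if shared else Predictor("RS_all", {cohort.panel[0].snp_id: 0.0})
    )
    predictors.append(
        ScorePredictor("RS_male", male, sex="male") if male
        else Predictor("RS_male", {cohort.panel[0].snp_id: 0.0}, sex="male")
    )
    predictors.append(
        ScorePredictor("RS_female", female, sex="female") if female
        else Predictor("RS_female", {cohort.panel[0].snp_id: 0.0}, sex="female")
    )
    design = build_design(cohort, predictors, sex_filter="all")
    res = ConditionalLogit(design).fit()
    return JointScoreFit(
        grr_all=res.estimates[0],
        grr_male=res.estimates[1],
        grr_female=res.estimates[2],
        overall_p=res.lr_pvalue,
        results=res,
    )
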