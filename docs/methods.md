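# Methods

This note documents the statistical procedures `sibscore` implements, the
assumptions behind them, the defaults of the synthetic family generator,
and the numerical choices that matter for reproducing results.

## Study design being modelled

The pipeline targets a two-sample family design for a disease with a strong
male excess (autism is the motivating case): an *exploratory* sample of
nuclear families ascertained through at least one affected child, with no
unaffected siblings retained, used to select markers, fit the score model
and choose high-risk thresholds; and an independent *replication* sample of
families with at least one affected and one unaffected sibling, used to
validate the frozen model. Because the exploratory sample contains no
unaffected children, all relative risks are estimated within families via
the case-pseudocontrol device, and specificity in the exploratory sample is
computed against pseudocontrol scores.

## Case-pseudocontrol conditional logistic regression

For each affected child, the four possible parental transmissions at a SNP
— (father transmitted, mother transmitted), (T,U), (U,T), (U,U) — define a
matched stratum in which the observed child occupies the (T,T) slot and the
other three slots are pseudocontrols. The per-allele genetic relative risk
(GRR) is the exponentiated coefficient of a conditional logistic regression
on these 1:3 strata,

    L(beta) = sum_s [ eta_case,s − log sum_{j in s} exp(eta_j,s) ],
    eta = X beta,

which conditions out all between-family effects; the estimator is therefore
robust to population structure and to ascertainment through affected
children. Assumptions: both parents genotyped, autosomal biallelic markers,
multiplicative (log-additive) allele effects, and linkage equilibrium
between panel markers — the pseudocontrols are aligned across SNPs by
transmission-pattern index rather than enumerating the full 4^L − 1
multilocus genotype set, which is valid when the markers segregate
independently (here: ten markers in ten genes on different chromosomal
regions).

Numerical details:

* Newton-Raphson with step-halving, gradient-norm tolerance 1e-8, at most
  50 iterations; single-predictor fits run on aggregated transmission
  patterns (unique stratum rows with multiplicities), with a Brent
  root-finding fallback on the score function over [−40, 40].
* Complete separation (the case value extreme in every informative
  stratum) is detected combinatorially before iterating; the fit is
  reported as diverged with GRR +inf (or 0), the limiting log-likelihood,
  and a likelihood-ratio p-value in place of the Wald test.
* Strata that are constant in every predictor contribute nothing to the
  likelihood but are retained and counted; wholly non-informative
  predictors are reported as such with GRR 1 and p 1.
* Wald standard errors come from the observed information at the optimum;
  95% CIs are exp(beta ± 1.96 se). Multi-predictor fits also expose the
  likelihood-ratio statistic against the all-zero null.
* When both parents and the child are heterozygous, which parent
  transmitted the risk allele is ambiguous; the father is assigned it. The
  four-slot count multiset is identical either way, so estimates are
  unaffected (asserted by test).
* Multiple affected siblings form separate strata conditioning on the same
  parents; no cluster correction is applied to the variance, matching the
  design being reproduced.

## Bootstrap reproducibility index

The reproducibility index (RI) of a marker is the fraction of bootstrap
pseudosamples — families resampled with replacement, a family drawn k
times contributing its affected children k times — in which the risk
allele's single-SNP GRR point estimate exceeds 1.00. One family-level
resample per pseudosample serves the three case groups (all, male,
female). Conventions, which matter because the RI depends on them:

* the criterion is the point estimate, not a confidence bound;
* positively diverged fits count as "above 1", negatively diverged fits do
  not; pseudosamples where the SNP is non-informative are dropped from that
  SNP's denominator and counted;
* the master seed spawns one RNG substream per pseudosample, so results are
  independent of execution order;
* default 1000 pseudosamples.

Selection applies a 0.80 RI gate in all children, then classifies
survivors by sex: shared if both sex RIs reach the threshold, male- or
female-specific if only one does; a survivor failing both is excluded with
a warning. Under a null effect the RI of a dataset is approximately the
bootstrap tail probability at the observed z-score, i.e. close to uniform
across datasets, which is why the gate passes null markers with modest
probability on any single dataset; the RI is a stability filter, not a
test. A consequence at a 4:1 male:female case ratio: markers whose effect
is confined to females are diluted in the all-children estimate and can
fail the overall gate even when their female RI is high.

## Scores, weights, thresholds, PPV

Risk scores are plain risk-allele counts summed over the shared
(`RS_all`), male-specific and female-specific marker sets. The genetic
score of an individual is `GS_sex = W_all*RS_all + W_sex*RS_sex`, with
integer weights obtained by rounding each score's fitted GRR to the
nearest integer (half away from zero, floor 1; a score with fitted GRR
below 1 is rejected by the scoring layer — the discovery pipeline demotes
such markers to excluded with a warning instead of aborting). The
opposite-sex score is reported as a diagnostic but never enters the GS.
Missing genotypes make an individual unscoreable under the default strict
policy; an optional policy imputes the rounded panel expectation
2*risk_freq and flags the score.

Classification uses score >= threshold. Sensitivity/specificity tables run
over every integer threshold between the observed extremes with Wald
binomial 95% CIs (Wilson available); the high-risk threshold is the one
with maximal sensitivity among those with specificity strictly above 0.80
(false-positive rate below 20%), ties broken toward the lower threshold.
AUC is the rank-sum estimator with ties counted 1/2; its standard error
uses case/control placement variances (DeLong-style) for the test against
0.5. PPV converts sensitivity, specificity and a prior risk:
`sens*prior / (sens*prior + (1−spec)(1−prior))`. The prior is the sibling
recurrence risk, split by sex from an overall value assuming equal sibling
sex frequency: `female = 2*overall/(1+ratio)`, `male = ratio*female`
(defaults 0.10 overall, ratio 4:1, giving 0.16/0.04).

In discovery the three score GRRs come from one joint conditional
likelihood over all strata (male strata contribute `b_all*RS_all +
b_male*RS_male`, female strata `b_all*RS_all + b_female*RS_female`) whose
3-df likelihood-ratio test gives the overall model p-value. In replication
one index case per family — the first affected child by individual id — is
excluded from the sensitivity denominator; specificity uses unaffected
siblings, and the control source is recorded in every report because
pseudocontrols and unaffected siblings are not interchangeable control
populations.

## Quality control

Mendelian consistency flags every (child, SNP) whose risk-allele count is
unreachable as one paternal plus one maternal transmission; families with
any inconsistency are excluded. Hardy-Weinberg equilibrium is assessed on
founders only with the conditional exact test (sum of probabilities of
heterozygote counts no more probable than observed, given the allele
counts); the exact test is used because chi-square approximations misbehave
at the near-fixed allele frequencies several panel markers have. No
HWE-based exclusion is applied by default — p-values are reported. Markers
with missingness at or above 5% are flagged, never silently dropped.

## Synthetic cohort generator

The generator supplies cohorts with exactly the structure the estimators
assume: founder genotypes drawn in HWE at the panel allele frequencies,
independent Mendelian transmission per SNP (linkage equilibrium), child sex
Bernoulli(0.5), and affection Bernoulli with probability
`min(1, f0_sex * prod_s g_{s,sex}^count_s)`. The baseline `f0_sex` is
calibrated in closed form so the population mean risk equals a target,
using the per-SNP expectation `p^2 g^2 + 2p(1−p)g + (1−p)^2`; calibration
fails loudly if the implied maximal genotype risk exceeds 1. Ascertainment
is by rejection sampling (exact, with an acceptance-probability guard that
aborts below 1e-6) under the exploratory scheme (>= 1 affected child;
unaffected children dropped) or the replication scheme (>= 1 affected and
>= 1 unaffected, all children kept).

Defaults, chosen once as the package's emulation of the target design:

* per-child target risks 0.16 (male) / 0.04 (female) — the sibling
  recurrence risks, because simulated children stand for siblings of
  affected children, for whom the recurrence risk (overall 0.10 at a 4:1
  male:female ratio), not the population prevalence, is the relevant
  baseline; this also makes ascertainment acceptance rates realistic;
* two children per family (three under the replication scheme, since a
  two-child family with one affected and one unaffected child has no
  affected sibling left once the index case is excluded);
* effect-size fixture: shared markers GRR 1.25 in both sexes,
  male-specific 1.3/1.0, female-specific 1.0/2.3 — the order of magnitude
  of the score GRRs the design is meant to detect;
* missingness 0 by default; when requested it is injected uniformly but
  never removes both parents at a SNP.

What the generator deliberately omits — and what passing tests therefore
do not establish about real data: linkage disequilibrium between markers,
de novo and copy-number variation, a polygenic liability background shared
by siblings, diagnostic heterogeneity, and genotyping error beyond the
explicit Mendelian-error injector. The absence of shared liability means
simulated families are far less multiplex than real autism sibships
(about 1.05 affected children per exploratory family versus 1.76 in the
motivating study); estimator calibration is unaffected, but simulated
replication samples have few non-index affected siblings, so
replication-side sensitivity estimates carry wide intervals at realistic
sample sizes.

## Problem sizes used in the test suite

Stochastic properties are verified at the scale the design prescribes
where that is cheap (480-family cohorts for parameter recovery — 50
replicates at GRR 1.5 — and for the null-RI calibration — 50 datasets of
200 pseudosamples each) and at reduced but sufficient scale elsewhere
(bootstrap determinism and audit-trail checks at 40–200 pseudosamples;
power-style monotonicity at 150 families). Exact oracles (transmission
enumeration, HWE enumeration, grid-search MLE, brute-force AUC) run at
full precision.

## Known limitations

* Only complete nuclear families are supported: no missing parents,
  half-siblings, multi-generation pedigrees, or X-linked models.
* The RI's behaviour under the null (approximately uniform per dataset)
  means single-dataset selections are unstable for GRRs near 1.25 at 480
  families; the index measures stability, it does not control type-I
  error.
* Integer weighting discards effect-size precision by design (it mirrors
  the weighted-score construction being reproduced); no shrinkage or
  penalised estimation is provided.
* Wald CIs for proportions are used for comparability with the reference
  tables; they are known to undercover near 0 and 1 (Wilson intervals are
  available as an option).
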