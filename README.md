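# sibscore

Sex-specific genetic-score risk assessment for siblings of affected
children, built for family-based studies of disorders with a strong sex
bias (autism is the motivating case). Given nuclear families with
genotyped parents, `sibscore` estimates per-allele genetic relative risks
without unaffected controls, selects reproducible markers, builds weighted
sex-specific risk scores, and evaluates how well those scores identify
high-risk siblings.

It is aimed at statistical geneticists and epidemiologists working with
trio/sibship panels of candidate SNPs, and at anyone who needs a tested
reference implementation of the case-pseudocontrol + reproducibility-index
+ weighted-score workflow, including a synthetic family generator for
methods work when real genotypes are restricted.

## The method

**Case-pseudocontrol GRR estimation.** For an affected child, the four
possible parental transmissions at a SNP define a matched 1:3 stratum: the
observed child is the (T,T) outcome, and the three *pseudocontrols* are
the genotypes built from the untransmitted alleles. The genetic relative
risk per risk allele (or per score point) is exp(β) from conditional
logistic regression,

    L(β) = Σ_strata [ η_case − log Σ_j exp(η_j) ],   η = x'β,

fitted by Newton-Raphson with analytic separation handling
(`ConditionalLogit(design).fit()` returns a results object with GRRs,
standard errors, CIs, Wald and likelihood-ratio tests and a `summary()`
table). The design conditions out population structure and ascertainment.

**Reproducibility index (RI).** Families are resampled with replacement
(default 1000 pseudosamples); each marker's RI is the fraction of
pseudosamples in which its estimated GRR stays above 1.00, computed in all
cases, male cases and female cases. Markers need RI ≥ 0.80 overall, and
are then classed as shared, male-specific or female-specific by their
per-sex RIs.

**Weighted sex-specific scores.** With RS_all, RS_male, RS_female the sums
of risk-allele counts over the three marker sets,

    GS_sex = W_all · RS_all + W_sex · RS_sex,

where each weight is that score's fitted GRR rounded to the nearest
integer (minimum 1).

**Risk groups.** The high-risk threshold maximises sensitivity subject to
specificity > 0.80; AUC (rank-sum, DeLong-style test against 0.5) and PPV
are reported, the latter under a prior sibling recurrence risk split by
sex: overall 0.10 at a 4:1 male:female ratio gives 0.16 / 0.04.

See `docs/methods.md` for assumptions, numerical details and limitations.

## Worked example

Simulate an exploratory cohort of 480 families on the packaged ten-gene
panel (shared effects GRR 1.25, male-specific 1.3, female-specific 2.3),
run discovery, and validate the frozen model on an independent
replication-style sample:

```
$ sibscore simulate --seed 7 --n-families 480 -o sim
$ sibscore discover --ped sim/cohort.ped --panel sim/panel.tsv \
      --seed 7 --n-boot 1000 -o disc
selected SNPs: shared=['rs12410279', 'rs7794745', 'rs1861972', 'rs7766973'] \
  male=['rs2278556', 'rs6872664', 'rs10951154'] female=[] \
  excluded=['rs2292813', 'rs2235076', 'rs5918']
weights: w_all=1 w_male=1 w_female=1
male: threshold=12 sens=0.16 spec=0.85 AUC=0.57 PPV=0.17
female: threshold=7 sens=0.17 spec=0.86 AUC=0.58 PPV=0.05
```

Reading this output: the bootstrap kept 7 of the 10 markers (the two
simulated-null markers rs2292813 and rs2235076 are correctly excluded);
each sex's threshold holds the false-positive rate under 20% among
pseudocontrols, and at that cutoff a male sibling in the high-risk group
has an estimated 17% risk against the 16% male prior — at these moderate
effect sizes the score separates weakly, which the AUC near 0.57 makes
plain. Note the run's sampling noise: one female-effect marker landed in
the shared set and one was excluded; single-dataset selection at GRR ≈
1.25 is unstable, which is exactly the phenomenon the RI quantifies.

```
$ sibscore simulate --seed 8 --n-families 187 --ascertainment replication -o repsim
$ sibscore replicate --ped repsim/cohort.ped --panel repsim/panel.tsv \
      --model disc/score_model.json --thresholds male=12,female=7 -o rep
male:   threshold=12  sens=0.125  spec=0.894  n_cases=8   n_controls=180  PPV=0.18
female: threshold=7   sens=0.200  spec=0.834  n_cases=5   n_controls=181  PPV=0.05
```

Replication scores affected siblings with one index case per family
excluded and unaffected siblings as controls. Because simulated sibling
risks are independent given the parents (no shared liability background),
few families are multiplex and the sensitivity side rests on only 8 male
and 5 female non-index cases — the wide uncertainty this implies is
discussed in `docs/methods.md`.

The library mirrors the CLI: `simulate_cohort`, `apply_qc`,
`build_design`/`ConditionalLogit`, `bootstrap_ri`/`select_snps`,
`build_score_model`/`compute_gs`, `sens_spec_table`/`select_threshold`/
`auc`/`ppv`, and `discover`/`replicate` for whole pipelines on in-memory
cohorts.

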