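# panelreact

Tools for analysing the **re-activation** of a longitudinal survey panel:
what happens when former participants of a child/adolescent health survey
are invited, years later, to register with an online panel and take part in
a follow-up study — who comes back, how selective the return is, and how to
correct for that selectivity with longitudinal inverse-probability weights.

The package is aimed at survey methodologists and epidemiologists working
with panel attrition. Because the microdata of such studies are typically
access-restricted, the package ships a first-class synthetic-cohort
generator that reproduces the *structure* of the problem — two subsamples
(a long-running cohort and a cross-sectional refreshment), realistic
covariate marginals, calibrated base weights, and a known selective
two-stage dropout mechanism — so every stage of the analysis can be
validated against known truth.

## What it computes

**Disposition rates.** Contact outcomes are classified into AAPOR-style
final disposition codes (registered; eligible non-respondents; unknown
eligibility; not eligible) and summarized as recruitment, consent and
completion rates with numerators and denominators disclosed.

**Re-activation models.** Two age-stratified logistic regressions per
outcome (panel registration; study participation), reporting odds ratios
with Wald 95% CIs. The 11+ stratum adds psychosocial scales, cohort
membership, and a cohort × age interaction.

**Longitudinal weights.** Each re-participant *i* receives

```
wLS_i = wQS_i / θ_i
```

where `θ_i` is the predicted re-participation propensity from a weighted
logistic model and `wQS_i` the cross-sectional base weight. The propensity
model is selected semi-automatically: ≤5% missingness screen → median/mode
imputation → bidirectional stepwise (AIC) → interactions with age, sex and
parental education → plausibility pruning (cell sizes, extreme estimates and
standard errors, Wald p) → restart to a fixed point. Stages chain
(participation weights start from registration weights) and the two
subsamples merge by a convex combination proportional to their Kish
effective case numbers, `n_eff = (Σw)²/Σw²`. Diagnostics report min, median,
max, CV and effectiveness (`100·n_eff/n`), which satisfies
`effectiveness = 100/(1+(CV/100)²)`.

**Benchmarking.** A weighted 0–10 life-satisfaction mean of the re-activated
sample is compared against a reference sample after raking the former to the
reference's age × sex × education × region margins; means come with
Kish-effective-n standard errors and a two-sample t-test.

## Worked example

Running the numbered analysis scripts end to end:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_disposition_rates.py
python analysis/04_longitudinal_weights.py
```

prints (abridged):

```
generated 11,800 invitees (cohort 4,400, cross-section 7,400)
registration rate: 37.5%
participation rate among registrants: 68.4%

reference registration process:
  invited 11,737, registered 4,451
  recruitment rate (simple):   37.9%  (4,451/11,737)
  recruitment rate (AAPOR-E1): 38.0%  (4,451/11,718)

weight diagnostics (participation stage, combined):
                            min   median      max     CV %    eff %
            unweighted    1.000    1.000    1.000     0.00   100.00
           base_weight    0.742    0.917    2.710    32.42    90.49
   longitudinal_weight    0.318    0.797    7.640    66.29    69.47

balance (max |weighted - reference| per parameter, pp):
  sex: 0.07
  age_group: 2.94
  edu_casmin: 1.19
  parents_birth: 1.66
  general_health: 0.51
```

Reading: the simulated cohort registers at 37.5% (its calibrated target),
and the recruitment-rate arithmetic on the reference study's printed counts
is exact. Weighting pulls the participants' covariate shares back to within
about a percentage point of the baseline composition for the variables that
drove dropout (sex: 0.07 pp), while effectiveness falls from 90.5% to 69.5%
— the familiar bias-variance trade-off of inverse-probability weighting.
(Age-band imbalance grows slightly, which the weighted cohort inherits from
selection terms that the stepwise model does not carry.)

The library surface mirrors the scripts; a `panelreact` console command
exposes `simulate`, `rates`, `fit`, `weight`, `balance` and `benchmark`
subcommands for the same steps.

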