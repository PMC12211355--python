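# Methods

This note documents the models and procedures implemented in `panelreact`,
the choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## The problem

A baseline survey of children and adolescents is followed, years later, by a
push-to-online-panel re-contact: invitees first *register* on a panel
platform, and registrants are then invited to *participate* in a follow-up
survey. Both steps are selective — return probabilities vary with sex,
socioeconomic status, mental-health scores and other baseline covariates —
so the re-activated sample no longer represents the baseline sample. The
package quantifies that selectivity (disposition rates, selection models)
and corrects for it (longitudinal inverse-probability weights), then checks
the corrected sample against an external reference (benchmarking).

## Synthetic cohort generator

`panelreact.synthetic` draws a baseline cohort of `n_cohort + n_cross`
invitees. Defaults are the study conditions of the reference setting:

- **Marginals.** Sex 49.5/50.5 male/female; parents' country of birth
  82.7/8.2/9.1 (both Germany / one abroad / both abroad); parental CASMIN
  education 10.2/54.2/35.6 (basic/intermediate/higher); age bands
  15.0/42.7/41.0/1.3 over 6–9/10–13/14–17/18+. Cohort members exclude the
  youngest band, since the original cohort contained no members that young
  at baseline. General health is reported collapsed (95.9% very good/good)
  in the reference tables; the generator splits the top group 57.0/38.9 into
  excellent-very-good/good, keeping 4.1% moderate-to-very-poor.
- **Scores.** SDQ-type total difficulties: rounded N(8, 5) clipped to
  [0, 40] (puts roughly 9% in the borderline and 4% in the conspicuous
  range). SES subscores on 1–7: N(3.5, 1.4); the education subscore is drawn
  around CASMIN-level means (2.3/3.5/5.2) so the two education measures
  cohere. Social support (3–15) and self-efficacy (10–40) exist only from
  age 11; below that they are structurally missing, which the pipeline
  distinguishes from item-missingness throughout.
- **Covariate independence.** Apart from the education link, covariates are
  drawn independently: only marginal distributions are published for the
  reference sample, and the downstream stages need marginal realism plus a
  *known* dropout mechanism, not a realistic copula. Selectivity tests
  therefore exercise marginal recovery; joint-distribution effects are out
  of reach of the generator by construction.
- **Base weight.** `w_qs` is produced by raking to deliberately offset
  population margins (sex, age band, education), giving mean-1 weights with
  modest dispersion (effectiveness around 90%), standing in for the
  cross-sectional calibration weight of the baseline survey.
- **Re-activation.** Registration is Bernoulli with per-covariate generating
  log-odds defaulting to the published 11+ registration odds ratios (female
  +log 2.61, problem score +log 0.98, education subscore +log 1.13, …,
  cohort × age +log 1.05); participation is drawn only among registrants
  with the corresponding participation effects (female log 2.85, …).
  Psychosocial terms contribute only where the scales exist. Intercepts are
  calibrated by deterministic root-finding (Brent) so the marginal rates hit
  their targets (37.9% registration; 68.8% participation among registrants)
  in expectation — no trial simulation, hence bit-reproducible.
- **Missingness.** Item-missingness is MCAR per variable (defaults 1–3%,
  all below the 5% screen); an MAR option shifts missingness odds along one
  standardized covariate with the marginal rate preserved by the same
  intercept calibration. Structural missings are never overwritten.
- **Dispositions.** Non-registrants draw a final disposition code from a
  mixture proportional to the reference registration-process counts
  (refusal 60, restricted access 32, nothing returned 6,479, unclear address
  696, deceased 4, moved abroad 15, of 7,286), independently of covariates —
  only code totals are published.
- **Reproducibility.** One integer seed; each operation derives its own
  substream (`default_rng([seed, k])`), so inserting or skipping a stage
  does not perturb the others.

## Disposition rates

Codes follow the four-block AAPOR-style layout. The default recruitment rate
is the *simple* variant, registered/invited, because 4,451/11,737 reproduces
the printed overall rate (37.9%) exactly; an `aapor_e1` variant excludes the
confirmed-not-eligible block from the denominator. All rates are rounded
half-up to one decimal, matching every printed rate checked. The
subsample-specific cohort recruitment denominator of the reference study is
not reverse-engineered: 1,822/4,379 gives 41.6, not the printed 41.7, so
both variants are exposed and the discrepancy is left alone.

## Re-activation models

Complete-case logistic regressions per age stratum (under 11 / 11 and
older), maximum likelihood via IRLS, OR = exp(β), Wald 95% CIs
(β ± 1.96·SE) and Wald p-values. Continuous predictors enter on their raw
scales (the published per-unit ORs imply unstandardized predictors). The
participation outcome is coded 1 iff the person registered *and*
participated, on the same complete-case frame as the registration model —
the two published models share an observation count, which implies the
unconditional coding; a conditional-on-registration variant is available
and is the correctly specified model for data simulated by this package's
own generator. These are unweighted selection analyses, deliberately
separate from the weighting pipeline. Separation is flagged (|log-odds| >
10 or SE > 100) rather than penalized; penalized or exact logistic
regression is out of scope.

## Weighting pipeline

- **Screen**: variables with item-missing fraction above 5% are dropped;
  structural missings count toward neither numerator nor denominator.
- **Impute**: continuous → lower median of observed values (the lower of
  the two central order statistics at even counts — deterministic and
  order-free); categorical → mode, ties broken by declared level order.
- **User-missing merging**: a designated user-missing category is folded
  into the observed category with the nearest re-participation rate, ties
  toward the larger category; every merge is logged.
- **Selection**: bidirectional stepwise minimizing AIC (the reference
  procedure names only "stepwise regression"; an information criterion
  makes the search deterministic), then all interactions of selected
  variables with age, sex and parental education (partner main effects are
  forced in, and symmetric duplicates are collapsed), then plausibility
  pruning: dummy cells under 25 observations, |log-odds| above 5, SE above
  2, or minimum Wald p above 0.05. Implausible *interactions* are deleted
  before main effects are judged — an interaction with an uncentered
  partner is collinear with its parent and inflates the parent's SE, so
  deleting the interaction first and restarting avoids discarding genuine
  main effects. The stepwise restarts without deleted terms until a fixed
  point (or 10 iterations, then flagged non-converged). All caps are
  configuration-exposed; the reference procedure states the checks but not
  the numbers.
- **Propensity and weights**: θ is the fitted probability from the
  base-weight-weighted logistic fit, floored at 0.01 before inversion
  (logged); `wLS = base/θ` over the stage's re-participants. Registration
  uses `w_qs` as base; participation uses the registration-stage `wLS`, so
  chaining is exact: `w_qs/(θ_reg·θ_part)`.
- **Combination**: per-stage weights of the two subsamples merge by a
  convex combination with proportions λ_k proportional to Kish effective
  case numbers; each subsample is rescaled so its weighted share of the
  combined total equals λ_k (one faithful reading of "merged accordingly";
  the exact rescaling mechanics are not published, and the choice is
  recorded in the audit output), then the combined vector is renormalized
  to mean 1. Allocating by effective rather than nominal size downweights
  the more dispersed subsample and cannot lower combined effectiveness;
  within-subsample weight ordering is preserved.
- **Diagnostics**: min/median/max, CV (population SD over mean, in %), and
  effectiveness `100·n_eff/n`. With the population-SD convention the
  identity `effectiveness = 100/(1+(CV/100)²)` is exact, and an unweighted
  vector reports CV 0, effectiveness 100 exactly.
- **Balance**: unweighted and weighted category percentages with 95%
  normal-approximation CIs in which the Kish effective n replaces n, plus
  the maximum absolute weighted-vs-reference discrepancy per parameter.
- No trimming of final weights by default (an optional propensity floor is
  the only dispersion control), and no re-calibration of longitudinal
  weights to external margins — the base weight already carries that.

## Benchmarking

The re-activated sample is standardized to the reference composition by
raking over four marginal dimensions (age, sex, education, region) rather
than full cross-classification — joint cells are not published and raking
is robust to empty ones. Convergence: worst margin discrepancy below 1e-6,
at most 100 cycles; convergence is checked before each update cycle, so an
already standardized sample passes through bit-unchanged (idempotence).
Weighted means use SE = weighted SD / √n_eff (Kish approximation; no design
strata are available for either sample), CIs are mean ± 1.96·SE, and the
two-sample t-test uses the pooled SE with df = ⌊n_eff,a⌋ + ⌊n_eff,b⌋ − 2.
The published df of the reference comparison is not reconstructible from
the published sample sizes and is not reproduced.

## Problem sizes

The test suite and the acceptance script scale the simulations to run
comfortably on one CPU: marginal-distribution checks at n = 10,000, IPW
bias-correction at n = 20,000, single-fit OR recovery at n = 50,000, CI
coverage at 100 replicates of n = 5,000, stepwise power/null at 20 seeds of
n = 5,000, and t-test calibration at 200 replicates of n = 5,000. The
benchmark simulation in the acceptance script uses the reference sample
sizes (3,063 and 7,761), a truncated-normal life-satisfaction item whose
location is solved so the truncated mean equals the target exactly, and a
lognormal weight mixture with CV ≈ 1.4 to mirror the dispersion of chained
longitudinal weights (effectiveness near one third).

## Known limitations

- Covariates are (nearly) independent in the generator; balance results do
  not speak to correlated-covariate regimes.
- The stepwise null-retention rule uses the minimum Wald p across a term's
  columns, which retains some noise interactions for many-level categorical
  pairs.
- MCAR/MAR missingness only; the imputation rules are simple single
  imputations, as in the reference procedure, and understate uncertainty.
- No replication-based variance estimation for weighted estimates.
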