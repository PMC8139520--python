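# pseudocohort

Birth-cohort life-course smoking estimates from repeated cross-sectional
surveys — with a microsimulation ground truth that makes every stage of
the reconstruction verifiable.

## The problem

National smoking surveys are snapshots: each one reports who smokes at a
single point in time. But tobacco-control questions are about *cohorts*
— how the men and women born in, say, 1920–29 took up, carried and quit
smoking across their lives. A pseudo-cohort (synthetic cohort) analysis
recovers those life-course trajectories by pooling many independent
cross-sections: every respondent is assigned a birth year
(`survey_year − age`), and estimates for the same birth cohort are
linked across surveys conducted decades apart.

This package implements that synthesis as a tested pipeline for
epidemiologists and simulation modellers:

1. **harmonize** — recode heterogeneous per-survey status vocabularies to
   current/former/never (daily/regular smoking defines *current*; at
   most weekly counts as *never*), exclude records missing status, age
   or sex, and keep an auditable exclusion report. Surveys whose
   questionnaire cannot separate former from never smokers contribute
   only to current-smoking estimates.
2. **pclm** — surveys reporting only multi-year age groups are
   disaggregated to single years of age with a penalized composite link
   model: group counts are Poisson with mean μ = Cγ, γ = exp(η) the
   latent single-age intensities, and a difference penalty (λ/2)‖D_d η‖²
   enforces smoothness; single ages are then drawn within each reported
   group with probability ∝ γ. λ is chosen by AIC.
3. **rake** — post-stratification weights by iterative proportional
   fitting, so weighted sex × 5-year-age-band margins match external
   population tables, starting from each survey's design weights.
4. **cohorts** — one weighted prevalence point per (cohort, sex, survey),
   with Kish effective-sample-size standard errors
   (n_eff = (Σw)²/Σw²), suppression of cells with n < 100 or relative
   standard error ≥ 0.25, men-minus-women difference curves, and a
   binomial logit GLM in age and birth year as a display trend.
5. **initiation** — mean/SD/median age at daily-smoking initiation and
   the cumulative percentage initiating by ages 15…40, among ever
   smokers surveyed after age 30 (younger respondents are excluded so
   late starters are not censored away).
6. **simulate** — the part that makes the rest testable: a discrete
   annual-time life-course microsimulator (never → current → former,
   with mortality at baseline × hazard-ratio-by-status) whose exact
   state-occupancy recursion gives the true survivor composition of
   every cohort at every age. A survey generator draws realistic
   cross-sections: differential response, grouped age reporting, missing
   data, recanting (former smokers reporting "never"), and series that
   lack the former-smoker or initiation questions.

The default synthetic scenario emulates a 33-survey national landscape
(1962–2018, per-survey n from 600 to 54,576, ≈392k pooled respondents,
cohorts 1910–1989, ages 12–99).

## Worked example

```bash
python analysis/01_generate_study.py   # write the synthetic study
python analysis/02_run_pipeline.py     # reconstruct cohorts from it
python analysis/03_recovery_check.py   # compare with the exact truth
python analysis/04_bias_scenarios.py   # the two reporting-bias demos
```

`02_run_pipeline.py` prints, for the default study:

```
harmonized: 379,725 of 392,276 respondents retained (12,551 missing status/age/sex, 0 outside the 12-99 / 1910-1989 window)
trajectories: 450 (cohort, sex, survey) cells, 402 retained for current smoking after the n>=100 / RSE<0.25 filter
mean initiation age by cohort (M vs F):
  1910s: men 16.8, women 24.2
  1920s: men 16.7, women 22.3
  ...
  1970s: men 17.7, women 17.6
```

Reading this: ~3.2% of drawn respondents are excluded for missing
fields; the 450 cohort-by-survey cells are the raw trajectory points of
which 402 survive the precision filter; and the initiation table shows
the generated history the scenario encodes — women in early cohorts
starting ~7 years later than men, the gap closing to under half a year
by the 1960s-born cohort.

`03_recovery_check.py` then quantifies how well the reconstruction
tracks the exact survivor composition of the simulation:

```
1104 retained (cell, status) comparisons
  within 2pp of truth: 74.1%
  95% CI coverage:     94.6%
  mean |error|:        1.55pp
```

Coverage near 95% means the reported standard errors fully account for
the deviations: the estimator is unbiased, and the cells that miss the
2-percentage-point band are the ones from small historical surveys
whose sampling noise is intrinsically larger (the per-series table the
script prints makes this explicit).

`04_bias_scenarios.py` reproduces the two known distortions of
retrospective cross-sectional data: with 20% recanting the observed
never-smoker share is inflated to within Monte-Carlo error of
p_never + 0.2 · p_former, and under smoker excess mortality a cohort
surveyed only at ages 69–78 overstates its mean initiation age by
+0.2 (men) to +0.5 (women) years.

A `pseudocohort` CLI wraps the same library
(`pseudocohort simulate -c scenario.yaml -o DIR`,
`pseudocohort run -c pipeline.yaml`, `pseudocohort report -i DIR`).

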