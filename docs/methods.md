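# Methods

This note documents the models, conventions and numerical choices
behind `pseudocohort`, and what the synthetic-data experiments do and do
not demonstrate about real survey data.

## The life-course model and its exact solution

Each simulated person moves through never → current → former smoking in
discrete annual steps. Within the year a person is age `a`, the smoking
transition happens first — never → current with initiation hazard
h_i(a) (supported on ages 10–40), current → former with cessation
hazard h_c(a) — and mortality second, with probability
q(a) · HR(status), clipped at 1, where q is the never-smoker baseline
and HR_current ≥ HR_former ≥ 1 encode smoker excess mortality. Relapse
(former → current) is not modelled: one quit event per biography.

Three boundary conventions follow from this ordering and are relied on
throughout: a person who quits at age `a` is *former* when interviewed
at `a`; one who initiates at `a` is *current* at `a` (and can quit no
earlier than `a+1`); one whose death year is `a` is not interviewable at
`a`. The function `true_cohort_prevalence` evaluates the same chain as
an exact forward recursion over state-occupancy probabilities and
normalizes over the alive states, giving the survivor composition
(p_never, p_current, p_former) of a cohort at any age to machine
precision. This recursion — not the scenario's input hazards — is the
ground truth for every recovery experiment, because the quantity the
pipeline estimates is prevalence *in the surviving population*.

Recanting is modelled as an interview-time reporting error: a former
smoker reports "never" with probability r, independently at every
survey. It therefore inflates the observed never share by exactly
r · p_former in expectation while leaving the underlying biography
untouched, which is what the recanting scenario verifies.

## Survey drawing

Surveys sample age-eligible survivors without replacement with
inclusion probability proportional to a (sex, age-band) response rate,
implemented by Gumbel top-k keys so a draw is a pure function of the
seed. Design weights, where the survey "ships" them, are inverse
response probabilities. Grouped-age designs report the containing bin
instead of the single age; quota-poll-style designs collapse
former/never into a single non-smoker code; initiation age is emitted
only by designs that ask for it. A configurable fraction of rows has
one of status/age/sex blanked completely at random (the exclusion step
downstream assumes nothing about the mechanism; missing-at-random
variants can be configured through the response-rate maps instead).

## Harmonization and exclusions

Status mappings are explicit per-survey dictionaries onto
{current, former, never, noncurrent, missing}; an unmapped code is an
error, never a silent missing. "Noncurrent" marks respondents from
questionnaires that cannot separate former from never; such surveys
contribute only to current-smoking estimates. Rows missing status, age
(or age group) or sex are excluded and counted; rows outside ages 12–99
or birth years 1910–1989 are counted separately so the report stays
auditable (the two reasons are not conflated even though a pooled study
may publish a single exclusion figure). Occasional (at most weekly)
smokers are mapped to never by convention, configurable per survey.

## PCLM ungrouping

Grouped age counts y are modelled as Poisson with mean μ = Cγ,
γ = exp(η) on the single-age grid, C the 0/1 membership matrix, and the
penalized log-likelihood

    l(η) = Σ_g [y_g log μ_g − μ_g] − (λ/2)‖D_d η‖²

is maximized by penalized IRLS (working matrix X = C·diag(γ)/μ, system
(X'WX + λD'D)η⁺ = X'WX·η + X'(y−μ), W = diag(μ), with a 1e-10 ridge for
solvability and a ±50 clip on η for overflow safety). Because the
order-d difference penalty annihilates constants, the stationarity
condition along the constant direction forces Σγ = Σy; the pipeline
asserts this to 1e-6 relative on every stratum. Defaults: d = 2,
convergence when max|Δη| < 1e-6, λ selected by AIC
(deviance + 2·tr[(X'WX+λD'D)⁻¹X'WX]) over a geometric grid
10⁻²…10⁵ with 8 points per decade, ties toward the smoother fit.
Open-ended top groups are closed at age 99. Fitting is stratified by
(survey, sex), since age structure differs across survey years and
sexes; the correctness reference in the tests is a generic L-BFGS
maximizer of the same objective.

Single ages are then drawn within each record's reported group with
probability ∝ γ, so containment in the reported group is exact by
construction. One canonical assignment (a named seed) feeds the
headline pipeline; `robustness_check` re-draws the assignment and
reports the per-cell spread. That spread behaves like reassignment
noise with sd ≈ sqrt(2(1−f)p(1−p)/n) for a cell receiving a fraction f
of a bin — a few percentage points for cells of a few hundred — which
is why the headline run fixes one assignment and treats the spread as a
quantified sensitivity, not as something averaged away.

## Raking

Post-stratification weights are computed per survey by classical IPF:
weights are cyclically rescaled (w ← w · target/current) over the
sex and 5-year-age-band dimensions until every weighted margin is
within 1e-8 relative of its target (at most 1000 cycles;
non-convergence is flagged, never silently accepted). Weights are
normalized to population counts, so per-survey weight totals equal the
covered population total — margins are restricted to the age bands the
survey actually samples, which keeps partial age coverage from
demanding impossible targets. Raking starts from the supplied design
weights, preserving relative weights within every cross-cell. Weight
trimming is not applied by default. Records with grouped ages are raked
after PCLM assignment so band membership is unambiguous.

## Cohort trajectories

Birth year is survey_year − age; this is exact in the simulator and at
most a one-year cohort-boundary blur for real respondents whose
birthday had not passed at interview. Cohorts are 10-year bins
1910–1989 (5-year bins as a supplementary width; the 5-year cells
aggregate exactly to the 10-year cells within a survey, which the tests
assert to 1e-9). Each (cohort, sex, survey) cell yields one point:
weighted proportions, the weighted mean contributor age as the
representative age, and SE = sqrt(p(1−p)/n_eff) with the Kish effective
size n_eff = (Σw)²/Σw². The Kish approximation ignores the
finite-population correction and any clustering, making intervals
mildly conservative at large sampling fractions. Cells are reported
only with n ≥ 100 and RSE < 0.25, evaluated per status, so a cell can
be retained for current smoking and suppressed for former. The
binomial logit GLM (individual records, main effects in age and birth
year, final weights as frequency weights, statsmodels) is a display
trend only; no reported proportion comes from it.

## Initiation

Initiation summaries are unweighted (a weighted variant exists behind a
flag), restricted to current/former smokers with a reported initiation
age, from surveys that asked the question, interviewed after age 30 —
the exclusion prevents the downward bias of cohorts observed before
their late starters have started. SD is the n−1 sample value (0 for a
singleton cell); the median of an even cell is the midpoint of the two
central order statistics. Cumulative thresholds (≤15 … ≤40, inclusive)
are reported as missing when the cell's maximum interview age is below
the threshold, rather than as a spuriously censored 100%. Initiation
ages exceeding the interview age are dropped with a logged count.

## The default scenario, and what recovery does and does not show

The default study is one concrete, realistic landscape: 33 surveys over
1962–2018 with per-survey n from 600 to 54,576 (≈392k pooled), five
series differing in age reporting, questionnaire content and weighting,
a population of 500,000 (3,125 per birth-year × sex), cohort
ever-smoking calibrated by root-finding to targets that follow the
historical narrative (men ~74–76% in the earliest cohorts declining to
~40%; women rising from ~30% to a 1960s peak of ~53%), triangular
initiation-age profiles whose peak falls from 25 to 17 across women's
cohorts, cessation rising across cohorts, Gompertz baseline mortality
and HR 2.0/1.3 for current/former smokers. Recanting is off in the
headline scenario so that recovery against the exact recursion is
meaningful; it is exercised in its own scenario (r = 0.20). The
differential-mortality scenario uses a 1910s-style baseline with
substantial background adult mortality (floor 0.006/year, HR 3.0/1.8),
because initiation-age selection can only operate through mortality
experienced during the initiation window.

On this study the reconstruction is unbiased — empirical 95% interval
coverage ≈ 95% — with mean absolute error ≈ 1.5pp across ~1,100
retained cell-status comparisons. About a quarter of retained cells
deviate from truth by more than 2pp; these are concentrated in the
small historical series (a retained cell needs only n ≥ 100, i.e. SEs
up to ~5pp), and their deviations are exactly the size their reported
SEs predict. Passing these checks shows the machinery introduces no
systematic error under a design-faithful generative model; it does not
validate the behavioural realism of any real survey series, nor guard
against mechanisms the simulator omits (non-ignorable nonresponse,
recall error in initiation ages, migration, relapse).

## Numerical and reproducibility choices

All randomness flows through named integer seeds expanded with numpy
`SeedSequence.spawn`, so populations, survey draws and PCLM assignments
are independently reproducible; two runs with the same config are
byte-identical (CSV written with a fixed float format). Degenerate
inputs fail loudly: empty process lists, all-zero grouped counts,
unmapped status codes, raking categories with positive targets but no
sample mass. Problem sizes in the test suite are chosen so the full
suite (including one default-scale end-to-end study) completes in well
under a minute on one CPU.
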