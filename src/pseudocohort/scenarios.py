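"""Study scenarios: cohort dynamics and survey designs for the simulator.

The default scenario emulates the pooled Australian survey landscape the
pipeline was built for: 33 cross-sectional surveys over 1962-2018 drawn
from birth cohorts 1910-1989, per-survey samples between 600 and 54,576
(about 392k pooled respondents), early surveys reporting only grouped
ages, one quota-poll series without the former-smoker question, and
initiation ages carried only by the health/drug-survey-style series.
Cohort ever-smoking levels follow the historical narrative — roughly
three-quarters of mid-century men and a quarter of mid-century women
ever smoking, converging after the 1960s cohorts — with differential
mortality (current-smoker hazard ratio 2.0, former 1.3).  These are
*inputs* to recovery experiments, never ground truth for any test: the
truth is whatever the exact occupancy recursion says about them.

Two small purpose-built scenarios reproduce the reporting biases the
cross-sectional design is known to suffer: recanting (former smokers
reporting never) and differential-mortality distortion of retrospective
initiation ages in cohorts only surveyed old.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .simulate import AGE_MAX, CohortProcess, SurveyDesign

__all__ = [
    "Scenario",
    "default_scenario",
    "recanting_scenario",
    "differential_mortality_scenario",
    "initiation_hazard_for_target",
    "baseline_mortality",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


@dataclass
class Scenario:
    processes: list
    surveys: list
    n_per_cohort_year: int
    description: str = ""

    @property
    def total_sample_size(self) -> int:
        return sum(s.sample_size for s in self.surveys)


def baseline_mortality(scale: float = 3.5e-5, slope: float = 0.092, floor: float = 3e-4) -> np.ndarray:
    """Gompertz-style never-smoker annual death probability by age."""
    ages = np.arange(AGE_MAX + 1)
    return np.clip(floor + scale * np.exp(slope * ages), 0.0, 1.0)


def _triangular_shape(peak: int, lo: int = 12, hi: int = 34, span: float = 12.0) -> np.ndarray:
    ages = np.arange(AGE_MAX + 1, dtype=float)
    shape = np.clip(1.0 - np.abs(ages - peak) / span, 0.0, None)
    shape[(ages < lo) | (ages > hi)] = 0.0
    return shape


def initiation_hazard_for_target(
    ever_target: float, peak: int, lo: int = 12, hi: int = 34
) -> np.ndarray:
    """Annual initiation hazards with a triangular age profile calibrated so
    the cumulative probability of ever smoking by the end of the support
    equals ``ever_target`` (solved exactly by root finding)."""
    shape = _triangular_shape(peak, lo, hi)
    if not 0.0 < ever_target < 1.0:
        raise ValueError("ever_target must be in (0, 1)")

    def cum_minus_target(s):
        return 1.0 - np.prod(1.0 - s * shape[shape > 0]) - ever_target

    s_hi = 0.999 / shape.max()
    s = brentq(cum_minus_target, 1e-9, s_hi, xtol=1e-12)
    return s * shape


def _cessation_hazard(base: float) -> np.ndarray:
    """Modest quitting from age 18, stepping up at 25."""
    h = np.zeros(AGE_MAX + 1)
    h[18:25] = 0.008
    h[25:] = base
    return h


# per 10-year cohort (1910s .. 1980s): target ever-smoking by end of
# initiation support, and the age profile peak
_MEN_EVER = (0.74, 0.76, 0.72, 0.66, 0.58, 0.52, 0.45, 0.40)
_MEN_PEAK = (17, 17, 17, 17, 17, 17, 17, 18)
_WOMEN_EVER = (0.30, 0.36, 0.42, 0.47, 0.51, 0.53, 0.45, 0.40)
_WOMEN_PEAK = (25, 23, 22, 20, 19, 18, 17, 17)
_QUIT_BASE = (0.015, 0.018, 0.020, 0.025, 0.030, 0.035, 0.040, 0.045)

HR_CURRENT = 2.0
HR_FORMER = 1.3

_CODES_STANDARD = {"current": "daily", "former": "ex-smoker", "never": "never"}

# mild, plausible response differentials: younger men respond least
_RESPONSE = {
    "M": [(12, 29, 0.62), (30, 59, 0.75), (60, AGE_MAX, 0.80)],
    "F": [(12, 29, 0.72), (30, 59, 0.85), (60, AGE_MAX, 0.86)],
}

_MISSING_FRAC = 0.032

_AGP_BINS = [(16, 20), (21, 29), (30, 39), (40, 49), (50, 59), (60, 70)]
_CCV_BINS = [(14, 17), (18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 99)]


def _default_processes(recant_prob: float = 0.0) -> list:
    q = baseline_mortality()
    processes = []
    for i, start in enumerate(range(1910, 1990, 10)):
        for sex in ("M", "F"):
            ever = _MEN_EVER[i] if sex == "M" else _WOMEN_EVER[i]
            peak = _MEN_PEAK[i] if sex == "M" else _WOMEN_PEAK[i]
            processes.append(
                CohortProcess(
                    birth_years=(start, start + 9),
                    sex=sex,
                    initiation_hazard=initiation_hazard_for_target(ever, peak),
                    cessation_hazard=_cessation_hazard(_QUIT_BASE[i]),
                    baseline_mortality=q,
                    hr_current=HR_CURRENT,
                    hr_former=HR_FORMER,
                    recant_prob=recant_prob,
                    label=f"{start}s:{sex}",
                )
            )
    return processes


def _default_surveys() -> list:
    surveys = []
    # quota-poll series: grouped ages, no former-smoker question, no weights
    for year, n in [(1962, 600), (1964, 1700), (1967, 2000), (1970, 2200), (1974, 2400), (1979, 2600)]:
        surveys.append(
            SurveyDesign(
                survey_id=f"AGP{year}", survey_year=year, sample_size=n,
                age_range=(16, 70), age_reporting=_AGP_BINS,
                has_former_question=False, has_initiation_age=False,
                response_rate=_RESPONSE, weight_style="none",
                missing_frac=_MISSING_FRAC, series="AGP",
            )
        )
    # cancer-council-style series: former question, no initiation ages,
    # grouped ages in the early waves
    ccv = [(1974, 4000), (1976, 4000), (1980, 4200), (1983, 4300),
           (1986, 4400), (1989, 4500), (1992, 4500), (1998, 4500)]
    for year, n in ccv:
        grouped = year <= 1983
        surveys.append(
            SurveyDesign(
                survey_id=f"CCV{year}", survey_year=year, sample_size=n,
                age_range=(14, 99), age_reporting=_CCV_BINS if grouped else "exact",
                has_former_question=True, has_initiation_age=False,
                response_rate=_RESPONSE, weight_style="design",
                missing_frac=_MISSING_FRAC, status_codes=_CODES_STANDARD, series="CCV",
            )
        )
    # capital-city risk-factor series: exact ages 20-69, initiation ages
    for year, n in [(1980, 5600), (1983, 7600), (1989, 9100)]:
        surveys.append(
            SurveyDesign(
                survey_id=f"RFPS{year}", survey_year=year, sample_size=n,
                age_range=(20, 69), age_reporting="exact",
                has_former_question=True, has_initiation_age=True,
                response_rate=_RESPONSE, weight_style="design",
                missing_frac=_MISSING_FRAC, status_codes=_CODES_STANDARD, series="RFPS",
            )
        )
    # household drug-survey series: wide age range, initiation ages
    ndshs = [(1990, 3500), (1993, 3800), (1995, 4000), (1998, 10000), (2001, 24000),
             (2004, 24000), (2007, 23000), (2010, 26000), (2013, 23500), (2016, 23700)]
    for year, n in ndshs:
        surveys.append(
            SurveyDesign(
                survey_id=f"NDSHS{year}", survey_year=year, sample_size=n,
                age_range=(12, 99), age_reporting="exact",
                has_former_question=True, has_initiation_age=True,
                response_rate=_RESPONSE, weight_style="design",
                missing_frac=_MISSING_FRAC, status_codes=_CODES_STANDARD, series="NDSHS",
            )
        )
    # national health survey series: the large waves
    nhs = [(1989, 22000), (1995, 54576), (2001, 26000), (2007, 21000), (2014, 19000), (2018, 16000)]
    for year, n in nhs:
        surveys.append(
            SurveyDesign(
                survey_id=f"NHS{year}", survey_year=year, sample_size=n,
                age_range=(15, 99), age_reporting="exact",
                has_former_question=True, has_initiation_age=True,
                response_rate=_RESPONSE, weight_style="design",
                missing_frac=_MISSING_FRAC, status_codes=_CODES_STANDARD, series="NHS",
            )
        )
    return surveys


def default_scenario(n_per_cohort_year: int = 3125, survey_scale: float = 1.0) -> Scenario:
    """The headline 33-survey study (recanting off, so recovery against
    the exact recursion is meaningful).

    ``n_per_cohort_year = 3125`` gives a population of 500,000
    (80 birth years x 2 sexes).  ``survey_scale`` shrinks every survey
    (and should shrink the population along with it) for fast tests;
    the defaults are the study conditions.
    """
    surveys = _default_surveys()
    if survey_scale != 1.0:
        for s in surveys:
            s.sample_size = max(30, int(round(s.sample_size * survey_scale)))
    return Scenario(
        processes=_default_processes(recant_prob=0.0),
        surveys=surveys,
        n_per_cohort_year=n_per_cohort_year,
        description="default 33-survey study, 1962-2018, cohorts 1910-1989",
    )


def recanting_scenario(recant_prob: float = 0.20, n_per_cohort_year: int = 8000) -> Scenario:
    """Single mid-century cohort with recanting at interview.

    Mortality is held at baseline (no smoker excess) so the only gap
    between the drawn survey and the recursion truth is the reporting
    error: the expected never-smoker share is inflated by exactly
    ``recant_prob * p_former``.
    """
    q = baseline_mortality()
    processes = [
        CohortProcess(
            birth_years=(1930, 1939), sex=sex,
            initiation_hazard=initiation_hazard_for_target(0.6, 18),
            cessation_hazard=_cessation_hazard(0.03),
            baseline_mortality=q,
            hr_current=1.0, hr_former=1.0,
            recant_prob=recant_prob, label=f"recant:{sex}",
        )
        for sex in ("M", "F")
    ]
    surveys = [
        SurveyDesign(
            survey_id="RECANT1985", survey_year=1985, sample_size=30000,
            age_range=(40, 60), age_reporting="exact",
            has_former_question=True, has_initiation_age=False,
            weight_style="none", status_codes=_CODES_STANDARD, series="RECANT",
        )
    ]
    return Scenario(processes, surveys, n_per_cohort_year, "recanting bias scenario")


def differential_mortality_scenario(
    hr_current: float = 3.0, hr_former: float = 1.8, n_per_cohort_year: int = 12000
) -> Scenario:
    """Earliest cohort surveyed only at old ages under smoker excess mortality.

    Early initiators accumulate more smoking years and die sooner, so the
    ever smokers still alive at the survey started later on average than
    the cohort's ever smokers as a whole — the retrospective initiation
    bias affecting cohorts captured only in late surveys.  The selection
    only differentiates by initiation age through mortality experienced
    *during* the initiation window, so the baseline carries the
    substantial background adult mortality of an early-1900s birth
    cohort (floor 0.006/year) rather than a modern low-mortality
    schedule.
    """
    q = baseline_mortality(scale=6e-5, slope=0.095, floor=6e-3)
    processes = [
        CohortProcess(
            birth_years=(1910, 1919), sex=sex,
            initiation_hazard=initiation_hazard_for_target(0.7 if sex == "M" else 0.3, 20),
            cessation_hazard=_cessation_hazard(0.012),
            baseline_mortality=q,
            hr_current=hr_current, hr_former=hr_former,
            recant_prob=0.0, label=f"diffmort:{sex}",
        )
        for sex in ("M", "F")
    ]
    surveys = [
        SurveyDesign(
            survey_id="LATE1988", survey_year=1988, sample_size=20000,
            age_range=(69, 78), age_reporting="exact",
            has_former_question=True, has_initiation_age=True,
            weight_style="none", status_codes=_CODES_STANDARD, series="LATE",
        )
    ]
    return Scenario(processes, surveys, n_per_cohort_year, "differential-mortality bias scenario")


# --- YAML round trip -------------------------------------------------------

def _runs(arr: np.ndarray) -> list:
    """Compress a per-age hazard vector into (age_start, age_end, value) runs."""
    runs = []
    start = 0
    for a in range(1, len(arr) + 1):
        if a == len(arr) or arr[a] != arr[start]:
            if arr[start] != 0.0:
                runs.append([int(start), int(a - 1), float(arr[start])])
            start = a
    return runs


def scenario_to_yaml(scenario: Scenario, path) -> None:
    import yaml

    doc = {
        "description": scenario.description,
        "n_per_cohort_year": scenario.n_per_cohort_year,
        "cohorts": [
            {
                "birth_years": list(p.birth_years),
                "sex": p.sex,
                "label": p.label,
                "initiation_hazard": _runs(p.initiation_hazard),
                "cessation_hazard": _runs(p.cessation_hazard),
                "baseline_mortality": [
                    [0, AGE_MAX, -1.0]  # placeholder replaced below
                ],
                "hr_current": p.hr_current,
                "hr_former": p.hr_former,
                "recant_prob": p.recant_prob,
            }
            for p in scenario.processes
        ],
        "surveys": [
            {
                "survey_id": s.survey_id,
                "survey_year": s.survey_year,
                "sample_size": s.sample_size,
                "age_range": list(s.age_range),
                "age_reporting": "exact" if not s.grouped else [list(b) for b in s.age_reporting],
                "has_former_question": s.has_former_question,
                "has_initiation_age": s.has_initiation_age,
                "response_rate": (
                    None if s.response_rate is None
                    else {k: [list(r) for r in v] if not np.isscalar(v) else v
                          for k, v in s.response_rate.items()}
                ),
                "weight_style": s.weight_style,
                "missing_frac": s.missing_frac,
                "status_codes": s.status_codes,
                "series": s.series,
            }
            for s in scenario.surveys
        ],
    }
    # mortality is rarely piecewise-constant; store it as a dense vector
    for block, p in zip(doc["cohorts"], scenario.processes):
        block["baseline_mortality"] = [float(v) for v in p.baseline_mortality]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    processes = [
        CohortProcess(
            birth_years=tuple(c["birth_years"]),
            sex=c["sex"],
            initiation_hazard=[tuple(r) for r in c.get("initiation_hazard", [])],
            cessation_hazard=[tuple(r) for r in c.get("cessation_hazard", [])],
            baseline_mortality=c.get("baseline_mortality"),
            hr_current=c.get("hr_current", 1.0),
            hr_former=c.get("hr_former", 1.0),
            recant_prob=c.get("recant_prob", 0.0),
            label=c.get("label", ""),
        )
        for c in doc["cohorts"]
    ]
    surveys = []
    for s in doc["surveys"]:
        rr = s.get("response_rate")
        if isinstance(rr, dict):
            rr = {k: [tuple(r) for r in v] if isinstance(v, list) else v for k, v in rr.items()}
        rep = s.get("age_reporting", "exact")
        if rep != "exact":
            rep = [tuple(b) for b in rep]
        surveys.append(
            SurveyDesign(
                survey_id=s["survey_id"],
                survey_year=s["survey_year"],
                sample_size=s["sample_size"],
                age_range=tuple(s.get("age_range", (12, AGE_MAX))),
                age_reporting=rep,
                has_former_question=s.get("has_former_question", True),
                has_initiation_age=s.get("has_initiation_age", False),
                response_rate=rr,
                weight_style=s.get("weight_style", "none"),
                missing_frac=s.get("missing_frac", 0.0),
                status_codes=s.get("status_codes"),
                series=s.get("series", ""),
            )
        )
    return Scenario(
        processes=processes,
        surveys=surveys,
        n_per_cohort_year=doc.get("n_per_cohort_year", 1000),
        description=doc.get("description", ""),
    )
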