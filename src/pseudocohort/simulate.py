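"""Life-course microsimulation of smoking biographies.

This module generates synthetic populations whose members initiate,
quit, and die according to annual discrete-time hazards, and draws
cross-sectional surveys from the survivors.  It provides the ground
truth against which the pseudo-cohort reconstruction pipeline
(harmonization, age disaggregation, raking, cohort estimation) is
verified by parameter recovery, since the real survey microdata it
emulates are restricted-access.

Time convention
---------------
Discrete annual steps.  Within a person's year at integer age ``a`` the
smoking transition happens first (never -> current with the initiation
hazard, current -> former with the cessation hazard), then mortality is
applied with probability ``baseline(a) * HR(status)`` clipped to 1.
Consequences of this convention, relied on by the exact occupancy
recursion (:func:`true_cohort_prevalence`):

* a person who quits at age ``a`` reports as a *former* smoker when
  interviewed at age ``a``;
* a person who initiates at age ``a`` reports as *current* at age ``a``
  and can quit no earlier than ``a + 1``;
* a person whose death age is ``a`` is not interviewable at age ``a``
  (``dead`` iff ``age >= death_age``).

Recanting — a former smoker reporting "never" — is an interview-time
reporting error: it is applied independently at every survey draw and
leaves the underlying life course untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

AGE_MAX = 99
SEXES = ("M", "F")
#: ages at which daily-smoking initiation is allowed to occur
INITIATION_SUPPORT = (10, 40)

__all__ = [
    "AGE_MAX",
    "SEXES",
    "CohortProcess",
    "LifeCourse",
    "SurveyDesign",
    "hazard_array",
    "simulate_population",
    "smoking_status_at",
    "statuses_at",
    "true_cohort_prevalence",
    "prevalence_schedule",
    "draw_survey",
]


def hazard_array(spec, age_max: int = AGE_MAX) -> np.ndarray:
    """Normalize a hazard specification to a per-age probability vector.

    Accepts ``None`` (all zero), a mapping ``{age: p}``, an iterable of
    ``(age_lo, age_hi, p)`` runs (inclusive bounds), or a full vector of
    length ``age_max + 1``.  All probabilities must lie in [0, 1].
    """
    arr = np.zeros(age_max + 1, dtype=float)
    if spec is None:
        pass
    elif isinstance(spec, dict):
        for age, p in spec.items():
            arr[int(age)] = p
    elif isinstance(spec, np.ndarray) and spec.ndim == 1 and len(spec) == age_max + 1:
        arr = spec.astype(float).copy()
    else:
        items = list(spec)
        if items and np.isscalar(items[0]):
            if len(items) != age_max + 1:
                raise ValueError(
                    f"hazard vector must have length {age_max + 1}, got {len(items)}"
                )
            arr = np.asarray(items, dtype=float)
        else:
            for lo, hi, p in items:
                if lo > hi:
                    raise ValueError(f"malformed hazard run ({lo}, {hi})")
                arr[int(lo): int(hi) + 1] = p
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("hazards must be probabilities in [0, 1]")
    return arr


@dataclass
class CohortProcess:
    """Generative smoking dynamics for one (birth-year range, sex) stratum.

    Parameters
    ----------
    birth_years:
        Inclusive ``(first, last)`` calendar birth years covered.
    initiation_hazard, cessation_hazard, baseline_mortality:
        Annual transition probabilities by integer age, in any form
        accepted by :func:`hazard_array`.  Initiation must be supported
        only on ages 10–40.
    hr_current, hr_former:
        Multiplicative hazard ratios on never-smoker mortality; the
        differential-mortality mechanism requires
        ``hr_current >= hr_former >= 1``.
    recant_prob:
        Probability that a former smoker reports "never" at any single
        interview (memoryless across surveys).
    """

    birth_years: tuple[int, int]
    sex: str
    initiation_hazard: object = None
    cessation_hazard: object = None
    baseline_mortality: object = None
    hr_current: float = 1.0
    hr_former: float = 1.0
    recant_prob: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        lo, hi = self.birth_years
        if lo > hi:
            raise ValueError("birth_years must be an ordered interval")
        self.birth_years = (int(lo), int(hi))
        self.initiation_hazard = hazard_array(self.initiation_hazard)
        self.cessation_hazard = hazard_array(self.cessation_hazard)
        self.baseline_mortality = hazard_array(self.baseline_mortality)
        s_lo, s_hi = INITIATION_SUPPORT
        outside = np.flatnonzero(self.initiation_hazard)
        if outside.size and (outside.min() < s_lo or outside.max() > s_hi):
            raise ValueError(
                f"initiation hazard must be zero outside ages {s_lo}-{s_hi}"
            )
        if not (self.hr_current >= self.hr_former >= 1.0):
            raise ValueError("require hr_current >= hr_former >= 1")
        if not 0.0 <= self.recant_prob <= 1.0:
            raise ValueError("recant_prob must be in [0, 1]")

    @property
    def cohort_start(self) -> int:
        return self.birth_years[0]


@dataclass
class LifeCourse:
    """One person's smoking biography (the scalar ground-truth unit)."""

    birth_year: int
    sex: str
    initiation_age: Optional[int] = None
    cessation_age: Optional[int] = None
    death_age: int = AGE_MAX + 1

    def __post_init__(self):
        if self.cessation_age is not None:
            if self.initiation_age is None:
                raise ValueError("cessation without initiation")
            if self.cessation_age < self.initiation_age:
                raise ValueError("cessation_age < initiation_age")
        if self.death_age < 0:
            raise ValueError("death_age must be >= 0")


def smoking_status_at(lc: LifeCourse, year: int) -> str:
    """Smoking status of ``lc`` at interview time ``year``.

    Returns one of ``never``, ``current``, ``former``, ``dead``.  The
    cessation year itself counts as former; the death year counts as
    dead (see module time convention).
    """
    age = year - lc.birth_year
    if age < 0:
        raise ValueError(f"year {year} precedes birth year {lc.birth_year}")
    if age >= lc.death_age:
        return "dead"
    if lc.initiation_age is None or age < lc.initiation_age:
        return "never"
    if lc.cessation_age is not None and age >= lc.cessation_age:
        return "former"
    return "current"


def statuses_at(population: pd.DataFrame, year: int) -> np.ndarray:
    """Vectorized :func:`smoking_status_at` over a population table."""
    age = year - population["birth_year"].to_numpy()
    if np.any(age < 0):
        raise ValueError("year precedes some birth years in the population")
    init = population["initiation_age"].to_numpy(dtype=float)
    cess = population["cessation_age"].to_numpy(dtype=float)
    death = population["death_age"].to_numpy(dtype=float)
    ever = ~np.isnan(init) & (age >= init)
    former = ever & ~np.isnan(cess) & (age >= cess)
    out = np.where(
        age >= death, "dead", np.where(former, "former", np.where(ever, "current", "never"))
    )
    return out


def population_to_lifecourses(population: pd.DataFrame) -> list[LifeCourse]:
    """Convert population rows into :class:`LifeCourse` objects."""
    out = []
    for row in population.itertuples(index=False):
        out.append(
            LifeCourse(
                birth_year=int(row.birth_year),
                sex=row.sex,
                initiation_age=None if np.isnan(row.initiation_age) else int(row.initiation_age),
                cessation_age=None if np.isnan(row.cessation_age) else int(row.cessation_age),
                death_age=int(row.death_age),
            )
        )
    return out


def simulate_population(
    processes: Sequence[CohortProcess],
    n_per_cohort_year: int,
    seed,
) -> pd.DataFrame:
    """Simulate complete life courses for every stratum.

    Each person evolves year by year through never -> current -> former
    with the stratum's annual transition probabilities, then faces
    mortality at ``baseline * HR(status)``.  Identical seeds give
    identical output.

    Returns a DataFrame with one row per person: ``birth_year``, ``sex``,
    ``initiation_age``, ``cessation_age`` (NaN where absent),
    ``death_age`` (``AGE_MAX + 1`` for those surviving the whole span),
    and the stratum's ``recant_prob``/``label`` carried along for survey
    drawing.
    """
    processes = list(processes)
    if not processes:
        raise ValueError("no cohort processes supplied")
    if n_per_cohort_year <= 0:
        raise ValueError("n_per_cohort_year must be positive")
    seen: set[tuple[int, str]] = set()
    for proc in processes:
        for by in range(proc.birth_years[0], proc.birth_years[1] + 1):
            key = (by, proc.sex)
            if key in seen:
                raise ValueError(f"overlapping strata at birth year {by}, sex {proc.sex}")
            seen.add(key)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(processes))
    frames = []
    for proc, child in zip(processes, children):
        rng = np.random.default_rng(child)
        years = np.arange(proc.birth_years[0], proc.birth_years[1] + 1)
        n = len(years) * n_per_cohort_year
        birth_year = np.repeat(years, n_per_cohort_year)

        state = np.zeros(n, dtype=np.int8)  # 0 never, 1 current, 2 former
        alive = np.ones(n, dtype=bool)
        init_age = np.full(n, np.nan)
        cess_age = np.full(n, np.nan)
        death_age = np.full(n, AGE_MAX + 1, dtype=np.int16)
        hi, hc, q0 = proc.initiation_hazard, proc.cessation_hazard, proc.baseline_mortality
        hrs = np.array([1.0, proc.hr_current, proc.hr_former])

        for a in range(AGE_MAX + 1):
            if not alive.any():
                break
            r = rng.random(n)
            starters = alive & (state == 0) & (r < hi[a])
            quitters = alive & (state == 1) & (r < hc[a])
            if starters.any():
                state[starters] = 1
                init_age[starters] = a
            if quitters.any():
                state[quitters] = 2
                cess_age[quitters] = a
            q_eff = np.minimum(q0[a] * hrs[state], 1.0)
            dies = alive & (rng.random(n) < q_eff)
            if dies.any():
                death_age[dies] = a
                alive[dies] = False

        frames.append(
            pd.DataFrame(
                {
                    "birth_year": birth_year,
                    "sex": proc.sex,
                    "initiation_age": init_age,
                    "cessation_age": cess_age,
                    "death_age": death_age,
                    "recant_prob": proc.recant_prob,
                    "cohort_process": proc.label or f"{proc.birth_years[0]}-{proc.birth_years[1]}:{proc.sex}",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _occupancy(process: CohortProcess, max_age: int) -> np.ndarray:
    """Exact forward recursion over annual state-occupancy probabilities.

    Returns an ``(max_age + 1, 3)`` array of the probability a cohort
    member is (never, current, former) *and alive* at the end of each
    age's step, mirroring the simulation's transition-then-mortality
    order exactly.
    """
    hi, hc, q0 = process.initiation_hazard, process.cessation_hazard, process.baseline_mortality
    hrc, hrf = process.hr_current, process.hr_former
    n, c, f = 1.0, 0.0, 0.0
    out = np.empty((max_age + 1, 3))
    for a in range(max_age + 1):
        n2 = n * (1.0 - hi[a])
        c2 = c * (1.0 - hc[a]) + n * hi[a]
        f2 = f + c * hc[a]
        sn = 1.0 - min(q0[a], 1.0)
        sc = 1.0 - min(q0[a] * hrc, 1.0)
        sf = 1.0 - min(q0[a] * hrf, 1.0)
        n, c, f = n2 * sn, c2 * sc, f2 * sf
        out[a] = (n, c, f)
    return out


def true_cohort_prevalence(process: CohortProcess, age: int) -> tuple[float, float, float]:
    """Exact ``(p_never, p_current, p_former)`` among survivors at ``age``.

    This is the analysis target: the smoking-status composition of the
    *surviving* population of the cohort, normalized over alive states.
    """
    if not 0 <= age <= AGE_MAX:
        raise ValueError(f"age must be in [0, {AGE_MAX}]")
    n, c, f = _occupancy(process, age)[age]
    tot = n + c + f
    if tot <= 0:
        return (np.nan, np.nan, np.nan)
    return (n / tot, c / tot, f / tot)


def prevalence_schedule(process: CohortProcess, ages: Optional[Iterable[int]] = None) -> pd.DataFrame:
    """Survivor-composition table over a range of ages (single recursion pass)."""
    ages = list(ages) if ages is not None else list(range(AGE_MAX + 1))
    occ = _occupancy(process, max(ages))
    rows = []
    for a in ages:
        n, c, f = occ[a]
        tot = n + c + f
        if tot <= 0:
            rows.append((a, np.nan, np.nan, np.nan))
        else:
            rows.append((a, n / tot, c / tot, f / tot))
    return pd.DataFrame(rows, columns=["age", "p_never", "p_current", "p_former"]).assign(
        cohort_start=process.cohort_start, sex=process.sex
    )


@dataclass
class SurveyDesign:
    """Design of one cross-sectional survey drawn from the population.

    ``age_reporting`` is ``"exact"`` or a list of inclusive ``(lo, hi)``
    bins partitioning ``age_range``.  ``response_rate`` maps sex to a
    scalar or a list of ``(age_lo, age_hi, p)`` runs; inclusion is
    proportional to it.  ``weight_style="design"`` attaches inverse
    response-probability weights.  A ``missing_frac`` fraction of rows
    has one of status/age/sex blanked completely at random.
    """

    survey_id: str
    survey_year: int
    sample_size: int
    age_range: tuple[int, int] = (12, AGE_MAX)
    age_reporting: object = "exact"
    has_former_question: bool = True
    has_initiation_age: bool = False
    response_rate: object = None
    weight_style: str = "none"
    missing_frac: float = 0.0
    status_codes: Optional[dict] = None
    series: str = ""

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.weight_style not in ("none", "design"):
            raise ValueError("weight_style must be 'none' or 'design'")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError("age_range must be ordered")
        if self.age_reporting != "exact":
            bins = [(int(a), int(b)) for a, b in self.age_reporting]
            bins.sort()
            if bins[0][0] != lo or bins[-1][1] != hi:
                raise ValueError("bins must span age_range exactly")
            for (a0, b0), (a1, _b1) in zip(bins, bins[1:]):
                if a0 > b0 or a1 != b0 + 1:
                    raise ValueError("bins must be contiguous, non-overlapping")
            self.age_reporting = bins

    @property
    def grouped(self) -> bool:
        return self.age_reporting != "exact"


def _response_probs(design: SurveyDesign, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
    p = np.ones(len(sex), dtype=float)
    rr = design.response_rate
    if rr is None:
        return p
    if np.isscalar(rr):
        return np.full(len(sex), float(rr))
    for s, spec in rr.items():
        m = sex == s
        if np.isscalar(spec):
            p[m] = float(spec)
        else:
            for lo, hi, val in spec:
                p[m & (age >= lo) & (age <= hi)] = float(val)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("response rates must be in (0, 1]")
    return p


# canonical reported status -> emitted code, by questionnaire type
_DEFAULT_CODES = {"current": "current", "former": "former", "never": "never"}
_DEFAULT_CODES_NO_FORMER = {"current": "smoker", "former": "non-smoker", "never": "non-smoker"}

RAW_COLUMNS = [
    "survey_id",
    "survey_year",
    "sex",
    "age",
    "age_group_lo",
    "age_group_hi",
    "status_code",
    "initiation_age",
    "weight",
]


def draw_survey(population: pd.DataFrame, design: SurveyDesign, seed) -> pd.DataFrame:
    """Draw one cross-sectional survey table from the living population.

    Samples age-eligible survivors without replacement with inclusion
    probability proportional to the design's response rates (Gumbel
    top-k keys, so the draw is reproducible), applies recanting to
    reported status, collapses former/never to a single non-smoker code
    when the questionnaire lacks the former-smoker item, reports age
    exactly or as the containing bin, and injects completely-at-random
    missingness.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    age_all = design.survey_year - population["birth_year"].to_numpy()
    lo, hi = design.age_range
    eligible = (age_all >= lo) & (age_all <= hi) & (age_all < population["death_age"].to_numpy())
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError(f"survey {design.survey_id}: no eligible persons")
    k = design.sample_size
    if k > idx.size:
        warnings.warn(
            f"survey {design.survey_id}: sample_size {k} exceeds {idx.size} eligible; truncating"
        )
        k = idx.size

    sex_el = population["sex"].to_numpy()[idx]
    age_el = age_all[idx]
    p = _response_probs(design, sex_el, age_el)
    keys = np.log(p) + rng.gumbel(size=idx.size)
    take = np.argsort(keys)[::-1][:k]
    sel = idx[take]

    age = age_all[sel].astype(float)
    sex = population["sex"].to_numpy()[sel].astype(object)
    status = statuses_at(population.iloc[sel], design.survey_year)
    # all selected are alive by construction
    recant_p = population["recant_prob"].to_numpy()[sel]
    recant = (status == "former") & (rng.random(k) < recant_p)
    reported = np.where(recant, "never", status)

    if design.has_former_question:
        vocab = design.status_codes or _DEFAULT_CODES
    else:
        vocab = design.status_codes or _DEFAULT_CODES_NO_FORMER
    code = np.array([vocab[s] for s in reported], dtype=object)

    if design.grouped:
        lows = np.array([b[0] for b in design.age_reporting])
        highs = np.array([b[1] for b in design.age_reporting])
        pos = np.searchsorted(lows, age, side="right") - 1
        g_lo = lows[pos].astype(float)
        g_hi = highs[pos].astype(float)
        age_out = np.full(k, np.nan)
    else:
        g_lo = np.full(k, np.nan)
        g_hi = np.full(k, np.nan)
        age_out = age

    init = np.full(k, np.nan)
    if design.has_initiation_age:
        raw_init = population["initiation_age"].to_numpy()[sel]
        ever_reported = np.isin(reported, ("current", "former"))
        init[ever_reported] = raw_init[ever_reported]

    if design.weight_style == "design":
        weight = 1.0 / p[take]
    else:
        weight = np.full(k, np.nan)

    n_miss = int(round(design.missing_frac * k))
    if n_miss:
        rows = rng.choice(k, size=n_miss, replace=False)
        which = rng.integers(0, 3, size=n_miss)
        code[rows[which == 0]] = None
        age_out[rows[which == 1]] = np.nan
        g_lo[rows[which == 1]] = np.nan
        g_hi[rows[which == 1]] = np.nan
        sex[rows[which == 2]] = None

    return pd.DataFrame(
        {
            "survey_id": design.survey_id,
            "survey_year": design.survey_year,
            "sex": sex,
            "age": age_out,
            "age_group_lo": g_lo,
            "age_group_hi": g_hi,
            "status_code": code,
            "initiation_age": init,
            "weight": weight,
        }
    )[RAW_COLUMNS]
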