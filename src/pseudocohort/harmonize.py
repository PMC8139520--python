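"""Harmonize heterogeneous survey tables into the common analysis schema.

Each source survey ships its own smoking-status vocabulary; a
:class:`StatusMapping` recodes it into ``current`` / ``former`` /
``never`` (plus ``noncurrent`` for questionnaires that cannot separate
former from never, and ``missing``).  Rows lacking status, age (or age
group), or sex are excluded — never imputed — and counted in an
auditable :class:`ExclusionReport`, separately from rows whose age or
birth year falls outside the 12–99 / 1910–1989 analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AGE_LO, AGE_HI = 12, 99
COHORT_LO, COHORT_HI = 1910, 1989

#: categories a status mapping may target
ALLOWED_TARGETS = {"current", "former", "never", "noncurrent", "missing"}

HARMONIZED_COLUMNS = [
    "survey_id",
    "survey_year",
    "sex",
    "age",
    "age_group_lo",
    "age_group_hi",
    "smoking_status",
    "initiation_age",
    "base_weight",
    "has_former_question",
    "has_initiation_age",
]


@dataclass
class StatusMapping:
    """Per-survey recode of source status codes to harmonized categories."""

    survey_id: str
    code_map: dict
    notes: str = ""

    def __post_init__(self):
        bad = set(self.code_map.values()) - ALLOWED_TARGETS
        if bad:
            raise ValueError(f"mapping targets outside {sorted(ALLOWED_TARGETS)}: {sorted(bad)}")


@dataclass
class ExclusionReport:
    """Bookkeeping of rows removed during harmonization.

    ``retained`` is derived, so the identity
    ``retained = total - excluded_missing - excluded_range`` holds by
    construction and is checkable against externally reported totals.
    """

    total: int
    excluded_missing: int
    excluded_range: int = 0
    per_survey: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.total, self.excluded_missing, self.excluded_range) < 0:
            raise ValueError("counts must be non-negative")
        if self.retained < 0:
            raise ValueError("exclusions exceed total")

    @property
    def retained(self) -> int:
        return self.total - self.excluded_missing - self.excluded_range

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "excluded_missing": self.excluded_missing,
            "excluded_range": self.excluded_range,
            "retained": self.retained,
            "per_survey": self.per_survey,
        }


def combine_reports(reports: Sequence[ExclusionReport]) -> ExclusionReport:
    per_survey: dict = {}
    for r in reports:
        for sid, counts in r.per_survey.items():
            if sid in per_survey:
                raise ValueError(f"duplicate survey id in reports: {sid}")
            per_survey[sid] = counts
    return ExclusionReport(
        total=sum(r.total for r in reports),
        excluded_missing=sum(r.excluded_missing for r in reports),
        excluded_range=sum(r.excluded_range for r in reports),
        per_survey=per_survey,
    )


def harmonize_table(raw: pd.DataFrame, mapping: StatusMapping, meta) -> tuple[pd.DataFrame, ExclusionReport]:
    """Recode one raw survey table and apply the exclusion rules.

    ``meta`` supplies ``survey_id``, ``survey_year``,
    ``has_former_question`` and ``has_initiation_age`` (a
    :class:`~pseudocohort.simulate.SurveyDesign` works).  Unmapped status
    codes fail fast by name; rows with missing status/age/sex are counted
    as ``excluded_missing``; rows whose age or implied birth year is
    entirely outside the analysis window are counted as
    ``excluded_range``.
    """
    df = raw.reset_index(drop=True)
    total = len(df)

    status_col = "status_code" if "status_code" in df.columns else "smoking_status"
    codes = df[status_col]
    observed = {c for c in codes.dropna().unique()}
    unmapped = observed - set(mapping.code_map)
    if unmapped:
        raise ValueError(
            f"survey {meta.survey_id}: unmapped status codes {sorted(map(str, unmapped))}"
        )
    mapped = codes.map(mapping.code_map)
    status_missing = codes.isna() | (mapped == "missing")

    sex_ok = df["sex"].isin(["M", "F"]) if "sex" in df.columns else pd.Series(False, index=df.index)

    def _col(name):
        return (
            pd.to_numeric(df[name], errors="coerce")
            if name in df.columns
            else pd.Series(np.nan, index=df.index)
        )

    age = _col("age")
    g_lo = _col("age_group_lo")
    g_hi = _col("age_group_hi")
    has_age = age.notna()
    has_grp = g_lo.notna() & g_hi.notna() & ~has_age
    bad_grp = g_lo.notna() & g_hi.notna() & (g_lo > g_hi)
    if bad_grp.any():
        i = int(bad_grp.idxmax())
        raise ValueError(
            f"survey {meta.survey_id}: malformed age group "
            f"({g_lo[i]:.0f} > {g_hi[i]:.0f}) at row {i}"
        )

    missing_mask = status_missing | ~sex_ok | ~(has_age | has_grp)

    year = int(meta.survey_year)
    birth_exact = year - age
    by_min = year - g_hi  # oldest possible birth year in the group
    by_max = year - g_lo
    range_exact = has_age & (
        (age < AGE_LO) | (age > AGE_HI) | (birth_exact < COHORT_LO) | (birth_exact > COHORT_HI)
    )
    range_grp = has_grp & (
        (g_hi < AGE_LO) | (g_lo > AGE_HI) | (by_max < COHORT_LO) | (by_min > COHORT_HI)
    )
    range_mask = (range_exact | range_grp) & ~missing_mask

    keep = ~missing_mask & ~range_mask
    n_missing = int(missing_mask.sum())
    n_range = int(range_mask.sum())

    weight = _col("weight") if "weight" in df.columns else _col("base_weight")
    base_weight = weight.fillna(1.0)
    if (base_weight[keep] <= 0).any():
        raise ValueError(f"survey {meta.survey_id}: non-positive base weights")

    init = _col("initiation_age")
    if not getattr(meta, "has_initiation_age", False):
        init = pd.Series(np.nan, index=df.index)

    out = pd.DataFrame(
        {
            "survey_id": meta.survey_id,
            "survey_year": year,
            "sex": df["sex"],
            "age": age.where(has_age),
            "age_group_lo": g_lo.where(has_grp),
            "age_group_hi": g_hi.where(has_grp),
            "smoking_status": mapped,
            "initiation_age": init,
            "base_weight": base_weight,
            "has_former_question": bool(getattr(meta, "has_former_question", True)),
            "has_initiation_age": bool(getattr(meta, "has_initiation_age", False)),
        }
    )[keep].reset_index(drop=True)[HARMONIZED_COLUMNS]

    report = ExclusionReport(
        total=total,
        excluded_missing=n_missing,
        excluded_range=n_range,
        per_survey={
            meta.survey_id: {
                "total": total,
                "excluded_missing": n_missing,
                "excluded_range": n_range,
                "retained": total - n_missing - n_range,
            }
        },
    )
    return out, report


def pool(datasets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate harmonized survey tables, preserving provenance.

    Survey ids must be unique across inputs; the pooled row count is the
    sum of the inputs by construction.
    """
    seen: set = set()
    for d in datasets:
        ids = set(d["survey_id"].unique())
        dup = seen & ids
        if dup:
            raise ValueError(f"duplicate survey ids across datasets: {sorted(dup)}")
        seen |= ids
    return pd.concat(list(datasets), ignore_index=True)


def identity_mapping(survey_id: str) -> StatusMapping:
    """Mapping under which harmonizing an already-harmonized table is a no-op."""
    return StatusMapping(
        survey_id, {c: c for c in ("current", "former", "never", "noncurrent")}
    )
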