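"""Birth-cohort assignment and weighted prevalence trajectories.

A pseudo-cohort trajectory links, across independent cross-sectional
surveys, the weighted proportion of current/former/never smokers among
respondents of the same birth cohort.  Birth year is ``survey_year -
age`` (a <= 1-year blur for respondents whose birthday had not yet
passed), cohorts are 10-year (or supplementary 5-year) bins over
1910-1989, and each (cohort, sex, survey) cell yields one point at the
weighted mean contributor age.  Standard errors use the Kish effective
sample size ``n_eff = (sum w)^2 / sum w^2``; cells are suppressed below
100 respondents or at a relative standard error of 0.25 or more.
A binomial logit GLM in age and birth year provides a display trend
only — reported proportions are always the observed survey points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

COHORT_LO, COHORT_HI = 1910, 1989
STATUSES = ("current", "former", "never")

__all__ = [
    "assign_cohort",
    "estimate_points",
    "filter_points",
    "sex_difference",
    "fit_smoother",
    "SmootherFit",
    "cohort_label",
]


def cohort_label(start: int, width: int) -> str:
    return f"{start}-{start + width - 1}"


def assign_cohort(records: pd.DataFrame, width: int = 10) -> pd.DataFrame:
    """Attach birth_year / cohort columns; flag out-of-scope cohorts.

    Uses a supplied ``birth_year`` column when present, otherwise
    ``survey_year - age``.  Requires single ages (post-PCLM).
    """
    if width not in (5, 10):
        raise ValueError("cohort width must be 5 or 10")
    out = records.copy()
    if out["age"].isna().any():
        raise ValueError("single age required for cohort assignment (run PCLM first)")
    if "birth_year" in out.columns and out["birth_year"].notna().all():
        by = out["birth_year"].astype(int)
    else:
        by = (out["survey_year"] - out["age"]).astype(int)
    out["birth_year"] = by
    out["cohort_start"] = (by // width) * width
    out["cohort_width"] = width
    out["out_of_scope"] = (by < COHORT_LO) | (by > COHORT_HI)
    return out


def _cell_stats(g: pd.DataFrame, weight_col: str, min_n: int, max_rse: float) -> dict:
    w = g[weight_col].to_numpy(dtype=float)
    sw = w.sum()
    n = len(g)
    n_eff = sw * sw / np.sum(w * w)
    row = {
        "age": float(np.sum(w * g["age"].to_numpy()) / sw),
        "n": n,
        "n_eff": n_eff,
        "sum_w": sw,
    }
    has_former = bool(g["has_former_question"].all()) if "has_former_question" in g else True
    status = g["smoking_status"].to_numpy()
    for s in STATUSES:
        if s != "current" and not has_former:
            row[f"p_{s}"] = np.nan
            row[f"se_{s}"] = np.nan
            row[f"rse_{s}"] = np.nan
            row[f"retained_{s}"] = False
            continue
        p = float(w[status == s].sum() / sw)
        se = float(np.sqrt(p * (1.0 - p) / n_eff))
        rse = se / p if p > 0 else np.inf
        row[f"p_{s}"] = p
        row[f"se_{s}"] = se
        row[f"rse_{s}"] = rse
        row[f"retained_{s}"] = bool(n >= min_n and rse < max_rse)
    return row


def estimate_points(
    records: pd.DataFrame,
    min_n: int = 100,
    max_rse: float = 0.25,
    weight_col: str = "weight",
) -> pd.DataFrame:
    """One weighted prevalence point per (cohort, sex, survey) cell.

    Surveys whose questionnaire cannot separate former from never
    smokers contribute only the current-smoking proportion.  The
    retention flag is evaluated per reported status: a cell can be
    retained for one proportion and suppressed for another.
    """
    df = records
    if "out_of_scope" in df.columns:
        df = df[~df["out_of_scope"]]
    if df.empty:
        raise ValueError("no in-scope records")
    if df[weight_col].isna().any():
        raise ValueError(f"missing weights in column {weight_col!r}")
    keys = ["cohort_start", "cohort_width", "sex", "survey_id"]
    rows = []
    for key, g in df.groupby(keys, sort=True):
        row = dict(zip(keys, key))
        row.update(_cell_stats(g, weight_col, min_n, max_rse))
        rows.append(row)
    pts = pd.DataFrame(rows)
    pts["cohort"] = [
        cohort_label(int(s), int(wd)) for s, wd in zip(pts["cohort_start"], pts["cohort_width"])
    ]
    return pts


def filter_points(points: pd.DataFrame, min_n: int = 100, max_rse: float = 0.25) -> pd.DataFrame:
    """Re-evaluate the per-status retention flags on existing points."""
    out = points.copy()
    for s in STATUSES:
        out[f"retained_{s}"] = (
            (out["n"] >= min_n) & (out[f"rse_{s}"] < max_rse) & out[f"p_{s}"].notna()
        )
    return out


def sex_difference(points: pd.DataFrame, status: str = "current") -> pd.DataFrame:
    """Men-minus-women percentage-point difference at matched survey points.

    Pairs male and female points of the same (cohort, survey) where both
    are retained for ``status``; the difference is reported at the mean
    of the two representative ages.
    """
    if status not in STATUSES:
        raise ValueError(f"unknown status {status!r}")
    r = points[points[f"retained_{status}"]]
    keys = ["cohort_start", "cohort_width", "survey_id"]
    m = r[r["sex"] == "M"][keys + ["age", f"p_{status}"]]
    f = r[r["sex"] == "F"][keys + ["age", f"p_{status}"]]
    merged = m.merge(f, on=keys, suffixes=("_m", "_f"))
    if merged.empty:
        return pd.DataFrame(columns=keys + ["age", "status", "diff_pp"])
    merged["age"] = (merged["age_m"] + merged["age_f"]) / 2.0
    merged["status"] = status
    merged["diff_pp"] = 100.0 * (merged[f"p_{status}_m"] - merged[f"p_{status}_f"])
    return merged[keys + ["age", "status", "diff_pp"]].sort_values(keys).reset_index(drop=True)


@dataclass
class SmootherFit:
    """Binomial logit GLM of a smoking status on age and birth year."""

    sex: str
    status: str
    link: str
    intercept: float
    beta_age: float
    beta_birth_year: float
    bse: tuple
    n: int
    deviance: float
    converged: bool
    warning: str = ""

    def predict(self, age, birth_year) -> np.ndarray:
        lin = self.intercept + self.beta_age * np.asarray(age, float) + (
            self.beta_birth_year * np.asarray(birth_year, float)
        )
        return 1.0 / (1.0 + np.exp(-lin))


def fit_smoother(
    records: pd.DataFrame,
    sex: str,
    status: str,
    weight_col: str = "weight",
) -> SmootherFit:
    """Weighted individual-record logit trend for one sex and status.

    Display-only: illustrates the line of best fit through the observed
    points, never replacing them.  Complete separation is flagged on the
    returned fit rather than raised.
    """
    sub = records[records["sex"] == sex]
    if status != "current" and "has_former_question" in sub.columns:
        sub = sub[sub["has_former_question"]]
    if "out_of_scope" in sub.columns:
        sub = sub[~sub["out_of_scope"]]
    if len(sub) < 100:
        raise ValueError(f"need >= 100 records for sex {sex!r}, got {len(sub)}")
    if "birth_year" in sub.columns:
        by = sub["birth_year"].to_numpy(float)
    else:
        by = (sub["survey_year"] - sub["age"]).to_numpy(float)
    y = (sub["smoking_status"] == status).to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), sub["age"].to_numpy(float), by])
    w = sub[weight_col].to_numpy(float)
    w = w * (len(w) / w.sum())  # population-scale weights -> effective frequencies

    warn_msg = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit()
        for c in caught:
            if "separation" in str(c.message).lower() or "converge" in str(c.message).lower():
                warn_msg = str(c.message)
    params = res.params
    return SmootherFit(
        sex=sex,
        status=status,
        link="logit",
        intercept=float(params[0]),
        beta_age=float(params[1]),
        beta_birth_year=float(params[2]),
        bse=tuple(float(b) for b in res.bse),
        n=len(sub),
        deviance=float(res.deviance),
        converged=res.converged if hasattr(res, "converged") else not warn_msg,
        warning=warn_msg,
    )
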