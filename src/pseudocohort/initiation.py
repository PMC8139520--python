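"""Smoking-initiation summaries among eligible ever smokers.

Initiation age is the unweighted self-reported age at which daily or
regular smoking commenced.  Because whole-of-population initiation can
continue up to about age 30, ever smokers interviewed at 30 years or
younger are excluded — otherwise younger cohorts, observed before their
late starters have started, would appear to initiate earlier than they
ultimately do.  Only surveys whose questionnaire asked for initiation
age contribute.  Outputs are the per-(cohort, sex) mean/SD/median table
and the cumulative percentage initiating at or below each age threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (15, 20, 25, 30, 35, 40)
#: ever smokers aged <= this at interview are excluded
MAX_EXCLUDED_AGE = 30

__all__ = [
    "eligible_ever_smokers",
    "summarize_initiation",
    "cumulative_initiation",
    "DEFAULT_THRESHOLDS",
]


def eligible_ever_smokers(records: pd.DataFrame, apply_age_rule: bool = True) -> pd.DataFrame:
    """Subset contributing to initiation analyses.

    Keeps current/former smokers with a reported initiation age from
    surveys carrying the initiation question, interviewed at age >= 31
    (``apply_age_rule=False`` disables that exclusion for sensitivity
    checks).  Initiation ages exceeding the age at interview are
    internally inconsistent and dropped with a logged count.
    """
    df = records
    m = pd.Series(True, index=df.index)
    if "has_initiation_age" in df.columns:
        m &= df["has_initiation_age"].astype(bool)
    m &= df["smoking_status"].isin(["current", "former"])
    m &= df["initiation_age"].notna()
    if apply_age_rule:
        m &= df["age"] > MAX_EXCLUDED_AGE
    inconsistent = m & (df["initiation_age"] > df["age"])
    if inconsistent.any():
        logger.warning("dropping %d records with initiation age after survey age", int(inconsistent.sum()))
        m &= ~inconsistent
    return df[m]


def _groups(subset: pd.DataFrame):
    for col in ("cohort_start", "cohort_width", "sex"):
        if col not in subset.columns:
            raise ValueError(f"column {col!r} required (run assign_cohort first)")
    df = subset
    if "out_of_scope" in df.columns:
        df = df[~df["out_of_scope"]]
    return df.groupby(["cohort_start", "cohort_width", "sex"], sort=True)


def summarize_initiation(subset: pd.DataFrame, weight_col: str | None = None) -> pd.DataFrame:
    """Unweighted mean/SD/median initiation age per (cohort, sex).

    SD is the n-1 sample standard deviation (0 for singleton cells);
    the median of an even-sized sample is the midpoint of the two
    central order statistics.  Passing ``weight_col`` switches to a
    weighted mean/SD as a sensitivity variant.
    """
    rows = []
    for (start, width, sex), g in _groups(subset):
        x = g["initiation_age"].to_numpy(dtype=float)
        n = len(x)
        if weight_col is None:
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        else:
            w = g[weight_col].to_numpy(dtype=float)
            mean = float(np.sum(w * x) / w.sum())
            var = float(np.sum(w * (x - mean) ** 2) / w.sum())
            sd = float(np.sqrt(var))
        rows.append(
            {
                "cohort_start": start,
                "cohort_width": width,
                "sex": sex,
                "n": n,
                "mean": mean,
                "sd": sd,
                "median": float(np.median(x)),
            }
        )
    return pd.DataFrame(rows)


def cumulative_initiation(
    subset: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Percent of ever smokers initiating at or below each threshold.

    Thresholds are inclusive.  A threshold no respondent in the cell
    could have been observed beyond (the cell's maximum interview age is
    below the threshold) is reported as missing rather than a spuriously
    censored 100%.
    """
    thresholds = sorted(int(t) for t in thresholds)
    rows = []
    for (start, width, sex), g in _groups(subset):
        x = g["initiation_age"].to_numpy(dtype=float)
        max_age = float(g["age"].max())
        for t in thresholds:
            pct = 100.0 * float(np.mean(x <= t)) if max_age >= t else np.nan
            rows.append(
                {
                    "cohort_start": start,
                    "cohort_width": width,
                    "sex": sex,
                    "n": len(x),
                    "threshold": t,
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)
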