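"""Parameter-recovery comparison of pipeline estimates against truth.

For each (cohort, sex, survey) trajectory point the matching truth is
the *weighted mixture* of the exact survivor composition over the cell's
contributing record ages — a cell pools up to ten single ages of a
cohort, so comparing at a single representative age would confound
method error with within-cell age structure.  The comparison reports,
per retained proportion, the error in percentage points and whether the
nominal 95% interval (p ± 1.96 SE) covers the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUSES = ("current", "former", "never")

__all__ = ["compare_to_truth"]


def compare_to_truth(
    assigned_records: pd.DataFrame,
    points: pd.DataFrame,
    truth: pd.DataFrame,
    weight_col: str = "weight",
    within_pp: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Merge points with cell-level truth; summarize recovery quality.

    ``truth`` is the exact recursion table (columns ``cohort_start, sex,
    age, p_never, p_current, p_former``); ``assigned_records`` must
    carry cohort assignments and final weights.  Returns the per-cell
    detail and a summary with the share of retained comparisons within
    ``within_pp`` percentage points and the empirical 95% coverage.
    """
    rec = assigned_records
    if "out_of_scope" in rec.columns:
        rec = rec[~rec["out_of_scope"]]
    rec = rec.merge(
        truth[["cohort_start", "sex", "age", "p_never", "p_current", "p_former"]],
        on=["cohort_start", "sex", "age"],
        how="left",
        suffixes=("", "_true"),
    )
    if rec[["p_never", "p_current", "p_former"]].isna().any().any():
        missing = rec[rec["p_current"].isna()][["cohort_start", "sex", "age"]].drop_duplicates()
        raise ValueError(f"truth table missing cells:\n{missing.head()}")

    w = rec[weight_col].to_numpy(float)
    keys = ["cohort_start", "sex", "survey_id"]
    agg = rec.assign(
        _wn=w * rec["p_never"], _wc=w * rec["p_current"], _wf=w * rec["p_former"], _w=w
    ).groupby(keys).agg(
        true_never=("_wn", "sum"),
        true_current=("_wc", "sum"),
        true_former=("_wf", "sum"),
        sw=("_w", "sum"),
    )
    for s in STATUSES:
        agg[f"true_{s}"] = agg[f"true_{s}"] / agg["sw"]
    agg = agg.drop(columns="sw").reset_index()

    detail = points.merge(agg, on=keys, how="left")
    n_within = n_total = n_cover = 0
    rows = []
    for _, r in detail.iterrows():
        for s in STATUSES:
            if not r.get(f"retained_{s}", False) or np.isnan(r[f"p_{s}"]):
                continue
            err = r[f"p_{s}"] - r[f"true_{s}"]
            cover = abs(err) <= 1.96 * r[f"se_{s}"]
            n_total += 1
            n_within += abs(err) * 100.0 <= within_pp
            n_cover += cover
            rows.append(
                {
                    "cohort_start": r["cohort_start"],
                    "sex": r["sex"],
                    "survey_id": r["survey_id"],
                    "status": s,
                    "age": r["age"],
                    "n": r["n"],
                    "p_hat": r[f"p_{s}"],
                    "p_true": r[f"true_{s}"],
                    "err_pp": 100.0 * err,
                    "se": r[f"se_{s}"],
                    "covered": bool(cover),
                }
            )
    detail_long = pd.DataFrame(rows)
    summary = {
        "n_comparisons": int(n_total),
        "pct_within_tolerance": 100.0 * n_within / n_total if n_total else np.nan,
        "tolerance_pp": within_pp,
        "coverage_pct": 100.0 * n_cover / n_total if n_total else np.nan,
        "max_abs_err_pp": float(detail_long["err_pp"].abs().max()) if n_total else np.nan,
        "mean_abs_err_pp": float(detail_long["err_pp"].abs().mean()) if n_total else np.nan,
    }
    return detail_long, summary
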