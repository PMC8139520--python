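"""Post-stratification weighting by iterative proportional fitting (IPF).

Survey base weights are cyclically rescaled, one categorical dimension
at a time (``w <- w * target / current`` for each record's category),
until every weighted margin matches its external population target.
Within any full cross-classification cell the relative weights among
records are preserved from the base weights — the defining property of
raking.  Weights are normalized to population counts, so per-survey
weight totals equal the (covered) population total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MarginSpec", "RakeResult", "rake_weights", "apply_margins_per_survey", "age_band_label"]


@dataclass
class MarginSpec:
    """Target margins for raking.

    ``dimensions`` is an ordered list of ``(column_name, {category: target})``
    pairs.  Every dimension's targets must sum to the common grand total;
    dimensions that disagree by more than 1e-9 relative are rescaled to
    the first dimension's total with a logged warning.
    """

    dimensions: list
    reference_year: int | None = None
    grand_total: float | None = None

    def __post_init__(self):
        if not self.dimensions:
            raise ValueError("at least one dimension required")
        self.dimensions = [(name, dict(targets)) for name, targets in self.dimensions]
        for name, targets in self.dimensions:
            if not targets:
                raise ValueError(f"dimension {name} has no categories")
            if any(v < 0 for v in targets.values()):
                raise ValueError(f"dimension {name} has negative targets")
        totals = [sum(t.values()) for _, t in self.dimensions]
        if self.grand_total is None:
            self.grand_total = totals[0]
        if self.grand_total <= 0:
            raise ValueError("grand_total must be positive")
        for i, ((name, targets), tot) in enumerate(zip(self.dimensions, totals)):
            if abs(tot - self.grand_total) > 1e-9 * self.grand_total:
                logger.warning(
                    "margin dimension %s sums to %.6g, rescaling to grand total %.6g",
                    name, tot, self.grand_total,
                )
                scale = self.grand_total / tot
                self.dimensions[i] = (name, {k: v * scale for k, v in targets.items()})


@dataclass
class RakeResult:
    weights: np.ndarray
    n_iterations: int
    max_margin_dev: float
    converged: bool
    deviation_path: list = field(default_factory=list)


def _margin_dev(w, dim_codes, dim_targets):
    dev = 0.0
    for codes, targets in zip(dim_codes, dim_targets):
        cur = np.bincount(codes, weights=w, minlength=len(targets))
        for j, t in enumerate(targets):
            if t > 0:
                dev = max(dev, abs(cur[j] - t) / t)
            elif cur[j] > 0:
                dev = max(dev, np.inf)
    return dev


def rake_weights(
    records: pd.DataFrame,
    base_weights,
    spec: MarginSpec,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> RakeResult:
    """Rake ``base_weights`` until weighted margins match ``spec``.

    Raises if a record's category is absent from the spec, or if a
    category with a positive target has zero weighted sample mass (it
    can never be matched).  Non-convergence within ``max_iter`` is
    flagged; the last iteration's weights are returned.
    """
    w = np.asarray(base_weights, dtype=float).copy()
    if len(w) != len(records):
        raise ValueError("base_weights length mismatch")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("base weights must be positive and finite")

    dim_codes, dim_targets, dim_cats = [], [], []
    for name, targets in spec.dimensions:
        cats = list(targets)
        lookup = {c: j for j, c in enumerate(cats)}
        vals = records[name]
        unseen = set(vals.unique()) - set(cats)
        if unseen:
            raise ValueError(f"dimension {name}: sample categories not in spec: {sorted(map(str, unseen))}")
        codes = vals.map(lookup).to_numpy(dtype=np.int64)
        t = np.array([targets[c] for c in cats], dtype=float)
        mass = np.bincount(codes, weights=w, minlength=len(cats))
        empty = (t > 0) & (mass <= 0)
        if empty.any():
            bad = [cats[j] for j in np.flatnonzero(empty)]
            raise ValueError(f"dimension {name}: positive target but zero sample mass for {bad}")
        dim_codes.append(codes)
        dim_targets.append(t)
        dim_cats.append(cats)

    path = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for codes, t in zip(dim_codes, dim_targets):
            cur = np.bincount(codes, weights=w, minlength=len(t))
            factor = np.ones_like(t)
            nz = cur > 0
            factor[nz] = t[nz] / cur[nz]
            w *= factor[codes]
        dev = _margin_dev(w, dim_codes, dim_targets)
        path.append(dev)
        if dev < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"raking did not converge in {max_iter} iterations (dev={path[-1]:.3g})")
    return RakeResult(
        weights=w,
        n_iterations=n_iter,
        max_margin_dev=path[-1],
        converged=converged,
        deviation_path=path,
    )


def age_band_label(age, width: int = 5) -> pd.Series:
    """Map single ages to '<lo>-<hi>' band labels (bands aligned to 0)."""
    age = pd.Series(age)
    lo = (age // width * width).astype(int)
    return lo.astype(str) + "-" + (lo + width - 1).astype(str)


def apply_margins_per_survey(
    pooled: pd.DataFrame,
    margins: pd.DataFrame,
    band_width: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    nearest_year_fallback: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach a final analysis weight to every record, survey by survey.

    ``margins`` has columns ``year, sex, age_lo, age_hi, population_count``
    (bands of ``band_width`` years).  Each survey is raked — starting
    from its supplied base weights — to the sex and age-band margins of
    its survey year (nearest available year as a logged fallback),
    restricted to the bands its sample actually covers so that partial
    age coverage does not demand impossible margins.  Returns the pooled
    table with a ``weight`` column plus a per-survey diagnostics table.

    Requires single ages (run PCLM assignment first for grouped surveys).
    """
    if pooled["age"].isna().any():
        raise ValueError("all records need a single age before raking")
    margin_years = np.sort(margins["year"].unique())
    out_frames, diags = [], []
    for sid, sub in pooled.groupby("survey_id", sort=True):
        sub = sub.copy()
        year = int(sub["survey_year"].iloc[0])
        if year in margin_years:
            use_year = year
        elif nearest_year_fallback:
            use_year = int(margin_years[np.argmin(np.abs(margin_years - year))])
            logger.warning("survey %s: no margins for %d, using nearest year %d", sid, year, use_year)
        else:
            raise ValueError(f"survey {sid}: no margin table for year {year}")
        m = margins[margins["year"] == use_year].copy()
        m["age_band"] = m["age_lo"].astype(int).astype(str) + "-" + m["age_hi"].astype(int).astype(str)

        sub["age_band"] = age_band_label(sub["age"].to_numpy(), band_width).to_numpy()
        observed = set(sub["age_band"])
        missing = observed - set(m["age_band"])
        if missing:
            raise ValueError(f"survey {sid}: no population margins for bands {sorted(missing)}")
        m_obs = m[m["age_band"].isin(observed)]
        band_targets = m_obs.groupby("age_band")["population_count"].sum().to_dict()
        sex_targets = m_obs.groupby("sex")["population_count"].sum().to_dict()
        sex_targets = {s: t for s, t in sex_targets.items() if s in set(sub["sex"])}
        spec = MarginSpec(
            [("age_band", band_targets), ("sex", sex_targets)], reference_year=use_year
        )
        res = rake_weights(sub, sub["base_weight"].to_numpy(), spec, tol=tol, max_iter=max_iter)
        sub["weight"] = res.weights
        out_frames.append(sub.drop(columns=["age_band"]))
        diags.append(
            {
                "survey_id": sid,
                "margin_year": use_year,
                "n": len(sub),
                "n_iterations": res.n_iterations,
                "max_margin_dev": res.max_margin_dev,
                "converged": res.converged,
                "min_weight": float(res.weights.min()),
                "max_weight": float(res.weights.max()),
                "sum_weight": float(res.weights.sum()),
                "grand_total": spec.grand_total,
            }
        )
    return pd.concat(out_frames, ignore_index=True), pd.DataFrame(diags)
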