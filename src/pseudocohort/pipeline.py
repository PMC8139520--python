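"""End-to-end pipeline: generate or ingest a study, then reconstruct cohorts.

Orchestrates the full reconstruction from a single config: synthetic
study generation (or ingestion of CSV surveys + YAML status mappings),
harmonization with an exclusion report, PCLM single-age assignment for
grouped surveys, post-stratification raking to population margins,
cohort trajectory estimation with reporting filters at both 10- and
5-year widths, men-minus-women difference curves, the GLM display
trend, and the initiation tables.  All randomness flows through named
seeds spawned from the config, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohorts as cohorts_mod
from . import harmonize as harmonize_mod
from . import initiation as initiation_mod
from . import pclm as pclm_mod
from . import rake as rake_mod
from . import recovery as recovery_mod
from . import scenarios as scenarios_mod
from .simulate import (
    AGE_MAX,
    SurveyDesign,
    draw_survey,
    prevalence_schedule,
    simulate_population,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

__all__ = ["PipelineConfig", "run_pipeline", "generate_synthetic_study"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode="synthetic"`` generates the study from ``scenario`` (the
    default 33-survey scenario when None); ``mode="ingest"`` reads an
    existing study directory (survey CSVs, mapping YAMLs, margins CSV).
    """

    out_dir: str
    mode: str = "synthetic"
    study_dir: str | None = None
    scenario: object = None
    cohort_widths: tuple = (10, 5)
    seed_simulation: int = 20260920
    seed_pclm_assignment: int = 716
    min_n: int = 100
    max_rse: float = 0.25
    initiation_thresholds: tuple = initiation_mod.DEFAULT_THRESHOLDS
    glm: bool = True
    robustness_repeats: int = 0
    pclm_lambda_grid: object = None
    pclm_penalty_order: int = 2
    rake_tol: float = 1e-8
    rake_max_iter: int = 1000

    def __post_init__(self):
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError("mode must be 'synthetic' or 'ingest'")
        if self.min_n < 0 or self.max_rse <= 0:
            raise ValueError("thresholds must be positive")
        widths = tuple(self.cohort_widths)
        if not widths or set(widths) - {5, 10}:
            raise ValueError("cohort_widths must be a subset of {5, 10}")
        self.cohort_widths = widths
        if self.mode == "ingest" and self.study_dir is None:
            raise ValueError("ingest mode requires study_dir")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def manifest_dict(self) -> dict:
        # filesystem locations are not part of the scientific configuration
        d = {k: v for k, v in asdict(self).items() if k not in ("scenario", "out_dir", "study_dir")}
        d["scenario"] = getattr(self.scenario, "description", None) if self.scenario else "default"
        return d


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def generate_synthetic_study(scenario, out_dir, seed) -> dict:
    """Write a complete synthetic multi-survey study to ``out_dir``.

    Produces one CSV per survey, a YAML status mapping per survey, the
    population margins table (sex x 5-year age band x survey year,
    counted from the living simulated population), and the ground-truth
    survivor-composition table from the exact recursion.  Returns the
    paths plus in-memory objects for immediate pipeline use.
    """
    out = Path(out_dir)
    (out / "surveys").mkdir(parents=True, exist_ok=True)
    (out / "mappings").mkdir(exist_ok=True)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_ss, survey_ss = ss.spawn(2)
    population = simulate_population(scenario.processes, scenario.n_per_cohort_year, pop_ss)

    children = survey_ss.spawn(len(scenario.surveys))
    survey_paths, mapping_paths = [], []
    n_drawn = 0
    for design, child in zip(scenario.surveys, children):
        table = draw_survey(population, design, child)
        n_drawn += len(table)
        spath = out / "surveys" / f"{design.survey_id}.csv"
        _write_csv(table, spath)
        survey_paths.append(spath)
        mapping = _mapping_for_design(design)
        mpath = out / "mappings" / f"{design.survey_id}.yaml"
        with open(mpath, "w") as fh:
            yaml.safe_dump(mapping, fh, sort_keys=False)
        mapping_paths.append(mpath)

    years = sorted({s.survey_year for s in scenario.surveys})
    margins = _population_margins(population, years)
    _write_csv(margins, out / "margins.csv")

    truth = pd.concat(
        [prevalence_schedule(p, range(12, AGE_MAX + 1)) for p in scenario.processes],
        ignore_index=True,
    )
    _write_csv(truth, out / "truth.csv")
    logger.info("synthetic study: %d surveys, %d drawn respondents", len(scenario.surveys), n_drawn)
    return {
        "dir": out,
        "surveys": survey_paths,
        "mappings": mapping_paths,
        "margins": out / "margins.csv",
        "truth": out / "truth.csv",
        "population": population,
        "n_drawn": n_drawn,
    }


def _mapping_for_design(design: SurveyDesign) -> dict:
    if design.has_former_question:
        vocab = design.status_codes or {"current": "current", "former": "former", "never": "never"}
        code_map = {}
        for canonical, code in vocab.items():
            code_map[code] = canonical
    else:
        vocab = design.status_codes or {"current": "smoker", "former": "non-smoker", "never": "non-smoker"}
        code_map = {vocab["current"]: "current", vocab["never"]: "noncurrent"}
    return {
        "survey_id": design.survey_id,
        "survey_year": design.survey_year,
        "has_former_question": design.has_former_question,
        "has_initiation_age": design.has_initiation_age,
        "code_map": code_map,
    }


def _population_margins(population: pd.DataFrame, years, band_width: int = 5) -> pd.DataFrame:
    rows = []
    by = population["birth_year"].to_numpy()
    death = population["death_age"].to_numpy()
    sex = population["sex"].to_numpy()
    for year in years:
        age = year - by
        alive = (age >= 0) & (age < death)
        for s in ("M", "F"):
            m = alive & (sex == s)
            ages = age[m]
            for lo in range(10, AGE_MAX + 1, band_width):
                hi = lo + band_width - 1
                count = int(np.sum((ages >= lo) & (ages <= hi)))
                rows.append({"year": year, "sex": s, "age_lo": lo, "age_hi": hi,
                             "population_count": count})
    return pd.DataFrame(rows)


class _MappingMeta:
    def __init__(self, doc):
        self.survey_id = doc["survey_id"]
        self.survey_year = doc["survey_year"]
        self.has_former_question = doc.get("has_former_question", True)
        self.has_initiation_age = doc.get("has_initiation_age", False)


def _load_study(study_dir: Path) -> tuple[list, pd.DataFrame]:
    """Read survey CSVs + mapping YAMLs; returns [(raw, mapping, meta)], margins."""
    sdir = study_dir / "surveys"
    mdir = study_dir / "mappings"
    if not sdir.is_dir():
        raise FileNotFoundError(f"no surveys directory under {study_dir}")
    entries = []
    for spath in sorted(sdir.glob("*.csv")):
        mpath = mdir / (spath.stem + ".yaml")
        if not mpath.exists():
            raise FileNotFoundError(f"missing status mapping for survey {spath.stem}")
        with open(mpath) as fh:
            doc = yaml.safe_load(fh)
        raw = pd.read_csv(spath)
        mapping = harmonize_mod.StatusMapping(doc["survey_id"], doc["code_map"])
        entries.append((raw, mapping, _MappingMeta(doc)))
    margins = pd.read_csv(study_dir / "margins.csv")
    return entries, margins


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole reconstruction; returns the output directory.

    Deterministic given the config's seeds.  Any stage error propagates
    tagged with the stage and survey id.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: study ------------------------------------------------------
    if config.mode == "synthetic":
        scenario = config.scenario or scenarios_mod.default_scenario()
        study_dir = Path(config.study_dir) if config.study_dir else out / "study"
        study = generate_synthetic_study(scenario, study_dir, config.seed_simulation)
    else:
        study_dir = Path(config.study_dir)
        study = None
    entries, margins = _load_study(study_dir)

    # --- stage: harmonize --------------------------------------------------
    frames, reports = [], []
    for raw, mapping, meta in entries:
        try:
            hframe, report = harmonize_mod.harmonize_table(raw, mapping, meta)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage context
            raise RuntimeError(f"stage harmonize, survey {meta.survey_id}: {exc}") from exc
        frames.append(hframe)
        reports.append(report)
    pooled = harmonize_mod.pool(frames)
    report = harmonize_mod.combine_reports(reports)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    # --- stage: pclm -------------------------------------------------------
    grouped_mask = pooled["age"].isna()
    fits: dict = {}
    diag_rows = []
    for (sid, sex), g in pooled[grouped_mask].groupby(["survey_id", "sex"], sort=True):
        try:
            gc = pclm_mod.grouped_counts_from_records(g)
            fit = pclm_mod.select_lambda(
                gc,
                lambda_grid=config.pclm_lambda_grid,
                penalty_order=config.pclm_penalty_order,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage pclm, survey {sid}/{sex}: {exc}") from exc
        fits[(sid, sex)] = fit
        diag_rows.append(
            {
                "survey_id": sid,
                "sex": sex,
                "lambda": fit.lam,
                "aic": fit.aic,
                "effective_dim": fit.effective_dim,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "total_rel_err": fit.total_rel_err,
            }
        )
    if fits:
        pooled = pclm_mod.assign_with_fits(
            pooled, fits, np.random.SeedSequence(config.seed_pclm_assignment)
        )
    _write_csv(pd.DataFrame(diag_rows), out / "pclm_diagnostics.csv")
    _write_csv(pooled, out / "harmonized.csv")

    # --- stage: rake -------------------------------------------------------
    try:
        weighted, rake_diag = rake_mod.apply_margins_per_survey(
            pooled, margins, tol=config.rake_tol, max_iter=config.rake_max_iter
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage rake: {exc}") from exc
    _write_csv(rake_diag, out / "rake_diagnostics.csv")

    # --- stage: cohorts ----------------------------------------------------
    assigned_by_width = {}
    for width in config.cohort_widths:
        assigned = cohorts_mod.assign_cohort(weighted, width)
        assigned_by_width[width] = assigned
        points = cohorts_mod.estimate_points(
            assigned, min_n=config.min_n, max_rse=config.max_rse
        )
        _write_csv(points, out / f"trajectories_w{width}.csv")
        diffs = pd.concat(
            [cohorts_mod.sex_difference(points, s) for s in cohorts_mod.STATUSES],
            ignore_index=True,
        )
        _write_csv(diffs, out / f"differences_w{width}.csv")

        subset = initiation_mod.eligible_ever_smokers(assigned)
        _write_csv(initiation_mod.summarize_initiation(subset), out / f"initiation_summary_w{width}.csv")
        _write_csv(
            initiation_mod.cumulative_initiation(subset, config.initiation_thresholds),
            out / f"cumulative_initiation_w{width}.csv",
        )

    if config.glm:
        width0 = config.cohort_widths[0]
        rows = []
        for sex in ("M", "F"):
            for status in cohorts_mod.STATUSES:
                f = cohorts_mod.fit_smoother(assigned_by_width[width0], sex, status)
                rows.append(
                    {
                        "sex": sex,
                        "status": status,
                        "intercept": f.intercept,
                        "beta_age": f.beta_age,
                        "beta_birth_year": f.beta_birth_year,
                        "n": f.n,
                        "deviance": f.deviance,
                        "warning": f.warning,
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "smoother.csv")

    # --- stage: robustness -------------------------------------------------
    if config.robustness_repeats >= 2 and fits:
        spread = pclm_mod.robustness_check(
            weighted, fits, config.robustness_repeats, config.seed_pclm_assignment + 1
        )
        _write_csv(spread, out / "assignment_robustness.csv")

    # --- stage: recovery (synthetic mode only) -----------------------------
    if 10 in config.cohort_widths and (study_dir / "truth.csv").exists():
        truth = pd.read_csv(study_dir / "truth.csv")
        points10 = pd.read_csv(out / "trajectories_w10.csv")
        detail, summary = recovery_mod.compare_to_truth(
            cohorts_mod.assign_cohort(weighted, 10), points10, truth
        )
        _write_csv(detail, out / "recovery.csv")
        with open(out / "recovery_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "config": config.manifest_dict(),
        "n_pooled": int(len(pooled)),
        "exclusions": report.to_dict(),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
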