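import numpy as np
import pandas as pd
import pytest

from pseudocohort.cohorts import (
    assign_cohort,
    estimate_points,
    filter_points,
    fit_smoother,
    sex_difference,
)


class TestAssignCohort:
    def _rec(self, year, age):
        return pd.DataFrame(
            {"survey_id": "S", "survey_year": [year], "sex": "M", "age": [float(age)],
             "smoking_status": "current", "base_weight": 1.0}
        )

    @pytest.mark.parametrize(
        "year,age,start,oos",
        [
            (2000, 40, 1960, False),
            (1962, 52, 1910, False),  # inclusive lower cohort bound
            (2018, 12, 2000, True),   # born 2006, after the 1989 cutoff
            (1962, 53, 1900, True),   # born 1909, before 1910
        ],
    )
    def test_boundaries(self, year, age, start, oos):
        out = assign_cohort(self._rec(year, age), width=10)
        assert out.loc[0, "birth_year"] == year - age
        assert out.loc[0, "cohort_start"] == start
        assert bool(out.loc[0, "out_of_scope"]) is oos

    def test_five_year_widths(self):
        out = assign_cohort(self._rec(2000, 42), width=5)
        assert out.loc[0, "cohort_start"] == 1955

    def test_missing_age_rejected(self):
        rec = self._rec(2000, 40)
        rec.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="single age"):
            assign_cohort(rec)


def _points_from(cell):
    return estimate_points(assign_cohort(cell, 10), min_n=0, max_rse=np.inf)


class TestEstimatePoints:
    def test_six_record_cell_hand_computed(self, six_record_cell):
        pts = _points_from(six_record_cell)
        assert len(pts) == 1
        p = pts.iloc[0]
        assert p["p_current"] == pytest.approx(1 / 3, abs=1e-12)
        assert p["p_former"] == pytest.approx(1 / 6, abs=1e-12)
        assert p["p_never"] == pytest.approx(1 / 2, abs=1e-12)
        assert p["n_eff"] == pytest.approx(6.0, abs=1e-12)
        assert p["se_current"] == pytest.approx(np.sqrt((1 / 3) * (2 / 3) / 6), abs=1e-12)
        assert p["rse_current"] == pytest.approx(np.sqrt((1 / 3) * (2 / 3) / 6) / (1 / 3), abs=1e-12)

    def test_unequal_weights_hand_computed(self, six_record_cell):
        cell = six_record_cell.copy()
        cell["weight"] = [2.0, 2.0, 1.0, 1.0, 1.0, 1.0]
        p = _points_from(cell).iloc[0]
        assert p["p_current"] == pytest.approx(0.5, abs=1e-12)
        assert p["n_eff"] == pytest.approx(64 / 12, abs=1e-12)

    def test_equal_weights_match_unweighted(self, six_record_cell):
        cell = six_record_cell.copy()
        cell["weight"] = 7.3
        p = _points_from(cell).iloc[0]
        assert p["p_current"] == pytest.approx((cell["smoking_status"] == "current").mean())

    def test_decomposition_and_zero_proportion_rse(self, six_record_cell):
        cell = six_record_cell.copy()
        cell["smoking_status"] = ["current", "current", "never", "never", "never", "never"]
        p = _points_from(cell).iloc[0]
        assert p["p_current"] + p["p_former"] == pytest.approx(1 - p["p_never"], abs=1e-9)
        assert np.isinf(p["rse_former"])

    def test_former_suppressed_without_questionnaire_support(self, six_record_cell):
        cell = six_record_cell.copy()
        cell["has_former_question"] = False
        cell["smoking_status"] = ["current", "current", "noncurrent", "noncurrent", "noncurrent", "noncurrent"]
        p = _points_from(cell).iloc[0]
        assert p["p_current"] == pytest.approx(1 / 3)
        assert np.isnan(p["p_former"]) and np.isnan(p["p_never"])

    def test_representative_age_is_weighted_mean(self, six_record_cell):
        cell = six_record_cell.copy()
        cell["weight"] = [3.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        p = _points_from(cell).iloc[0]
        assert p["age"] == pytest.approx(np.average(cell["age"], weights=cell["weight"]))


class TestFilterPoints:
    def _pts(self, n, rse):
        return pd.DataFrame(
            {
                "n": [n], "p_current": [0.4], "rse_current": [rse],
                "p_former": [0.2], "rse_former": [rse],
                "p_never": [0.4], "rse_never": [rse],
            }
        )

    @pytest.mark.parametrize(
        "n,rse,kept",
        [
            (99, 0.01, False),   # below the at-least-100 floor
            (100, 0.25, False),  # RSE bound is strict
            (100, 0.249, True),
            (100, 0.251, False),
            (1000, 0.01, True),
        ],
    )
    def test_boundaries(self, n, rse, kept):
        out = filter_points(self._pts(n, rse))
        assert bool(out.loc[0, "retained_current"]) is kept

    def test_monotone_in_thresholds(self):
        pts = pd.concat([self._pts(n, r) for n in (50, 100, 500) for r in (0.1, 0.3)],
                        ignore_index=True)
        base = filter_points(pts, min_n=100, max_rse=0.25)["retained_current"]
        no_rse = filter_points(pts, min_n=100, max_rse=np.inf)["retained_current"]
        low_n = filter_points(pts, min_n=50, max_rse=0.25)["retained_current"]
        assert (base <= no_rse).all()  # enabling the RSE filter never adds points
        assert (base <= low_n).all()   # lowering the n threshold never removes


class TestSexDifference:
    def _points(self, p_m, p_f):
        rows = []
        for sex, p in (("M", p_m), ("F", p_f)):
            rows.append(
                {"cohort_start": 1950, "cohort_width": 10, "sex": sex, "survey_id": "S",
                 "age": 40.0 if sex == "M" else 42.0, "n": 500,
                 "p_current": p, "se_current": 0.01, "rse_current": 0.03,
                 "retained_current": True}
            )
        return pd.DataFrame(rows)

    def test_identical_points_give_zero(self):
        d = sex_difference(self._points(0.4, 0.4))
        assert d["diff_pp"].iloc[0] == pytest.approx(0.0)

    def test_twenty_point_gap(self):
        d = sex_difference(self._points(0.50, 0.30))
        assert d["diff_pp"].iloc[0] == pytest.approx(20.0)
        assert d["age"].iloc[0] == pytest.approx(41.0)

    def test_antisymmetry(self):
        pts = self._points(0.50, 0.30)
        swapped = pts.copy()
        swapped["sex"] = swapped["sex"].map({"M": "F", "F": "M"})
        d = sex_difference(pts)
        d_swapped = sex_difference(swapped)
        assert d_swapped["diff_pp"].iloc[0] == pytest.approx(-d["diff_pp"].iloc[0])

    def test_unmatched_cohort_gives_empty_curve(self):
        pts = self._points(0.5, 0.3)
        pts.loc[pts["sex"] == "F", "survey_id"] = "OTHER"
        assert sex_difference(pts).empty


class TestSmoother:
    @staticmethod
    def _simulated(beta_age=-0.05, beta_by=-0.02, n=200_000, seed=19):
        rng = np.random.default_rng(seed)
        age = rng.uniform(15, 80, n)
        by = rng.uniform(1910, 1989, n)
        lin = 40.0 + beta_age * age + beta_by * by
        p = 1 / (1 + np.exp(-lin))
        y = rng.random(n) < p
        return pd.DataFrame(
            {
                "survey_id": "S", "survey_year": (by + age).round(),
                "sex": "M", "age": age, "birth_year": by,
                "smoking_status": np.where(y, "current", "never"),
                "weight": 1.0, "has_former_question": True,
            }
        )

    def test_recovers_generating_slopes(self):
        df = self._simulated()
        fit = fit_smoother(df, "M", "current")
        assert abs(fit.beta_age - (-0.05)) < 3 * fit.bse[1]
        assert abs(fit.beta_birth_year - (-0.02)) < 3 * fit.bse[2]

    def test_constant_probability_gives_null_slopes(self):
        rng = np.random.default_rng(7)
        df = self._simulated(beta_age=0.0, beta_by=0.0, n=50_000, seed=8)
        # rebuild outcome at constant p = 0.3
        df["smoking_status"] = np.where(rng.random(len(df)) < 0.3, "current", "never")
        fit = fit_smoother(df, "M", "current")
        assert abs(fit.beta_age) < 3 * fit.bse[1]
        assert abs(fit.beta_birth_year) < 3 * fit.bse[2]

    def test_fitted_probabilities_in_unit_interval(self):
        fit = fit_smoother(self._simulated(n=20_000), "M", "current")
        probs = fit.predict(np.linspace(15, 80, 50), np.linspace(1910, 1989, 50))
        assert ((probs > 0) & (probs < 1)).all()

    def test_too_few_records_rejected(self):
        df = self._simulated(n=50)
        with pytest.raises(ValueError, match="100"):
            fit_smoother(df, "M", "current")


class TestWidthConsistency:
    def test_five_year_points_aggregate_to_ten_year(self):
        rng = np.random.default_rng(3)
        n = 4000
        rec = pd.DataFrame(
            {
                "survey_id": "S", "survey_year": 2000, "sex": "M",
                "age": rng.integers(30, 50, n).astype(float),
                "smoking_status": rng.choice(["current", "former", "never"], n),
                "weight": rng.uniform(0.5, 3.0, n),
                "base_weight": 1.0,
                "has_former_question": True,
            }
        )
        p10 = estimate_points(assign_cohort(rec, 10), min_n=0, max_rse=np.inf)
        p5 = estimate_points(assign_cohort(rec, 5), min_n=0, max_rse=np.inf)
        for _, row in p10.iterrows():
            halves = p5[(p5["cohort_start"] // 10 * 10) == row["cohort_start"]]
            assert halves["n"].sum() == row["n"]
            for s in ("current", "former", "never"):
                combo = np.average(halves[f"p_{s}"], weights=halves["sum_w"])
                assert combo == pytest.approx(row[f"p_{s}"], abs=1e-9)
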