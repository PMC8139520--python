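import numpy as np
import pandas as pd
import pytest

from pseudocohort.simulate import (
    CohortProcess,
    LifeCourse,
    SurveyDesign,
    draw_survey,
    simulate_population,
    smoking_status_at,
    statuses_at,
    true_cohort_prevalence,
)


def geometric_ever(h: float, n_years: int) -> float:
    """Independent closed-form / brute-force probability of ever smoking."""
    p_never = 1.0
    for _ in range(n_years):  # enumeration of the survival chain
        p_never *= 1.0 - h
    return 1.0 - p_never


class TestSimulatePopulation:
    def test_null_hazard_population_never_smokes(self):
        proc = CohortProcess(birth_years=(1950, 1954), sex="F")
        pop = simulate_population([proc], 200, seed=3)
        assert pop["initiation_age"].isna().all()
        assert pop["cessation_age"].isna().all()

    def test_geometric_initiation_matches_closed_form(self, geometric_process):
        expected = geometric_ever(0.1, 10)
        assert expected == pytest.approx(1 - 0.9**10)
        n = 100_000
        pop = simulate_population([geometric_process], n, seed=11)
        emp = pop["initiation_age"].notna().mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(emp - expected) < 3 * se
        # the exact recursion reproduces the closed form (everyone survives)
        p_never, p_current, p_former = true_cohort_prevalence(geometric_process, 30)
        assert p_current == pytest.approx(expected, abs=1e-12)
        assert p_former == 0.0

    def test_identical_seed_identical_population(self, geometric_process):
        a = simulate_population([geometric_process], 500, seed=7)
        b = simulate_population([geometric_process], 500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_degenerate_inputs(self, geometric_process):
        with pytest.raises(ValueError):
            simulate_population([], 10, seed=0)
        with pytest.raises(ValueError):
            simulate_population([geometric_process], 0, seed=0)
        with pytest.raises(ValueError):
            simulate_population([geometric_process, geometric_process], 10, seed=0)

    def test_differential_mortality_depletes_ever_smokers(self):
        proc = CohortProcess(
            birth_years=(1910, 1910),
            sex="M",
            initiation_hazard=[(15, 24, 0.08)],
            baseline_mortality=[(0, 99, 0.01)],
            hr_current=2.0,
            hr_former=1.3,
        )
        pop = simulate_population([proc], 150_000, seed=5)
        ever_all = pop["initiation_age"].notna()
        survivors = pop["death_age"] > 80
        frac_survivors = ever_all[survivors].mean()
        frac_all = ever_all.mean()
        assert frac_survivors < frac_all


class TestStatusAt:
    lc = LifeCourse(birth_year=1940, sex="M", initiation_age=18, cessation_age=30, death_age=70)

    @pytest.mark.parametrize(
        "offset,expected",
        [(17, "never"), (18, "current"), (25, "current"), (30, "former"), (69, "former"), (70, "dead")],
    )
    def test_boundary_conventions(self, offset, expected):
        assert smoking_status_at(self.lc, 1940 + offset) == expected

    def test_year_before_birth_rejected(self):
        with pytest.raises(ValueError):
            smoking_status_at(self.lc, 1939)

    def test_vectorized_agrees_with_scalar(self):
        pop = pd.DataFrame(
            {
                "birth_year": [1940, 1940, 1940],
                "sex": "M",
                "initiation_age": [18.0, np.nan, 20.0],
                "cessation_age": [30.0, np.nan, np.nan],
                "death_age": [70, 50, 90],
            }
        )
        got = statuses_at(pop, 1940 + 35)
        expected = [
            smoking_status_at(
                LifeCourse(
                    1940, "M",
                    None if np.isnan(r.initiation_age) else int(r.initiation_age),
                    None if np.isnan(r.cessation_age) else int(r.cessation_age),
                    int(r.death_age),
                ),
                1975,
            )
            for r in pop.itertuples()
        ]
        assert list(got) == expected


class TestTrueCohortPrevalence:
    def test_all_zero_hazards_everyone_never(self):
        proc = CohortProcess(birth_years=(1950, 1959), sex="M")
        for age in (0, 20, 60, 99):
            assert true_cohort_prevalence(proc, age) == (1.0, 0.0, 0.0)

    def test_probabilities_sum_to_one(self):
        proc = CohortProcess(
            birth_years=(1920, 1929),
            sex="F",
            initiation_hazard=[(12, 30, 0.05)],
            cessation_hazard=[(20, 99, 0.03)],
            baseline_mortality=[(0, 99, 0.01)],
            hr_current=2.0,
            hr_former=1.3,
        )
        for age in range(100):
            assert sum(true_cohort_prevalence(proc, age)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [1_000, 10_000, 100_000])
    def test_monte_carlo_converges_to_recursion(self, n):
        proc = CohortProcess(
            birth_years=(1930, 1930),
            sex="M",
            initiation_hazard=[(14, 28, 0.06)],
            cessation_hazard=[(25, 99, 0.02)],
            baseline_mortality=[(0, 99, 0.008)],
            hr_current=2.0,
            hr_former=1.2,
        )
        pop = simulate_population([proc], n, seed=n)
        for age in (20, 40, 60):
            status = statuses_at(pop, 1930 + age)
            alive = status != "dead"
            n_alive = alive.sum()
            p_never, p_current, p_former = true_cohort_prevalence(proc, age)
            for label, p in (("never", p_never), ("current", p_current), ("former", p_former)):
                emp = (status[alive] == label).mean()
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_alive)
                assert abs(emp - p) < max(3 * se, 5e-4), (age, label, n)

    def test_survivor_initiation_age_bias_is_upward(self):
        proc = CohortProcess(
            birth_years=(1910, 1910),
            sex="M",
            initiation_hazard=[(12, 30, 0.07)],
            baseline_mortality=[(40, 99, 0.03)],
            hr_current=2.5,
            hr_former=1.5,
        )
        pop = simulate_population([proc], 200_000, seed=17)
        ever = pop["initiation_age"].notna()
        mean_all = pop.loc[ever, "initiation_age"].mean()
        survivors = ever & (pop["death_age"] > 70)
        mean_surv = pop.loc[survivors, "initiation_age"].mean()
        assert mean_surv >= mean_all


class TestDrawSurvey:
    def _population(self, seed=23, n=4000):
        proc = CohortProcess(
            birth_years=(1940, 1959),
            sex="M",
            initiation_hazard=[(14, 28, 0.05)],
            cessation_hazard=[(25, 99, 0.03)],
        )
        return simulate_population([proc], n // 20, seed=seed)

    def test_passthrough_reporting_matches_true_status(self):
        pop = self._population()
        design = SurveyDesign("S", 1995, sample_size=500, age_range=(12, 99))
        table = draw_survey(pop, design, seed=1)
        # recant_prob 0, exact ages, full response: codes are the truth
        ages = 1995 - pop["birth_year"]
        by_status = pd.Series(statuses_at(pop, 1995)).groupby(
            pd.Series(np.where(ages < 12, "under", "ok"))
        )
        counts = table["status_code"].value_counts()
        assert set(counts.index) <= {"current", "former", "never"}
        # cross-check the drawn joint (age, status) cells against the truth
        truth = pd.DataFrame({"age": ages, "status": statuses_at(pop, 1995)})
        truth = truth[(truth["status"] != "dead") & (truth["age"] >= 12)]
        for age, grp in table.groupby("age"):
            possible = set(truth.loc[truth["age"] == age, "status"])
            assert set(grp["status_code"]) <= possible

    def test_recanting_extremes(self):
        proc = CohortProcess(
            birth_years=(1930, 1939), sex="F",
            initiation_hazard=[(15, 24, 0.08)],
            cessation_hazard=[(25, 99, 0.05)],
            recant_prob=1.0,
        )
        pop = simulate_population([proc], 300, seed=2)
        design = SurveyDesign("R", 1980, sample_size=1500, age_range=(12, 99))
        table = draw_survey(pop, design, seed=3)
        assert (table["status_code"] == "former").sum() == 0

    def test_recanting_inflates_never_by_expected_amount(self):
        recant = 0.3
        proc = CohortProcess(
            birth_years=(1935, 1935), sex="M",
            initiation_hazard=[(15, 24, 0.08)],
            cessation_hazard=[(25, 99, 0.05)],
            recant_prob=recant,
        )
        pop = simulate_population([proc], 60_000, seed=4)
        year = 1985  # age 50
        p_never, p_current, p_former = true_cohort_prevalence(proc, 50)
        design = SurveyDesign("R", year, sample_size=30_000, age_range=(12, 99))
        table = draw_survey(pop, design, seed=5)
        expected = p_never + recant * p_former
        emp = (table["status_code"] == "never").mean()
        se = np.sqrt(expected * (1 - expected) / len(table))
        assert abs(emp - expected) < 4 * se

    def test_grouped_reporting_bins_contain_true_age(self):
        # two single-age cohorts: every drawn row's bin is determined by truth
        procs = [
            CohortProcess(birth_years=(1978, 1978), sex="M"),
            CohortProcess(birth_years=(1973, 1973), sex="F"),
        ]
        pop = simulate_population(procs, 100, seed=6)  # ages 22 and 27 in 2000
        design = SurveyDesign(
            "G", 2000, sample_size=200, age_range=(20, 29),
            age_reporting=[(20, 24), (25, 29)],
        )
        table = draw_survey(pop, design, seed=7)
        men = table[table["sex"] == "M"]  # true age 22
        women = table[table["sex"] == "F"]  # true age 27
        assert ((men["age_group_lo"] == 20) & (men["age_group_hi"] == 24)).all()
        assert ((women["age_group_lo"] == 25) & (women["age_group_hi"] == 29)).all()
        assert table["age"].isna().all()

    def test_sample_size_truncates_with_warning(self):
        pop = self._population(n=400)
        design = SurveyDesign("T", 1995, sample_size=10_000, age_range=(12, 99))
        with pytest.warns(UserWarning, match="exceeds"):
            table = draw_survey(pop, design, seed=8)
        assert len(table) <= 400

    def test_no_former_question_collapses_codes(self):
        pop = self._population()
        design = SurveyDesign(
            "A", 1995, sample_size=300, age_range=(12, 99), has_former_question=False
        )
        table = draw_survey(pop, design, seed=9)
        assert set(table["status_code"].dropna()) <= {"smoker", "non-smoker"}
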