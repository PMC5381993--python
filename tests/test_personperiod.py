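"""Person-period expansion, design matrices and the spline basis."""

import numpy as np
import pandas as pd
import pytest

from gfcohort.exposure import ExposureCoefficients, LagSpec, lagged_window_sums
from gfcohort.personperiod import DesignInfo, expand_to_person_periods, worker_outcomes
from gfcohort.splines import default_knots, rcs_basis

KNOTS = (30.0, 45.0, 57.5, 70.0, 82.0)


def _tiny_tables():
    baseline = pd.DataFrame(
        {
            "worker_id": [1, 2],
            "entry_age": [30, 40],
            "entry_year": [1950, 1945],
            "birth_year": [1920, 1905],
            "us_born": [1, 0],
            "pre_entry_years_worked": [1.0, 5.0],
            "pre_entry_exposure_mgm3yr": [0.29, 1.45],
        }
    )
    rows = []
    # worker 1: enters at 30, dies of heart disease at 33 -> 4 rows
    for age, cat, cause in [
        (30, "light", "none"),
        (31, "medium", "none"),
        (32, "none", "none"),
        (33, "none", "heart"),
    ]:
        rows.append((1, age, 1920 + age, int(cat != "none"), cat, cause))
    # worker 2: alive through administrative end at 45
    for age in range(40, 46):
        rows.append((2, age, 1905 + age, 1, "heavy", "none"))
    history = pd.DataFrame(
        rows,
        columns=["worker_id", "age", "calendar_year", "employed", "exposure_category", "death_cause"],
    )
    return baseline, history


class TestRcsBasis:
    def test_matches_textbook_formula_at_a_point(self):
        # Harrell restricted cubic spline evaluated by hand at x = 50
        t = np.array([30.0, 45.0, 57.5, 70.0, 82.0])
        x = 50.0
        norm = (82.0 - 30.0) ** 2
        plus = lambda u: max(u, 0.0) ** 3
        expected_j0 = (
            plus(x - 30)
            - plus(x - 70) * (82 - 30) / (82 - 70)
            + plus(x - 82) * (70 - 30) / (82 - 70)
        ) / norm
        basis = rcs_basis(np.array([x]), t)
        assert basis.shape == (1, 4)
        assert basis[0, 0] == pytest.approx(50.0)
        assert basis[0, 1] == pytest.approx(expected_j0)

    def test_reproduces_linear_function(self):
        x = np.linspace(20, 90, 200)
        basis = rcs_basis(x, np.array(KNOTS))
        coef = np.zeros(basis.shape[1])
        coef[0] = 2.5
        assert np.allclose(basis @ coef, 2.5 * x)

    def test_linear_beyond_boundary_knots(self):
        x = np.array([85.0, 88.0, 91.0, 94.0])
        basis = rcs_basis(x, np.array(KNOTS))
        rng = np.random.default_rng(0)
        coef = rng.normal(size=basis.shape[1])
        y = basis @ coef
        second_diff = np.diff(y, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_default_knots_need_events(self):
        with pytest.raises(ValueError, match="too few events"):
            default_knots(np.array([60.0, 61.0]))


class TestExpansion:
    def test_death_worker_rows_and_indicator(self):
        baseline, history = _tiny_tables()
        pp = expand_to_person_periods(baseline, history)
        w1 = pp[pp.worker_id == 1]
        assert len(w1) == 4
        assert list(w1.age) == [30, 31, 32, 33]
        assert list(w1.d_heart) == [0, 0, 0, 1]
        assert w1[["d_resp", "d_other"]].to_numpy().sum() == 0

    def test_alive_at_admin_end_all_outcomes_zero(self):
        baseline, history = _tiny_tables()
        pp = expand_to_person_periods(baseline, history)
        w2 = pp[pp.worker_id == 2]
        assert w2[["d_resp", "d_heart", "d_other"]].to_numpy().sum() == 0

    def test_row_count_identity(self, small_cohort):
        _, history, _ = small_cohort
        pp = expand_to_person_periods(*small_cohort[:2])
        wo = worker_outcomes(history)
        assert len(pp) == int((wo.exit_age - wo.entry_age + 1).sum())

    def test_transition_outcomes(self):
        baseline, history = _tiny_tables()
        pp = expand_to_person_periods(baseline, history)
        w1 = pp[pp.worker_id == 1]
        # employed at 30,31; unemployed 32,33 -> leave fires on the age-31 row
        assert list(w1.leave_work.iloc[:2]) == [0.0, 1.0]
        assert np.isnan(w1.leave_work.iloc[2]) and np.isnan(w1.leave_work.iloc[3])
        assert w1.return_work.iloc[2] == 0.0
        assert np.isnan(w1.return_work.iloc[3])  # final row: next period unobserved

    def test_window_columns_match_scalar_path(self, small_cohort):
        baseline, history, _ = small_cohort
        pp = expand_to_person_periods(baseline, history)
        coeffs = ExposureCoefficients()
        for wid_val, grp in list(pp.groupby("worker_id"))[:25]:
            incs = grp["increment"].to_numpy()
            entry = int(grp["age"].iloc[0])
            for j in range(len(grp)):
                age = entry + j
                expected = lagged_window_sums(incs[:j], age, start_age=entry)
                got = tuple(grp.iloc[j][["w_2_5", "w_5_10", "w_10_20"]])
                assert got == pytest.approx(expected, abs=1e-12)

    def test_cum_work_counts_employed_periods(self):
        baseline, history = _tiny_tables()
        pp = expand_to_person_periods(baseline, history)
        assert list(pp[pp.worker_id == 1].cum_years_worked) == [1, 2, 2, 2]

    @pytest.mark.parametrize(
        "mutate,message",
        [
            (lambda h: h.assign(age=h.age.where(h.index != 1, h.age.iloc[0])), "overlapping"),
            (lambda h: h.drop(index=1), "gap"),
            (
                lambda h: h.assign(
                    death_cause=np.where(h.index == 0, "heart", h.death_cause)
                ),
                "final person-period",
            ),
            (
                lambda h: h.assign(
                    exposure_category=np.where(h.index == 2, "light", h.exposure_category)
                ),
                "unemployed",
            ),
            (
                lambda h: h.assign(
                    death_cause=np.where(h.index == 3, "plague", h.death_cause)
                ),
                "unknown cause",
            ),
        ],
    )
    def test_invalid_histories_rejected(self, mutate, message):
        baseline, history = _tiny_tables()
        with pytest.raises(ValueError, match=message):
            expand_to_person_periods(baseline, mutate(history))


class TestDesignMatrix:
    def test_unknown_covariate(self):
        design = DesignInfo(knots=KNOTS)
        with pytest.raises(ValueError, match="unknown covariate"):
            design.build({"age": np.array([50.0])}, ["smoking"])

    def test_zero_exposure_history_zero_columns(self):
        baseline, history = _tiny_tables()
        history = history.assign(
            exposure_category=np.where(history.employed == 1, "none", "none")
        )
        pp = expand_to_person_periods(baseline, history)
        design = DesignInfo(knots=KNOTS)
        X, names = design.build(pp, ["w_2_5", "w_5_10", "w_10_20"], intercept=False)
        assert np.all(X == 0.0)

    def test_only_year_terms_change_with_calendar_year(self):
        design = DesignInfo(knots=KNOTS)
        covs = ["age_rcs", "year", "age_x_year", "employed", "w_2_5"]
        base = {
            "age": np.array([50.0, 50.0]),
            "calendar_year": np.array([1950.0, 1960.0]),
            "employed": np.array([1.0, 1.0]),
            "w_2_5": np.array([0.6, 0.6]),
        }
        X, names = design.build(base, covs)
        differing = {names[j] for j in range(X.shape[1]) if X[0, j] != X[1, j]}
        assert differing == {"year", "age_x_year"}

    def test_spline_block_matches_direct_evaluation(self):
        design = DesignInfo(knots=KNOTS)
        X, names = design.build({"age": np.array([53.0])}, ["age_rcs"])
        z = (53.0 - 60.0) / 10.0
        zk = (np.array(KNOTS) - 60.0) / 10.0
        expected = rcs_basis(np.array([z]), zk)
        assert X[0, 0] == 1.0  # intercept
        assert X[0, 1:] == pytest.approx(expected[0])
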