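"""Monte Carlo engine: stepping order, interventions, determinism."""

import numpy as np
import pandas as pd
import pytest

from gfcohort.engine import (
    INTERVENTIONS,
    EngineState,
    InterventionSpec,
    ModelSuite,
    histories_from_tables,
    sample_baselines,
    simulate_pseudo_cohort,
    step_person_year,
)
from gfcohort.exposure import ExposureCoefficients, LagSpec
from gfcohort.models import FittedModel, ModelSpec
from gfcohort.personperiod import DesignInfo


def _intercept_suite(
    h_resp=0.06, h_heart=0.10, h_other=0.15, p_leave=0.3, p_return=0.2,
    max_age=62, admin_end=2100,
):
    """Hand-built suite with intercept-only models (known constant hazards)."""
    from scipy.special import logit

    def binmod(name, p):
        return FittedModel.from_params(
            "binary_logit", name, ["intercept"], [logit(p)],
            spec=ModelSpec(outcome=name, covariates=(), family="binary_logit"),
        )

    models = {
        "d_resp": binmod("d_resp", h_resp),
        "d_heart": binmod("d_heart", h_heart),
        "d_other": binmod("d_other", h_other),
        "leave_work": binmod("leave_work", p_leave),
        "return_work": binmod("return_work", p_return),
        "exposure_category": FittedModel.from_params(
            "proportional_odds", "exposure_category",
            ["thresh_1", "thresh_2"], [logit(0.5), logit(0.75)],
            spec=ModelSpec(
                outcome="exposure_category", covariates=(), family="proportional_odds"
            ),
            n_thresholds=2,
        ),
    }
    return ModelSuite(
        models=models,
        design=DesignInfo(knots=(30.0, 50.0, 70.0)),
        coeffs=ExposureCoefficients(),
        lag_spec=LagSpec(),
        max_age=max_age,
        admin_end_year=admin_end,
    )


def _one_type_baseline(n, entry_age=60, entry_year=1950):
    return pd.DataFrame(
        {
            "worker_id": np.arange(n),
            "entry_age": entry_age,
            "entry_year": entry_year,
            "birth_year": entry_year - entry_age,
            "us_born": 1,
            "pre_entry_years_worked": 1.0,
            "pre_entry_exposure_mgm3yr": 0.29,
        }
    )


class TestTwoPeriodEnumeration:
    """Empirical path frequencies vs hand-computed products on a 2-period tree."""

    def test_death_and_employment_probabilities(self):
        suite = _intercept_suite()
        n = 200_000
        sim = simulate_pseudo_cohort(
            suite, _one_type_baseline(64), "natural_course", mc_size=n, seed=31
        )
        # per-period death probability with sequential competing-cause resolution
        d = 0.06 + 0.10 * 0.94 + 0.15 * 0.94 * 0.90  # 0.2809
        p_die1 = d
        p_die2 = (1 - d) * d
        died1 = (sim.exit_age == 60) & (sim.cause_code > 0)
        died2 = (sim.exit_age == 61) & (sim.cause_code > 0)
        se = np.sqrt(d * (1 - d) / n)
        assert abs(died1.mean() - p_die1) < 4 * se
        assert abs(died2.mean() - p_die2) < 4 * se
        # cause split in period 1
        assert abs((sim.cause_code[died1] == 1).mean() - 0.06 / d) < 0.01
        assert abs((sim.cause_code[died1] == 2).mean() - 0.094 / d) < 0.01
        # employment in period 2 among survivors of period 1: leave prob 0.3
        surv1 = sim.exit_age == 61
        emp2 = sim.emp[surv1, 61 - sim.age_min]
        assert abs(emp2.mean() - 0.7) < 0.01
        # exposure category split while employed: (1/2, 1/4, 1/4)
        cat1 = sim.cat[:, 60 - sim.age_min]
        freqs = np.bincount(cat1, minlength=4) / n
        assert freqs[0] == 0.0  # everyone employed at entry
        assert np.allclose(freqs[1:], [0.5, 0.25, 0.25], atol=0.01)
        # survivors of both periods are censored at the age cap with no cause
        assert ((sim.cause_code == 0) == (sim.exit_age == 61) & ~died2).all()

    def test_zero_hazards_mean_administrative_censoring(self):
        suite = _intercept_suite(h_resp=1e-12, h_heart=1e-12, h_other=1e-12)
        sim = simulate_pseudo_cohort(
            suite, _one_type_baseline(500), "natural_course", mc_size=500, seed=3
        )
        assert (sim.cause_code == 0).all()
        assert (sim.exit_age == 61).all()  # age cap 62 -> last interval [61, 62)


class TestInterventions:
    def test_never_exposed_forces_zero_increments(self):
        suite = _intercept_suite()
        sim = simulate_pseudo_cohort(
            suite, _one_type_baseline(2000), "never_exposed", mc_size=2000, seed=8
        )
        assert np.all(sim.inc == 0.0)
        assert np.all(sim.cat == 0)

    def test_always_heavy_forces_heavy_while_employed(self):
        suite = _intercept_suite()
        sim = simulate_pseudo_cohort(
            suite, _one_type_baseline(2000), "always_heavy", mc_size=2000, seed=8
        )
        ai = 61 - sim.age_min
        at_risk = sim.exit_age >= 61
        emp = sim.emp[:, ai] == 1
        assert np.all(sim.cat[at_risk & emp, ai] == 3)
        assert np.all(sim.cat[at_risk & ~emp, ai] == 0)
        assert np.all(sim.inc[at_risk & emp, ai] == pytest.approx(1.14))

    def test_unknown_intervention_rejected(self):
        with pytest.raises(ValueError, match="unknown intervention"):
            InterventionSpec("sometimes_exposed")

    def test_common_random_numbers_same_seed(self):
        suite = _intercept_suite()
        base = _one_type_baseline(1000)
        a = simulate_pseudo_cohort(suite, base, "natural_course", 1000, seed=5)
        b = simulate_pseudo_cohort(suite, base, "natural_course", 1000, seed=5)
        assert np.array_equal(a.exit_age, b.exit_age)
        assert np.array_equal(a.cause_code, b.cause_code)
        assert np.array_equal(a.inc, b.inc)
        c = simulate_pseudo_cohort(suite, base, "natural_course", 1000, seed=6)
        assert not np.array_equal(a.exit_age, c.exit_age)


class TestSampleBaselines:
    def test_identity_hook(self):
        base = _one_type_baseline(10)
        out = sample_baselines(base, 10, np.random.default_rng(0), identity=True)
        pd.testing.assert_frame_equal(out, base)
        with pytest.raises(ValueError, match="identity"):
            sample_baselines(base, 5, np.random.default_rng(0), identity=True)

    def test_with_replacement_preserves_means(self, small_cohort):
        baseline, _, _ = small_cohort
        rng = np.random.default_rng(11)
        out = sample_baselines(baseline, 30_000, rng)
        for col in ("entry_age", "us_born", "pre_entry_exposure_mgm3yr"):
            mu, sd = baseline[col].mean(), baseline[col].std()
            assert abs(out[col].mean() - mu) < 3 * sd / np.sqrt(len(baseline))

    def test_edge_cases(self):
        base = _one_type_baseline(4)
        out = sample_baselines(base, 1, np.random.default_rng(0))
        assert len(out) == 1
        with pytest.raises(ValueError, match="empty"):
            sample_baselines(base.iloc[:0], 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="positive"):
            sample_baselines(base, 0, np.random.default_rng(0))


class TestStepping:
    def test_step_person_year_advances_and_guards(self):
        suite = _intercept_suite(h_resp=1e-9, h_heart=1e-9, h_other=1e-9)
        state = EngineState(
            entry_age=np.array([60]),
            birth_year=np.array([1890]),
            us_born=np.array([1.0]),
            pre_entry_years_worked=np.array([1.0]),
            pre_entry_exposure=np.array([0.29]),
            age_min=60,
            n_steps=2,
        )
        rng = np.random.default_rng(0)
        step_person_year(state, suite, INTERVENTIONS["natural_course"], rng)
        assert state.age == 60 and state.employed[0] == 1
        step_person_year(state, suite, INTERVENTIONS["natural_course"], rng)
        assert state.done[0]  # censored at the age cap
        with pytest.raises(ValueError, match="dead/censored"):
            step_person_year(state, suite, INTERVENTIONS["natural_course"], rng)

    def test_unconverged_suite_refused(self):
        suite = _intercept_suite()
        suite["d_resp"].converged = False
        with pytest.raises(ValueError, match="unconverged"):
            simulate_pseudo_cohort(
                suite, _one_type_baseline(10), "natural_course", 10, seed=1
            )
        sim = simulate_pseudo_cohort(
            suite, _one_type_baseline(10), "natural_course", 10, seed=1,
            allow_unconverged=True,
        )
        assert sim.n == 10


class TestRoundTrip:
    def test_history_frame_round_trip(self, small_cohort):
        """Observed tables -> SimulatedHistories -> tables is the identity."""
        _, history, _ = small_cohort
        hobj = histories_from_tables(history)
        back = hobj.to_history_frame()
        orig = history.sort_values(["worker_id", "age"]).reset_index(drop=True)
        for col in ("age", "calendar_year", "employed", "exposure_category", "death_cause"):
            assert np.array_equal(back[col].to_numpy(), orig[col].to_numpy()), col
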