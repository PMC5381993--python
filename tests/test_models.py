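"""Pooled logistic and proportional-odds maximum likelihood."""

import numpy as np
import pytest
from scipy.special import expit, logit

from gfcohort.models import (
    ModelFitError,
    fit_pooled_logistic,
    fit_proportional_odds,
    predict_category_probs,
    predict_hazard,
)


def _sim_logit(n, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
    eta = -1.0 + 0.7 * X[:, 1] - 0.5 * X[:, 2]
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


class TestPooledLogistic:
    def test_intercept_only_closed_form(self):
        y = np.repeat([0.0, 1.0], [70, 30])
        m = fit_pooled_logistic(np.ones((100, 1)), y, ["intercept"])
        assert m.params[0] == pytest.approx(logit(0.3), abs=1e-10)

    def test_two_by_two_log_odds_ratio(self):
        # cells: x=0 -> 40 events / 160 non-events; x=1 -> 30 / 70
        x = np.repeat([0.0, 1.0], [200, 100])
        y = np.concatenate([np.repeat([1.0, 0.0], [40, 160]), np.repeat([1.0, 0.0], [30, 70])])
        m = fit_pooled_logistic(np.column_stack([np.ones(300), x]), y, ["intercept", "x"])
        lor = np.log((30 * 160) / (70 * 40))
        assert m.params[1] == pytest.approx(lor, abs=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _sim_logit(4000)
        m = fit_pooled_logistic(X, y, ["c", "x1", "x2"])
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(m.params, ref.params, atol=1e-8)
        assert np.allclose(m.bse, ref.bse, atol=1e-8)
        assert m.llf == pytest.approx(ref.llf, abs=1e-8)
        assert m.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_frequency_weights_equal_row_replication(self):
        X, y = _sim_logit(300, seed=4)
        rng = np.random.default_rng(5)
        w = rng.integers(0, 4, 300).astype(float)
        keep = w > 0
        m_w = fit_pooled_logistic(X, y, ["c", "x1", "x2"], weights=w)
        rep = np.repeat(np.arange(300), w.astype(int))
        m_r = fit_pooled_logistic(X[rep], y[rep], ["c", "x1", "x2"])
        assert np.allclose(m_w.params, m_r.params, atol=1e-8)
        assert m_w.llf == pytest.approx(m_r.llf, abs=1e-6)

    def test_degenerate_outcome_errors_name_the_outcome(self):
        X = np.ones((50, 1))
        with pytest.raises(ModelFitError, match="d_resp.*no events"):
            fit_pooled_logistic(X, np.zeros(50), ["intercept"], outcome="d_resp")
        with pytest.raises(ModelFitError, match="no non-events"):
            fit_pooled_logistic(X, np.ones(50), ["intercept"], outcome="d_resp")

    def test_separation_reported(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.raises(ModelFitError):
            fit_pooled_logistic(np.column_stack([np.ones(40), x]), y, ["c", "x"])

    def test_warm_start_same_solution(self):
        X, y = _sim_logit(1000, seed=9)
        m0 = fit_pooled_logistic(X, y, ["c", "x1", "x2"])
        m1 = fit_pooled_logistic(X, y, ["c", "x1", "x2"], start=m0.params + 0.3)
        assert np.allclose(m0.params, m1.params, atol=1e-7)

    def test_mle_beats_truth_loglik(self, small_cohort, fitted_small):
        """Optimization sanity: fitted likelihood >= generating-truth likelihood."""
        _, _, truth = small_cohort
        model = fitted_small.model
        for name in ("d_resp", "d_heart", "d_other", "leave_work"):
            d = model._data[name]
            fit = fitted_small.suite[name]
            tr = np.array([truth[name][t] for t in fit.param_names])

            def ll(beta):
                eta = d.X @ beta
                return float(d.y @ eta - np.logaddexp(0.0, eta).sum())

            assert ll(fit.params) >= ll(tr) - 1e-6


class TestProportionalOdds:
    def test_closed_form_thresholds(self):
        y = np.repeat([0, 1, 2], [500, 250, 250])
        m = fit_proportional_odds(np.empty((1000, 0)), y, [])
        assert m.params[0] == pytest.approx(logit(0.5), abs=1e-9)
        assert m.params[1] == pytest.approx(logit(0.75), abs=1e-9)

    def test_matches_statsmodels(self):
        om_mod = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        rng = np.random.default_rng(1)
        n = 4000
        X = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.5, n)])
        eta = 0.8 * X[:, 0] - 0.4 * X[:, 1]
        u = rng.random(n)
        y = np.where(u < expit(0.0 - eta), 0, np.where(u < expit(1.1 - eta), 1, 2))
        m = fit_proportional_odds(X, y, ["x1", "x2"])
        ref = om_mod.OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        cuts = np.array([ref.params[-2], ref.params[-2] + np.exp(ref.params[-1])])
        assert np.allclose(m.beta, ref.params[:2], atol=1e-4)
        assert np.allclose(m.thresholds, cuts, atol=1e-4)

    def test_missing_category_errors(self):
        y = np.repeat([0, 2], [50, 50])
        with pytest.raises(ModelFitError, match="absent"):
            fit_proportional_odds(np.empty((100, 0)), y, [])

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(7)
        n = 10000
        x = rng.normal(size=n)
        u = rng.random(n)
        y = np.where(u < expit(0.5 - 0.9 * x), 0, np.where(u < expit(1.8 - 0.9 * x), 1, 2))
        m = fit_proportional_odds(x[:, None], y, ["x"])
        se = m.bse[2]
        assert abs(m.params[2] - 0.9) < 2 * se


class TestPrediction:
    def test_hazard_values(self):
        from gfcohort.models import FittedModel

        m = FittedModel.from_params("binary_logit", "d", ["c", "x"], [-3.0, 0.5])
        assert predict_hazard(m, np.array([[1.0, 2.0]]))[0] == pytest.approx(
            expit(-2.0)
        )  # ~0.1192
        zero = FittedModel.from_params("binary_logit", "d", ["c"], [0.0])
        assert predict_hazard(zero, np.ones((1, 1)))[0] == 0.5

    def test_intercept_only_predicts_event_fraction(self):
        y = np.repeat([0.0, 1.0], [60, 40])
        m = fit_pooled_logistic(np.ones((100, 1)), y, ["intercept"])
        assert predict_hazard(m, np.ones((1, 1)))[0] == pytest.approx(0.4, abs=1e-10)

    def test_wrong_width_rejected(self):
        from gfcohort.models import FittedModel

        m = FittedModel.from_params("binary_logit", "d", ["c", "x"], [-3.0, 0.5])
        with pytest.raises(ValueError, match="expects"):
            predict_hazard(m, np.ones((1, 3)))

    def test_category_probs_closed_form_and_sum(self):
        from gfcohort.models import FittedModel

        m = FittedModel.from_params(
            "proportional_odds",
            "exposure_category",
            ["thresh_1", "thresh_2", "x"],
            [logit(0.5), logit(0.75), 0.8],
            n_thresholds=2,
        )
        p = predict_category_probs(m, np.zeros((1, 1)))
        assert p[0] == pytest.approx([0.5, 0.25, 0.25])
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 1))
        P = predict_category_probs(m, X)
        assert np.all(P > 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_heavy_probability_monotone_in_linear_predictor(self):
        from gfcohort.models import FittedModel

        m = FittedModel.from_params(
            "proportional_odds",
            "exposure_category",
            ["thresh_1", "thresh_2", "x"],
            [0.0, 1.1, 1.0],
            n_thresholds=2,
        )
        X = np.linspace(-4, 4, 50)[:, None]
        p_heavy = predict_category_probs(m, X)[:, 2]
        assert np.all(np.diff(p_heavy) > 0)
        # extreme linear predictor concentrates mass on heavy
        assert predict_category_probs(m, np.array([[40.0]]))[0, 2] > 0.999999
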