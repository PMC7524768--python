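"""Counterfactual exposure simulation and coefficient sweeps."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from machtrust.counterfactual import predict_alpha, simulate_exposure, sweep_coefficient
from machtrust.covariates import build_covariate_table
from machtrust.regression import RegressionFit, Standardization, fit_model
from machtrust.scoring import brier
from machtrust.types import MachineForecast, ProbabilityForecast, ValidationError


def _toy_fit(**extra):
    params = {
        "skill[high]": 0.82,
        "skill[low]": 0.90,
        "confirming": -0.05,
        "difficulty": 0.04,
        "distance": -0.037,
        "uncertainty": -0.03,
        "reputation": -0.02,
        "helpfulness": -0.05,
    }
    params.update(extra)
    return RegressionFit(
        model_id="eq3",
        params=params,
        bse={k: 0.01 for k in params},
        pvalues={k: 0.01 for k in params},
        r_squared=0.5,
        r_squared_adj=0.5,
        n_obs=100,
        standardization=Standardization(means={}, sds={}),
    )


def _row(**kw):
    base = {
        "skill": "high",
        "confirming": 0.0,
        "difficulty": 0.0,
        "distance": 0.0,
        "uncertainty": 0.0,
        "reputation": 0.0,
        "helpfulness": 0.0,
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestPredictAlpha:
    def test_centered_row_gives_stratum_baseline(self):
        fit = _toy_fit()
        assert predict_alpha(fit, _row())[0] == pytest.approx(0.82)
        assert predict_alpha(fit, _row(skill="low"))[0] == pytest.approx(0.90)

    def test_clamped_to_unit_interval(self):
        fit = _toy_fit(**{"skill[high]": 1.3})
        assert predict_alpha(fit, _row())[0] == 1.0
        fit = _toy_fit(**{"skill[high]": -0.5})
        assert predict_alpha(fit, _row(), alpha_floor=0.01)[0] == 0.01

    def test_hand_computed_dot_product(self):
        fit = _toy_fit()
        row = _row(
            confirming=1.0, difficulty=0.5, distance=-1.2, uncertainty=2.0,
            reputation=0.3, helpfulness=-0.7,
        )
        expected = (
            0.82 - 0.05 + 0.04 * 0.5 - 0.037 * -1.2 - 0.03 * 2.0
            - 0.02 * 0.3 - 0.05 * -0.7
        )
        assert predict_alpha(fit, row)[0] == pytest.approx(expected, abs=1e-12)

    def test_unknown_coefficient_override_rejected(self):
        with pytest.raises(ValidationError):
            predict_alpha(_toy_fit(), _row(), overrides={"nonsense": 1.0})


class TestSimulateExposure:
    @staticmethod
    def _setup():
        day = dt.date(2019, 2, 1)
        control = [
            ProbabilityForecast(
                user_id="u", question_id="q", condition="control",
                timestamp=dt.datetime(2019, 2, 1, 12), probs=np.array([0.6, 0.4]),
            )
        ]
        machine = {
            day: MachineForecast(
                question_id="q", date=day, probs=np.array([0.9, 0.1]),
                point_estimate=1.0, interval_95=(0.0, 2.0),
            )
        }
        return control, machine

    def test_full_trust_is_identity(self):
        control, machine = self._setup()
        out = simulate_exposure(control, machine, 1.0)
        np.testing.assert_array_equal(out[0], control[0].probs)

    def test_zero_trust_is_machine(self):
        control, machine = self._setup()
        out = simulate_exposure(control, machine, 0.0)
        np.testing.assert_array_equal(out[0], machine[dt.date(2019, 2, 1)].probs)

    def test_half_trust_arithmetic(self):
        control, machine = self._setup()
        out = simulate_exposure(control, machine, 0.5)
        np.testing.assert_allclose(out[0], [0.75, 0.25], atol=1e-15)

    def test_missing_day_uses_nearest_earlier(self):
        control, machine = self._setup()
        later = [
            ProbabilityForecast(
                user_id="u", question_id="q", condition="control",
                timestamp=dt.datetime(2019, 2, 5, 12), probs=np.array([0.6, 0.4]),
            )
        ]
        out = simulate_exposure(later, machine, 0.5)
        assert len(out) == 1  # fell back to the Feb 1 machine forecast


@pytest.fixture(scope="module")
def pipeline(small_tournament_module):
    t = small_tournament_module
    from machtrust.influence import estimate_tournament

    ests = estimate_tournament(t.questions, t.forecasts, t.machine_forecasts)
    table = build_covariate_table(ests, t.questions, t.forecasts, t.machine_forecasts)
    fit = fit_model(table, "eq3")
    return t, table, fit


@pytest.fixture(scope="module")
def small_tournament_module():
    from machtrust.synthetic import SyntheticConfig, generate_tournament

    return generate_tournament(
        SyntheticConfig(n_questions=8, alpha_star=0.6, n_independent_questions=5, seed=21)
    )


class TestSweep:
    def test_baseline_grid_point_is_exactly_zero(self, pipeline):
        t, table, fit = pipeline
        results = sweep_coefficient(
            fit, table, t.questions, t.forecasts, t.machine_forecasts,
            "helpfulness", n_grid=5,
        )
        at_learned = [
            r for r in results if np.isclose(r.grid_value, fit.params["helpfulness"])
        ]
        assert at_learned
        for r in at_learned:
            assert r.median_pct_change == 0.0
            assert r.iqr_lo == 0.0 and r.iqr_hi == 0.0

    def test_forced_full_trust_reproduces_control_brier(self, pipeline):
        t, table, fit = pipeline
        forced = RegressionFit(
            model_id="eq3",
            params={k: (2.0 if k.startswith("skill[") else 0.0) for k in fit.params},
            bse=fit.bse, pvalues=fit.pvalues, r_squared=0.0, r_squared_adj=0.0,
            n_obs=fit.n_obs, standardization=fit.standardization,
        )
        work = fit.standardization.transform(table)
        alphas = predict_alpha(forced, work)
        assert np.all(alphas == 1.0)
        qmap = {q.question_id: q for q in t.questions}
        by_day = {}
        for m in t.machine_forecasts:
            by_day.setdefault(m.question_id, {})[m.date] = m
        row = table.iloc[0]
        q = qmap[row.question_id]
        control = [
            f for f in t.forecasts
            if f.question_id == row.question_id and f.condition == "control"
            and row.window_start <= f.date <= row.window_end
        ]
        sim = simulate_exposure(control, by_day[row.question_id], 1.0)
        direct = brier([f.probs for f in control], q.resolved_option, q)
        assert brier(sim, q.resolved_option, q) == pytest.approx(direct, abs=1e-15)

    def test_curves_continuous_no_stratum_flips(self, pipeline):
        t, table, fit = pipeline
        results = sweep_coefficient(
            fit, table, t.questions, t.forecasts, t.machine_forecasts,
            "distance", n_grid=7,
        )
        by_stratum = {}
        for r in results:
            by_stratum.setdefault(r.stratum, []).append(r.n_cells)
        for counts in by_stratum.values():
            assert len(set(counts)) == 1  # membership fixed along the sweep

    def test_grid_must_include_learned_value(self, pipeline):
        t, table, fit = pipeline
        with pytest.raises(ValidationError):
            sweep_coefficient(
                fit, table, t.questions, t.forecasts, t.machine_forecasts,
                "distance", grid=[999.0],
            )
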