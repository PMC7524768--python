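"""Binary projection, windows, plug-in priors, and the trust-weight MLE."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy.stats import norm

from machtrust.influence import (
    InfluenceEstimate,
    TimeWindow,
    WindowPrior,
    build_windows,
    compare_condition_variances,
    estimate_alpha,
    estimate_prior,
    estimate_tournament,
    log_likelihood,
    project_binary,
)
from machtrust.types import PipelineConfig, ProbabilityForecast, Question, ValidationError


def _window():
    return TimeWindow("q0", dt.date(2019, 1, 1), dt.date(2019, 1, 7))


class TestProjectBinary:
    @pytest.mark.parametrize(
        "probs, resolved, expected",
        [
            ([0.2, 0.3, 0.5], 2, 0.5),
            ([0.25, 0.25, 0.25, 0.25], 1, 0.25),
            ([0.0, 1.0], 1, 1.0),
        ],
    )
    def test_extracts_correct_option_mass(self, probs, resolved, expected):
        assert project_binary(np.array(probs), resolved) == expected

    def test_unresolved_question_rejected(self):
        with pytest.raises(ValidationError):
            project_binary(np.array([0.5, 0.5]), None)

    def test_invariant_to_incorrect_option_relabeling(self):
        a = project_binary(np.array([0.5, 0.3, 0.2]), 0)
        b = project_binary(np.array([0.5, 0.2, 0.3]), 0)
        assert a == b


class TestBuildWindows:
    @staticmethod
    def _question(duration):
        return Question(
            question_id="q",
            n_options=2,
            t_open=dt.date(2019, 1, 1),
            t_close=dt.date(2019, 1, 1) + dt.timedelta(days=duration),
            option_edges=(10.0,),
            resolved_option=0,
        )

    @pytest.mark.parametrize(
        "duration, setting, expected_length",
        [
            (28, "quarter_duration", 7),
            (12, "max_of_both", 7),
            (60, "max_of_both", 15),
            (30, "weekly", 7),
        ],
    )
    def test_window_length_rule(self, duration, setting, expected_length):
        windows = build_windows(self._question(duration), setting)
        assert all(w.length_days == expected_length for w in windows)

    def test_short_question_single_full_span(self):
        q = self._question(5)
        windows = build_windows(q, "weekly")
        assert len(windows) == 1
        assert windows[0].start == q.t_open
        assert windows[0].end == q.t_close - dt.timedelta(days=1)

    def test_windows_inside_open_span(self):
        q = self._question(40)
        for w in build_windows(q, "max_of_both", stride_days=7):
            assert w.start >= q.t_open
            assert w.end < q.t_close


class TestEstimatePrior:
    def test_two_point_sample(self):
        p = estimate_prior([0.4, 0.6])
        assert p.mu == pytest.approx(0.5)
        assert p.sigma2 == pytest.approx(0.02)

    def test_four_point_sample(self):
        p = estimate_prior([0.2, 0.4, 0.6, 0.8])
        assert p.mu == pytest.approx(0.5)
        assert p.sigma2 == pytest.approx(0.0667, abs=5e-5)

    def test_degenerate_floored_and_flagged(self):
        p = estimate_prior([0.5] * 10)
        assert p.degenerate
        assert p.sigma2 == 1e-6


class TestLogLikelihood:
    def test_unit_normal_peak_is_zero(self):
        prior = WindowPrior(mu=0.5, sigma2=1 / (2 * math.pi), n_control=10)
        assert log_likelihood(1.0, [0.5], [0.9], prior) == pytest.approx(0.0, abs=1e-12)

    def test_moving_away_from_mean_decreases(self):
        prior = WindowPrior(mu=0.6, sigma2=0.01, n_control=10)
        center = 0.5 * 0.6 + 0.5 * 0.9
        vals = [
            log_likelihood(0.5, [center + d], [0.9], prior) for d in (0.0, 0.05, 0.1)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_alpha_zero_is_domain_error(self):
        prior = WindowPrior(mu=0.5, sigma2=0.01, n_control=10)
        with pytest.raises(ValidationError):
            log_likelihood(0.0, [0.5], [0.9], prior)

    def test_matches_brute_force_density_product(self, rng):
        """Independent oracle: sum of scipy normal log-densities."""
        for _ in range(100):
            n = int(rng.integers(2, 30))
            y = rng.uniform(0, 1, n)
            m = rng.uniform(0, 1, n)
            alpha = rng.uniform(0.05, 1.0)
            prior = WindowPrior(
                mu=rng.uniform(0.2, 0.8), sigma2=rng.uniform(0.001, 0.1), n_control=n
            )
            oracle = float(
                np.sum(
                    norm.logpdf(
                        y,
                        loc=alpha * prior.mu + (1 - alpha) * m,
                        scale=alpha * np.sqrt(prior.sigma2),
                    )
                )
            )
            assert log_likelihood(alpha, y, m, prior) == pytest.approx(oracle, abs=1e-9)


class TestEstimateAlpha:
    @staticmethod
    def _simulate(alpha, n, mu=0.6, sigma=0.1, m=0.9, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(mu, sigma, n)
        y = alpha * x + (1 - alpha) * m
        prior_draws = rng.normal(mu, sigma, n)
        return y, np.full(n, m), estimate_prior(prior_draws)

    def test_control_like_treatment_estimates_near_one(self):
        y, m, prior = self._simulate(1.0, 200, seed=1)
        est = estimate_alpha(_window(), y, m, prior)
        assert est.alpha_hat >= 0.95

    def test_pure_machine_followers_hit_floor(self):
        prior = WindowPrior(mu=0.6, sigma2=0.01, n_control=10)
        y = np.full(20, 0.9)
        m = np.full(20, 0.9)
        est = estimate_alpha(_window(), y, m, prior)
        assert est.alpha_hat == pytest.approx(0.01)

    def test_parameter_recovery_at_half(self):
        y, m, prior = self._simulate(0.5, 200, seed=2)
        est = estimate_alpha(_window(), y, m, prior)
        assert 0.45 <= est.alpha_hat <= 0.55

    def test_matches_grid_oracle(self, rng):
        for seed in range(10):
            alpha = float(rng.uniform(0.1, 1.0))
            y, m, prior = self._simulate(alpha, 50, seed=seed)
            est = estimate_alpha(_window(), y, m, prior)
            grid = np.arange(0.01, 1.0005, 0.001)
            ll = [log_likelihood(a, y, m, prior) for a in grid]
            assert abs(est.alpha_hat - grid[int(np.argmax(ll))]) <= 0.002


class TestTournamentEstimation:
    def test_recovery_on_synthetic_tournament(self, small_tournament, small_estimates):
        alphas = np.array([e.alpha_hat for e in small_estimates])
        assert len(alphas) >= 20
        assert np.abs(alphas - 0.5).mean() <= 0.05

    def test_minimum_forecast_filter(self, small_tournament):
        t = small_tournament
        few = [f for f in t.forecasts if f.user_id in ("c000", "t000")]
        ests = estimate_tournament(
            t.questions, few, t.machine_forecasts, PipelineConfig(min_forecasts=4)
        )
        # one user per condition at 50% daily activity cannot reach 4
        # forecasts per condition in most windows
        full = estimate_tournament(t.questions, t.forecasts, t.machine_forecasts)
        assert len(ests) < len(full)

    def test_variance_relation(self, small_tournament):
        vc = compare_condition_variances(
            small_tournament.questions, small_tournament.forecasts
        )
        ratio = vc.mean_var_treatment / vc.mean_var_control
        assert ratio == pytest.approx(0.25, abs=0.05)
        assert vc.p_value < 0.05

    def test_identical_conditions_no_difference(self, small_tournament):
        t = small_tournament
        mirrored = []
        for f in t.forecasts:
            if f.condition == "control":
                mirrored.append(f)
                mirrored.append(
                    ProbabilityForecast(
                        user_id=f.user_id.replace("c", "t"),
                        question_id=f.question_id,
                        timestamp=f.timestamp,
                        condition="treatment",
                        probs=f.probs,
                    )
                )
        vc = compare_condition_variances(t.questions, mirrored)
        assert vc.mean_var_treatment == pytest.approx(vc.mean_var_control)
        assert vc.p_value > 0.9
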