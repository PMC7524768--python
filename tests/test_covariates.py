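"""Worked examples and invariants for the eight regression predictors."""

import datetime as dt

import numpy as np
import pytest

from machtrust.covariates import (
    build_covariate_table,
    confirming,
    difficulty,
    distance,
    helpfulness,
    lifetime,
    machine_reputation,
    uncertainty,
)
from machtrust.influence import TimeWindow
from machtrust.types import PipelineConfig, Question, ValidationError


class TestUncertainty:
    def test_identical_forecasts_zero(self):
        assert uncertainty([[0.3, 0.7]] * 5) == 0.0

    def test_binary_worked_example(self):
        assert uncertainty([[0.4, 0.6], [0.6, 0.4]]) == pytest.approx(0.02)

    def test_invariant_under_option_reordering(self, rng):
        probs = rng.dirichlet(np.ones(4), size=10)
        perm = rng.permutation(4)
        assert uncertainty(probs) == pytest.approx(uncertainty(probs[:, perm]))

    def test_population_variant_duplication_invariant(self, rng):
        probs = list(rng.dirichlet(np.ones(3), size=6))
        assert uncertainty(probs, ddof=0) == pytest.approx(
            uncertainty(probs + probs, ddof=0)
        )


class TestDifficulty:
    @staticmethod
    def _question():
        return Question(
            question_id="q",
            n_options=2,
            t_open=dt.date(2019, 1, 1),
            t_close=dt.date(2019, 2, 1),
            option_edges=(10.0,),
            resolved_option=0,
        )

    def test_perfect_control_zero(self):
        assert difficulty([[1.0, 0.0]] * 3, self._question()) == 0.0

    def test_uniform_binary_ordinal(self):
        assert difficulty([[0.5, 0.5]] * 3, self._question()) == pytest.approx(0.25)

    def test_agrees_with_scoring_module(self, rng):
        from machtrust.scoring import brier

        q = self._question()
        probs = rng.dirichlet(np.ones(2), size=50)
        expected = np.mean([brier(p, 0, q) for p in probs])
        assert difficulty(list(probs), q) == pytest.approx(expected)


class TestConfirming:
    def test_machine_equal_to_reference_confirms(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(int(rng.integers(2, 6))))
            assert confirming(p, p) == 1

    def test_machine_beyond_reference_confirms(self):
        assert confirming(np.array([0.9, 0.1]), np.array([0.6, 0.4])) == 1

    def test_machine_opposing_reference_disconfirms(self):
        assert confirming(np.array([0.4, 0.6]), np.array([0.6, 0.4])) == 0

    def test_uniform_tie_goes_to_lowest_index(self):
        from machtrust.covariates import nearest_extreme

        x = nearest_extreme(np.array([0.5, 0.5]))
        np.testing.assert_array_equal(x, [1.0, 0.0])


class TestHelpfulness:
    def test_machine_best_of_all(self):
        assert helpfulness([0.5] * 10, 0.1) == 1.0

    def test_machine_worst(self):
        assert helpfulness([0.1] * 10, 0.5) == 0.0

    def test_beats_six_of_ten(self):
        users = [0.1, 0.15, 0.2, 0.25, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        assert helpfulness(users, 0.3) == pytest.approx(0.6)

    def test_ties_count_half(self):
        assert helpfulness([0.2, 0.3, 0.3, 0.5], 0.3) == pytest.approx(
            (1 + 0.5 + 0.5 + 0) / 4
        )


class TestLifetime:
    @staticmethod
    def _question(duration=40):
        return Question(
            question_id="q",
            n_options=2,
            t_open=dt.date(2019, 1, 1),
            t_close=dt.date(2019, 1, 1) + dt.timedelta(days=duration),
            option_edges=(10.0,),
            resolved_option=0,
        )

    def test_window_ending_at_close_full(self):
        q = self._question()
        w = TimeWindow("q", q.t_close - dt.timedelta(days=7), q.t_close)
        assert lifetime(w, q) == 1.0

    def test_day_ten_of_forty(self):
        q = self._question()
        w = TimeWindow("q", dt.date(2019, 1, 4), q.t_open + dt.timedelta(days=10))
        assert lifetime(w, q) == pytest.approx(0.25)

    def test_monotone_in_window_end(self):
        q = self._question()
        ends = [q.t_open + dt.timedelta(days=d) for d in (7, 14, 21, 28)]
        vals = [lifetime(TimeWindow("q", e - dt.timedelta(days=6), e), q) for e in ends]
        assert vals == sorted(vals)


class TestDistance:
    def test_machine_equals_forecasts_zero(self, rng):
        p = rng.dirichlet(np.ones(3))
        assert distance([(p, p)] * 4) == 0.0

    def test_binary_worked_example(self):
        m, p = np.array([0.9, 0.1]), np.array([0.6, 0.4])
        assert distance([(m, p)]) == pytest.approx(0.3)

    def test_three_option_worked_example(self):
        m, p = np.array([0.5, 0.3, 0.2]), np.array([0.2, 0.3, 0.5])
        assert distance([(m, p)]) == pytest.approx(np.sqrt(0.18), abs=1e-6)

    def test_duplication_invariant(self, rng):
        pairs = [
            (rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))) for _ in range(5)
        ]
        assert distance(pairs) == pytest.approx(distance(pairs + pairs))


class TestMachineReputation:
    @staticmethod
    def _q(qid, open_day, close_day):
        return Question(
            question_id=qid,
            n_options=2,
            t_open=dt.date(2019, 1, open_day),
            t_close=dt.date(2019, 1, close_day),
            option_edges=(10.0,),
            resolved_option=0,
        )

    def test_mean_of_resolved_briers(self):
        qs = [self._q("a", 1, 5), self._q("b", 1, 8), self._q("c", 10, 20)]
        rep, imputed = machine_reputation(qs[2], qs, {"a": 0.2, "b": 0.4})
        assert rep == pytest.approx(-0.3)
        assert not imputed

    def test_perfect_history_zero(self):
        qs = [self._q("a", 1, 5), self._q("c", 10, 20)]
        rep, _ = machine_reputation(qs[1], qs, {"a": 0.0})
        assert rep == 0.0

    def test_first_question_imputed(self):
        qs = [self._q("a", 1, 20), self._q("b", 1, 20)]
        rep, imputed = machine_reputation(qs[0], qs, {"a": 0.2, "b": 0.4})
        assert imputed
        assert rep == pytest.approx(-0.3)  # eventual global mean

    def test_no_lookahead(self):
        # question b closes after c opens: must not contribute
        qs = [self._q("a", 1, 5), self._q("b", 1, 15), self._q("c", 10, 20)]
        rep, _ = machine_reputation(qs[2], qs, {"a": 0.2, "b": 0.0})
        assert rep == pytest.approx(-0.2)


class TestBuildTable:
    def test_one_row_per_estimate_with_bounds(self, small_tournament, small_estimates):
        t = small_tournament
        table = build_covariate_table(
            small_estimates, t.questions, t.forecasts, t.machine_forecasts
        )
        assert len(table) == len(small_estimates)
        assert table["helpfulness"].between(0, 1).all()
        assert table["lifetime"].between(0, 1).all()
        assert (table["distance"] >= 0).all()
        assert table["confirming"].isin([0, 1]).all()
        assert np.isfinite(table["reputation"]).all()

    def test_reference_group_config_switch(self, small_tournament, small_estimates):
        t = small_tournament
        a = build_covariate_table(
            small_estimates, t.questions, t.forecasts, t.machine_forecasts,
            PipelineConfig(confirmation_reference="treatment"),
        )
        b = build_covariate_table(
            small_estimates, t.questions, t.forecasts, t.machine_forecasts,
            PipelineConfig(confirmation_reference="control"),
        )
        # both are valid dummies; they may disagree on some windows
        assert a["confirming"].isin([0, 1]).all()
        assert b["confirming"].isin([0, 1]).all()
        assert (a.drop(columns="confirming") == b.drop(columns="confirming")).all().all()
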