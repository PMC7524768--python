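"""Synthetic forecasting tournament with planted trust-weight structure.

Generates everything the analysis pipeline consumes — ordinal questions
with daily historical series, control and treatment forecasts, daily
machine forecasts, and independent skill-assessment questions — so every
downstream stage is testable end to end with known ground truth.

The generative story mirrors the hybrid-tournament design:

* Each question tracks a daily AR(1)-with-drift quantity; answer-option
  bins come from quantiles of the pre-open history and the question
  resolves to the bin containing the value at close.
* Control forecasters draw their correct-option probability from a
  normal group prior ``N(mu_t, sigma_prior^2)`` (clipped to [0.01, 0.99]),
  whose mean drifts linearly from an initial offset toward the truth as
  evidence accumulates over the question's life.
* Treatment forecasters draw an independent prior from the same
  distribution and report the convex combination
  ``y = alpha * x + (1 - alpha) * m_t`` with the day's machine forecast,
  applied to the full probability vector (so forecasts stay on the
  simplex by construction).  The planted ``alpha`` is either a constant
  or a linear function of per-question covariates with chosen
  coefficients plus noise.
* The machine forecasts the resolution-day value from the (optionally
  noise-corrupted) series seen through each day, via a closed-form AR(1)
  plug-in predictive distribution by default, or the full stepwise-ARIMA
  machinery of :mod:`machtrust.machine`.
* Skill questions are machine-free binary items on which each user's
  accuracy is governed by a latent skill level.

Users follow a Bernoulli daily activity schedule, producing the sparse,
uneven forecast streams the rolling windows must tolerate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .machine import daily_machine_forecasts, forecast_to_bins
from .types import (
    MachineForecast,
    ProbabilityForecast,
    Question,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Tournament",
    "generate_questions",
    "generate_control_forecasts",
    "generate_treatment_forecasts",
    "generate_skill_questions",
    "generate_tournament",
]

#: covariates of the planted linear trust-weight process
ALPHA_COVARIATES = (
    "confirming",
    "difficulty",
    "distance",
    "uncertainty",
    "reputation",
    "helpfulness",
)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the emulated study conditions.

    Durations are gamma-distributed with mean 53 and sd 33 days (redrawn
    below 7 days so a weekly window fits); the planted constant trust
    weight defaults to 0.86, the population-average weight the analysis
    is designed to recover.  ``machine_noise_sd`` degrades the series the
    machine sees, ``machine_bias`` shifts its point forecasts — together
    the machine-quality knobs.
    """

    n_questions: int = 50
    n_users: int = 30  # per condition
    n_independent_questions: int = 126
    duration_mean: float = 53.0
    duration_sd: float = 33.0
    start_date: dt.date = dt.date(2019, 1, 1)
    open_span_days: int = 180  # question starts staggered over this span
    history_days: int = 60  # pre-open burn-in seen by the machine
    # prior process
    sigma_prior: float = 0.1
    prior_initial_range: tuple[float, float] = (0.3, 0.6)
    prior_drift_rate: float = 0.5  # fraction of the gap to certainty closed by t_close
    # planted trust weight
    alpha_process: Literal["constant", "covariate"] = "constant"
    alpha_star: float = 0.86
    alpha_beta: dict = field(
        default_factory=lambda: {
            "intercept": 0.80,
            "confirming": -0.05,
            "difficulty": 0.04,
            "distance": -0.037,
            "uncertainty": -0.03,
            "reputation": -0.02,
            "helpfulness": -0.05,
        }
    )
    alpha_noise_sd: float = 0.05
    alpha_floor: float = 0.05
    # machine
    machine_method: Literal["ar1", "arima"] = "ar1"
    machine_noise_sd: float = 0.0
    machine_bias: float = 0.0
    # behavior
    activity_rate: float = 0.5
    skill_range: tuple[float, float] = (0.35, 0.85)
    skill_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_star <= 1:
            raise ValidationError("alpha_star must lie in (0, 1]")
        if self.sigma_prior < 0 or self.alpha_noise_sd < 0 or self.machine_noise_sd < 0:
            raise ValidationError("noise scales must be non-negative")
        if not 0 < self.activity_rate <= 1:
            raise ValidationError("activity_rate must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted values the pipeline should recover."""

    alpha_by_question: dict[str, float]
    covariates_by_question: dict[str, dict[str, float]]
    latent_skill: dict[str, float]
    prior_mu0: dict[str, float]


@dataclass
class Tournament:
    """A complete generated tournament."""

    config: SyntheticConfig
    questions: list[Question]
    history: dict[str, pd.Series]
    forecasts: list[ProbabilityForecast]
    machine_forecasts: list[MachineForecast]
    skill_questions: list[Question]
    skill_forecasts: list[ProbabilityForecast]
    truth: GroundTruth

    @property
    def users(self) -> list[str]:
        seen = {f.user_id for f in self.forecasts} | {
            f.user_id for f in self.skill_forecasts
        }
        return sorted(seen)


def _draw_duration(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    shape = (cfg.duration_mean / cfg.duration_sd) ** 2
    scale = cfg.duration_sd**2 / cfg.duration_mean
    while True:
        d = int(round(rng.gamma(shape, scale)))
        if d >= 7:
            return d


def _gen_series(
    t_start: dt.date, n_days: int, rng: np.random.Generator
) -> pd.Series:
    """Daily AR(1)-with-drift level series."""
    phi = rng.uniform(0.7, 0.95)
    drift = rng.normal(0.0, 0.05)
    sd = rng.uniform(1.0, 3.0)
    level = rng.uniform(50.0, 150.0)
    x = np.empty(n_days)
    x[0] = level
    shocks = rng.normal(0.0, sd, size=n_days)
    for t in range(1, n_days):
        x[t] = level + drift * t + phi * (x[t - 1] - level - drift * (t - 1)) + shocks[t]
    idx = [t_start + dt.timedelta(days=i) for i in range(n_days)]
    return pd.Series(x, index=idx)


def generate_questions(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[Question], dict[str, pd.Series]]:
    """Questions with daily historical series, bins from history quantiles.

    The series spans ``history_days`` before open through the close date;
    ``resolved_option`` is the bin containing the series value at close.
    """
    rng = rng or np.random.default_rng(config.seed)
    questions, history = [], {}
    for i in range(config.n_questions):
        qid = f"q{i:03d}"
        duration = _draw_duration(config, rng)
        t_open = config.start_date + dt.timedelta(
            days=int(rng.integers(0, config.open_span_days))
        )
        t_close = t_open + dt.timedelta(days=duration)
        series = _gen_series(
            t_open - dt.timedelta(days=config.history_days),
            config.history_days + duration + 1,
            rng,
        )
        n_options = int(rng.integers(2, 6))
        burn_in = series.iloc[: config.history_days].to_numpy()
        qs = np.linspace(0, 1, n_options + 1)[1:-1]
        edges = np.quantile(burn_in, qs)
        # enforce strictly increasing edges on near-degenerate histories
        for j in range(1, len(edges)):
            if edges[j] <= edges[j - 1]:
                edges[j] = edges[j - 1] + 1e-9
        resolved = int(np.searchsorted(edges, series.iloc[-1], side="right"))
        questions.append(
            Question(
                question_id=qid,
                n_options=n_options,
                t_open=t_open,
                t_close=t_close,
                is_ordinal=True,
                option_edges=tuple(edges),
                resolved_option=resolved,
                has_machine=True,
            )
        )
        history[qid] = series
    return questions, history


def _prior_mu(question: Question, mu0: float, drift_rate: float, day: dt.date) -> float:
    frac = (day - question.t_open).days / max(question.duration_days - 1, 1)
    return mu0 + drift_rate * (1.0 - mu0) * min(frac, 1.0)


def _spread_vector(p_correct: float, n: int, resolved: int) -> np.ndarray:
    probs = np.full(n, (1.0 - p_correct) / (n - 1))
    probs[resolved] = p_correct
    return probs


def _draw_condition_forecasts(
    question: Question,
    config: SyntheticConfig,
    rng: np.random.Generator,
    condition: str,
    mu0: float,
) -> tuple[list[dt.date], list[str], np.ndarray]:
    """Active (day, user) pairs and their clipped prior p_correct draws."""
    days = [
        question.t_open + dt.timedelta(days=i) for i in range(question.duration_days)
    ]
    users = [f"{condition[0]}{j:03d}" for j in range(config.n_users)]
    active = rng.random((len(days), len(users))) < config.activity_rate
    day_idx, user_idx = np.nonzero(active)
    mus = np.array(
        [_prior_mu(question, mu0, config.prior_drift_rate, days[i]) for i in day_idx]
    )
    draws = np.clip(rng.normal(mus, config.sigma_prior), 0.01, 0.99)
    return [days[i] for i in day_idx], [users[j] for j in user_idx], draws


def generate_control_forecasts(
    question: Question,
    config: SyntheticConfig,
    rng: np.random.Generator,
    mu0: float,
) -> list[ProbabilityForecast]:
    """Control-condition forecasts around the drifting group prior."""
    days, users, draws = _draw_condition_forecasts(question, config, rng, "control", mu0)
    noon = dt.time(12, 0)
    return [
        ProbabilityForecast(
            user_id=u,
            question_id=question.question_id,
            timestamp=dt.datetime.combine(d, noon),
            condition="control",
            probs=_spread_vector(p, question.n_options, question.resolved_option),
        )
        for d, u, p in zip(days, users, draws)
    ]


def generate_treatment_forecasts(
    question: Question,
    machine_by_day: dict[dt.date, MachineForecast],
    alpha: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    mu0: float,
) -> list[ProbabilityForecast]:
    """Treatment forecasts: independent prior blended with the day's machine."""
    if not 0 < alpha <= 1:
        raise ValidationError(f"planted alpha {alpha} outside (0, 1]")
    days, users, draws = _draw_condition_forecasts(
        question, config, rng, "treatment", mu0
    )
    noon = dt.time(12, 0)
    out = []
    for d, u, p in zip(days, users, draws):
        mf = machine_by_day.get(d)
        if mf is None:
            continue
        x = _spread_vector(p, question.n_options, question.resolved_option)
        y = alpha * x + (1.0 - alpha) * mf.probs
        out.append(
            ProbabilityForecast(
                user_id=u,
                question_id=question.question_id,
                timestamp=dt.datetime.combine(d, noon),
                condition="treatment",
                probs=y,
            )
        )
    return out


def _ar1_plugin_forecasts(
    question: Question,
    series: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[MachineForecast]:
    """Closed-form AR(1) predictive distribution, updated daily.

    Fits ``x_{t+1} = c + phi x_t + eps`` by least squares on the data seen
    through each day and propagates the h-step mean and variance
    analytically; near-unit-root fits fall back to a random walk with
    drift.  The machine-quality knobs corrupt the series it sees.
    """
    values_all = series.to_numpy()
    if config.machine_noise_sd > 0:
        values_all = values_all + rng.normal(0, config.machine_noise_sd, len(values_all))
    dates = list(series.index)
    out = []
    for t, day in enumerate(dates):
        if not question.is_open(day):
            continue
        x = values_all[: t + 1]
        h = max((question.t_close - day).days, 1)
        x0, x1 = x[:-1], x[1:]
        A = np.column_stack([np.ones_like(x0), x0])
        (c, phi), *_ = np.linalg.lstsq(A, x1, rcond=None)
        resid = x1 - (c + phi * x0)
        s2 = float(np.var(resid, ddof=2)) if len(resid) > 2 else 1.0
        if abs(phi) < 0.999:
            mean_h = c * (1 - phi**h) / (1 - phi) + phi**h * x[-1]
            var_h = s2 * (1 - phi ** (2 * h)) / (1 - phi**2)
        else:
            diffs = np.diff(x)
            mean_h = x[-1] + h * float(diffs.mean())
            var_h = h * float(np.var(diffs, ddof=1))
        mean_h += config.machine_bias
        sd = float(np.sqrt(max(var_h, 1e-6)))
        probs = forecast_to_bins(mean_h, sd, question.option_edges)
        out.append(
            MachineForecast(
                question_id=question.question_id,
                date=day,
                probs=probs,
                point_estimate=float(mean_h),
                interval_95=(mean_h - 1.96 * sd, mean_h + 1.96 * sd),
            )
        )
    return out


def generate_skill_questions(
    config: SyntheticConfig,
    rng: np.random.Generator,
    latent_skill: dict[str, float],
) -> tuple[list[Question], list[ProbabilityForecast]]:
    """Machine-free binary questions whose accuracy orders users by skill."""
    questions, forecasts = [], []
    users = sorted(latent_skill)
    noon = dt.time(12, 0)
    for i in range(config.n_independent_questions):
        qid = f"s{i:03d}"
        t_open = config.start_date + dt.timedelta(days=int(rng.integers(0, 30)))
        q = Question(
            question_id=qid,
            n_options=2,
            t_open=t_open,
            t_close=t_open + dt.timedelta(days=7),
            is_ordinal=False,
            option_edges=None,
            resolved_option=int(rng.integers(0, 2)),
            has_machine=False,
        )
        questions.append(q)
        draws = np.clip(
            rng.normal([latent_skill[u] for u in users], config.skill_noise_sd),
            0.01,
            0.99,
        )
        for u, p in zip(users, draws):
            forecasts.append(
                ProbabilityForecast(
                    user_id=u,
                    question_id=qid,
                    timestamp=dt.datetime.combine(q.t_open, noon),
                    condition="control" if u.startswith("c") else "treatment",
                    probs=_spread_vector(p, 2, q.resolved_option),
                )
            )
    return questions, forecasts


def _planted_alpha(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[float, dict[str, float]]:
    if config.alpha_process == "constant":
        return config.alpha_star, {}
    cov = {
        name: (float(rng.integers(0, 2)) if name == "confirming" else float(rng.normal()))
        for name in ALPHA_COVARIATES
    }
    beta = config.alpha_beta
    alpha = beta["intercept"] + sum(beta[k] * cov[k] for k in ALPHA_COVARIATES)
    alpha += rng.normal(0.0, config.alpha_noise_sd)
    return float(np.clip(alpha, config.alpha_floor, 1.0)), cov


def generate_tournament(config: SyntheticConfig) -> Tournament:
    """Generate a full tournament; bit-identical for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    questions, history = generate_questions(config, rng)

    alpha_by_q: dict[str, float] = {}
    cov_by_q: dict[str, dict[str, float]] = {}
    mu0_by_q: dict[str, float] = {}
    forecasts: list[ProbabilityForecast] = []
    machine_forecasts: list[MachineForecast] = []

    for q in questions:
        series = history[q.question_id]
        if config.machine_method == "ar1":
            mfs = _ar1_plugin_forecasts(q, series, config, rng)
        else:
            mfs = daily_machine_forecasts(q, series)
        machine_forecasts.extend(mfs)
        by_day = {m.date: m for m in mfs}

        mu0 = float(rng.uniform(*config.prior_initial_range))
        mu0_by_q[q.question_id] = mu0
        alpha, cov = _planted_alpha(config, rng)
        alpha_by_q[q.question_id] = alpha
        cov_by_q[q.question_id] = cov

        forecasts.extend(generate_control_forecasts(q, config, rng, mu0))
        forecasts.extend(
            generate_treatment_forecasts(q, by_day, alpha, config, rng, mu0)
        )

    lo, hi = config.skill_range
    latent = {}
    for cond in ("c", "t"):
        for j in range(config.n_users):
            latent[f"{cond}{j:03d}"] = float(rng.uniform(lo, hi))
    skill_questions, skill_forecasts = generate_skill_questions(config, rng, latent)

    return Tournament(
        config=config,
        questions=questions,
        history=history,
        forecasts=forecasts,
        machine_forecasts=machine_forecasts,
        skill_questions=skill_questions,
        skill_forecasts=skill_forecasts,
        truth=GroundTruth(
            alpha_by_question=alpha_by_q,
            covariates_by_question=cov_by_q,
            latent_skill=latent,
            prior_mu0=mu0_by_q,
        ),
    )
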