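"""Maximum-likelihood estimation of the trust weight placed on machine advice.

The belief-combination model: a forecaster exposed to machine advice
reports ``y = alpha * x + (1 - alpha) * m``, where ``x`` is the (latent)
prior belief, ``m`` the machine forecast of the day, and ``alpha`` in
``(0, 1]`` the weight kept on the prior.  Priors are taken to be normally
distributed, ``x ~ N(mu, sigma^2)``, with ``mu`` and ``sigma^2`` plugged
in from the realized forecasts of the unexposed control group, so the
exposed (treatment) forecasts follow

    y_i ~ N(alpha * mu + (1 - alpha) * m_i,  alpha^2 * sigma^2).

To sidestep sparse data and singular covariances, forecasts over 2-5
answer options are first collapsed to a binary question — the probability
placed on the (eventually) correct option versus everything else — which
makes the likelihood univariate.  ``alpha`` is estimated per question and
rolling time window (optionally per skill stratum, with stratum-specific
control priors) by bounded scalar maximization of the log-likelihood on
``[alpha_floor, 1]``; the density is singular at 0 and weights above 1
(anti-machine contrarianism) are outside the model.

Estimation is retrospective: the projection needs the resolved option.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import ttest_ind

from .scoring import SkillLabel
from .types import (
    MachineForecast,
    PipelineConfig,
    ProbabilityForecast,
    Question,
    TimeWindow,
    ValidationError,
    WindowSetting,
)

__all__ = [
    "WindowPrior",
    "InfluenceEstimate",
    "project_binary",
    "build_windows",
    "estimate_prior",
    "log_likelihood",
    "estimate_alpha",
    "estimate_question",
    "estimate_tournament",
    "compare_condition_variances",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class WindowPrior:
    """Plug-in prior for one window: moments of control-group projections."""

    mu: float
    sigma2: float
    n_control: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma2": self.sigma2,
            "n_control": self.n_control,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class InfluenceEstimate:
    """Estimated trust weight for one (question, window, stratum)."""

    question_id: str
    window: TimeWindow
    stratum: str
    alpha_hat: float
    log_likelihood: float
    n_treatment: int
    prior: WindowPrior

    def to_dict(self) -> dict:
        return {
            "question_id": self.question_id,
            "window": {
                "start": self.window.start.isoformat(),
                "end": self.window.end.isoformat(),
                "setting": self.window.setting,
            },
            "stratum": self.stratum,
            "alpha_hat": self.alpha_hat,
            "log_likelihood": self.log_likelihood,
            "n_treatment": self.n_treatment,
            "prior": self.prior.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InfluenceEstimate":
        w = d["window"]
        return cls(
            question_id=d["question_id"],
            window=TimeWindow(
                question_id=d["question_id"],
                start=dt.date.fromisoformat(w["start"]),
                end=dt.date.fromisoformat(w["end"]),
                setting=w["setting"],
            ),
            stratum=d["stratum"],
            alpha_hat=d["alpha_hat"],
            log_likelihood=d["log_likelihood"],
            n_treatment=d["n_treatment"],
            prior=WindowPrior(**d["prior"]),
        )


def project_binary(probs: np.ndarray, resolved_option: int | None) -> float:
    """Probability placed on the correct option (the binary collapse)."""
    if resolved_option is None:
        raise ValidationError("binary projection requires a resolved question")
    probs = np.asarray(probs, dtype=float)
    if not 0 <= resolved_option < len(probs):
        raise ValidationError("resolved option index out of range")
    return float(probs[resolved_option])


def window_length_days(duration_days: int, setting: WindowSetting) -> int:
    if setting == "weekly":
        return 7
    quarter = math.ceil(duration_days / 4)
    if setting == "quarter_duration":
        return quarter
    if setting == "max_of_both":
        return max(7, quarter)
    raise ValidationError(f"unknown window setting {setting!r}")


def build_windows(
    question: Question,
    setting: WindowSetting = "max_of_both",
    stride_days: int = 7,
) -> list[TimeWindow]:
    """Trailing rolling windows over a question's open span.

    Window length L is 7 days (weekly), one fourth of the question's
    duration (quarter_duration), or the maximum of the two (max_of_both,
    the default setting).  Windows are end-inclusive, advanced by
    ``stride_days``, and clipped to the open span; a question shorter than
    L yields a single full-span window.  Filtering of windows with too few
    forecasts happens at estimation time, where the forecasts are known.
    """
    duration = question.duration_days
    L = window_length_days(duration, setting)
    last_day = question.t_close - dt.timedelta(days=1)  # half-open span
    if duration <= L:
        return [
            TimeWindow(question.question_id, question.t_open, last_day, setting)
        ]
    windows = []
    end = question.t_open + dt.timedelta(days=L - 1)
    while end <= last_day:
        windows.append(
            TimeWindow(
                question.question_id, end - dt.timedelta(days=L - 1), end, setting
            )
        )
        end += dt.timedelta(days=stride_days)
    if windows and windows[-1].end < last_day:  # cover the closing days
        windows.append(
            TimeWindow(
                question.question_id, last_day - dt.timedelta(days=L - 1), last_day, setting
            )
        )
    return windows


def estimate_prior(projections: Sequence[float]) -> WindowPrior:
    """Sample mean and unbiased variance of control projections in a window.

    A degenerate (zero-variance) window gets its variance floored at 1e-6
    and flagged, keeping the likelihood finite.
    """
    arr = np.asarray(projections, dtype=float)
    if len(arr) < 2:
        raise ValidationError("prior estimation needs at least 2 control projections")
    mu = float(arr.mean())
    sigma2 = float(arr.var(ddof=1))
    degenerate = sigma2 < _VAR_FLOOR
    return WindowPrior(
        mu=mu,
        sigma2=max(sigma2, _VAR_FLOOR),
        n_control=len(arr),
        degenerate=degenerate,
    )


def log_likelihood(
    alpha: float,
    treatment: np.ndarray | Sequence[float],
    machine: np.ndarray | Sequence[float],
    prior: WindowPrior,
) -> float:
    """Log-likelihood of the treatment projections at a given trust weight.

    Each projection ``y_i`` is paired with the machine projection of its
    own day; the model density is Normal(alpha*mu + (1-alpha)*m_i,
    alpha^2 * sigma^2).  Undefined at alpha <= 0 (the variance collapses).
    """
    if alpha <= 0:
        raise ValidationError("log-likelihood undefined at alpha <= 0")
    y = np.asarray(treatment, dtype=float)
    m = np.asarray(machine, dtype=float)
    if y.shape != m.shape:
        raise ValidationError("treatment and machine projections must align")
    var = alpha * alpha * prior.sigma2
    resid = y - alpha * prior.mu - (1.0 - alpha) * m
    return float(
        -0.5 * len(y) * np.log(2.0 * np.pi * var) - 0.5 * np.sum(resid * resid) / var
    )


def _grid_argmax(
    treatment: np.ndarray, machine: np.ndarray, prior: WindowPrior, floor: float
) -> float:
    grid = np.arange(floor, 1.0 + 5e-4, 0.001)
    grid[-1] = 1.0
    vals = [log_likelihood(a, treatment, machine, prior) for a in grid]
    return float(grid[int(np.argmax(vals))])


def estimate_alpha(
    window: TimeWindow,
    treatment: Sequence[float],
    machine: Sequence[float],
    prior: WindowPrior,
    stratum: str = "all",
    alpha_floor: float = 0.01,
) -> InfluenceEstimate:
    """Bounded scalar MLE of the trust weight on ``[alpha_floor, 1]``.

    Falls back to a 0.001-step grid search if the optimizer fails; the
    optimum always matches such a grid within 0.002 (tested invariant).
    """
    y = np.asarray(treatment, dtype=float)
    m = np.asarray(machine, dtype=float)
    try:
        res = minimize_scalar(
            lambda a: -log_likelihood(a, y, m, prior),
            bounds=(alpha_floor, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(res.message)
        alpha_hat = float(np.clip(res.x, alpha_floor, 1.0))
    except (RuntimeError, ValueError) as exc:
        logger.warning("scalar optimizer failed (%s); using grid search", exc)
        alpha_hat = _grid_argmax(y, m, prior, alpha_floor)
    # the boundary can beat an interior stationary point
    for boundary in (alpha_floor, 1.0):
        if log_likelihood(boundary, y, m, prior) > log_likelihood(alpha_hat, y, m, prior):
            alpha_hat = boundary
    return InfluenceEstimate(
        question_id=window.question_id,
        window=window,
        stratum=stratum,
        alpha_hat=alpha_hat,
        log_likelihood=log_likelihood(alpha_hat, y, m, prior),
        n_treatment=len(y),
        prior=prior,
    )


# ---------------------------------------------------------------------------
# pipeline drivers


def _machine_by_day(
    machine_forecasts: Sequence[MachineForecast],
) -> dict[str, dict[dt.date, MachineForecast]]:
    by: dict[str, dict[dt.date, MachineForecast]] = {}
    for mf in machine_forecasts:
        by.setdefault(mf.question_id, {})[mf.date] = mf
    return by


def machine_on_day(
    by_day: Mapping[dt.date, MachineForecast], day: dt.date
) -> MachineForecast | None:
    """Same-day machine forecast, else the nearest earlier day."""
    if day in by_day:
        return by_day[day]
    earlier = [d for d in by_day if d < day]
    if not earlier:
        return None
    return by_day[max(earlier)]


def estimate_question(
    question: Question,
    forecasts: Sequence[ProbabilityForecast],
    machine_by_day: Mapping[dt.date, MachineForecast],
    config: PipelineConfig,
    skill_labels: Mapping[str, SkillLabel] | None = None,
) -> list[InfluenceEstimate]:
    """All window/stratum trust-weight estimates for one resolved question.

    Windows with fewer than ``config.min_forecasts`` forecasts in either
    condition (within the stratum) are discarded.  Without skill labels a
    single "all" stratum is used; with labels, both the control prior and
    the treatment forecasts are restricted to the stratum.
    """
    if question.resolved_option is None:
        raise ValidationError(f"{question.question_id}: estimation requires resolution")
    strata = ["all"] if skill_labels is None else ["high", "low"]
    estimates: list[InfluenceEstimate] = []
    qf = [f for f in forecasts if f.question_id == question.question_id]
    for window in build_windows(question, config.window_setting, config.stride_days):
        in_win = [f for f in qf if window.contains(f.date)]
        for stratum in strata:
            if skill_labels is None:
                sf = in_win
            else:
                sf = [
                    f
                    for f in in_win
                    if f.user_id in skill_labels
                    and skill_labels[f.user_id].stratum == stratum
                ]
            control = [f for f in sf if f.condition == "control"]
            treatment = [f for f in sf if f.condition == "treatment"]
            if len(control) < config.min_forecasts or len(treatment) < config.min_forecasts:
                continue
            pairs = [
                (f, machine_on_day(machine_by_day, f.date)) for f in treatment
            ]
            pairs = [(f, mf) for f, mf in pairs if mf is not None]
            if len(pairs) < config.min_forecasts:
                continue
            prior = estimate_prior(
                [project_binary(f.probs, question.resolved_option) for f in control]
            )
            y = [project_binary(f.probs, question.resolved_option) for f, _ in pairs]
            m = [project_binary(mf.probs, question.resolved_option) for _, mf in pairs]
            estimates.append(
                estimate_alpha(
                    window, y, m, prior, stratum=stratum, alpha_floor=config.alpha_floor
                )
            )
    return estimates


def estimate_tournament(
    questions: Sequence[Question],
    forecasts: Sequence[ProbabilityForecast],
    machine_forecasts: Sequence[MachineForecast],
    config: PipelineConfig | None = None,
    skill_labels: Mapping[str, SkillLabel] | None = None,
) -> list[InfluenceEstimate]:
    """Trust-weight estimates across every resolved machine-paired question."""
    config = config or PipelineConfig()
    by_q = _machine_by_day(machine_forecasts)
    by_question_forecasts: dict[str, list[ProbabilityForecast]] = {}
    for f in forecasts:
        by_question_forecasts.setdefault(f.question_id, []).append(f)
    out: list[InfluenceEstimate] = []
    for q in questions:
        if not q.has_machine or q.resolved_option is None:
            continue
        out.extend(
            estimate_question(
                q,
                by_question_forecasts.get(q.question_id, []),
                by_q.get(q.question_id, {}),
                config,
                skill_labels,
            )
        )
    return out


@dataclass(frozen=True)
class VarianceComparison:
    """Condition-wise mean per-question forecast variance and its t-test."""

    mean_var_control: float
    mean_var_treatment: float
    t_statistic: float
    p_value: float
    n_questions: int

    def to_dict(self) -> dict:
        return {
            "mean_var_control": self.mean_var_control,
            "mean_var_treatment": self.mean_var_treatment,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_questions": self.n_questions,
        }


def compare_condition_variances(
    questions: Sequence[Question],
    forecasts: Sequence[ProbabilityForecast],
) -> VarianceComparison:
    """Validation check: machine exposure shrinks forecast dispersion.

    Under the belief-combination model the treatment variance of the
    correct-option probability is ``alpha^2`` times the control variance,
    so with any alpha < 1 the treatment condition is strictly less
    dispersed.  Dispersion is the diversity of contemporaneous opinion:
    per question, the variance of same-day projections is computed for
    each day with at least two forecasts and averaged over days (the
    group prior drifts day to day, so pooling across days would mix
    opinion diversity with the prior's motion).  A two-sample t-test
    compares the per-question variances between conditions.
    """
    resolved = [q for q in questions if q.resolved_option is not None and q.has_machine]
    if len(resolved) < 2:
        raise ValidationError("variance comparison needs at least 2 resolved questions")
    by_q: dict[str, dict[str, dict[dt.date, list[float]]]] = {
        q.question_id: {"control": {}, "treatment": {}} for q in resolved
    }
    res_opt = {q.question_id: q.resolved_option for q in resolved}
    for f in forecasts:
        if f.question_id in by_q:
            by_q[f.question_id][f.condition].setdefault(f.date, []).append(
                project_binary(f.probs, res_opt[f.question_id])
            )
    var_c, var_t = [], []
    for qid, d in by_q.items():
        daily_c = [np.var(v, ddof=1) for v in d["control"].values() if len(v) >= 2]
        daily_t = [np.var(v, ddof=1) for v in d["treatment"].values() if len(v) >= 2]
        if daily_c and daily_t:
            var_c.append(float(np.mean(daily_c)))
            var_t.append(float(np.mean(daily_t)))
    if len(var_c) < 2:
        raise ValidationError("too few questions with forecasts in both conditions")
    t, p = ttest_ind(var_t, var_c)
    return VarianceComparison(
        mean_var_control=float(np.mean(var_c)),
        mean_var_treatment=float(np.mean(var_t)),
        t_statistic=float(t),
        p_value=float(p),
        n_questions=len(var_c),
    )
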