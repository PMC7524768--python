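"""The eight regression predictors, one row per (question, window, stratum).

Each trust-weight estimate is paired with the cognitive covariates
computed from the same window:

* **uncertainty** — mean of the per-option variances of the control
  group's forecast vectors (diagonal of their covariance matrix): how
  much contemporaneous opinion diverges.
* **difficulty** — mean Brier score of the control group's forecasts
  (prior beliefs) in the window; ordinal variant for ordinal questions.
* **confirming** — whether the machine forecast lies at least as close to
  the reference group's nearest one-hot extreme as the reference mean
  forecast itself (the operational definition of the machine "agreeing"
  with the crowd).
* **helpfulness** — fraction of control users the machine outperformed in
  the window (ties count half): the machine's quantile in the human
  accuracy distribution.
* **lifetime** — fraction of the question's span elapsed at window end.
* **distance** — mean Euclidean distance between cumulative machine and
  cumulative control forecast vectors (same-day pairing).
* **machine reputation** — negative mean machine Brier over questions
  already resolved when the current question opened (no look-ahead);
  imputed with the eventual global mean when no prior history exists.
* **skill** — the stratum label carried over from the estimate.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .influence import InfluenceEstimate, machine_on_day
from .scoring import SkillLabel, brier
from .types import (
    MachineForecast,
    PipelineConfig,
    ProbabilityForecast,
    Question,
    TimeWindow,
    ValidationError,
)

__all__ = [
    "uncertainty",
    "difficulty",
    "confirming",
    "helpfulness",
    "lifetime",
    "distance",
    "machine_reputation",
    "machine_question_brier",
    "build_covariate_table",
]


def uncertainty(control_probs: Sequence[np.ndarray], ddof: int = 1) -> float:
    """Mean per-option variance across control forecast vectors."""
    arr = np.asarray(control_probs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("uncertainty needs >= 2 full forecast vectors")
    return float(arr.var(axis=0, ddof=ddof).mean())


def difficulty(
    control_probs: Sequence[np.ndarray], question: Question
) -> float:
    """Mean per-forecast Brier of control priors in the window."""
    if question.resolved_option is None:
        raise ValidationError("difficulty requires a resolved question")
    return float(
        np.mean([brier(p, question.resolved_option, question) for p in control_probs])
    )


def nearest_extreme(p: np.ndarray) -> np.ndarray:
    """Closest one-hot vertex of the simplex (lowest index on ties)."""
    p = np.asarray(p, dtype=float)
    x = np.zeros_like(p)
    x[int(np.argmax(p))] = 1.0
    return x


def confirming(m: np.ndarray, p: np.ndarray) -> int:
    """1 iff the machine is at least as close to p's nearest extreme as p."""
    x = nearest_extreme(p)
    return int(np.linalg.norm(x - np.asarray(m)) <= np.linalg.norm(x - np.asarray(p)))


def helpfulness(user_briers: Sequence[float], machine_brier: float) -> float:
    """Machine's quantile among control users: P(user worse), ties half."""
    arr = np.asarray(user_briers, dtype=float)
    if len(arr) == 0:
        raise ValidationError("helpfulness needs at least one scored control user")
    return float(np.mean((arr > machine_brier) + 0.5 * (arr == machine_brier)))


def lifetime(window: TimeWindow, question: Question) -> float:
    """Fraction of the question's total span elapsed at window end."""
    return (window.end - question.t_open).days / question.duration_days


def _cum(v: np.ndarray) -> np.ndarray:
    return np.cumsum(np.asarray(v, dtype=float))


def distance(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Mean cumulative-probability Euclidean distance over (machine, human) pairs."""
    if not pairs:
        raise ValidationError("distance needs at least one forecast pair")
    return float(
        np.mean([np.linalg.norm(_cum(m) - _cum(p)) for m, p in pairs])
    )


def machine_question_brier(
    question: Question, machine_forecasts: Sequence[MachineForecast]
) -> float:
    """Machine accuracy over a question's life (time-averaged Brier)."""
    probs = [m.probs for m in machine_forecasts if m.question_id == question.question_id]
    if not probs:
        raise ValidationError(f"no machine forecasts for {question.question_id}")
    return brier(probs, question.resolved_option, question)


def machine_reputation(
    question: Question,
    questions: Sequence[Question],
    machine_briers: Mapping[str, float],
    fallback: Literal["global_mean", "zero"] = "global_mean",
) -> tuple[float, bool]:
    """Negative mean machine Brier on questions resolved before this one opened.

    Returns ``(value, imputed)``; with no prior resolutions the eventual
    global mean (or zero) stands in and the flag is set.
    """
    prior = [
        machine_briers[q.question_id]
        for q in questions
        if q.question_id in machine_briers
        and q.question_id != question.question_id
        and q.t_close <= question.t_open
    ]
    if prior:
        return float(-np.mean(prior)), False
    if fallback == "zero" or not machine_briers:
        return 0.0, True
    return float(-np.mean(list(machine_briers.values()))), True


def build_covariate_table(
    estimates: Sequence[InfluenceEstimate],
    questions: Sequence[Question],
    forecasts: Sequence[ProbabilityForecast],
    machine_forecasts: Sequence[MachineForecast],
    config: PipelineConfig | None = None,
    skill_labels: Mapping[str, SkillLabel] | None = None,
) -> pd.DataFrame:
    """One regression observation per trust-weight estimate.

    Rows whose window lacks the forecasts a covariate needs (e.g. fewer
    than two control vectors for uncertainty) are dropped.
    """
    config = config or PipelineConfig()
    qmap = {q.question_id: q for q in questions}
    mf_by_q: dict[str, dict[dt.date, MachineForecast]] = {}
    for m in machine_forecasts:
        mf_by_q.setdefault(m.question_id, {})[m.date] = m
    f_by_q: dict[str, list[ProbabilityForecast]] = {}
    for f in forecasts:
        f_by_q.setdefault(f.question_id, []).append(f)

    machine_briers = {
        qid: machine_question_brier(qmap[qid], list(by_day.values()))
        for qid, by_day in mf_by_q.items()
        if qid in qmap and qmap[qid].resolved_option is not None
    }

    rows = []
    for est in estimates:
        q = qmap[est.question_id]
        window = est.window
        in_win = [f for f in f_by_q.get(q.question_id, []) if window.contains(f.date)]
        if skill_labels is not None and est.stratum in ("high", "low"):
            in_win = [
                f
                for f in in_win
                if f.user_id in skill_labels
                and skill_labels[f.user_id].stratum == est.stratum
            ]
        control = [f for f in in_win if f.condition == "control"]
        reference = [
            f for f in in_win if f.condition == config.confirmation_reference
        ]
        by_day = mf_by_q.get(q.question_id, {})
        machine_days = [
            machine_on_day(by_day, d)
            for d in sorted({f.date for f in in_win})
        ]
        machine_days = [m for m in machine_days if m is not None]
        if len(control) < 2 or not reference or not machine_days:
            continue

        control_probs = [f.probs for f in control]
        m_mean = np.mean([m.probs for m in machine_days], axis=0)
        ref_mean = np.mean([f.probs for f in reference], axis=0)

        per_user: dict[str, list[float]] = {}
        pairs = []
        for f in control:
            per_user.setdefault(f.user_id, []).append(
                brier(f.probs, q.resolved_option, q)
            )
            mf = machine_on_day(by_day, f.date)
            if mf is not None:
                pairs.append((mf.probs, f.probs))
        user_briers = [float(np.mean(v)) for _, v in sorted(per_user.items())]
        window_machine_brier = float(
            np.mean([brier(m.probs, q.resolved_option, q) for m in machine_days])
        )
        reputation, imputed = machine_reputation(
            q, questions, machine_briers, config.reputation_fallback
        )
        rows.append(
            {
                "question_id": q.question_id,
                "window_start": window.start,
                "window_end": window.end,
                "skill": est.stratum,
                "alpha": est.alpha_hat,
                "confirming": confirming(m_mean, ref_mean),
                "difficulty": difficulty(control_probs, q),
                "distance": distance(pairs),
                "uncertainty": uncertainty(control_probs),
                "reputation": reputation,
                "reputation_imputed": imputed,
                "helpfulness": helpfulness(user_briers, window_machine_brier),
                "lifetime": lifetime(window, q),
            }
        )
    return pd.DataFrame(rows)
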