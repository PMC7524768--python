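"""Forecast accuracy: Brier scores and the forecaster skill split.

Two variants of the Brier score are used throughout:

* **density** — for a forecast ``p`` and one-hot outcome ``o``,
  ``sum_i (p_i - o_i)^2``, in ``[0, 2]``; a forecast *series* over a
  question is scored by the time average of the per-day scores.
* **ordinal** — the same squared error applied to the *cumulative*
  probability vectors, so a miss into an adjacent bin of an ordered
  question is penalized less than a miss into a distant bin.  The final
  cumulative component is identically 1 and contributes 0; the range is
  ``[0, n_options - 1]`` and for binary questions the ordinal score equals
  exactly half the density score.

Skill is assessed on the independent (machine-free) question set: per-
question scores are normalized across users, averaged per user, and the
population is median-split into high and low skill (lower score = better).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .types import ProbabilityForecast, Question, ValidationError

__all__ = [
    "brier_density",
    "brier_ordinal",
    "brier",
    "SkillLabel",
    "skill_split",
]

Variant = Literal["density", "ordinal"]


def _one_hot(n: int, index: int) -> np.ndarray:
    if not 0 <= index < n:
        raise ValidationError(f"outcome index {index} out of range for {n} options")
    o = np.zeros(n)
    o[index] = 1.0
    return o


def brier_density(
    probs: np.ndarray | Sequence[np.ndarray], outcome: int
) -> float:
    """Density-form Brier score of one forecast or a series of forecasts.

    A series is averaged over its days (each element one forecast vector).
    """
    arr = np.atleast_2d(np.asarray(probs, dtype=float))
    if arr.size == 0:
        raise ValidationError("cannot score an empty forecast series")
    o = _one_hot(arr.shape[1], outcome)
    return float(np.mean(np.sum((arr - o) ** 2, axis=1)))


def brier_ordinal(
    probs: np.ndarray | Sequence[np.ndarray], outcome: int
) -> float:
    """Cumulative-probability Brier score for ordered answer options."""
    arr = np.atleast_2d(np.asarray(probs, dtype=float))
    if arr.size == 0:
        raise ValidationError("cannot score an empty forecast series")
    cum_p = np.cumsum(arr, axis=1)
    cum_o = np.cumsum(_one_hot(arr.shape[1], outcome))
    return float(np.mean(np.sum((cum_p - cum_o) ** 2, axis=1)))


def brier(
    probs: np.ndarray | Sequence[np.ndarray],
    outcome: int,
    question: Question | None = None,
    variant: Variant | None = None,
) -> float:
    """Score with the variant appropriate to the question.

    Ordinal questions use the cumulative form; categorical questions always
    use the density form.  Requesting the ordinal variant for a categorical
    question is an error directing the caller to the density form.
    """
    if variant is None:
        if question is None:
            raise ValidationError("need a question or an explicit variant")
        variant = "ordinal" if question.is_ordinal else "density"
    if variant == "ordinal":
        if question is not None and not question.is_ordinal:
            raise ValidationError(
                "ordinal Brier requires ordered options; use the density variant"
            )
        return brier_ordinal(probs, outcome)
    return brier_density(probs, outcome)


@dataclass(frozen=True)
class SkillLabel:
    user_id: str
    normalized_score: float
    stratum: Literal["high", "low"]


def skill_split(
    forecasts: Sequence[ProbabilityForecast],
    questions: Sequence[Question],
    normalization: Literal["zscore", "rank", "raw"] = "zscore",
) -> dict[str, SkillLabel]:
    """Median-split users by accuracy on the independent question set.

    Per resolved question, each user's forecasts are scored (density form —
    the independent questions are mostly categorical) and averaged; scores
    are then normalized across the users of that question (default:
    z-scores, which removes question-difficulty level differences), and
    averaged per user.  Users at or below the median normalized score are
    labeled ``high`` (lower is better); exact median ties are broken
    deterministically by ``user_id`` order so the split is reproducible.

    Users with no resolved forecast are excluded.
    """
    qmap: Mapping[str, Question] = {q.question_id: q for q in questions}
    # per (question, user) mean score
    per_q: dict[str, dict[str, list[float]]] = {}
    for f in forecasts:
        q = qmap.get(f.question_id)
        if q is None or q.resolved_option is None:
            continue
        per_q.setdefault(q.question_id, {}).setdefault(f.user_id, []).append(
            brier_density(f.probs, q.resolved_option)
        )

    user_scores: dict[str, list[float]] = {}
    for qid, by_user in per_q.items():
        users = sorted(by_user)
        means = np.array([np.mean(by_user[u]) for u in users])
        if normalization == "zscore":
            sd = means.std(ddof=1) if len(means) > 1 else 0.0
            normed = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        elif normalization == "rank":
            order = means.argsort(kind="stable").argsort()
            normed = order / max(len(means) - 1, 1)
        elif normalization == "raw":
            normed = means
        else:
            raise ValidationError(f"unknown normalization {normalization!r}")
        for u, z in zip(users, normed):
            user_scores.setdefault(u, []).append(float(z))

    if not user_scores:
        raise ValidationError("no user has a resolved independent-question forecast")

    users = sorted(user_scores)
    mean_z = np.array([np.mean(user_scores[u]) for u in users])
    median = float(np.median(mean_z))
    labels: dict[str, SkillLabel] = {}
    n_high = 0
    target_high = (len(users) + 1) // 2
    for u, z in zip(users, mean_z):
        if z < median:
            stratum = "high"
        elif z > median:
            stratum = "low"
        else:  # exact ties at the median: fill 'high' in user_id order
            stratum = "high" if n_high < target_high else "low"
        if stratum == "high":
            n_high += 1
        labels[u] = SkillLabel(user_id=u, normalized_score=float(z), stratum=stratum)
    # users strictly below the median already counted toward target_high
    return labels
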