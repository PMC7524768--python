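"""Core domain types shared by all pipeline stages.

Forecasting questions, probabilistic forecasts (human and machine), rolling
time windows, and the pipeline configuration.  Conventions:

* Timestamps are calendar dates at daily resolution.  Intra-day ordering of
  forecasts is preserved in the input files but never used.
* A question is *open* on days ``d`` with ``t_open <= d < t_close``
  (half-open); resolution happens at ``t_close``.
* Every probability vector lives on the simplex: non-negative entries
  summing to 1 within ``SIMPLEX_TOL``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SIMPLEX_TOL",
    "Condition",
    "WindowSetting",
    "Question",
    "ProbabilityForecast",
    "MachineForecast",
    "TimeWindow",
    "PipelineConfig",
    "ValidationError",
]

#: tolerance on |sum(probs) - 1| before a forecast is rejected
SIMPLEX_TOL = 1e-6

Condition = Literal["control", "treatment"]
WindowSetting = Literal["weekly", "quarter_duration", "max_of_both"]


class ValidationError(ValueError):
    """A record violates a stated invariant (bad simplex, bad dates, ...)."""


def _check_simplex(probs: np.ndarray, tol: float = SIMPLEX_TOL) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1:
        raise ValidationError("probability vector must be one-dimensional")
    if np.any(probs < 0):
        raise ValidationError(f"negative probability in {probs}")
    s = probs.sum()
    if abs(s - 1.0) > tol:
        raise ValidationError(f"probabilities sum to {s:.8f}, not 1 within {tol}")
    if abs(s - 1.0) > 1e-12:  # renormalize material drift, keep exact vectors bitwise
        probs = probs / s
    return probs


@dataclass(frozen=True)
class Question:
    """A forecasting question with 2-5 answer options.

    Parameters
    ----------
    option_edges
        For ordinal questions: the ``n_options - 1`` strictly increasing
        numeric boundaries separating the answer-option bins (outer bins are
        open-ended).  For categorical questions: ``None``.
    resolved_option
        Index of the correct option once the question closes, else ``None``.
    has_machine
        ``False`` for independent skill-assessment questions, which have no
        historical data and no machine forecasts.
    """

    question_id: str
    n_options: int
    t_open: dt.date
    t_close: dt.date
    is_ordinal: bool = True
    option_edges: tuple[float, ...] | None = None
    resolved_option: int | None = None
    has_machine: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.n_options <= 5:
            raise ValidationError(
                f"{self.question_id}: n_options={self.n_options} outside [2, 5]"
            )
        if self.t_open >= self.t_close:
            raise ValidationError(f"{self.question_id}: t_open >= t_close")
        if self.is_ordinal:
            if self.option_edges is None or len(self.option_edges) != self.n_options - 1:
                raise ValidationError(
                    f"{self.question_id}: ordinal question needs n_options-1 edges"
                )
            edges = np.asarray(self.option_edges, dtype=float)
            if not np.all(np.diff(edges) > 0):
                raise ValidationError(f"{self.question_id}: edges not strictly increasing")
        if self.resolved_option is not None and not (
            0 <= self.resolved_option < self.n_options
        ):
            raise ValidationError(f"{self.question_id}: resolved_option out of range")

    @property
    def duration_days(self) -> int:
        return (self.t_close - self.t_open).days

    def is_open(self, day: dt.date) -> bool:
        return self.t_open <= day < self.t_close

    def bin_of(self, value: float) -> int:
        """Answer-option index containing a numeric value (ordinal only)."""
        if not self.is_ordinal or self.option_edges is None:
            raise ValidationError(f"{self.question_id}: bin_of requires an ordinal question")
        return int(np.searchsorted(np.asarray(self.option_edges), value, side="right"))


@dataclass(frozen=True)
class ProbabilityForecast:
    """A single human forecast: a point on the simplex with provenance."""

    user_id: str
    question_id: str
    timestamp: dt.datetime
    condition: Condition
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _check_simplex(self.probs))
        if self.condition not in ("control", "treatment"):
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def date(self) -> dt.date:
        return self.timestamp.date()

    @property
    def n_options(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class MachineForecast:
    """One day's machine forecast for a question.

    ``probs`` is the predictive mass over the answer options;
    ``point_estimate`` and ``interval_95`` describe the underlying numeric
    forecast that was discretized.
    """

    question_id: str
    date: dt.date
    probs: np.ndarray
    point_estimate: float
    interval_95: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _check_simplex(self.probs))
        lo, hi = self.interval_95
        if not (lo <= self.point_estimate <= hi):
            raise ValidationError(
                f"{self.question_id}@{self.date}: interval does not cover point estimate"
            )


@dataclass(frozen=True)
class TimeWindow:
    """A trailing, end-inclusive estimation window of L calendar days.

    Membership: day ``d`` belongs to the window iff ``start <= d <= end``,
    where ``end - start == L - 1`` days, so a weekly window covers 7 dates.
    """

    question_id: str
    start: dt.date
    end: dt.date
    setting: WindowSetting = "max_of_both"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.question_id}: window start after end")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class PipelineConfig:
    """Tunable analysis settings with the defaults used throughout.

    ``alpha_floor`` is the lower bound of the trust weight's search interval
    (the likelihood is singular at zero); ``min_forecasts`` is the per-
    condition count below which a window is discarded.
    """

    window_setting: WindowSetting = "max_of_both"
    stride_days: int = 7
    min_forecasts: int = 4
    alpha_floor: float = 0.01
    confirmation_reference: Literal["treatment", "control"] = "treatment"
    skill_normalization: Literal["zscore", "rank", "raw"] = "zscore"
    reputation_fallback: Literal["global_mean", "zero"] = "global_mean"
    cluster_se_by_question: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_floor <= 0:
            raise ValidationError("alpha_floor must be positive")
        if self.stride_days < 1:
            raise ValidationError("stride must be at least one day")
        if self.min_forecasts < 1:
            raise ValidationError("min_forecasts must be at least 1")


def mean_forecast(forecasts: Sequence[ProbabilityForecast]) -> np.ndarray:
    """Mean probability vector of a non-empty set of forecasts."""
    if not forecasts:
        raise ValidationError("cannot average an empty forecast set")
    return np.mean([f.probs for f in forecasts], axis=0)
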