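"""Daily probabilistic machine forecasts from historical time series.

The machine side of the hybrid system: fit an ARIMA model to a question's
daily history, forecast the quantity at resolution with its analytic
prediction variance, and discretize the (normal) predictive distribution
into the question's answer-option bins.

Order selection is a stepwise search minimizing AICc over ``p, q <= 3``
with the differencing order ``d <= 2`` chosen by repeated KPSS tests —
the convention of the standard automatic-selection packages.  Ties are
broken toward the smaller model.  As new data accrues the fitted model is
updated daily (Kalman-filter state extension); coefficients are re-fit on
a configurable cadence.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, InterpolationWarning
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import kpss

from .types import MachineForecast, Question, ValidationError

__all__ = [
    "FittedSeriesModel",
    "fit_series_model",
    "forecast_to_bins",
    "daily_machine_forecasts",
]

_FIT_WARNINGS = (ConvergenceWarning, InterpolationWarning, UserWarning, RuntimeWarning)


@dataclass
class FittedSeriesModel:
    """An ARIMA fit: selected orders, coefficients and residual scale.

    ``degenerate`` marks a constant input series, for which the model is a
    point mass at the constant (zero residual variance).
    """

    order: tuple[int, int, int]
    params: np.ndarray
    resid_sd: float
    aicc: float
    degenerate: bool = False
    _result: object | None = field(default=None, repr=False, compare=False)

    def forecast(self, horizon: int) -> tuple[float, float]:
        """Point forecast and forecast standard deviation ``horizon`` steps out.

        The sd uses the model's analytic forecast-variance growth, so
        longer horizons widen the predictive distribution consistently.
        """
        if horizon < 1:
            raise ValidationError("horizon must be >= 1 step")
        if self.degenerate:
            return float(self.params[0]), 0.0
        fc = self._result.get_forecast(horizon)  # type: ignore[attr-defined]
        return float(fc.predicted_mean[-1]), float(fc.se_mean[-1])

    def extended(self, new_values: Sequence[float]) -> "FittedSeriesModel":
        """Model updated with newly observed values (no re-estimation)."""
        if self.degenerate:
            return self
        res = self._result.append(np.asarray(new_values, float), refit=False)  # type: ignore[attr-defined]
        return FittedSeriesModel(
            order=self.order,
            params=self.params,
            resid_sd=self.resid_sd,
            aicc=self.aicc,
            _result=res,
        )


def _kpss_d(values: np.ndarray, max_d: int) -> int:
    """Differencing order by repeated KPSS stationarity tests."""
    d = 0
    x = values.astype(float)
    while d < max_d:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", _FIT_WARNINGS)
            try:
                _, pvalue, *_ = kpss(x, regression="c", nlags="auto")
            except (ValueError, OverflowError):
                break
        if pvalue >= 0.05:  # cannot reject stationarity
            break
        d += 1
        x = np.diff(x)
    return d


def _fit_one(values: np.ndarray, order: tuple[int, int, int]):
    trend = "c" if order[1] == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", _FIT_WARNINGS)
        model = ARIMA(values, order=order, trend=trend)
        return model.fit(method_kwargs={"maxiter": 100})


def fit_series_model(
    history: Sequence[float] | np.ndarray | pd.Series,
    max_p: int = 3,
    max_q: int = 3,
    max_d: int = 2,
) -> FittedSeriesModel:
    """Select and fit an ARIMA model by stepwise AICc search.

    Starts from the usual seed set ``{(2,d,2), (1,d,1), (0,d,0), (1,d,0),
    (0,d,1)}`` and walks to neighboring orders while the criterion
    improves; exact ties go to the smaller model (fewer ``p+q`` terms).

    Requires at least 10 observations; a constant series yields a
    degenerate point-mass model.
    """
    values = np.asarray(
        history.to_numpy() if isinstance(history, pd.Series) else history, dtype=float
    )
    if len(values) < 10:
        raise ValidationError(f"need >= 10 observations, got {len(values)}")
    if np.ptp(values) == 0.0:
        return FittedSeriesModel(
            order=(0, 0, 0),
            params=np.array([values[-1], 0.0]),
            resid_sd=0.0,
            aicc=-np.inf,
            degenerate=True,
        )

    d = _kpss_d(values, max_d)
    cache: dict[tuple[int, int, int], tuple[float, object]] = {}

    def score(p: int, q: int) -> float:
        order = (p, d, q)
        if order in cache:
            return cache[order][0]
        if not (0 <= p <= max_p and 0 <= q <= max_q):
            return np.inf
        try:
            res = _fit_one(values, order)
            aicc = float(res.aicc)
            if not np.isfinite(aicc):
                aicc = np.inf
        except (ValueError, np.linalg.LinAlgError):
            aicc, res = np.inf, None
        cache[order] = (aicc, res)
        return aicc

    seeds = [(2, 2), (1, 1), (0, 0), (1, 0), (0, 1)]
    best = min(seeds, key=lambda pq: (score(*pq), pq[0] + pq[1]))
    while True:
        p, q = best
        neighbors = [
            (p + 1, q), (p - 1, q), (p, q + 1), (p, q - 1),
            (p + 1, q + 1), (p - 1, q - 1),
        ]
        candidates = [best] + [n for n in neighbors if n not in (best,)]
        new_best = min(candidates, key=lambda pq: (score(*pq), pq[0] + pq[1]))
        if new_best == best:
            break
        best = new_best

    aicc, res = cache[(best[0], d, best[1])]
    if res is None:
        res = _fit_one(values, (0, d, 0))  # guaranteed fallback
        best, aicc = (0, 0), float(res.aicc)
    resid_sd = float(np.sqrt(max(res.params[-1], 0.0)))  # sigma2 is last param
    return FittedSeriesModel(
        order=(best[0], d, best[1]),
        params=np.asarray(res.params),
        resid_sd=resid_sd,
        aicc=aicc,
        _result=res,
    )


def forecast_to_bins(
    point: float,
    sd: float,
    option_edges: Sequence[float],
    degenerate: bool = False,
) -> np.ndarray:
    """Discretize a normal predictive distribution into answer-option bins.

    Bin ``i`` receives the Normal(point, sd^2) mass between its edges; the
    outer bins take the open tails.  With ``degenerate`` (sd = 0) all mass
    goes to the bin containing the point.
    """
    edges = np.asarray(option_edges, dtype=float)
    if len(edges) == 0 or np.any(np.diff(edges) <= 0):
        raise ValidationError("option edges must be non-empty and strictly increasing")
    n = len(edges) + 1
    if sd <= 0:
        if not degenerate:
            raise ValidationError("sd must be positive unless the model is degenerate")
        probs = np.zeros(n)
        probs[int(np.searchsorted(edges, point, side="right"))] = 1.0
        return probs
    cdf = norm.cdf(edges, loc=point, scale=sd)
    probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    return probs / probs.sum()


def daily_machine_forecasts(
    question: Question,
    history: pd.Series,
    refit_every: int = 14,
    **fit_kwargs,
) -> list[MachineForecast]:
    """One machine forecast per open day of a question.

    On each day ``t`` with ``t_open <= t < t_close`` the model sees the
    history through ``t`` and forecasts the quantity at resolution
    (horizon ``t_close - t`` days).  Orders are selected on the first open
    day; coefficients are re-estimated every ``refit_every`` days and the
    Kalman state is extended with each new observation in between, so the
    forecast always conditions on the latest data.
    """
    if not question.is_ordinal or question.option_edges is None:
        raise ValidationError("machine forecasts require an ordinal question with edges")
    days = [d for d in history.index if question.is_open(d)]
    if not days:
        return []
    out: list[MachineForecast] = []
    model: FittedSeriesModel | None = None
    last_len = 0
    for i, day in enumerate(days):
        values = history[history.index <= day]
        if model is None or i % refit_every == 0:
            model = fit_series_model(values, **fit_kwargs)
        elif len(values) > last_len:
            model = model.extended(values.to_numpy()[last_len:])
        last_len = len(values)
        horizon = max((question.t_close - day).days, 1)
        point, sd = model.forecast(horizon)
        probs = forecast_to_bins(point, sd, question.option_edges, degenerate=model.degenerate)
        out.append(
            MachineForecast(
                question_id=question.question_id,
                date=day,
                probs=probs,
                point_estimate=point,
                interval_95=(point - 1.96 * sd, point + 1.96 * sd),
            )
        )
    return out
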