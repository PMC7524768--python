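"""Counterfactual accuracy impact of the cognitive factors.

Given a fitted trust-weight regression, the framework (i) predicts the
weight each (question, window, stratum) cell would apply from its
covariates, (ii) transforms the realized control forecasts into simulated
machine-exposed forecasts via the belief-combination rule
``y = alpha_hat * x + (1 - alpha_hat) * m``, and (iii) sweeps one
regression coefficient at a time over a grid, measuring the percent
change in Brier score relative to the learned-coefficient baseline.
Positive change = accuracy lost.  Results are stratified by machine
helpfulness (> 0.5: the machine beat most of the control group).

The transformation acts on realized control forecasts (a deterministic
mapping), not fresh prior draws, so sweep comparisons carry no Monte
Carlo noise, and stratification is fixed by the unmodified helpfulness
values so curves are continuous in the grid.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .influence import machine_on_day
from .regression import RegressionFit, design_matrix
from .scoring import brier
from .types import (
    MachineForecast,
    ProbabilityForecast,
    Question,
    ValidationError,
)

__all__ = [
    "predict_alpha",
    "simulate_exposure",
    "sweep_coefficient",
    "CounterfactualResult",
]

logger = logging.getLogger(__name__)


def predict_alpha(
    fit: RegressionFit,
    table: pd.DataFrame,
    alpha_floor: float = 0.01,
    overrides: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Linear-predictor trust weights, clamped to ``[alpha_floor, 1]``.

    ``table`` must already be standardized with the fit's transform;
    ``overrides`` replaces named coefficients (the sweep mechanism).
    """
    X = design_matrix(table, fit.model_id)
    params = dict(fit.params)
    if overrides:
        for name, value in overrides.items():
            if name not in params:
                raise ValidationError(f"fit has no coefficient named {name!r}")
            params[name] = value
    missing = [c for c in X.columns if c not in params]
    if missing:
        raise ValidationError(f"fit lacks coefficients for terms {missing}")
    beta = np.array([params[c] for c in X.columns])
    return np.clip(X.to_numpy() @ beta, alpha_floor, 1.0)


def simulate_exposure(
    control: Sequence[ProbabilityForecast],
    machine_by_day: Mapping[dt.date, MachineForecast],
    alpha_hat: float,
) -> list[np.ndarray]:
    """Map realized control forecasts to simulated machine-exposed ones.

    Each control vector ``x`` becomes ``alpha_hat*x + (1-alpha_hat)*m``
    with the same-day machine forecast (nearest earlier day when the same
    day is missing, logged); forecasts with no usable machine are skipped.
    """
    out = []
    for f in control:
        mf = machine_by_day.get(f.date)
        if mf is None:
            mf = machine_on_day(machine_by_day, f.date)
            if mf is None:
                continue
            logger.debug("no machine forecast on %s; using %s", f.date, mf.date)
        out.append(alpha_hat * f.probs + (1.0 - alpha_hat) * mf.probs)
    return out


@dataclass(frozen=True)
class CounterfactualResult:
    """Brier percent-change summary at one grid value of one coefficient."""

    coefficient: str
    grid_value: float
    stratum: str  # "high_quality" (helpfulness > 0.5) or "low_quality"
    median_pct_change: float
    iqr_lo: float
    iqr_hi: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "grid_value": self.grid_value,
            "stratum": self.stratum,
            "median_pct_change": self.median_pct_change,
            "iqr_lo": self.iqr_lo,
            "iqr_hi": self.iqr_hi,
            "n_cells": self.n_cells,
        }


def _cell_briers(
    table: pd.DataFrame,
    alphas: np.ndarray,
    questions: Mapping[str, Question],
    control_by_cell: Sequence[list[ProbabilityForecast]],
    machine_by_q: Mapping[str, Mapping[dt.date, MachineForecast]],
) -> np.ndarray:
    scores = np.full(len(table), np.nan)
    for i, (row, a) in enumerate(zip(table.itertuples(), alphas)):
        q = questions[row.question_id]
        sim = simulate_exposure(
            control_by_cell[i], machine_by_q.get(row.question_id, {}), float(a)
        )
        if sim:
            scores[i] = brier(sim, q.resolved_option, q)
    return scores


def sweep_coefficient(
    fit: RegressionFit,
    table: pd.DataFrame,
    questions: Sequence[Question],
    forecasts: Sequence[ProbabilityForecast],
    machine_forecasts: Sequence[MachineForecast],
    coefficient: str,
    grid: Sequence[float] | None = None,
    n_grid: int = 13,
    alpha_floor: float = 0.01,
) -> list[CounterfactualResult]:
    """Percent change in Brier vs the learned coefficient, per stratum.

    The default grid spans the learned value +/- 3 standard errors in
    ``n_grid`` steps and always includes the learned value itself, so the
    baseline point has exactly zero median change in both strata.
    Covariates are standardized once with the fit's transform and never
    re-standardized along the sweep.
    """
    if coefficient not in fit.params:
        raise ValidationError(f"fit has no coefficient named {coefficient!r}")
    learned = fit.params[coefficient]
    if grid is None:
        se = fit.bse.get(coefficient, 0.0) or abs(learned) or 1.0
        grid = np.linspace(learned - 3 * se, learned + 3 * se, n_grid)
        if not np.any(np.isclose(grid, learned)):
            grid = np.sort(np.append(grid, learned))
    grid = np.asarray(grid, dtype=float)
    if not np.any(np.isclose(grid, learned)):
        raise ValidationError("grid must include the learned coefficient value")

    work = fit.standardization.transform(table).reset_index(drop=True)
    qmap = {q.question_id: q for q in questions}
    machine_by_q: dict[str, dict[dt.date, MachineForecast]] = {}
    for m in machine_forecasts:
        machine_by_q.setdefault(m.question_id, {})[m.date] = m
    control_by_q: dict[str, list[ProbabilityForecast]] = {}
    for f in forecasts:
        if f.condition == "control":
            control_by_q.setdefault(f.question_id, []).append(f)
    control_by_cell = [
        [
            f
            for f in control_by_q.get(row.question_id, [])
            if row.window_start <= f.date <= row.window_end
        ]
        for row in table.itertuples()
    ]

    # stratification is fixed by the *unstandardized* helpfulness values
    high_quality = (table["helpfulness"] > 0.5).to_numpy()

    baseline_alpha = predict_alpha(fit, work, alpha_floor)
    baseline = _cell_briers(work, baseline_alpha, qmap, control_by_cell, machine_by_q)
    usable = np.isfinite(baseline) & (baseline > 0)

    results: list[CounterfactualResult] = []
    for g in grid:
        alphas = predict_alpha(fit, work, alpha_floor, overrides={coefficient: float(g)})
        scores = _cell_briers(work, alphas, qmap, control_by_cell, machine_by_q)
        pct = 100.0 * (scores - baseline) / baseline
        for stratum, mask in (
            ("high_quality", high_quality),
            ("low_quality", ~high_quality),
        ):
            sel = pct[mask & usable & np.isfinite(pct)]
            if len(sel) == 0:
                logger.warning("empty %s stratum at grid value %g", stratum, g)
                continue
            lo, med, hi = np.percentile(sel, [25, 50, 75])
            results.append(
                CounterfactualResult(
                    coefficient=coefficient,
                    grid_value=float(g),
                    stratum=stratum,
                    median_pct_change=float(med),
                    iqr_lo=float(lo),
                    iqr_hi=float(hi),
                    n_cells=int(len(sel)),
                )
            )
    return results


def plot_sweep(results: Sequence[CounterfactualResult], learned_value: float, path=None):
    """Render a sweep as median curves with IQR bands per quality stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for stratum, color in (("high_quality", "tab:blue"), ("low_quality", "tab:orange")):
        pts = sorted(
            (r for r in results if r.stratum == stratum), key=lambda r: r.grid_value
        )
        if not pts:
            continue
        xs = [r.grid_value for r in pts]
        ax.plot(xs, [r.median_pct_change for r in pts], color=color, label=stratum)
        ax.fill_between(
            xs, [r.iqr_lo for r in pts], [r.iqr_hi for r in pts], color=color, alpha=0.2
        )
    ax.axvline(learned_value, color="k", ls="--", lw=1, label="learned value")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel(results[0].coefficient if results else "coefficient")
    ax.set_ylabel("% change in Brier score")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
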