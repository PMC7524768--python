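"""Least-squares models of the trust weight on the cognitive covariates.

Three model variants mirror the analysis's regression table:

* **Model 1** — skill cell means plus the main effects (confirming,
  difficulty, distance, uncertainty, reputation, helpfulness, lifetime).
* **Model 2** — Model 1 plus interactions of helpfulness, uncertainty and
  confirming with the high-skill indicator.
* **Model 3** — Model 1 plus the distance x confirming interaction.
* **"eq3"** — the counterfactual predictor set: skill cell means,
  confirming, difficulty, distance, uncertainty, reputation, helpfulness.

Continuous predictors are z-scored over the regression sample so each
coefficient is the effect of a one-standard-deviation change; binary
predictors stay dummy-coded and the response is untransformed.  Skill
enters as cell-mean indicator columns (one per stratum, no global
intercept), so the skill coefficients are directly the stratum baselines.
Interactions are built from the standardized mains.  Standard errors are
classical by default, optionally cluster-robust by question.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ValidationError

__all__ = [
    "CONTINUOUS_PREDICTORS",
    "Standardization",
    "RegressionFit",
    "standardize",
    "fit_model",
    "design_matrix",
]

CONTINUOUS_PREDICTORS = (
    "difficulty",
    "distance",
    "uncertainty",
    "reputation",
    "helpfulness",
    "lifetime",
)

_MODEL_MAINS: dict[object, tuple[str, ...]] = {
    1: ("confirming",) + CONTINUOUS_PREDICTORS,
    2: ("confirming",) + CONTINUOUS_PREDICTORS,
    3: ("confirming",) + CONTINUOUS_PREDICTORS,
    "eq3": ("confirming", "difficulty", "distance", "uncertainty", "reputation", "helpfulness"),
}
_MODEL_INTERACTIONS: dict[object, tuple[tuple[str, str], ...]] = {
    1: (),
    2: (("helpfulness", "skill_high"), ("uncertainty", "skill_high"), ("confirming", "skill_high")),
    3: (("distance", "confirming"),),
    "eq3": (),
}


@dataclass(frozen=True)
class Standardization:
    """Per-column z-score transform fitted on the regression sample."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            if col in out:
                out[col] = (out[col] - mu) / self.sds[col]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            if col in out:
                out[col] = out[col] * self.sds[col] + mu
        return out

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds}


def standardize(
    table: pd.DataFrame,
    columns: Sequence[str] = CONTINUOUS_PREDICTORS,
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score the continuous predictors; dummies and response untouched.

    Zero-variance columns are dropped (with a warning via the returned
    transform simply omitting them).
    """
    if len(table) < 2:
        raise ValidationError("standardization needs at least 2 rows")
    means, sds = {}, {}
    out = table.copy()
    for col in columns:
        if col not in table:
            continue
        sd = float(table[col].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            out = out.drop(columns=[col])
            continue
        mu = float(table[col].mean())
        means[col], sds[col] = mu, sd
        out[col] = (table[col] - mu) / sd
    return out, Standardization(means=means, sds=sds)


def _strata(table: pd.DataFrame) -> list[str]:
    return sorted(table["skill"].unique())


def design_matrix(table: pd.DataFrame, model_id: object) -> pd.DataFrame:
    """Named design columns for a model variant (cell-means skill coding)."""
    if model_id not in _MODEL_MAINS:
        raise ValidationError(f"unknown model id {model_id!r}")
    X = pd.DataFrame(index=table.index)
    for s in _strata(table):
        X[f"skill[{s}]"] = (table["skill"] == s).astype(float)
    for col in _MODEL_MAINS[model_id]:
        if col not in table:
            raise ValidationError(f"covariate table lacks required column {col!r}")
        X[col] = table[col].astype(float)
    for a, b in _MODEL_INTERACTIONS[model_id]:
        bcol = (table["skill"] == "high").astype(float) if b == "skill_high" else table[b]
        X[f"{a}:{b}"] = table[a].astype(float) * np.asarray(bcol, dtype=float)
    return X


@dataclass
class RegressionFit:
    """A fitted trust-weight regression in the table's term layout."""

    model_id: object
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    r_squared_adj: float
    n_obs: int
    standardization: Standardization
    cluster_by_question: bool = False

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "bse": self.bse,
            "pvalues": self.pvalues,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "n_obs": self.n_obs,
            "standardization": self.standardization.to_dict(),
            "cluster_by_question": self.cluster_by_question,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        return cls(
            model_id=d["model_id"],
            params=d["params"],
            bse=d["bse"],
            pvalues=d["pvalues"],
            r_squared=d["r_squared"],
            r_squared_adj=d["r_squared_adj"],
            n_obs=d["n_obs"],
            standardization=Standardization(**d["standardization"]),
            cluster_by_question=d.get("cluster_by_question", False),
        )


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    bad = []
    arr = X.to_numpy()
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        coef, res, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        fitted = others @ coef
        if np.allclose(fitted, arr[:, j], atol=1e-10):
            bad.append(col)
    return bad


def fit_model(
    table: pd.DataFrame,
    model_id: object = 1,
    pre_standardized: bool = False,
    cluster_by_question: bool = False,
) -> RegressionFit:
    """OLS fit of the trust weight on a model variant's terms.

    ``table`` is a covariate table with an ``alpha`` response and a
    ``skill`` column; continuous predictors are z-scored here unless
    ``pre_standardized``.  The design carries no global intercept — the
    skill indicator columns span it — so reported R-squared is centered.
    Rank deficiency raises an error naming the collinear terms.
    """
    complete = table.dropna(subset=["alpha"]).reset_index(drop=True)
    if pre_standardized:
        std = Standardization(means={}, sds={})
        work = complete
    else:
        work, std = standardize(complete)
    X = design_matrix(work, model_id)
    y = work["alpha"].astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError(f"rank-deficient design; collinear terms: {_collinear_terms(X)}")
    model = sm.OLS(y, X, hasconst=True)
    res = model.fit()
    if cluster_by_question:
        res = res.get_robustcov_results(
            cov_type="cluster", groups=complete["question_id"]
        )
        bse = dict(zip(X.columns, np.asarray(res.bse)))
        pvals = dict(zip(X.columns, np.asarray(res.pvalues)))
    else:
        bse = {k: float(v) for k, v in res.bse.items()}
        pvals = {k: float(v) for k, v in res.pvalues.items()}
    return RegressionFit(
        model_id=model_id,
        params={k: float(v) for k, v in zip(X.columns, np.asarray(res.params))},
        bse={k: float(v) for k, v in bse.items()},
        pvalues={k: float(v) for k, v in pvals.items()},
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        n_obs=int(res.nobs),
        standardization=std,
        cluster_by_question=cluster_by_question,
    )
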