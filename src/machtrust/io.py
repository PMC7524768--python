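"""Readers and writers for the pipeline's file formats.

CSV schemas
-----------
``forecasts.csv``
    ``user_id, question_id, timestamp, condition, p1..p5`` — probability
    columns are fixed-width with blanks beyond the question's ``n_options``
    so 2- to 5-option questions share one schema.
``questions.csv``
    ``question_id, t_open, t_close, n_options, is_ordinal, has_machine,
    resolved_option, option_edges`` — edges ``;``-joined.
``machine_forecasts.csv``
    ``question_id, date, point_estimate, lo95, hi95, p1..p5``.
``history.csv``
    ``question_id, date, value`` — daily numeric series (long format).

Estimates, regression fits and counterfactual results are JSON; covariate
tables are CSV.  Every reader/writer pair is a lossless round trip at
1e-12 (floats are written with ``repr`` precision).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    MachineForecast,
    PipelineConfig,
    ProbabilityForecast,
    Question,
    ValidationError,
)

_MAX_OPTIONS = 5
_PCOLS = [f"p{i}" for i in range(1, _MAX_OPTIONS + 1)]


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# forecasts


def read_forecasts(path: str | Path) -> list[ProbabilityForecast]:
    """Read and validate human forecasts from CSV.

    Probabilities are renormalized when ``|sum - 1| <= 1e-6`` and rejected
    otherwise; malformed rows raise :class:`ValidationError` carrying the
    1-based line number.
    """
    out: list[ProbabilityForecast] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                probs = np.array(
                    [float(row[c]) for c in _PCOLS if row.get(c, "") not in ("", None)]
                )
                out.append(
                    ProbabilityForecast(
                        user_id=row["user_id"],
                        question_id=row["question_id"],
                        timestamp=dt.datetime.fromisoformat(row["timestamp"]),
                        condition=row["condition"],  # type: ignore[arg-type]
                        probs=probs,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_forecasts(forecasts: Iterable[ProbabilityForecast], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user_id", "question_id", "timestamp", "condition", *_PCOLS])
        for f in forecasts:
            pads = [""] * (_MAX_OPTIONS - len(f.probs))
            writer.writerow(
                [
                    f.user_id,
                    f.question_id,
                    f.timestamp.isoformat(),
                    f.condition,
                    *[_fmt(p) for p in f.probs],
                    *pads,
                ]
            )


# ---------------------------------------------------------------------------
# questions


def read_questions(path: str | Path) -> list[Question]:
    out: list[Question] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                edges_raw = row.get("option_edges", "")
                edges = (
                    tuple(float(e) for e in edges_raw.split(";")) if edges_raw else None
                )
                resolved = row.get("resolved_option", "")
                out.append(
                    Question(
                        question_id=row["question_id"],
                        n_options=int(row["n_options"]),
                        t_open=_parse_date(row["t_open"]),
                        t_close=_parse_date(row["t_close"]),
                        is_ordinal=row["is_ordinal"].lower() in ("1", "true"),
                        option_edges=edges,
                        resolved_option=int(resolved) if resolved != "" else None,
                        has_machine=row["has_machine"].lower() in ("1", "true"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_questions(questions: Iterable[Question], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "question_id",
                "t_open",
                "t_close",
                "n_options",
                "is_ordinal",
                "has_machine",
                "resolved_option",
                "option_edges",
            ]
        )
        for q in questions:
            writer.writerow(
                [
                    q.question_id,
                    q.t_open.isoformat(),
                    q.t_close.isoformat(),
                    q.n_options,
                    str(q.is_ordinal).lower(),
                    str(q.has_machine).lower(),
                    "" if q.resolved_option is None else q.resolved_option,
                    ";".join(_fmt(e) for e in q.option_edges) if q.option_edges else "",
                ]
            )


# ---------------------------------------------------------------------------
# machine forecasts


def read_machine_forecasts(path: str | Path) -> list[MachineForecast]:
    out: list[MachineForecast] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                probs = np.array(
                    [float(row[c]) for c in _PCOLS if row.get(c, "") not in ("", None)]
                )
                out.append(
                    MachineForecast(
                        question_id=row["question_id"],
                        date=_parse_date(row["date"]),
                        probs=probs,
                        point_estimate=float(row["point_estimate"]),
                        interval_95=(float(row["lo95"]), float(row["hi95"])),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_machine_forecasts(
    forecasts: Iterable[MachineForecast], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["question_id", "date", "point_estimate", "lo95", "hi95", *_PCOLS])
        for m in forecasts:
            pads = [""] * (_MAX_OPTIONS - len(m.probs))
            writer.writerow(
                [
                    m.question_id,
                    m.date.isoformat(),
                    _fmt(m.point_estimate),
                    _fmt(m.interval_95[0]),
                    _fmt(m.interval_95[1]),
                    *[_fmt(p) for p in m.probs],
                    *pads,
                ]
            )


# ---------------------------------------------------------------------------
# historical series


def read_history(path: str | Path) -> dict[str, pd.Series]:
    """Daily numeric series per question, keyed by question_id."""
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, pd.Series] = {}
    for qid, grp in df.groupby("question_id", sort=False):
        s = pd.Series(grp["value"].to_numpy(), index=grp["date"].dt.date.to_numpy())
        out[str(qid)] = s.sort_index()
    return out


def write_history(history: dict[str, pd.Series], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["question_id", "date", "value"])
        for qid, series in history.items():
            for day, value in series.items():
                writer.writerow([qid, day.isoformat(), _fmt(value)])


# ---------------------------------------------------------------------------
# JSON results (estimates, fits, counterfactuals) with stable field order


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    return obj


def write_results(records: Any, path: str | Path) -> None:
    """Write any result collection (estimates, fits, counterfactuals) as JSON.

    Objects exposing ``to_dict`` are serialized through it; an empty
    collection yields a valid empty container.
    """
    with open(path, "w") as fh:
        json.dump(_jsonify(records), fh, indent=1)


def read_results(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# covariate tables (CSV via pandas) and configuration (YAML)


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
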