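"""Aggregation, scenario differencing and validation against published
reference tables.

The reference fixtures transcribe the published per-state
incidence/prevalence/mortality table (base case 2009 and 2020
projection) and the scenario-outcome table exactly as printed; every
cell carries a source tag. Validation of a simulated run against them
is diagnostic: the original model's historical incidence series,
treatment-mix weights and routing split are unpublished, so simulated
headline totals are compared at a stated tolerance rather than
digit-for-digit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .states import State

__all__ = [
    "AggregateTotals",
    "DiffReport",
    "aggregate_report",
    "scenario_diff",
    "scenario_delta",
    "load_reference_table",
    "reference_report",
    "load_scenario_reference",
    "scenario_reference_delta",
    "validate_against_reference",
    "round_to_5",
    "write_report_csv",
    "write_summary_json",
]

_METRICS = ("incidence", "prevalence", "mortality")


@dataclass(frozen=True)
class AggregateTotals:
    incidence: float
    prevalence: float
    mortality: float


def _subset_values(states: Iterable[State | str] | None) -> list[str] | None:
    if states is None:
        return None
    return [s.value if isinstance(s, State) else str(s) for s in states]


def aggregate_report(
    report: pd.DataFrame, year: int, states: Iterable[State | str] | None = None
) -> AggregateTotals:
    """Exact sums of incidence/prevalence/mortality over a state subset
    (all living states when ``states`` is None)."""
    if year not in set(report["year"]):
        raise ValueError(f"year {year} not in report")
    sub = report[report["year"] == year]
    names = _subset_values(states)
    if names is not None:
        sub = sub[sub["state"].isin(names)]
    return AggregateTotals(
        incidence=float(sub["incidence"].sum()),
        prevalence=float(sub["prevalence"].sum()),
        mortality=float(sub["mortality"].sum()),
    )


def scenario_delta(baseline_value: float, scenario_value: float) -> tuple[float, float]:
    """(absolute, relative) reduction of a metric under a scenario:
    ``delta = baseline - scenario``, relative to baseline."""
    delta = baseline_value - scenario_value
    rel = delta / baseline_value if baseline_value else 0.0
    return delta, rel


def scenario_diff(
    baseline: pd.DataFrame,
    scenario: pd.DataFrame,
    year: int,
    metric: str,
    states: Iterable[State | str] | None = None,
) -> tuple[float, float]:
    """Scenario effect on an aggregated report metric for one year."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    b = getattr(aggregate_report(baseline, year, states), metric)
    s = getattr(aggregate_report(scenario, year, states), metric)
    return scenario_delta(b, s)


def _reference_text(name: str) -> str:
    return (resources.files("pcstates.data.reference") / name).read_text()


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Published per-state table as long-form rows
    (year, state, metric, value, source)."""
    text = (
        Path(path).read_text()
        if path is not None
        else _reference_text("state_table_2009_2020.yaml")
    )
    raw = yaml.safe_load(text)["table"]
    rows = []
    for year, states in raw.items():
        for state, cells in states.items():
            src = cells.get("source", "")
            for metric in _METRICS:
                rows.append(
                    {
                        "year": int(year),
                        "state": State(state).value,
                        "metric": metric,
                        "value": float(cells[metric]),
                        "source": src,
                    }
                )
    return pd.DataFrame(rows)


def reference_report(path: str | Path | None = None) -> pd.DataFrame:
    """The reference table reshaped like a simulation report
    (year, state, incidence, prevalence, mortality)."""
    long = load_reference_table(path)
    wide = long.pivot_table(
        index=["year", "state"], columns="metric", values="value"
    ).reset_index()
    wide.columns.name = None
    return wide[["year", "state", *_METRICS]]


def load_scenario_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Published scenario-outcome table as rows
    (year, metric, scenario, value, source); printed "NA" cells are NaN."""
    text = (
        Path(path).read_text() if path is not None else _reference_text("scenario_table.yaml")
    )
    raw = yaml.safe_load(text)["table"]
    rows = []
    for year, metrics in raw.items():
        for metric, cells in metrics.items():
            src = cells.get("source", "")
            for scen, value in cells.items():
                if scen == "source":
                    continue
                rows.append(
                    {
                        "year": int(year),
                        "metric": metric,
                        "scenario": scen,
                        "value": np.nan if value is None else float(value),
                        "source": src,
                    }
                )
    return pd.DataFrame(rows)


def scenario_reference_delta(
    reference: pd.DataFrame, year: int, metric: str, scenario: str
) -> tuple[float, float]:
    """(absolute, relative) baseline-minus-scenario delta of a published
    scenario-table metric."""
    sub = reference[(reference["year"] == year) & (reference["metric"] == metric)]
    if sub.empty:
        raise ValueError(f"no reference rows for {metric!r} in {year}")
    base = float(sub.loc[sub["scenario"] == "baseline", "value"].iloc[0])
    scen = float(sub.loc[sub["scenario"] == scenario, "value"].iloc[0])
    return scenario_delta(base, scen)


@dataclass
class DiffReport:
    """Cell-by-cell comparison of a report against a reference table."""

    frame: pd.DataFrame  # year, state, metric, computed, reference, abs/rel diff, passed
    tolerance: float

    @property
    def ok(self) -> bool:
        return bool(self.frame["passed"].all())

    def failures(self) -> pd.DataFrame:
        return self.frame[~self.frame["passed"]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tolerance": self.tolerance,
            "passed": self.ok,
            "cells": self.frame.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def validate_against_reference(
    report: pd.DataFrame, reference: pd.DataFrame, tolerance: float
) -> DiffReport:
    """Compare per-cell; pass iff |relative difference| <= tolerance.

    ``reference`` is long-form (as from :func:`load_reference_table`).
    Raises if the report covers none of the reference years.
    """
    years = sorted(set(reference["year"]) & set(report["year"]))
    if not years:
        raise ValueError(
            f"no overlapping years: report has {sorted(set(report['year']))[:3]}..., "
            f"reference has {sorted(set(reference['year']))}"
        )
    rows = []
    for _, ref in reference[reference["year"].isin(years)].iterrows():
        sub = report[(report["year"] == ref["year"]) & (report["state"] == ref["state"])]
        if sub.empty:
            continue
        computed = float(sub[ref["metric"]].iloc[0])
        abs_diff = computed - ref["value"]
        rel_diff = abs_diff / ref["value"] if ref["value"] else np.inf * np.sign(abs_diff or 1)
        rows.append(
            {
                "year": int(ref["year"]),
                "state": ref["state"],
                "metric": ref["metric"],
                "computed": computed,
                "reference": float(ref["value"]),
                "abs_diff": float(abs_diff),
                "rel_diff": float(rel_diff),
                "passed": bool(abs(rel_diff) <= tolerance),
            }
        )
    return DiffReport(frame=pd.DataFrame(rows), tolerance=tolerance)


def round_to_5(report: pd.DataFrame) -> pd.DataFrame:
    """Round numeric report columns to the nearest 5 persons (the
    published tables print multiples of 5)."""
    out = report.copy()
    for col in _METRICS:
        if col in out.columns:
            out[col] = (out[col] / 5.0).round() * 5.0
    return out


def write_report_csv(report: pd.DataFrame, path: str | Path, *, round5: bool = False) -> None:
    (round_to_5(report) if round5 else report).to_csv(path, index=False)


def write_summary_json(report: pd.DataFrame, path: str | Path) -> None:
    """Totals per year across all states, as a small JSON summary."""
    years = sorted(set(report["year"]))
    summary = {}
    for y in years:
        agg = aggregate_report(report, y)
        summary[str(y)] = {
            "incidence": agg.incidence,
            "prevalence": agg.prevalence,
            "mortality": agg.mortality,
        }
    Path(path).write_text(json.dumps(summary, indent=2))
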