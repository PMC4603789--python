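"""Individual-level Monte-Carlo oracle.

An independent check on the cohort engine: each simulated man carries a
state and a tenure, and within each year competing exponential clocks
at the cell's (progression, death) rates decide whether he progresses
(destination drawn from the routing fractions), dies, or stays. The
conventions mirror the cohort engine exactly -- annual cycles,
full-year exposure from the entry year, progressors landing at tenure 0
and not re-exposed until the next year -- so the engine is the exact
expectation of this microsimulation and per-cell occupancy counts are
Binomial(n, p) around the engine's prediction.

The simulated population of size ``n`` is allocated across the
(entry year, stage) cells of the incidence series multinomially with
probabilities proportional to the cell counts; each individual then
represents ``total incidence / n`` persons.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import DEFAULT_TENURE_CAP, _STATE_INDEX, _scenario_rate_matrices
from .hazards import PiecewiseHazard, Scenario
from .incidence import STAGES, IncidenceSeries
from .states import ENTRY_STATES, LIVING_STATES, RoutingTable, State

__all__ = ["OracleResult", "microsim_oracle"]

_DEAD_CODE = len(LIVING_STATES)  # integer state code for death
_UNBORN = -1  # not yet diagnosed


@dataclass
class OracleResult:
    """Microsimulation outputs in individual counts.

    ``occupancy``: year x state end-of-year individual counts;
    ``deaths``: year x state death counts; ``weight``: persons
    represented by one individual.
    """

    occupancy: pd.DataFrame
    deaths: pd.DataFrame
    weight: float
    n: int

    def occupancy_persons(self) -> pd.DataFrame:
        return self.occupancy * self.weight


def microsim_oracle(
    hazard_profile: Mapping[State, PiecewiseHazard],
    routing: RoutingTable,
    incidence: IncidenceSeries,
    *,
    start: int,
    horizon: int,
    n_individuals: int,
    seed: int,
    scenarios: Sequence[Scenario] | None = None,
    scenario_scope: str = "all_patients",
    tenure_cap: int = DEFAULT_TENURE_CAP,
) -> OracleResult:
    """Run the individual-level oracle; seed-deterministic."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    years = np.arange(start, horizon + 1)

    # Allocate individuals to (entry year, stage) cells.
    cells = []
    weights = []
    for y in years:
        row = incidence.year(int(y))
        for stage in STAGES:
            if row[stage] > 0:
                cells.append((int(y), _STATE_INDEX[ENTRY_STATES[stage]]))
                weights.append(row[stage])
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("incidence series has no mass over the run window")
    cell_idx = rng.choice(len(cells), size=n_individuals, p=weights / total)
    entry_year = np.array([cells[i][0] for i in cell_idx])
    entry_state = np.array([cells[i][1] for i in cell_idx])

    # Routing as cumulative destination probabilities per source.
    n_states = len(LIVING_STATES)
    routing_cum = np.zeros((n_states, n_states))
    for src in LIVING_STATES:
        i = _STATE_INDEX[src]
        acc = 0.0
        for dst in LIVING_STATES:
            acc += routing.destinations(src).get(dst, 0.0)
            routing_cum[i, _STATE_INDEX[dst]] = acc

    state = np.full(n_individuals, _UNBORN, dtype=np.int64)
    tenure = np.zeros(n_individuals, dtype=np.int64)

    occ = np.zeros((len(years), n_states), dtype=np.int64)
    deaths = np.zeros_like(occ)
    scenarios = list(scenarios or [])

    for yi, year in enumerate(years):
        newly = entry_year == year
        state[newly] = entry_state[newly]
        tenure[newly] = 0

        active = (state >= 0) & (state != _DEAD_CODE)
        idx = np.nonzero(active)[0]
        if idx.size:
            hp_mat, hd_mat = _scenario_rate_matrices(
                hazard_profile, scenarios, int(year), tenure_cap, scenario_scope
            )
            hp = hp_mat[state[idx], tenure[idx]]
            hd = hd_mat[state[idx], tenure[idx]]
            total_h = hp + hd
            p_exit = -np.expm1(-total_h)
            with np.errstate(invalid="ignore"):
                p_die = np.where(total_h > 0, p_exit * hd / np.where(total_h > 0, total_h, 1.0), 0.0)
                p_prog = np.where(total_h > 0, p_exit * hp / np.where(total_h > 0, total_h, 1.0), 0.0)
            u = rng.random(idx.size)
            die = u < p_die
            prog = (~die) & (u < p_die + p_prog)
            stay = ~(die | prog)

            die_idx = idx[die]
            if die_idx.size:  # record against the state died from
                deaths[yi] += np.bincount(state[die_idx], minlength=n_states)[:n_states]
                state[die_idx] = _DEAD_CODE

            prog_idx = idx[prog]
            if prog_idx.size:
                u2 = rng.random(prog_idx.size)
                cum = routing_cum[state[prog_idx]]
                dest = (u2[:, None] >= cum).sum(axis=1)
                state[prog_idx] = dest
                tenure[prog_idx] = 0

            stay_idx = idx[stay]
            tenure[stay_idx] = np.minimum(tenure[stay_idx] + 1, tenure_cap)

        alive = (state >= 0) & (state != _DEAD_CODE)
        occ[yi] = np.bincount(state[alive], minlength=n_states)[:n_states]

    occupancy = pd.DataFrame(
        occ, index=pd.Index(years, name="year"), columns=[s.value for s in LIVING_STATES]
    )
    deaths_df = pd.DataFrame(
        deaths, index=pd.Index(years, name="year"), columns=[s.value for s in LIVING_STATES]
    )
    return OracleResult(
        occupancy=occupancy, deaths=deaths_df, weight=total / n_individuals, n=n_individuals
    )
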