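"""Tenure-structured cohort engine.

The simulator advances a deterministic cohort ledger one calendar year
at a time. Occupancy is held per (living state, whole years of tenure
in that state); tenure selects the hazard segment. Each year:

1. incident diagnoses enter their entry state at tenure 0 and (under
   the default full-year convention) are exposed that same year;
2. every (state, tenure) cell splits into progressors, deaths and
   stayers by the competing-risk annual probabilities;
3. progressors are distributed over destination states by the routing
   fractions and land at tenure 0, *not* re-exposed until next year
   (no same-year multi-hop cascades);
4. stayers advance one year of tenure, capped at ``tenure_cap``;
5. deaths accumulate in the absorbing death count.

Occupancies are real-valued (fractional persons); the engine is the
exact expectation of the individual-level microsimulation in
:mod:`pcstates.oracle` under identical conventions, which is the basis
of the cross-validation tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hazards import PiecewiseHazard, Scenario, apply_scenarios
from .incidence import IncidenceSeries
from .states import (
    ENTRY_STATES,
    LIVING_STATES,
    MCRPC_STATES,
    RoutingTable,
    State,
    TransitionTopology,
    validate_topology,
)

__all__ = [
    "DEFAULT_TENURE_CAP",
    "CohortLedger",
    "FlowRecord",
    "SimulationResult",
    "initialize",
    "step_year",
    "run_simulation",
]

DEFAULT_TENURE_CAP = 30

#: Conservation tolerance (relative): occupancy + deaths vs injected.
CONSERVATION_RTOL = 1e-6

_STATE_INDEX: dict[State, int] = {s: i for i, s in enumerate(LIVING_STATES)}
_DIAGNOSIS = "DIAGNOSIS"  # pseudo-source label for incident entries


@dataclass
class CohortLedger:
    """Occupancy per (living state, tenure) plus cumulative bookkeeping.

    ``year`` is the next calendar year to be simulated.
    """

    year: int
    occupancy: np.ndarray  # shape (n_living_states, tenure_cap + 1)
    cumulative_deaths: float = 0.0
    cumulative_incidence: float = 0.0

    @property
    def tenure_cap(self) -> int:
        return self.occupancy.shape[1] - 1

    def state_occupancy(self, state: State) -> float:
        return float(self.occupancy[_STATE_INDEX[state]].sum())

    def total_alive(self) -> float:
        return float(self.occupancy.sum())

    def conservation_error(self) -> float:
        """Relative bookkeeping residual: |alive + dead - injected|."""
        injected = self.cumulative_incidence
        residual = abs(self.total_alive() + self.cumulative_deaths - injected)
        return residual / max(injected, 1.0)

    def check_conservation(self, rtol: float = CONSERVATION_RTOL) -> None:
        err = self.conservation_error()
        if err > rtol:
            raise AssertionError(f"conservation violated: relative error {err:.3e}")


@dataclass
class FlowRecord:
    """Person flows of one simulated year."""

    year: int
    moves: dict[tuple[State, State], float] = field(default_factory=dict)
    deaths: dict[State, float] = field(default_factory=dict)
    entries: dict[State, float] = field(default_factory=dict)

    def inflow(self, state: State) -> float:
        """Total inflow: incident diagnoses plus routed progression."""
        routed = sum(v for (_, dst), v in self.moves.items() if dst is state)
        return self.entries.get(state, 0.0) + routed

    def mcrpc_entry(self) -> float:
        """First entries into any mCRPC state (from non-mCRPC sources)."""
        return sum(
            v
            for (src, dst), v in self.moves.items()
            if dst in MCRPC_STATES and src not in MCRPC_STATES
        )

    def mcrpc_entry_by_source(self) -> dict[State, float]:
        out: dict[State, float] = {}
        for (src, dst), v in self.moves.items():
            if dst in MCRPC_STATES and src not in MCRPC_STATES:
                out[src] = out.get(src, 0.0) + v
        return out


def initialize(start_year: int, *, tenure_cap: int = DEFAULT_TENURE_CAP) -> CohortLedger:
    """Empty ledger positioned at the first year to simulate."""
    return CohortLedger(
        year=start_year,
        occupancy=np.zeros((len(LIVING_STATES), tenure_cap + 1)),
    )


def _transition_matrices(
    hp: np.ndarray, hd: np.ndarray, exposure: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elementwise competing-risk annual probabilities from rate arrays."""
    total = hp + hd
    p_exit = -np.expm1(-total * exposure)
    with np.errstate(invalid="ignore", divide="ignore"):
        share_p = np.where(total > 0, hp / np.where(total > 0, total, 1.0), 0.0)
        share_d = np.where(total > 0, hd / np.where(total > 0, total, 1.0), 0.0)
    return p_exit * share_p, p_exit * share_d, 1.0 - p_exit


def rate_matrices(
    hazards: Mapping[State, PiecewiseHazard], tenure_cap: int
) -> tuple[np.ndarray, np.ndarray]:
    """(h_prog, h_death) arrays of shape (n_living, tenure_cap + 1)."""
    tenures = np.arange(tenure_cap + 1, dtype=float)
    hp = np.zeros((len(LIVING_STATES), tenure_cap + 1))
    hd = np.zeros_like(hp)
    for s in LIVING_STATES:
        hp[_STATE_INDEX[s]], hd[_STATE_INDEX[s]] = hazards[s].rate_arrays(tenures)
    return hp, hd


def _routing_matrix(routing: RoutingTable) -> np.ndarray:
    n = len(LIVING_STATES)
    r = np.zeros((n, n))
    for src in LIVING_STATES:
        for dst, frac in routing.destinations(src).items():
            r[_STATE_INDEX[src], _STATE_INDEX[dst]] = frac
    return r


def step_year(
    ledger: CohortLedger,
    hazards: Mapping[State, PiecewiseHazard] | tuple[np.ndarray, np.ndarray],
    routing: RoutingTable,
    incidence: Mapping[str, float],
    *,
    entry_exposure: str = "full",
) -> tuple[CohortLedger, FlowRecord]:
    """Advance the ledger by one calendar year.

    Parameters
    ----------
    hazards
        Per-state piecewise hazards (a scenario-adjusted profile for
        this year), or precomputed ``(h_prog, h_death)`` rate matrices.
    incidence
        Stage -> diagnosed count for ``ledger.year``.
    entry_exposure
        ``"full"`` exposes same-year entrants to the whole year's risk
        (enter January 1); ``"half"`` exposes them for half a year
        (enter mid-year on average).
    """
    if entry_exposure not in ("full", "half"):
        raise ValueError(f"unknown entry exposure {entry_exposure!r}")
    cap = ledger.tenure_cap
    if isinstance(hazards, tuple):
        hp, hd = hazards
    else:
        hp, hd = rate_matrices(hazards, cap)

    year = ledger.year
    occ = ledger.occupancy.copy()
    entries: dict[State, float] = {}
    entrants = np.zeros(len(LIVING_STATES))
    for stage, state in ENTRY_STATES.items():
        count = float(incidence.get(stage, 0.0))
        if count < 0:
            raise ValueError(f"negative incidence for stage {stage!r}")
        if count:
            entries[state] = count
            entrants[_STATE_INDEX[state]] = count
    if entry_exposure == "full":
        occ[:, 0] += entrants
        entrants = np.zeros_like(entrants)

    pp, pd_, _ = _transition_matrices(hp, hd)
    prog_cells = occ * pp
    death_cells = occ * pd_
    stay_cells = occ - prog_cells - death_cells

    new_occ = np.zeros_like(occ)
    new_occ[:, 1:] = stay_cells[:, :-1]
    new_occ[:, cap] += stay_cells[:, cap]  # cells at the cap stay there

    prog_by_state = prog_cells.sum(axis=1)
    deaths_by_state = death_cells.sum(axis=1)

    if entrants.any():  # half-cycle entrants: half-year exposure at tenure 0
        epp, epd, _ = _transition_matrices(hp[:, 0], hd[:, 0], exposure=0.5)
        e_prog = entrants * epp
        e_death = entrants * epd
        prog_by_state += e_prog
        deaths_by_state += e_death
        new_occ[:, 1] += entrants - e_prog - e_death

    rmat = _routing_matrix(routing)
    routed = rmat.T @ prog_by_state  # progressors land at tenure 0
    new_occ[:, 0] += routed

    flow = FlowRecord(year=year, entries=entries)
    for src in LIVING_STATES:
        i = _STATE_INDEX[src]
        if deaths_by_state[i]:
            flow.deaths[src] = float(deaths_by_state[i])
        if prog_by_state[i]:
            for dst, frac in routing.destinations(src).items():
                if frac:
                    flow.moves[(src, dst)] = float(frac * prog_by_state[i])

    new_ledger = CohortLedger(
        year=year + 1,
        occupancy=new_occ,
        cumulative_deaths=ledger.cumulative_deaths + float(deaths_by_state.sum()),
        cumulative_incidence=ledger.cumulative_incidence + float(sum(entries.values())),
    )
    new_ledger.check_conservation()
    return new_ledger, flow


@dataclass
class SimulationResult:
    """Annual per-state report plus the underlying flow records.

    ``report`` has one row per (year, living state) with columns
    ``incidence`` (total inflow: diagnoses plus routed progression),
    ``prevalence`` (end-of-year occupancy) and ``mortality`` (deaths
    during the year).
    """

    report: pd.DataFrame
    flows: pd.DataFrame
    final_ledger: CohortLedger
    scenario_names: tuple[str, ...] = ()

    def mcrpc_entry_incidence(self) -> pd.Series:
        """First entries into any mCRPC state, per year."""
        f = self.flows
        mask = (
            f["destination"].isin([s.value for s in MCRPC_STATES])
            & ~f["source"].isin([s.value for s in MCRPC_STATES])
            & (f["source"] != _DIAGNOSIS)
        )
        out = f[mask].groupby("year")["persons"].sum()
        years = self.report["year"].unique()
        return out.reindex(years, fill_value=0.0)

    def mcrpc_entry_by_source(self) -> pd.DataFrame:
        """Year x source-state table of first entries into mCRPC."""
        f = self.flows
        mask = (
            f["destination"].isin([s.value for s in MCRPC_STATES])
            & ~f["source"].isin([s.value for s in MCRPC_STATES])
            & (f["source"] != _DIAGNOSIS)
        )
        return (
            f[mask]
            .pivot_table(index="year", columns="source", values="persons", aggfunc="sum")
            .fillna(0.0)
        )


def _scenario_rate_matrices(
    profile: Mapping[State, PiecewiseHazard],
    scenarios: Sequence[Scenario],
    year: int,
    cap: int,
    scope: str,
) -> tuple[np.ndarray, np.ndarray]:
    base_hp, base_hd = rate_matrices(profile, cap)
    if not scenarios:
        return base_hp, base_hd
    adj = apply_scenarios(profile, scenarios, year)
    hp, hd = rate_matrices(adj, cap)
    if scope == "all_patients":
        return hp, hd
    # new_entrants: a cell at tenure t in `year` entered in year - t, so
    # the intervention reaches only tenures t <= year - introduction.
    intro = min(sc.introduction_year for sc in scenarios)
    tenures = np.arange(cap + 1)
    mask = tenures[None, :] <= max(year - intro, -1)
    return np.where(mask, hp, base_hp), np.where(mask, hd, base_hd)


def run_simulation(
    hazard_profile: Mapping[State, PiecewiseHazard],
    topology: TransitionTopology,
    routing: RoutingTable,
    incidence: IncidenceSeries,
    *,
    start: int,
    horizon: int,
    scenarios: Sequence[Scenario] | Scenario | None = None,
    entry_exposure: str = "full",
    scenario_scope: str = "all_patients",
    tenure_cap: int = DEFAULT_TENURE_CAP,
) -> SimulationResult:
    """Deterministic cohort run from ``start`` through ``horizon``.

    Validates the topology/routing pair up front, then steps the ledger
    year by year, applying any intervention scenarios to the hazard
    profile from their introduction year.

    ``scenario_scope="new_entrants"`` restricts the intervention to
    patients entering a target state after the introduction year
    (identified by tenure); the default applies it to everyone in the
    state from that year on (drug availability, not cohort entry).
    """
    if start > horizon:
        raise ValueError(f"start {start} after horizon {horizon}")
    if scenario_scope not in ("all_patients", "new_entrants"):
        raise ValueError(f"unknown scenario scope {scenario_scope!r}")
    check = validate_topology(topology, routing)
    if not check.ok:
        raise ValueError("invalid topology/routing: " + "; ".join(check.violations))
    missing = [s for s in LIVING_STATES if s not in hazard_profile]
    if missing:
        raise ValueError(f"hazard profile missing states {missing}")
    if not (incidence.start <= start and incidence.end >= horizon):
        raise ValueError(
            f"incidence series covers {incidence.start}-{incidence.end}, "
            f"need {start}-{horizon}"
        )
    if isinstance(scenarios, Scenario):
        scenarios = [scenarios]
    scenarios = list(scenarios or [])

    ledger = initialize(start, tenure_cap=tenure_cap)
    report_rows = []
    flow_rows = []
    for year in range(start, horizon + 1):
        rates = _scenario_rate_matrices(
            hazard_profile, scenarios, year, tenure_cap, scenario_scope
        )
        ledger, flow = step_year(
            ledger, rates, routing, incidence.year(year), entry_exposure=entry_exposure
        )
        for state in LIVING_STATES:
            report_rows.append(
                {
                    "year": year,
                    "state": state.value,
                    "incidence": flow.inflow(state),
                    "prevalence": float(
                        ledger.occupancy[_STATE_INDEX[state]].sum()
                    ),
                    "mortality": flow.deaths.get(state, 0.0),
                }
            )
        for state, n in flow.entries.items():
            flow_rows.append(
                {"year": year, "source": _DIAGNOSIS, "destination": state.value, "persons": n}
            )
        for (src, dst), n in flow.moves.items():
            flow_rows.append(
                {"year": year, "source": src.value, "destination": dst.value, "persons": n}
            )
        for state, n in flow.deaths.items():
            flow_rows.append(
                {"year": year, "source": state.value, "destination": State.DEAD.value, "persons": n}
            )

    return SimulationResult(
        report=pd.DataFrame(report_rows),
        flows=pd.DataFrame(flow_rows, columns=["year", "source", "destination", "persons"]),
        final_ledger=ledger,
        scenario_names=tuple(sc.name for sc in scenarios),
    )
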