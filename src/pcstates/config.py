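"""Configuration loading: survival rate table, topology/routing,
scenarios, and assembly of the shipped default model.

All inputs are plain YAML/CSV so a run is fully specified by text
files; the packaged defaults transcribe the published survival table
and scenario definitions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .hazards import (
    DEFAULT_SURVIVAL_FLOOR,
    PiecewiseHazard,
    Scenario,
    SurvivalSummary,
    TreatmentArm,
    build_hazard_profile,
)
from .incidence import IncidenceSeries, default_series, load_series
from .states import (
    RoutingTable,
    State,
    TransitionTopology,
    build_default_topology,
)

__all__ = [
    "ModelConfig",
    "load_rate_table",
    "load_topology",
    "load_scenarios",
    "default_config",
]


def _data_text(name: str) -> str:
    return (resources.files("pcstates.data") / name).read_text()


def load_rate_table(path: str | Path | None = None) -> dict[State, list[TreatmentArm]]:
    """Load a per-state treatment-arm survival table (packaged default
    when no path is given)."""
    text = Path(path).read_text() if path is not None else _data_text("survival_rates.yaml")
    raw = yaml.safe_load(text)
    table: dict[State, list[TreatmentArm]] = {}
    for state_name, block in raw["states"].items():
        state = State(state_name)
        arms = []
        for arm in block["arms"]:
            arms.append(
                TreatmentArm(
                    label=str(arm["label"]),
                    weight=float(arm["weight"]),
                    hormonal=bool(arm.get("hormonal", False)),
                    source=str(arm.get("source", "")),
                    survival=SurvivalSummary(
                        os5=float(arm["os5"]),
                        os10=float(arm["os10"]),
                        pfs5=float(arm["pfs5"]),
                        pfs10=float(arm["pfs10"]),
                    ),
                )
            )
        table[state] = arms
    return table


def load_topology(path: str | Path | None = None) -> tuple[TransitionTopology, RoutingTable]:
    """Load topology edges and routing fractions from YAML (packaged
    default when no path is given). Death edges are added implicitly."""
    text = Path(path).read_text() if path is not None else _data_text("topology.yaml")
    raw = yaml.safe_load(text)
    edges = {(State(a), State(b)) for a, b in raw["edges"]}
    edges.update((s, State.DEAD) for s in State if s is not State.DEAD)
    routing = RoutingTable(
        fractions={
            State(src): {State(dst): float(f) for dst, f in (dests or {}).items()}
            for src, dests in raw["routing"].items()
        }
    )
    return TransitionTopology(edges=frozenset(edges)), routing


def load_scenarios(
    name_or_path: str | Path, *, semantics: str = "extend_time"
) -> list[Scenario]:
    """Load a scenario set by packaged name (``nmcrpc``, ``mcrpc``,
    ``combined``) or from a YAML file with the same schema."""
    packaged = yaml.safe_load(_data_text("scenarios.yaml"))["scenarios"]
    if isinstance(name_or_path, str) and name_or_path in packaged:
        entries = packaged[name_or_path]
    else:
        raw = yaml.safe_load(Path(name_or_path).read_text())
        entries = raw["scenarios"] if "scenarios" in raw else raw
        if isinstance(entries, Mapping):  # single scenario mapping
            entries = [entries]
    return [
        Scenario(
            name=str(e.get("name", "scenario")),
            states=frozenset(State(s) for s in e["states"]),
            pfs_improvement=float(e.get("pfs_improvement", 0.0)),
            os_improvement=float(e.get("os_improvement", 0.0)),
            introduction_year=int(e.get("introduction_year", 2015)),
            semantics=semantics,
        )
        for e in entries
    ]


@dataclass
class ModelConfig:
    """Everything a simulation run needs."""

    rate_table: Mapping[State, Sequence[TreatmentArm]]
    topology: TransitionTopology
    routing: RoutingTable
    incidence: IncidenceSeries
    start: int = 1990
    horizon: int = 2020
    survival_floor: float = DEFAULT_SURVIVAL_FLOOR
    max_hazard: float | None = None
    entry_exposure: str = "full"
    scenario_scope: str = "all_patients"
    scenarios: list[Scenario] = field(default_factory=list)

    def hazard_profile(self) -> dict[State, PiecewiseHazard]:
        return build_hazard_profile(
            self.rate_table,
            survival_floor=self.survival_floor,
            max_hazard=self.max_hazard,
        )


def default_config(
    *,
    start: int = 1990,
    horizon: int = 2020,
    incidence_path: str | Path | None = None,
    rates_path: str | Path | None = None,
    topology_path: str | Path | None = None,
    scenario: str | Path | None = None,
    scenario_semantics: str = "extend_time",
) -> ModelConfig:
    """Assemble the shipped default model (overridable piecewise).

    With no topology file, routing is rebuilt from the rate table so
    the locally-advanced split tracks the hormonal-arm weight share.
    """
    rate_table = load_rate_table(rates_path)
    if topology_path is not None:
        topology, routing = load_topology(topology_path)
    else:
        topology, routing = build_default_topology(rate_table)
    incidence = (
        load_series(incidence_path) if incidence_path is not None else default_series(horizon)
    )
    scenarios = load_scenarios(scenario, semantics=scenario_semantics) if scenario else []
    return ModelConfig(
        rate_table=rate_table,
        topology=topology,
        routing=routing,
        incidence=incidence,
        start=start,
        horizon=horizon,
        scenarios=scenarios,
    )
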