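"""Clinical states of the prostate cancer disease continuum and the
progression graph between them.

The model partitions the course of diagnosed prostate cancer into eight
living clinical states -- milestones defined by the status of the
primary tumour, presence of metastases, prior/current treatment and
testosterone level -- plus an absorbing death state. Patients enter at
diagnosis into one of three stages (localized, locally advanced, or
metastatic non-castrate) and can only move "forward" along the graph:
disease progresses, it never regresses.

Progression outflow from a state is split among its living successors
by a :class:`RoutingTable` of fractions that sum to one per source.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "State",
    "LIVING_STATES",
    "ENTRY_STATES",
    "MCRPC_STATES",
    "NONMETASTATIC_STATES",
    "METASTATIC_STATES",
    "TransitionTopology",
    "RoutingTable",
    "TopologyValidation",
    "build_default_topology",
    "validate_topology",
]

_ROUTING_TOL = 1e-9


class State(str, enum.Enum):
    """The eight living prostate cancer clinical states plus death."""

    #: Newly diagnosed disease confined to the gland.
    LOCALIZED = "LOCALIZED"
    #: Newly diagnosed high-risk disease beyond the capsule, no distant
    #: metastases.
    LOCALLY_ADVANCED = "LOCALLY_ADVANCED"
    #: Biochemical failure after local therapy, non-castrate
    #: testosterone, no detectable metastases.
    RISING_PSA_NONCASTRATE = "RISING_PSA_NONCASTRATE"
    #: Non-metastatic castration-resistant disease: rising PSA despite
    #: castrate testosterone (<50 ng/dl), no detectable metastases.
    NMCRPC = "NMCRPC"
    #: Metastases detectable at diagnosis, hormone-sensitive.
    METASTATIC_NONCASTRATE = "METASTATIC_NONCASTRATE"
    #: Asymptomatic / minimally symptomatic metastatic
    #: castration-resistant disease, chemotherapy-naive or not failed.
    MCRPC_ASYMPTOMATIC = "MCRPC_ASYMPTOMATIC"
    #: Symptomatic mCRPC, chemotherapy-naive or not failed.
    MCRPC_SYMPTOMATIC = "MCRPC_SYMPTOMATIC"
    #: mCRPC progressed on/after first-line chemotherapy (terminal
    #: living state).
    MCRPC_POSTCHEMO = "MCRPC_POSTCHEMO"
    #: Absorbing death state (all-cause).
    DEAD = "DEAD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LIVING_STATES: tuple[State, ...] = tuple(s for s in State if s is not State.DEAD)

#: Diagnosis stage -> state entered at diagnosis.
ENTRY_STATES: Mapping[str, State] = {
    "localized": State.LOCALIZED,
    "locally_advanced": State.LOCALLY_ADVANCED,
    "metastatic": State.METASTATIC_NONCASTRATE,
}

MCRPC_STATES: frozenset[State] = frozenset(
    {State.MCRPC_ASYMPTOMATIC, State.MCRPC_SYMPTOMATIC, State.MCRPC_POSTCHEMO}
)
NONMETASTATIC_STATES: frozenset[State] = frozenset(
    {
        State.LOCALIZED,
        State.LOCALLY_ADVANCED,
        State.RISING_PSA_NONCASTRATE,
        State.NMCRPC,
    }
)
METASTATIC_STATES: frozenset[State] = frozenset(
    {State.METASTATIC_NONCASTRATE} | MCRPC_STATES
)


@dataclass(frozen=True)
class TransitionTopology:
    """Directed graph of allowed transitions between clinical states."""

    edges: frozenset[tuple[State, State]]

    def successors(self, state: State) -> frozenset[State]:
        return frozenset(dst for src, dst in self.edges if src is state)

    def living_successors(self, state: State) -> frozenset[State]:
        return frozenset(s for s in self.successors(state) if s is not State.DEAD)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(State)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class RoutingTable:
    """Per source state, destination fractions of progression outflow.

    Fractions cover living destinations only (death is a competing
    risk handled by the hazard layer, not a routing destination) and
    sum to 1 per source; a terminal living state has an empty mapping.
    """

    fractions: Mapping[State, Mapping[State, float]]

    def destinations(self, state: State) -> Mapping[State, float]:
        return self.fractions.get(state, {})


@dataclass
class TopologyValidation:
    """Outcome of structural checks on a topology + routing pair."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


#: Default progression edges (living-to-living); death edges implied.
DEFAULT_PROGRESSION_EDGES: tuple[tuple[State, State], ...] = (
    (State.LOCALIZED, State.RISING_PSA_NONCASTRATE),
    (State.LOCALLY_ADVANCED, State.RISING_PSA_NONCASTRATE),
    (State.LOCALLY_ADVANCED, State.NMCRPC),
    (State.RISING_PSA_NONCASTRATE, State.NMCRPC),
    (State.NMCRPC, State.MCRPC_ASYMPTOMATIC),
    (State.NMCRPC, State.MCRPC_SYMPTOMATIC),
    (State.METASTATIC_NONCASTRATE, State.MCRPC_ASYMPTOMATIC),
    (State.METASTATIC_NONCASTRATE, State.MCRPC_SYMPTOMATIC),
    (State.MCRPC_ASYMPTOMATIC, State.MCRPC_SYMPTOMATIC),
    (State.MCRPC_SYMPTOMATIC, State.MCRPC_POSTCHEMO),
)


def _with_death_edges(edges: Iterable[tuple[State, State]]) -> frozenset[tuple[State, State]]:
    all_edges = set(edges)
    all_edges.update((s, State.DEAD) for s in LIVING_STATES)
    return frozenset(all_edges)


def build_default_topology(
    rate_table: Mapping | None = None,
    *,
    nmcrpc_asymptomatic_split: float = 0.5,
    include_localized_to_locally_advanced: bool = False,
) -> tuple[TransitionTopology, RoutingTable]:
    """Build the default transition graph and routing fractions.

    Parameters
    ----------
    rate_table
        Optional state -> list-of-arm mapping (as loaded by
        :func:`pcstates.config.load_rate_table`). When given, the
        locally-advanced progression split between non-castrate rising
        PSA and nmCRPC is recomputed as the weight share of arms whose
        regimen includes hormonal therapy (castrate relapse); otherwise
        the shipped default of 0.5 is used.
    nmcrpc_asymptomatic_split
        Fraction of nmCRPC (and metastatic non-castrate) progressors
        routed to asymptomatic rather than symptomatic mCRPC. The
        published model derived this split from an external
        chemotherapy-sequencing cohort without printing it; 0.5 is a
        placeholder, not a published value.
    include_localized_to_locally_advanced
        Add a LOCALIZED -> LOCALLY_ADVANCED edge (an active-surveillance
        patient whose local disease worsens). Off by default: the
        model's flow diagram routes localized failures to rising PSA.
        When enabled, routing for LOCALIZED stays entirely on the
        rising-PSA edge; callers wanting mass on the new edge supply
        their own routing.
    """
    edges = list(DEFAULT_PROGRESSION_EDGES)
    if include_localized_to_locally_advanced:
        edges.append((State.LOCALIZED, State.LOCALLY_ADVANCED))

    la_to_nmcrpc = 0.5
    if rate_table is not None:
        arms = rate_table[State.LOCALLY_ADVANCED]
        la_to_nmcrpc = sum(a.weight for a in arms if a.hormonal)

    split = float(nmcrpc_asymptomatic_split)
    if not 0.0 <= split <= 1.0:
        raise ValueError(f"nmcrpc_asymptomatic_split must be in [0, 1], got {split}")

    routing = RoutingTable(
        fractions={
            State.LOCALIZED: {State.RISING_PSA_NONCASTRATE: 1.0},
            State.LOCALLY_ADVANCED: {
                State.RISING_PSA_NONCASTRATE: 1.0 - la_to_nmcrpc,
                State.NMCRPC: la_to_nmcrpc,
            },
            State.RISING_PSA_NONCASTRATE: {State.NMCRPC: 1.0},
            State.NMCRPC: {
                State.MCRPC_ASYMPTOMATIC: split,
                State.MCRPC_SYMPTOMATIC: 1.0 - split,
            },
            State.METASTATIC_NONCASTRATE: {
                State.MCRPC_ASYMPTOMATIC: split,
                State.MCRPC_SYMPTOMATIC: 1.0 - split,
            },
            State.MCRPC_ASYMPTOMATIC: {State.MCRPC_SYMPTOMATIC: 1.0},
            State.MCRPC_SYMPTOMATIC: {State.MCRPC_POSTCHEMO: 1.0},
            State.MCRPC_POSTCHEMO: {},
        }
    )
    return TransitionTopology(edges=_with_death_edges(edges)), routing


def validate_topology(topology: TransitionTopology, routing: RoutingTable) -> TopologyValidation:
    """Structural checks: acyclic progression, death edges, routing mass.

    Returns a report listing every violation rather than raising, so a
    configuration can be diagnosed in one pass.
    """
    report = TopologyValidation()
    g = topology.graph()

    living = g.subgraph(LIVING_STATES)
    if not nx.is_directed_acyclic_graph(living):
        cycle = nx.find_cycle(living)
        report.violations.append(
            "cycle among living states (disease only progresses): "
            + " -> ".join(str(e[0]) for e in cycle)
        )

    for s in LIVING_STATES:
        if (s, State.DEAD) not in topology.edges:
            report.violations.append(f"{s} has no edge to DEAD")
        elif not nx.has_path(g, s, State.DEAD):  # pragma: no cover - implied
            report.violations.append(f"{s} cannot reach DEAD")

    if topology.successors(State.DEAD):
        report.violations.append("DEAD must be absorbing (has outgoing edges)")

    for src in LIVING_STATES:
        dests = routing.destinations(src)
        allowed = topology.living_successors(src)
        for dst, frac in dests.items():
            if frac < 0:
                report.violations.append(f"negative routing fraction {src} -> {dst}")
            if frac > 0 and dst not in allowed:
                report.violations.append(
                    f"routing mass {src} -> {dst} without a topology edge"
                )
        mass = sum(dests.values())
        if dests and abs(mass - 1.0) > _ROUTING_TOL:
            report.violations.append(
                f"routing fractions from {src} sum to {mass:.12g}, expected 1"
            )
        if not dests and allowed:
            report.violations.append(
                f"{src} has living successors {sorted(map(str, allowed))} but no routing"
            )
    return report
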