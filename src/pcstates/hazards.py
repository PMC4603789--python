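"""Piecewise-exponential hazard recovery from landmark survival.

Each clinical state carries published 5- and 10-year overall-survival
(OS) and progression-free-survival (PFS) fractions, measured from entry
into the state. Under a piecewise-constant hazard with breakpoints at 5
and 10 years of state tenure, the landmark fractions pin the rates
exactly:

    h[0,5)  = -ln(S(5)) / 5
    h[5,10) = -ln(S(10) / S(5)) / 5

and the 5-10-year rate is extrapolated beyond 10 years (no third
landmark exists). PFS events are the union of progression and death, so
the cause-specific progression hazard is the excess of the PFS event
rate over the death rate, clamped at zero when the published curves
cross:

    h_death = h_os
    h_prog  = max(h_pfs - h_os, 0)

States with several treatment arms blend the per-arm cause-specific
hazards by arm weight (a mixture of exponential pathways, collapsed to
its rate-mixture approximation at annual resolution).

Annual transition probabilities follow the standard competing-risk
discretization: total exit probability 1 - exp(-(h_p + h_d)) over a
one-year cycle, split between causes in proportion to their rates.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .states import State

__all__ = [
    "SurvivalSummary",
    "TreatmentArm",
    "PiecewiseHazard",
    "Scenario",
    "hazard_from_survival",
    "decompose_competing_risks",
    "arm_hazard",
    "blend_arms",
    "annual_transition_probs",
    "build_hazard_profile",
    "apply_scenario",
    "apply_scenarios",
]

logger = logging.getLogger(__name__)

#: Tenure breakpoints (years in state) of the hazard segments.
BREAKPOINTS: tuple[float, float] = (5.0, 10.0)

#: Landmark fractions below this are clamped before the log transform.
#: Half the resolution of a 3-decimal printed fraction: a printed 0.000
#: is read as "below 0.0005", not as literally zero survival.
DEFAULT_SURVIVAL_FLOOR = 5e-4

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SurvivalSummary:
    """5- and 10-year OS and PFS fractions from state entry."""

    os5: float
    os10: float
    pfs5: float
    pfs10: float

    def floored(self, floor: float) -> "SurvivalSummary":
        return SurvivalSummary(
            os5=max(self.os5, floor),
            os10=max(self.os10, floor),
            pfs5=max(self.pfs5, floor),
            pfs10=max(self.pfs10, floor),
        )


@dataclass(frozen=True)
class TreatmentArm:
    """One treatment approach within a state, with its population share."""

    label: str
    survival: SurvivalSummary
    weight: float
    #: Regimen includes hormonal therapy (drives locally-advanced routing).
    hormonal: bool = False
    source: str = ""


@dataclass(frozen=True)
class PiecewiseHazard:
    """Cause-specific annual hazards by tenure segment [0,5), [5,10), [10,inf)."""

    progression: tuple[float, float, float]
    death: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, rates in (("progression", self.progression), ("death", self.death)):
            if len(rates) != 3:
                raise ValueError(f"{name} must have 3 segment rates")
            for r in rates:
                if not math.isfinite(r) or r < 0:
                    raise ValueError(f"{name} rate {r!r} must be finite and >= 0")

    def _segment(self, tenure: float) -> int:
        if tenure < BREAKPOINTS[0]:
            return 0
        if tenure < BREAKPOINTS[1]:
            return 1
        return 2

    def rates_at(self, tenure: float) -> tuple[float, float]:
        """(h_progression, h_death) applying at the given tenure."""
        i = self._segment(tenure)
        return self.progression[i], self.death[i]

    def rate_arrays(self, tenures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`rates_at` over an array of tenures."""
        seg = np.digitize(tenures, BREAKPOINTS)
        return (
            np.asarray(self.progression, dtype=float)[seg],
            np.asarray(self.death, dtype=float)[seg],
        )

    def scaled(self, progression_factor: float = 1.0, death_factor: float = 1.0) -> "PiecewiseHazard":
        return PiecewiseHazard(
            progression=tuple(h * progression_factor for h in self.progression),
            death=tuple(h * death_factor for h in self.death),
        )


@dataclass(frozen=True)
class Scenario:
    """A hypothetical intervention: relative PFS/OS gains in target states.

    Improvements are relative gains (0.25 = "25% improvement"). From
    ``introduction_year`` onward, the progression hazard of each target
    state is divided by ``1 + pfs_improvement`` and the death hazard by
    ``1 + os_improvement`` (the gain read as an extension of expected
    event-free time). The alternative reading -- hazard multiplied by
    ``1 - improvement`` -- is selected with ``semantics="hazard_scale"``.
    """

    name: str
    states: frozenset[State]
    pfs_improvement: float = 0.0
    os_improvement: float = 0.0
    introduction_year: int = 2015
    semantics: str = "extend_time"

    def __post_init__(self) -> None:
        if self.pfs_improvement < 0 or self.os_improvement < 0:
            raise ValueError("scenario improvements must be >= 0")
        if self.semantics not in ("extend_time", "hazard_scale"):
            raise ValueError(f"unknown scenario semantics {self.semantics!r}")
        object.__setattr__(self, "states", frozenset(self.states))

    def hazard_factors(self) -> tuple[float, float]:
        """(progression multiplier, death multiplier) for target states."""
        if self.semantics == "extend_time":
            return 1.0 / (1.0 + self.pfs_improvement), 1.0 / (1.0 + self.os_improvement)
        return 1.0 - self.pfs_improvement, 1.0 - self.os_improvement


def hazard_from_survival(s5: float, s10: float) -> tuple[float, float]:
    """Recover (h[0,5), h[5,10)) from 5- and 10-year survival fractions.

    Exact inversion of the piecewise-exponential survival curve:
    ``exp(-5*h1) == s5`` and ``exp(-5*h1 - 5*h2) == s10``.

    Raises
    ------
    ValueError
        If the landmarks are non-positive, exceed 1, or increase over
        time; the message names the offending landmark.
    """
    if not 0.0 < s5 <= 1.0:
        raise ValueError(f"5-year survival landmark must be in (0, 1], got {s5!r}")
    if not 0.0 < s10 <= 1.0:
        raise ValueError(f"10-year survival landmark must be in (0, 1], got {s10!r}")
    if s10 > s5:
        raise ValueError(
            f"10-year landmark {s10!r} exceeds 5-year landmark {s5!r}: "
            "survival must be non-increasing"
        )
    h1 = -math.log(s5) / 5.0
    h2 = -math.log(s10 / s5) / 5.0
    return max(h1, 0.0), max(h2, 0.0)


def decompose_competing_risks(h_pfs: float, h_os: float) -> tuple[float, float]:
    """Split a PFS event rate into cause-specific (progression, death) rates.

    PFS events include deaths, so the death hazard is the OS hazard and
    progression is the excess rate, clamped at zero if the inputs cross
    (a data inconsistency between independently sourced curves).
    """
    if h_pfs < 0 or h_os < 0:
        raise ValueError("hazard rates must be >= 0")
    return max(h_pfs - h_os, 0.0), h_os


def arm_hazard(
    arm: TreatmentArm,
    *,
    survival_floor: float = DEFAULT_SURVIVAL_FLOOR,
    max_hazard: float | None = None,
) -> PiecewiseHazard:
    """Cause-specific piecewise hazard of a single treatment arm."""
    s = arm.survival.floored(survival_floor)
    h_os = hazard_from_survival(s.os5, s.os10)
    h_pfs = hazard_from_survival(s.pfs5, s.pfs10)
    prog, death = [], []
    for seg in range(2):
        if h_pfs[seg] < h_os[seg] and s.pfs5 > survival_floor:
            logger.warning(
                "arm %s, years %s: PFS hazard %.4g below OS hazard %.4g "
                "(published curves cross); progression clamped at 0",
                arm.label, ("0-5", "5-10")[seg], h_pfs[seg], h_os[seg],
            )
        p, d = decompose_competing_risks(h_pfs[seg], h_os[seg])
        prog.append(p)
        death.append(d)
    prog.append(prog[1])  # constant-hazard tail beyond 10 years
    death.append(death[1])
    if max_hazard is not None:
        prog = [min(h, max_hazard) for h in prog]
        death = [min(h, max_hazard) for h in death]
    return PiecewiseHazard(progression=tuple(prog), death=tuple(death))


def blend_arms(
    arms: Sequence[TreatmentArm],
    *,
    survival_floor: float = DEFAULT_SURVIVAL_FLOOR,
    max_hazard: float | None = None,
) -> PiecewiseHazard:
    """Weight-average the cause-specific hazards of a state's arms."""
    if not arms:
        raise ValueError("need at least one treatment arm")
    total = sum(a.weight for a in arms)
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"arm weights sum to {total!r}, expected 1.0")
    hazards = [
        arm_hazard(a, survival_floor=survival_floor, max_hazard=max_hazard)
        for a in arms
    ]
    prog = tuple(
        sum(a.weight * h.progression[i] for a, h in zip(arms, hazards))
        for i in range(3)
    )
    death = tuple(
        sum(a.weight * h.death[i] for a, h in zip(arms, hazards)) for i in range(3)
    )
    return PiecewiseHazard(progression=prog, death=death)


def annual_transition_probs(
    hazard: PiecewiseHazard, tenure: float, *, exposure: float = 1.0
) -> tuple[float, float, float]:
    """(p_progress, p_die, p_stay) over one annual cycle at a given tenure.

    Competing exponential clocks at the segment's rates: the total exit
    probability is ``1 - exp(-(h_p + h_d) * exposure)``, split between
    causes proportionally to their rates. Probabilities sum to 1.
    """
    if tenure < 0:
        raise ValueError("tenure must be >= 0")
    h_p, h_d = hazard.rates_at(tenure)
    total = h_p + h_d
    if total == 0.0:
        return 0.0, 0.0, 1.0
    p_exit = -math.expm1(-total * exposure)
    return p_exit * h_p / total, p_exit * h_d / total, 1.0 - p_exit


def build_hazard_profile(
    rate_table: Mapping[State, Sequence[TreatmentArm]],
    *,
    survival_floor: float = DEFAULT_SURVIVAL_FLOOR,
    max_hazard: float | None = None,
    terminal_states: Iterable[State] = (State.MCRPC_POSTCHEMO,),
) -> dict[State, PiecewiseHazard]:
    """Per-state blended hazards from a rate table.

    Terminal living states (no living successor) get their progression
    hazard forced to zero: their PFS events have nowhere to route and
    are indistinguishable from remaining in state.
    """
    terminal = frozenset(terminal_states)
    profile: dict[State, PiecewiseHazard] = {}
    for state, arms in rate_table.items():
        h = blend_arms(arms, survival_floor=survival_floor, max_hazard=max_hazard)
        if state in terminal:
            h = replace(h, progression=(0.0, 0.0, 0.0))
        profile[state] = h
    return profile


def apply_scenario(
    profile: Mapping[State, PiecewiseHazard],
    scenario: Scenario,
    year: int,
) -> dict[State, PiecewiseHazard]:
    """Hazard profile in effect in ``year`` under an intervention.

    Before the introduction year, or for states outside the target set,
    hazards are unchanged. The input profile is never mutated.
    """
    unknown = scenario.states - set(profile)
    if unknown:
        raise KeyError(f"scenario targets unknown states: {sorted(map(str, unknown))}")
    out = dict(profile)
    if year < scenario.introduction_year:
        return out
    f_prog, f_death = scenario.hazard_factors()
    for state in scenario.states:
        out[state] = profile[state].scaled(f_prog, f_death)
    return out


def apply_scenarios(
    profile: Mapping[State, PiecewiseHazard],
    scenarios: Iterable[Scenario],
    year: int,
) -> dict[State, PiecewiseHazard]:
    """Compose several (disjoint or stacked) interventions for one year."""
    out = dict(profile)
    for sc in scenarios:
        out = apply_scenario(out, sc, year)
    return out
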