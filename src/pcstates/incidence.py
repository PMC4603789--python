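"""Annual diagnosed-incidence inputs by stage at diagnosis.

The simulation is driven by the number of men diagnosed each calendar
year in each of three stages: localized, locally advanced, and
metastatic (non-castrate). The historical series the original model
drew from cancer-registry age-specific rates is not published, so this
module provides (a) a CSV loader for a user-supplied series, (b) a
geometric forward projection anchored to printed target values, and
(c) a deterministic synthetic-series generator that interpolates
between anchor years -- the shipped default interpolates a chosen 1990
level to the published 2009 values and is explicitly non-authoritative.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STAGES",
    "IncidenceSeries",
    "ProjectionSpec",
    "load_series",
    "project_forward",
    "synthesize_historical_series",
    "default_series",
]

#: Diagnosis stages, in the column order of incidence CSV files.
STAGES: tuple[str, ...] = ("localized", "locally_advanced", "metastatic")


@dataclass(frozen=True)
class IncidenceSeries:
    """Diagnosed counts (persons/year) per calendar year per stage.

    Wraps a DataFrame indexed by contiguous years with one non-negative
    column per stage.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in STAGES if c not in f.columns]
        if missing:
            raise ValueError(f"incidence series missing stage columns {missing}")
        years = f.index.to_numpy()
        if len(years) == 0:
            raise ValueError("incidence series is empty")
        if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
            raise ValueError("incidence series years must be contiguous")
        if (f[list(STAGES)].to_numpy() < 0).any():
            raise ValueError("incidence counts must be >= 0")

    @property
    def start(self) -> int:
        return int(self.frame.index[0])

    @property
    def end(self) -> int:
        return int(self.frame.index[-1])

    def year(self, year: int) -> dict[str, float]:
        """Stage -> count for one calendar year."""
        row = self.frame.loc[year]
        return {s: float(row[s]) for s in STAGES}

    def total(self, year: int | None = None) -> float:
        if year is not None:
            return float(sum(self.year(year).values()))
        return float(self.frame[list(STAGES)].to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        out = self.frame[list(STAGES)].copy()
        out.insert(0, "year", out.index)
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class ProjectionSpec:
    """How counts grow after a base year.

    Either fixed per-stage geometric growth rates, or per-stage
    ``(target_year, target_count)`` anchors from which the growth rate
    is solved so the anchor is hit exactly.
    """

    base_year: int
    growth: Mapping[str, float] | None = None
    anchors: Mapping[str, tuple[int, float]] | None = None

    def __post_init__(self) -> None:
        if (self.growth is None) == (self.anchors is None):
            raise ValueError("provide exactly one of growth or anchors")
        if self.growth is not None:
            for stage, g in self.growth.items():
                if g <= -1:
                    raise ValueError(f"growth rate for {stage} must be > -1, got {g}")

    def rate(self, stage: str, base_count: float) -> float:
        if self.growth is not None:
            return float(self.growth.get(stage, 0.0))
        year, target = self.anchors[stage]
        if year <= self.base_year:
            raise ValueError(f"anchor year {year} must be after base year {self.base_year}")
        if base_count <= 0:
            raise ValueError(f"cannot anchor stage {stage} with zero base count")
        return float((target / base_count) ** (1.0 / (year - self.base_year)) - 1.0)


def load_series(path: str | Path) -> IncidenceSeries:
    """Read an incidence CSV (columns: year, localized, locally_advanced,
    metastatic) with row-level validation."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty incidence file") from exc
    required = ["year", *STAGES]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in frame.iterrows():
        for col in required:
            v = row[col]
            if pd.isna(v):
                raise ValueError(f"{path} row {i + 2}: missing value in {col!r}")
        if any(row[s] < 0 for s in STAGES):
            raise ValueError(f"{path} row {i + 2}: negative count")
    frame = frame.astype({"year": int}).set_index("year").sort_index()
    years = frame.index.to_numpy()
    gaps = set(range(int(years[0]), int(years[-1]) + 1)) - set(int(y) for y in years)
    if gaps:
        raise ValueError(f"{path}: missing years {sorted(gaps)}")
    return IncidenceSeries(frame=frame[list(STAGES)].astype(float))


def project_forward(
    series: IncidenceSeries, spec: ProjectionSpec, horizon: int
) -> IncidenceSeries:
    """Extend a series to ``horizon`` by per-stage geometric growth.

    ``count(y) = count(base) * (1 + g)^(y - base)``; with anchor pairs
    the growth rate is solved so the anchor year's value is exact.
    """
    if horizon < spec.base_year:
        raise ValueError(f"horizon {horizon} before base year {spec.base_year}")
    if not series.start <= spec.base_year <= series.end:
        raise ValueError(f"base year {spec.base_year} not in series")
    base = series.year(spec.base_year)
    rows = {}
    for y in range(spec.base_year + 1, horizon + 1):
        rows[y] = {
            s: base[s] * (1.0 + spec.rate(s, base[s])) ** (y - spec.base_year)
            for s in STAGES
        }
    head = series.frame.loc[: spec.base_year]
    tail = pd.DataFrame.from_dict(rows, orient="index")
    frame = pd.concat([head, tail]) if rows else head.copy()
    frame.index.name = "year"
    return IncidenceSeries(frame=frame[list(STAGES)])


def synthesize_historical_series(
    anchors: Mapping[int, Mapping[str, float]],
    *,
    shape: str = "linear",
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> IncidenceSeries:
    """Interpolate stage counts between anchor years.

    Parameters
    ----------
    anchors
        year -> {stage: count}; at least two anchor years per stage,
        in increasing year order.
    shape
        ``"linear"`` or ``"log_linear"`` (geometric) interpolation.
    seed, noise_cv
        Optional multiplicative lognormal noise with the given
        coefficient of variation, deterministic for a fixed seed.
    """
    years = list(anchors)
    if years != sorted(years):
        raise ValueError("anchor years must be in increasing order")
    if len(years) < 2:
        raise ValueError("need at least 2 anchor years")
    if shape not in ("linear", "log_linear"):
        raise ValueError(f"unknown interpolation shape {shape!r}")
    grid = np.arange(years[0], years[-1] + 1)
    data = {}
    for stage in STAGES:
        vals = np.array([float(anchors[y][stage]) for y in years])
        if shape == "linear":
            data[stage] = np.interp(grid, years, vals)
        else:
            if (vals <= 0).any():
                raise ValueError("log_linear interpolation needs positive anchors")
            data[stage] = np.exp(np.interp(grid, years, np.log(vals)))
    frame = pd.DataFrame(data, index=pd.Index(grid, name="year"))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=frame.shape)
        frame = frame * noise
    return IncidenceSeries(frame=frame)


def _default_anchor_config() -> dict:
    ref = resources.files("pcstates.data") / "incidence_anchors.yaml"
    return yaml.safe_load(ref.read_text())


def default_series(horizon: int = 2020, *, shape: str = "linear") -> IncidenceSeries:
    """The shipped default series: 1990 level interpolated to the
    published 2009 stage counts, then projected geometrically so the
    2020 values hit the published anchors exactly.

    Non-authoritative: the true historical series is not published.
    """
    cfg = _default_anchor_config()
    anchors = {int(y): v for y, v in cfg["anchors"].items()}
    series = synthesize_historical_series(anchors, shape=shape)
    proj = cfg["projection"]
    if horizon <= series.end:
        return IncidenceSeries(frame=series.frame.loc[:horizon])
    spec = ProjectionSpec(
        base_year=int(proj["base_year"]),
        anchors={s: (int(a[0]), float(a[1])) for s, a in proj["anchors"].items()},
    )
    return project_forward(series, spec, horizon)
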