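"""Typed data model for reservoir nutrient mass balances.

Concentrations are g m⁻³ (≡ mg L⁻¹) throughout, chlorophyll *a* in mg m⁻³;
discharges are m³ s⁻¹; element loads are metric tonnes per year.  Dates are
calendar dates without time of day, and the balance year is the calendar
year (the unit-conversion constant is fixed at 365 days even in leap years,
so that stock-change and areal-rate arithmetic stays bit-compatible across
years).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Analyte",
    "RouteRole",
    "AnalyteSample",
    "FlowSeries",
    "ReservoirSpec",
    "AnnualBudget",
    "SourceLoadBreakdown",
    "SedimentStoichiometry",
    "CascadeTopology",
    "PumpingEvent",
    "WaterBudget",
    "SedimentBudget",
    "RetentionLedger",
    "RatioRecord",
    "CorrelationCell",
    "DomainError",
    "CoverageError",
    "total_nitrogen",
]


class DomainError(ValueError):
    """An input is outside the physically meaningful domain."""


def total_nitrogen(no3: float, no2: float, kjeldahl: float) -> float:
    """Total nitrogen (g m⁻³) as the sum of nitrate-N, nitrite-N and
    Kjeldahl (organic + ammonium) nitrogen."""
    for name, v in (("no3", no3), ("no2", no2), ("kjeldahl", kjeldahl)):
        if v < 0:
            raise DomainError(f"negative nitrogen component {name}={v}")
    return float(no3 + no2 + kjeldahl)


class CoverageError(ValueError):
    """A daily series does not cover the requested balance period."""

    def __init__(self, message: str, missing_days: Sequence[dt.date] = ()):
        super().__init__(message)
        self.missing_days = list(missing_days)


class Analyte(str, Enum):
    """Water-chemistry determinands carried through the balance."""

    TN = "TN"
    NO3 = "N-NO3"
    NO2 = "N-NO2"
    NH4 = "N-NH4"
    KJELDAHL = "N_Kjeld"
    TP = "TP"
    PO4 = "P-PO4"
    DSI = "DSi"
    TOC = "TOC"
    CHLOROPHYLL = "chlorophyll_a"

    @classmethod
    def parse(cls, code: str) -> "Analyte":
        try:
            return cls(code)
        except ValueError:
            raise DomainError(
                f"unknown analyte code {code!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


class RouteRole(str, Enum):
    """How a water route is wired into the cascade."""

    AFFLUENT_MAJOR = "affluent_major"
    AFFLUENT_MINOR = "affluent_minor"
    INTER_RESERVOIR = "inter_reservoir"
    PUMPING_REVERSE = "pumping_reverse"
    OUTFLOW = "outflow"


@dataclass(frozen=True)
class AnalyteSample:
    """One dated concentration measurement at a station.

    ``concentration`` is g m⁻³ for all analytes except chlorophyll *a*,
    which is mg m⁻³.
    """

    station_id: str
    analyte: Analyte
    date: dt.date
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DomainError(
                f"negative concentration {self.concentration} at "
                f"{self.station_id}/{self.analyte.value} on {self.date}"
            )


@dataclass
class FlowSeries:
    """Daily discharge record (m³ s⁻¹) for one water route.

    ``discharge`` is a pandas Series indexed by normalized daily
    timestamps.  ``validate`` enforces non-negativity and gap-free daily
    coverage inside the span of the series.
    """

    route_id: str
    role: RouteRole
    discharge: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.discharge).astype(float)
        s.index = pd.DatetimeIndex(s.index).normalize()
        s = s.sort_index()
        self.discharge = s

    def validate(self) -> "FlowSeries":
        if (self.discharge < 0).any():
            bad = self.discharge[self.discharge < 0].index[0].date()
            raise DomainError(
                f"negative discharge on route {self.route_id} at {bad}"
            )
        full = pd.date_range(self.discharge.index[0], self.discharge.index[-1])
        missing = full.difference(self.discharge.index)
        if len(missing):
            raise CoverageError(
                f"route {self.route_id} has {len(missing)} missing days "
                f"(first: {missing[0].date()})",
                [ts.date() for ts in missing],
            )
        if self.discharge.index.has_duplicates:
            raise DomainError(f"route {self.route_id} has duplicate days")
        return self

    def year_slice(self, year: int) -> pd.Series:
        return self.discharge[self.discharge.index.year == year]


@dataclass
class ReservoirSpec:
    """Morphometry and hydrology of one reservoir."""

    name: str
    volume: float               # m³
    mean_depth: float           # m
    surface_area: float         # m²
    hrt: float                  # days
    backwater_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.backwater_fraction <= 1.0:
            raise DomainError(
                f"backwater_fraction {self.backwater_fraction} outside [0, 1]"
            )
        implied = self.mean_depth * self.surface_area
        if implied > 0 and abs(self.volume - implied) > 0.2 * implied:
            warnings.warn(
                f"reservoir {self.name}: volume {self.volume:.3g} m³ differs "
                f"from mean_depth × surface_area = {implied:.3g} m³ by more "
                "than 20 %",
                stacklevel=2,
            )


@dataclass
class SourceLoadBreakdown:
    """External input loads (t yr⁻¹) for one element and reservoir.

    The direct-drainage term aggregates point sources, nonpoint runoff and
    the recreational (bather) load; its sub-model estimation happens
    upstream of this package and the three summands arrive as numbers.
    """

    element: Analyte
    riverine: float = 0.0
    point: float = 0.0
    nonpoint: float = 0.0
    bathers: float = 0.0
    atmospheric: float = 0.0
    pumping_in: float = 0.0

    def __post_init__(self) -> None:
        for name in ("riverine", "point", "nonpoint", "bathers",
                     "atmospheric", "pumping_in"):
            if getattr(self, name) < 0:
                raise DomainError(f"negative load component {name}")

    @property
    def direct_drainage(self) -> float:
        return self.point + self.nonpoint + self.bathers

    @property
    def external(self) -> float:
        """Sum of sources external to the cascade (pumping excluded)."""
        return self.riverine + self.direct_drainage + self.atmospheric

    @property
    def total(self) -> float:
        return self.external + self.pumping_in


@dataclass(frozen=True)
class SedimentStoichiometry:
    """Mass ratios of benthic deposits used to convert the P budget.

    ``np_ratio`` is total-N : total-P and ``cn_ratio`` organic-C : total-N
    in the surface sediment layer.
    """

    np_ratio: float
    cn_ratio: float

    def __post_init__(self) -> None:
        if self.np_ratio <= 0 or self.cn_ratio <= 0:
            raise DomainError("sediment stoichiometry ratios must be > 0")


@dataclass(frozen=True)
class PumpingEvent:
    start: dt.date
    end: dt.date
    rate: float  # m³ s⁻¹, lower → upper


@dataclass
class CascadeTopology:
    """Wiring of routes to an ordered (upper → lower) reservoir cascade."""

    reservoirs: list[ReservoirSpec]
    routes: dict[str, tuple[RouteRole, str]]  # route_id -> (role, reservoir fed/drained)
    pumping: list[PumpingEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        outflows = [r for r, (role, _) in self.routes.items()
                    if role is RouteRole.OUTFLOW]
        if len(outflows) != 1:
            raise DomainError(
                f"cascade must have exactly one outflow route, got {outflows}"
            )

    @property
    def outflow_route(self) -> str:
        return next(r for r, (role, _) in self.routes.items()
                    if role is RouteRole.OUTFLOW)

    def inflow_routes(self, reservoir: str) -> list[str]:
        """Routes delivering water into *reservoir* (incl. transfers)."""
        keep = (RouteRole.AFFLUENT_MAJOR, RouteRole.AFFLUENT_MINOR,
                RouteRole.INTER_RESERVOIR, RouteRole.PUMPING_REVERSE)
        return [r for r, (role, res) in self.routes.items()
                if res == reservoir and role in keep]

    def affluent_routes(self, reservoir: str) -> list[str]:
        keep = (RouteRole.AFFLUENT_MAJOR, RouteRole.AFFLUENT_MINOR)
        return [r for r, (role, res) in self.routes.items()
                if res == reservoir and role in keep]


@dataclass
class WaterBudget:
    """Annual hydraulic budget; w_ret = inflow − outflow volume (m³)."""

    reservoir: str
    year: int
    inflow_volume: float
    outflow_volume: float

    @property
    def w_ret(self) -> float:
        return self.inflow_volume - self.outflow_volume


@dataclass
class AnnualBudget:
    """Input/output/retention for one element, reservoir (or the whole
    complex) and year, in t yr⁻¹.

    ``retention`` may be negative; a negative value is *elimination* (the
    water body exported more than it received) and is reported through
    ``elimination_pct``.  Exactly one of the two percentage fields is set
    whenever retention is nonzero; both are zero for a closed balance and
    both are ``None`` when the input load is zero (percentage undefined).
    Closure input − output − retention = 0 holds exactly by construction.
    """

    element: Analyte
    reservoir: str
    year: int
    input_load: float
    output_load: float
    retention: float
    retention_pct: Optional[float] = None
    elimination_pct: Optional[float] = None
    load_uncertainty_pct: Optional[float] = None
    retention_uncertainty: Optional[float] = None
    undefined_pct: bool = False
    sources: Optional[SourceLoadBreakdown] = None
    upstream_in: float = 0.0

    def __post_init__(self) -> None:
        resid = self.input_load - self.output_load - self.retention
        if abs(resid) > 1e-9 * max(1.0, abs(self.input_load)):
            raise DomainError(
                f"budget closure violated by {resid} t for "
                f"{self.element.value}/{self.reservoir}/{self.year}"
            )
        if self.retention_pct is not None and self.elimination_pct is not None:
            if self.retention_pct != 0.0 or self.elimination_pct != 0.0:
                raise DomainError(
                    "retention_pct and elimination_pct are mutually exclusive"
                )


@dataclass
class SedimentBudget:
    """Phosphorus-anchored sedimentation estimate for a reservoir-period."""

    reservoir: str
    period: str
    p_ret: float            # t yr⁻¹
    delta_p: float          # t yr⁻¹, water-column stock change rate
    n_sed: float            # t yr⁻¹
    c_sed: float            # t yr⁻¹
    n_backwater: float = 0.0
    n_lacustrine: float = 0.0
    c_backwater: float = 0.0
    c_lacustrine: float = 0.0
    n_rate: Optional[float] = None  # g m⁻² day⁻¹
    c_rate: Optional[float] = None


@dataclass
class RetentionLedger:
    """Partition of a retained mass into named process terms.

    ``indefinite`` is the residual retention − Σ terms, closing the ledger
    exactly; ``shares`` holds derived percentages (e.g. denitrification as
    a share of retention).
    """

    element: Analyte
    inflow: float
    retention: float
    terms: dict[str, float]
    indefinite: float
    shares: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        resid = self.retention - sum(self.terms.values()) - self.indefinite
        if abs(resid) > 1e-9 * max(1.0, abs(self.retention)):
            raise DomainError(f"ledger closure violated by {resid} t")


@dataclass
class RatioRecord:
    """Water-column nutrient stoichiometry at one station and date.

    Molar ratios are ``None`` when the denominator concentration is zero
    (undefined, flagged downstream rather than infinite).
    """

    station: str
    date: dt.date
    np_molar: Optional[float]
    si_n_molar: Optional[float]
    si_p_molar: Optional[float]
    dsi: float
    chl_a: Optional[float] = None


@dataclass(frozen=True)
class CorrelationCell:
    """One Pearson cell of the retention-vs-drivers screen."""

    response: str
    driver: str
    r: float
    p_value: float
    significance_tier: str  # "p<0.001" | "p<0.01" | "p<0.05" | "ns"
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise DomainError(f"|r| = {abs(self.r)} exceeds 1")
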