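"""Seeded synthetic monitoring campaigns for a two-reservoir cascade.

The generator emulates a large, hypolimnetically coupled mountain
reservoir pair: an upper main reservoir (default 502 × 10⁶ m³, mean depth
22 m, hydraulic retention time 215 d, mean through-flow 35 m³ s⁻¹) fed by
three major affluents carrying ~90 % of the water supply plus three minor
ones, and a small downstream compensatory reservoir (10 × 10⁶ m³, 5 m,
6 d) fed ~90 % by the hypolimnetic outflow of the upper one.  Sporadic
reverse pumping returns lower-reservoir water upstream.

Daily discharges follow a sinusoidal seasonal cycle with an early-spring
maximum plus lognormal day-to-day noise; the complex outflow is defined
pointwise as the sum of external inflows, so the annual water balance of
the cascade closes by construction.  True daily concentrations are shaped
(seasonality, optional discharge dependence for organic carbon, a summer
drawdown for dissolved silicon) and then scaled per route and year so the
true annual input loads hit configured targets; outflow concentrations are
scaled to impose configured true retention fractions.  The sparse observed
dataset is drawn from the daily truth at a jittered 1–6-week cadence with
lognormal measurement noise, which is what a real campaign would see.

Every quantity the estimation pipeline later infers — input, output and
retention per element, reservoir and year — is therefore known exactly and
reported by :func:`truth_report` for recovery testing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    Analyte,
    AnalyteSample,
    CascadeTopology,
    DomainError,
    FlowSeries,
    PumpingEvent,
    ReservoirSpec,
    RouteRole,
)

__all__ = [
    "ElementScenario",
    "ScenarioConfig",
    "ScenarioTruth",
    "ScenarioData",
    "generate_flows",
    "generate_chemistry",
    "truth_report",
    "simulate",
    "DEFAULT_ELEMENTS",
]

SECONDS_PER_DAY = 86400.0
UPPER, LOWER = "upper", "lower"


@dataclass(frozen=True)
class ElementScenario:
    """Ground-truth parameters for one element.

    ``total_input`` is the true external annual input to the whole complex
    (t yr⁻¹); ``riverine_share`` the fraction arriving with affluent
    waters (the remainder is booked as direct-drainage and atmospheric
    side loads).  Retention fractions apply to each reservoir's external
    throughput.  ``flow_exponent`` couples concentration to discharge
    (c ∝ Q^b); ``summer_drawdown`` deepens the in-reservoir summer minimum
    of the outflowing concentration (used for dissolved silicon, whose
    epilimnetic depletion the diagnostics should detect).
    """

    total_input: float
    riverine_share: float
    upper_retention: float
    lower_retention: float
    seasonal_amplitude: float = 0.0
    flow_exponent: float = 0.0
    summer_drawdown: float = 0.0


#: Default study conditions: annual external inputs within the observed
#: ranges of a large mesotrophic mountain cascade, riverine shares from the
#: observed source apportionment, and retention fractions around the
#: 15–30 % sink behaviour, concentrated in the upper reservoir.
DEFAULT_ELEMENTS: dict[Analyte, ElementScenario] = {
    Analyte.TN: ElementScenario(1700.0, 0.87, 0.15, 0.02),
    Analyte.TP: ElementScenario(90.0, 0.81, 0.25, 0.02),
    Analyte.DSI: ElementScenario(2150.0, 0.81, 0.15, 0.02,
                                 seasonal_amplitude=0.3, summer_drawdown=0.8),
    Analyte.TOC: ElementScenario(2700.0, 0.90, 0.12, 0.02,
                                 seasonal_amplitude=0.1, flow_exponent=0.4),
}


def _default_reservoirs() -> list[ReservoirSpec]:
    return [
        ReservoirSpec(UPPER, volume=502e6, mean_depth=22.0,
                      surface_area=22.8e6, hrt=215.0, backwater_fraction=2 / 3),
        ReservoirSpec(LOWER, volume=10e6, mean_depth=5.0,
                      surface_area=2.0e6, hrt=6.0, backwater_fraction=0.0),
    ]


@dataclass
class ScenarioConfig:
    seed: int = 0
    years: int = 3
    start_year: int = 2004
    reservoirs: list[ReservoirSpec] = field(default_factory=_default_reservoirs)
    mean_discharge: float = 35.0              # m³ s⁻¹, upper-reservoir supply
    major_shares: tuple[float, ...] = (0.50, 0.25, 0.15)
    minor_shares: tuple[float, ...] = (0.04, 0.03, 0.03)
    lower_minor_shares: tuple[float, ...] = (0.5, 0.3, 0.2)
    lower_external_fraction: float = 0.1      # share of lower supply not hypolimnetic
    flow_cv: float = 0.3
    seasonal_flow_amplitude: float = 0.4
    flow_peak_doy: int = 80                   # early-spring discharge maximum
    storage_drift_cv: float = 0.02            # annual inflow/outflow imbalance
    noise_cv: float = 0.15                    # lognormal measurement noise
    mean_sampling_gap: float = 33.0           # days between visits
    sampling_gap_min: float = 7.0             # jitter window: 1–6 weeks
    sampling_gap_max: float = 42.0
    pumping_events_per_year: int = 2
    pumping_rate: float = 20.0                # m³ s⁻¹ during an event
    pumping_duration: int = 4                 # days per event
    elements: dict[Analyte, ElementScenario] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENTS)
    )

    def __post_init__(self) -> None:
        total = sum(self.major_shares) + sum(self.minor_shares)
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"upper supply shares sum to {total}, not 1")
        if abs(sum(self.lower_minor_shares) - 1.0) > 1e-9:
            raise DomainError("lower minor shares must sum to 1")
        for a, e in self.elements.items():
            if not -0.2 < e.upper_retention < 0.6:
                raise DomainError(
                    f"{a.value}: upper retention fraction outside (−0.2, 0.6)"
                )
            if not -0.2 < e.lower_retention < 0.6:
                raise DomainError(
                    f"{a.value}: lower retention fraction outside (−0.2, 0.6)"
                )

    @property
    def calendar(self) -> pd.DatetimeIndex:
        return pd.date_range(
            f"{self.start_year}-01-01",
            f"{self.start_year + self.years - 1}-12-31",
        )

    @property
    def year_range(self) -> range:
        return range(self.start_year, self.start_year + self.years)


@dataclass
class ScenarioTruth:
    """Exact generator-side budgets: one row per element/reservoir/year
    (reservoir ``complex`` for the cascade), closing input − output −
    retention = 0 by construction."""

    budgets: pd.DataFrame
    water: pd.DataFrame

    def lookup(self, element: Analyte, reservoir: str, year: int) -> pd.Series:
        b = self.budgets
        row = b[(b.element == element.value) & (b.reservoir == reservoir)
                & (b.year == year)]
        if len(row) != 1:
            raise KeyError((element, reservoir, year))
        return row.iloc[0]


@dataclass
class ScenarioData:
    config: ScenarioConfig
    flows: dict[str, FlowSeries]
    topology: CascadeTopology
    samples: list[AnalyteSample]
    truth: ScenarioTruth
    side_loads: dict[tuple[str, str], dict[str, float]]
    daily_concentration: dict[tuple[str, str], pd.Series]  # (route, element)


def _season(doy: np.ndarray, amplitude: float, peak_doy: float) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _lognoise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1 + cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, n))


def _route_table(config: ScenarioConfig) -> dict[str, tuple[RouteRole, str, float]]:
    """route_id -> (role, reservoir fed, mean discharge m³ s⁻¹)."""
    routes: dict[str, tuple[RouteRole, str, float]] = {}
    for i, share in enumerate(config.major_shares, 1):
        routes[f"major_{i}"] = (RouteRole.AFFLUENT_MAJOR, UPPER,
                                share * config.mean_discharge)
    for i, share in enumerate(config.minor_shares, 1):
        routes[f"minor_{i}"] = (RouteRole.AFFLUENT_MINOR, UPPER,
                                share * config.mean_discharge)
    lower_ext = config.mean_discharge * config.lower_external_fraction / (
        1 - config.lower_external_fraction
    )
    for i, share in enumerate(config.lower_minor_shares, 1):
        routes[f"lminor_{i}"] = (RouteRole.AFFLUENT_MINOR, LOWER,
                                 share * lower_ext)
    return routes


def generate_flows(
    config: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, FlowSeries], CascadeTopology]:
    """Daily discharge series for every route, plus the wired topology.

    The hypolimnetic transfer equals the summed upper inflows plus any
    pumped water (steady-state storage), and the dam outflow equals the
    total external inflow, so annual cascade inflow and outflow volumes
    are identical by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    cal = config.calendar
    doy = cal.dayofyear.to_numpy().astype(float)
    season = _season(doy, config.seasonal_flow_amplitude, config.flow_peak_doy)

    flows: dict[str, FlowSeries] = {}
    routes = _route_table(config)
    for rid, (role, _fed, mean_q) in routes.items():
        q = mean_q * season * _lognoise(rng, len(cal), config.flow_cv)
        flows[rid] = FlowSeries(rid, role, pd.Series(q, index=cal))

    pump_q = np.zeros(len(cal))
    events: list[PumpingEvent] = []
    for year in config.year_range:
        in_year = cal.year == year
        offsets = np.flatnonzero(in_year)
        for _ in range(config.pumping_events_per_year):
            start = int(rng.integers(0, in_year.sum() - config.pumping_duration))
            sel = offsets[start:start + config.pumping_duration]
            pump_q[sel] = config.pumping_rate
            events.append(
                PumpingEvent(cal[sel[0]].date(), cal[sel[-1]].date(),
                             config.pumping_rate)
            )
    flows["pumping"] = FlowSeries(
        "pumping", RouteRole.PUMPING_REVERSE, pd.Series(pump_q, index=cal)
    )

    upper_in = sum(
        flows[r].discharge for r, (role, fed, _) in routes.items() if fed == UPPER
    )
    lower_ext = sum(
        flows[r].discharge for r, (role, fed, _) in routes.items() if fed == LOWER
    )
    # small annual storage drift so hydraulic retention (W_ret) is not
    # identically zero; the cascade water balance still closes to within
    # storage_drift_cv each year
    year_of = cal.year.to_numpy()
    drift_u = np.ones(len(cal))
    drift_l = np.ones(len(cal))
    for year in config.year_range:
        sel = year_of == year
        drift_u[sel] = 1.0 + rng.normal(0.0, config.storage_drift_cv)
        drift_l[sel] = 1.0 + rng.normal(0.0, config.storage_drift_cv)
    flows["hypolimnetic"] = FlowSeries(
        "hypolimnetic", RouteRole.INTER_RESERVOIR, (upper_in + pump_q) * drift_u
    )
    flows["dam_outflow"] = FlowSeries(
        "dam_outflow", RouteRole.OUTFLOW, (upper_in + lower_ext) * drift_l
    )

    wiring = {rid: (role, fed) for rid, (role, fed, _) in routes.items()}
    wiring["hypolimnetic"] = (RouteRole.INTER_RESERVOIR, LOWER)
    wiring["pumping"] = (RouteRole.PUMPING_REVERSE, UPPER)
    wiring["dam_outflow"] = (RouteRole.OUTFLOW, LOWER)
    topology = CascadeTopology(config.reservoirs, wiring, events)
    return flows, topology


def _annual_route_load(conc: pd.Series, q: pd.Series, year: int) -> float:
    sel = conc.index.year == year
    return float(
        (conc[sel] * q[sel]).sum() * SECONDS_PER_DAY / 1e6
    )


def _scale_to_targets(
    shape: pd.Series, q: pd.Series, targets: dict[int, float]
) -> pd.Series:
    """Scale a positive concentration shape per year so that the annual
    load c·Q·86400/10⁶ equals each year's target exactly."""
    conc = shape.copy()
    for year, target in targets.items():
        sel = conc.index.year == year
        raw = _annual_route_load(shape, q, year)
        conc[sel] = shape[sel] * (target / raw if raw > 0 else 0.0)
    return conc


def _summer_bump(doy: np.ndarray, center: float = 210.0, width: float = 45.0) -> np.ndarray:
    return np.exp(-(((doy - center) / width) ** 2))


def generate_chemistry(
    config: ScenarioConfig,
    flows: dict[str, FlowSeries],
    rng: Optional[np.random.Generator] = None,
) -> tuple[
    list[AnalyteSample],
    ScenarioTruth,
    dict[tuple[str, str], dict[str, float]],
    dict[tuple[str, str], pd.Series],
]:
    """True daily concentrations, the exact budget truth, side loads, and
    the sparse noisy observed samples.

    Returns ``(samples, truth, side_loads, daily_concentration)``; the
    daily truth is keyed by (route_id, analyte code).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    cal = config.calendar
    doy = cal.dayofyear.to_numpy().astype(float)
    routes = _route_table(config)
    years = list(config.year_range)

    upper_aff = [r for r, (_, fed, _) in routes.items() if fed == UPPER]
    lower_aff = [r for r, (_, fed, _) in routes.items() if fed == LOWER]
    upper_water = sum(routes[r][2] for r in upper_aff)
    lower_water = sum(routes[r][2] for r in lower_aff)
    total_water = upper_water + lower_water

    daily: dict[tuple[str, str], pd.Series] = {}
    side_loads: dict[tuple[str, str], dict[str, float]] = {}
    truth_rows = []

    for analyte, sc in config.elements.items():
        riverine_total = sc.total_input * sc.riverine_share
        non_riverine = sc.total_input - riverine_total
        dd_total, atm_total = 0.8 * non_riverine, 0.2 * non_riverine
        for res, frac in ((UPPER, 0.9), (LOWER, 0.1)):
            side_loads[(res, analyte.value)] = {
                "point": 0.5 * dd_total * frac,
                "nonpoint": 0.4 * dd_total * frac,
                "bathers": 0.1 * dd_total * frac,
                "atmospheric": atm_total * frac,
            }

        # riverine truth, split by water contribution
        route_targets: dict[str, dict[int, float]] = {}
        for rid in upper_aff + lower_aff:
            share = routes[rid][2] / total_water
            route_targets[rid] = {y: riverine_total * share for y in years}

        for rid, targets in route_targets.items():
            q = flows[rid].discharge
            shape = pd.Series(
                _season(doy, sc.seasonal_amplitude,
                        20.0 if sc.summer_drawdown else 300.0),
                index=cal,
            )
            if sc.flow_exponent:
                shape = shape * (q / q.mean()).pow(sc.flow_exponent)
            daily[(rid, analyte.value)] = _scale_to_targets(shape, q, targets)

        def ext(res: str) -> dict[int, float]:
            aff = upper_aff if res == UPPER else lower_aff
            dd_atm = sum(side_loads[(res, analyte.value)].values())
            return {
                y: sum(route_targets[r][y] for r in aff) + dd_atm for y in years
            }

        e_u, e_l = ext(UPPER), ext(LOWER)
        o_u0 = {y: (1 - sc.upper_retention) * e_u[y] for y in years}
        i_l0 = {y: o_u0[y] + e_l[y] for y in years}
        o_l0 = {y: (1 - sc.lower_retention) * i_l0[y] for y in years}

        # in-reservoir processing shapes the outflowing concentration;
        # dissolved silicon additionally shows a summer epilimnetic drawdown
        out_shape = pd.Series(
            _season(doy, sc.seasonal_amplitude / 2,
                    20.0 if sc.summer_drawdown else 300.0),
            index=cal,
        )
        if sc.summer_drawdown:
            out_shape = out_shape * np.maximum(
                1.0 - sc.summer_drawdown * _summer_bump(doy), 0.05
            )
        q_out = flows["dam_outflow"].discharge
        c_out = _scale_to_targets(out_shape, q_out, o_l0)
        daily[("dam_outflow", analyte.value)] = c_out

        # pumped water is lower-reservoir water
        q_pump = flows["pumping"].discharge
        c_pump = c_out.copy()
        daily[("pumping", analyte.value)] = c_pump
        p_load = {y: _annual_route_load(c_pump, q_pump, y) for y in years}

        q_inter = flows["hypolimnetic"].discharge
        inter_targets = {y: o_u0[y] + p_load[y] for y in years}
        daily[("hypolimnetic", analyte.value)] = _scale_to_targets(
            out_shape, q_inter, inter_targets
        )

        for y in years:
            rows = [
                (UPPER, e_u[y] + p_load[y], o_u0[y] + p_load[y]),
                (LOWER, i_l0[y] + p_load[y], o_l0[y] + p_load[y]),
                ("complex", e_u[y] + e_l[y], o_l0[y]),
            ]
            for res, inp, out in rows:
                truth_rows.append(
                    {
                        "element": analyte.value,
                        "reservoir": res,
                        "year": y,
                        "input_t": inp,
                        "output_t": out,
                        "retention_t": inp - out,
                        "retention_pct": 100.0 * (inp - out) / inp if inp else np.nan,
                    }
                )

    # in-reservoir epilimnion stations feeding the stoichiometry
    # diagnostics and the water-column P stock
    station_truth: dict[tuple[str, str], pd.Series] = {}
    for station, warm in (("epi_upper", 1.0), ("epi_lower", 0.6)):
        bump = _summer_bump(doy)
        station_truth[(station, Analyte.TP.value)] = pd.Series(
            0.03 * (1 + 0.15 * np.sin(2 * np.pi * doy / 365.25)), index=cal
        )
        station_truth[(station, Analyte.TN.value)] = pd.Series(
            np.full(len(cal), 1.2), index=cal
        )
        station_truth[(station, Analyte.DSI.value)] = pd.Series(
            1.6 * (1 - 0.9 * warm * bump), index=cal
        )
        station_truth[(station, Analyte.CHLOROPHYLL.value)] = pd.Series(
            2.0 + 10.0 * warm * bump, index=cal
        )

    samples = _draw_samples(config, rng, {**daily, **station_truth})

    water_rows = []
    for res in (UPPER, LOWER, "complex"):
        if res == UPPER:
            inflow = sum(flows[r].discharge for r in upper_aff) + q_pump
            outflow = q_inter
        elif res == LOWER:
            inflow = q_inter + sum(flows[r].discharge for r in lower_aff)
            outflow = q_out + q_pump
        else:
            inflow = sum(flows[r].discharge for r in upper_aff + lower_aff)
            outflow = q_out
        for y in years:
            sel = cal.year == y
            water_rows.append(
                {
                    "reservoir": res,
                    "year": y,
                    "inflow_m3": float(inflow[sel].sum()) * SECONDS_PER_DAY,
                    "outflow_m3": float(outflow[sel].sum()) * SECONDS_PER_DAY,
                }
            )

    truth = ScenarioTruth(pd.DataFrame(truth_rows), pd.DataFrame(water_rows))
    return samples, truth, side_loads, daily


def _visit_dates(config: ScenarioConfig, rng: np.random.Generator) -> list[pd.Timestamp]:
    """Jittered sampling visits.

    Gaps are drawn as gmin + (gmax − gmin)·Beta(a, 1) days with *a* chosen
    so the mean gap equals ``mean_sampling_gap`` (defaults: 1–6 weeks with
    a ~33-day mean, i.e. ~33 visits over three years).  A mean at or below
    the window minimum degenerates to a fixed cadence starting on day one
    (e.g. ``mean_sampling_gap=1`` → daily sampling).
    """
    cal = config.calendar
    gmin, gmax, mean = (config.sampling_gap_min, config.sampling_gap_max,
                        config.mean_sampling_gap)
    dates = []
    if mean <= gmin:
        step = max(1, int(round(mean)))
        t = cal[0]
        while t <= cal[-1]:
            dates.append(t)
            t = t + pd.Timedelta(days=step)
        return dates
    frac = min((mean - gmin) / (gmax - gmin), 0.999)
    a = frac / (1.0 - frac)  # mean of Beta(a, 1) is a/(a+1)
    t = cal[0] + pd.Timedelta(days=int(rng.integers(0, int(gmin))))
    while t <= cal[-1]:
        dates.append(t)
        gap = gmin + (gmax - gmin) * rng.beta(a, 1.0)
        t = t + pd.Timedelta(days=int(round(gap)))
    return dates


def _draw_samples(
    config: ScenarioConfig,
    rng: np.random.Generator,
    truth: dict[tuple[str, str], pd.Series],
) -> list[AnalyteSample]:
    visits = _visit_dates(config, rng)
    samples = []
    for (station, code), series in truth.items():
        noise = _lognoise(rng, len(visits), config.noise_cv)
        for ts, f in zip(visits, noise):
            samples.append(
                AnalyteSample(
                    station_id=station,
                    analyte=Analyte(code),
                    date=ts.date(),
                    concentration=float(series.loc[ts] * f),
                )
            )
    samples.sort(key=lambda s: (s.station_id, s.analyte.value, s.date))
    return samples


def simulate(config: Optional[ScenarioConfig] = None, seed: Optional[int] = None) -> ScenarioData:
    """Generate a complete campaign (flows, topology, samples, truth)."""
    config = config or ScenarioConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    flows, topology = generate_flows(config, rng)
    samples, truth, side_loads, daily = generate_chemistry(config, flows, rng)
    return ScenarioData(config, flows, topology, samples, truth, side_loads, daily)


def truth_report(config: ScenarioConfig) -> ScenarioTruth:
    """Regenerate the scenario deterministically and return its exact
    ground-truth budgets."""
    return simulate(config).truth
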