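"""Stage orchestration: samples + flows → loads → budgets → ledgers →
diagnostics → report.

Each stage is a plain function over the library types and can be run
standalone (the CLI maps one subcommand to each); :func:`run_pipeline`
chains them on files, writing delimited tables and a plain-text summary,
and logs per-stage row counts to standard error.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .balance import (
    complex_balance,
    reservoir_balance,
    round_half_up,
    water_budget_from_topology,
)
from .diagnostics import (
    LimitationThresholds,
    build_ratio_records,
    limitation_flags,
    pearson_screen,
    screen_frame,
)
from .loads import (
    annual_load,
    daily_load_series,
    interpolate_daily_concentration,
    load_uncertainty,
)
from .sediment import DEFAULT_STOICHIOMETRY, sediment_budget
from .synthetic import ScenarioConfig, ScenarioData, simulate
from .types import (
    Analyte,
    AnalyteSample,
    AnnualBudget,
    CascadeTopology,
    FlowSeries,
    RouteRole,
    SedimentStoichiometry,
)

log = logging.getLogger("resbalance")

__all__ = [
    "RunConfig",
    "estimate_route_loads",
    "estimate_budgets",
    "run_pipeline",
    "render_report",
    "DEFAULT_UNCERTAINTY_COMPONENTS",
]

#: sampling, chemical analysis, discharge measurement (percent)
DEFAULT_UNCERTAINTY_COMPONENTS = (15.0, 2.0, 2.0)

BALANCE_ELEMENTS = (Analyte.TN, Analyte.TP, Analyte.DSI, Analyte.TOC)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    scenario: Optional[ScenarioConfig] = None
    elements: Sequence[Analyte] = BALANCE_ELEMENTS
    method: str = "linear"
    uncertainty_components: Sequence[float] = DEFAULT_UNCERTAINTY_COMPONENTS
    stoichiometry: SedimentStoichiometry = DEFAULT_STOICHIOMETRY
    denitrification_rate: float = 4.0     # g N m⁻² yr⁻¹
    denitrification_area: Optional[float] = None  # m²; default: upper surface
    # share of TP retention routed through phytoplankton biomass, used for
    # the P ledger when phosphate budgets are not separately balanced
    po4_biomass_fraction: float = 0.6
    thresholds: LimitationThresholds = field(default_factory=LimitationThresholds)
    rounding_units: dict[str, float] = field(
        default_factory=lambda: {"TN": 1.0, "TOC": 10.0}
    )


def _samples_by_station(
    samples: Iterable[AnalyteSample],
) -> dict[tuple[str, str], list[AnalyteSample]]:
    grouped: dict[tuple[str, str], list[AnalyteSample]] = {}
    for s in samples:
        grouped.setdefault((s.station_id, s.analyte.value), []).append(s)
    return grouped


def estimate_route_loads(
    samples: Iterable[AnalyteSample],
    flows: dict[str, FlowSeries],
    elements: Sequence[Analyte],
    years: Sequence[int],
    method: str = "linear",
    uncertainty_components: Sequence[float] = DEFAULT_UNCERTAINTY_COMPONENTS,
) -> pd.DataFrame:
    """Annual element loads per route from sparse samples × daily Q.

    Concentrations are interpolated to daily resolution (station id ==
    route id), multiplied by daily discharge and summed per calendar year.
    Returns columns route, element, year, load_t, uncertainty_pct.
    """
    grouped = _samples_by_station(samples)
    unc = load_uncertainty(uncertainty_components)
    rows = []
    for rid, fs in flows.items():
        calendar = fs.discharge.index
        for analyte in elements:
            smp = grouped.get((rid, analyte.value))
            if not smp:
                continue
            conc = interpolate_daily_concentration(
                smp, calendar, method=method,
                discharge=fs.discharge if method == "flow_stratified" else None,
            )
            series = daily_load_series(conc, fs, analyte)
            for year in years:
                rows.append(
                    {
                        "route": rid,
                        "element": analyte.value,
                        "year": year,
                        "load_t": annual_load(series, year),
                        "uncertainty_pct": unc,
                    }
                )
    return pd.DataFrame(rows)


def estimate_budgets(
    route_loads: pd.DataFrame,
    topology: CascadeTopology,
    side_loads: dict[tuple[str, str], dict[str, float]],
    uncertainty_pct: Optional[float] = None,
) -> list[AnnualBudget]:
    """Close per-reservoir and complex balances from route loads.

    ``side_loads`` maps (reservoir, element) to direct-drainage and
    atmospheric scalars (keys point, nonpoint, bathers, atmospheric).
    """
    if uncertainty_pct is None and len(route_loads):
        uncertainty_pct = float(route_loads["uncertainty_pct"].iloc[0])

    def load_of(route: str, element: str, year: int) -> float:
        sel = route_loads[
            (route_loads.route == route)
            & (route_loads.element == element)
            & (route_loads.year == year)
        ]
        return float(sel.load_t.sum())

    names = [r.name for r in topology.reservoirs]
    budgets: list[AnnualBudget] = []
    for element in sorted(route_loads.element.unique()):
        for year in sorted(route_loads.year.unique()):
            per_res = []
            for pos, res in enumerate(names):
                side = side_loads.get((res, element), {})
                dd = sum(side.get(k, 0.0) for k in ("point", "nonpoint", "bathers"))
                atm = side.get("atmospheric", 0.0)
                riverine = sum(
                    load_of(r, element, year)
                    for r in topology.affluent_routes(res)
                )
                pumping_in = upstream_in = 0.0
                output = 0.0
                for rid, (role, fed) in topology.routes.items():
                    if role is RouteRole.PUMPING_REVERSE:
                        if fed == res:
                            pumping_in += load_of(rid, element, year)
                        elif pos == len(names) - 1:
                            output += load_of(rid, element, year)
                    elif role is RouteRole.INTER_RESERVOIR:
                        if fed == res:
                            upstream_in += load_of(rid, element, year)
                        elif pos + 1 < len(names) and fed == names[pos + 1]:
                            output += load_of(rid, element, year)
                    elif role is RouteRole.OUTFLOW and pos == len(names) - 1:
                        output += load_of(rid, element, year)
                per_res.append(
                    reservoir_balance(
                        Analyte(element), int(year),
                        riverine=riverine, direct_drainage=dd, atmospheric=atm,
                        pumping_in=pumping_in, output=output,
                        reservoir=res, upstream_in=upstream_in,
                        load_uncertainty_pct=uncertainty_pct,
                    )
                )
            budgets.extend(per_res)
            budgets.append(complex_balance(per_res, topology))
    return budgets


def _ledger_frame(ledgers: list) -> pd.DataFrame:
    rows = []
    for led in ledgers:
        row = {
            "element": led.element.value,
            "inflow_t": led.inflow,
            "retention_t": led.retention,
            "indefinite_t": led.indefinite,
        }
        row.update({f"term_{k}_t": v for k, v in led.terms.items()})
        row.update(led.shares)
        row["flags"] = ";".join(led.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate → loads → balance → ledger → diagnose → correlate →
    report, writing every artifact under ``config.out_dir``.

    Returns the mapping of artifact names to paths.  Deterministic under a
    fixed seed and config.
    """
    from .sediment import (
        carbon_ledger,
        denitrification_annual,
        nitrogen_ledger,
        phosphorus_ledger,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = dt.datetime.now()

    scenario = config.scenario or ScenarioConfig(seed=config.seed)
    data = simulate(scenario)
    log.info("simulate: %d routes, %d samples", len(data.flows), len(data.samples))

    paths: dict[str, Path] = {}
    rio.write_samples(data.samples, out / "samples.csv")
    rio.write_flows(data.flows.values(), out / "flows.csv")
    paths["samples"] = out / "samples.csv"
    paths["flows"] = out / "flows.csv"

    years = list(scenario.year_range)
    elements = list(config.elements)
    route_loads = estimate_route_loads(
        data.samples, data.flows, elements, years, config.method,
        config.uncertainty_components,
    )
    route_loads.to_csv(out / "loads.csv", index=False)
    paths["loads"] = out / "loads.csv"
    log.info("loads: %d route-year loads", len(route_loads))

    budgets = estimate_budgets(
        route_loads, data.topology, data.side_loads
    )
    rio.write_budgets(budgets, out / "budgets.csv")
    paths["budgets"] = out / "budgets.csv"
    log.info("balance: %d budgets", len(budgets))

    # ledgers on complex-mean quantities over the run years
    bf = rio.budgets_frame(budgets)
    cx = bf[bf.reservoir == "complex"].groupby("element").mean(numeric_only=True)
    upper = config.scenario.reservoirs[0] if config.scenario else data.topology.reservoirs[0]
    area = config.denitrification_area or upper.surface_area
    ledgers = []
    if "TP" in cx.index:
        p_ret = float(cx.loc["TP", "retention_t"])
        sed = sediment_budget(
            upper.name, f"{years[0]}-{years[-1]}",
            p_ret=p_ret, delta_p_rate=0.0, stoich=config.stoichiometry,
            backwater_fraction=upper.backwater_fraction,
            surface_area=upper.surface_area,
            rounding_units=(config.rounding_units.get("TN"),
                            config.rounding_units.get("TOC")),
        )
        pd.DataFrame(
            [
                {
                    "reservoir": sed.reservoir, "period": sed.period,
                    "p_ret_t": sed.p_ret, "delta_p_t": sed.delta_p,
                    "n_sed_t": sed.n_sed, "c_sed_t": sed.c_sed,
                    "n_backwater_t": sed.n_backwater,
                    "n_lacustrine_t": sed.n_lacustrine,
                    "c_backwater_t": sed.c_backwater,
                    "c_lacustrine_t": sed.c_lacustrine,
                    "n_rate_g_m2_d": sed.n_rate, "c_rate_g_m2_d": sed.c_rate,
                }
            ]
        ).to_csv(out / "sedimentation.csv", index=False)
        paths["sedimentation"] = out / "sedimentation.csv"
        if "TN" in cx.index:
            denit = denitrification_annual(config.denitrification_rate, area)
            ledgers.append(
                nitrogen_ledger(
                    float(cx.loc["TN", "input_t"]),
                    float(cx.loc["TN", "retention_t"]),
                    sed.n_sed, denit,
                )
            )
        po4_ret = (
            float(cx.loc["P-PO4", "retention_t"]) if "P-PO4" in cx.index
            else config.po4_biomass_fraction * p_ret
        )
        ledgers.append(phosphorus_ledger(p_ret, po4_ret,
                                         float(cx.loc["TP", "input_t"])))
        if "TOC" in cx.index:
            ledgers.append(
                carbon_ledger(float(cx.loc["TOC", "retention_t"]), sed.c_sed,
                              float(cx.loc["TOC", "input_t"]))
            )
    if ledgers:
        _ledger_frame(ledgers).to_csv(out / "ledgers.csv", index=False)
        paths["ledgers"] = out / "ledgers.csv"
    log.info("ledger: %d ledgers", len(ledgers))

    records = build_ratio_records(data.samples)
    diag_rows = [
        {
            "station": r.station,
            "date": r.date.isoformat(),
            "np_molar": r.np_molar,
            "si_n_molar": r.si_n_molar,
            "si_p_molar": r.si_p_molar,
            "dsi": r.dsi,
            "chl_a": r.chl_a,
            "flags": ";".join(sorted(limitation_flags(r, config.thresholds))),
        }
        for r in records
    ]
    diag = pd.DataFrame(diag_rows)
    diag.to_csv(out / "diagnostics.csv", index=False)
    paths["diagnostics"] = out / "diagnostics.csv"
    log.info("diagnose: %d ratio records", len(diag))

    # retention-vs-drivers screen over reservoir-years
    resp, drv = _screen_tables(bf, data)
    cells = pearson_screen(resp, drv)
    screen_frame(cells).to_csv(out / "correlations.csv", index=False)
    paths["correlations"] = out / "correlations.csv"
    log.info("correlate: %d cells", len(cells))

    report = render_report(budgets, ledgers, diag)
    (out / "report.txt").write_text(report, encoding="utf-8")
    paths["report"] = out / "report.txt"
    log.info("report written; total %.2f s", (dt.datetime.now() - t0).total_seconds())
    return paths


def _screen_tables(bf: pd.DataFrame, data: ScenarioData):
    """Reservoir-year observation matrix for the correlation screen."""
    hrt = {r.name: r.hrt for r in data.topology.reservoirs}
    water = data.truth.water.set_index(["reservoir", "year"])
    obs = bf[bf.reservoir != "complex"].copy()
    obs["ret_pct"] = np.where(
        obs.retention_pct.notna(), obs.retention_pct, -obs.elimination_pct
    )
    resp = obs.pivot_table(index=["reservoir", "year"], columns="element",
                           values="ret_pct")
    resp.columns = [f"{c}_ret_pct" for c in resp.columns]
    inp = obs.pivot_table(index=["reservoir", "year"], columns="element",
                          values="input_t")
    drv = pd.DataFrame(index=resp.index)
    if "TN" in [c.split("_")[0] for c in resp.columns]:
        drv["L_input_TN"] = inp.get("TN")
    drv["HRT"] = [hrt[r] for r, _ in resp.index]
    drv["W_ret"] = [
        water.loc[(r, y), "inflow_m3"] - water.loc[(r, y), "outflow_m3"]
        for r, y in resp.index
    ]
    drv["Q"] = [water.loc[(r, y), "inflow_m3"] / (365 * 86400.0)
                for r, y in resp.index]
    return resp, drv


def render_report(
    budgets: Sequence[AnnualBudget],
    ledgers: Sequence = (),
    diagnostics: Optional[pd.DataFrame] = None,
) -> str:
    """Human-readable summary of a run.

    Loads are presentation-rounded to whole tonnes and percentages to
    whole percent; elimination is rendered instead of (never alongside)
    retention percentage.
    """
    lines = ["Reservoir element mass balance", "=" * 34, ""]
    for b in budgets:
        if b.undefined_pct:
            pct = "pct undefined (zero input)"
        elif b.elimination_pct is not None and b.retention_pct is None:
            pct = f"elimination {round_half_up(b.elimination_pct):.0f} %"
        else:
            pct = f"retention {round_half_up(b.retention_pct or 0.0):.0f} %"
        unc = (
            f" ± {round_half_up(b.retention_uncertainty):.0f}"
            if b.retention_uncertainty is not None
            else ""
        )
        lines.append(
            f"{b.element.value:5s} {b.reservoir:10s} {b.year}  "
            f"in {round_half_up(b.input_load):6.0f} t  "
            f"out {round_half_up(b.output_load):6.0f} t  "
            f"ret {round_half_up(b.retention):6.0f}{unc} t  ({pct})"
        )
    lines.append("")
    if ledgers:
        lines.append("Retention ledgers (t yr⁻¹)")
        lines.append("-" * 26)
        for led in ledgers:
            terms = ", ".join(
                f"{k} {round_half_up(v):.0f}" for k, v in led.terms.items()
            )
            lines.append(
                f"{led.element.value:5s} inflow {round_half_up(led.inflow):.0f}, "
                f"retention {round_half_up(led.retention):.0f}, {terms}, "
                f"indefinite {round_half_up(led.indefinite):.0f}"
            )
            for k, v in led.shares.items():
                lines.append(f"      {k}: {v:.1f}")
        lines.append("")
    lines.append("Diagnostics")
    lines.append("-" * 11)
    if diagnostics is None or diagnostics.empty or not diagnostics["flags"].astype(bool).any():
        lines.append("no flags")
    else:
        flagged = diagnostics[diagnostics["flags"].astype(bool)]
        counts = (
            flagged["flags"].str.split(";").explode().value_counts().sort_index()
        )
        for flag, n in counts.items():
            lines.append(f"{flag}: {n} station-dates")
    lines.append("")
    return "\n".join(lines)
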