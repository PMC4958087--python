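"""Delimited-table and YAML readers/writers.

All tabular artifacts are comma-separated UTF-8 text with a header row.
Samples:  station, analyte, date (ISO-8601), concentration
Flows:    route, role, date, discharge_m3s
Budgets:  element, reservoir, year, input_t, output_t, retention_t,
          retention_pct, elimination_pct, load_uncertainty_pct,
          retention_uncertainty_t

Unknown extra columns are ignored with a logged warning; malformed rows
raise a parse error naming the offending row.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import yaml

from .types import (
    Analyte,
    AnalyteSample,
    AnnualBudget,
    CascadeTopology,
    DomainError,
    FlowSeries,
    PumpingEvent,
    ReservoirSpec,
    RouteRole,
    SedimentStoichiometry,
)

log = logging.getLogger("resbalance")

PathLike = Union[str, Path]

SAMPLE_COLUMNS = ["station", "analyte", "date", "concentration"]
FLOW_COLUMNS = ["route", "role", "date", "discharge_m3s"]


class ParseError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring extra columns %s", path, extra)


def _parse_date(value, path: PathLike, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise ParseError(
            f"{path}: row {row}: malformed date {value!r} (expected ISO-8601)"
        ) from None


def read_samples(path: PathLike) -> list[AnalyteSample]:
    """Read dated concentration samples, validated and sorted by
    (station, analyte, date)."""
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, SAMPLE_COLUMNS, path)
    samples = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(rec.date, path, i)
        try:
            conc = float(rec.concentration)
        except ValueError:
            raise ParseError(
                f"{path}: row {i}: non-numeric concentration "
                f"{rec.concentration!r}"
            ) from None
        try:
            samples.append(
                AnalyteSample(str(rec.station), Analyte.parse(rec.analyte),
                              date, conc)
            )
        except DomainError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
    samples.sort(key=lambda s: (s.station_id, s.analyte.value, s.date))
    for a, b in zip(samples, samples[1:]):
        if (a.station_id, a.analyte) == (b.station_id, b.analyte) and a.date == b.date:
            raise ParseError(
                f"{path}: duplicate sample for {a.station_id}/"
                f"{a.analyte.value} on {a.date}"
            )
    return samples


def write_samples(samples: Iterable[AnalyteSample], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "station": s.station_id,
                "analyte": s.analyte.value,
                "date": s.date.isoformat(),
                "concentration": repr(s.concentration),
            }
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_flows(path: PathLike) -> dict[str, FlowSeries]:
    """Read daily discharge series, one FlowSeries per route."""
    df = pd.read_csv(path, dtype={"route": str, "role": str},
                     float_precision="round_trip")
    _check_columns(df, FLOW_COLUMNS, path)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ParseError(f"{path}: malformed date in flow table: {exc}") from None
    out: dict[str, FlowSeries] = {}
    for (route, role), grp in df.groupby(["route", "role"], sort=False):
        series = pd.Series(
            grp["discharge_m3s"].astype(float).values,
            index=pd.DatetimeIndex(grp["date"]),
        )
        try:
            fs = FlowSeries(route, RouteRole(role), series).validate()
        except ValueError as exc:
            raise ParseError(f"{path}: route {route}: {exc}") from None
        out[route] = fs
    return out


def write_flows(flows: Iterable[FlowSeries], path: PathLike) -> None:
    frames = []
    for fs in flows:
        frames.append(
            pd.DataFrame(
                {
                    "route": fs.route_id,
                    "role": fs.role.value,
                    "date": fs.discharge.index.strftime("%Y-%m-%d"),
                    "discharge_m3s": fs.discharge.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def budgets_frame(budgets: Iterable[AnnualBudget]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element": b.element.value,
                "reservoir": b.reservoir,
                "year": b.year,
                "input_t": b.input_load,
                "output_t": b.output_load,
                "retention_t": b.retention,
                "retention_pct": b.retention_pct,
                "elimination_pct": b.elimination_pct,
                "load_uncertainty_pct": b.load_uncertainty_pct,
                "retention_uncertainty_t": b.retention_uncertainty,
            }
            for b in budgets
        ]
    )


def write_budgets(budgets: Iterable[AnnualBudget], path: PathLike) -> None:
    budgets_frame(budgets).to_csv(path, index=False)


def read_budgets(path: PathLike) -> list[AnnualBudget]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for rec in df.itertuples(index=False):
        def _opt(v):
            return None if pd.isna(v) else float(v)
        out.append(
            AnnualBudget(
                element=Analyte.parse(rec.element),
                reservoir=str(rec.reservoir),
                year=int(rec.year),
                input_load=float(rec.input_t),
                output_load=float(rec.output_t),
                retention=float(rec.retention_t),
                retention_pct=_opt(rec.retention_pct),
                elimination_pct=_opt(rec.elimination_pct),
                load_uncertainty_pct=_opt(rec.load_uncertainty_pct),
                retention_uncertainty=_opt(rec.retention_uncertainty_t),
            )
        )
    return out


def _reservoir_from_dict(d: dict) -> ReservoirSpec:
    return ReservoirSpec(
        name=d["name"],
        volume=float(d["volume"]),
        mean_depth=float(d["mean_depth"]),
        surface_area=float(d["surface_area"]),
        hrt=float(d["hrt"]),
        backwater_fraction=float(d.get("backwater_fraction", 0.0)),
    )


def read_config(path: PathLike) -> dict:
    """Read the YAML run configuration.

    Recognised top-level keys (all optional): ``reservoirs`` (list),
    ``routes`` (route → {role, reservoir}), ``pumping`` (list of
    {start, end, rate}), ``side_loads`` (reservoir → element →
    {point, nonpoint, bathers, atmospheric}), ``stoichiometry``
    ({np_ratio, cn_ratio}), ``uncertainty_components`` (list of %),
    ``thresholds``, ``rounding_profile`` (element → tonnes unit), ``seed``.
    Structured objects are materialised; unknown keys pass through.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(raw)
    if "reservoirs" in raw:
        cfg["reservoirs"] = [_reservoir_from_dict(d) for d in raw["reservoirs"]]
    if "routes" in raw:
        cfg["routes"] = {
            rid: (RouteRole(spec["role"]), spec["reservoir"])
            for rid, spec in raw["routes"].items()
        }
    if "pumping" in raw:
        cfg["pumping"] = [
            PumpingEvent(
                dt.date.fromisoformat(str(p["start"])),
                dt.date.fromisoformat(str(p["end"])),
                float(p["rate"]),
            )
            for p in raw["pumping"]
        ]
    if {"reservoirs", "routes"} <= cfg.keys():
        cfg["topology"] = CascadeTopology(
            cfg["reservoirs"], cfg["routes"], cfg.get("pumping", [])
        )
    if "stoichiometry" in raw:
        cfg["stoichiometry"] = SedimentStoichiometry(
            np_ratio=float(raw["stoichiometry"]["np_ratio"]),
            cn_ratio=float(raw["stoichiometry"]["cn_ratio"]),
        )
    return cfg
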