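"""Annual element mass balance for reservoirs and the whole cascade.

For each element, reservoir and year the balance closes

    L_riverine + L_direct_drainage + L_atmospheric (+ transfers) =
        L_outflow + R(E)

where R(E) is the retention (positive: the water body is a sink) or
elimination (negative: a source) of the element.  Transfers are the
inter-reservoir supply received from upstream and reverse pumping received
from downstream; they appear in partial balances but cancel in the balance
of the reservoir complex, whose input counts only sources external to the
cascade and whose output is the final outflow.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .loads import retention_uncertainty
from .types import (
    Analyte,
    AnnualBudget,
    CascadeTopology,
    DomainError,
    FlowSeries,
    SourceLoadBreakdown,
    WaterBudget,
)
from . import loads as _loads

__all__ = [
    "reservoir_balance",
    "complex_balance",
    "retention_percent",
    "round_half_up",
    "water_budget",
    "water_budget_from_topology",
]

SECONDS_PER_DAY = 86400.0


def round_half_up(value: float, unit: float = 1.0) -> float:
    """Round to the nearest multiple of *unit*, ties away from zero.

    Used only at presentation time; internal arithmetic keeps full
    precision.
    """
    q = Decimal(repr(value)) / Decimal(repr(unit))
    return float(q.to_integral_value(rounding=ROUND_HALF_UP)) * unit


def retention_percent(retention: float, input_load: float,
                      rounded: bool = True) -> float:
    """Retention as a percentage of the input load.

    By default presentation-rounded half-up to a whole percent, matching
    how reservoir budgets are conventionally tabulated; pass
    ``rounded=False`` for full precision.
    """
    if input_load <= 0:
        raise DomainError(
            f"retention percentage undefined for input load {input_load}"
        )
    pct = 100.0 * retention / input_load
    return round_half_up(pct) if rounded else pct


def reservoir_balance(
    element: Analyte,
    year: int,
    riverine: float,
    direct_drainage: float,
    atmospheric: float,
    pumping_in: float,
    output: float,
    *,
    reservoir: str = "complex",
    upstream_in: float = 0.0,
    load_uncertainty_pct: Optional[float] = None,
) -> AnnualBudget:
    """Close the annual balance for one reservoir (or the complex).

    All loads are t yr⁻¹ and must be non-negative; retention is derived as
    input − output and may be negative (elimination).  ``upstream_in`` is
    the load received from the upstream reservoir through the
    inter-reservoir route (zero for the uppermost reservoir and for
    complex-level budgets built from external sources only).

    When ``load_uncertainty_pct`` is given, the retention uncertainty is
    propagated by root mean square over the input and output loads.
    """
    for name, v in (
        ("riverine", riverine),
        ("direct_drainage", direct_drainage),
        ("atmospheric", atmospheric),
        ("pumping_in", pumping_in),
        ("upstream_in", upstream_in),
        ("output", output),
    ):
        if v < 0:
            raise DomainError(f"negative load term {name}={v}")

    input_load = riverine + direct_drainage + atmospheric + pumping_in + upstream_in
    retention = input_load - output

    retention_pct = elimination_pct = None
    undefined = False
    if input_load > 0:
        pct = 100.0 * retention / input_load
        if retention >= 0:
            retention_pct = pct
            if retention == 0:
                elimination_pct = 0.0
        else:
            elimination_pct = -pct
    else:
        undefined = output > 0
        if undefined:
            warnings.warn(
                f"{element.value}/{reservoir}/{year}: zero input with "
                f"nonzero output {output} t — percentage undefined",
                stacklevel=2,
            )
        else:
            retention_pct = elimination_pct = 0.0

    ret_unc = None
    if load_uncertainty_pct is not None:
        ret_unc = retention_uncertainty(
            [(input_load, load_uncertainty_pct), (output, load_uncertainty_pct)]
        )

    sources = SourceLoadBreakdown(
        element=element,
        riverine=riverine,
        nonpoint=direct_drainage,  # aggregate; sub-terms via SourceLoadBreakdown
        atmospheric=atmospheric,
        pumping_in=pumping_in,
    )
    return AnnualBudget(
        element=element,
        reservoir=reservoir,
        year=year,
        input_load=input_load,
        output_load=output,
        retention=retention,
        retention_pct=retention_pct,
        elimination_pct=elimination_pct,
        load_uncertainty_pct=load_uncertainty_pct,
        retention_uncertainty=ret_unc,
        undefined_pct=undefined,
        sources=sources,
        upstream_in=upstream_in,
    )


def complex_balance(
    budgets: Sequence[AnnualBudget],
    topology: Optional[CascadeTopology] = None,
) -> AnnualBudget:
    """Aggregate per-reservoir budgets into the cascade-level balance.

    The complex input counts only external sources (riverine, direct
    drainage, atmospheric) of every reservoir; the output is the final
    outflow, i.e. the summed outputs minus the internal transfers
    (inter-reservoir supply and reverse pumping), which cancel exactly.
    Consequently the complex retention equals the sum of the per-reservoir
    retentions and is invariant to the magnitude and timing of pumping.
    """
    if not budgets:
        raise DomainError("no budgets to aggregate")
    elements = {b.element for b in budgets}
    years = {b.year for b in budgets}
    if len(elements) != 1 or len(years) != 1:
        raise DomainError(
            f"mismatched element/year across budgets: {elements}, {years}"
        )
    for b in budgets:
        if b.sources is None:
            raise DomainError(
                f"budget for {b.reservoir} lacks a source breakdown; "
                "build it with reservoir_balance()"
            )
    external = sum(b.sources.external for b in budgets)
    transfers = sum(b.upstream_in + b.sources.pumping_in for b in budgets)
    final_outflow = sum(b.output_load for b in budgets) - transfers
    if final_outflow < -1e-9:
        raise DomainError(
            f"internal transfers ({transfers} t) exceed summed outputs"
        )
    unc = next((b.load_uncertainty_pct for b in budgets
                if b.load_uncertainty_pct is not None), None)
    return reservoir_balance(
        element=next(iter(elements)),
        year=next(iter(years)),
        riverine=sum(b.sources.riverine for b in budgets),
        direct_drainage=sum(b.sources.direct_drainage for b in budgets),
        atmospheric=sum(b.sources.atmospheric for b in budgets),
        pumping_in=0.0,
        output=max(final_outflow, 0.0),
        reservoir="complex",
        load_uncertainty_pct=unc,
    )


def water_budget(
    inflows: Iterable[FlowSeries],
    outflows: Iterable[FlowSeries],
    reservoir: str,
    year: int,
) -> WaterBudget:
    """Annual hydraulic budget: volumes as Σ Q·86400 over the year.

    Raises :class:`CoverageError` if any route lacks daily coverage of the
    year.
    """
    def volume(series_set: Iterable[FlowSeries]) -> float:
        total = 0.0
        for fs in series_set:
            q = fs.year_slice(year)
            total += _loads.annual_load(q * SECONDS_PER_DAY, year)
        return total

    return WaterBudget(
        reservoir=reservoir,
        year=year,
        inflow_volume=volume(inflows),
        outflow_volume=volume(outflows),
    )


def water_budget_from_topology(
    flows: dict[str, FlowSeries],
    topology: CascadeTopology,
    reservoir: str,
    year: int,
) -> WaterBudget:
    """Water budget with routes selected by their wiring in the cascade.

    The outflow of a non-terminal reservoir is the inter-reservoir route it
    feeds; pumping drawn *from* a reservoir counts toward its outflow.
    """
    names = [r.name for r in topology.reservoirs]
    if reservoir not in names:
        raise DomainError(f"unknown reservoir {reservoir!r}")
    pos = names.index(reservoir)
    inflow_ids = topology.inflow_routes(reservoir)
    outflow_ids = []
    for rid, (role, fed) in topology.routes.items():
        if role.value == "inter_reservoir" and pos + 1 < len(names) and fed == names[pos + 1]:
            outflow_ids.append(rid)
        if role.value == "outflow" and pos == len(names) - 1:
            outflow_ids.append(rid)
        if role.value == "pumping_reverse" and pos == len(names) - 1:
            outflow_ids.append(rid)  # pumped water leaves the lower reservoir
    return water_budget(
        [flows[r] for r in inflow_ids if r in flows],
        [flows[r] for r in outflow_ids if r in flows],
        reservoir,
        year,
    )
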