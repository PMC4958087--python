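"""Water-column nutrient-ratio diagnostics and the retention-vs-drivers
correlation screen.

Molar N:P, Si:N and Si:P ratios are compared against the Redfield
stoichiometry of plankton (N:P = 16:1 molar, extended with Si:N ≈ 1.07 and
Si:P ≈ 17.2 for diatoms).  A dissolved-silicon concentration falling below
an empirical epilimnetic threshold (default 0.7 g m⁻³) marks conditions
under which diatom growth becomes Si-limited and chlorophyll increasingly
reflects non-diatom algae; a molar N:P well above 16 marks stoichiometric
N excess over P.

The correlation screen relates retention-percentage series to hydrological
drivers (input load, discharge, hydraulic retention time, hydraulic water
retention W_ret, and other retention series) by Pearson's r with two-sided
significance classified into p < 0.001 / 0.01 / 0.05 tiers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnalyteSample, Analyte, CorrelationCell, DomainError, RatioRecord

__all__ = [
    "MOLAR_MASS",
    "REDFIELD_NP_MOLAR",
    "molar_ratio",
    "mass_to_molar_np",
    "build_ratio_records",
    "LimitationThresholds",
    "limitation_flags",
    "pearson_screen",
    "screen_frame",
]

MOLAR_MASS = {"N": 14.007, "P": 30.974, "Si": 28.086, "C": 12.011}

REDFIELD_NP_MOLAR = 16.0


def molar_ratio(
    conc_a: float, molar_mass_a: float, conc_b: float, molar_mass_b: float
) -> Optional[float]:
    """Molar ratio of two mass concentrations; ``None`` when undefined.

    Returns (conc_a/M_a)/(conc_b/M_b), or ``None`` when the denominator
    concentration is zero (the ratio is flagged undefined rather than
    infinite).
    """
    if molar_mass_a <= 0 or molar_mass_b <= 0:
        raise DomainError("molar masses must be positive")
    if conc_a < 0 or conc_b < 0:
        raise DomainError("negative concentration")
    if conc_b == 0:
        return None
    return (conc_a / molar_mass_a) / (conc_b / molar_mass_b)


def mass_to_molar_np(mass_ratio: float) -> float:
    """Convert a mass N:P ratio to molar (× M_P/M_N)."""
    return mass_ratio * MOLAR_MASS["P"] / MOLAR_MASS["N"]


def build_ratio_records(samples: Iterable[AnalyteSample]) -> list[RatioRecord]:
    """Assemble per-(station, date) stoichiometry records from samples.

    Uses TN, TP and DSi concentrations (g m⁻³) and chlorophyll *a*
    (mg m⁻³) where present; a record is emitted for every (station, date)
    with at least a DSi measurement.
    """
    rows: dict[tuple[str, dt.date], dict[Analyte, float]] = {}
    for s in samples:
        rows.setdefault((s.station_id, s.date), {})[s.analyte] = s.concentration
    records = []
    for (station, date), vals in sorted(rows.items()):
        if Analyte.DSI not in vals:
            continue
        tn, tp, dsi = vals.get(Analyte.TN), vals.get(Analyte.TP), vals[Analyte.DSI]
        np_m = si_n = si_p = None
        if tn is not None and tp is not None:
            np_m = molar_ratio(tn, MOLAR_MASS["N"], tp, MOLAR_MASS["P"])
        if tn is not None:
            si_n = molar_ratio(dsi, MOLAR_MASS["Si"], tn, MOLAR_MASS["N"])
        if tp is not None:
            si_p = molar_ratio(dsi, MOLAR_MASS["Si"], tp, MOLAR_MASS["P"])
        records.append(
            RatioRecord(station, date, np_m, si_n, si_p, dsi,
                        vals.get(Analyte.CHLOROPHYLL))
        )
    return records


@dataclass(frozen=True)
class LimitationThresholds:
    """Configurable diagnostic thresholds (empirical, not constants)."""

    dsi_depletion: float = 0.7       # g m⁻³ epilimnetic DSi
    np_excess: float = 16.0          # molar N:P
    si_n_redfield: float = 1.07      # molar Si:N reference
    si_p_redfield: float = 17.2      # molar Si:P reference


def limitation_flags(
    record: RatioRecord,
    thresholds: LimitationThresholds = LimitationThresholds(),
) -> set[str]:
    """Nutrient-limitation flags for one stoichiometry record.

    * ``si_depleted`` — DSi strictly below the depletion threshold (a DSi
      exactly at the threshold is not depleted);
    * ``n_excess`` — molar N:P strictly above the Redfield reference;
    * ``si_limiting`` — DSi depleted *and* both Si:N and Si:P below their
      Redfield references, i.e. silicon is the element limiting diatom
      production.

    Undefined ratios leave the corresponding flags unset and add a
    ``ratio_undefined`` warning flag.
    """
    flags: set[str] = set()
    if record.dsi < thresholds.dsi_depletion:
        flags.add("si_depleted")
    if record.np_molar is None:
        flags.add("ratio_undefined")
    elif record.np_molar > thresholds.np_excess:
        flags.add("n_excess")
    if record.si_n_molar is None or record.si_p_molar is None:
        flags.add("ratio_undefined")
    elif (
        "si_depleted" in flags
        and record.si_n_molar < thresholds.si_n_redfield
        and record.si_p_molar < thresholds.si_p_redfield
    ):
        flags.add("si_limiting")
    return flags


SIGNIFICANCE_TIERS = (
    (0.001, "p<0.001"),
    (0.01, "p<0.01"),
    (0.05, "p<0.05"),
)


def _tier(p: float) -> str:
    for cutoff, label in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return label
    return "ns"


def pearson_screen(
    responses: pd.DataFrame, drivers: pd.DataFrame
) -> list[CorrelationCell]:
    """Pearson correlation of every response against every driver.

    ``responses`` and ``drivers`` are column-named frames of paired
    observations (rows aligned on the index).  Pairs with fewer than 3
    complete observations or a constant series yield an undefined cell
    (r = NaN, tier ``undefined``).
    """
    cells = []
    for rname, rcol in responses.items():
        for dname, dcol in drivers.items():
            pair = pd.concat([rcol, dcol], axis=1, keys=["y", "x"]).dropna()
            n = len(pair)
            if n < 3 or pair["y"].nunique() == 1 or pair["x"].nunique() == 1:
                cells.append(
                    CorrelationCell(str(rname), str(dname), float("nan"),
                                    float("nan"), "undefined", n)
                )
                continue
            r, p = stats.pearsonr(pair["y"], pair["x"])
            cells.append(
                CorrelationCell(str(rname), str(dname), float(r), float(p),
                                _tier(float(p)), n)
            )
    return cells


def screen_frame(cells: Iterable[CorrelationCell]) -> pd.DataFrame:
    """Tabulate correlation cells; non-significant r values are masked
    with a dash, mirroring conventional correlation tables."""
    rows = []
    for c in cells:
        shown = f"{c.r:.4f}" if c.significance_tier.startswith("p<") else "–"
        rows.append(
            {
                "response": c.response,
                "driver": c.driver,
                "r": c.r,
                "p_value": c.p_value,
                "tier": c.significance_tier,
                "n": c.n,
                "display": shown,
            }
        )
    return pd.DataFrame(rows)
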