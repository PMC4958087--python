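"""Daily and annual element loads from sampled concentrations × discharge.

A load time series is the product of a (daily-interpolated) concentration
in g m⁻³ and the daily mean discharge in m³ s⁻¹, converted to tonnes per
day (× 86400 s day⁻¹ / 10⁶ g t⁻¹).  Annual loads are sums of daily loads
over the calendar year; they are never computed as mean concentration ×
mean flow, which is biased whenever concentration and discharge covary.

Load uncertainty combines component percentage errors (sampling, chemical
analysis, flow measurement) additively; the uncertainty of a *retention*
(a difference of several loads) is propagated by root-mean-square over the
absolute load errors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import AnalyteSample, Analyte, CoverageError, DomainError, FlowSeries

__all__ = [
    "DailyLoadSeries",
    "interpolate_daily_concentration",
    "daily_load",
    "daily_load_series",
    "annual_load",
    "load_uncertainty",
    "retention_uncertainty",
    "direct_drainage_load",
]

TONNES_PER_DAY = 86400.0 / 1e6  # (g m⁻³ · m³ s⁻¹) → t day⁻¹

INTERPOLATION_METHODS = ("linear", "step", "flow_stratified")


@dataclass
class DailyLoadSeries:
    """Daily element load (t day⁻¹) on one route."""

    route_id: str
    element: Analyte
    load: pd.Series  # indexed by normalized daily timestamps


def _sample_series(samples: Union[Sequence[AnalyteSample], pd.Series]) -> pd.Series:
    if isinstance(samples, pd.Series):
        s = samples.copy()
        s.index = pd.DatetimeIndex(s.index).normalize()
    else:
        if not samples:
            raise DomainError("empty sample series")
        s = pd.Series(
            [x.concentration for x in samples],
            index=pd.DatetimeIndex([pd.Timestamp(x.date) for x in samples]),
        )
    s = s.astype(float).sort_index()
    if len(s) == 0:
        raise DomainError("empty sample series")
    if s.index.has_duplicates:
        raise DomainError("duplicate sample dates")
    return s


def interpolate_daily_concentration(
    samples: Union[Sequence[AnalyteSample], pd.Series],
    calendar: pd.DatetimeIndex,
    method: str = "linear",
    discharge: Optional[pd.Series] = None,
) -> pd.Series:
    """Expand sparse samples to one concentration per calendar day.

    Methods:

    ``linear``
        Linear in time between consecutive samples.
    ``step``
        Piecewise constant: each day carries the most recent sample.
    ``flow_stratified``
        Ordinary least squares of concentration on log-discharge fitted at
        the sample days, evaluated on the daily discharge, plus a
        linearly-interpolated residual correction.  The correction makes
        the method exact at sample dates (like the other two); when the
        samples lie on the regression line it reduces to the plain fit.
        Requires ``discharge`` covering both sample and calendar days.

    Every method extends the nearest sample value (or, for
    ``flow_stratified``, the nearest residual) beyond the sampled span.
    """
    conc = _sample_series(samples)
    calendar = pd.DatetimeIndex(calendar).normalize()
    if method not in INTERPOLATION_METHODS:
        raise DomainError(
            f"unknown interpolation method {method!r}; "
            f"expected one of {INTERPOLATION_METHODS}"
        )

    t_cal = calendar.view("int64").astype(float)
    t_smp = conc.index.view("int64").astype(float)
    values = conc.to_numpy()

    if method == "linear" or len(conc) == 1:
        out = np.interp(t_cal, t_smp, values)
    elif method == "step":
        idx = np.searchsorted(t_smp, t_cal, side="right") - 1
        idx = np.clip(idx, 0, len(values) - 1)
        out = values[idx]
    else:  # flow_stratified
        if discharge is None:
            raise DomainError("flow_stratified interpolation requires discharge")
        q = pd.Series(discharge).astype(float)
        q.index = pd.DatetimeIndex(q.index).normalize()
        missing = conc.index.difference(q.index).union(calendar.difference(q.index))
        if len(missing):
            raise CoverageError(
                f"discharge missing for {len(missing)} days needed by "
                "flow_stratified interpolation",
                [ts.date() for ts in missing],
            )
        if (q <= 0).any():
            raise DomainError("flow_stratified requires strictly positive discharge")
        logq_smp = np.log(q.reindex(conc.index).to_numpy())
        if np.ptp(logq_smp) == 0:
            # degenerate: constant discharge carries no stratification signal
            fitted_smp = np.full_like(values, values.mean())
            fitted_cal = np.full(len(calendar), values.mean())
        else:
            slope, intercept = np.polyfit(logq_smp, values, 1)
            fitted_smp = intercept + slope * logq_smp
            fitted_cal = intercept + slope * np.log(q.reindex(calendar).to_numpy())
        resid = values - fitted_smp
        out = fitted_cal + np.interp(t_cal, t_smp, resid)
    return pd.Series(np.maximum(out, 0.0), index=calendar)


def daily_load(concentration, discharge):
    """t day⁻¹ from concentration (g m⁻³) and discharge (m³ s⁻¹).

    Accepts scalars or aligned arrays.
    """
    c = np.asarray(concentration, dtype=float)
    q = np.asarray(discharge, dtype=float)
    if (c < 0).any() if c.ndim else c < 0:
        raise DomainError("negative concentration")
    if (q < 0).any() if q.ndim else q < 0:
        raise DomainError("negative discharge")
    out = c * q * TONNES_PER_DAY
    return float(out) if out.ndim == 0 else out


def daily_load_series(
    concentration: pd.Series, flow: FlowSeries, element: Analyte
) -> DailyLoadSeries:
    """Multiply a daily concentration series with a route's discharge."""
    conc = concentration.reindex(flow.discharge.index)
    if conc.isna().any():
        missing = conc.index[conc.isna()]
        raise CoverageError(
            f"concentration missing for {len(missing)} flow days on route "
            f"{flow.route_id}",
            [ts.date() for ts in missing],
        )
    load = pd.Series(
        daily_load(conc.to_numpy(), flow.discharge.to_numpy()),
        index=flow.discharge.index,
    )
    return DailyLoadSeries(flow.route_id, element, load)


def annual_load(daily: Union[DailyLoadSeries, pd.Series], year: int) -> float:
    """Sum of daily loads (t) over one calendar year.

    Raises :class:`CoverageError` listing the missing days if the year is
    not fully covered.
    """
    series = daily.load if isinstance(daily, DailyLoadSeries) else daily
    sel = series[series.index.year == year]
    expected = pd.date_range(f"{year}-01-01", f"{year}-12-31")
    missing = expected.difference(sel.index)
    if len(missing):
        raise CoverageError(
            f"year {year} not fully covered: {len(missing)} missing days "
            f"(first: {missing[0].date()})",
            [ts.date() for ts in missing],
        )
    return float(sel.sum())


def load_uncertainty(components: Iterable[float]) -> float:
    """Cumulative (additive) percentage uncertainty of an annual load.

    The components are the percentage errors of the contributing steps —
    field sampling, chemical analysis, discharge measurement — combined by
    simple summation as a conservative cumulative error.
    """
    comps = [float(c) for c in components]
    if any(c < 0 for c in comps):
        raise DomainError("negative uncertainty component")
    return float(sum(comps))


def retention_uncertainty(loads: Iterable[tuple[float, float]]) -> float:
    """Root-mean-square propagation of absolute load errors (t yr⁻¹).

    ``loads`` is a sequence of (load in t yr⁻¹, uncertainty in %); the
    result is sqrt(Σ (load·u/100)²) — the probable error of any sum or
    difference of the given loads, e.g. a retention.
    """
    terms = []
    for load, unc in loads:
        if unc < 0:
            raise DomainError("negative uncertainty component")
        terms.append((load * unc / 100.0) ** 2)
    return float(np.sqrt(sum(terms)))


def direct_drainage_load(point: float, nonpoint: float, bathers: float = 0.0) -> float:
    """Total direct-drainage load (t yr⁻¹) = point + nonpoint + bathers."""
    for name, v in (("point", point), ("nonpoint", nonpoint), ("bathers", bathers)):
        if v < 0:
            raise DomainError(f"negative {name} load")
    return float(point + nonpoint + bathers)
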