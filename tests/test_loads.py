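"""Load estimation: interpolation, unit conversion, annual sums,
uncertainty combination."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resbalance import (
    Analyte,
    AnalyteSample,
    CoverageError,
    DomainError,
    annual_load,
    daily_load,
    direct_drainage_load,
    interpolate_daily_concentration,
    load_uncertainty,
    retention_uncertainty,
)


def _samples(pairs, station="S", analyte=Analyte.TN):
    return [
        AnalyteSample(station, analyte, d, c)
        for d, c in pairs
    ]


CAL10 = pd.date_range("2004-01-01", periods=10)


class TestInterpolation:
    def test_single_sample_extends_constant(self):
        out = interpolate_daily_concentration(
            _samples([(dt.date(2004, 1, 4), 1.0)]), CAL10
        )
        assert (out == 1.0).all()

    def test_linear_midpoint(self):
        smp = _samples([(dt.date(2004, 1, 1), 1.0), (dt.date(2004, 1, 11), 2.0)])
        out = interpolate_daily_concentration(
            smp, pd.date_range("2004-01-01", periods=11)
        )
        assert out.loc["2004-01-06"] == pytest.approx(1.5)

    def test_step_holds_previous_sample(self):
        smp = _samples([(dt.date(2004, 1, 1), 1.0), (dt.date(2004, 1, 6), 3.0)])
        out = interpolate_daily_concentration(smp, CAL10, method="step")
        assert out.loc["2004-01-05"] == 1.0
        assert out.loc["2004-01-06"] == 3.0
        assert out.loc["2004-01-10"] == 3.0

    @pytest.mark.parametrize("method", ["linear", "step", "flow_stratified"])
    def test_exact_at_sample_dates(self, method):
        rng = np.random.default_rng(0)
        days = [dt.date(2004, 1, d) for d in (2, 9, 17, 25)]
        smp = _samples([(d, c) for d, c in zip(days, rng.uniform(0.5, 2, 4))])
        cal = pd.date_range("2004-01-01", periods=31)
        q = pd.Series(rng.uniform(5, 50, 31), index=cal)
        out = interpolate_daily_concentration(smp, cal, method=method, discharge=q)
        for s in smp:
            assert out.loc[pd.Timestamp(s.date)] == pytest.approx(
                s.concentration, abs=1e-12
            )

    def test_flow_stratified_matches_regression_oracle(self):
        # samples constructed exactly on c = a + b·log Q: the method must
        # reproduce the independent least-squares prediction everywhere
        rng = np.random.default_rng(1)
        cal = pd.date_range("2004-01-01", periods=60)
        q = pd.Series(rng.uniform(5, 80, 60), index=cal)
        a, b = 0.8, 0.35
        sample_days = cal[::7]
        smp = _samples(
            [
                (ts.date(), a + b * np.log(q.loc[ts]))
                for ts in sample_days
            ]
        )
        out = interpolate_daily_concentration(
            smp, cal, method="flow_stratified", discharge=q
        )
        # independent brute-force fit
        x = np.log(q.loc[sample_days].to_numpy())
        y = np.array([s.concentration for s in smp])
        xb, yb = x.mean(), y.mean()
        slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
        intercept = yb - slope * xb
        expected = intercept + slope * np.log(q.to_numpy())
        assert np.allclose(out.to_numpy(), expected, atol=1e-9)

    def test_empty_series_and_unknown_method_raise(self):
        with pytest.raises(DomainError):
            interpolate_daily_concentration([], CAL10)
        with pytest.raises(DomainError, match="unknown interpolation"):
            interpolate_daily_concentration(
                _samples([(dt.date(2004, 1, 1), 1.0)]), CAL10, method="spline"
            )


class TestDailyLoad:
    def test_zero_concentration(self):
        assert daily_load(0.0, 123.0) == 0.0

    def test_unit_conversion_identity(self):
        assert daily_load(1.0, 1.0) == pytest.approx(0.0864)

    def test_hand_conversion(self):
        # 2 g m⁻³ × 10 m³ s⁻¹ × 86400 s = 1.728e6 g = 1.728 t
        assert daily_load(2.0, 10.0) == pytest.approx(1.728)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            daily_load(-1.0, 1.0)
        with pytest.raises(DomainError):
            daily_load(1.0, -1.0)


class TestAnnualLoad:
    def test_constant_series_sums_to_365(self):
        series = pd.Series(1.0, index=pd.date_range("2005-01-01", "2005-12-31"))
        assert annual_load(series, 2005) == pytest.approx(365.0)

    def test_zero_series(self):
        series = pd.Series(0.0, index=pd.date_range("2005-01-01", "2005-12-31"))
        assert annual_load(series, 2005) == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        idx = pd.date_range("2005-01-01", "2005-12-31")
        vals = rng.uniform(0, 5, len(idx))
        total = annual_load(pd.Series(vals, index=idx), 2005)
        perm = rng.permutation(len(idx))
        shuffled = pd.Series(vals[perm], index=idx[perm])
        assert annual_load(shuffled, 2005) == pytest.approx(total, rel=1e-12)

    def test_gap_raises_listing_missing_days(self):
        idx = pd.date_range("2005-01-01", "2005-12-30")  # missing Dec 31
        with pytest.raises(CoverageError) as err:
            annual_load(pd.Series(1.0, index=idx), 2005)
        assert dt.date(2005, 12, 31) in err.value.missing_days


class TestUncertainty:
    def test_cumulative_components(self):
        assert load_uncertainty([15, 2, 2]) == 19
        assert load_uncertainty([0, 0, 0]) == 0
        assert load_uncertainty([7]) == 7

    def test_retention_single_term_collapse(self):
        assert retention_uncertainty([(100, 19)]) == pytest.approx(19.0)

    def test_retention_root_two(self):
        assert retention_uncertainty([(100, 10), (100, 10)]) == pytest.approx(
            10 * np.sqrt(2)
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1e4), st.floats(0, 50)), min_size=1, max_size=6
        )
    )
    def test_retention_matches_direct_formula(self, terms):
        expected = sum((load * unc / 100.0) ** 2 for load, unc in terms) ** 0.5
        assert retention_uncertainty(terms) == pytest.approx(expected, rel=1e-12)


def test_direct_drainage_load_sums_and_defaults():
    assert direct_drainage_load(0, 0, 0) == 0
    assert direct_drainage_load(3, 1, 0.5) == pytest.approx(4.5)
    assert direct_drainage_load(3, 1) == pytest.approx(4.0)
    with pytest.raises(DomainError):
        direct_drainage_load(-1, 0)


def test_annual_load_linearity_in_concentration(scenario):
    """Scaling all concentrations by k scales every annual load by k."""
    fs = scenario.flows["major_1"]
    conc = scenario.daily_concentration[("major_1", "TN")]
    base = annual_load(
        pd.Series(daily_load(conc.to_numpy(), fs.discharge.to_numpy()),
                  index=conc.index),
        2004,
    )
    scaled = annual_load(
        pd.Series(daily_load(3.0 * conc.to_numpy(), fs.discharge.to_numpy()),
                  index=conc.index),
        2004,
    )
    assert scaled == pytest.approx(3.0 * base, rel=1e-12)


def test_merged_routes_add(scenario):
    """Annual load of a merged pair of routes equals the sum of the
    individual annual loads."""
    tot = 0.0
    merged = None
    for rid in ("major_1", "major_2"):
        fs = scenario.flows[rid]
        conc = scenario.daily_concentration[(rid, "TN")]
        load = pd.Series(
            daily_load(conc.to_numpy(), fs.discharge.to_numpy()), index=conc.index
        )
        tot += annual_load(load, 2005)
        merged = load if merged is None else merged + load
    assert annual_load(merged, 2005) == pytest.approx(tot, rel=1e-12)
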