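"""Phosphorus-anchored sedimentation arithmetic and retention ledgers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resbalance import (
    DomainError,
    SedimentStoichiometry,
    areal_rate,
    carbon_ledger,
    carbon_sedimentation,
    delta_p,
    denitrification_annual,
    nitrogen_ledger,
    nitrogen_sedimentation,
    phosphorus_ledger,
    spatial_partition,
)


class TestDeltaP:
    def test_no_change_is_zero(self):
        assert delta_p(0.05, 0.05, 502e6, 30) == 0.0

    def test_hand_evaluation(self):
        # (0.06−0.05)·502e6/30 · 365/1e6 = 61.0766… t yr⁻¹
        assert delta_p(0.05, 0.06, 502e6, 30) == pytest.approx(61.07666, rel=1e-6)

    def test_antisymmetry(self):
        assert delta_p(0.03, 0.07, 1e8, 14) == -delta_p(0.07, 0.03, 1e8, 14)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(DomainError):
            delta_p(0.05, 0.06, 502e6, 0)

    def test_telescoping_to_total_stock_change(self):
        """Σ ΔP·Δt/365 over consecutive intervals equals
        (P_last − P_first)·V_R/10⁶."""
        rng = np.random.default_rng(3)
        conc = rng.uniform(0.02, 0.08, 12)
        dts = rng.integers(10, 45, 11)
        v = 502e6
        total = sum(
            delta_p(conc[i], conc[i + 1], v, dts[i]) * dts[i] / 365.0
            for i in range(11)
        )
        assert total == pytest.approx((conc[-1] - conc[0]) * v / 1e6, rel=1e-9)


STOICH = SedimentStoichiometry(np_ratio=5.0, cn_ratio=2.0)


class TestStoichiometricSedimentation:
    def test_simple_multiplication(self):
        assert nitrogen_sedimentation(10, 0, STOICH) == pytest.approx(50.0)

    def test_cancelled_budget(self):
        assert nitrogen_sedimentation(10, 10, STOICH) == 0.0

    def test_carbon_from_back_computed_ratio(self):
        stoich = SedimentStoichiometry(np_ratio=3.03, cn_ratio=11.818)
        assert carbon_sedimentation(110, stoich) == pytest.approx(1300.0, rel=1e-3)

    def test_carbon_identity_ratio(self):
        assert carbon_sedimentation(1, SedimentStoichiometry(1, 1)) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-100, 100),
           st.floats(0.1, 20), st.floats(0.1, 20))
    def test_matches_direct_formula(self, p_ret, dp, np_ratio, cn_ratio):
        stoich = SedimentStoichiometry(np_ratio, cn_ratio)
        n = nitrogen_sedimentation(p_ret, dp, stoich)
        assert n == pytest.approx((p_ret - dp) * np_ratio, rel=1e-12, abs=1e-12)
        assert carbon_sedimentation(n, stoich) == pytest.approx(
            n * cn_ratio, rel=1e-12, abs=1e-12
        )


class TestSpatialPartition:
    def test_even_split(self):
        assert spatial_partition(100, 0.5) == (50.0, 50.0)

    def test_shares_sum_to_total_before_rounding(self):
        back, lac = spatial_partition(117.3, 2 / 3)
        assert back + lac == pytest.approx(117.3, rel=1e-12)

    def test_whole_tonne_reconciliation(self):
        assert spatial_partition(110, 2 / 3, rounding_unit=1) == (73.0, 37.0)

    def test_round_to_ten_reconciliation(self):
        assert spatial_partition(1300, 2 / 3, rounding_unit=10) == (870.0, 430.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 5000), st.floats(0, 1), st.sampled_from([1.0, 10.0]))
    def test_reconciled_shares_sum_to_rounded_total(self, total, frac, unit):
        back, lac = spatial_partition(total, frac, rounding_unit=unit)
        total_r = round(total / unit) * unit
        assert abs(back + lac - total) <= unit  # within one rounding unit
        assert back + lac == pytest.approx(
            spatial_partition(total, frac, rounding_unit=unit)[0]
            + spatial_partition(total, frac, rounding_unit=unit)[1]
        )

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            spatial_partition(10, 1.2)


class TestArealRates:
    def test_unit_identity(self):
        assert areal_rate(365, 1e6) == pytest.approx(1.0)
        assert areal_rate(0, 1e6) == 0.0

    def test_back_solved_area_roundtrip(self):
        # 1300 t yr⁻¹ over 21.99 km² → 0.162 g m⁻² day⁻¹
        assert areal_rate(1300, 21.99e6) == pytest.approx(0.162, abs=5e-4)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(DomainError):
            areal_rate(10, 0)


class TestDenitrification:
    def test_unit_identity(self):
        assert denitrification_annual(1, 1e6) == pytest.approx(1.0)
        assert denitrification_annual(0, 1e6) == 0.0

    def test_back_solved_effective_area(self):
        assert denitrification_annual(4, 17.5e6) == pytest.approx(70.0)


class TestLedgers:
    def test_nitrogen_fully_explained_by_sedimentation(self):
        led = nitrogen_ledger(500, 120, 120, 0)
        assert led.indefinite == 0.0

    def test_nitrogen_ledger_closure(self):
        led = nitrogen_ledger(1957, 174, 110, 70)
        assert led.retention - sum(led.terms.values()) - led.indefinite == 0.0

    def test_phosphorus_split(self):
        led = phosphorus_ledger(23, 12)
        assert led.terms["particulate_P"] == pytest.approx(11.0)
        assert led.terms["biomass_P"] == pytest.approx(12.0)

    def test_phosphorus_degenerate_splits(self):
        assert phosphorus_ledger(30, 30).terms["particulate_P"] == 0.0
        assert phosphorus_ledger(30, 0).terms["particulate_P"] == pytest.approx(30.0)

    def test_carbon_equal_means_no_internal_production(self):
        led = carbon_ledger(500, 500)
        assert led.terms["autochthonous_C"] == 0.0
        assert led.shares["sed_to_retention_ratio"] == pytest.approx(1.0)

    def test_carbon_zero_retention_is_flagged(self):
        led = carbon_ledger(0, 100)
        assert led.flags

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 3000), st.floats(-500, 1500),
           st.floats(0, 800), st.floats(0, 300))
    def test_ledger_closure_property(self, inflow, retention, sed, denit):
        led = nitrogen_ledger(inflow, retention, sed, denit)
        assert led.retention - sum(led.terms.values()) - led.indefinite == pytest.approx(
            0.0, abs=1e-9
        )
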