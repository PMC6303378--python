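"""Flux-based ozone damage scheme."""

import numpy as np
import pytest

from firegpp import ozone
from firegpp import photosynthesis as ph


class TestUnitBridge:
    def test_zero_is_zero(self):
        assert ozone.ppbv_to_concentration(0.0, 298.15, 101325.0) == 0.0

    def test_ideal_gas_arithmetic(self):
        # 40 ppbv at 298.15 K, 101325 Pa -> ~1634.9 nmol m-3
        got = ozone.ppbv_to_concentration(40.0, 298.15, 101325.0)
        assert got == pytest.approx(1634.9, rel=1e-3)

    def test_linear_in_pressure(self):
        full = ozone.ppbv_to_concentration(40.0, 298.15, 101325.0)
        half = ozone.ppbv_to_concentration(40.0, 298.15, 101325.0 / 2)
        assert half == pytest.approx(full / 2)

    def test_nonpositive_state_rejected(self):
        with pytest.raises(ValueError):
            ozone.ppbv_to_concentration(40.0, 0.0, 101325.0)
        with pytest.raises(ValueError):
            ozone.ppbv_to_concentration(40.0, 298.15, -1.0)


class TestStomatalFlux:
    def test_direct_evaluation(self):
        got = ozone.stomatal_o3_flux(1635.0, 20.0, 180.0, 1.67)
        assert got == pytest.approx(1635.0 / (20.0 + 1.67 * 180.0), rel=1e-12)
        assert got == pytest.approx(5.10, abs=0.01)

    def test_closed_stomata_take_up_nothing(self):
        assert ozone.stomatal_o3_flux(2000.0, 20.0, 1e12) == pytest.approx(0.0, abs=1e-6)

    def test_zero_concentration_zero_flux(self):
        assert ozone.stomatal_o3_flux(0.0, 20.0, 100.0) == 0.0

    def test_nonpositive_resistances_rejected(self):
        with pytest.raises(ValueError):
            ozone.stomatal_o3_flux(100.0, 0.0, 100.0)

    def test_decreasing_in_each_resistance(self):
        base = ozone.stomatal_o3_flux(1000.0, 20.0, 100.0)
        assert ozone.stomatal_o3_flux(1000.0, 40.0, 100.0) < base
        assert ozone.stomatal_o3_flux(1000.0, 20.0, 200.0) < base


class TestDamageFraction:
    def test_zero_at_threshold_and_continuous(self):
        assert ozone.damage_fraction(1.6, 0.04, 1.6) == 0.0
        assert ozone.damage_fraction(1.6 + 1e-9, 0.04, 1.6) == pytest.approx(0.0, abs=1e-9)

    def test_linear_above_threshold(self):
        assert ozone.damage_fraction(3.6, 0.04, 1.6) == pytest.approx(-0.08)

    def test_zero_below_threshold(self):
        assert ozone.damage_fraction(1.0, 0.04, 1.6) == 0.0

    def test_magnitude_monotone_in_sensitivity(self):
        flux = 6.0
        low = ozone.damage_fraction(flux, 0.02, 1.6)
        high = ozone.damage_fraction(flux, 0.1, 1.6)
        assert abs(high) >= abs(low)

    def test_scaling_coefficients_scales_damage_linearly(self, dbf):
        """A 33% coefficient reduction cuts damage by 33% at fixed flux."""
        flux = 7.5
        scaled = dbf.with_scaled_damage(0.67)
        for a_full, a_scaled in ((dbf.a_low, scaled.a_low), (dbf.a_high, scaled.a_high)):
            f_full = ozone.damage_fraction(flux, a_full, dbf.t_o3)
            f_scaled = ozone.damage_fraction(flux, a_scaled, dbf.t_o3)
            assert abs(f_scaled) == pytest.approx(0.67 * abs(f_full), rel=0.02)


class TestDamagedPhotosynthesis:
    def _leaf(self, dbf, par=300.0):
        return ph.leaf_photosynthesis(par, 298.15, 0.7, 400.0, dbf)

    @staticmethod
    def _cs(leaf):
        """Leaf-surface CO2 consistent with the converged leaf state."""
        return 400.0 - 1.37 * np.maximum(leaf.a_net, 0.0) / ph.GB_MOL

    def test_no_ozone_no_change(self, dbf):
        leaf = self._leaf(dbf)
        a_dam, gs_dam, state = ozone.damaged_photosynthesis(
            leaf, 0.0, 3.0, 0.7, self._cs(leaf), 298.15, 101325.0, dbf, "high"
        )
        np.testing.assert_allclose(a_dam, leaf.a_net)
        np.testing.assert_allclose(gs_dam, leaf.g_s)
        assert np.all(state.damage == 0.0)

    def test_low_conductance_shields_high_ozone(self, dbf):
        """Nearly closed stomata keep the flux below threshold at high [O3]."""
        dark = self._leaf(dbf, par=0.0)  # g_s at the intercept
        _, _, state = ozone.damaged_photosynthesis(
            dark, 60.0, 3.0, 0.7, 400.0, 298.15, 101325.0, dbf, "high"
        )
        assert np.all(state.f_o3 <= dbf.t_o3)
        assert np.all(state.damage == 0.0)

    def test_damaged_never_exceeds_undamaged(self, dbf):
        leaf = self._leaf(dbf)
        for o3 in (20.0, 40.0, 80.0):
            a_dam, _, _ = ozone.damaged_photosynthesis(
                leaf, o3, 3.0, 0.7, 400.0, 298.15, 101325.0, dbf, "high"
            )
            assert np.all(a_dam <= leaf.a_net + 1e-12)

    def test_damage_magnitude_monotone_in_concentration(self, dbf):
        leaf = self._leaf(dbf)
        damages = []
        for o3 in (20.0, 40.0, 60.0, 80.0):
            _, _, state = ozone.damaged_photosynthesis(
                leaf, o3, 3.0, 0.7, 400.0, 298.15, 101325.0, dbf, "mean"
            )
            damages.append(float(np.mean(state.damage)))
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(damages, damages[1:]))

    def test_fixed_point_matches_exhaustive_scan(self, dbf):
        """Oracle: scan damage factors on a 1e-5 grid for self-consistency."""
        leaf = self._leaf(dbf)
        o3, wind, rh, t, p = 60.0, 3.0, 0.7, 298.15, 101325.0
        cs = self._cs(leaf)
        a_dam, gs_dam, state = ozone.damaged_photosynthesis(
            leaf, o3, wind, rh, cs, t, p, dbf, "high"
        )
        conc = ozone.ppbv_to_concentration(o3, t, p)
        r_b = ozone.boundary_layer_resistance(wind)
        a0 = float(leaf.a_net)

        grid = np.arange(-0.999, 1e-5, 1e-5)  # candidate damage F values
        a_trial = (1.0 + grid) * a0
        gs_trial = ph.stomatal_conductance(
            a_trial, rh, float(cs),
            dbf.ball_berry_slope, dbf.ball_berry_intercept,
        )
        r_s = ozone.stomatal_resistance(gs_trial, t, p)
        flux = ozone.stomatal_o3_flux(conc, r_b, r_s)
        implied = ozone.damage_fraction(flux, dbf.a_high, dbf.t_o3)
        best = grid[np.argmin(np.abs(implied - grid))]
        assert float(state.damage) == pytest.approx(best, abs=2e-4)
        assert float(a_dam) == pytest.approx((1.0 + best) * a0, rel=1e-3)

    def test_mean_sensitivity_is_central_value_of_low_high(self, dbf):
        leaf = self._leaf(dbf)
        args = (leaf, 60.0, 3.0, 0.7, 400.0, 298.15, 101325.0, dbf)
        a_lo, _, _ = ozone.damaged_photosynthesis(*args, "low")
        a_hi, _, _ = ozone.damaged_photosynthesis(*args, "high")
        a_mean, _, _ = ozone.damaged_photosynthesis(*args, "mean")
        np.testing.assert_allclose(a_mean, 0.5 * (a_lo + a_hi), rtol=1e-12)
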