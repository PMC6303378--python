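"""Column optics and the delta-Eddington two-stream PAR scheme."""

import numpy as np
import pytest

from firegpp import forcing as fo
from firegpp import radiation as rad
from conftest import monte_carlo_transmission


class TestMixOptics:
    def test_vacuum_column_convention(self):
        col = rad.mix_optics(0.0, 0.0, 0.0, 0.0)
        assert col.tau_total == 0.0
        assert col.single_scattering_albedo == 1.0

    def test_hand_weighted_albedo(self):
        # equal parts scattering (0.95) and absorbing (0.30) aerosol
        col = rad.mix_optics(0.5, 0.5, 0.0, 0.0)
        assert col.single_scattering_albedo == pytest.approx(0.625)
        assert col.tau_total == pytest.approx(1.0)

    def test_tau_is_linear_in_components(self):
        a = rad.mix_optics(0.3, 0.1, 2.0, 0.1)
        b = rad.mix_optics(0.6, 0.2, 4.0, 0.2)
        assert b.tau_total == pytest.approx(2.0 * a.tau_total)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rad.mix_optics(-0.1, 0.0)


class TestCloudOpticalDepth:
    def test_zero_lwp_gives_zero_tau(self):
        assert rad.cloud_optical_depth(0.0) == 0.0

    def test_stated_formula_arithmetic(self):
        # tau = 3 LWP / (2 rho_w r_e): 100 g m-2 at 10 um -> 15
        assert rad.cloud_optical_depth(100.0, 10.0) == pytest.approx(15.0)

    def test_strictly_increasing_in_lwp(self):
        lwp = np.linspace(0.0, 300.0, 50)
        tau = rad.cloud_optical_depth(lwp)
        assert np.all(np.diff(tau) > 0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rad.cloud_optical_depth(10.0, 0.0)


class TestSurfacePar:
    def test_clean_atmosphere_direct_beam_is_rayleigh_beer_law(self):
        flx = rad.surface_par(1000.0, 0.0, 0.0, 0.0)
        par_toa = rad.PAR_FRACTION * 1000.0
        expect = par_toa * np.exp(-rad.TAU_RAYLEIGH_PAR)
        assert float(flx.par_direct) == pytest.approx(expect, rel=1e-9)
        assert 0.0 < float(flx.diffuse_fraction) < 0.2

    def test_sun_below_horizon_gives_zero_fluxes(self):
        flx = rad.surface_par(0.0, 95.0, 0.5, 0.1, 0.5, 50.0)
        assert float(flx.par_direct) == 0.0
        assert float(flx.par_diffuse) == 0.0

    def test_opaque_cloud_limit_is_all_diffuse(self):
        flx = rad.surface_par(1000.0, 0.0, 0.0, 0.0, cloud_fraction=1.0,
                              cloud_lwp=1e5)
        assert float(flx.par_direct) == pytest.approx(0.0, abs=1e-12)
        assert float(flx.diffuse_fraction) == pytest.approx(1.0)

    def test_energy_bound_over_random_columns(self):
        rng = np.random.default_rng(0)
        n = 100_000
        toa = rng.uniform(0.0, 1400.0, n)
        zen = rng.uniform(0.0, 89.0, n)
        flx = rad.surface_par(
            toa, zen,
            rng.uniform(0, 3, n), rng.uniform(0, 1, n),
            rng.uniform(0, 1, n), rng.uniform(0, 300, n),
        )
        assert np.all(flx.par_total <= rad.PAR_FRACTION * toa + 1e-9)
        assert np.all(flx.par_direct >= 0)
        assert np.all(flx.par_diffuse >= 0)

    def test_direct_beam_decreasing_and_total_decreasing_in_absorber(self):
        aods = np.linspace(0.0, 3.0, 30)
        flx_s = rad.surface_par(1000.0, 30.0, aods, 0.0)
        assert np.all(np.diff(flx_s.par_direct) < 0)
        flx_a = rad.surface_par(1000.0, 30.0, 0.0, aods)
        assert np.all(np.diff(flx_a.par_total) < 0)

    def test_diffuse_fraction_increasing_in_scattering_aod(self):
        aods = np.linspace(0.0, 3.0, 30)
        flx = rad.surface_par(1000.0, 30.0, aods, 0.0)
        assert np.all(np.diff(flx.diffuse_fraction) > 0)

    @pytest.mark.parametrize(
        "tau,ssa,g,mu0",
        [
            (0.5, 0.95, 0.65, 1.0),
            (1.5, 0.95, 0.65, 0.7),
            (3.0, 0.90, 0.70, 0.5),
            (0.6, 0.55, 0.60, 0.8),
            (2.0, 0.9995, 0.85, 0.9),
            (3.0, 0.95, 0.65, 0.9),
        ],
    )
    def test_two_stream_within_ten_percent_of_photon_tracking(self, tau, ssa, g, mu0):
        """Total downward transmission vs. an independent Monte Carlo solver."""
        td, tf = rad.delta_two_stream(tau, ssa, g, mu0)
        mc_dir, mc_dif = monte_carlo_transmission(tau, ssa, g, mu0)
        total = float(td + tf)
        mc_total = mc_dir + mc_dif
        assert total == pytest.approx(mc_total, rel=0.10)

    def test_direct_transmittance_uses_delta_scaled_depth(self):
        # overhead sun, aerosol 0.5 (ssa 0.95, g 0.65) plus Rayleigh
        col = rad.mix_optics(0.5, 0.0, 0.0, rad.TAU_RAYLEIGH_PAR)
        td, _ = rad.delta_two_stream(
            col.tau_total, col.single_scattering_albedo, col.asymmetry, 1.0
        )
        f = float(col.asymmetry) ** 2
        tau_scaled = (1.0 - float(col.single_scattering_albedo) * f) * float(col.tau_total)
        assert float(td) == pytest.approx(np.exp(-tau_scaled), rel=1e-9)


class TestCloudScaling:
    def _atmos(self, seed=0, n_days=6):
        return fo.generate_pollution_scenario(seed=seed, n_days=n_days)

    def test_identity_at_factor_one(self):
        atm = self._atmos()
        out = rad.apply_cloud_scaling(atm, 1.0)
        np.testing.assert_array_equal(out.cloud_fraction, atm.cloud_fraction)
        np.testing.assert_array_equal(out.cloud_lwp, atm.cloud_lwp)

    def test_factor_zero_removes_cloud(self):
        out = rad.apply_cloud_scaling(self._atmos(), 0.0)
        assert np.all(out.cloud_fraction == 0.0)
        assert np.all(out.cloud_lwp == 0.0)

    def test_fraction_capped_at_one(self):
        out = rad.apply_cloud_scaling(self._atmos(), 10.0)
        assert np.all(out.cloud_fraction <= 1.0)
        assert out.cloud_fraction.max() == pytest.approx(1.0)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            rad.apply_cloud_scaling(self._atmos(), -0.5)

    def test_diffuse_par_rises_then_falls_with_scaling(self):
        """Mean diffuse PAR peaks near scaling ~1.5 for the default column."""
        from firegpp import model as model_mod

        f = fo.generate_site_forcing(n_days=6, seed=2)
        atm = fo.generate_pollution_scenario(
            seed=2, n_days=6,
            cloud_spec=fo.CloudSpec(fraction_mean=0.69, fraction_sd=0.2,
                                    lwp_mean=60.0),
        )
        factors = np.linspace(0.0, 4.0, 17)
        dif = [
            model_mod.radiation_from_atmos(
                f, rad.apply_cloud_scaling(atm, fac), aerosol_mode="none"
            ).par_diffuse.mean()
            for fac in factors
        ]
        peak = factors[int(np.argmax(dif))]
        assert 1.0 <= peak <= 2.0
        assert dif[0] < max(dif)          # rises from clear sky
        assert dif[-1] < max(dif)         # falls under heavy scaling
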