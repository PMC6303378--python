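"""Factorial arms, cloud-scaling sweep, perturbation suite, uncertainty."""

import numpy as np
import pytest

from firegpp import experiments as ex
from firegpp import forcing as fo


N_DAYS = 10


@pytest.fixture(scope="module")
def setting(pft_table):
    forcing = fo.generate_site_forcing(
        n_days=N_DAYS, climate_archetype="midlatitude_summer", seed=21
    )
    scen = ex.ScenarioConfig(n_days=N_DAYS, seed=21)
    return forcing, scen, pft_table["deciduous_broadleaf_forest"]


@pytest.fixture(scope="module")
def factorial(setting):
    forcing, scen, params = setting
    return ex.run_factorial(forcing, scen.build(), params)


class TestFactorial:
    def test_null_arm_equals_clean_air_baseline(self, setting):
        forcing, scen, params = setting
        from firegpp import model as model_mod

        atm = scen.build()
        na = ex.run_arm(ex.ARM_DEFS["NA"], forcing, atm, params)
        # clean-air baseline computed directly, bypassing the arm machinery
        flx = model_mod.radiation_from_atmos(forcing, atm, aerosol_mode="none")
        direct = model_mod.run_site(forcing, flx, params)
        assert na.gpp_total == direct.gpp_total

    def test_unknown_arm_rejected(self, setting):
        forcing, scen, params = setting
        with pytest.raises(ValueError, match="unknown arm"):
            ex.run_factorial(forcing, scen.build(), params, arms=["XYZ"])

    def test_all_eleven_arms_produced(self, factorial):
        assert set(factorial) == {
            "NA", "AA", "FA", "NOH", "NOL", "FOH", "FOL",
            "AAOH", "AAOL", "FAOH", "FAOL",
        }

    def test_fire_o3_attribution_matches_hand_recombination(self, factorial):
        att = ex.fire_attribution(factorial)
        lo = factorial["FOL"].gpp_total - factorial["NOL"].gpp_total
        hi = factorial["FOH"].gpp_total - factorial["NOH"].gpp_total
        assert att["o3"][0] == pytest.approx(0.5 * (lo + hi))
        assert att["o3"][1] == pytest.approx(0.5 * abs(hi - lo))

    def test_telescoping_arm_differences(self, factorial):
        a = factorial["FAOH"].gpp_total
        b = factorial["AAOH"].gpp_total
        c = factorial["NOH"].gpp_total
        assert (a - b) + (b - c) == pytest.approx(a - c, abs=1e-9)

    def test_deterministic_across_reruns(self, setting, factorial):
        forcing, scen, params = setting
        again = ex.run_factorial(forcing, scen.build(), params, arms=["FAOH"])
        assert again["FAOH"].gpp_total == factorial["FAOH"].gpp_total
        np.testing.assert_array_equal(
            again["FAOH"].gpp_series, factorial["FAOH"].gpp_series
        )

    def test_no_fire_scenario_gives_exactly_zero_attribution(self, pft_table):
        forcing = fo.generate_site_forcing(n_days=N_DAYS, seed=5)
        scen = ex.ScenarioConfig(n_days=N_DAYS, seed=5, fire_o3_delta=0.0)
        atm = scen.build(fire_aod_on=False)
        res = ex.run_factorial(
            forcing, atm, pft_table["deciduous_broadleaf_forest"]
        )
        att = ex.fire_attribution(res)
        assert att["o3"] == (0.0, 0.0)
        assert att["aerosol"] == (0.0, 0.0)
        assert att["combined"] == (0.0, 0.0)


class TestCloudScalingSweep:
    def test_zero_cloud_site_is_flagged_degenerate(self, setting):
        forcing, scen, params = setting
        atm = scen.build()
        import dataclasses

        atm = dataclasses.replace(
            atm.copy(),
            cloud_fraction=np.zeros_like(atm.cloud_fraction),
            cloud_lwp=np.zeros_like(atm.cloud_lwp),
        )
        sweep = ex.cloud_scaling_sweep(forcing, atm, params,
                                       factors=np.linspace(0, 10, 8))
        assert sweep.degenerate
        assert sweep.threshold == 0.0  # smallest factor on a flat response

    def test_unimodal_response_and_agreement_with_fine_grid(self, setting):
        forcing, scen, params = setting
        atm = scen.build()
        coarse = ex.cloud_scaling_sweep(forcing, atm, params)
        fine = ex.cloud_scaling_sweep(
            forcing, atm, params, factors=np.linspace(0.0, 10.0, 200)
        )
        # single interior maximum on the fine grid
        d = np.diff(fine.gpp)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
        assert sign_changes <= 1
        step = coarse.factors[1] - coarse.factors[0]
        assert abs(coarse.threshold - fine.threshold) <= step

    def test_archetype_threshold_ordering(self, pft_table):
        """Dense tropical cloud is past its optimum; arid sites are not."""
        thresholds = {}
        for arche in ("arid", "tropical_wet"):
            arch = fo.ARCHETYPES[arche]
            forcing = fo.generate_site_forcing(
                n_days=20, climate_archetype=arche, seed=13
            )
            scen = ex.ScenarioConfig(n_days=20, seed=13, cloud_spec=arch.cloud)
            sweep = ex.cloud_scaling_sweep(
                forcing, scen.build(), pft_table[arch.pft]
            )
            thresholds[arche] = sweep.threshold
        assert thresholds["arid"] > 1.0
        assert thresholds["tropical_wet"] < 1.0

    def test_empty_factor_list_rejected(self, setting):
        forcing, scen, params = setting
        with pytest.raises(ValueError):
            ex.cloud_scaling_sweep(forcing, scen.build(), params, factors=[1.0])


@pytest.fixture(scope="module")
def suite(setting):
    forcing, scen, params = setting
    return ex.perturbation_suite(forcing, scen, params)


class TestPerturbationSuite:
    def test_all_members_present(self, suite):
        assert set(suite) == set(ex.PERTURBATIONS)

    def test_less_absorbing_smoke_fertilizes_more(self, suite):
        assert suite["BC05"]["delta_gpp"] >= suite["BC20"]["delta_gpp"]

    def test_thinner_cloud_leaves_more_room_for_fertilization(self, suite):
        assert suite["C05"]["delta_gpp"] >= suite["C20"]["delta_gpp"]

    def test_scaling_zero_fire_aerosol_changes_nothing(self, pft_table):
        forcing = fo.generate_site_forcing(n_days=N_DAYS, seed=6)
        scen = ex.ScenarioConfig(
            n_days=N_DAYS, seed=6,
            aod_spec=fo.AODSpec(fire_scattering=0.0, fire_absorbing=0.0),
        )
        params = pft_table["deciduous_broadleaf_forest"]
        atm_base = scen.build()
        fa_base = ex.run_arm(ex.ARM_DEFS["FA"], forcing, atm_base, params)
        out = ex.perturbation_suite(forcing, scen, params, names=["FA2"])
        assert out["FA2"]["fa_total"] == fa_base.gpp_total

    def test_unknown_perturbation_rejected(self, setting):
        forcing, scen, params = setting
        with pytest.raises(ValueError, match="unknown perturbation"):
            ex.perturbation_suite(forcing, scen, params, names=["BC99"])


class TestCombineUncertainty:
    def test_published_arithmetic_convention(self):
        central, half = ex.combine_uncertainty(-1.29, -0.55)
        assert central == pytest.approx(-0.92)
        assert half == pytest.approx(0.37)

    def test_equal_arms_zero_half_range(self):
        assert ex.combine_uncertainty(2.0, 2.0) == (2.0, 0.0)

    def test_symmetric_in_arguments(self):
        assert ex.combine_uncertainty(1.0, 3.0) == ex.combine_uncertainty(3.0, 1.0)

    def test_mismatched_references_rejected(self):
        a = ex.ExperimentResult("x", np.zeros(1), 1.0, reference="NA")
        b = ex.ExperimentResult("y", np.zeros(1), 2.0, reference="AA")
        with pytest.raises(ValueError, match="reference"):
            ex.combine_uncertainty(a, b)
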