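"""Site-level GPP driver coupling radiation, canopy, leaf and ozone stages.

`run_site` evaluates the whole chain for one site column: surface PAR from
the column optics, sunlit/shaded canopy partitioning, the coupled
Farquhar/Ball-Berry leaf solution per layer, optional flux-based ozone
damage, and trapezoidal integration to canopy GPP.  Everything is
vectorised over (time, canopy node).

Units: PAR in W m-2, GPP in umol CO2 m-2 s-1 internally and
g C m-2 day-1 at the reporting layer (12 g C per mol CO2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import canopy as canopy_mod
from . import ozone as ozone_mod
from . import radiation as rad_mod
from . import solar
from .forcing import AtmosphericState, SiteForcing
from .pft import PFTParams
from .photosynthesis import leaf_photosynthesis

__all__ = ["SiteResult", "relative_humidity", "radiation_from_atmos", "run_site"]

GC_PER_UMOL = 12.0e-6  # g C per umol CO2


def relative_humidity(specific_humidity, temperature, pressure):
    """Relative humidity from specific humidity (Tetens saturation pressure)."""
    t_c = np.asarray(temperature, dtype=float) - 273.15
    esat = 610.8 * np.exp(17.27 * t_c / (t_c + 237.3))
    e = np.asarray(specific_humidity, dtype=float) * np.asarray(pressure, dtype=float) / 0.622
    return np.clip(e / esat, 0.01, 1.0)


@dataclass
class SiteResult:
    """Per-timestep outputs of one site run."""

    forcing: SiteForcing
    gpp: np.ndarray              # umol CO2 m-2 ground s-1
    gs_canopy: np.ndarray        # LAI-mean stomatal conductance, mol m-2 s-1
    par_direct: np.ndarray       # W m-2
    par_diffuse: np.ndarray
    solar_zenith: np.ndarray     # degrees

    @property
    def par_total(self) -> np.ndarray:
        return self.par_direct + self.par_diffuse

    @property
    def diffuse_fraction(self) -> np.ndarray:
        total = self.par_total
        return np.where(total > 0, self.par_diffuse / np.where(total > 0, total, 1.0), 1.0)

    def daily_gpp(self) -> np.ndarray:
        """Daily GPP [g C m-2 day-1]."""
        n = self.forcing.n_steps_per_day
        per_day = self.gpp.reshape(-1, n).mean(axis=1)
        return per_day * GC_PER_UMOL * 86400.0

    @property
    def gpp_total(self) -> float:
        """Run-total GPP [g C m-2]."""
        return float(self.daily_gpp().sum())


def radiation_from_atmos(
    forcing: SiteForcing,
    atmos: Optional[AtmosphericState],
    aerosol_mode: str = "all",
    cloud_on: bool = True,
    optics: rad_mod.ComponentOptics = rad_mod.DEFAULT_OPTICS,
) -> rad_mod.RadiationFluxes:
    """Surface PAR for a forcing series under a pollution scenario.

    ``aerosol_mode``: ``none`` (aerosol-free), ``nonfire`` (background
    only) or ``all`` (background plus fire).
    """
    zen = solar.solar_zenith(forcing.latitude, forcing.day_of_year, forcing.hour)
    if atmos is None:
        aod_s = aod_a = cf = lwp = 0.0
    else:
        idx = atmos.slot_index(forcing)
        idx = np.clip(idx, 0, atmos.cloud_fraction.size - 1)
        if aerosol_mode == "none":
            aod_s = aod_a = np.zeros(len(forcing))
        elif aerosol_mode == "nonfire":
            aod_s = atmos.aod_scattering_bg[idx]
            aod_a = atmos.aod_absorbing_bg[idx]
        elif aerosol_mode == "all":
            aod_s = atmos.aod_scattering[idx]
            aod_a = atmos.aod_absorbing[idx]
        else:
            raise ValueError(f"unknown aerosol_mode {aerosol_mode!r}")
        if cloud_on:
            cf = atmos.cloud_fraction[idx]
            lwp = atmos.cloud_lwp[idx]
        else:
            cf = lwp = 0.0
    return rad_mod.surface_par(
        forcing.toa_insolation, zen, aod_s, aod_a, cf, lwp, optics=optics
    )


def run_site(
    forcing: SiteForcing,
    fluxes: rad_mod.RadiationFluxes,
    params: PFTParams,
    o3_ppbv=None,
    sensitivity: str = "mean",
    n_layers: int = canopy_mod.N_LAYERS_DEFAULT,
    soil_stress: float = 1.0,
) -> SiteResult:
    """Run the canopy model over a forcing series.

    ``o3_ppbv`` may be None (no ozone effect), a scalar (prescribed uniform
    concentration, as in the offline sensitivity protocol) or a
    per-timestep array.  ``soil_stress`` is an optional multiplier on
    assimilation (default off at 1.0).
    """
    light = canopy_mod.partition_canopy_light(
        fluxes.par_direct, fluxes.par_diffuse, fluxes.solar_zenith,
        forcing.lai, n_layers=n_layers,
    )
    t_leaf = forcing.air_temperature[:, None]
    rh = relative_humidity(
        forcing.specific_humidity, forcing.air_temperature, forcing.surface_pressure
    )[:, None]
    ca = forcing.co2[:, None]
    pressure = forcing.surface_pressure[:, None]

    sun = leaf_photosynthesis(light.par_sunlit, t_leaf, rh, ca, params)
    sha = leaf_photosynthesis(light.par_shaded, t_leaf, rh, ca, params)

    if o3_ppbv is not None:
        o3 = np.asarray(o3_ppbv, dtype=float)
        if o3.ndim == 0:
            o3 = np.full(len(forcing), float(o3))
        o3 = o3[:, None]
        wind = forcing.wind_speed[:, None]
        cs = ca - 1.37 * np.maximum(sun.a_net, 0.0) / 2.0
        a_sl, gs_sl, _ = ozone_mod.damaged_photosynthesis(
            sun, o3, wind, rh, cs, t_leaf, pressure, params, sensitivity
        )
        cs = ca - 1.37 * np.maximum(sha.a_net, 0.0) / 2.0
        a_sh, gs_sh, _ = ozone_mod.damaged_photosynthesis(
            sha, o3, wind, rh, cs, t_leaf, pressure, params, sensitivity
        )
    else:
        a_sl, gs_sl = sun.a_net, sun.g_s
        a_sh, gs_sh = sha.a_net, sha.g_s

    a_sl = soil_stress * a_sl
    a_sh = soil_stress * a_sh
    rd = sun.rd  # same kinetics for both leaf classes

    gpp = canopy_mod.canopy_gpp(a_sl, a_sh, light.f_sl, light.cumulative_lai, rd=rd)
    gs_layer = light.f_sl * gs_sl + (1.0 - light.f_sl) * gs_sh
    lai_safe = np.maximum(forcing.lai, 1e-9)
    gs_mean = np.trapezoid(gs_layer, light.cumulative_lai, axis=-1) / lai_safe

    return SiteResult(
        forcing=forcing,
        gpp=gpp,
        gs_canopy=gs_mean,
        par_direct=np.asarray(fluxes.par_direct, dtype=float),
        par_diffuse=np.asarray(fluxes.par_diffuse, dtype=float),
        solar_zenith=np.asarray(fluxes.solar_zenith, dtype=float),
    )
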