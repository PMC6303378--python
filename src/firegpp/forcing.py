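"""Seeded synthetic forcing: site meteorology and pollution scenarios.

The generators stand in for reanalysis meteorology, chemistry-transport
pollution fields and satellite cloud products.  They reproduce the
statistical structure the downstream stages care about -- a correct diurnal
solar cycle, archetype-specific temperature and humidity with lag-1
autoregressive daily anomalies, fire-season ozone enhancements of a few
ppbv, aerosol optical depths in [0, 3] and cloud fractions in [0, 1] --
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import solar

__all__ = [
    "SiteForcing",
    "AtmosphericState",
    "AODSpec",
    "CloudSpec",
    "ARCHETYPES",
    "generate_site_forcing",
    "generate_pollution_scenario",
]


@dataclass
class SiteForcing:
    """Hourly (or finer) meteorological driver for one site column."""

    latitude: float                      # degrees, [-90, 90]
    pft: str                             # plant functional type key
    day_of_year: np.ndarray              # integer [1, 366] per step
    hour: np.ndarray                     # fractional local solar hours
    air_temperature: np.ndarray          # K
    specific_humidity: np.ndarray        # kg kg-1
    surface_pressure: np.ndarray         # Pa
    wind_speed: np.ndarray               # m s-1
    toa_insolation: np.ndarray           # W m-2
    co2: np.ndarray                      # ppm
    lai: np.ndarray                      # m2 m-2, prescribed seasonal cycle
    timestep_hours: float = 1.0
    archetype: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if np.any(self.toa_insolation < 0):
            raise ValueError("toa_insolation must be non-negative")
        if np.any(self.lai < 0):
            raise ValueError("lai must be non-negative")
        if np.any(self.specific_humidity < 0):
            raise ValueError("specific_humidity must be non-negative")
        if np.any((self.surface_pressure < 50e3) | (self.surface_pressure > 110e3)):
            raise ValueError("surface_pressure outside [50 kPa, 110 kPa]")

    def __len__(self):
        return self.day_of_year.size

    @property
    def n_steps_per_day(self) -> int:
        return int(round(24.0 / self.timestep_hours))

    @property
    def day_index(self) -> np.ndarray:
        """0-based simulation-day index per timestep."""
        return np.arange(len(self)) // self.n_steps_per_day

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day_of_year": self.day_of_year,
                "hour": self.hour,
                "air_temperature": self.air_temperature,
                "specific_humidity": self.specific_humidity,
                "surface_pressure": self.surface_pressure,
                "wind_speed": self.wind_speed,
                "toa_insolation": self.toa_insolation,
                "co2": self.co2,
                "lai": self.lai,
            }
        )


@dataclass
class AtmosphericState:
    """Pollution and cloud drivers, split into background and fire parts.

    Series are at daily or 3-hourly resolution; ozone is per forcing
    timestep (hourly) because the damage scheme is instantaneous.
    """

    o3_background: np.ndarray        # ppbv, per forcing timestep
    o3_fire: np.ndarray              # ppbv, per forcing timestep
    aod_scattering_bg: np.ndarray    # per cloud-resolution slot
    aod_absorbing_bg: np.ndarray
    aod_scattering_fire: np.ndarray
    aod_absorbing_fire: np.ndarray
    cloud_fraction: np.ndarray       # [0, 1], per slot
    cloud_lwp: np.ndarray            # g m-2, per slot
    resolution: str = "daily"        # "daily" | "three_hourly"

    def __post_init__(self):
        if self.resolution not in ("daily", "three_hourly"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        for name in ("o3_background", "o3_fire", "aod_scattering_bg",
                     "aod_absorbing_bg", "aod_scattering_fire",
                     "aod_absorbing_fire", "cloud_lwp"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any((self.cloud_fraction < 0) | (self.cloud_fraction > 1)):
            raise ValueError("cloud_fraction outside [0, 1]")

    @property
    def aod_scattering(self) -> np.ndarray:
        return self.aod_scattering_bg + self.aod_scattering_fire

    @property
    def aod_absorbing(self) -> np.ndarray:
        return self.aod_absorbing_bg + self.aod_absorbing_fire

    @property
    def o3_total(self) -> np.ndarray:
        return self.o3_background + self.o3_fire

    @property
    def slots_per_day(self) -> int:
        return 1 if self.resolution == "daily" else 8

    def slot_index(self, forcing: SiteForcing) -> np.ndarray:
        """Map forcing timesteps onto cloud/aerosol resolution slots."""
        if self.resolution == "daily":
            return forcing.day_index
        slot_in_day = (forcing.hour // 3.0).astype(int)
        return forcing.day_index * 8 + slot_in_day

    def copy(self) -> "AtmosphericState":
        return replace(
            self,
            o3_background=self.o3_background.copy(),
            o3_fire=self.o3_fire.copy(),
            aod_scattering_bg=self.aod_scattering_bg.copy(),
            aod_absorbing_bg=self.aod_absorbing_bg.copy(),
            aod_scattering_fire=self.aod_scattering_fire.copy(),
            aod_absorbing_fire=self.aod_absorbing_fire.copy(),
            cloud_fraction=self.cloud_fraction.copy(),
            cloud_lwp=self.cloud_lwp.copy(),
        )


@dataclass
class AODSpec:
    """Mean aerosol optical depths, background vs. fire plume.

    Fire smoke is dominated by scattering organic carbon with a small
    absorbing black-carbon share (BC emission factors are roughly a tenth
    of OC's), hence the default split.
    """

    background_scattering: float = 0.12
    background_absorbing: float = 0.02
    fire_scattering: float = 0.12
    fire_absorbing: float = 0.02
    daily_cv: float = 0.3  # lognormal day-to-day coefficient of variation


@dataclass
class CloudSpec:
    """Cloud fraction / liquid-water-path statistics for the generator."""

    fraction_mean: float = 0.55
    fraction_sd: float = 0.25
    lwp_mean: float = 60.0   # g m-2, in cloudy portion
    resolution: str = "daily"


@dataclass
class Archetype:
    t_mean: float            # K, seasonal-mean air temperature
    t_diurnal: float         # K, half peak-to-trough diurnal amplitude
    t_anom_sd: float         # K, sd of AR(1) daily anomalies
    q_mean: float            # kg kg-1
    wind_mean: float         # m s-1
    pressure: float          # Pa
    lai_peak: float          # m2 m-2
    lai_min: float
    lai_peak_doy: int
    pft: str
    start_doy: int           # first simulated day of year
    latitude: float          # default site latitude
    cloud: CloudSpec = field(default_factory=CloudSpec)


#: Study conditions per climate archetype.  LAI peaks and cloud statistics
#: are climatological values for the matching biome; the midlatitude summer
#: column is the default site used throughout the diagnostics.
ARCHETYPES = {
    "tropical_wet": Archetype(
        t_mean=299.0, t_diurnal=4.0, t_anom_sd=0.8, q_mean=0.016,
        wind_mean=2.0, pressure=100.5e3, lai_peak=5.5, lai_min=4.8,
        lai_peak_doy=1, pft="evergreen_broadleaf_forest", start_doy=1,
        latitude=-3.0,
        cloud=CloudSpec(fraction_mean=0.80, fraction_sd=0.12, lwp_mean=180.0),
    ),
    "midlatitude_summer": Archetype(
        t_mean=293.0, t_diurnal=7.0, t_anom_sd=2.2, q_mean=0.010,
        wind_mean=3.0, pressure=98.0e3, lai_peak=5.0, lai_min=1.0,
        lai_peak_doy=200, pft="deciduous_broadleaf_forest", start_doy=152,
        latitude=45.0,
        cloud=CloudSpec(fraction_mean=0.55, fraction_sd=0.25, lwp_mean=60.0),
    ),
    "boreal_summer": Archetype(
        t_mean=287.0, t_diurnal=8.0, t_anom_sd=3.0, q_mean=0.007,
        wind_mean=3.5, pressure=99.0e3, lai_peak=4.0, lai_min=1.5,
        lai_peak_doy=195, pft="evergreen_needleleaf_forest", start_doy=152,
        latitude=60.0,
        cloud=CloudSpec(fraction_mean=0.68, fraction_sd=0.2, lwp_mean=70.0),
    ),
    "arid": Archetype(
        t_mean=301.0, t_diurnal=12.0, t_anom_sd=2.0, q_mean=0.005,
        wind_mean=4.0, pressure=95.0e3, lai_peak=1.6, lai_min=1.0,
        lai_peak_doy=120, pft="shrubland", start_doy=121,
        latitude=30.0,
        cloud=CloudSpec(fraction_mean=0.15, fraction_sd=0.1, lwp_mean=25.0),
    ),
}


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = 0.7) -> np.ndarray:
    """Stationary lag-1 autoregressive series with marginal sd ``sd``."""
    eps = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def _seasonal_lai(doy, arch: Archetype) -> np.ndarray:
    amp = 0.5 * (arch.lai_peak - arch.lai_min)
    mid = 0.5 * (arch.lai_peak + arch.lai_min)
    return mid + amp * np.cos(2.0 * np.pi * (np.asarray(doy) - arch.lai_peak_doy) / 365.0)


def generate_site_forcing(
    latitude: Optional[float] = None,
    n_days: int = 90,
    climate_archetype: str = "midlatitude_summer",
    seed: int = 0,
    timestep_hours: float = 1.0,
    co2_ppm: float = 390.0,
    lai: Optional[float] = None,
) -> SiteForcing:
    """Generate a seeded site forcing series for one climate archetype.

    Parameters
    ----------
    latitude
        Site latitude; defaults to the archetype's representative latitude.
    n_days
        Length of the series in days (>= 1).
    climate_archetype
        One of ``tropical_wet``, ``midlatitude_summer``, ``boreal_summer``,
        ``arid``.
    seed
        Seed for the generator; identical seeds give bit-identical series.
    timestep_hours
        Forcing resolution; 1.0 for hourly, 0.5 for the half-hourly
        flux-tower-style protocols.
    lai
        If given, a constant LAI overriding the archetype seasonal cycle.
    """
    if climate_archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {climate_archetype!r}; "
            f"expected one of {sorted(ARCHETYPES)}"
        )
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    arch = ARCHETYPES[climate_archetype]
    if latitude is None:
        latitude = arch.latitude

    rng = np.random.default_rng(seed)
    steps_per_day = int(round(24.0 / timestep_hours))
    n = n_days * steps_per_day

    day_idx = np.arange(n) // steps_per_day
    doy = (arch.start_doy - 1 + day_idx) % 365 + 1
    hour = (np.arange(n) % steps_per_day) * timestep_hours + 0.5 * timestep_hours

    t_anom = _ar1(rng, n_days, arch.t_anom_sd)[day_idx]
    # diurnal cycle peaking mid-afternoon (14h), trough before dawn
    diurnal = arch.t_diurnal * np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)
    t_air = arch.t_mean + t_anom + diurnal

    q_anom = _ar1(rng, n_days, 0.12 * arch.q_mean)[day_idx]
    q = np.clip(arch.q_mean + q_anom, 1e-5, None)

    wind = np.clip(
        arch.wind_mean * (1.0 + 0.25 * _ar1(rng, n_days, 1.0)[day_idx])
        + 0.3 * rng.standard_normal(n),
        0.2,
        None,
    )

    toa = solar.toa_insolation(latitude, doy, hour)

    lai_series = (
        np.full(n, float(lai)) if lai is not None else _seasonal_lai(doy, arch)
    )

    return SiteForcing(
        latitude=float(latitude),
        pft=arch.pft,
        day_of_year=doy,
        hour=hour,
        air_temperature=t_air,
        specific_humidity=q,
        surface_pressure=np.full(n, arch.pressure),
        wind_speed=wind,
        toa_insolation=np.asarray(toa, dtype=float),
        co2=np.full(n, co2_ppm),
        lai=lai_series,
        timestep_hours=timestep_hours,
        archetype=climate_archetype,
    )


def _fire_window_shape(day_idx: np.ndarray, window, ramp_days: float = 10.0) -> np.ndarray:
    """Smooth-ramped fire-season weight, normalised to mean 1 inside the window."""
    lo, hi = window
    d = day_idx.astype(float)
    up = np.clip((d - lo) / ramp_days, 0.0, 1.0)
    down = np.clip((hi - d) / ramp_days, 0.0, 1.0)
    shape = np.where((d >= lo) & (d <= hi), np.minimum(up, down), 0.0)
    inside = shape[(d >= lo) & (d <= hi)]
    if inside.size and inside.mean() > 0:
        shape = shape / inside.mean()
    return shape


def generate_pollution_scenario(
    base_o3_mean: float = 30.0,
    fire_o3_delta: float = 0.0,
    aod_spec: Optional[AODSpec] = None,
    cloud_spec: Optional[CloudSpec] = None,
    seed: int = 0,
    n_days: int = 90,
    timestep_hours: float = 1.0,
    fire_window: Optional[tuple] = None,
    fire_aod_on: bool = True,
) -> AtmosphericState:
    """Generate a seeded pollution/cloud scenario.

    ``fire_o3_delta`` is the mean fire ozone enhancement inside the fire
    window (simulation-day indices, default the middle half of the run);
    outside the window the fire component is identically zero.  Fire
    aerosols follow the same seasonal window.
    """
    if base_o3_mean < 0 or fire_o3_delta < 0:
        raise ValueError("ozone means must be non-negative")
    aod_spec = aod_spec or AODSpec()
    cloud_spec = cloud_spec or CloudSpec()
    if fire_window is None:
        fire_window = (n_days // 4, n_days - n_days // 4 - 1)

    rng = np.random.default_rng(seed)
    steps_per_day = int(round(24.0 / timestep_hours))
    n = n_days * steps_per_day
    day_idx = np.arange(n) // steps_per_day
    hour = (np.arange(n) % steps_per_day) * timestep_hours + 0.5 * timestep_hours

    # --- ozone: daily AR(1) background with an afternoon-peaking diurnal cycle
    o3_daily = np.clip(base_o3_mean * (1.0 + 0.15 * _ar1(rng, n_days, 1.0)), 0.0, None)
    diurnal = 1.0 + 0.2 * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
    o3_bg = np.clip(o3_daily[day_idx] * diurnal, 0.0, None)

    if fire_o3_delta > 0:
        shape = _fire_window_shape(np.arange(n_days), fire_window)
        noise = np.clip(1.0 + 0.08 * _ar1(rng, n_days, 1.0), 0.0, None)
        # renormalise so the in-window mean equals the requested delta
        w = (np.arange(n_days) >= fire_window[0]) & (np.arange(n_days) <= fire_window[1])
        prod = shape * noise
        if prod[w].mean() > 0:
            prod = prod / prod[w].mean()
        o3_fire = (fire_o3_delta * prod)[day_idx]
    else:
        rng.standard_normal(n_days)  # keep stream layout stable
        o3_fire = np.zeros(n)

    # --- aerosols at cloud resolution (daily or 3-hourly slots)
    slots = n_days * (1 if cloud_spec.resolution == "daily" else 8)
    slot_day = np.arange(slots) // (1 if cloud_spec.resolution == "daily" else 8)

    def lognormal_series(mean):
        if mean <= 0:
            return np.zeros(slots)
        cv = aod_spec.daily_cv
        sigma = np.sqrt(np.log(1.0 + cv**2))
        daily = mean * np.exp(sigma * _ar1(rng, n_days, 1.0) - 0.5 * sigma**2)
        return daily[slot_day]

    aod_s_bg = lognormal_series(aod_spec.background_scattering)
    aod_a_bg = lognormal_series(aod_spec.background_absorbing)
    fire_shape = _fire_window_shape(np.arange(n_days), fire_window)[slot_day]
    if fire_aod_on:
        aod_s_fire = lognormal_series(aod_spec.fire_scattering) * fire_shape
        aod_a_fire = lognormal_series(aod_spec.fire_absorbing) * fire_shape
    else:
        aod_s_fire = np.zeros(slots)
        aod_a_fire = np.zeros(slots)

    # --- cloud: truncated-Gaussian AR(1) daily fraction, LWP tied to fraction
    cf_daily = np.clip(
        cloud_spec.fraction_mean + _ar1(rng, n_days, cloud_spec.fraction_sd),
        0.0, 1.0,
    )
    lwp_noise = np.exp(0.4 * _ar1(rng, n_days, 1.0) - 0.08)
    lwp_daily = cloud_spec.lwp_mean * lwp_noise * (0.5 + cf_daily)
    cf = cf_daily[slot_day]
    lwp = lwp_daily[slot_day]
    if cloud_spec.resolution == "three_hourly":
        jitter = np.clip(1.0 + 0.25 * rng.standard_normal(slots), 0.0, None)
        cf = np.clip(cf * jitter, 0.0, 1.0)
        lwp = lwp * np.clip(1.0 + 0.25 * rng.standard_normal(slots), 0.0, None)

    return AtmosphericState(
        o3_background=o3_bg,
        o3_fire=o3_fire,
        aod_scattering_bg=aod_s_bg,
        aod_absorbing_bg=aod_a_bg,
        aod_scattering_fire=aod_s_fire,
        aod_absorbing_fire=aod_a_fire,
        cloud_fraction=cf,
        cloud_lwp=lwp,
        resolution=cloud_spec.resolution,
    )
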