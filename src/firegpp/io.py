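"""Series I/O (NetCDF / CSV), strict TOML configuration, run manifests.

Forcing and pollution series round-trip through CF-style NetCDF (scipy
backend) or flat CSV (one row per timestep/slot, full float precision).
Time is hours since the run start with a calendar-free convention.  Config
files are TOML with strict key checking: misspelled keys are rejected, not
ignored.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .forcing import AODSpec, AtmosphericState, CloudSpec, SiteForcing

__all__ = [
    "SCHEMA_VERSION",
    "write_forcing", "read_forcing",
    "write_atmos", "read_atmos",
    "load_config", "config_hash", "write_manifest",
]

SCHEMA_VERSION = "1"

FORCING_VARS = (
    "day_of_year", "hour", "air_temperature", "specific_humidity",
    "surface_pressure", "wind_speed", "toa_insolation", "co2", "lai",
)
ATMOS_VARS = (
    "o3_background", "o3_fire", "aod_scattering_bg", "aod_absorbing_bg",
    "aod_scattering_fire", "aod_absorbing_fire", "cloud_fraction", "cloud_lwp",
)


def _forcing_dataset(forcing: SiteForcing) -> xr.Dataset:
    time = np.arange(len(forcing)) * forcing.timestep_hours
    ds = xr.Dataset(
        {name: ("time", np.asarray(getattr(forcing, name), dtype=float))
         for name in FORCING_VARS},
        coords={"time": ("time", time, {"long_name": "hours since run start"})},
        attrs={
            "schema_version": SCHEMA_VERSION,
            "latitude": forcing.latitude,
            "pft": forcing.pft,
            "archetype": forcing.archetype,
            "timestep_hours": forcing.timestep_hours,
        },
    )
    return ds


def write_forcing(path, forcing: SiteForcing, fmt: str = "netcdf") -> Path:
    """Write a forcing series as NetCDF or CSV; returns the path written."""
    path = Path(path)
    ds = _forcing_dataset(forcing)
    if fmt == "netcdf":
        ds.to_netcdf(path, engine="scipy")
    elif fmt == "csv":
        df = ds.to_dataframe().reset_index()
        header = (
            f"# schema_version={SCHEMA_VERSION} latitude={forcing.latitude!r} "
            f"pft={forcing.pft} archetype={forcing.archetype} "
            f"timestep_hours={forcing.timestep_hours!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _check_missing(present, required, what):
    missing = [v for v in required if v not in present]
    if missing:
        raise ValueError(f"{what} missing variables: {missing}")


def read_forcing(path, fmt: str = "netcdf") -> SiteForcing:
    """Read a forcing series; errors name any missing variable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        if str(ds.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise ValueError("missing or unsupported schema_version tag")
        _check_missing(ds.data_vars, FORCING_VARS, "forcing file")
        kw = {name: ds[name].values for name in FORCING_VARS}
        attrs = ds.attrs
    elif fmt == "csv":
        with open(path) as fh:
            header = fh.readline()
            if "schema_version" not in header:
                raise ValueError("missing schema_version tag in CSV header")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("#").split()
            )
            if meta["schema_version"] != SCHEMA_VERSION:
                raise ValueError("unsupported schema_version")
            df = pd.read_csv(fh)
        _check_missing(df.columns, FORCING_VARS, "forcing file")
        kw = {name: df[name].to_numpy() for name in FORCING_VARS}
        attrs = {
            "latitude": float(meta["latitude"]),
            "pft": meta["pft"],
            "archetype": meta.get("archetype", ""),
            "timestep_hours": float(meta["timestep_hours"]),
        }
    else:
        raise ValueError(f"unknown format {fmt!r}")
    kw["day_of_year"] = kw["day_of_year"].astype(int)
    return SiteForcing(
        latitude=float(attrs["latitude"]),
        pft=str(attrs["pft"]),
        archetype=str(attrs.get("archetype", "")),
        timestep_hours=float(attrs["timestep_hours"]),
        **kw,
    )


def write_atmos(path, atmos: AtmosphericState, fmt: str = "netcdf") -> Path:
    path = Path(path)
    data = {name: ("slot", np.asarray(getattr(atmos, name), dtype=float))
            for name in ATMOS_VARS}
    # ozone is stored on its own (forcing-timestep) axis
    n_o3 = atmos.o3_background.size
    data["o3_background"] = ("time", atmos.o3_background.astype(float))
    data["o3_fire"] = ("time", atmos.o3_fire.astype(float))
    ds = xr.Dataset(
        data,
        attrs={"schema_version": SCHEMA_VERSION, "resolution": atmos.resolution},
    )
    if fmt == "netcdf":
        ds.to_netcdf(path, engine="scipy")
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# schema_version={SCHEMA_VERSION} resolution={atmos.resolution} "
                     f"n_o3={n_o3}\n")
            slot_df = pd.DataFrame(
                {name: getattr(atmos, name) for name in ATMOS_VARS
                 if name not in ("o3_background", "o3_fire")}
            )
            o3_df = pd.DataFrame(
                {"o3_background": atmos.o3_background, "o3_fire": atmos.o3_fire}
            )
            df = pd.concat([o3_df, slot_df], axis=1)
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_atmos(path, fmt: str = "netcdf") -> AtmosphericState:
    path = Path(path)
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        if str(ds.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise ValueError("missing or unsupported schema_version tag")
        _check_missing(ds.data_vars, ATMOS_VARS, "atmospheric state file")
        return AtmosphericState(
            resolution=str(ds.attrs["resolution"]),
            **{name: ds[name].values for name in ATMOS_VARS},
        )
    if fmt == "csv":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(item.split("=", 1) for item in header.lstrip("#").split())
            df = pd.read_csv(fh)
        _check_missing(df.columns, ATMOS_VARS, "atmospheric state file")
        slot_cols = [c for c in ATMOS_VARS if c not in ("o3_background", "o3_fire")]
        slot_df = df[slot_cols].dropna()
        return AtmosphericState(
            o3_background=df["o3_background"].dropna().to_numpy(),
            o3_fire=df["o3_fire"].dropna().to_numpy(),
            resolution=meta["resolution"],
            **{c: slot_df[c].to_numpy() for c in slot_cols},
        )
    raise ValueError(f"unknown format {fmt!r}")


# --- configuration -------------------------------------------------------

_KNOWN_KEYS = {
    "forcing": {"archetype", "n_days", "latitude", "timestep_hours", "seed",
                "co2_ppm", "lai"},
    "scenario": {"base_o3_mean", "fire_o3_delta", "cloud_fraction_mean",
                 "cloud_fraction_sd", "cloud_lwp_mean", "cloud_resolution",
                 "aod_background_scattering", "aod_background_absorbing",
                 "aod_fire_scattering", "aod_fire_absorbing", "seed"},
    "radiation": {"par_fraction", "tau_rayleigh", "ssa_scattering",
                  "g_scattering", "ssa_absorbing", "g_absorbing",
                  "ssa_cloud", "g_cloud", "scaling"},
    "experiments": {"arms", "pft", "pft_table"},
    "run": {"seed", "output_dir", "log_level"},
}


def load_config(path) -> dict:
    """Load a TOML run configuration with strict key checking."""
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for section, content in cfg.items():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"unknown config section [{section}]")
        unknown = set(content) - _KNOWN_KEYS[section]
        if unknown:
            raise ValueError(
                f"unknown keys in [{section}]: {sorted(unknown)}"
            )
    return cfg


def scenario_from_config(cfg: dict):
    """Build (AODSpec, CloudSpec, scalars) from the [scenario] section."""
    sc = cfg.get("scenario", {})
    aod = AODSpec(
        background_scattering=sc.get("aod_background_scattering", 0.12),
        background_absorbing=sc.get("aod_background_absorbing", 0.02),
        fire_scattering=sc.get("aod_fire_scattering", 0.25),
        fire_absorbing=sc.get("aod_fire_absorbing", 0.04),
    )
    cloud = CloudSpec(
        fraction_mean=sc.get("cloud_fraction_mean", 0.55),
        fraction_sd=sc.get("cloud_fraction_sd", 0.25),
        lwp_mean=sc.get("cloud_lwp_mean", 60.0),
        resolution=sc.get("cloud_resolution", "daily"),
    )
    return aod, cloud, sc.get("base_o3_mean", 30.0), sc.get("fire_o3_delta", 5.0)


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, *, seed, inputs, config=None, extra=None) -> Path:
    """Write a reproducibility manifest next to the run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "inputs": [str(i) for i in inputs],
        "config_hash": config_hash(config) if config else None,
        "schema_version": SCHEMA_VERSION,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
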