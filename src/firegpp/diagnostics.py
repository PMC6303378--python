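"""Measurement protocols: GPP-O3 slopes, diffuse-PAR slopes, diffuse optimum.

Three offline protocols quantify how the modelled canopy responds to its
pollution drivers:

* ``o3_sensitivity_slope`` -- prescribe uniform ozone levels, compare each
  run with the ozone-free baseline, and regress the percent GPP change on
  concentration (percent per ppbv).
* ``diffuse_slope`` -- the flux-tower binning protocol: keep only
  high-diffuse records (diffuse fraction > 0.8), average GPP in fixed
  diffuse-PAR bins, regress the bin means, and normalise by the mean GPP
  of the filtered records (percent per W m-2).
* ``diffuse_optimum`` -- sweep scattering aerosol under clear sky and
  report the midday diffuse fraction of the sweep member with maximal
  daily GPP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import model as model_mod
from .forcing import SiteForcing
from .pft import PFTParams

__all__ = [
    "SensitivitySlope",
    "ProtocolError",
    "ols_slope",
    "o3_sensitivity_slope",
    "diffuse_slope",
    "diffuse_optimum",
    "percent_delta_gpp",
]

PAR_BIN_WIDTH = 50.0  # W m-2


class ProtocolError(RuntimeError):
    """A measurement protocol could not be applied to the data."""


@dataclass
class SensitivitySlope:
    pft: str
    slope: float            # % GPP per ppbv, or % per W m-2
    ci95: tuple             # (low, high)
    n_points: int
    protocol: str           # "o3" | "diffuse"

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("slope requires at least 3 points")
        if not (self.ci95[0] <= self.slope <= self.ci95[1]):
            raise ValueError("ci95 must contain the slope")


def ols_slope(x, y):
    """OLS slope with a 95% confidence interval from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ProtocolError(f"need >= 3 points for a slope, got {x.size}")
    if np.ptp(y) == 0.0:
        return 0.0, (0.0, 0.0)
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    half = tcrit * res.stderr
    return float(res.slope), (float(res.slope - half), float(res.slope + half))


def percent_delta_gpp(perturbed: float, baseline: float) -> float:
    """Percent GPP change of a perturbed run against its baseline."""
    if baseline <= 0:
        raise ProtocolError("baseline GPP must be positive for a percent change")
    return 100.0 * (perturbed - baseline) / baseline


def o3_sensitivity_slope(
    forcing: SiteForcing,
    fluxes,
    params: PFTParams,
    o3_levels: Sequence[float],
    sensitivity: str = "mean",
) -> SensitivitySlope:
    """Percent-GPP-per-ppbv response from prescribed uniform ozone levels.

    Each level is run against the shared ozone-free baseline; the percent
    changes are regressed on concentration by OLS.  The slope is negative
    for any damaging coefficient.
    """
    levels = np.asarray(sorted(o3_levels), dtype=float)
    if levels.size < 3 or np.ptp(levels) < 40.0:
        raise ProtocolError("need >= 3 ozone levels spanning >= 40 ppbv")
    base = model_mod.run_site(forcing, fluxes, params)
    if base.gpp_total <= 0:
        raise ProtocolError("ozone-free baseline GPP is zero")
    pct = np.array(
        [
            percent_delta_gpp(
                model_mod.run_site(
                    forcing, fluxes, params, o3_ppbv=lev, sensitivity=sensitivity
                ).gpp_total,
                base.gpp_total,
            )
            for lev in levels
        ]
    )
    slope, ci = ols_slope(levels, pct)
    return SensitivitySlope(
        pft=params.pft_name, slope=slope, ci95=ci,
        n_points=levels.size, protocol="o3",
    )


def diffuse_slope(
    gpp,
    par_diffuse,
    diffuse_fraction,
    pft: str = "",
    bin_width: float = PAR_BIN_WIDTH,
    diffuse_threshold: float = 0.8,
    min_records: int = 100,
    min_bins: int = 3,
) -> SensitivitySlope:
    """High-diffuse binning protocol on (half-)hourly records.

    Records with diffuse fraction > ``diffuse_threshold`` are kept, GPP is
    averaged in fixed diffuse-PAR bins of ``bin_width`` W m-2, and the
    bin-mean GPP is regressed on the bin-mean PAR.  The slope is expressed
    as percent of the filtered-record mean GPP per W m-2.
    """
    gpp = np.asarray(gpp, dtype=float)
    par = np.asarray(par_diffuse, dtype=float)
    df = np.asarray(diffuse_fraction, dtype=float)
    keep = (df > diffuse_threshold) & (par > 0)
    n_kept = int(keep.sum())
    if n_kept < min_records:
        raise ProtocolError(
            f"only {n_kept} records pass the diffuse-fraction filter "
            f"(need >= {min_records})"
        )
    gpp_k, par_k = gpp[keep], par[keep]
    edges = np.arange(0.0, par_k.max() + bin_width, bin_width)
    which = np.digitize(par_k, edges)
    xs, ys = [], []
    for b in np.unique(which):
        sel = which == b
        if sel.sum() >= 3:
            xs.append(par_k[sel].mean())
            ys.append(gpp_k[sel].mean())
    if len(xs) < min_bins:
        raise ProtocolError(f"only {len(xs)} populated PAR bins (need >= {min_bins})")
    slope_abs, ci_abs = ols_slope(np.array(xs), np.array(ys))
    mean_gpp = gpp_k.mean()
    if mean_gpp <= 0:
        raise ProtocolError("mean GPP of filtered records is zero")
    scale = 100.0 / mean_gpp
    return SensitivitySlope(
        pft=pft, slope=slope_abs * scale,
        ci95=(ci_abs[0] * scale, ci_abs[1] * scale),
        n_points=len(xs), protocol="diffuse",
    )


@dataclass
class DiffuseOptimum:
    diffuse_fraction: float     # midday diffuse fraction of the best member
    aod: float                  # scattering AOD of the best member
    gpp: np.ndarray             # daily GPP per sweep member
    diffuse_fractions: np.ndarray
    degenerate: bool            # optimum on the sweep boundary


def diffuse_optimum(
    forcing: SiteForcing,
    params: PFTParams,
    aod_grid: Sequence[float],
) -> DiffuseOptimum:
    """GPP-maximising diffuse fraction over a clear-sky scattering-AOD sweep."""
    aods = np.asarray(aod_grid, dtype=float)
    if aods.size < 1:
        raise ProtocolError("empty AOD sweep")
    from . import radiation as rad_mod
    from . import solar

    zen = solar.solar_zenith(forcing.latitude, forcing.day_of_year, forcing.hour)
    gpps = np.empty(aods.size)
    dfs = np.empty(aods.size)
    midday = np.abs(forcing.hour - 12.0) <= 1.0
    for i, aod in enumerate(aods):
        flx = rad_mod.surface_par(forcing.toa_insolation, zen, aod, 0.0)
        res = model_mod.run_site(forcing, flx, params)
        gpps[i] = res.daily_gpp().mean()
        dfs[i] = float(res.diffuse_fraction[midday].mean())
    best = int(np.argmax(gpps))
    degenerate = best in (0, aods.size - 1)
    return DiffuseOptimum(
        diffuse_fraction=float(dfs[best]), aod=float(aods[best]),
        gpp=gpps, diffuse_fractions=dfs, degenerate=degenerate,
    )
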