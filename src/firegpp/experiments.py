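"""Factorial attribution experiments, cloud-scaling sweep, perturbation suite.

The factorial matrix isolates ozone damage and aerosol diffuse
fertilization from fire and non-fire sources with eleven arms sharing one
forcing realisation:

======  ============  =====================  ==================
arm     aerosols      ozone                  damage sensitivity
======  ============  =====================  ==================
NA      none          none                   --
AA      non-fire      none                   --
FA      all           none                   --
NOH/L   none          non-fire               high / low
FOH/L   none          all (incl. fire)       high / low
AAOH/L  non-fire      non-fire               high / low
FAOH/L  all           all                    high / low
======  ============  =====================  ==================

Fire-attributable changes are differences of matching fire and non-fire
arms (FA-type minus AA-type), with low/high damage arms combined as
central value +/- half range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from . import model as model_mod
from . import radiation as rad_mod
from .forcing import (
    AODSpec,
    AtmosphericState,
    CloudSpec,
    SiteForcing,
    generate_pollution_scenario,
)
from .pft import PFTParams

__all__ = [
    "ScenarioConfig",
    "ExperimentSpec",
    "ExperimentResult",
    "ARM_DEFS",
    "run_arm",
    "run_factorial",
    "fire_attribution",
    "cloud_scaling_sweep",
    "perturbation_suite",
    "combine_uncertainty",
]


@dataclass
class ScenarioConfig:
    """Inputs to the pollution generator shared by an experiment family."""

    base_o3_mean: float = 30.0
    fire_o3_delta: float = 5.0
    aod_spec: AODSpec = field(default_factory=AODSpec)
    cloud_spec: CloudSpec = field(default_factory=CloudSpec)
    n_days: int = 90
    seed: int = 0
    fire_window: Optional[tuple] = None

    def build(self, timestep_hours: float = 1.0, resolution: Optional[str] = None,
              fire_aod_on: bool = True) -> AtmosphericState:
        cloud = self.cloud_spec
        if resolution is not None:
            cloud = replace(cloud, resolution=resolution)
        return generate_pollution_scenario(
            base_o3_mean=self.base_o3_mean,
            fire_o3_delta=self.fire_o3_delta,
            aod_spec=self.aod_spec,
            cloud_spec=cloud,
            seed=self.seed,
            n_days=self.n_days,
            timestep_hours=timestep_hours,
            fire_window=self.fire_window,
            fire_aod_on=fire_aod_on,
        )


@dataclass
class ExperimentSpec:
    """One factorial arm."""

    name: str
    aerosol_mode: str = "none"       # none | nonfire | all
    o3_mode: str = "none"            # none | nonfire | all
    o3_sensitivity: Optional[str] = None  # low | high (None when o3_mode=none)
    cloud_mode: str = "daily"        # daily | three_hourly | none | scaled
    cloud_factor: float = 1.0

    def __post_init__(self):
        if self.aerosol_mode not in ("none", "nonfire", "all"):
            raise ValueError(f"unknown aerosol_mode {self.aerosol_mode!r}")
        if self.o3_mode not in ("none", "nonfire", "all"):
            raise ValueError(f"unknown o3_mode {self.o3_mode!r}")
        if self.o3_mode != "none" and self.o3_sensitivity not in ("low", "high", "mean"):
            raise ValueError("o3 arms need o3_sensitivity low|high|mean")
        if self.cloud_mode not in ("daily", "three_hourly", "none", "scaled"):
            raise ValueError(f"unknown cloud_mode {self.cloud_mode!r}")
        if self.cloud_factor < 0:
            raise ValueError("cloud_factor must be non-negative")


#: The eleven standard arms.
ARM_DEFS: Dict[str, ExperimentSpec] = {
    "NA": ExperimentSpec("NA"),
    "AA": ExperimentSpec("AA", aerosol_mode="nonfire"),
    "FA": ExperimentSpec("FA", aerosol_mode="all"),
    "NOH": ExperimentSpec("NOH", o3_mode="nonfire", o3_sensitivity="high"),
    "NOL": ExperimentSpec("NOL", o3_mode="nonfire", o3_sensitivity="low"),
    "FOH": ExperimentSpec("FOH", o3_mode="all", o3_sensitivity="high"),
    "FOL": ExperimentSpec("FOL", o3_mode="all", o3_sensitivity="low"),
    "AAOH": ExperimentSpec("AAOH", aerosol_mode="nonfire", o3_mode="nonfire",
                           o3_sensitivity="high"),
    "AAOL": ExperimentSpec("AAOL", aerosol_mode="nonfire", o3_mode="nonfire",
                           o3_sensitivity="low"),
    "FAOH": ExperimentSpec("FAOH", aerosol_mode="all", o3_mode="all",
                           o3_sensitivity="high"),
    "FAOL": ExperimentSpec("FAOL", aerosol_mode="all", o3_mode="all",
                           o3_sensitivity="low"),
}


@dataclass
class ExperimentResult:
    """GPP outcome of one arm, with percent change vs. a named reference."""

    name: str
    gpp_series: np.ndarray           # daily, g C m-2 day-1
    gpp_total: float                 # g C m-2
    reference: str = ""
    delta_vs_reference: float = float("nan")   # percent
    uncertainty_range: Optional[tuple] = None  # ordered (low, high) percent


def run_arm(
    spec: ExperimentSpec,
    forcing: SiteForcing,
    atmos: AtmosphericState,
    params: PFTParams,
) -> ExperimentResult:
    """Run one factorial arm; deterministic for a fixed forcing/scenario."""
    cloud_on = spec.cloud_mode != "none"
    atm = atmos
    if spec.cloud_mode == "scaled":
        atm = rad_mod.apply_cloud_scaling(atmos, spec.cloud_factor)
    fluxes = model_mod.radiation_from_atmos(
        forcing, atm, aerosol_mode=spec.aerosol_mode, cloud_on=cloud_on
    )
    if spec.o3_mode == "none":
        o3 = None
    elif spec.o3_mode == "nonfire":
        o3 = atm.o3_background
    else:
        o3 = atm.o3_total
    res = model_mod.run_site(
        forcing, fluxes, params, o3_ppbv=o3,
        sensitivity=spec.o3_sensitivity or "mean",
    )
    return ExperimentResult(
        name=spec.name, gpp_series=res.daily_gpp(), gpp_total=res.gpp_total
    )


def run_factorial(
    forcing: SiteForcing,
    atmos: AtmosphericState,
    params: PFTParams,
    arms: Optional[Sequence[str]] = None,
) -> Dict[str, ExperimentResult]:
    """Run the requested arms (default: all eleven) against the NA reference."""
    names = list(arms) if arms is not None else list(ARM_DEFS)
    unknown = [n for n in names if n not in ARM_DEFS]
    if unknown:
        raise ValueError(f"unknown arm names {unknown}; known: {sorted(ARM_DEFS)}")
    if "NA" not in names:
        names = ["NA"] + names
    results = {n: run_arm(ARM_DEFS[n], forcing, atmos, params) for n in names}
    ref = results["NA"].gpp_total
    for r in results.values():
        r.reference = "NA"
        r.delta_vs_reference = 100.0 * (r.gpp_total - ref) / ref if ref > 0 else float("nan")
    return results


def combine_uncertainty(low_result, high_result):
    """Central value and half range of low/high sensitivity results.

    Accepts two floats or two :class:`ExperimentResult` with matching
    reference arms.  Returns ``(central, half_range)``; symmetric in its
    arguments.
    """
    if isinstance(low_result, ExperimentResult):
        if not isinstance(high_result, ExperimentResult):
            raise ValueError("cannot mix result objects and scalars")
        if low_result.reference != high_result.reference:
            raise ValueError(
                f"mismatched reference arms: {low_result.reference!r} "
                f"vs {high_result.reference!r}"
            )
        lo, hi = low_result.gpp_total, high_result.gpp_total
    else:
        lo, hi = float(low_result), float(high_result)
    return 0.5 * (lo + hi), 0.5 * abs(hi - lo)


def fire_attribution(results: Dict[str, ExperimentResult]) -> Dict[str, tuple]:
    """Fire-attributable GPP changes [g C m-2] as (central, half_range).

    ``o3``: fire ozone with aerosol effects off (FO* - NO*);
    ``aerosol``: fire aerosols with ozone off (FA - AA, half range 0);
    ``combined``: fire pollution with both effects on (FAO* - AAO*).
    """
    out = {}
    if all(k in results for k in ("FOH", "FOL", "NOH", "NOL")):
        out["o3"] = combine_uncertainty(
            results["FOL"].gpp_total - results["NOL"].gpp_total,
            results["FOH"].gpp_total - results["NOH"].gpp_total,
        )
    if all(k in results for k in ("FA", "AA")):
        d = results["FA"].gpp_total - results["AA"].gpp_total
        out["aerosol"] = (d, 0.0)
    if all(k in results for k in ("FAOH", "FAOL", "AAOH", "AAOL")):
        out["combined"] = combine_uncertainty(
            results["FAOL"].gpp_total - results["AAOL"].gpp_total,
            results["FAOH"].gpp_total - results["AAOH"].gpp_total,
        )
    return out


@dataclass
class CloudSweepResult:
    factors: np.ndarray
    gpp: np.ndarray              # mean daily GPP per factor, g C m-2 day-1
    threshold: float             # factor maximising GPP (ties -> smaller)
    degenerate: bool             # flat response across the sweep


def cloud_scaling_sweep(
    forcing: SiteForcing,
    atmos: AtmosphericState,
    params: PFTParams,
    factors: Optional[Sequence[float]] = None,
) -> CloudSweepResult:
    """GPP across cloud scaling factors (aerosol radiative effects off).

    The returned ``threshold`` is the factor with maximal GPP -- the cloud
    scaling threshold of the site; ties break toward the smaller factor.
    """
    facs = np.linspace(0.0, 10.0, 20) if factors is None else np.asarray(factors, float)
    if facs.size < 2:
        raise ValueError("need at least 2 scaling factors")
    if np.any(facs < 0):
        raise ValueError("scaling factors must be non-negative")
    gpps = np.empty(facs.size)
    for i, fac in enumerate(facs):
        atm = rad_mod.apply_cloud_scaling(atmos, float(fac))
        fluxes = model_mod.radiation_from_atmos(forcing, atm, aerosol_mode="none")
        gpps[i] = model_mod.run_site(forcing, fluxes, params).daily_gpp().mean()
    degenerate = bool(np.ptp(gpps) < 1e-9 * max(abs(gpps).max(), 1.0))
    best = int(np.argmax(gpps))  # argmax returns the first (smallest) on ties
    return CloudSweepResult(
        factors=facs, gpp=gpps, threshold=float(facs[best]), degenerate=degenerate
    )


#: Perturbations of the fire-aerosol/cloud drivers.
PERTURBATIONS = ("BC05", "BC20", "FA2", "FA3", "C00", "C05", "C20", "C3H")


def _perturb_atmos(name: str, scen: ScenarioConfig, timestep_hours: float) -> AtmosphericState:
    if name == "C3H":
        return scen.build(timestep_hours, resolution="three_hourly")
    atm = scen.build(timestep_hours)
    if name == "BC05":
        return replace(
            atm.copy(),
            aod_absorbing_fire=0.5 * atm.aod_absorbing_fire,
            aod_scattering_fire=1.05 * atm.aod_scattering_fire,
        )
    if name == "BC20":
        return replace(
            atm.copy(),
            aod_absorbing_fire=2.0 * atm.aod_absorbing_fire,
            aod_scattering_fire=0.9 * atm.aod_scattering_fire,
        )
    if name in ("FA2", "FA3"):
        k = 2.0 if name == "FA2" else 3.0
        return replace(
            atm.copy(),
            aod_scattering_fire=k * atm.aod_scattering_fire,
            aod_absorbing_fire=k * atm.aod_absorbing_fire,
        )
    if name == "C00":
        return rad_mod.apply_cloud_scaling(atm, 0.0)
    if name == "C05":
        return rad_mod.apply_cloud_scaling(atm, 0.5)
    if name == "C20":
        return rad_mod.apply_cloud_scaling(atm, 2.0)
    raise ValueError(f"unknown perturbation {name!r}; known: {PERTURBATIONS}")


def perturbation_suite(
    forcing: SiteForcing,
    scen: ScenarioConfig,
    params: PFTParams,
    names: Sequence[str] = PERTURBATIONS,
) -> Dict[str, dict]:
    """Fire-aerosol GPP effect under perturbed aerosol/cloud drivers.

    For each perturbation the fire-aerosol effect is the all-aerosol (FA)
    minus non-fire-aerosol (AA) difference, ozone off, both arms under the
    perturbed scenario.  Returns per perturbation the absolute difference
    [g C m-2], the percent change and the two arm totals.
    """
    out = {}
    for name in names:
        atm = _perturb_atmos(name, scen, forcing.timestep_hours)
        fa = run_arm(ARM_DEFS["FA"], forcing, atm, params)
        aa = run_arm(ARM_DEFS["AA"], forcing, atm, params)
        out[name] = {
            "delta_gpp": fa.gpp_total - aa.gpp_total,
            "delta_pct": 100.0 * (fa.gpp_total - aa.gpp_total) / aa.gpp_total,
            "fa_total": fa.gpp_total,
            "aa_total": aa.gpp_total,
        }
    return out
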