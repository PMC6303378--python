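"""Single-band surface PAR from aerosol, Rayleigh and cloud optics.

The column is one homogeneous layer over a black surface, solved with a
delta-Eddington two-stream scheme for the diffuse field and Beer's law
(on the delta-scaled optical depth) for the direct beam.  Cloudy and clear
sub-columns are combined linearly in cloud fraction (independent-column
approximation).  Everything is broadband PAR: the 0.4-0.7 um window carries
a fixed fraction of the extraterrestrial shortwave flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcing import AtmosphericState

__all__ = [
    "RadiationFluxes",
    "OpticalColumn",
    "ComponentOptics",
    "PAR_FRACTION",
    "TAU_RAYLEIGH_PAR",
    "mix_optics",
    "cloud_optical_depth",
    "delta_two_stream",
    "surface_par",
    "apply_cloud_scaling",
]

#: PAR share of broadband extraterrestrial shortwave flux.
PAR_FRACTION = 0.45
#: Vertical Rayleigh optical depth of the PAR band.
TAU_RAYLEIGH_PAR = 0.10


@dataclass
class ComponentOptics:
    """Single-scattering albedo and asymmetry per optical component.

    Representative broadband-PAR values: scattering (OC/sulfate-like)
    aerosol, absorbing (BC-like) aerosol, liquid cloud, and Rayleigh gas.
    """

    ssa_scattering: float = 0.95
    g_scattering: float = 0.65
    ssa_absorbing: float = 0.30
    g_absorbing: float = 0.60
    ssa_cloud: float = 0.9995
    g_cloud: float = 0.85
    ssa_rayleigh: float = 1.0
    g_rayleigh: float = 0.0


DEFAULT_OPTICS = ComponentOptics()


@dataclass
class OpticalColumn:
    """Mixed optical properties of one (sub-)column."""

    tau_total: np.ndarray
    single_scattering_albedo: np.ndarray
    asymmetry: np.ndarray
    tau_cloud: np.ndarray
    tau_rayleigh: np.ndarray


@dataclass
class RadiationFluxes:
    """Surface direct/diffuse PAR and solar geometry."""

    par_direct: np.ndarray     # W m-2 on horizontal
    par_diffuse: np.ndarray    # W m-2
    solar_zenith: np.ndarray   # degrees

    @property
    def par_total(self) -> np.ndarray:
        return self.par_direct + self.par_diffuse

    @property
    def diffuse_fraction(self) -> np.ndarray:
        """Diffuse share of total PAR; defined as 1 where total is zero."""
        total = self.par_total
        return np.where(total > 0, self.par_diffuse / np.where(total > 0, total, 1.0), 1.0)


def mix_optics(
    aod_scattering,
    aod_absorbing,
    tau_cloud=0.0,
    tau_rayleigh=TAU_RAYLEIGH_PAR,
    optics: ComponentOptics = DEFAULT_OPTICS,
) -> OpticalColumn:
    """Combine components into column optics by optical-depth weighting.

    The mixed single-scattering albedo is the tau-weighted mean of
    component albedos; the mixed asymmetry is weighted by scattering
    optical depth (tau * ssa), the standard mixing rule.  A vacuum column
    gets albedo 1 and asymmetry 0 by convention.
    """
    comps = [
        (np.asarray(aod_scattering, dtype=float), optics.ssa_scattering, optics.g_scattering),
        (np.asarray(aod_absorbing, dtype=float), optics.ssa_absorbing, optics.g_absorbing),
        (np.asarray(tau_cloud, dtype=float), optics.ssa_cloud, optics.g_cloud),
        (np.asarray(tau_rayleigh, dtype=float), optics.ssa_rayleigh, optics.g_rayleigh),
    ]
    for tau, _, _ in comps:
        if np.any(tau < 0):
            raise ValueError("optical depths must be non-negative")
    tau_total = sum(tau for tau, _, _ in comps)
    scat = sum(tau * ssa for tau, ssa, _ in comps)
    gscat = sum(tau * ssa * g for tau, ssa, g in comps)
    ssa_mix = np.where(tau_total > 0, scat / np.where(tau_total > 0, tau_total, 1.0), 1.0)
    g_mix = np.where(scat > 0, gscat / np.where(scat > 0, scat, 1.0), 0.0)
    return OpticalColumn(
        tau_total=tau_total,
        single_scattering_albedo=ssa_mix,
        asymmetry=g_mix,
        tau_cloud=comps[2][0] * np.ones_like(tau_total),
        tau_rayleigh=comps[3][0] * np.ones_like(tau_total),
    )


def cloud_optical_depth(cloud_lwp, effective_radius_um: float = 10.0):
    """Liquid-cloud optical depth: tau = 3 LWP / (2 rho_w r_e).

    ``cloud_lwp`` in g m-2, ``effective_radius_um`` in micrometres.
    """
    if effective_radius_um <= 0:
        raise ValueError("effective radius must be positive")
    lwp = np.asarray(cloud_lwp, dtype=float)
    if np.any(lwp < 0):
        raise ValueError("LWP must be non-negative")
    return 1.5 * lwp / effective_radius_um


def delta_two_stream(tau, ssa, g, mu0):
    """Delta-Eddington two-stream transmission of one layer, black surface.

    Returns ``(t_direct, t_diffuse)``: the direct-beam and diffuse downward
    fluxes at the surface per unit incident direct flux on the horizontal.
    The forward-peak fraction f = g^2 is folded into the unscattered beam
    (delta scaling), so ``t_direct`` uses the scaled optical depth.
    """
    tau = np.asarray(tau, dtype=float)
    ssa = np.clip(np.asarray(ssa, dtype=float), 0.0, 0.999999)
    g = np.asarray(g, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)

    # delta scaling
    f = g * g
    tau_p = (1.0 - ssa * f) * tau
    ssa_p = np.clip((1.0 - f) * ssa / (1.0 - ssa * f), 0.0, 0.999999)
    g_p = g / (1.0 + g)

    # Eddington closure coefficients
    g1 = 0.25 * (7.0 - ssa_p * (4.0 + 3.0 * g_p))
    g2 = -0.25 * (1.0 - ssa_p * (4.0 - 3.0 * g_p))
    g3 = 0.25 * (2.0 - 3.0 * g_p * mu0)
    g4 = 1.0 - g3

    lam = np.sqrt(np.maximum(g1 * g1 - g2 * g2, 1e-12))
    # avoid the removable singularity at lam*mu0 = 1
    mu0 = np.where(np.abs(1.0 - lam * mu0) < 1e-6, mu0 * (1.0 + 1e-5), mu0)

    # Coupled ODEs in (F_up, F_down):
    #   dF_up/dtau   = g1 F_up - g2 F_dn - ssa g3 / mu0 * exp(-tau/mu0)
    #   dF_dn/dtau   = g2 F_up - g1 F_dn + ssa g4 / mu0 * exp(-tau/mu0)
    # with unit incident direct flux on the horizontal and a black surface.
    # Particular solution w * exp(-tau/mu0): (A + I/mu0) w = -b
    b1 = -ssa_p * g3 / mu0
    b2 = ssa_p * g4 / mu0
    det_p = 1.0 / mu0**2 - lam**2
    det_p = np.where(np.abs(det_p) < 1e-12, 1e-12, det_p)
    w1 = -((1.0 / mu0 - g1) * b1 + g2 * b2) / det_p
    w2 = -(-g2 * b1 + (g1 + 1.0 / mu0) * b2) / det_p

    # Homogeneous modes exp(+-lam tau); r is the semi-infinite reflectance.
    r = g2 / (g1 + lam)
    tau_eff = np.minimum(tau_p, 500.0)  # opaque beyond this
    e_lam = np.exp(-lam * tau_eff)
    edir = np.exp(-np.minimum(tau_eff / np.maximum(mu0, 1e-9), 500.0))

    # Boundary conditions F_dn(0) = 0, F_up(tau*) = 0 give a 2x2 system in
    # the (overflow-rescaled) mode amplitudes.
    det_c = 1.0 - (r * e_lam) ** 2
    c1 = (-w1 * edir + r * e_lam * w2) / det_c
    c2 = (-w2 + r * e_lam * w1 * edir) / det_c

    t_direct = edir
    t_diffuse = np.clip(c1 * r + c2 * e_lam + w2 * edir, 0.0, None)
    return t_direct, np.asarray(t_diffuse)


def surface_par(
    toa_insolation,
    zenith_deg,
    aod_scattering,
    aod_absorbing,
    cloud_fraction=0.0,
    cloud_lwp=0.0,
    optics: ComponentOptics = DEFAULT_OPTICS,
    par_fraction: float = PAR_FRACTION,
    tau_rayleigh: float = TAU_RAYLEIGH_PAR,
) -> RadiationFluxes:
    """Surface direct and diffuse PAR for one (vectorised) column state.

    The clear and cloudy sub-columns are solved separately and combined
    linearly by cloud fraction.  Zenith angles at or beyond 90 degrees
    yield zero fluxes.
    """
    zen = np.asarray(zenith_deg, dtype=float)
    mu0 = np.cos(np.radians(zen))
    up = mu0 > 1e-6
    mu0s = np.where(up, mu0, 1.0)
    par_toa = par_fraction * np.asarray(toa_insolation, dtype=float)

    cf = np.clip(np.asarray(cloud_fraction, dtype=float), 0.0, 1.0)
    tau_c = cloud_optical_depth(cloud_lwp)

    clear = mix_optics(aod_scattering, aod_absorbing, 0.0, tau_rayleigh, optics)
    cloudy = mix_optics(aod_scattering, aod_absorbing, tau_c, tau_rayleigh, optics)

    td_clr, tf_clr = delta_two_stream(
        clear.tau_total, clear.single_scattering_albedo, clear.asymmetry, mu0s
    )
    td_cld, tf_cld = delta_two_stream(
        cloudy.tau_total, cloudy.single_scattering_albedo, cloudy.asymmetry, mu0s
    )

    t_dir = (1.0 - cf) * td_clr + cf * td_cld
    t_dif = (1.0 - cf) * tf_clr + cf * tf_cld

    par_direct = np.where(up, par_toa * t_dir, 0.0)
    par_diffuse = np.where(up, par_toa * t_dif, 0.0)
    return RadiationFluxes(
        par_direct=np.asarray(par_direct, dtype=float),
        par_diffuse=np.asarray(par_diffuse, dtype=float),
        solar_zenith=zen * np.ones_like(np.asarray(par_direct, dtype=float)),
    )


def apply_cloud_scaling(atmos: AtmosphericState, factor: float) -> AtmosphericState:
    """Scale cloud amount: fraction' = min(1, factor * fraction), LWP' = factor * LWP."""
    if factor < 0:
        raise ValueError("cloud scaling factor must be non-negative")
    out = atmos.copy()
    return replace(
        out,
        cloud_fraction=np.minimum(1.0, factor * out.cloud_fraction),
        cloud_lwp=factor * out.cloud_lwp,
    )
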