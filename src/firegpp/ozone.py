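"""Flux-based ozone damage to photosynthesis.

The instantaneous damage scheme: the fractional GPP change is
F = -a * (F_O3 - T_O3) when the stomatal ozone flux F_O3 exceeds the
threshold T_O3, and zero otherwise.  The flux is
F_O3 = [O3] / (r_b + k r_s), with [O3] the concentration at the top of
the canopy, r_b the leaf boundary-layer resistance, r_s = 1/g_s the
stomatal resistance and k = 1.67 the O3:H2O diffusivity ratio.  Because
damage lowers assimilation, which lowers Ball-Berry conductance, which
lowers the flux, the (F, g_s) pair is solved as a fixed point.

High ozone alone does not injure a leaf whose stomata are nearly closed:
the flux stays below threshold however large the concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .photosynthesis import LeafState, stomatal_conductance

__all__ = [
    "DamageState",
    "K_O3_H2O",
    "ppbv_to_concentration",
    "boundary_layer_resistance",
    "stomatal_resistance",
    "stomatal_o3_flux",
    "damage_fraction",
    "damaged_photosynthesis",
]

R_GAS = 8.314462618
#: O3:H2O diffusivity ratio through stomata.
K_O3_H2O = 1.67
#: Characteristic leaf dimension for the boundary-layer formula [m].
LEAF_DIMENSION = 0.05


@dataclass
class DamageState:
    """Converged ozone-damage diagnostics (vectorised)."""

    f_o3: np.ndarray       # stomatal O3 flux, nmol m-2 s-1
    damage: np.ndarray     # fractional change F <= 0
    r_b: np.ndarray        # s m-1
    r_s: np.ndarray        # s m-1
    converged: np.ndarray
    n_iter: int


def ppbv_to_concentration(o3_ppbv, temperature, pressure):
    """Convert an ozone mixing ratio [ppbv] to concentration [nmol m-3]."""
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("temperature and pressure must be positive")
    return np.asarray(o3_ppbv, dtype=float) * p / (R_GAS * t)


def boundary_layer_resistance(wind_speed, leaf_dimension: float = LEAF_DIMENSION):
    """Flat-leaf boundary-layer resistance r_b = 132 (d/u)^0.5 [s m-1]."""
    u = np.maximum(np.asarray(wind_speed, dtype=float), 0.1)
    return 132.0 * np.sqrt(leaf_dimension / u)


def stomatal_resistance(g_s_mol, temperature, pressure):
    """Stomatal resistance [s m-1] from conductance in mol H2O m-2 s-1."""
    g_ms = np.maximum(np.asarray(g_s_mol, dtype=float), 1e-6) * R_GAS \
        * np.asarray(temperature, dtype=float) / np.asarray(pressure, dtype=float)
    return 1.0 / g_ms


def stomatal_o3_flux(o3_concentration, r_b, r_s, k: float = K_O3_H2O):
    """Stomatal ozone flux [O3] / (r_b + k r_s) [nmol m-2 s-1]."""
    r_b = np.asarray(r_b, dtype=float)
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_b <= 0) or np.any(r_s <= 0):
        raise ValueError("resistances must be positive")
    return np.asarray(o3_concentration, dtype=float) / (r_b + k * r_s)


def damage_fraction(f_o3, a, t_o3):
    """Piecewise-linear fractional GPP change, -a (F_O3 - T_O3) above threshold."""
    if np.any(np.asarray(a) < 0) or np.any(np.asarray(t_o3) < 0):
        raise ValueError("a and t_o3 must be non-negative")
    excess = np.maximum(np.asarray(f_o3, dtype=float) - t_o3, 0.0)
    return -a * excess


def _damage_fixed_point(
    leaf: LeafState,
    o3_conc,
    r_b,
    rh,
    cs,
    temperature,
    pressure,
    params,
    a_coef,
    tol: float = 1e-4,
    max_iter: int = 50,
):
    """Solve the coupled (F, g_s) pair for one damage coefficient."""
    f_prev = np.zeros_like(np.asarray(leaf.a_net, dtype=float))
    a_dam = leaf.a_net
    gs = leaf.g_s
    converged = np.zeros_like(f_prev, dtype=bool)
    n_done = max_iter
    for it in range(max_iter):
        r_s = stomatal_resistance(gs, temperature, pressure)
        flux = stomatal_o3_flux(o3_conc, r_b, r_s)
        f_new = damage_fraction(flux, a_coef, params.t_o3)
        f_new = np.maximum(f_new, -1.0)
        converged = np.abs(f_new - f_prev) < tol
        # damped relaxation guards against gs <-> flux oscillation
        f_prev = np.where(converged, f_prev, 0.5 * f_prev + 0.5 * f_new)
        a_dam = (1.0 + f_prev) * leaf.a_net
        gs = stomatal_conductance(
            a_dam, rh, cs, params.ball_berry_slope, params.ball_berry_intercept
        )
        if converged.all():
            n_done = it + 1
            break
    r_s = stomatal_resistance(gs, temperature, pressure)
    flux = stomatal_o3_flux(o3_conc, r_b, r_s)
    state = DamageState(
        f_o3=flux, damage=f_prev, r_b=np.broadcast_to(np.asarray(r_b, float), f_prev.shape),
        r_s=r_s, converged=converged, n_iter=n_done,
    )
    return a_dam, gs, state


def damaged_photosynthesis(
    leaf: LeafState,
    o3_ppbv,
    wind_speed,
    rh,
    cs,
    temperature,
    pressure,
    params,
    sensitivity: str = "mean",
    tol: float = 1e-4,
    max_iter: int = 50,
):
    """Apply flux-based ozone damage to a converged leaf state.

    The multiplicative factor (1 + F) reduces assimilation; conductance
    follows through the Ball-Berry coupling and the flux is recomputed
    until (F, g_s) is a fixed point.  ``sensitivity`` selects the low or
    high damage coefficient; ``"mean"`` reports the central value of the
    low- and high-sensitivity solutions, the convention used for all
    headline damage numbers.

    Returns ``(a_damaged, g_s_damaged, DamageState)``.
    """
    o3_conc = ppbv_to_concentration(o3_ppbv, temperature, pressure)
    r_b = boundary_layer_resistance(wind_speed)
    if sensitivity == "mean":
        lo = _damage_fixed_point(
            leaf, o3_conc, r_b, rh, cs, temperature, pressure, params,
            params.a_low, tol, max_iter,
        )
        hi = _damage_fixed_point(
            leaf, o3_conc, r_b, rh, cs, temperature, pressure, params,
            params.a_high, tol, max_iter,
        )
        a_dam = 0.5 * (lo[0] + hi[0])
        gs = 0.5 * (lo[1] + hi[1])
        state = DamageState(
            f_o3=0.5 * (lo[2].f_o3 + hi[2].f_o3),
            damage=0.5 * (lo[2].damage + hi[2].damage),
            r_b=lo[2].r_b,
            r_s=0.5 * (lo[2].r_s + hi[2].r_s),
            converged=lo[2].converged & hi[2].converged,
            n_iter=max(lo[2].n_iter, hi[2].n_iter),
        )
        return a_dam, gs, state
    a_coef = params.damage_coefficient(sensitivity)
    return _damage_fixed_point(
        leaf, o3_conc, r_b, rh, cs, temperature, pressure, params,
        a_coef, tol, max_iter,
    )
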