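"""Coupled Farquhar photosynthesis and Ball-Berry stomatal conductance.

Leaf net assimilation is the minimum of the Rubisco-, light- (and, for C4,
PEP-carboxylase-) limited rates minus dark respiration.  Stomatal
conductance follows Ball-Berry, g_s = m A h_s / c_s + b with A floored at
zero inside the conductance term.  The internal CO2 concentration is
solved by a damped fixed point with a bisection fallback; the returned
(A, g_s, c_i) triple is consistent to 1e-4 umol m-2 s-1.

All temperature responses use standard Arrhenius/peaked forms with
kinetic constants from the C3 literature; everything is vectorised over
numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LeafState", "leaf_photosynthesis", "stomatal_conductance"]

R_GAS = 8.314462618  # J mol-1 K-1
TREF = 298.15
O2_MMOL = 210.0      # mmol mol-1 intercellular oxygen
QUANTA_PER_J_PAR = 4.6   # umol photons per J of PAR
THETA_J = 0.7        # curvature of the light response
ALPHA_J = 0.3        # e- per absorbed photon (leaf-absorbed basis)
ALPHA_C4 = 0.04      # mol CO2 per mol absorbed photons (C4 quantum yield)
RD_FRAC = 0.015      # dark respiration as fraction of Vcmax25
GB_MOL = 2.0         # leaf boundary-layer conductance for H2O, mol m-2 s-1


def _arrhenius(k25, ha_kj, tleaf):
    return k25 * np.exp(ha_kj * 1e3 * (tleaf - TREF) / (R_GAS * TREF * tleaf))


def _peaked(k25, ha_kj, tleaf, hd_kj=200.0, ds=0.65):
    """Peaked Arrhenius (high-temperature deactivation), ds in kJ mol-1 K-1."""
    arr = _arrhenius(k25, ha_kj, tleaf)
    num = 1.0 + np.exp((ds * TREF - hd_kj) * 1e3 / (R_GAS * TREF))
    den = 1.0 + np.exp((ds * tleaf - hd_kj) * 1e3 / (R_GAS * tleaf))
    return arr * num / den


@dataclass
class LeafState:
    """Converged leaf gas-exchange solution (all vectorised)."""

    a_net: np.ndarray        # umol CO2 m-2 s-1
    g_s: np.ndarray          # mol H2O m-2 s-1
    c_i: np.ndarray          # ppm
    rd: np.ndarray           # umol CO2 m-2 s-1
    converged: np.ndarray    # bool


def stomatal_conductance(a_net, rh, cs, m, b):
    """Ball-Berry: g_s = m * max(A, 0) * h_s / c_s + b."""
    return m * np.maximum(a_net, 0.0) * rh / np.maximum(cs, 1.0) + b


def _demand(ci, par_umol, tleaf, params):
    """Biochemical demand A_net(ci) [umol m-2 s-1]."""
    vcmax = _peaked(params.vcmax25, 65.33, tleaf)
    rd = _arrhenius(RD_FRAC * params.vcmax25, 46.39, tleaf)
    if params.pathway == "C4":
        wj = ALPHA_C4 * par_umol
        wc = vcmax
        wp = 0.02 * vcmax * ci
        a = np.minimum(np.minimum(wc, wj), wp) - rd
        return a, rd
    gamma = _arrhenius(42.75, 37.83, tleaf)
    kc = _arrhenius(404.9, 79.43, tleaf)
    ko = _arrhenius(278.4, 36.38, tleaf)
    km = kc * (1.0 + O2_MMOL / ko)
    jmax = _peaked(params.jmax_ratio * params.vcmax25, 43.9, tleaf)
    i2 = ALPHA_J * par_umol * 4.0  # electron flux potential, 4 e- per CO2
    j = (
        i2 + jmax - np.sqrt((i2 + jmax) ** 2 - 4.0 * THETA_J * i2 * jmax)
    ) / (2.0 * THETA_J)
    wc = vcmax * (ci - gamma) / (ci + km)
    wj = j * (ci - gamma) / (4.0 * ci + 8.0 * gamma)
    a = np.minimum(wc, wj) - rd
    return np.maximum(a, -rd), rd


def _supply_residual(ci, par_umol, tleaf, rh, ca, params):
    """Residual of supply minus demand at a trial ci; also returns (A, gs)."""
    a, rd = _demand(ci, par_umol, tleaf, params)
    cs = ca - 1.37 * a / GB_MOL
    cs = np.maximum(cs, 1.0)
    gs = stomatal_conductance(a, rh, cs, params.ball_berry_slope, params.ball_berry_intercept)
    gtot = 1.0 / (1.37 / GB_MOL + 1.6 / gs)
    supply = gtot * (ca - ci)
    return supply - a, a, gs, rd


def leaf_photosynthesis(
    par_absorbed,
    t_leaf,
    rh,
    ca,
    params,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> LeafState:
    """Solve the coupled (A, g_s, c_i) leaf system.

    Parameters
    ----------
    par_absorbed
        Leaf-absorbed PAR [W m-2 leaf].
    t_leaf
        Leaf temperature [K] (taken equal to air temperature).
    rh
        Relative humidity at the leaf surface, [0, 1].
    ca
        Ambient CO2 [ppm].
    params
        PFT parameter record with ``vcmax25``, ``jmax_ratio``,
        ``ball_berry_slope``, ``ball_berry_intercept``, ``pathway``.
    """
    par_umol = QUANTA_PER_J_PAR * np.asarray(par_absorbed, dtype=float)
    t_leaf = np.asarray(t_leaf, dtype=float)
    rh = np.clip(np.asarray(rh, dtype=float), 0.01, 1.0)
    ca = np.asarray(ca, dtype=float)
    shape = np.broadcast_shapes(par_umol.shape, t_leaf.shape, rh.shape, ca.shape)
    par_umol, t_leaf, rh, ca = np.broadcast_arrays(par_umol, t_leaf, rh, ca)

    ci = 0.7 * ca.astype(float).copy()
    converged = np.zeros(shape, dtype=bool)
    for _ in range(max_iter):
        resid, a, gs, rd = _supply_residual(ci, par_umol, t_leaf, rh, ca, params)
        gtot = 1.0 / (1.37 / GB_MOL + 1.6 / gs)
        ci_new = ca - a / gtot
        ci_new = np.clip(ci_new, 1.0, 1.5 * ca)
        converged = np.abs(resid) < tol
        if converged.all():
            break
        ci = np.where(converged, ci, 0.5 * ci + 0.5 * ci_new)

    if not converged.all():
        # bisection fallback on the supply-demand residual, which is
        # decreasing in ci for both pathways
        lo = np.full(shape, 1.0)
        hi = 1.5 * ca
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            resid, _, _, _ = _supply_residual(mid, par_umol, t_leaf, rh, ca, params)
            lo = np.where(resid > 0, mid, lo)
            hi = np.where(resid > 0, hi, mid)
        ci = np.where(converged, ci, 0.5 * (lo + hi))
        resid, a, gs, rd = _supply_residual(ci, par_umol, t_leaf, rh, ca, params)
        converged = converged | (np.abs(resid) < 10 * tol)

    return LeafState(a_net=a, g_s=gs, c_i=ci, rd=rd, converged=converged)
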