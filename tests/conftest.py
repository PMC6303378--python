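"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from firegpp import forcing as fo
from firegpp import pft as pft_mod


@pytest.fixture(scope="session")
def pft_table():
    return pft_mod.load_pft_table()


@pytest.fixture(scope="session")
def dbf(pft_table):
    return pft_table["deciduous_broadleaf_forest"]


@pytest.fixture(scope="session")
def midlat_forcing():
    """Short default midlatitude-summer forcing shared across tests."""
    return fo.generate_site_forcing(
        n_days=10, climate_archetype="midlatitude_summer", seed=42
    )


@pytest.fixture(scope="session")
def midlat_scenario():
    return fo.generate_pollution_scenario(seed=42, n_days=10)


def monte_carlo_transmission(tau, ssa, g, mu0, n_photons=200_000, seed=0):
    """Photon-tracking transmission oracle for a homogeneous slab.

    Independent of the two-stream solver: explicit random-walk transport
    with Henyey-Greenstein scattering over a black surface.  Returns
    (direct, diffuse) downward transmittance per unit incident flux on the
    horizontal.
    """
    rng = np.random.default_rng(seed)
    n = n_photons
    z = np.zeros(n)
    mu = np.full(n, -mu0)  # negative = travelling downward
    alive = np.ones(n, bool)
    scattered = np.zeros(n, bool)
    t_dir = t_dif = 0.0
    for _ in range(10_000):
        if not alive.any():
            break
        idx = np.where(alive)[0]
        step = rng.exponential(size=idx.size)
        znew = z[idx] - step * mu[idx]
        exit_bot = (znew >= tau) & (mu[idx] < 0)
        exit_top = (znew <= 0) & (mu[idx] > 0)
        bot = idx[exit_bot]
        t_dir += np.sum(~scattered[bot])
        t_dif += np.sum(scattered[bot])
        alive[bot] = False
        alive[idx[exit_top]] = False
        inside = ~exit_bot & ~exit_top
        rem = idx[inside]
        z[rem] = znew[inside]
        survives = rng.random(rem.size) < ssa
        alive[rem[~survives]] = False
        sc = rem[survives]
        scattered[sc] = True
        if g != 0.0:
            u = rng.random(sc.size)
            ct = (1 + g * g - ((1 - g * g) / (1 - g + 2 * g * u)) ** 2) / (2 * g)
        else:
            ct = 2 * rng.random(sc.size) - 1
        phi = 2 * np.pi * rng.random(sc.size)
        st = np.sqrt(np.maximum(0.0, 1 - ct**2))
        mu_old = mu[sc]
        s_old = np.sqrt(np.maximum(0.0, 1 - mu_old**2))
        mu[sc] = mu_old * ct + s_old * st * np.cos(phi)
    return t_dir / n, t_dif / n
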