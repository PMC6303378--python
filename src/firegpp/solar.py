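"""Solar geometry: declination, zenith angle, and top-of-atmosphere insolation.

All angles are handled in degrees at the public interface.  Declination and
the Sun--Earth distance correction use the Spencer Fourier-series
approximations, which are accurate to better than +/- 0.3 degrees in
declination -- ample for a single-band canopy radiation scheme.
"""

from __future__ import annotations

import numpy as np

#: Solar constant at mean Sun-Earth distance [W m-2].
SOLAR_CONSTANT = 1361.0


def _day_angle(day_of_year):
    """Fractional year angle [radians] for Spencer-type series."""
    return 2.0 * np.pi * (np.asarray(day_of_year, dtype=float) - 1.0) / 365.0


def declination(day_of_year):
    """Solar declination [degrees] from the Spencer Fourier series."""
    g = _day_angle(day_of_year)
    dec = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(dec)


def eccentricity_factor(day_of_year):
    """Squared ratio of mean to actual Sun-Earth distance (Spencer series)."""
    g = _day_angle(day_of_year)
    return (
        1.000110
        + 0.034221 * np.cos(g)
        + 0.001280 * np.sin(g)
        + 0.000719 * np.cos(2 * g)
        + 0.000077 * np.sin(2 * g)
    )


def cos_zenith(latitude, day_of_year, hour):
    """Cosine of the solar zenith angle.

    ``hour`` is local solar time in fractional hours (solar noon at 12.0);
    the runs use a calendar-free, timezone-free convention.
    """
    lat = np.radians(np.asarray(latitude, dtype=float))
    dec = np.radians(declination(day_of_year))
    h = np.radians(15.0 * (np.asarray(hour, dtype=float) - 12.0))
    mu = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(h)
    return np.clip(mu, -1.0, 1.0)


def solar_zenith(latitude, day_of_year, hour):
    """Solar zenith angle [degrees], in [0, 180]."""
    return np.degrees(np.arccos(cos_zenith(latitude, day_of_year, hour)))


def toa_insolation(latitude, day_of_year, hour):
    """Instantaneous extraterrestrial flux on a horizontal plane [W m-2].

    Zero whenever the Sun is at or below the horizon.
    """
    mu = cos_zenith(latitude, day_of_year, hour)
    flux = SOLAR_CONSTANT * eccentricity_factor(day_of_year) * mu
    return np.where(mu > 0.0, flux, 0.0)
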