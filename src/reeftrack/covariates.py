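"""Hourly covariate table for movement models: cycles, moon, twilight, weather.

The downstream smoothing-regression layer (out of scope here) consumes
one row per fish-hour carrying the response metrics (hourly home range,
mean height above bottom, mean distance to reef) together with temporal
covariates (UTC hour, day of year, lunar phase), twilight flags, buoy
meteorology and receiver-logged bottom temperature.  This module builds
that table and houses the native ephemeris calculations.

Lunar phase follows the elongation convention: the geocentric ecliptic
longitude of the Moon minus that of the Sun, in radians divided by pi,
mapped to [0, 2) — 0 is new moon, 0.5 first quarter, 1 full moon, 1.5
last quarter.  Solar events use standard solar-geometry equations
(declination + equation of time from the mean anomaly series): sunrise
and sunset at solar altitude -0.833 deg, nautical twilight at -12 deg.
Dawn spans [nautical twilight start, sunrise]; dusk spans [sunset,
nautical twilight end].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import TwilightUndefinedError

_DEG = np.pi / 180.0


def _julian_day(ts) -> np.ndarray:
    """Julian day (UT) from UTC timestamps (scalar or array-like)."""
    scalar = np.isscalar(ts) or isinstance(ts, (str, pd.Timestamp, np.datetime64))
    idx = pd.DatetimeIndex([ts] if scalar else pd.to_datetime(ts, utc=True))
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    unix = idx.asi8 / 1e9
    return unix / 86400.0 + 2440587.5


def _sun_moon_longitudes(jd: np.ndarray):
    """Geocentric ecliptic longitudes of the Sun and Moon (degrees).

    Truncated series (solar equation of centre; six principal lunar
    terms), accurate to a few tenths of a degree — ample for a phase
    expressed on a [0, 2) half-turn scale.
    """
    T = (jd - 2451545.0) / 36525.0
    # Sun
    L0 = 280.46646 + 36000.76983 * T
    M = 357.52911 + 35999.05029 * T
    C = (
        1.914602 * np.sin(M * _DEG)
        + 0.019993 * np.sin(2 * M * _DEG)
        + 0.000289 * np.sin(3 * M * _DEG)
    )
    lam_sun = L0 + C
    # Moon (principal periodic terms)
    Lp = 218.3164477 + 481267.88123421 * T
    D = 297.8501921 + 445267.1114034 * T
    Mp = 134.9633964 + 477198.8675055 * T
    F = 93.2720950 + 483202.0175233 * T
    lam_moon = (
        Lp
        + 6.288774 * np.sin(Mp * _DEG)
        + 1.274027 * np.sin((2 * D - Mp) * _DEG)
        + 0.658314 * np.sin(2 * D * _DEG)
        + 0.213618 * np.sin(2 * Mp * _DEG)
        - 0.185116 * np.sin(M * _DEG)
        - 0.114332 * np.sin(2 * F * _DEG)
    )
    return lam_sun, lam_moon


def moon_phase(ts):
    """Lunar phase in [0, 2): elongation (Moon - Sun longitude) / pi.

    0 = new moon, 0.5 = first quarter, 1 = full moon, 1.5 = last quarter.
    Accepts a scalar timestamp or an array-like; vectorised.
    """
    scalar = np.isscalar(ts) or isinstance(ts, (str, pd.Timestamp, np.datetime64))
    jd = _julian_day(ts)
    lam_sun, lam_moon = _sun_moon_longitudes(jd)
    phase = ((lam_moon - lam_sun) % 360.0) / 180.0
    return float(phase[0]) if scalar else phase


@dataclass
class TwilightIntervals:
    """Dawn and dusk intervals (UTC) for one date at one location."""

    date: pd.Timestamp
    dawn_start: pd.Timestamp  # nautical twilight begins (sun at -12 deg)
    sunrise: pd.Timestamp     # sun at -0.833 deg, rising
    sunset: pd.Timestamp      # sun at -0.833 deg, setting
    dusk_end: pd.Timestamp    # nautical twilight ends

    @property
    def dawn(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.dawn_start, self.sunrise)

    @property
    def dusk(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.sunset, self.dusk_end)


def _solar_params(jd_noonish: float):
    """Solar declination (deg) and equation of time (minutes)."""
    T = (jd_noonish - 2451545.0) / 36525.0
    L0 = (280.46646 + 36000.76983 * T) % 360.0
    M = 357.52911 + 35999.05029 * T
    e = 0.016708634 - 0.000042037 * T
    C = (
        1.914602 * np.sin(M * _DEG)
        + 0.019993 * np.sin(2 * M * _DEG)
        + 0.000289 * np.sin(3 * M * _DEG)
    )
    lam = L0 + C
    eps = 23.439291 - 0.0130042 * T
    decl = np.degrees(np.arcsin(np.sin(eps * _DEG) * np.sin(lam * _DEG)))
    y = np.tan(eps * _DEG / 2.0) ** 2
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0 * _DEG)
        - 2.0 * e * np.sin(M * _DEG)
        + 4.0 * e * y * np.sin(M * _DEG) * np.cos(2 * L0 * _DEG)
        - 0.5 * y * y * np.sin(4 * L0 * _DEG)
        - 1.25 * e * e * np.sin(2 * M * _DEG)
    )
    return float(decl), float(eot)


def _hour_angle(lat: float, decl: float, altitude: float) -> float:
    """Hour angle (deg) at which the sun centre reaches ``altitude`` deg."""
    cos_h = (
        np.sin(altitude * _DEG) - np.sin(lat * _DEG) * np.sin(decl * _DEG)
    ) / (np.cos(lat * _DEG) * np.cos(decl * _DEG))
    if not -1.0 <= cos_h <= 1.0:
        raise TwilightUndefinedError(
            f"sun never reaches altitude {altitude} deg at latitude {lat}"
        )
    return float(np.degrees(np.arccos(cos_h)))


def twilight(date, lat: float, lon: float) -> TwilightIntervals:
    """Dawn/dusk intervals for a calendar date (UTC) at (lat, lon).

    Raises :class:`TwilightUndefinedError` where the sun does not cross
    the required altitude on that date (high latitudes).
    """
    day = pd.Timestamp(date).tz_localize(None).normalize()
    jd0 = _julian_day(pd.Timestamp(day, tz="UTC"))[0] + 0.5 - lon / 360.0
    decl, eot = _solar_params(jd0)
    solar_noon_min = 720.0 - 4.0 * lon - eot  # minutes after 00:00 UTC
    ha_rise = _hour_angle(lat, decl, -0.833)
    ha_naut = _hour_angle(lat, decl, -12.0)
    base = pd.Timestamp(day, tz="UTC")
    minute = pd.Timedelta(minutes=1)
    return TwilightIntervals(
        date=base,
        dawn_start=base + (solar_noon_min - 4.0 * ha_naut) * minute,
        sunrise=base + (solar_noon_min - 4.0 * ha_rise) * minute,
        sunset=base + (solar_noon_min + 4.0 * ha_rise) * minute,
        dusk_end=base + (solar_noon_min + 4.0 * ha_naut) * minute,
    )


def assemble_covariate_table(
    responses: pd.DataFrame,
    env: pd.DataFrame,
    bottom_temp: pd.DataFrame | None = None,
    fish_lengths: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Join hourly response metrics with environmental covariates.

    ``responses`` carries ``fish_id, t`` (clock hours, UTC) plus any
    response columns (e.g. ``area_m2``, ``height_above_bottom``,
    ``distance_m``).  ``env`` is the hourly buoy frame; ``bottom_temp``
    an hourly ``t, bottom_temp`` frame from the centre receiver's log.
    The join is exact-hour (no interpolation — the series are hourly
    averages already); missing environmental values propagate as NaN but
    the row is retained.  Derived columns: ``hour`` (0-23 UTC),
    ``day_of_year`` (1-366) and ``moon_phase`` ([0, 2)).
    """
    if len(responses) == 0:
        raise ValueError("no response rows")
    out = responses.copy()
    out["t"] = pd.to_datetime(out["t"], utc=True).dt.floor("h")
    env = env.copy()
    env["t"] = pd.to_datetime(env["t"], utc=True).dt.floor("h")
    if not set(out["t"]) & set(env["t"]):
        raise ValueError("no overlapping hours between responses and environment")
    out = out.merge(env, on="t", how="left")
    if bottom_temp is not None:
        bt = bottom_temp.copy()
        bt["t"] = pd.to_datetime(bt["t"], utc=True).dt.floor("h")
        out = out.merge(bt[["t", "bottom_temp"]], on="t", how="left")
    if fish_lengths is not None:
        out["fish_length"] = out["fish_id"].map(fish_lengths)
    out["hour"] = out["t"].dt.hour
    out["day_of_year"] = out["t"].dt.dayofyear
    out["moon_phase"] = moon_phase(out["t"])
    return out
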