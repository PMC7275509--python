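"""Solar geometry: daylight/darkness classification and light seasons.

Uses the standard NOAA low-accuracy solar position algorithm (fractional
year -> equation of time and declination -> hour angle -> elevation).
Accuracy is a few minutes of sunrise/sunset time, ample for classifying
hourly fixes, and the formulation degrades gracefully at polar latitudes:
during the midnight sun the elevation simply never drops below the
horizon, during the polar night it never rises above it.

A timestamp counts as *daylight* when the solar elevation exceeds
-0.833 degrees (the conventional sunrise/sunset zenith of 90.833 degrees,
accounting for refraction and the solar disc).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "solar_elevation",
    "compute_light",
    "light_season",
    "SUNRISE_ELEVATION_DEG",
]

SUNRISE_ELEVATION_DEG = -0.833


def _to_utc_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps))
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    return idx.tz_convert("UTC")


def solar_elevation(lat: float, lon: float, timestamps) -> np.ndarray:
    """Solar elevation angle in degrees at UTC timestamps.

    Parameters
    ----------
    lat, lon : float
        Degrees; east longitude positive.
    timestamps : datetime-like sequence (naive values taken as UTC)
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    idx = _to_utc_index(timestamps)
    doy = idx.dayofyear.to_numpy(float)
    hours = (
        idx.hour.to_numpy(float)
        + idx.minute.to_numpy(float) / 60.0
        + idx.second.to_numpy(float) / 3600.0
    )
    # fractional year (radians)
    g = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    tst = hours * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat_r = np.deg2rad(lat)
    sin_el = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def compute_light(lat: float, lon: float, timestamps) -> np.ndarray:
    """Classify timestamps as ``"daylight"`` or ``"darkness"``.

    Daylight iff the sun stands above the sunrise/sunset elevation;
    polar-day dates are therefore all daylight and polar-night dates all
    darkness, with no special-casing needed.
    """
    el = solar_elevation(lat, lon, timestamps)
    out = np.where(el > SUNRISE_ELEVATION_DEG, "daylight", "darkness")
    return out if out.ndim else out[None][0]


def light_season(lat: float, lon: float, timestamps) -> np.ndarray:
    """Label each timestamp's date with one of four light seasons.

    ``midnight_sun``: the sun never sets on that date; ``polar_night``:
    it never rises; the remaining dates are ``increasing_light`` before
    the summer solstice (June 21 / December 21 on the southern
    hemisphere) and ``decreasing_light`` after.
    """
    idx = _to_utc_index(timestamps)
    out = np.empty(len(idx), dtype=object)
    solstice_doy = 172 if lat >= 0 else 355
    for date in np.unique(idx.date):
        day_hours = pd.date_range(
            pd.Timestamp(date, tz="UTC"), periods=24, freq="h"
        )
        el = solar_elevation(lat, lon, day_hours)
        if np.all(el > SUNRISE_ELEVATION_DEG):
            label = "midnight_sun"
        elif np.all(el <= SUNRISE_ELEVATION_DEG):
            label = "polar_night"
        else:
            doy = pd.Timestamp(date).dayofyear
            # distance to the solstice on a circular year
            delta = (doy - solstice_doy) % 365
            label = "decreasing_light" if delta < 365 / 2 else "increasing_light"
        out[np.asarray(idx.date) == date] = label
    return out.astype(str)
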