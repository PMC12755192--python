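"""Low-precision solar position (NOAA-style).

Used to classify movement steps as day or night for the diurnality index.
The algorithm is the standard Astronomical-Almanac approximation: mean solar
elements as linear functions of days since J2000, ecliptic longitude with a
two-term equation of centre, and the hour angle from Greenwich mean sidereal
time. Accuracy is a few hundredths of a degree over the satellite-tracking
era — far inside the <= 0.5 degree tolerance that a day/night classifier
needs (atmospheric refraction near the horizon is larger than that).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_J2000_UNIX = 946_728_000.0  # 2000-01-01 12:00:00 UTC


def _unix_seconds(t) -> np.ndarray:
    """Coerce datetime-like input (tz-aware or naive=UTC) to unix seconds."""
    ts = pd.to_datetime(t, utc=True)
    if isinstance(ts, pd.Timestamp):
        return np.asarray(ts.value / 1e9)
    return np.asarray(pd.DatetimeIndex(ts).asi8 / 1e9)


def sun_elevation(lat, lon, t) -> np.ndarray | float:
    """Solar elevation angle in degrees above the geometric horizon.

    Parameters
    ----------
    lat, lon : float or array
        Observer position, decimal degrees WGS84.
    t : datetime-like or array
        Time(s), UTC (naive values are taken as UTC).
    """
    n = (_unix_seconds(t) - _J2000_UNIX) / 86400.0  # days since J2000
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)

    L = np.radians((280.460 + 0.9856474 * n) % 360.0)       # mean longitude
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)       # mean anomaly
    lam = L + np.radians(1.915) * np.sin(g) + np.radians(0.020) * np.sin(2 * g)
    eps = np.radians(23.439 - 0.0000004 * n)                 # obliquity

    sin_dec = np.sin(eps) * np.sin(lam)
    dec = np.arcsin(sin_dec)
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))

    gmst_h = (18.697374558 + 24.06570982441908 * n) % 24.0   # hours
    lst = np.radians(gmst_h * 15.0) + np.radians(lon)        # local sidereal
    ha = lst - ra                                            # hour angle

    phi = np.radians(lat)
    sin_elev = np.sin(phi) * sin_dec + np.cos(phi) * np.cos(dec) * np.cos(ha)
    elev = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    if np.ndim(elev) == 0:
        return float(elev)
    return elev


def is_day(lat, lon, t, threshold_deg: float = 0.0):
    """True where the sun is above ``threshold_deg`` (geometric horizon)."""
    return sun_elevation(lat, lon, t) > threshold_deg
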