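"""Shared fixture builders: small deterministic tracks in degrees/metres."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracktraits.geometry import M_PER_DEG
from tracktraits.preprocess import resample_track


def make_fixes(lons, lats, start="2024-06-01 00:00:00", interval_s=3600,
               individual_id="ind1"):
    """Fix DataFrame at a regular cadence through the given positions."""
    n = len(lons)
    t0 = pd.Timestamp(start, tz="UTC")
    times = t0 + pd.to_timedelta(np.arange(n) * interval_s, unit="s")
    return pd.DataFrame({
        "individual_id": individual_id,
        "timestamp": times,
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
    })


def make_track(lons, lats, start="2024-06-01 00:00:00", interval_s=3600,
               individual_id="ind1", tolerance_s=None):
    """RegularTrack through the given positions (exact-cadence input, so the
    resampling is an identity selection)."""
    if tolerance_s is None:
        tolerance_s = interval_s // 4
    fixes = make_fixes(lons, lats, start, interval_s, individual_id)
    return resample_track(fixes, interval_s, tolerance_s, individual_id)


def km_to_deg_lon(km: float, lat: float = 0.0) -> float:
    return km * 1000.0 / (M_PER_DEG * np.cos(np.radians(lat)))


def km_to_deg_lat(km: float) -> float:
    return km * 1000.0 / M_PER_DEG


def square_perimeter_km(side_km: float = 1.0, laps: int = 1):
    """Positions (deg lon, deg lat) walking the perimeter of a square of the
    given side at the equator: corners + edge midpoints, closing each lap.
    One lap = 9 fixes, path length = 4 * side_km."""
    pts_km = [(0, 0), (0.5, 0), (1, 0), (1, 0.5), (1, 1), (0.5, 1),
              (0, 1), (0, 0.5)]
    pts_km = [(x * side_km, y * side_km) for x, y in pts_km]
    seq = pts_km * laps + [pts_km[0]]
    lons = [km_to_deg_lon(x) for x, _ in seq]
    lats = [km_to_deg_lat(y) for _, y in seq]
    return lons, lats


@pytest.fixture
def square_track():
    lons, lats = square_perimeter_km(1.0, laps=1)
    return make_track(lons, lats)
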