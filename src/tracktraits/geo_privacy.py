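"""Annotation fields with location privacy.

Published trait summaries must support environmental annotation without
disclosing where a sensitive animal actually was. The individual tier
therefore reports the tracking period exactly, but the mean coordinate only
as the centre of a standardised grid cell (~1, 100 or 10,000 km^2).

Grid construction: latitude bands of height s/111.32 degrees (s = cell side
in km), each band split into longitude cells of width s/(111.32 cos(band
centre latitude)) degrees, origin at (0, 0). Near-equal cell area away from
the poles; diffusing a cell centre returns the same centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import GridSpec
from .geometry import unit_vector_mean

KM_PER_DEG = 111.32  # nominal kilometres per degree of latitude


@dataclass(frozen=True)
class TrackingPeriod:
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def length_days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)


def mean_coordinate(fixes: pd.DataFrame) -> tuple[float, float]:
    """Spherical (unit-vector) mean of the fix locations, as (lon, lat).

    Antimeridian-safe: fixes straddling 180 degrees average to a point near
    180, not near 0. Raises on empty input or a degenerate (cancelling)
    configuration.
    """
    if len(fixes) == 0:
        raise ValueError("mean_coordinate requires at least one fix")
    return unit_vector_mean(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())


def diffuse_coordinate(lon: float, lat: float,
                       grid: GridSpec) -> tuple[float, float]:
    """Snap a point to the centre of its grid cell. Idempotent.

    Polar cells (|lat| > 89 degrees) are unsupported: the longitude division
    degenerates there.
    """
    if abs(lat) > 89.0:
        raise ValueError("diffuse_coordinate: |lat| > 89 deg unsupported")
    s = grid.cell_side_km
    band_h = s / KM_PER_DEG
    band = math.floor(lat / band_h)
    centre_lat = (band + 0.5) * band_h
    width = s / (KM_PER_DEG * math.cos(math.radians(centre_lat)))
    col = math.floor(lon / width)
    centre_lon = (col + 0.5) * width
    return centre_lon, centre_lat


def tracking_period(fixes: pd.DataFrame) -> TrackingPeriod:
    """First/last fix timestamps and the (fractional) span in days.
    Order-invariant."""
    if len(fixes) == 0:
        raise ValueError("tracking_period requires at least one fix")
    ts = fixes["timestamp"]
    return TrackingPeriod(start=ts.min(), end=ts.max())
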