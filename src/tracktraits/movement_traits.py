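"""The movement-trait metrics, computed from regular tracks.

Five traits, each at its stated timescales:

==================  =========================  =============================
trait               timescales                 definition
==================  =========================  =============================
displacement        hourly, daily              great-circle distance between
                                               consecutive gap-free fixes
max_displacement    daily, weekly, annual      max over *all* pairwise fix
                                               distances in the window
range_size          daily, weekly, monthly,    area of the 95% minimum
                    annual                     convex polygon, km^2
intensity_of_use    daily, monthly             cumulative gap-free path
                                               length / sqrt(MCP area)
diurnality          whole_track                normalised day/night contrast
                                               of movement rates, in [-1, 1]
==================  =========================  =============================

Feed mapping: daily and weekly windows are cut from the hourly track,
monthly and annual windows (and daily displacement) from the daily track —
this keeps the O(n^2) pairwise scans bounded and matches each metric's
intended grain.

Window alignment: daily/monthly/annual windows are calendar-aligned in
*local solar time* (UTC offset = round(mean longitude / 15 deg) hours), so a
biological day is not split across two windows for longitudes far from
Greenwich; weekly windows are consecutive 7-day blocks from the first fix.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .config import DAILY, HOURLY, ThresholdConfig
from .database import TRAIT_UNITS
from .geometry import azimuthal_equal_area, great_circle_distance
from .preprocess import ParameterError, RegularTrack
from .solar import sun_elevation

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["individual_id", "trait", "timescale",
                    "window_start", "window_end", "value", "unit", "n_fixes"]

#: which resampled track feeds each windowed timescale
WINDOW_SOURCE_INTERVAL = {"daily": HOURLY, "weekly": HOURLY,
                          "monthly": DAILY, "annual": DAILY}


def _estimates(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def _solar_offset_hours(track: RegularTrack) -> int:
    sel = track.selected()
    if len(sel) == 0:
        return 0
    return int(round(float(sel["lon"].mean()) / 15.0))


def assign_windows(track: RegularTrack, window: str) -> pd.DataFrame:
    """Label each selected fix with its window's (start, end) UTC instants.

    Returns the selected frame plus ``window_start``/``window_end`` columns
    and the original grid position ``grid_idx`` (used to detect gaps when
    summing consecutive displacements).
    """
    sel = track.selected().copy()
    sel["grid_idx"] = sel.index
    if len(sel) == 0:
        sel["window_start"] = pd.NaT
        sel["window_end"] = pd.NaT
        return sel

    if window == "weekly":
        first = track.frame["target_time"].iloc[0]
        block = ((sel["target_time"] - first) // pd.Timedelta(days=7))
        sel["window_start"] = first + block * pd.Timedelta(days=7)
        sel["window_end"] = sel["window_start"] + pd.Timedelta(days=7)
        return sel

    offset = pd.Timedelta(hours=_solar_offset_hours(track))
    local = (sel["target_time"] + offset).dt.tz_localize(None)
    if window == "daily":
        start_local = local.dt.floor("D")
        end_local = start_local + pd.Timedelta(days=1)
    elif window == "monthly":
        per = local.dt.to_period("M")
        start_local = per.dt.start_time
        end_local = (per + 1).dt.start_time
    elif window == "annual":
        per = local.dt.to_period("Y")
        start_local = per.dt.start_time
        end_local = (per + 1).dt.start_time
    else:
        raise ParameterError(f"unknown window {window!r}")
    sel["window_start"] = start_local.dt.tz_localize("UTC") - offset
    sel["window_end"] = end_local.dt.tz_localize("UTC") - offset
    return sel


def _require_interval(track: RegularTrack, window: str, op: str) -> None:
    want = WINDOW_SOURCE_INTERVAL.get(window)
    if want is None:
        raise ParameterError(f"{op}: unknown window {window!r}")
    if track.interval_s != want:
        raise ParameterError(
            f"{op}: {window} windows are computed from the "
            f"{'hourly' if want == HOURLY else 'daily'} track, "
            f"got interval {track.interval_s}s")


# ---------------------------------------------------------------- displacement

def displacement_series(track: RegularTrack) -> pd.DataFrame:
    """Step lengths between consecutive gap-free fixes.

    One estimate per adjacent pair of grid targets that both carry a fix;
    pairs spanning a gap marker are skipped, so data holes never masquerade
    as long steps.
    """
    if track.interval_s == HOURLY:
        timescale = "hourly"
    elif track.interval_s == DAILY:
        timescale = "daily"
    else:
        raise ParameterError(
            "displacement is defined for the hourly and daily tracks")
    f = track.frame
    ok = f["timestamp"].notna().to_numpy()
    adjacent = ok[:-1] & ok[1:]
    if not adjacent.any():
        return _estimates([])
    i = np.flatnonzero(adjacent)
    lon, lat = f["lon"].to_numpy(), f["lat"].to_numpy()
    d = great_circle_distance(lon[i], lat[i], lon[i + 1], lat[i + 1])
    d = np.atleast_1d(d)
    tt = f["target_time"]
    rows = [{
        "individual_id": track.individual_id,
        "trait": "displacement",
        "timescale": timescale,
        "window_start": tt.iloc[j],
        "window_end": tt.iloc[j + 1],
        "value": float(dist),
        "unit": TRAIT_UNITS["displacement"],
        "n_fixes": 2,
    } for j, dist in zip(i, d)]
    return _estimates(rows)


# ----------------------------------------------------------- max displacement

def _pairwise_max_m(lon: np.ndarray, lat: np.ndarray) -> float:
    d = great_circle_distance(lon[:, None], lat[:, None],
                              lon[None, :], lat[None, :])
    return float(np.max(d))


def max_displacement(track: RegularTrack, window: str,
                     thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Maximum over all pairwise (not just consecutive) fix distances per
    window — a capacity measure: how far apart the animal's positions got."""
    _require_interval(track, window, "max_displacement")
    thresholds = thresholds or ThresholdConfig()
    min_fixes = thresholds.fixes_for("max_displacement", window)
    sel = assign_windows(track, window)
    rows = []
    for (ws, we), g in sel.groupby(["window_start", "window_end"], sort=True):
        if len(g) < max(min_fixes, 2):
            continue
        rows.append({
            "individual_id": track.individual_id,
            "trait": "max_displacement",
            "timescale": window,
            "window_start": ws, "window_end": we,
            "value": _pairwise_max_m(g["lon"].to_numpy(), g["lat"].to_numpy()),
            "unit": TRAIT_UNITS["max_displacement"],
            "n_fixes": len(g),
        })
    return _estimates(rows)


# -------------------------------------------------------------------- 95% MCP

def project_window(lon: np.ndarray, lat: np.ndarray):
    """Project a point set to its local equal-area plane (metres), centred
    on the arithmetic lon/lat centroid. Exposed for oracle checks."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return azimuthal_equal_area(lon, lat, float(lon.mean()), float(lat.mean()))


def mcp_area(lon, lat, retain: float = 0.95) -> float:
    """Area (km^2) of the minimum convex polygon over the retained points.

    The classic centroid-peeling rule: project to a local equal-area plane,
    keep the ceil(retain * n) points nearest the projected centroid (ties
    broken by input order), and take the convex-hull area. Fewer than three
    non-collinear retained points give area 0.
    """
    if not (0 < retain <= 1):
        raise ParameterError("retain must be in (0, 1]")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    if n == 0:
        raise ParameterError("mcp_area needs at least one point")
    x, y = project_window(lon, lat)
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    keep = int(math.ceil(retain * n))
    if keep < n:
        d2 = (x - x.mean()) ** 2 + (y - y.mean()) ** 2
        order = np.argsort(d2, kind="stable")  # stable: input order breaks ties
        idx = np.sort(order[:keep])
        x, y = x[idx], y[idx]
    if len(x) < 3:
        return 0.0
    hull = MultiPoint(list(zip(x, y))).convex_hull
    return float(hull.area) / 1e6


def range_size_series(track: RegularTrack, window: str,
                      thresholds: ThresholdConfig | None = None,
                      retain: float = 0.95) -> pd.DataFrame:
    """95% MCP area per qualifying window (km^2)."""
    _require_interval(track, window, "range_size")
    thresholds = thresholds or ThresholdConfig()
    min_fixes = thresholds.fixes_for("range_size", window)
    sel = assign_windows(track, window)
    rows = []
    for (ws, we), g in sel.groupby(["window_start", "window_end"], sort=True):
        if len(g) < min_fixes:
            continue
        area = mcp_area(g["lon"].to_numpy(), g["lat"].to_numpy(), retain)
        rows.append({
            "individual_id": track.individual_id,
            "trait": "range_size",
            "timescale": window,
            "window_start": ws, "window_end": we,
            "value": area,
            "unit": TRAIT_UNITS["range_size"],
            "n_fixes": len(g),
        })
    return _estimates(rows)


# ----------------------------------------------------------- intensity of use

def intensity_of_use_series(track: RegularTrack, window: str,
                            thresholds: ThresholdConfig | None = None,
                            retain: float = 0.95) -> pd.DataFrame:
    """Cumulative gap-free path length divided by sqrt(95% MCP area).

    Dimensionless tortuosity-of-use measure: low for directed (e.g.
    migratory) movement, high for clustered movement. Windows whose MCP
    degenerates to zero area (all fixes identical or collinear) are skipped
    and logged — the ratio is undefined there.
    """
    _require_interval(track, window, "intensity_of_use")
    thresholds = thresholds or ThresholdConfig()
    min_fixes = thresholds.fixes_for("intensity_of_use", window)
    sel = assign_windows(track, window)
    rows = []
    for (ws, we), g in sel.groupby(["window_start", "window_end"], sort=True):
        if len(g) < min_fixes:
            continue
        gi = g["grid_idx"].to_numpy()
        adj = np.diff(gi) == 1  # consecutive grid slots: gap-free steps
        if not adj.any():
            continue
        lon, lat = g["lon"].to_numpy(), g["lat"].to_numpy()
        i = np.flatnonzero(adj)
        path = float(np.sum(np.atleast_1d(great_circle_distance(
            lon[i], lat[i], lon[i + 1], lat[i + 1]))))
        area_m2 = mcp_area(lon, lat, retain) * 1e6
        if area_m2 <= 0:
            logger.info("%s intensity_of_use %s window %s: degenerate MCP, "
                        "skipped", track.individual_id, window, ws)
            continue
        rows.append({
            "individual_id": track.individual_id,
            "trait": "intensity_of_use",
            "timescale": window,
            "window_start": ws, "window_end": we,
            "value": path / math.sqrt(area_m2),
            "unit": TRAIT_UNITS["intensity_of_use"],
            "n_fixes": len(g),
        })
    return _estimates(rows)


# ------------------------------------------------------------------ diurnality

def diurnality_index(track: RegularTrack,
                     thresholds: ThresholdConfig | None = None,
                     sun_threshold_deg: float = 0.0) -> pd.DataFrame:
    """Whole-track diurnality in [-1, 1].

    Each gap-free hourly step is classified day/night by the solar elevation
    at its start fix. With Md, Mn the summed day/night displacements and
    Hd, Hn the day/night step counts (exposure), the index is

        (Md/Hd - Mn/Hn) / (Md/Hd + Mn/Hn)

    i.e. the normalised contrast of movement *rates*, which conditions on
    day length: an animal tracked under long days is not called diurnal
    merely for being awake more hours. +1 = all movement in daylight,
    -1 = all at night. Tracks with no day or no night exposure (polar
    deployments) or no movement yield no estimate.
    """
    if track.interval_s != HOURLY:
        raise ParameterError("diurnality is computed from the hourly track")
    thresholds = thresholds or ThresholdConfig()
    min_steps = thresholds.fixes_for("diurnality", "whole_track")

    f = track.frame
    ok = f["timestamp"].notna().to_numpy()
    adjacent = ok[:-1] & ok[1:]
    i = np.flatnonzero(adjacent)
    if len(i) == 0 or len(i) < min_steps:
        return _estimates([])
    lon, lat = f["lon"].to_numpy(), f["lat"].to_numpy()
    step_m = np.atleast_1d(great_circle_distance(
        lon[i], lat[i], lon[i + 1], lat[i + 1]))
    start_times = f["timestamp"].iloc[i]
    elev = np.atleast_1d(sun_elevation(lat[i], lon[i], start_times))
    day = elev > sun_threshold_deg

    hd, hn = int(day.sum()), int((~day).sum())
    if hd == 0 or hn == 0:
        logger.info("%s diurnality: no %s exposure, skipped",
                    track.individual_id, "day" if hd == 0 else "night")
        return _estimates([])
    md, mn = float(step_m[day].sum()), float(step_m[~day].sum())
    if md == 0 and mn == 0:
        logger.info("%s diurnality: no movement, skipped", track.individual_id)
        return _estimates([])
    rate_d, rate_n = md / hd, mn / hn
    value = (rate_d - rate_n) / (rate_d + rate_n)
    sel = track.selected()
    return _estimates([{
        "individual_id": track.individual_id,
        "trait": "diurnality",
        "timescale": "whole_track",
        "window_start": sel["target_time"].iloc[0],
        "window_end": sel["target_time"].iloc[-1],
        "value": value,
        "unit": TRAIT_UNITS["diurnality"],
        "n_fixes": int(len(i)),
    }])


# ------------------------------------------------------------------ dispatcher

def compute_all_traits(hourly: RegularTrack, daily: RegularTrack,
                       thresholds: ThresholdConfig | None = None,
                       enabled: list[str] | None = None,
                       sun_threshold_deg: float = 0.0,
                       mcp_retain: float = 0.95) -> pd.DataFrame:
    """All enabled traits for one individual from its hourly + daily tracks."""
    thresholds = thresholds or ThresholdConfig()
    if enabled is None:
        enabled = ["displacement", "max_displacement", "range_size",
                   "intensity_of_use", "diurnality"]
    parts: list[pd.DataFrame] = []
    if "displacement" in enabled:
        parts.append(displacement_series(hourly))
        parts.append(displacement_series(daily))
    if "max_displacement" in enabled:
        parts.append(max_displacement(hourly, "daily", thresholds))
        parts.append(max_displacement(hourly, "weekly", thresholds))
        parts.append(max_displacement(daily, "annual", thresholds))
    if "range_size" in enabled:
        parts.append(range_size_series(hourly, "daily", thresholds, mcp_retain))
        parts.append(range_size_series(hourly, "weekly", thresholds, mcp_retain))
        parts.append(range_size_series(daily, "monthly", thresholds, mcp_retain))
        parts.append(range_size_series(daily, "annual", thresholds, mcp_retain))
    if "intensity_of_use" in enabled:
        parts.append(intensity_of_use_series(hourly, "daily", thresholds,
                                             mcp_retain))
        parts.append(intensity_of_use_series(daily, "monthly", thresholds,
                                             mcp_retain))
    if "diurnality" in enabled:
        parts.append(diurnality_index(hourly, thresholds, sun_threshold_deg))
    parts = [p for p in parts if len(p)]
    if not parts:
        return _estimates([])
    return pd.concat(parts, ignore_index=True)
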