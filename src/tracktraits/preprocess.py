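"""Fix cleaning and regularisation onto fixed-interval grids.

GPS deployments are sampled irregularly and with gaps; every windowed trait
downstream assumes a regular time series. ``resample_track`` therefore lays
a target grid (anchored at the first fix, so no fabricated clock rounding)
over the cleaned fixes and picks, per target, the temporally nearest unused
fix within a tolerance. Targets with no qualifying fix become explicit gap
markers — positions are never interpolated or invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CleaningParams
from .geometry import great_circle_distance

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class RegularTrack:
    """One individual's fixes snapped to a regular grid.

    ``frame`` has one row per grid target: ``target_time`` (UTC), and the
    selected fix's ``timestamp``/``lon``/``lat`` (NaT/NaN at gaps).
    """
    individual_id: str
    interval_s: int
    tolerance_s: int
    frame: pd.DataFrame

    @property
    def n_targets(self) -> int:
        return len(self.frame)

    @property
    def n_selected(self) -> int:
        return int(self.frame["timestamp"].notna().sum())

    @property
    def n_gaps(self) -> int:
        return self.n_targets - self.n_selected

    def selected(self) -> pd.DataFrame:
        """Grid rows that carry a fix (gap markers dropped)."""
        return self.frame[self.frame["timestamp"].notna()]


def clean_fixes(
    fixes: pd.DataFrame,
    params: CleaningParams | None = None,
    movement_mode: str = "unknown",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean one individual's fixes; returns (cleaned, report).

    Rules, in order: exact duplicate rows collapse to one; among distinct
    fixes sharing a timestamp the first in input order wins; if a speed
    ceiling is configured for ``movement_mode``, any fix whose implied
    speeds to *both* temporal neighbours exceed it is removed, iterating
    until stable (a single bad fix inflates two neighbouring speeds, so the
    two-sided rule removes the outlier, not its neighbours). Output is
    strictly time-ordered.
    """
    params = params or CleaningParams()
    report = {"duplicates": 0, "timestamp_conflicts": 0, "speed_filtered": 0}
    if len(fixes) == 0:
        return fixes.copy(), report

    df = fixes.reset_index(drop=True)
    before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "lon", "lat"], keep="first")
    report["duplicates"] = before - len(df)

    if params.drop_duplicate_timestamps:
        before = len(df)
        # stable sort preserves input order within a timestamp; keep first
        df = df.sort_values("timestamp", kind="mergesort")
        df = df.drop_duplicates(subset=["timestamp"], keep="first")
        report["timestamp_conflicts"] = before - len(df)
    else:
        df = df.sort_values("timestamp", kind="mergesort")
    df = df.reset_index(drop=True)

    limit = params.speed_limit(movement_mode)
    if limit is not None and len(df) > 2:
        while True:
            t = df["timestamp"].astype("int64").to_numpy() / 1e9
            d = great_circle_distance(df["lon"].to_numpy()[:-1],
                                      df["lat"].to_numpy()[:-1],
                                      df["lon"].to_numpy()[1:],
                                      df["lat"].to_numpy()[1:])
            dt = np.diff(t)
            speed = np.divide(d, dt, out=np.full_like(d, np.inf),
                              where=dt > 0)
            exceed = speed > limit
            # interior fix i has incoming speed[i-1] and outgoing speed[i]
            bad = np.zeros(len(df), dtype=bool)
            bad[1:-1] = exceed[:-1] & exceed[1:]
            if not bad.any():
                break
            report["speed_filtered"] += int(bad.sum())
            df = df[~bad].reset_index(drop=True)
            if len(df) <= 2:
                break
    return df, report


def resample_track(
    fixes: pd.DataFrame,
    interval_s: int,
    tolerance_s: int,
    individual_id: str | None = None,
) -> RegularTrack:
    """Snap cleaned, time-ordered fixes to a regular grid.

    The grid is anchored at the first fix's timestamp and extends to the
    last fix. Per target (in time order) the temporally nearest fix within
    ±``tolerance_s`` that has not already been claimed by an earlier target
    is selected; an earlier fix wins exact ties. Deterministic.
    """
    if interval_s <= 0:
        raise ParameterError("interval_s must be > 0")
    if tolerance_s < 0:
        raise ParameterError("tolerance_s must be >= 0")
    if individual_id is None:
        individual_id = (str(fixes["individual_id"].iloc[0])
                         if len(fixes) and "individual_id" in fixes else "")

    if len(fixes) == 0:
        frame = pd.DataFrame({
            "target_time": pd.DatetimeIndex([], tz="UTC"),
            "timestamp": pd.DatetimeIndex([], tz="UTC"),
            "lon": [], "lat": []})
        return RegularTrack(individual_id, interval_s, tolerance_s, frame)

    ts = fixes["timestamp"]
    t_ns = ts.astype("int64").to_numpy()
    if np.any(np.diff(t_ns) < 0):
        raise ParameterError("fixes must be time-ordered (run clean_fixes)")

    step = int(interval_s) * 1_000_000_000
    tol = int(tolerance_s) * 1_000_000_000
    n_targets = int((t_ns[-1] - t_ns[0]) // step) + 1
    targets = t_ns[0] + step * np.arange(n_targets, dtype=np.int64)

    used = np.zeros(len(t_ns), dtype=bool)
    chosen = np.full(n_targets, -1, dtype=np.int64)
    lo_all = np.searchsorted(t_ns, targets - tol, side="left")
    hi_all = np.searchsorted(t_ns, targets + tol, side="right")
    for k in range(n_targets):
        best = -1
        best_diff = tol + 1
        for j in range(lo_all[k], hi_all[k]):
            if used[j]:
                continue
            diff = abs(int(t_ns[j]) - int(targets[k]))
            if diff < best_diff:  # strict: earlier fix wins ties
                best, best_diff = j, diff
        if best >= 0:
            used[best] = True
            chosen[k] = best

    sel = chosen >= 0
    frame = pd.DataFrame({
        "target_time": pd.to_datetime(targets, utc=True),
        "timestamp": pd.Series(pd.NaT, index=range(n_targets),
                               dtype="datetime64[ns, UTC]"),
        "lon": np.nan,
        "lat": np.nan,
    })
    if sel.any():
        idx = chosen[sel]
        frame.loc[sel, "timestamp"] = ts.to_numpy()[idx]
        frame.loc[sel, "lon"] = fixes["lon"].to_numpy()[idx]
        frame.loc[sel, "lat"] = fixes["lat"].to_numpy()[idx]
    return RegularTrack(individual_id, interval_s, tolerance_s, frame)
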