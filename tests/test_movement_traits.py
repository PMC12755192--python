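import numpy as np
import pandas as pd
import pytest

from tracktraits.config import ThresholdConfig
from tracktraits.geometry import M_PER_DEG
from tracktraits.movement_traits import (diurnality_index,
                                         displacement_series,
                                         intensity_of_use_series,
                                         max_displacement, mcp_area,
                                         project_window, range_size_series)
from tracktraits.preprocess import ParameterError

from .conftest import (km_to_deg_lat, km_to_deg_lon, make_fixes, make_track,
                       square_perimeter_km)

LOW = ThresholdConfig(min_fixes={})  # no window minimums, for closed forms


# ------------------------------------------------------------- displacement

def test_stationary_track_gives_zero_displacements():
    track = make_track([10.0] * 5, [47.0] * 5)
    est = displacement_series(track)
    assert len(est) == 4
    assert (est["value"] == 0).all()
    assert (est["unit"] == "m").all()


def test_equator_hundredth_degree_steps():
    track = make_track([0.0, 0.01, 0.02], [0.0, 0.0, 0.0])
    est = displacement_series(track)
    assert len(est) == 2
    np.testing.assert_allclose(est["value"], 1111.9493, atol=0.01)


def test_displacement_skips_gap_spanning_pairs():
    f = make_fixes([0.0, 0.01, 0.03], [0.0, 0.0, 0.0])
    f.loc[2, "timestamp"] = pd.Timestamp("2024-06-01 03:00:00", tz="UTC")
    from tracktraits.preprocess import resample_track
    track = resample_track(f, 3600, 900)
    est = displacement_series(track)
    assert len(est) == 1  # only the 0h -> 1h pair; hour 2 is a gap
    assert est["window_start"].iloc[0].hour == 0


def test_displacement_requires_hourly_or_daily_track():
    track = make_track([0.0, 0.01], [0.0, 0.0], interval_s=604800)
    with pytest.raises(ParameterError):
        displacement_series(track)


# --------------------------------------------------------- max displacement

def test_collinear_march_daily_max_is_span():
    lons = [i * 0.01 for i in range(24)]
    track = make_track(lons, [0.0] * 24)
    est = max_displacement(track, "daily")
    assert len(est) == 1
    assert est["value"].iloc[0] == pytest.approx(23 * 1111.9493, abs=1.0)
    assert est["n_fixes"].iloc[0] == 24


def test_circle_max_is_diameter():
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    lons = [km_to_deg_lon(np.cos(a)) for a in ang]
    lats = [km_to_deg_lat(np.sin(a)) for a in ang]
    est = max_displacement(make_track(lons, lats), "daily", LOW)
    assert est["value"].iloc[0] == pytest.approx(2000.0, rel=1e-3)


def test_max_displacement_exceeds_consecutive_max():
    rng = np.random.default_rng(11)
    lons = np.cumsum(rng.normal(0, 0.001, 24))
    lats = np.cumsum(rng.normal(0, 0.001, 24))
    track = make_track(lons, lats)
    pairwise = max_displacement(track, "daily", LOW)["value"].iloc[0]
    consecutive = displacement_series(track)["value"].max()
    assert pairwise >= consecutive - 1e-9


def test_single_fix_window_yields_no_estimate():
    est = max_displacement(make_track([0.0], [0.0]), "daily", LOW)
    assert len(est) == 0
    with pytest.raises(ParameterError):
        max_displacement(make_track([0.0, 0.01], [0.0, 0.0]), "fortnightly")


def test_window_feed_mapping_enforced():
    daily_track = make_track([0.0, 0.01], [0.0, 0.0], interval_s=86400)
    with pytest.raises(ParameterError):
        max_displacement(daily_track, "daily")  # daily windows need hourly


# --------------------------------------------------------------------- MCP

def _shoelace_hull_area(x, y):
    """Independent oracle: monotone-chain convex hull + shoelace area."""
    pts = sorted(set(zip(x, y)))
    if len(pts) < 3:
        return 0.0

    def half(points):
        out = []
        for p in points:
            while len(out) >= 2:
                (x1, y1), (x2, y2) = out[-2], out[-1]
                if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) <= 0:
                    out.pop()
                else:
                    break
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    xs = np.array([p[0] for p in hull])
    ys = np.array([p[1] for p in hull])
    return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))


def test_mcp_unit_square():
    lons = [0, km_to_deg_lon(1), km_to_deg_lon(1), 0]
    lats = [0, 0, km_to_deg_lat(1), km_to_deg_lat(1)]
    assert mcp_area(lons, lats, retain=1.0) == pytest.approx(1.0, rel=1e-3)


def test_mcp_95_percent_drops_outlier():
    rng = np.random.default_rng(5)
    lons = list(km_to_deg_lon(1) * rng.random(19))
    lats = list(km_to_deg_lat(1) * rng.random(19))
    area_inliers = mcp_area(lons, lats, retain=1.0)
    lons.append(km_to_deg_lon(50.0))  # outlier 50 km east
    lats.append(0.0)
    area_95 = mcp_area(lons, lats, retain=0.95)  # ceil(0.95*20)=19 retained
    # brute-force check: the outlier is the farthest from the centroid
    x, y = project_window(np.array(lons), np.array(lats))
    d2 = (x - x.mean()) ** 2 + (y - y.mean()) ** 2
    assert np.argmax(d2) == 19
    assert area_95 == pytest.approx(area_inliers, rel=1e-2)
    assert area_95 < mcp_area(lons, lats, retain=1.0)


def test_mcp_degenerate_inputs():
    assert mcp_area([0.0, 0.01], [0.0, 0.0], retain=1.0) == 0.0
    assert mcp_area([0.0] * 5, [0.0] * 5) == 0.0
    with pytest.raises(ParameterError):
        mcp_area([0.0], [0.0], retain=1.5)
    with pytest.raises(ParameterError):
        mcp_area([], [])


def test_mcp_matches_brute_force_oracle_and_peel_monotone():
    """200 random point sets: shapely-backed area equals an independent
    monotone-chain + shoelace oracle in the projected plane (rel err
    <= 1e-9), and the 95% peel never exceeds the full hull."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = rng.integers(3, 31)
        lon0, lat0 = rng.uniform(-170, 170), rng.uniform(-60, 60)
        lons = lon0 + rng.normal(0, 0.02, n)
        lats = lat0 + rng.normal(0, 0.02, n)
        ours_km2 = mcp_area(lons, lats, retain=1.0)
        x, y = project_window(lons, lats)
        oracle_km2 = _shoelace_hull_area(x, y) / 1e6
        if oracle_km2 > 0:
            assert abs(ours_km2 - oracle_km2) / oracle_km2 <= 1e-9
        else:
            assert ours_km2 == 0.0
        assert mcp_area(lons, lats, 0.95) <= ours_km2 + 1e-12


# --------------------------------------------------------------- range size

def test_monthly_range_requires_14_daily_fixes():
    # 13 daily fixes -> nothing; 14 -> one estimate
    rng = np.random.default_rng(3)
    for n, expect in ((13, 0), (14, 1)):
        lons = rng.normal(0, 0.01, n)
        lats = rng.normal(0, 0.01, n)
        track = make_track(lons, lats, start="2024-06-01", interval_s=86400)
        est = range_size_series(track, "monthly")
        assert len(est) == expect


def test_range_size_of_identical_fixes_is_zero():
    track = make_track([5.0] * 20, [50.0] * 20, interval_s=86400)
    est = range_size_series(track, "monthly")
    assert est["value"].iloc[0] == 0.0


def test_range_size_equals_direct_mcp():
    rng = np.random.default_rng(9)
    lons = rng.normal(0, 0.01, 30)
    lats = rng.normal(0, 0.01, 30)
    track = make_track(lons, lats, start="2024-06-01", interval_s=86400)
    est = range_size_series(track, "monthly")
    assert est["value"].iloc[0] == pytest.approx(
        mcp_area(lons, lats, 0.95), rel=1e-12)


# ---------------------------------------------------------- intensity of use

def test_intensity_single_square_traversal_is_four():
    lons, lats = square_perimeter_km(1.0, laps=1)
    est = intensity_of_use_series(make_track(lons, lats), "daily", LOW)
    assert len(est) == 1
    assert est["value"].iloc[0] == pytest.approx(4.0, rel=0.01)


def test_intensity_double_traversal_is_eight():
    lons, lats = square_perimeter_km(1.0, laps=2)
    est = intensity_of_use_series(make_track(lons, lats), "daily", LOW)
    assert est["value"].iloc[0] == pytest.approx(8.0, rel=0.01)


def test_intensity_undefined_for_collinear_march():
    lons = [i * 0.01 for i in range(10)]
    est = intensity_of_use_series(make_track(lons, [0.0] * 10), "daily", LOW)
    assert len(est) == 0


# ----------------------------------------------------------------- diurnality

D_LOW = ThresholdConfig(min_fixes={"diurnality.whole_track": 1})


def _two_day_track(move_hours):
    """48 hourly fixes at the equator; the animal moves 500 m east during
    steps starting in ``move_hours`` (UTC), else holds position."""
    lon = 0.0
    lons = []
    for h in range(48):
        lons.append(lon)
        if h % 24 in move_hours:
            lon += 0.0045
    return make_track(lons, [0.0] * 48, start="2024-03-21 00:00:00")


def test_all_daytime_movement_is_plus_one():
    est = diurnality_index(_two_day_track(range(8, 16)), D_LOW)
    assert est["value"].iloc[0] == pytest.approx(1.0)


def test_all_night_movement_is_minus_one():
    est = diurnality_index(_two_day_track(list(range(0, 4))
                                          + list(range(20, 24))), D_LOW)
    assert est["value"].iloc[0] == pytest.approx(-1.0)


def test_uniform_movement_rate_is_zero():
    # identical displacement every hour: day and night rates are equal
    lons = [i * 0.0045 for i in range(48)]
    est = diurnality_index(make_track(lons, [0.0] * 48,
                                      start="2024-03-21 00:00:00"), D_LOW)
    assert est["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_diurnality_antisymmetric_under_day_night_swap():
    day = diurnality_index(_two_day_track(range(8, 16)), D_LOW)
    night = diurnality_index(_two_day_track(list(range(0, 4))
                                            + list(range(20, 24))), D_LOW)
    assert day["value"].iloc[0] == pytest.approx(-night["value"].iloc[0])


def test_diurnality_needs_both_exposures_and_movement():
    # polar winter: no daytime steps at all -> no estimate
    track = make_track([i * 0.001 for i in range(24)], [80.0] * 24,
                       start="2024-12-21 00:00:00")
    assert len(diurnality_index(track, D_LOW)) == 0
    # no movement at all -> no estimate
    still = make_track([0.0] * 48, [0.0] * 48, start="2024-03-21 00:00:00")
    assert len(diurnality_index(still, D_LOW)) == 0
    # below the minimum classified-step threshold -> no estimate
    assert len(diurnality_index(_two_day_track(range(8, 16)))) == 0


def test_diurnality_requires_hourly_track():
    track = make_track([0.0, 0.01], [0.0, 0.0], interval_s=86400)
    with pytest.raises(ParameterError):
        diurnality_index(track)


# -------------------------------------------------------- shift invariance

def test_traits_invariant_to_whole_week_time_shift():
    """Shifting all timestamps by an integer number of weeks changes no
    daily/weekly trait value (diurnality exempt: it tracks solar time)."""
    rng = np.random.default_rng(21)
    lons = np.cumsum(rng.normal(0, 0.003, 72))
    lats = np.cumsum(rng.normal(0, 0.003, 72))
    a = make_track(lons, lats, start="2024-06-01 00:00:00")
    b = make_track(lons, lats, start="2024-06-15 00:00:00")  # +2 weeks
    for series in (
        lambda t: displacement_series(t)["value"],
        lambda t: max_displacement(t, "daily", LOW)["value"],
        lambda t: range_size_series(t, "daily", LOW)["value"],
        lambda t: intensity_of_use_series(t, "daily", LOW)["value"],
        lambda t: max_displacement(t, "weekly", LOW)["value"],
    ):
        np.testing.assert_allclose(series(a), series(b), rtol=1e-12)
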