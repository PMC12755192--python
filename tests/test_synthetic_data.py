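import numpy as np
import pandas as pd
import pytest

from tracktraits.config import MigrationLeg, SimulationParams, ThresholdConfig
from tracktraits.movement_traits import diurnality_index, displacement_series
from tracktraits.preprocess import resample_track
from tracktraits.synthetic_data import (expected_traits, simulate_deployment,
                                        simulate_track)


def test_same_seed_reproduces_fixes_exactly():
    p = SimulationParams(duration_days=3, gap_rate=0.1, noise_sd_m=20, seed=9)
    a = simulate_track(p)
    b = simulate_track(p)
    pd.testing.assert_frame_equal(a, b)


def test_fix_count_inclusive_endpoints():
    p = SimulationParams(duration_days=10, gap_rate=0.0, seed=1)
    assert len(simulate_track(p)) == 241


def test_gap_rate_drops_fixes():
    p = SimulationParams(duration_days=20, gap_rate=0.3, seed=2)
    n = len(simulate_track(p))
    assert 0.6 * 481 < n < 0.8 * 481


def test_mean_step_recovers_gamma_mean():
    """k*theta = 500 m, rho = 0, no noise, 10,000 steps: the sample mean
    hourly displacement lands within 3 standard errors of 500 m
    (SE = 500 / (sqrt(k) * sqrt(n)))."""
    p = SimulationParams(step_shape=2.0, step_scale_m=250.0,
                         turn_concentration=0.0, duration_days=10000 / 24,
                         seed=12)
    fixes = simulate_track(p)
    track = resample_track(fixes, 3600, 900)
    est = displacement_series(track)
    se = 500.0 / (np.sqrt(2.0) * np.sqrt(len(est)))
    assert abs(est["value"].mean() - 500.0) < 3 * se


def test_expected_traits_closed_forms():
    p = SimulationParams(step_shape=2.0, step_scale_m=250.0)
    exp = expected_traits(p)
    assert exp["expected_hourly_displacement_m"] == pytest.approx(500.0,
                                                                  rel=0.02)
    assert exp["expected_diurnality"] == 0.0
    p4 = p.model_copy(update={"day_activity_multiplier": 4.0})
    assert expected_traits(p4)["expected_diurnality"] == pytest.approx(0.6)
    # rho=0 RMS net displacement: sqrt(m k (k+1) theta^2)
    rms = exp["rms_net_displacement"](100)
    assert rms == pytest.approx(np.sqrt(100 * 2 * 3 * 250.0 ** 2), rel=0.02)
    rho = SimulationParams(turn_concentration=0.5)
    assert expected_traits(rho)["rms_net_displacement"](10) is None


def test_rms_net_displacement_matches_simulation():
    """CLT cross-check of the closed form: net displacement after m steps of
    an uncorrelated walk, averaged over independent replicates."""
    from tracktraits.geometry import great_circle_distance
    p = SimulationParams(step_shape=2.0, step_scale_m=250.0,
                         duration_days=200 / 24, seed=31)
    expected = expected_traits(p)["rms_net_displacement"](200)
    nets = []
    for s in range(40):
        fixes = simulate_track(p.model_copy(update={"seed": 100 + s}))
        nets.append(great_circle_distance(
            fixes["lon"].iloc[0], fixes["lat"].iloc[0],
            fixes["lon"].iloc[-1], fixes["lat"].iloc[-1]))
    rms = float(np.sqrt(np.mean(np.square(nets))))
    assert rms == pytest.approx(expected, rel=0.25)  # 40 replicates


def test_diurnality_monotone_in_day_activity():
    th = ThresholdConfig(min_fixes={"diurnality.whole_track": 100})
    values = []
    for delta in (0.5, 1.0, 2.0, 4.0):
        p = SimulationParams(duration_days=20, day_activity_multiplier=delta,
                             seed=5)
        track = resample_track(simulate_track(p), 3600, 900)
        values.append(diurnality_index(track, th)["value"].iloc[0])
    assert values == sorted(values)
    assert values[0] < 0 < values[2] < values[3]


def test_migration_lowers_whole_track_intensity_of_use():
    """With the same seed the gamma step draws — hence the cumulative path —
    are identical, but a mid-track migration leg stretches the hull into a
    long corridor, so path / sqrt(MCP area) drops: straighter movement,
    lower intensity of use."""
    from tracktraits.movement_traits import mcp_area

    def whole_track_iou(params):
        fixes = simulate_track(params)
        track = resample_track(fixes, 3600, 900)
        path_m = displacement_series(track)["value"].sum()
        area_m2 = mcp_area(fixes["lon"], fixes["lat"], 0.95) * 1e6
        return path_m / np.sqrt(area_m2)

    for seed in (8, 9, 10):
        base = dict(duration_days=30, step_shape=2.0, step_scale_m=250.0,
                    turn_concentration=0.0, seed=seed)
        resident = SimulationParams(**base)
        migrant = SimulationParams(
            migration=MigrationLeg(start_day=12, length_days=6,
                                   heading_deg=45.0, bias_strength=0.95),
            **base)
        assert whole_track_iou(migrant) < whole_track_iou(resident)


def test_deployment_tables_are_consistent():
    p = SimulationParams(n_individuals=3, duration_days=2, seed=6,
                         species="Testus examplei")
    locations, reference, truth = simulate_deployment(p)
    assert reference["individual_id"].is_unique
    assert set(locations["individual-local-identifier"]) == set(
        reference["individual_id"]) == set(truth["individual_id"])
    assert len(locations) == 3 * 49
    assert (truth["expected_hourly_displacement_m"] > 0).all()
    # different individuals take different paths
    by_ind = locations.groupby("individual-local-identifier")
    finals = by_ind["location-long"].last()
    assert finals.nunique() == 3


def test_noise_inflates_observed_steps():
    quiet = SimulationParams(duration_days=30, seed=13, noise_sd_m=0.0,
                             step_shape=2.0, step_scale_m=25.0)
    noisy = quiet.model_copy(update={"noise_sd_m": 200.0})
    d_quiet = displacement_series(
        resample_track(simulate_track(quiet), 3600, 900))["value"].mean()
    d_noisy = displacement_series(
        resample_track(simulate_track(noisy), 3600, 900))["value"].mean()
    assert d_noisy > d_quiet * 2
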