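"""Synthetic GPS deployments with known ground truth.

Movement model: a correlated random walk on the sphere. Per step, length is
drawn from Gamma(shape k, scale theta metres) — multiplied by the day
activity factor delta when the step starts in daylight (same solar
classifier the diurnality trait uses, so recovery tests are
self-consistent) — and the heading accumulates a wrapped-Cauchy innovation
with concentration rho (rho = 0: uncorrelated turning; rho -> 1: straight).
During an optional migration leg, headings are instead drawn around a fixed
bias heading, producing the directed, low-tortuosity movement typical of
migrations. Fixes can be dropped independently (data gaps) and jittered with
isotropic Gaussian noise in the local tangent plane (location error).

Steps advance positions in the local tangent plane converted to lon/lat
increments — adequate for step lengths far below the Earth radius; latitude
is capped at ±85 degrees where the metric would blow up.

Everything is reproducible from the seed, and ``expected_traits`` returns
the closed-form expectations the generator implies, so pipeline tests have
an analytic target rather than a circular re-simulation.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationParams
from .geometry import M_PER_DEG
from .solar import sun_elevation

TRUTH_COLUMNS = [
    "individual_id", "species", "step_shape", "step_scale_m",
    "turn_concentration", "day_activity_multiplier", "gap_rate", "noise_sd_m",
    "expected_hourly_displacement_m", "expected_diurnality",
]


def _wrapped_cauchy(rng: np.random.Generator, rho: float, n: int = 1):
    """Wrapped-Cauchy(0, rho) angles via the inverse-CDF transform."""
    u = rng.random(n)
    if rho == 0:
        return (u - 0.5) * 2.0 * np.pi
    return 2.0 * np.arctan(((1 - rho) / (1 + rho))
                           * np.tan(np.pi * (u - 0.5)))


def _day_shares(params: SimulationParams) -> tuple[float, float]:
    """Expected day/night shares of step starts, evaluated at the origin
    over the deployment's time grid (deterministic, no simulation)."""
    n_steps = int(round(params.duration_days * 86400 / params.interval_s))
    t0 = pd.Timestamp(params.start_time)
    times = t0 + pd.to_timedelta(
        np.arange(n_steps) * params.interval_s, unit="s")
    elev = sun_elevation(params.origin_lat, params.origin_lon, times)
    hd = float(np.mean(np.atleast_1d(elev) > 0))
    return hd, 1.0 - hd


def expected_traits(params: SimulationParams) -> dict:
    """Closed-form expectations implied by the generator parameters.

    - mean hourly displacement: k*theta weighted by the day/night mix,
      E = k*theta * (hd*delta + hn) / (hd + hn)
    - diurnality: rates are k*theta*delta (day) vs k*theta (night), so the
      normalised contrast is (delta - 1) / (delta + 1)
    - RMS net displacement after m steps (rho = 0 only): sqrt(m * E[L^2]),
      E[L^2] = k(k+1)theta^2 mixed over regimes.

    Quantities without a closed form (MCP areas, pairwise maxima under
    persistence) are reported as None.
    """
    k, th = params.step_shape, params.step_scale_m
    d = params.day_activity_multiplier
    hd, hn = _day_shares(params)
    expected_step = k * th * (hd * d + hn)
    expected_diurnality = (d - 1.0) / (d + 1.0) if (hd > 0 and hn > 0) else None

    def rms_net_displacement(m: int) -> float | None:
        if params.turn_concentration != 0:
            return None
        e_l2 = k * (k + 1) * th * th * (hd * d * d + hn)
        return math.sqrt(m * e_l2)

    return {
        "expected_hourly_displacement_m": (
            expected_step if params.interval_s == 3600 else None),
        "expected_step_m": expected_step,
        "expected_diurnality": expected_diurnality,
        "day_share": hd,
        "rms_net_displacement": rms_net_displacement,
        "expected_range_size_km2": None,
        "expected_max_displacement_m": None,
    }


def simulate_track(params: SimulationParams,
                   individual_id: str = "sim_001",
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one individual; returns a fix DataFrame
    (individual_id, timestamp UTC, lon, lat), gaps already dropped and
    noise applied."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration_days * 86400 / params.interval_s))
    t0 = pd.Timestamp(params.start_time)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    times = t0 + pd.to_timedelta(
        np.arange(n_steps + 1) * params.interval_s, unit="s")
    unix0 = times[0].value / 1e9

    lon = np.empty(n_steps + 1)
    lat = np.empty(n_steps + 1)
    lon[0], lat[0] = params.origin_lon, params.origin_lat

    heading = float(rng.uniform(0.0, 2.0 * np.pi))
    mig = params.migration
    steps = rng.gamma(params.step_shape, params.step_scale_m, size=n_steps)
    turns = np.asarray(_wrapped_cauchy(rng, params.turn_concentration,
                                       n_steps))
    mig_turns = (np.asarray(_wrapped_cauchy(rng, mig.bias_strength, n_steps))
                 if mig is not None else None)

    for i in range(n_steps):
        t_days = i * params.interval_s / 86400.0
        if mig is not None and mig.start_day <= t_days < (mig.start_day
                                                          + mig.length_days):
            heading = math.radians(mig.heading_deg) + float(mig_turns[i])
        else:
            heading = heading + float(turns[i])
        length = float(steps[i])
        if params.day_activity_multiplier != 1.0:
            elev = sun_elevation(lat[i], lon[i], times[i])
            if elev > 0:
                length *= params.day_activity_multiplier
        d_north = length * math.cos(heading)
        d_east = length * math.sin(heading)
        new_lat = lat[i] + d_north / M_PER_DEG
        new_lat = min(85.0, max(-85.0, new_lat))
        new_lon = lon[i] + d_east / (M_PER_DEG
                                     * math.cos(math.radians(new_lat)))
        new_lon = ((new_lon + 180.0) % 360.0) - 180.0
        lon[i + 1], lat[i + 1] = new_lon, new_lat

    if params.noise_sd_m > 0:
        lat_noisy = lat + rng.normal(0, params.noise_sd_m,
                                     n_steps + 1) / M_PER_DEG
        lon_noisy = lon + (rng.normal(0, params.noise_sd_m, n_steps + 1)
                           / (M_PER_DEG * np.cos(np.radians(lat))))
    else:
        lat_noisy, lon_noisy = lat, lon

    keep = np.ones(n_steps + 1, dtype=bool)
    if params.gap_rate > 0:
        keep = rng.random(n_steps + 1) >= params.gap_rate

    return pd.DataFrame({
        "individual_id": individual_id,
        "timestamp": times[keep],
        "lon": lon_noisy[keep],
        "lat": lat_noisy[keep],
    })


def simulate_deployment(
    params: SimulationParams,
    id_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate ``params.n_individuals`` individuals of one species.

    Returns (locations, reference, truth): a Movebank-dialect location
    table, the per-individual reference metadata, and the sidecar truth
    table with the generator parameters and analytic expectations per
    individual.
    """
    if id_prefix is None:
        parts = params.species.split()
        id_prefix = ("".join(p[0] for p in parts[:2]) or "sim").lower()
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_individuals)
    exp = expected_traits(params)
    locs, ref_rows, truth_rows = [], [], []
    for i, ss in enumerate(seeds):
        ind = f"{id_prefix}_{i + 1:03d}"
        rng = np.random.default_rng(ss)
        fixes = simulate_track(params, individual_id=ind, rng=rng)
        locs.append(fixes)
        ref_rows.append({
            "individual_id": ind, "species": params.species,
            "taxon_class": "other", "movement_mode": "walk",
            "sex": ("f", "m")[i % 2], "age": "adult",
            "body_mass_g": "", "data_owner": "synthetic",
        })
        truth_rows.append({
            "individual_id": ind, "species": params.species,
            "step_shape": params.step_shape,
            "step_scale_m": params.step_scale_m,
            "turn_concentration": params.turn_concentration,
            "day_activity_multiplier": params.day_activity_multiplier,
            "gap_rate": params.gap_rate, "noise_sd_m": params.noise_sd_m,
            "expected_hourly_displacement_m":
                exp["expected_hourly_displacement_m"],
            "expected_diurnality": exp["expected_diurnality"],
        })
    fixes = pd.concat(locs, ignore_index=True)
    locations = pd.DataFrame({
        "timestamp": fixes["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
        "location-long": fixes["lon"],
        "location-lat": fixes["lat"],
        "individual-local-identifier": fixes["individual_id"],
        "individual-taxon-canonical-name": params.species,
    })
    return (locations, pd.DataFrame(ref_rows),
            pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS))


def write_deployment(locations: pd.DataFrame, reference: pd.DataFrame,
                     truth: pd.DataFrame, out_dir: str | Path
                     ) -> dict[str, Path]:
    """Write the simulated tables (locations.csv, reference.csv, truth.csv)
    in the same dialect ``tracking_io`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"locations": out / "locations.csv",
             "reference": out / "reference.csv",
             "truth": out / "truth.csv"}
    locations.to_csv(paths["locations"], index=False)
    reference.to_csv(paths["reference"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
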