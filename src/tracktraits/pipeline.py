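"""Build orchestration: raw location table -> three-tier trait database.

Stages: read -> clean -> resample (hourly/daily/weekly) -> trait metrics ->
tier summaries -> annotation (tracking period, diffused mean coordinate,
reference metadata) -> write. The run report records per-stage counts and
echoes the fully resolved configuration, so a build is reproducible from its
report alone. Any stage failure aborts the run before anything is written —
no partial databases are left on disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DAILY, HOURLY, WEEKLY, BuildConfig
from .database import INDIVIDUAL_LEVEL_COLUMNS, TraitDatabase
from .geo_privacy import diffuse_coordinate, mean_coordinate, tracking_period
from .movement_traits import ESTIMATE_COLUMNS, compute_all_traits
from .preprocess import clean_fixes, resample_track
from .summarize import (assemble_database, build_individual_tier,
                        build_species_tier)
from .tracking_io import (REFERENCE_COLUMNS, read_locations, read_reference,
                          write_database)

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


def _default_reference(fixes: pd.DataFrame) -> pd.DataFrame:
    """Reference table inferred from the location file when none is given:
    species from the taxon column if present, all enums unknown."""
    ids = fixes["individual_id"].drop_duplicates()
    if "species" in fixes.columns:
        species = fixes.groupby("individual_id", sort=False)["species"].first()
        species = ids.map(species)
    else:
        species = pd.Series(["unknown"] * len(ids), index=ids.index)
    ref = pd.DataFrame({"individual_id": ids.to_numpy(),
                        "species": species.to_numpy()})
    ref["common_name"] = ""
    ref["taxon_class"] = "other"
    ref["movement_mode"] = "unknown"
    ref["sex"] = "unknown"
    ref["age"] = ""
    ref["body_mass_g"] = np.nan
    ref["data_owner"] = ""
    return ref[REFERENCE_COLUMNS]


def run_build(config: BuildConfig,
              locations_path: str | Path,
              reference_path: str | Path | None = None,
              out_dir: str | Path | None = None
              ) -> tuple[TraitDatabase, dict]:
    """Execute a full build; optionally write the database + run report.

    Returns (database, report). The report's ``config`` key is the resolved
    configuration; re-running with it and the same inputs is byte-identical.
    """
    logging.basicConfig(level=config.log_level)
    report: dict = {"stages": {}, "config": config.model_dump(mode="json"),
                    "inputs": {"locations": str(locations_path),
                               "reference": (str(reference_path)
                                             if reference_path else None)}}

    try:
        fixes, rejects = read_locations(locations_path, config.column_map,
                                        config.timezone_policy)
    except Exception as e:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError("read_locations", str(e)) from e
    report["stages"]["read"] = {
        "rows_read": rejects.n_read,
        "rows_accepted": rejects.n_accepted,
        "rows_rejected": rejects.n_rejected,
        "rejections_by_reason": rejects.counts_by_reason(),
    }

    try:
        if reference_path is not None:
            reference = read_reference(reference_path)
        else:
            reference = _default_reference(fixes)
    except Exception as e:
        raise PipelineError("read_reference", str(e)) from e
    ref_by_id = reference.set_index("individual_id")

    estimates_parts: list[pd.DataFrame] = []
    annotation_rows: list[dict] = []
    clean_counts: dict[str, dict] = {}
    track_counts: dict[str, dict] = {}
    for ind, ind_fixes in fixes.groupby("individual_id", sort=True):
        mode = (str(ref_by_id.loc[ind, "movement_mode"])
                if ind in ref_by_id.index else "unknown")
        try:
            cleaned, crep = clean_fixes(ind_fixes, config.cleaning, mode)
        except Exception as e:
            raise PipelineError("clean", f"{ind}: {e}") from e
        clean_counts[ind] = crep
        if len(cleaned) == 0:
            continue
        try:
            tracks = {iv: resample_track(cleaned, iv,
                                         config.resample.tolerance(iv), ind)
                      for iv in (HOURLY, DAILY, WEEKLY)}
        except Exception as e:
            raise PipelineError("resample", f"{ind}: {e}") from e
        track_counts[ind] = {
            "n_cleaned_fixes": len(cleaned),
            **{f"selected_{name}": tracks[iv].n_selected
               for iv, name in ((HOURLY, "hourly"), (DAILY, "daily"),
                                (WEEKLY, "weekly"))}}
        try:
            est = compute_all_traits(
                tracks[HOURLY], tracks[DAILY],
                thresholds=config.thresholds,
                enabled=config.traits.enabled,
                sun_threshold_deg=config.traits.sun_threshold_deg,
                mcp_retain=config.traits.mcp_retain)
        except Exception as e:
            raise PipelineError("traits", f"{ind}: {e}") from e
        if len(est):
            estimates_parts.append(est)

        period = tracking_period(cleaned)
        mlon, mlat = mean_coordinate(cleaned)
        try:
            dlon, dlat = diffuse_coordinate(mlon, mlat, config.grid)
        except ValueError:
            dlon, dlat = np.nan, np.nan  # polar track: no cell defined
        ann = {"individual_id": ind,
               "track_start": period.start.isoformat(),
               "track_end": period.end.isoformat(),
               "track_days": period.length_days,
               "mean_lon_diffused": dlon, "mean_lat_diffused": dlat,
               "grid_cell_area_km2": config.grid.cell_area_km2}
        if ind in ref_by_id.index:
            r = ref_by_id.loc[ind]
            ann.update({k: r[k] for k in
                        ("taxon_class", "movement_mode", "sex", "age",
                         "data_owner")})
            ann["body_mass_g"] = r["body_mass_g"]
            ann["species"] = r["species"]
        else:
            ann.update({"taxon_class": "other", "movement_mode": "unknown",
                        "sex": "unknown", "age": "", "body_mass_g": np.nan,
                        "data_owner": "", "species": "unknown"})
        annotation_rows.append(ann)

    estimates = (pd.concat(estimates_parts, ignore_index=True)
                 if estimates_parts else
                 pd.DataFrame(columns=ESTIMATE_COLUMNS))
    annotation = pd.DataFrame(annotation_rows)
    species_map = (annotation.set_index("individual_id")["species"]
                   if len(annotation) else pd.Series(dtype=object))
    if len(estimates):
        estimates.insert(1, "species",
                         estimates["individual_id"].map(species_map))
        for col in ("window_start", "window_end"):
            estimates[col] = pd.to_datetime(estimates[col], utc=True
                                            ).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    else:
        estimates.insert(1, "species", pd.Series(dtype=object))

    try:
        individual_tier = build_individual_tier(estimates, config.thresholds)
        if len(individual_tier):
            individual_tier = individual_tier.merge(annotation,
                                                    on="individual_id",
                                                    how="left")
        else:
            individual_tier = individual_tier.reindex(
                columns=INDIVIDUAL_LEVEL_COLUMNS)
        individual_tier = individual_tier.reindex(
            columns=INDIVIDUAL_LEVEL_COLUMNS)
        species_tier = build_species_tier(individual_tier, config.thresholds)
        db = assemble_database(estimates, individual_tier, species_tier,
                               config.thresholds)
    except Exception as e:
        raise PipelineError("summarize", str(e)) from e

    report["stages"]["clean"] = clean_counts
    report["stages"]["resample"] = track_counts
    report["stages"]["traits"] = {
        "n_estimates": int(len(estimates)),
        "estimates_per_trait": (
            estimates.groupby("trait").size().to_dict()
            if len(estimates) else {}),
    }
    report["stages"]["summarize"] = {
        "n_individual_rows": int(len(db.individual_level)),
        "n_species_rows": int(len(db.species_level)),
        "n_individuals": int(db.individual_level["individual_id"].nunique())
        if len(db.individual_level) else 0,
        "n_species": int(db.species_level["species"].nunique())
        if len(db.species_level) else 0,
    }

    if out_dir is not None:
        try:
            paths = write_database(db, out_dir)
            with open(Path(out_dir) / "run_report.json", "w",
                      encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, default=str)
        except Exception as e:
            raise PipelineError("write", str(e)) from e
        report["outputs"] = {k: str(v) for k, v in paths.items()}
    return db, report


def run_summarize(estimates: pd.DataFrame, config: BuildConfig
                  ) -> TraitDatabase:
    """Re-aggregate an existing within-individual table into the upper two
    tiers (no trait recomputation; annotation columns stay blank)."""
    individual_tier = build_individual_tier(estimates, config.thresholds)
    if len(individual_tier):
        species_map = estimates.groupby("individual_id")["species"].first()
        individual_tier.insert(1, "species",
                               individual_tier["individual_id"].map(species_map))
    individual_tier = individual_tier.reindex(columns=INDIVIDUAL_LEVEL_COLUMNS)
    species_tier = build_species_tier(individual_tier, config.thresholds)
    return assemble_database(estimates, individual_tier, species_tier,
                             config.thresholds)
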