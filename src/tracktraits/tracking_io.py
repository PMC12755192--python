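"""Read Movebank-dialect location and reference tables; write the database.

Location tables are comma-delimited UTF-8 with the Movebank export headers
by default (``timestamp``, ``location-long``, ``location-lat``,
``individual-local-identifier``, ``individual-taxon-canonical-name``); a
``column_map`` overrides them for other dialects. Malformed rows (bad
coordinates, unparseable timestamps) are rejected individually and counted —
biologging exports routinely contain empty-location rows, and a single bad
row must not sink a deployment.

In-memory representation: fixes are a pandas DataFrame with columns
``individual_id`` (str), ``timestamp`` (tz-aware UTC), ``lon``, ``lat``
(decimal degrees WGS84) and optionally ``species``, sorted by individual
then time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .database import TIER_COLUMNS, TraitDatabase

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["individual_id", "timestamp", "lon", "lat"]

#: Movebank export header -> canonical fix column
DEFAULT_COLUMN_MAP = {
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "individual-local-identifier": "individual_id",
    "individual-taxon-canonical-name": "species",
}

TAXON_CLASSES = {"mammal", "bird", "other"}
MOVEMENT_MODES = {"walk", "fly", "swim", "unknown"}
SEXES = {"f", "m", "unknown"}

REFERENCE_COLUMNS = [
    "individual_id", "species", "common_name", "taxon_class",
    "movement_mode", "sex", "age", "body_mass_g", "data_owner",
]


class ConfigurationError(Exception):
    """Input table does not match the declared dialect."""


@dataclass
class RejectionReport:
    """Per-file account of rows that failed validation."""
    n_read: int = 0
    n_accepted: int = 0
    rejections: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def reject(self, row_index: int, reason: str) -> None:
        self.rejections.append({"row": int(row_index), "reason": reason})

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rejections:
            out[r["reason"]] = out.get(r["reason"], 0) + 1
        return out


def read_locations(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    timezone_policy: str = "utc",
) -> tuple[pd.DataFrame, RejectionReport]:
    """Read a location table into a validated fix DataFrame.

    ``column_map`` maps source headers to canonical names (the Movebank
    export dialect is the default). Naive timestamps are interpreted
    according to ``timezone_policy`` ("utc" — the Movebank convention — or
    an IANA zone name to localise from). Returns the fixes plus a
    :class:`RejectionReport`; rejected rows are logged, never silently
    dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=[""], encoding="utf-8")
    report = RejectionReport(n_read=len(raw))
    if len(raw) == 0:
        logger.warning("location file %s is empty", path)
        return pd.DataFrame(columns=FIX_COLUMNS), report

    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    have = set(present.values())
    for required in ("timestamp", "lon", "lat", "individual_id"):
        if required not in have:
            src = [s for s, d in cmap.items() if d == required]
            raise ConfigurationError(
                f"missing column: no source column for {required!r} "
                f"(expected one of {src}) in {path}")

    df = raw[list(present)].rename(columns=present)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=False,
                        format="ISO8601")
    # timezone resolution: naive stamps get the declared zone, then -> UTC
    if getattr(ts.dt, "tz", None) is None:
        zone = "UTC" if timezone_policy == "utc" else timezone_policy
        ts = ts.dt.tz_localize(zone, ambiguous=False,
                               nonexistent="shift_forward")
    ts = ts.dt.tz_convert("UTC")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")

    bad_ts = ts.isna()
    bad_coord = (
        lon.isna() | lat.isna()
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    )
    bad_id = df["individual_id"].isna()
    for idx in df.index[bad_ts]:
        report.reject(idx, "unparseable timestamp")
    for idx in df.index[~bad_ts & bad_coord]:
        report.reject(idx, "invalid coordinates")
    for idx in df.index[~bad_ts & ~bad_coord & bad_id]:
        report.reject(idx, "missing individual_id")

    keep = ~(bad_ts | bad_coord | bad_id)
    fixes = pd.DataFrame({
        "individual_id": df.loc[keep, "individual_id"].astype(str),
        "timestamp": ts[keep],
        "lon": lon[keep].astype(float),
        "lat": lat[keep].astype(float),
    })
    if "species" in df.columns:
        fixes["species"] = df.loc[keep, "species"].astype(str)
    fixes = fixes.sort_values(["individual_id", "timestamp"],
                              kind="mergesort").reset_index(drop=True)
    report.n_accepted = len(fixes)
    if report.n_rejected:
        logger.info("%s: rejected %d/%d rows (%s)", path, report.n_rejected,
                    report.n_read, report.counts_by_reason())
    return fixes, report


def read_reference(path: str | Path) -> pd.DataFrame:
    """Read the per-individual reference metadata table.

    Requires ``individual_id`` and ``species`` columns; unknown enum values
    (taxon_class, movement_mode, sex) map to "unknown" with a warning.
    Duplicate individual identifiers are an error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""],
                      encoding="utf-8")
    for required in ("individual_id", "species"):
        if required not in raw.columns:
            raise ConfigurationError(
                f"missing column: {required!r} in reference table {path}")
    dupes = raw["individual_id"][raw["individual_id"].duplicated()]
    if len(dupes):
        raise ConfigurationError(
            "duplicate individual_id in reference table: "
            + ", ".join(sorted(set(dupes))))
    if raw["species"].isna().any():
        raise ConfigurationError("reference table has empty species values")

    out = pd.DataFrame({"individual_id": raw["individual_id"].astype(str),
                        "species": raw["species"].astype(str)})
    for col, allowed, default in (
        ("taxon_class", TAXON_CLASSES, "other"),
        ("movement_mode", MOVEMENT_MODES, "unknown"),
        ("sex", SEXES, "unknown"),
    ):
        if col in raw.columns:
            vals = raw[col].fillna(default).str.lower()
            bad = ~vals.isin(allowed)
            if bad.any():
                logger.warning("reference %s: unknown %s values %s -> %s",
                               path, col, sorted(set(vals[bad])),
                               "unknown" if "unknown" in allowed else default)
                vals = vals.where(~bad,
                                  "unknown" if "unknown" in allowed else default)
            out[col] = vals
        else:
            out[col] = default if col == "taxon_class" else "unknown"
    out["common_name"] = raw.get("common_name", pd.Series(dtype=str))
    out["age"] = raw.get("age", pd.Series(dtype=str))
    out["body_mass_g"] = pd.to_numeric(raw.get("body_mass_g"), errors="coerce")
    out["data_owner"] = raw.get("data_owner", pd.Series(dtype=str))
    return out[REFERENCE_COLUMNS]


def write_database(db: TraitDatabase, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tier tables as CSV; returns {tier: path}.

    Numeric values are written with 10 significant digits so a read-back
    reproduces the database well past the 6-significant-digit contract.
    Empty tiers produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tier, frame in db.tiers().items():
        cols = TIER_COLUMNS[tier]
        frame = frame.reindex(columns=cols)
        p = out_dir / f"{tier}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        paths[tier] = p
    return paths


def read_database(out_dir: str | Path) -> TraitDatabase:
    """Read back a written database (round-trip counterpart of
    :func:`write_database`)."""
    out_dir = Path(out_dir)
    frames = {}
    for tier, cols in TIER_COLUMNS.items():
        p = out_dir / f"{tier}.csv"
        frames[tier] = pd.read_csv(p).reindex(columns=cols)
    return TraitDatabase(**frames)
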