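"""The three-tier trait database container and its flat-table schema.

Tiers
-----
within_individual : repeated, time-windowed trait estimates per individual
individual_level  : per-individual summary statistics plus annotation
species_level     : unweighted aggregation of individual summaries
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

WITHIN_INDIVIDUAL_COLUMNS = [
    "individual_id", "species", "trait", "timescale",
    "window_start", "window_end", "value", "unit", "n_fixes",
]

INDIVIDUAL_LEVEL_COLUMNS = [
    "individual_id", "species", "trait", "timescale",
    "mean", "median", "cv", "q05", "q95", "n_estimates",
    "track_start", "track_end", "track_days",
    "mean_lon_diffused", "mean_lat_diffused", "grid_cell_area_km2",
    "taxon_class", "movement_mode", "sex", "age", "body_mass_g", "data_owner",
]

SPECIES_LEVEL_COLUMNS = [
    "species", "trait", "timescale",
    "mean_of_means", "mean_of_medians", "mean_of_cv",
    "mean_of_q05", "mean_of_q95", "n_individuals",
]

TIER_COLUMNS = {
    "within_individual": WITHIN_INDIVIDUAL_COLUMNS,
    "individual_level": INDIVIDUAL_LEVEL_COLUMNS,
    "species_level": SPECIES_LEVEL_COLUMNS,
}

TRAIT_UNITS = {
    "displacement": "m",
    "max_displacement": "m",
    "range_size": "km2",
    "intensity_of_use": "1",
    "diurnality": "1",
}


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class TraitDatabase:
    within_individual: pd.DataFrame = field(
        default_factory=lambda: _empty(WITHIN_INDIVIDUAL_COLUMNS))
    individual_level: pd.DataFrame = field(
        default_factory=lambda: _empty(INDIVIDUAL_LEVEL_COLUMNS))
    species_level: pd.DataFrame = field(
        default_factory=lambda: _empty(SPECIES_LEVEL_COLUMNS))

    def tiers(self) -> dict[str, pd.DataFrame]:
        return {
            "within_individual": self.within_individual,
            "individual_level": self.individual_level,
            "species_level": self.species_level,
        }

    def check_integrity(self, min_estimates_lookup=None) -> None:
        """Referential-integrity check across tiers.

        Every individual-tier (individual, trait, timescale) key must be
        backed by at least its minimum number of within-individual rows, and
        every species-tier key by at least one individual row. Raises
        ``IntegrityError`` listing offending keys.
        """
        offenders: list[str] = []
        wi = self.within_individual
        counts = (
            wi.groupby(["individual_id", "trait", "timescale"]).size()
            if len(wi) else pd.Series(dtype=int)
        )
        for row in self.individual_level.itertuples(index=False):
            key = (row.individual_id, row.trait, row.timescale)
            n = int(counts.get(key, 0))
            need = 1
            if min_estimates_lookup is not None:
                need = min_estimates_lookup(row.trait, row.timescale)
            if n < need:
                offenders.append(
                    f"individual_level {key}: {n} estimates < required {need}")
        ind_keys = set(
            map(tuple, self.individual_level[
                ["species", "trait", "timescale"]].itertuples(index=False))
        ) if len(self.individual_level) else set()
        for row in self.species_level.itertuples(index=False):
            key = (row.species, row.trait, row.timescale)
            if key not in ind_keys:
                offenders.append(f"species_level {key}: no individual rows")
        if offenders:
            raise IntegrityError(offenders)


class IntegrityError(Exception):
    def __init__(self, offenders: list[str]):
        self.offenders = offenders
        super().__init__(
            "trait database integrity violation:\n  " + "\n  ".join(offenders))
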