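"""Aggregation of repeated trait estimates into individual and species tiers.

An individual's repeated estimates collapse to mean, median, coefficient of
variation and the 5th/95th percentiles — but only once the individual has
enough repeated measures for those statistics to mean something (e.g. daily
displacement needs at least 30 days). Species statistics are *unweighted*
means of the individual statistics (the species 95th percentile is the mean
of individual 95th percentiles), so a heavily-tracked individual does not
dominate its species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .database import TraitDatabase


class ContractError(ValueError):
    """Input rows mix individuals/species/traits that must be homogeneous."""


def _stats(values: np.ndarray) -> dict[str, float]:
    """mean / median / cv / q05 / q95 with interpolated order statistics
    (position h = (n-1)p + 1) and the n-1 standard deviation."""
    q05, med, q95 = np.percentile(values, [5, 50, 95])  # linear interpolation
    mean = float(np.mean(values))
    if len(values) > 1 and mean != 0:
        cv = float(np.std(values, ddof=1) / mean)
    else:
        cv = np.nan  # undefined: zero mean or a single estimate
    return {"mean": mean, "median": float(med), "cv": cv,
            "q05": float(q05), "q95": float(q95)}


def summarize_individual_trait(
    estimates: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
) -> dict | None:
    """Summarise one individual's repeated estimates of one trait at one
    timescale; None when below the minimum-estimate threshold."""
    thresholds = thresholds or ThresholdConfig()
    if len(estimates) == 0:
        return None
    for col in ("individual_id", "trait", "timescale"):
        if estimates[col].nunique() != 1:
            raise ContractError(f"mixed {col} in estimates")
    trait = estimates["trait"].iloc[0]
    timescale = estimates["timescale"].iloc[0]
    n = len(estimates)
    if n < thresholds.estimates_for(trait, timescale):
        return None
    out = {
        "individual_id": estimates["individual_id"].iloc[0],
        "trait": trait,
        "timescale": timescale,
        "n_estimates": n,
    }
    out.update(_stats(estimates["value"].to_numpy(dtype=float)))
    return out


def build_individual_tier(estimates: pd.DataFrame,
                          thresholds: ThresholdConfig | None = None
                          ) -> pd.DataFrame:
    """Individual-tier statistics for every (individual, trait, timescale)
    group that clears its threshold. Annotation columns are joined later."""
    thresholds = thresholds or ThresholdConfig()
    rows = []
    if len(estimates):
        for _, group in estimates.groupby(
                ["individual_id", "trait", "timescale"], sort=True):
            row = summarize_individual_trait(group, thresholds)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows, columns=[
        "individual_id", "trait", "timescale",
        "mean", "median", "cv", "q05", "q95", "n_estimates"])


def summarize_species_trait(
    summaries: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
) -> dict | None:
    """Unweighted species means of individual statistics; None below the
    minimum-individuals threshold."""
    thresholds = thresholds or ThresholdConfig()
    if len(summaries) == 0:
        return None
    for col in ("species", "trait", "timescale"):
        if summaries[col].nunique() != 1:
            raise ContractError(f"mixed {col} in summaries")
    if len(summaries) < thresholds.min_individuals_species:
        return None
    return {
        "species": summaries["species"].iloc[0],
        "trait": summaries["trait"].iloc[0],
        "timescale": summaries["timescale"].iloc[0],
        "mean_of_means": float(summaries["mean"].mean()),
        "mean_of_medians": float(summaries["median"].mean()),
        "mean_of_cv": float(summaries["cv"].mean()),
        "mean_of_q05": float(summaries["q05"].mean()),
        "mean_of_q95": float(summaries["q95"].mean()),
        "n_individuals": int(len(summaries)),
    }


def build_species_tier(individual_tier: pd.DataFrame,
                       thresholds: ThresholdConfig | None = None
                       ) -> pd.DataFrame:
    thresholds = thresholds or ThresholdConfig()
    rows = []
    if len(individual_tier):
        for _, group in individual_tier.groupby(
                ["species", "trait", "timescale"], sort=True):
            row = summarize_species_trait(group, thresholds)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows, columns=[
        "species", "trait", "timescale", "mean_of_means", "mean_of_medians",
        "mean_of_cv", "mean_of_q05", "mean_of_q95", "n_individuals"])


def assemble_database(estimates: pd.DataFrame,
                      individual_tier: pd.DataFrame,
                      species_tier: pd.DataFrame,
                      thresholds: ThresholdConfig | None = None
                      ) -> TraitDatabase:
    """Bundle the three tiers, enforcing referential integrity: every
    individual row is backed by enough within-individual estimates, every
    species row by at least one individual row."""
    thresholds = thresholds or ThresholdConfig()
    db = TraitDatabase(within_individual=estimates.copy(),
                       individual_level=individual_tier.copy(),
                       species_level=species_tier.copy())
    db.check_integrity(min_estimates_lookup=thresholds.estimates_for)
    return db
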