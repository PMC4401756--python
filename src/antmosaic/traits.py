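"""Species-level and community-level functional ant traits from census tables.

Ant abundance on a plant is standardized to an intermediate plant size of 100
leaves (ants per 100 leaves).  Recruitment of a species is the maximum
standardized abundance it ever reached on any plant in any census — treated
as an intrinsic capacity for mass foraging.  Community-level traits of a
population are species trait means weighted by the number of plants each
species occupied there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyStability",
    "standardize_abundance",
    "plant_ant_abundance",
    "species_recruitment",
    "species_plant_means",
    "community_level_trait",
    "build_species_profiles",
    "community_traits",
    "plant_abundance_table",
    "occupancy_stability",
]

#: How occupancy weights count plants: distinct plants over both censuses
#: (default), a single census, or plant-census pairs.
WEIGHT_MODES = ("union", "t0", "t1", "pairs")


def standardize_abundance(count, n_leaves):
    """Ants per 100 leaves: ``count / n_leaves * 100``. Vectorized."""
    n_leaves = np.asarray(n_leaves, dtype=float)
    if np.any(n_leaves <= 0):
        raise ValueError("n_leaves must be positive for standardization")
    return np.asarray(count, dtype=float) / n_leaves * 100.0


def plant_ant_abundance(std_t0, std_t1):
    """Plant-level ant abundance: mean of the two standardized censuses."""
    if std_t0 is None or std_t1 is None:
        raise ValueError("both censuses required for plant ant abundance")
    return (np.asarray(std_t0, dtype=float) + np.asarray(std_t1, dtype=float)) / 2.0


def species_recruitment(standardized_observations: Iterable[float]) -> float:
    """Recruitment = the maximum standardized abundance over all plant-census pairs."""
    obs = list(standardized_observations)
    if not obs:
        raise ValueError("species never observed")
    return float(max(obs))


def species_plant_means(
    species: str,
    visited: pd.DataFrame,
    min_plants: int = 6,
) -> tuple[float, float, int, bool]:
    """Mean EFN and herbivory over the distinct plants a species visited.

    ``visited`` holds one row per distinct plant with columns ``plant_efn``
    and ``plant_herbivory``; a plant shared by several species contributes its
    phenotype to each.  Species visiting fewer than ``min_plants`` distinct
    plants are flagged ineligible ("more than five plants" read as >= 6) —
    exclusion is a status, not an error.
    """
    n = len(visited)
    eligible = n >= min_plants
    if n == 0:
        return (float("nan"), float("nan"), 0, False)
    return (
        float(visited["plant_efn"].mean()),
        float(visited["plant_herbivory"].mean()),
        n,
        eligible,
    )


def community_level_trait(
    traits: pd.Series | dict,
    weights: pd.Series | dict,
) -> float:
    """Occupancy-weighted community mean of a species trait.

    ``weights[s]`` is the number of distinct plants species ``s`` occupied in
    the population.  Raises if no species has positive weight.
    """
    traits = pd.Series(traits, dtype=float)
    weights = pd.Series(weights, dtype=float).reindex(traits.index).fillna(0.0)
    mask = (weights > 0) & traits.notna()
    if not mask.any():
        raise ValueError("population has no ant-occupied plants with known traits")
    w = weights[mask]
    return float((traits[mask] * w).sum() / w.sum())


def _standardized_observations(plants: pd.DataFrame, ant_obs: pd.DataFrame) -> pd.DataFrame:
    """Ant observations joined with plant size, plus the standardized abundance."""
    merged = ant_obs.merge(
        plants[["plant_id", "census", "n_leaves", "population_id"]],
        on=["plant_id", "census"],
        how="left",
        validate="many_to_one",
    )
    missing = merged["n_leaves"].isna()
    if missing.any():
        bad = merged.loc[missing, ["plant_id", "census"]].drop_duplicates()
        raise ValueError(f"ant observations reference unknown plant-census rows:\n{bad}")
    merged["std_abundance"] = standardize_abundance(merged["count"], merged["n_leaves"])
    return merged


def build_species_profiles(
    plants: pd.DataFrame,
    ant_obs: pd.DataFrame,
    ant_species: pd.DataFrame,
    plant_phenotypes: pd.DataFrame,
    min_plants: int = 6,
) -> pd.DataFrame:
    """One row per ant species: body size, recruitment, visited-plant means.

    ``plant_phenotypes`` carries one row per plant with ``plant_efn`` and
    ``plant_herbivory``.  Recruitment pools all plants and censuses of all
    populations (the global sample).
    """
    obs = _standardized_observations(plants, ant_obs)
    rec = obs.groupby("species")["std_abundance"].max()
    pheno = plant_phenotypes.set_index("plant_id")
    rows = []
    for sp, grp in obs.groupby("species"):
        plant_ids = grp["plant_id"].drop_duplicates()
        visited = pheno.reindex(plant_ids).dropna(subset=["plant_efn"])
        mean_efn, mean_herb, n_visited, eligible = species_plant_means(sp, visited, min_plants)
        rows.append((sp, rec[sp], mean_efn, mean_herb, n_visited, eligible))
    profiles = pd.DataFrame(
        rows,
        columns=[
            "species",
            "recruitment",
            "mean_efn_visited",
            "mean_herbivory_visited",
            "n_plants_visited",
            "eligible",
        ],
    )
    profiles = profiles.merge(
        ant_species[["species", "body_length_mm"]], on="species", how="left"
    )
    return profiles.sort_values("species", ignore_index=True)


def _occupancy_weights(
    plants: pd.DataFrame, ant_obs: pd.DataFrame, mode: str = "union"
) -> pd.DataFrame:
    """Plants-occupied weight per (population, species) under the chosen census mode."""
    if mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {mode!r}; expected one of {WEIGHT_MODES}")
    obs = ant_obs.merge(
        plants[["plant_id", "census", "population_id"]].drop_duplicates(),
        on=["plant_id", "census"],
        how="left",
    )
    if mode in ("t0", "t1"):
        obs = obs[obs["census"] == mode]
    if mode == "pairs":
        key = obs[["population_id", "species", "plant_id", "census"]].drop_duplicates()
    else:
        key = obs[["population_id", "species", "plant_id"]].drop_duplicates()
    w = key.groupby(["population_id", "species"]).size().rename("weight").reset_index()
    return w


def community_traits(
    plants: pd.DataFrame,
    ant_obs: pd.DataFrame,
    profiles: pd.DataFrame,
    mode: str = "union",
) -> pd.DataFrame:
    """Community-level ant size and recruitment per population.

    Populations with no ant-occupied plants get NaN traits (explicit
    no-value rather than an error, so downstream classification can mark
    them unclassifiable).
    """
    weights = _occupancy_weights(plants, ant_obs, mode)
    traits = profiles.set_index("species")
    rows = []
    for pop in sorted(plants["population_id"].unique()):
        wpop = weights[weights["population_id"] == pop].set_index("species")["weight"]
        if wpop.empty:
            rows.append((pop, float("nan"), float("nan"), 0))
            logger.warning("population %s has no ant-occupied plants", pop)
            continue
        size = community_level_trait(traits["body_length_mm"], wpop)
        recruit = community_level_trait(traits["recruitment"], wpop)
        rows.append((pop, size, recruit, int(wpop.sum())))
    return pd.DataFrame(
        rows,
        columns=["population_id", "community_size_mm", "community_recruitment", "total_weight"],
    )


def plant_abundance_table(plants: pd.DataFrame, ant_obs: pd.DataFrame) -> pd.DataFrame:
    """Per-plant ant abundance: mean of the two standardized censuses.

    A plant record present in only one census is excluded with a warning
    (no zero imputation).  A census with no ant observation on a recorded
    plant counts as zero ants observed.
    """
    obs = _standardized_observations(plants, ant_obs)
    per_census = (
        obs.groupby(["plant_id", "census"])["std_abundance"].sum().unstack(fill_value=0.0)
    )
    base = plants.pivot_table(
        index="plant_id", columns="census", values="n_leaves", aggfunc="first"
    )
    have_both = base.notna().all(axis=1)
    if (~have_both).any():
        dropped = list(base.index[~have_both])
        warnings.warn(f"plants missing one census excluded from abundance: {dropped}")
        logger.warning("excluded %d plants missing a census", len(dropped))
    idx = base.index[have_both]
    std0 = per_census.reindex(idx).get("t0", pd.Series(0.0, index=idx)).fillna(0.0)
    std1 = per_census.reindex(idx).get("t1", pd.Series(0.0, index=idx)).fillna(0.0)
    pops = plants.drop_duplicates("plant_id").set_index("plant_id")["population_id"]
    return pd.DataFrame(
        {
            "plant_id": idx,
            "population_id": pops.reindex(idx).to_numpy(),
            "std_t0": std0.to_numpy(),
            "std_t1": std1.to_numpy(),
            "ant_abundance": plant_ant_abundance(std0.to_numpy(), std1.to_numpy()),
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class OccupancyStability:
    """Season-to-season stability of ant occupancy across plants."""

    prop_occupied_both: float
    prop_occupied_neither: float
    prop_same_species: float  # among plants occupied in both censuses
    n_plants: int
    n_both: int

    def __post_init__(self) -> None:
        if self.prop_occupied_both + self.prop_occupied_neither > 1.0 + 1e-12:
            raise ValueError("both + neither proportions exceed 1")


def occupancy_stability(plants: pd.DataFrame, ant_obs: pd.DataFrame) -> OccupancyStability:
    """Proportions of plants occupied in both censuses, in neither, and (among
    the doubly occupied) by the same ant species."""
    base = plants.pivot_table(
        index="plant_id", columns="census", values="n_leaves", aggfunc="first"
    )
    paired = base.index[base.notna().all(axis=1)]
    if len(paired) == 0:
        raise ValueError("no plants with both censuses")
    by_census: dict[str, dict[str, set]] = {"t0": {}, "t1": {}}
    for row in ant_obs.itertuples():
        if row.census in by_census:
            by_census[row.census].setdefault(row.plant_id, set()).add(row.species)
    n_both = n_neither = n_same = 0
    for pid in paired:
        s0 = by_census["t0"].get(pid, set())
        s1 = by_census["t1"].get(pid, set())
        if s0 and s1:
            n_both += 1
            if s0 & s1:
                n_same += 1
        elif not s0 and not s1:
            n_neither += 1
    n = len(paired)
    return OccupancyStability(
        prop_occupied_both=n_both / n,
        prop_occupied_neither=n_neither / n,
        prop_same_species=(n_same / n_both) if n_both else float("nan"),
        n_plants=n,
        n_both=n_both,
    )
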