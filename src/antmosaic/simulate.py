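"""Synthetic multi-population ant-plant-herbivore survey generator.

Emulates a two-census field survey of an EFN-bearing shrub: 10 populations of
30 tagged plants spread over ~600 km of savanna, visited by a regional pool
of ~15 ant species whose body size trades off against recruitment capacity
(small ants mass-recruit, large ants forage in small numbers).  Each
population follows one of three scenarios:

* ``matched_small`` — low EFN abundance, assemblage dominated by small ants;
* ``matched_big``   — high EFN abundance, assemblage dominated by large ants;
* ``mismatched``    — EFN abundance unrelated to the (sparse, random) ant
  assemblage.

Under matched scenarios the occupant of a plant is drawn with probability
proportional to a Gaussian kernel around the "preferred" ant size ``g(EFN)``,
an increasing affine map from the plant's latent EFN abundance; under
mismatched scenarios occupants are uniform over the pool.  Herbivory follows
a Beta distribution whose logit mean decreases with the plant's standardized
ant abundance, and leaf production, flowering and seedling recruitment in
turn improve as herbivory falls.  Designated hotspot populations get a
narrower EFN dispersion and a lower herbivory baseline, mismatched
populations a higher one; the resulting labels are stored as ground truth so
the downstream classifier can be scored against a known mosaic.

All randomness flows from one master seed; per-population streams are derived
deterministically, so any single population can be regenerated on its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

SCENARIOS = ("matched_small", "matched_big", "mismatched")

#: CSV tables a survey is made of, in write order.
TABLE_NAMES = (
    "plants",
    "ant_observations",
    "herbivore_observations",
    "leaflets",
    "ant_species",
    "populations",
)

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticSurvey",
    "generate_species_pool",
    "generate_population",
    "generate_survey",
    "generate_interface_pool",
    "read_survey",
    "SCENARIOS",
]


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic survey.

    Defaults reproduce the survey design the analysis expects: 10 populations
    x 30 plants x 2 censuses, a 15-species ant pool with body lengths
    log-normal around 5 mm, a negative size-recruitment trade-off, EFN counts
    with coefficient of variation ~0.5, and 74 % occupant persistence between
    censuses.
    """

    n_populations: int = 10
    n_plants_per_pop: int = 30

    # --- ant species pool ---
    n_species: int = 15
    size_log_mean: float = math.log(7.0)  # log-mm; pool spans ~3-14 mm
    size_log_sd: float = 0.55
    # log recruitment (ants per 100 leaves) = intercept + slope * size_mm + noise
    tradeoff_intercept: float = 4.2
    tradeoff_slope: float = -0.28
    tradeoff_noise_sd: float = 0.30

    # --- per-population scenarios and designed hotspots ---
    scenarios: tuple[str, ...] = (
        ("matched_small",) + ("matched_big",) * 7 + ("mismatched",) * 2
    )
    hotspot_indices: tuple[int, ...] = (0, 1, 2)

    # --- EFN phenotype ---
    efn_mean_by_scenario: dict[str, float] = field(
        default_factory=lambda: {
            "matched_small": 3.2,
            "matched_big": 37.5,
            "mismatched": 55.0,
        }
    )
    # matched_big populations get means evenly spaced over this range (the
    # mosaic's high-EFN populations differ among themselves, as real EFN
    # surveys show); efn_mean_by_scenario["matched_big"] is the fallback when
    # a single population is generated in isolation.
    efn_matched_big_range: tuple[float, float] = (25.0, 50.0)
    efn_dispersion: float = 4.0  # NB size parameter k; CV ~ 1/sqrt(k)
    hotspot_dispersion_factor: float = 8.0  # hotspots: k scaled up -> narrower variance

    # --- ant visitation ---
    # preferred ant size for a plant: g(EFN) = pref_size_intercept + pref_size_slope * EFN
    pref_size_intercept: float = 2.6  # mm
    pref_size_slope: float = 0.22  # mm per EFN/leaflet
    visitation_kernel_sd: float = 0.8  # tau, mm
    occupancy_prob_matched: float = 0.85
    occupancy_prob_mismatched: float = 0.33
    persistence_prob: float = 0.74

    # --- herbivory and performance ---
    herbivory_base_logit: float = 0.5
    herbivory_effect: float = -0.12  # c1: logit shift per (ant / 100 leaves)
    herbivory_hotspot_shift: float = -1.5
    herbivory_mismatched_shift: float = 0.8
    herbivory_precision: float = 12.0  # Beta precision of plant-level herbivory
    growth_intercept: float = 0.35
    growth_herbivory_slope: float = -1.0
    growth_noise_sd: float = 0.12
    flowering_intercept: float = 0.0
    flowering_slope: float = 4.0
    seedling_log_intercept: float = 0.7
    seedling_slope: float = 2.0

    # --- plant size and leaflet sampling ---
    leaves_mean: float = 90.0
    leaves_dispersion: float = 6.0
    n_leaflets_sampled: int = 6
    leaflet_area_mean: float = 550.0  # mm^2
    leaflet_area_sd: float = 120.0
    leaflet_damage_precision: float = 25.0
    efn_diameter_mean: float = 0.17  # mm
    efn_diameter_sd: float = 0.02

    # --- herbivore assemblage ---
    n_herbivore_species: int = 6
    herbivore_total_rate: float = 1.5  # expected herbivores per plant-census
    herbivore_mismatched_factor: float = 3.0
    herbivore_lat_gradient: float = -0.25  # log-rate per degree latitude (southern richer)

    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_plants_per_pop < 1:
            raise ValueError("population and plant counts must be >= 1")
        if self.n_species < 3:
            raise ValueError(f"need at least 3 ant species, got {self.n_species}")
        if self.tradeoff_slope >= 0:
            raise ValueError("tradeoff_slope must be negative (size-recruitment trade-off)")
        if not 0.0 <= self.persistence_prob <= 1.0:
            raise ValueError("persistence_prob must be in [0, 1]")
        if len(self.scenarios) != self.n_populations:
            raise ValueError("one scenario label per population required")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        for s, m in self.efn_mean_by_scenario.items():
            if m <= 0:
                raise ValueError(f"EFN mean for {s!r} must be positive")
        for i in self.hotspot_indices:
            if not 0 <= i < self.n_populations:
                raise ValueError(f"hotspot index {i} out of range")
            if self.scenarios[i] == "mismatched":
                raise ValueError("designed hotspots must be matched populations")
        if self.pref_size_slope <= 0:
            raise ValueError("preferred-size map must be increasing in EFN abundance")


@dataclass
class GroundTruth:
    """Designed labels of a generated survey plus the true species parameters."""

    populations: dict[str, dict]  # pop id -> scenario / matched / matching_type / hotspot
    species: dict[str, dict]  # species -> body_length_mm / latent_recruitment

    def to_json(self) -> str:
        return json.dumps({"populations": self.populations, "species": self.species}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(populations=d["populations"], species=d["species"])


_DESIGNED_TYPE = {
    "matched_small": "small-ant/low-EFN",
    "matched_big": "big-ant/high-EFN",
    "mismatched": "not-applicable",
}


def generate_species_pool(config: ScenarioConfig, seed=None) -> pd.DataFrame:
    """Draw the regional ant species pool.

    Body lengths are log-normal; latent recruitment (ants per 100 leaves at
    carrying visitation) follows ``exp(intercept + slope * size + noise)``
    with a negative slope, the classic size-recruitment trade-off.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = rng.lognormal(config.size_log_mean, config.size_log_sd, config.n_species)
    noise = (
        rng.normal(0.0, config.tradeoff_noise_sd, config.n_species)
        if config.tradeoff_noise_sd > 0
        else np.zeros(config.n_species)
    )
    log_rec = config.tradeoff_intercept + config.tradeoff_slope * sizes + noise
    return pd.DataFrame(
        {
            "species": [f"ant{i + 1:02d}" for i in range(config.n_species)],
            "body_length_mm": sizes,
            "latent_recruitment": np.exp(log_rec),
        }
    )


def _draw_negbin(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    # Gamma-Poisson mixture: NB(mean, dispersion k); k -> inf degenerates to Poisson.
    lam = rng.gamma(k, mean / k, size)
    return rng.poisson(lam)


def _choose_occupants(
    rng: np.random.Generator,
    scenario: str,
    lam_efn: np.ndarray,
    sizes: np.ndarray,
    config: ScenarioConfig,
) -> np.ndarray:
    """Occupant species index per plant (visitation kernel or uniform)."""
    n = len(lam_efn)
    if scenario == "mismatched":
        return rng.integers(0, len(sizes), n)
    preferred = config.pref_size_intercept + config.pref_size_slope * lam_efn
    tau = config.visitation_kernel_sd
    out = np.empty(n, dtype=int)
    for i in range(n):
        if tau <= 0:
            out[i] = int(np.argmin(np.abs(sizes - preferred[i])))
            continue
        logw = -((sizes - preferred[i]) ** 2) / (2.0 * tau * tau)
        w = np.exp(logw - logw.max())
        out[i] = rng.choice(len(sizes), p=w / w.sum())
    return out


def generate_population(
    config: ScenarioConfig,
    scenario: str,
    species_pool: pd.DataFrame,
    seed,
    population_id: str = "pop01",
    hotspot: bool = False,
    herbivore_severity: float = 1.0,
    efn_mean: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate one population's plant-census records for both censuses.

    Returns the per-population slices of the ``plants``, ``ant_observations``,
    ``herbivore_observations`` and ``leaflets`` tables.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if len(species_pool) == 0:
        raise ValueError("empty species pool")
    rng = np.random.default_rng(seed)
    n = config.n_plants_per_pop
    sizes = species_pool["body_length_mm"].to_numpy()
    recruit = species_pool["latent_recruitment"].to_numpy()
    names = species_pool["species"].to_numpy()

    mu_efn = config.efn_mean_by_scenario[scenario] if efn_mean is None else efn_mean
    k_efn = config.efn_dispersion * (config.hotspot_dispersion_factor if hotspot else 1.0)
    lam_efn = rng.gamma(k_efn, mu_efn / k_efn, n)  # latent plant EFN phenotype

    leaves_t0 = np.maximum(
        _draw_negbin(rng, config.leaves_mean, config.leaves_dispersion, n), 5
    )

    occ_prob = (
        config.occupancy_prob_mismatched
        if scenario == "mismatched"
        else config.occupancy_prob_matched
    )

    occ0 = rng.random(n) < occ_prob
    who0 = _choose_occupants(rng, scenario, lam_efn, sizes, config)
    count0 = rng.poisson(recruit[who0] * leaves_t0 / 100.0)
    occ0 &= count0 > 0

    # Census t1: the occupant persists with probability persistence_prob,
    # otherwise occupancy and identity are redrawn from scratch.
    persist = rng.random(n) < config.persistence_prob
    who1_new = _choose_occupants(rng, scenario, lam_efn, sizes, config)
    occ1_new = rng.random(n) < occ_prob
    who1 = np.where(persist & occ0, who0, who1_new)
    occ1 = np.where(persist, occ0, occ1_new)
    count1 = rng.poisson(recruit[who1] * leaves_t0 / 100.0)
    occ1 &= count1 > 0

    std0 = np.where(occ0, count0 / leaves_t0 * 100.0, 0.0)
    std1 = np.where(occ1, count1 / leaves_t0 * 100.0, 0.0)
    abund = (std0 + std1) / 2.0

    shift = 0.0
    if hotspot:
        shift += config.herbivory_hotspot_shift
    if scenario == "mismatched":
        shift += config.herbivory_mismatched_shift
    mu_h = expit(config.herbivory_base_logit + shift + config.herbivory_effect * abund)
    phi = config.herbivory_precision
    herb = rng.beta(mu_h * phi, (1.0 - mu_h) * phi)

    rlp = config.growth_intercept + config.growth_herbivory_slope * herb
    if config.growth_noise_sd > 0:
        rlp = rlp + rng.normal(0.0, config.growth_noise_sd, n)
    rlp = np.maximum(rlp, -1.0)
    leaves_t1 = np.maximum(np.round(leaves_t0 * (1.0 + rlp)).astype(int), 1)

    p_flower = expit(config.flowering_intercept + config.flowering_slope * rlp)
    flower0 = rng.random(n) < p_flower
    flower1 = rng.random(n) < p_flower
    seedlings1 = rng.poisson(np.exp(config.seedling_log_intercept + config.seedling_slope * rlp))

    plant_ids = [f"{population_id}-{i + 1:03d}" for i in range(n)]
    plants = pd.DataFrame(
        {
            "population_id": population_id,
            "plant_id": plant_ids * 2,
            "census": ["t0"] * n + ["t1"] * n,
            "n_leaves": np.concatenate([leaves_t0, leaves_t1]),
            "flowering": np.concatenate([flower0, flower1]).astype(int),
            "n_seedlings_2m": np.concatenate([np.zeros(n, dtype=int), seedlings1]),
        }
    )

    ant_rows = []
    for census, occ, who, count in (("t0", occ0, who0, count0), ("t1", occ1, who1, count1)):
        for i in range(n):
            if occ[i]:
                ant_rows.append((plant_ids[i], census, names[who[i]], int(count[i])))
    ant_obs = pd.DataFrame(ant_rows, columns=["plant_id", "census", "species", "count"])

    # Herbivore assemblage: a shared regional profile, with the large damaging
    # species inflated in mismatched populations.
    nh = config.n_herbivore_species
    weights = np.exp(-0.5 * np.arange(nh))
    if scenario == "mismatched":
        weights = weights.copy()
        weights[0] *= config.herbivore_mismatched_factor
    weights = weights / weights.sum()
    rate = config.herbivore_total_rate * herbivore_severity * weights
    herb_rows = []
    for census in ("t0", "t1"):
        counts = rng.poisson(np.tile(rate, (n, 1)))
        for i in range(n):
            for h in range(nh):
                if counts[i, h] > 0:
                    herb_rows.append((plant_ids[i], census, f"herb{h + 1:02d}", int(counts[i, h])))
    herb_obs = pd.DataFrame(herb_rows, columns=["plant_id", "census", "species", "count"])

    leaflet_rows = []
    for i in range(n):
        m = config.n_leaflets_sampled
        counts = rng.poisson(lam_efn[i], m)
        total = np.maximum(rng.normal(config.leaflet_area_mean, config.leaflet_area_sd, m), 50.0)
        dphi = config.leaflet_damage_precision
        frac = rng.beta(
            np.clip(herb[i], 1e-4, 1 - 1e-4) * dphi,
            (1.0 - np.clip(herb[i], 1e-4, 1 - 1e-4)) * dphi,
            m,
        )
        diam = np.clip(rng.normal(config.efn_diameter_mean, config.efn_diameter_sd, m), 0.05, 0.40)
        for j in range(m):
            leaflet_rows.append(
                (
                    plant_ids[i],
                    f"{plant_ids[i]}-L{j + 1}",
                    round(float(total[j]), 2),
                    round(float(total[j] * frac[j]), 2),
                    int(counts[j]),
                    round(float(diam[j]), 3),
                )
            )
    leaflets = pd.DataFrame(
        leaflet_rows,
        columns=[
            "plant_id",
            "leaflet_id",
            "total_area_mm2",
            "damaged_area_mm2",
            "efn_count_base",
            "efn_diameter_mm",
        ],
    )
    return {
        "plants": plants,
        "ant_observations": ant_obs,
        "herbivore_observations": herb_obs,
        "leaflets": leaflets,
    }


@dataclass
class SyntheticSurvey:
    """A full generated survey: input tables plus the ground-truth sidecar."""

    tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth | None
    config: ScenarioConfig | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in TABLE_NAMES:
            self.tables[name].to_csv(out / f"{name}.csv", index=False)
        if self.ground_truth is not None:
            (out / "ground_truth.json").write_text(self.ground_truth.to_json())
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["scenarios"] = list(cfg["scenarios"])
            cfg["hotspot_indices"] = list(cfg["hotspot_indices"])
            (out / "scenario_config.json").write_text(json.dumps(cfg, indent=2))


def read_survey(in_dir) -> SyntheticSurvey:
    """Read a survey directory written by :meth:`SyntheticSurvey.write`."""
    src = Path(in_dir)
    tables = {}
    for name in TABLE_NAMES:
        path = src / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path)
        elif name == "herbivore_observations":
            tables[name] = pd.DataFrame(columns=["plant_id", "census", "species", "count"])
        else:
            raise FileNotFoundError(f"missing required table {path}")
    gt_path = src / "ground_truth.json"
    gt = GroundTruth.from_json(gt_path.read_text()) if gt_path.exists() else None
    return SyntheticSurvey(tables=tables, ground_truth=gt, config=None)


def generate_survey(config: ScenarioConfig) -> SyntheticSurvey:
    """Generate the full multi-population survey with ground-truth labels.

    Population coordinates are laid out along a ~600 km latitudinal span with
    small jitter; herbivore pressure follows a latitudinal gradient so that
    total herbivore abundance carries a geographic signal.
    """
    config.validate()
    pool = generate_species_pool(config, seed=[config.seed, 0])
    rng_geo = np.random.default_rng([config.seed, 1])

    pop_ids = [f"pop{i + 1:02d}" for i in range(config.n_populations)]
    lat0 = -16.8
    span = 5.7  # degrees latitude ~ 630 km
    step = span / max(config.n_populations - 1, 1)
    lat = lat0 + step * np.arange(config.n_populations) + rng_geo.normal(0, 0.08, config.n_populations)
    lon = -42.5 + rng_geo.normal(0, 0.5, config.n_populations)
    populations = pd.DataFrame(
        {"population_id": pop_ids, "lat": np.round(lat, 4), "lon": np.round(lon, 4)}
    )

    mean_lat = float(np.mean(lat))
    n_big = sum(s == "matched_big" for s in config.scenarios)
    lo, hi = config.efn_matched_big_range
    big_means = iter(np.linspace(lo, hi, n_big) if n_big > 1 else [(lo + hi) / 2.0])
    parts: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_NAMES if k not in ("ant_species", "populations")}
    gt_pops: dict[str, dict] = {}
    for i, (pid, scenario) in enumerate(zip(pop_ids, config.scenarios)):
        hotspot = i in config.hotspot_indices
        severity = math.exp(config.herbivore_lat_gradient * (lat[i] - mean_lat))
        efn_mean = float(next(big_means)) if scenario == "matched_big" else None
        tables = generate_population(
            config,
            scenario,
            pool,
            seed=[config.seed, 2 + i],
            population_id=pid,
            hotspot=hotspot,
            herbivore_severity=severity,
            efn_mean=efn_mean,
        )
        for k, df in tables.items():
            parts[k].append(df)
        gt_pops[pid] = {
            "scenario": scenario,
            "matched": scenario != "mismatched",
            "matching_type": _DESIGNED_TYPE[scenario],
            "hotspot": hotspot,
            "efn_mean": efn_mean if efn_mean is not None else config.efn_mean_by_scenario[scenario],
        }

    tables = {k: pd.concat(v, ignore_index=True) for k, v in parts.items()}
    tables["ant_species"] = pool[["species", "body_length_mm"]].round({"body_length_mm": 3})
    tables["populations"] = populations
    gt = GroundTruth(
        populations=gt_pops,
        species={
            row.species: {
                "body_length_mm": float(row.body_length_mm),
                "latent_recruitment": float(row.latent_recruitment),
            }
            for row in pool.itertuples()
        },
    )
    return SyntheticSurvey(tables=tables, ground_truth=gt, config=config)


def generate_interface_pool(
    n_species: int = 15,
    intercept: float = -10.0,
    slope: float = 4.5,
    noise_sd: float = 6.0,
    size_range: tuple[float, float] = (3.0, 14.0),
    seed=None,
) -> pd.DataFrame:
    """Species-profile pool with a known linear EFN ~ size structure.

    Used for parameter-recovery experiments on the phenotypic interface: mean
    EFN abundance of visited plants is exactly ``intercept + slope * size``
    plus optional Gaussian noise, so a fitted interface can be compared with
    the generating slope.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species for a regression pool")
    rng = np.random.default_rng(seed)
    sizes = np.sort(rng.uniform(*size_range, n_species))
    y = intercept + slope * sizes
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_species)
    return pd.DataFrame(
        {
            "species": [f"ant{i + 1:02d}" for i in range(n_species)],
            "body_length_mm": sizes,
            "mean_efn_visited": y,
            "n_plants_visited": 10,
            "eligible": True,
        }
    )
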