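"""End-to-end orchestration: schema validation, stage wiring, reproducible outputs.

The pipeline runs similarity -> trait aggregation -> plant metrics ->
phenotypic interface -> classification on a survey directory (or a freshly
simulated survey), writing every stage product as a labeled CSV plus a JSON
run report that fully determines re-running the identical analysis.  Every
stochastic stage receives a seed derived deterministically from the master
seed, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import metrics as _metrics
from . import similarity as _similarity
from . import traits as _traits
from .interface import fit_interface
from .simulate import ScenarioConfig, SyntheticSurvey, generate_survey, read_survey

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "validate_inputs",
    "analyze_survey",
    "run_pipeline",
]

REQUIRED_COLUMNS = {
    "plants": ["population_id", "plant_id", "census", "n_leaves", "flowering", "n_seedlings_2m"],
    "ant_observations": ["plant_id", "census", "species", "count"],
    "herbivore_observations": ["plant_id", "census", "species", "count"],
    "leaflets": [
        "plant_id",
        "leaflet_id",
        "total_area_mm2",
        "damaged_area_mm2",
        "efn_count_base",
        "efn_diameter_mm",
    ],
    "ant_species": ["species", "body_length_mm"],
    "populations": ["population_id", "lat", "lon"],
}


class PipelineError(RuntimeError):
    """A stage precondition or schema violation, tagged with its stage."""

    def __init__(self, stage: str, message: str, violations: pd.DataFrame | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.violations = violations


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    input_dir: str | None = None  # read a survey directory ...
    simulate: ScenarioConfig | None = None  # ... or generate one
    out_dir: str | None = None
    seed: int = 0
    alpha: float = 0.05  # test level for ANOVA / FK letters
    band_alpha: float = 0.05  # confidence level of the interface band
    n_boot: int = 1000
    n_perm: int = 5000
    matching_predictor: str = "size"
    band_kind: str = "prediction"  # prediction | mean | jackknife
    log_recruitment: bool = True
    weight_mode: str = "union"
    min_plants: int = 6
    compute_similarity: bool = True


@dataclass
class RunReport:
    config: dict
    row_counts: dict
    warnings: list = field(default_factory=list)
    statistics: dict = field(default_factory=dict)
    classification: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def validate_inputs(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema, range and referential-integrity checks over all input tables.

    Returns one row per violation (table, row, rule, message); an empty frame
    means the survey is well-formed.
    """
    v: list[tuple[str, object, str, str]] = []

    def add(table, row, rule, message):
        v.append((table, row, rule, message))

    for name, cols in REQUIRED_COLUMNS.items():
        if name not in tables:
            if name == "herbivore_observations":
                continue  # optional table
            add(name, None, "table-missing", f"required table {name!r} absent")
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            add(name, None, "columns-missing", f"missing columns {missing}")
    if any(rule in ("table-missing", "columns-missing") for _, _, rule, _ in v):
        return pd.DataFrame(v, columns=["table", "row", "rule", "message"])

    plants = tables["plants"]
    for idx, row in plants.iterrows():
        if row["census"] not in ("t0", "t1"):
            add("plants", idx, "census-invalid", f"census {row['census']!r} not in (t0, t1)")
        if not row["n_leaves"] > 0:
            add("plants", idx, "range", f"plant {row['plant_id']} has non-positive n_leaves")
        if row["flowering"] not in (0, 1, True, False):
            add("plants", idx, "range", f"plant {row['plant_id']} flowering not boolean")
        if row["n_seedlings_2m"] < 0:
            add("plants", idx, "range", f"plant {row['plant_id']} negative seedling count")
    dup = plants.duplicated(subset=["plant_id", "census"])
    for idx in plants.index[dup]:
        add("plants", idx, "duplicate", f"duplicate plant-census row {plants.loc[idx, 'plant_id']}")

    known_pairs = set(zip(plants["plant_id"], plants["census"]))
    known_plants = set(plants["plant_id"])
    for name in ("ant_observations", "herbivore_observations"):
        if name not in tables:
            continue
        for idx, row in tables[name].iterrows():
            if (row["plant_id"], row["census"]) not in known_pairs:
                add(
                    name,
                    idx,
                    "referential-integrity",
                    f"observation references unknown plant-census ({row['plant_id']}, {row['census']})",
                )
            if not row["count"] > 0:
                add(name, idx, "range", f"non-positive count on plant {row['plant_id']}")

    for idx, row in tables["leaflets"].iterrows():
        if row["plant_id"] not in known_plants:
            add("leaflets", idx, "referential-integrity", f"unknown plant {row['plant_id']}")
        if not row["total_area_mm2"] > 0:
            add("leaflets", idx, "range", f"leaflet {row['leaflet_id']} non-positive total area")
        elif row["damaged_area_mm2"] < 0 or row["damaged_area_mm2"] > row["total_area_mm2"] + 1e-9:
            add("leaflets", idx, "range", f"leaflet {row['leaflet_id']} damaged area outside [0, total]")
        if row["efn_count_base"] < 0:
            add("leaflets", idx, "range", f"leaflet {row['leaflet_id']} negative EFN count")

    pops = tables["populations"]
    for idx, row in pops.iterrows():
        if not -90 <= row["lat"] <= 90 or not -180 <= row["lon"] <= 180:
            add("populations", idx, "range", f"population {row['population_id']} coordinates out of range")
    dup = pops.duplicated(subset=["population_id"])
    for idx in pops.index[dup]:
        add("populations", idx, "duplicate", f"duplicate population {pops.loc[idx, 'population_id']}")
    missing_pops = set(plants["population_id"]) - set(pops["population_id"])
    if missing_pops:
        add("plants", None, "referential-integrity", f"populations without coordinates: {sorted(missing_pops)}")

    return pd.DataFrame(v, columns=["table", "row", "rule", "message"])


def _assemblages(plants, obs, label_prefix=""):
    merged = obs.merge(
        plants[["plant_id", "census", "population_id"]].drop_duplicates(),
        on=["plant_id", "census"],
        how="inner",
    )
    out = []
    for pop in sorted(plants["population_id"].unique()):
        sub = merged[merged["population_id"] == pop]
        counts = sub.groupby("species")["count"].sum().to_dict()
        out.append(_similarity.AssemblageCounts(label_prefix + pop, counts))
    return out


def _similarity_stage(tables, config: PipelineConfig) -> dict:
    plants = tables["plants"]
    pops = tables["populations"].set_index("population_id")
    coords = {p: (float(pops.loc[p, "lat"]), float(pops.loc[p, "lon"])) for p in pops.index}
    geo = _similarity.geographic_distance_matrix(coords)
    out: dict = {"geographic_km": geo}
    mantel_rows = []
    for kind, table in (("ant", "ant_observations"), ("herbivore", "herbivore_observations")):
        obs = tables.get(table)
        if obs is None or len(obs) == 0:
            continue
        asm = _assemblages(plants, obs)
        nonempty = [a for a in asm if a.total > 0]
        if len(nonempty) < 3:
            continue
        dm = _similarity.dissimilarity_matrix(nonempty)
        out[f"{kind}_dissimilarity"] = dm
        ps_vals = 1.0 - dm.data[np.triu_indices(dm.shape[0], k=1)]
        out[f"{kind}_mean_ps"] = float(np.mean(ps_vals))
        boot_rows = []
        for i in range(len(nonempty)):
            for j in range(i + 1, len(nonempty)):
                t = _similarity.bootstrap_ps_test(
                    nonempty[i],
                    nonempty[j],
                    n_boot=config.n_boot,
                    seed=[config.seed, 110, i, j],
                )
                boot_rows.append(
                    (
                        nonempty[i].label,
                        nonempty[j].label,
                        t.ps,
                        t.ci_low,
                        t.ci_high,
                        t.reject_dissimilarity,
                    )
                )
        out[f"{kind}_ps_tests"] = pd.DataFrame(
            boot_rows,
            columns=["locality_a", "locality_b", "ps", "ci_low", "ci_high", "reject_dissimilarity"],
        )
        geo_sub = geo.filter(dm.ids)
        res = _similarity.mantel_test(
            dm, geo_sub, n_perm=config.n_perm, tail="greater", seed=[config.seed, 101]
        )
        mantel_rows.append((f"1-PS ({kind} composition) vs geographic distance", res.r, res.p, res.n_perm))
        total = obs.merge(
            plants[["plant_id", "census", "population_id"]].drop_duplicates(),
            on=["plant_id", "census"],
        ).groupby("population_id")["count"].sum()
        scal = _similarity.scalar_dissimilarity(
            {p: float(total.get(p, 0.0)) for p in geo.ids}
        )
        res2 = _similarity.mantel_test(
            scal, geo, n_perm=config.n_perm, tail="greater", seed=[config.seed, 102]
        )
        mantel_rows.append((f"total {kind} abundance vs geographic distance", res2.r, res2.p, res2.n_perm))
    out["mantel_tests"] = pd.DataFrame(mantel_rows, columns=["comparison", "r", "p", "n_perm"])
    return out


def build_population_phenotypes(tables, config: PipelineConfig):
    """Assemble the per-population aggregates feeding classification."""
    plants = tables["plants"]
    pheno = _metrics.plant_phenotypes(tables["leaflets"])
    abund = _traits.plant_abundance_table(plants, tables["ant_observations"])
    profiles = _traits.build_species_profiles(
        plants, tables["ant_observations"], tables["ant_species"], pheno, min_plants=config.min_plants
    )
    comm = _traits.community_traits(
        plants, tables["ant_observations"], profiles, mode=config.weight_mode
    ).set_index("population_id")

    wide = plants.pivot_table(
        index=["population_id", "plant_id"],
        columns="census",
        values=["n_leaves", "flowering", "n_seedlings_2m"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()

    occupied = set(
        tables["ant_observations"].merge(
            plants[["plant_id", "census"]], on=["plant_id", "census"], how="inner"
        )["plant_id"]
    )
    pheno_pop = pheno.merge(
        plants.drop_duplicates("plant_id")[["plant_id", "population_id"]], on="plant_id"
    )

    phenotypes = []
    efn_groups: dict[str, np.ndarray] = {}
    for pop in sorted(plants["population_id"].unique()):
        sub = pheno_pop[pheno_pop["population_id"] == pop]
        wide_pop = wide[wide["population_id"] == pop].dropna(
            subset=["n_leaves_t0", "n_leaves_t1"]
        )
        perf = _metrics.population_performance(wide_pop)
        abund_pop = abund[abund["population_id"] == pop]["ant_abundance"]
        pop_plants = plants[plants["population_id"] == pop]["plant_id"].unique()
        efn_groups[pop] = sub["plant_efn"].to_numpy()
        phenotypes.append(
            _classify.PopulationPhenotype(
                population_id=pop,
                mean_efn=float(sub["plant_efn"].mean()),
                var_efn=float(sub["plant_efn"].var(ddof=1)) if len(sub) > 1 else 0.0,
                community_size_mm=float(comm.loc[pop, "community_size_mm"]),
                community_recruitment=float(comm.loc[pop, "community_recruitment"]),
                ant_abundance=float(abund_pop.mean()) if len(abund_pop) else float("nan"),
                prop_occupied=float(np.mean([p in occupied for p in pop_plants])),
                herbivory=float(sub["plant_herbivory"].mean()),
                relative_leaf_production=perf[0],
                prop_flowering=perf[1],
                seedling_density=perf[2],
            )
        )
    return phenotypes, profiles, comm.reset_index(), efn_groups, pheno


def analyze_survey(tables: dict[str, pd.DataFrame], config: PipelineConfig) -> dict:
    """Run all analysis stages in memory and return their products."""
    phenotypes, profiles, comm, efn_groups, pheno = build_population_phenotypes(tables, config)

    # EFN variance comparison on mean-standardized plant values (scale-free
    # dispersion, comparable across populations with very different means).
    std_groups = {
        pop: vals / vals.mean()
        for pop, vals in efn_groups.items()
        if len(vals) >= 2 and vals.mean() > 0
    }
    fk = _metrics.fligner_killeen(std_groups, alpha=config.alpha) if len(std_groups) >= 2 else None
    anova = (
        _metrics.anova_oneway({p: v for p, v in efn_groups.items() if len(v) >= 2}, alpha=config.alpha)
        if sum(len(v) >= 2 for v in efn_groups.values()) >= 2
        else None
    )

    try:
        size_model = fit_interface(
            profiles, "body_length_mm", "mean_efn_visited", alpha=config.band_alpha
        )
        rec_model = fit_interface(
            profiles,
            "recruitment",
            "mean_efn_visited",
            log_recruitment=config.log_recruitment,
            alpha=config.band_alpha,
        )
    except ValueError as exc:
        raise PipelineError("interface", str(exc)) from exc

    classification = _classify.classify_cohort(
        phenotypes,
        size_model,
        rec_model,
        fk.letters if fk is not None else {},
        alpha=config.band_alpha,
        primary=config.matching_predictor,
        band_kind=config.band_kind,
    )

    results = {
        "phenotypes": phenotypes,
        "profiles": profiles,
        "community_traits": comm,
        "plant_phenotypes": pheno,
        "fligner": fk,
        "anova": anova,
        "size_model": size_model,
        "recruitment_model": rec_model,
        "classification": classification,
        "stability": _traits.occupancy_stability(tables["plants"], tables["ant_observations"]),
    }
    if config.compute_similarity:
        results["similarity"] = _similarity_stage(tables, config)
    return results


def _dm_to_frame(dm) -> pd.DataFrame:
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def _interface_row(name, model):
    f = model.fit
    return {
        "model": name,
        "predictor": model.predictor,
        "transform": model.transform,
        "response": model.response,
        "slope": f.slope,
        "intercept": f.intercept,
        "jackknife_slope": f.jk_slope,
        "jackknife_se": f.jk_se,
        "t": f.t,
        "p": f.p,
        "tail": f.tail,
        "n_species": f.n,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and (optionally) write all stage outputs."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        survey: SyntheticSurvey = generate_survey(sim)
    elif config.input_dir is not None:
        survey = read_survey(config.input_dir)
    else:
        raise PipelineError("config", "either input_dir or simulate must be given")
    tables = survey.tables

    violations = validate_inputs(tables)
    if len(violations):
        first = violations.iloc[0]
        raise PipelineError(
            "validation",
            f"{len(violations)} violation(s); first: {first['table']} row {first['row']}: {first['message']}",
            violations,
        )

    results = analyze_survey(tables, config)

    stats: dict = {
        "interface_fits": [
            _interface_row("efn_vs_size", results["size_model"]),
            _interface_row("efn_vs_recruitment", results["recruitment_model"]),
        ],
        "occupancy_stability": dataclasses.asdict(results["stability"]),
    }
    if results["anova"] is not None:
        a = results["anova"]
        stats["efn_anova"] = {
            "F": a.f,
            "df_between": a.df_between,
            "df_within": a.df_within,
            "p": a.p,
            "letters": a.letters,
        }
    if results["fligner"] is not None:
        fk = results["fligner"]
        stats["efn_variance_fligner"] = {
            "statistic": fk.statistic,
            "df": fk.df,
            "p": fk.p,
            "letters": fk.letters,
        }
    if "similarity" in results:
        sim = results["similarity"]
        stats["mantel_tests"] = sim["mantel_tests"].to_dict("records")
        for key in ("ant_mean_ps", "herbivore_mean_ps"):
            if key in sim:
                stats[key] = sim[key]

    report = RunReport(
        config={
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "simulate"},
            "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
        },
        row_counts={k: int(len(v)) for k, v in tables.items()},
        statistics=stats,
        classification=results["classification"].to_dict("records"),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulate is not None:
            survey.write(out / "survey")
        results["profiles"].to_csv(out / "species_profiles.csv", index=False)
        results["community_traits"].to_csv(out / "community_traits.csv", index=False)
        pd.DataFrame(stats["interface_fits"]).to_csv(out / "interface_fits.csv", index=False)
        results["classification"].to_csv(out / "classification.csv", index=False)

        summary = results["classification"][
            [
                "population_id",
                "mean_efn",
                "var_efn",
                "community_size_mm",
                "community_recruitment",
                "ant_abundance",
                "prop_occupied",
                "herbivory",
                "relative_leaf_production",
                "prop_flowering",
                "seedling_density",
            ]
        ].copy()
        if results["anova"] is not None:
            summary["efn_anova_letters"] = summary["population_id"].map(results["anova"].letters)
        if results["fligner"] is not None:
            summary["efn_variance_letters"] = summary["population_id"].map(results["fligner"].letters)
        summary.to_csv(out / "population_summary.csv", index=False)

        if "similarity" in results:
            sim = results["similarity"]
            for key in ("ant_dissimilarity", "herbivore_dissimilarity", "geographic_km"):
                if key in sim:
                    _dm_to_frame(sim[key]).to_csv(out / f"{key}.csv")
            for key in ("ant_ps_tests", "herbivore_ps_tests"):
                if key in sim:
                    sim[key].to_csv(out / f"{key}.csv", index=False)
            sim["mantel_tests"].to_csv(out / "mantel_tests.csv", index=False)
        (out / "report.json").write_text(report.to_json())
        report.outputs = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())

    return report
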