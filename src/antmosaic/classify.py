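"""Matched/mismatched and hotspot/coldspot classification of populations.

A population is phenotypically *matched* when its mean EFN abundance lies
inside the confidence band of the cross-species interface model evaluated at
the population's community-level ant trait (by default the 95% prediction
band, which asks whether the population's EFN value is consistent with the
scatter of EFN values around the interface; a mean-response or
jackknife-propagated band can be selected instead).  Matching is
computed against both the ant-size and the ant-recruitment interface; the
final label follows the size model (the better descriptor of the mosaic),
with the recruitment flag co-reported and disagreements preserved, never
merged.

Matched populations split into two matching types by cohort medians (small
ants with few EFNs vs big ants with many EFNs), and a matched population is
an evolutionary *hotspot* when it additionally shows high performance (at
least two of the three descriptors strictly above the cohort median),
herbivory strictly below the cohort median, and EFN variance in the narrow
variance letter-group.  Hotspot implies matched by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interface import InterfaceModel, predict_band

__all__ = [
    "PopulationPhenotype",
    "MatchingResult",
    "HotspotResult",
    "classify_matching",
    "matching_type",
    "classify_hotspot",
    "classify_cohort",
]

MATCHING_TYPES = ("small-ant/low-EFN", "big-ant/high-EFN", "not-applicable")
PERFORMANCE_FIELDS = ("relative_leaf_production", "prop_flowering", "seedling_density")


@dataclass(frozen=True)
class PopulationPhenotype:
    """Population-level aggregates entering classification."""

    population_id: str
    mean_efn: float
    var_efn: float
    community_size_mm: float
    community_recruitment: float
    ant_abundance: float  # mean standardized ants per plant
    prop_occupied: float
    herbivory: float
    relative_leaf_production: float
    prop_flowering: float
    seedling_density: float

    def has_community_traits(self) -> bool:
        return np.isfinite(self.community_size_mm) and np.isfinite(self.community_recruitment)


@dataclass(frozen=True)
class MatchingResult:
    population_id: str
    matched_by_size: bool | None
    matched_by_recruitment: bool | None
    label: str  # "matched" | "mismatched" | "unclassifiable"
    matching_type: str
    detail: dict = field(default_factory=dict)  # band edges and residual distances


@dataclass(frozen=True)
class HotspotResult:
    population_id: str
    label: str  # "hotspot" | "coldspot-matched" | "coldspot-mismatched" | "unclassifiable"
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label == "hotspot" and not self.criteria.get("matched", False):
            raise ValueError("hotspot requires a matched population")


def _band_flag(pop: PopulationPhenotype, model: InterfaceModel, alpha: float, kind: str):
    """(inside-band flag, detail dict) for one predictor model, or (None, {})."""
    value = getattr(
        pop,
        "community_size_mm" if model.predictor == "body_length_mm" else "community_recruitment",
    )
    if not np.isfinite(value):
        return None, {}
    x0 = float(model.transform_x(value))
    yhat, lo, hi = predict_band(model, x0, alpha=alpha, kind=kind)
    inside = bool(lo <= pop.mean_efn <= hi)
    key = "size" if model.predictor == "body_length_mm" else "recruitment"
    detail = {
        f"{key}_x0": x0,
        f"{key}_predicted_efn": yhat,
        f"{key}_band_low": lo,
        f"{key}_band_high": hi,
        f"{key}_dist_low": pop.mean_efn - lo,
        f"{key}_dist_high": hi - pop.mean_efn,
    }
    return inside, detail


def classify_matching(
    pop: PopulationPhenotype,
    size_model: InterfaceModel | None = None,
    recruitment_model: InterfaceModel | None = None,
    alpha: float = 0.05,
    primary: str = "size",
    band_kind: str = "prediction",
) -> MatchingResult:
    """Classify one population as matched/mismatched against the interface.

    Matched iff the population mean EFN abundance falls within the model's
    confidence band evaluated at the community-level ant trait.  Populations
    without community traits (no occupied plants) are unclassifiable, not
    mismatched.
    """
    if primary not in ("size", "recruitment"):
        raise ValueError(f"primary predictor must be 'size' or 'recruitment', got {primary!r}")
    by_size = by_rec = None
    detail: dict = {}
    if size_model is not None:
        by_size, d = _band_flag(pop, size_model, alpha, band_kind)
        detail.update(d)
    if recruitment_model is not None:
        by_rec, d = _band_flag(pop, recruitment_model, alpha, band_kind)
        detail.update(d)
    primary_flag = by_size if primary == "size" else by_rec
    if primary_flag is None:
        label = "unclassifiable"
    else:
        label = "matched" if primary_flag else "mismatched"
    return MatchingResult(
        population_id=pop.population_id,
        matched_by_size=by_size,
        matched_by_recruitment=by_rec,
        label=label,
        matching_type="not-applicable",
        detail=detail,
    )


def matching_type(
    pop: PopulationPhenotype,
    matching: MatchingResult,
    cohort: pd.DataFrame,
) -> str:
    """Quadrant type of a matched population relative to cohort medians.

    ``cohort`` has columns ``community_size_mm`` and ``mean_efn`` over all
    classified populations.  Strictly below both medians: small-ant/low-EFN;
    at or above both: big-ant/high-EFN; mixed quadrants (or any non-matched
    label): not-applicable.
    """
    if len(cohort) < 3:
        raise ValueError("cohort must contain at least 3 populations")
    if matching.label != "matched":
        return "not-applicable"
    med_size = float(cohort["community_size_mm"].median())
    med_efn = float(cohort["mean_efn"].median())
    if pop.community_size_mm < med_size and pop.mean_efn < med_efn:
        return "small-ant/low-EFN"
    if pop.community_size_mm >= med_size and pop.mean_efn >= med_efn:
        return "big-ant/high-EFN"
    return "not-applicable"


def classify_hotspot(
    pop: PopulationPhenotype,
    matching: MatchingResult,
    cohort: pd.DataFrame,
    variance_letters: dict,
) -> HotspotResult:
    """Hotspot/coldspot label with the full criteria breakdown.

    hotspot iff matched AND >= 2 of the 3 performance descriptors strictly
    exceed the cohort median AND herbivory is strictly below the cohort
    median AND the population shares a variance letter with the
    narrowest-variance population.  The letter criterion operationalizes
    "lower variance of EFN abundance": being statistically indistinguishable
    from the tightest population.
    """
    if matching.label == "unclassifiable":
        return HotspotResult(pop.population_id, "unclassifiable", {})
    matched = matching.label == "matched"
    perf_flags = {
        f: bool(getattr(pop, f) > float(cohort[f].median())) for f in PERFORMANCE_FIELDS
    }
    perf_ok = sum(perf_flags.values()) >= 2
    herb_ok = bool(pop.herbivory < float(cohort["herbivory"].median()))
    narrow_pop = cohort.loc[cohort["var_efn"].idxmin(), "population_id"]
    own = set(variance_letters.get(pop.population_id, ""))
    narrow = set(variance_letters.get(narrow_pop, ""))
    var_ok = bool(own & narrow) if (own or narrow) else True
    criteria = {
        "matched": matched,
        "performance_above_median": perf_ok,
        **{f"{k}_above_median": v for k, v in perf_flags.items()},
        "herbivory_below_median": herb_ok,
        "variance_narrow_group": var_ok,
    }
    if matched and perf_ok and herb_ok and var_ok:
        label = "hotspot"
    else:
        label = "coldspot-matched" if matched else "coldspot-mismatched"
    return HotspotResult(pop.population_id, label, criteria)


def classify_cohort(
    phenotypes: list[PopulationPhenotype],
    size_model: InterfaceModel | None,
    recruitment_model: InterfaceModel | None,
    variance_letters: dict,
    alpha: float = 0.05,
    primary: str = "size",
    band_kind: str = "prediction",
) -> pd.DataFrame:
    """Classify every population; one row each, sorted by population id.

    Deterministic in the inputs and invariant to the order phenotypes are
    supplied in (cohort medians are order-free).
    """
    phenotypes = sorted(phenotypes, key=lambda p: p.population_id)
    matchings = {
        p.population_id: classify_matching(
            p, size_model, recruitment_model, alpha=alpha, primary=primary, band_kind=band_kind
        )
        for p in phenotypes
    }
    cohort = pd.DataFrame(
        [
            {
                "population_id": p.population_id,
                "community_size_mm": p.community_size_mm,
                "mean_efn": p.mean_efn,
                "var_efn": p.var_efn,
                "herbivory": p.herbivory,
                **{f: getattr(p, f) for f in PERFORMANCE_FIELDS},
            }
            for p in phenotypes
        ]
    )
    rows = []
    for p in phenotypes:
        m = matchings[p.population_id]
        mtype = (
            matching_type(p, m, cohort)
            if m.label == "matched" and len(cohort) >= 3
            else "not-applicable"
        )
        h = classify_hotspot(p, m, cohort, variance_letters)
        rows.append(
            {
                "population_id": p.population_id,
                "label": m.label,
                "matched_by_size": m.matched_by_size,
                "matched_by_recruitment": m.matched_by_recruitment,
                "matching_type": mtype,
                "hotspot_label": h.label,
                "mean_efn": p.mean_efn,
                "var_efn": p.var_efn,
                "community_size_mm": p.community_size_mm,
                "community_recruitment": p.community_recruitment,
                "ant_abundance": p.ant_abundance,
                "prop_occupied": p.prop_occupied,
                "herbivory": p.herbivory,
                "relative_leaf_production": p.relative_leaf_production,
                "prop_flowering": p.prop_flowering,
                "seedling_density": p.seedling_density,
                **{f"criterion_{k}": v for k, v in h.criteria.items()},
                **m.detail,
            }
        )
    return pd.DataFrame(rows)
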