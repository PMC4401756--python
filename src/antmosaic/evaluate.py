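"""Calibration and recovery experiments for the analysis pipeline.

These functions measure, by simulation, the statistical behaviour the
pipeline's components are supposed to have: type-I error of the Mantel and
Fligner-Killeen tests at their nominal level, power of the variance test,
coverage of the jackknife interface slope, and recovery of designed
matched/mismatched and hotspot labels from synthetic surveys.  They are used
by the test suite and the reproduction script, and are handy when adapting
the generator to a new study system.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .interface import fit_interface
from .metrics import fligner_killeen
from .pipeline import PipelineConfig, analyze_survey
from .similarity import DistanceMatrix, mantel_test
from .simulate import ScenarioConfig, generate_interface_pool, generate_survey

__all__ = [
    "mantel_null_rejection_rate",
    "fligner_type1_rate",
    "fligner_power_rate",
    "interface_slope_coverage",
    "matching_recovery",
]


def _random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"L{i}" for i in range(n)])


def mantel_null_rejection_rate(
    n_sims: int = 500,
    n_localities: int = 10,
    n_perm: int = 999,
    alpha: float = 0.05,
    tail: str = "greater",
    seed: int = 0,
) -> float:
    """Type-I error of the Mantel test on independent random distance matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        d1 = _random_distance_matrix(rng, n_localities)
        d2 = _random_distance_matrix(rng, n_localities)
        res = mantel_test(d1, d2, n_perm=n_perm, tail=tail, seed=int(rng.integers(2**31)))
        rejections += res.p <= alpha
    return rejections / n_sims


def fligner_type1_rate(
    n_sims: int = 500,
    n_groups: int = 4,
    group_size: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the FK omnibus test on equal-variance normal groups.

    Group sizes default to the regime the pipeline actually works in
    (tens of plants per population); the normal-scores statistic is known
    to be conservative for much smaller groups.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = {f"g{j}": rng.normal(j, 1.0, group_size) for j in range(n_groups)}
        res = fligner_killeen(groups, pairwise=False)
        rejections += res.p <= alpha
    return rejections / n_sims


def fligner_power_rate(
    n_sims: int = 200,
    n_groups: int = 4,
    group_size: int = 30,
    spread_factor: float = 10.0,
    p_threshold: float = 0.01,
    seed: int = 0,
) -> float:
    """Detection rate of one wide-spread group among otherwise equal groups."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_sims):
        groups = {f"g{j}": rng.normal(0.0, 1.0, group_size) for j in range(n_groups - 1)}
        groups["wide"] = rng.normal(0.0, spread_factor, group_size)
        res = fligner_killeen(groups, pairwise=False)
        detected += res.p < p_threshold
    return detected / n_sims


def interface_slope_coverage(
    n_sims: int = 200,
    n_species: int = 15,
    slope: float = 4.5,
    intercept: float = -10.0,
    noise_sd: float = 6.0,
    n_se: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of synthetic pools whose generating slope falls within
    ``n_se`` jackknife SEs of the fitted interface slope."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sims):
        pool = generate_interface_pool(
            n_species=n_species,
            intercept=intercept,
            slope=slope,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        model = fit_interface(pool, "body_length_mm", "mean_efn_visited")
        f = model.fit
        covered += abs(f.jk_slope - slope) <= n_se * f.jk_se
    return covered / n_sims


def matching_recovery(
    n_seeds: int = 100,
    base_config: ScenarioConfig | None = None,
    seed: int = 0,
) -> dict:
    """Recovery of designed matched/mismatched and hotspot labels.

    Runs the full analysis on ``n_seeds`` independently generated surveys of
    the default mosaic design and scores the classifier against the
    generator's ground truth.  Returns mean matched/mismatched accuracy,
    designed-hotspot recall, and the fraction of runs in which every hotspot
    label implied a matched label.
    """
    base = base_config if base_config is not None else ScenarioConfig()
    rng = np.random.default_rng(seed)
    accuracies, recalls, implies = [], [], []
    per_run = []
    for _ in range(n_seeds):
        cfg = dataclasses.replace(base, seed=int(rng.integers(2**31)))
        survey = generate_survey(cfg)
        results = analyze_survey(
            survey.tables, PipelineConfig(seed=cfg.seed, compute_similarity=False)
        )
        cls = results["classification"].set_index("population_id")
        gt = survey.ground_truth.populations
        correct = hot_hits = hot_total = 0
        ok = True
        for pop, truth in gt.items():
            predicted = cls.loc[pop, "label"]
            if predicted == ("matched" if truth["matched"] else "mismatched"):
                correct += 1
            if truth["hotspot"]:
                hot_total += 1
                hot_hits += cls.loc[pop, "hotspot_label"] == "hotspot"
            if cls.loc[pop, "hotspot_label"] == "hotspot" and predicted != "matched":
                ok = False
        accuracies.append(correct / len(gt))
        recalls.append(hot_hits / hot_total if hot_total else np.nan)
        implies.append(ok)
        per_run.append((cfg.seed, correct / len(gt), hot_hits / hot_total if hot_total else np.nan))
    return {
        "accuracy_mean": float(np.mean(accuracies)),
        "hotspot_recall_mean": float(np.nanmean(recalls)),
        "hotspot_implies_matched_rate": float(np.mean(implies)),
        "n_seeds": n_seeds,
        "per_run": pd.DataFrame(per_run, columns=["seed", "accuracy", "hotspot_recall"]),
    }
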