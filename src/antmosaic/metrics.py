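"""Per-plant herbivory / performance descriptors and population-level tests.

Herbivory is the mean proportion of leaflet area damaged per plant; the three
performance descriptors are relative leaf production (bounded below by -1),
the proportion of flowering plants, and seedling density around adults.
Population comparisons use one-way ANOVA with Tukey HSD letter displays,
jackknifed Pearson correlations, and the Fligner-Killeen test of equal
variances with Holm-adjusted pairwise letter groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "VarianceComparison",
    "JackknifeCorrelation",
    "plant_phenotypes",
    "herbivory_proportion",
    "relative_leaf_production",
    "population_performance",
    "anova_oneway",
    "fligner_killeen",
    "jackknife_correlation",
    "compact_letters",
]

TAILS = ("two-sided", "greater", "less")
_TINY_P = float(np.finfo(float).tiny)


def herbivory_proportion(total_areas, damaged_areas) -> float:
    """Mean over leaflets of damaged/total area, in [0, 1]."""
    total = np.asarray(total_areas, dtype=float)
    damaged = np.asarray(damaged_areas, dtype=float)
    if total.size == 0:
        raise ValueError("plant has no leaflet measurements")
    if np.any(total <= 0):
        raise ValueError("leaflet with zero or negative total area")
    if np.any(damaged < 0) or np.any(damaged > total + 1e-9):
        raise ValueError("damaged area outside [0, total]")
    return float(np.mean(damaged / total))


def plant_phenotypes(leaflets: pd.DataFrame) -> pd.DataFrame:
    """Per-plant EFN abundance and herbivory from leaflet measurements.

    Plant EFN abundance is the mean leaflet-base EFN count over the sampled
    leaflets; herbivory is the mean proportion of leaflet area damaged.
    """
    rows = []
    for pid, grp in leaflets.groupby("plant_id", sort=True):
        rows.append(
            (
                pid,
                float(grp["efn_count_base"].mean()),
                herbivory_proportion(grp["total_area_mm2"], grp["damaged_area_mm2"]),
                float(grp["efn_diameter_mm"].mean()),
            )
        )
    return pd.DataFrame(rows, columns=["plant_id", "plant_efn", "plant_herbivory", "plant_efn_diameter"])


def relative_leaf_production(n_t0, n_t1):
    """(leaves at t1 - leaves at t0) / leaves at t0; ranges from -1 upward."""
    n_t0 = np.asarray(n_t0, dtype=float)
    if np.any(n_t0 <= 0):
        raise ValueError("plant with no leaves at t0")
    return (np.asarray(n_t1, dtype=float) - n_t0) / n_t0


def population_performance(plants_wide: pd.DataFrame) -> tuple[float, float, float]:
    """(mean relative leaf production, proportion flowering, mean seedlings).

    ``plants_wide`` holds one row per plant with columns ``n_leaves_t0``,
    ``n_leaves_t1``, ``flowering_t1`` and ``n_seedlings_2m_t1``.
    """
    if len(plants_wide) == 0:
        raise ValueError("empty population")
    rlp = relative_leaf_production(plants_wide["n_leaves_t0"], plants_wide["n_leaves_t1"])
    return (
        float(np.mean(rlp)),
        float(np.mean(plants_wide["flowering_t1"].astype(float))),
        float(np.mean(plants_wide["n_seedlings_2m_t1"].astype(float))),
    )


def compact_letters(ordered_labels: Sequence, significant_pairs) -> dict:
    """Compact letter display from pairwise significance decisions.

    Labels must be ordered by the quantity being compared (ascending).  Groups
    are the maximal contiguous runs containing no significantly different
    pair; a shared letter means "not significantly different".
    """
    sig = {frozenset(p) for p in significant_pairs}
    n = len(ordered_labels)
    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and not any(
            frozenset((ordered_labels[a], ordered_labels[b])) in sig
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    # keep only maximal runs
    runs = [r for r in runs if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    runs.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict = {lab: "" for lab in ordered_labels}
    for k, (lo, hi) in enumerate(runs):
        for idx in range(lo, hi + 1):
            letters[ordered_labels[idx]] += alphabet[k % len(alphabet)]
    return letters


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    letters: dict = field(default_factory=dict)


def anova_oneway(groups: Mapping, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across populations with a Tukey HSD letter display.

    Tukey HSD (Tukey-Kramer under unequal group sizes) at ``alpha`` produces
    the letters: populations sharing a letter are not significantly different.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_tot = sum(len(a) for a in arrays)
    means = {lab: float(np.mean(a)) for lab, a in zip(labels, arrays)}

    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * len(a) for lab, a in zip(labels, arrays)])
    sig_pairs = set()
    if np.ptp(values) > 0:
        tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
        uniq = list(tk.groupsunique)
        for (i, j), reject in zip(
            [(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq))], tk.reject
        ):
            if reject:
                sig_pairs.add(frozenset((uniq[i], uniq[j])))
    order = sorted(labels, key=lambda lab: means[lab])
    letters = compact_letters(order, sig_pairs)
    return AnovaResult(
        f=float(f) if np.isfinite(f) else 0.0,
        df_between=k - 1,
        df_within=n_tot - k,
        p=float(p) if np.isfinite(p) else 1.0,
        group_means=means,
        letters=letters,
    )


def _fligner_statistic(arrays: Sequence[np.ndarray]) -> tuple[float, int]:
    """Fligner-Killeen chi-square via median-centered normal scores.

    Each group is centered at its median; the pooled absolute deviations are
    midranked and transformed to normal scores Phi^-1(1/2 + r/(2(N+1))); the
    statistic is sum n_j (A_j - abar)^2 / s^2 with s^2 the (N-1)-denominator
    variance of all scores.
    """
    absdev = [np.abs(a - np.median(a)) for a in arrays]
    pooled = np.concatenate(absdev)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)  # midranks for ties
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n_tot + 1.0)))
    abar = scores.mean()
    s2 = np.sum((scores - abar) ** 2) / (n_tot - 1)
    stat = 0.0
    pos = 0
    for a in arrays:
        gs = scores[pos : pos + a.size]
        pos += a.size
        stat += a.size * (gs.mean() - abar) ** 2
    return (stat / s2 if s2 > 0 else 0.0, len(arrays) - 1)


@dataclass(frozen=True)
class VarianceComparison:
    statistic: float
    df: int
    p: float
    group_variances: dict
    letters: dict = field(default_factory=dict)
    pairwise_p: dict = field(default_factory=dict)  # Holm-adjusted


def fligner_killeen(groups: Mapping, alpha: float = 0.05, pairwise: bool = True) -> VarianceComparison:
    """Fligner-Killeen test of equal variances with pairwise letter groups.

    The omnibus statistic is the normal-scores chi-square with k-1 df.
    Pairwise two-group FK tests, Holm-adjusted, feed a compact letter display
    over groups ordered by sample variance (shared letter: variances not
    significantly different).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("Fligner-Killeen needs >= 2 groups with >= 2 values each")
    stat, df = _fligner_statistic(arrays)
    p = float(stats.chi2.sf(stat, df))
    variances = {lab: float(np.var(a, ddof=1)) for lab, a in zip(labels, arrays)}

    letters: dict = {}
    adj: dict = {}
    if pairwise and len(arrays) > 1:
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        raw = []
        for i, j in pairs:
            s_ij, df_ij = _fligner_statistic([arrays[i], arrays[j]])
            raw.append(float(stats.chi2.sf(s_ij, df_ij)))
        # Holm step-down adjustment
        m = len(raw)
        order = np.argsort(raw)
        steps = np.minimum(1.0, (m - np.arange(m)) * np.asarray(raw)[order])
        adjusted = np.empty(m)
        adjusted[order] = np.maximum.accumulate(steps)
        sig_pairs = set()
        for (i, j), pa in zip(pairs, adjusted):
            adj[(labels[i], labels[j])] = float(pa)
            if pa <= alpha:
                sig_pairs.add(frozenset((labels[i], labels[j])))
        ordered = sorted(labels, key=lambda lab: variances[lab])
        letters = compact_letters(ordered, sig_pairs)
    return VarianceComparison(
        statistic=float(stat), df=df, p=p, group_variances=variances, letters=letters, pairwise_p=adj
    )


def _tail_p(t: float, df: int, tail: str) -> float:
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(min(max(p, _TINY_P), 1.0))


@dataclass(frozen=True)
class JackknifeCorrelation:
    r: float  # full-sample Pearson r
    estimate: float  # mean of jackknife pseudo-values
    se: float
    t: float
    p: float
    tail: str
    n: int


def jackknife_correlation(x, y, tail: str = "two-sided") -> JackknifeCorrelation:
    """Pearson correlation with delete-one jackknife inference.

    Pseudo-values r_i* = n r - (n-1) r_(-i); the estimate is their mean, the
    SE their sd/sqrt(n), and the test a t with n-1 df under the chosen tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"jackknife correlation needs n >= 4, got {n}")
    if y.size != n or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be equal-length finite arrays")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")

    def _r(xv, yv):
        xc = xv - xv.mean()
        yc = yv - yv.mean()
        return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))

    r_full = _r(x, y)
    idx = np.arange(n)
    loo = np.array([_r(x[idx != i], y[idx != i]) for i in range(n)])
    pseudo = n * r_full - (n - 1) * loo
    est = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        if est == 0.0:
            t, p = 0.0, _tail_p(0.0, n - 1, tail)
        else:
            t = math_inf_sign(est)
            p = _TINY_P if _direction_ok(est, tail) else 1.0
    else:
        t = est / se
        p = _tail_p(t, n - 1, tail)
    return JackknifeCorrelation(r=r_full, estimate=est, se=se, t=float(t), p=p, tail=tail, n=n)


def math_inf_sign(v: float) -> float:
    return float(np.inf if v >= 0 else -np.inf)


def _direction_ok(estimate: float, tail: str) -> bool:
    if tail == "greater":
        return estimate > 0
    if tail == "less":
        return estimate < 0
    return True
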