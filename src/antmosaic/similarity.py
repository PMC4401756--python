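"""Assemblage similarity, dissimilarity matrices and Mantel tests.

Localities are compared with the Steinhaus proportional similarity index

    PS = 2W / (A + B)

where ``W`` is the sum over species of the minimum abundance observed at the
two localities and ``A``, ``B`` are the two locality totals.  ``PS`` is 1 for
identical raw-abundance assemblages and 0 when no taxon is shared.  The null
hypothesis of "dissimilar assemblage composition" (PS = 0, no taxa in common)
is assessed with a bootstrap percentile confidence interval obtained by
resampling individual specimens (species tokens) within each assemblage.

Spatial dependence of ecological dissimilarity (1 - PS, or plain Euclidean
distance for scalar descriptors) is tested against great-circle geographic
distance with a Mantel permutation test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio.stats.distance import DistanceMatrix

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "AssemblageCounts",
    "PSTestResult",
    "MantelResult",
    "proportional_similarity",
    "bootstrap_ps_test",
    "dissimilarity_matrix",
    "scalar_dissimilarity",
    "geographic_distance_matrix",
    "mantel_test",
    "DistanceMatrix",
]


@dataclass(frozen=True)
class AssemblageCounts:
    """Species-abundance vector of one locality.

    Abundances may be raw specimen counts or standardized (real-valued)
    abundances; the PS formula is the same for both.
    """

    label: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative abundance for {sp!r} in {self.label!r}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def require_nonempty(self) -> None:
        if self.total <= 0:
            raise ValueError(f"assemblage {self.label!r} has zero total abundance")


@dataclass(frozen=True)
class PSTestResult:
    """Bootstrap significance test of one pairwise PS coefficient."""

    ps: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    reject_dissimilarity: bool


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None
    method: str = "permutation"


def proportional_similarity(a: AssemblageCounts, b: AssemblageCounts) -> float:
    """Steinhaus coefficient PS = 2W/(A+B) between two assemblages."""
    a.require_nonempty()
    b.require_nonempty()
    w = 0.0
    for sp in set(a.counts) & set(b.counts):
        w += min(a.counts[sp], b.counts[sp])
    return 2.0 * w / (a.total + b.total)


def _resample(counts: Mapping[str, float], rng: np.random.Generator) -> dict[str, float]:
    # Resample specimens with replacement.  For integer counts this is exactly
    # the multinomial over species tokens; real-valued (standardized)
    # abundances resample round(total) pseudo-specimens with the same species
    # proportions.
    species = list(counts)
    values = np.array([counts[s] for s in species], dtype=float)
    total = values.sum()
    n = max(int(round(total)), 1)
    draw = rng.multinomial(n, values / total) * (total / n)
    return {s: d for s, d in zip(species, draw) if d > 0}


def bootstrap_ps_test(
    a: AssemblageCounts,
    b: AssemblageCounts,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PSTestResult:
    """Percentile bootstrap CI for PS and the PS = 0 significance call.

    Specimens are resampled with replacement independently within each
    assemblage, PS recomputed per replicate, and the (1 - alpha) percentile
    interval reported.  The null "no taxa in common" is rejected when the
    lower confidence limit stays above zero.  The observed PS is included as
    one pseudo-replicate so the interval always covers the point estimate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_boot < 200:
        raise ValueError(f"n_boot must be at least 200, got {n_boot}")
    a.require_nonempty()
    b.require_nonempty()
    rng = np.random.default_rng(seed)
    ps_obs = proportional_similarity(a, b)
    reps = np.empty(n_boot + 1)
    for i in range(n_boot):
        ra = AssemblageCounts(a.label, _resample(a.counts, rng))
        rb = AssemblageCounts(b.label, _resample(b.counts, rng))
        reps[i] = proportional_similarity(ra, rb)
    reps[n_boot] = ps_obs
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return PSTestResult(
        ps=ps_obs,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        reject_dissimilarity=bool(lo > 0.0),
    )


def dissimilarity_matrix(assemblages: Sequence[AssemblageCounts]) -> DistanceMatrix:
    """Pairwise 1 - PS matrix over a set of localities."""
    labels = [a.label for a in assemblages]
    if len(labels) < 2:
        raise ValueError("need at least two localities")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate locality labels")
    n = len(assemblages)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = 1.0 - proportional_similarity(assemblages[i], assemblages[j])
    return DistanceMatrix(d, ids=labels)


def scalar_dissimilarity(values: Mapping[str, float]) -> DistanceMatrix:
    """Euclidean (absolute-difference) distance matrix of a per-locality scalar."""
    labels = list(values)
    if len(labels) < 2:
        raise ValueError("need at least two localities")
    x = np.array([values[k] for k in labels], dtype=float)
    if not np.all(np.isfinite(x)):
        bad = [k for k, v in values.items() if not math.isfinite(v)]
        raise ValueError(f"non-finite value for localities {bad}")
    d = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


def geographic_distance_matrix(coords: Mapping[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from per-locality (lat, lon) degrees."""
    labels = list(coords)
    lat = np.radians([coords[k][0] for k in labels])
    lon = np.radians([coords[k][1] for k in labels])
    if np.any(np.abs(np.degrees(lat)) > 90.0) or np.any(np.abs(np.degrees(lon)) > 180.0):
        raise ValueError("coordinates out of range (lat in [-90, 90], lon in [-180, 180])")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(np.sqrt(h), 1.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


def _pearson_rows(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Pearson correlation of each row of w against the fixed vector v.
    vc = v - v.mean()
    wc = w - w.mean(axis=-1, keepdims=True)
    num = wc @ vc
    den = np.sqrt((vc @ vc) * (wc * wc).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 5000,
    tail: str = "greater",
    seed: int | None = None,
    method: str = "permutation",
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    The statistic is the Pearson correlation of the corresponding
    upper-triangle entries; significance comes from jointly permuting the rows
    and columns of the second matrix.  ``method='permutation'`` draws
    ``n_perm`` random permutations and applies the +1 correction, so p is
    never 0 and never below 1/(n_perm + 1).  ``method='exact'`` enumerates all
    n! relabelings (n <= 8) and reports the exact fraction as or more extreme,
    identity included.

    tail: 'greater' (default; positive spatial dependence), 'less', or
    'two-sided' (on \\|r\\|).
    """
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share identical locality labels and order")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 localities")
    m1 = np.asarray(d1.data, dtype=float)
    m2 = np.asarray(d2.data, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    v1 = m1[iu, ju]
    r_obs = float(_pearson_rows(v1, m2[iu, ju][None, :])[0])

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 localities")
        perms = np.array(list(itertools.permutations(range(n))))
        n_used = len(perms)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    v2p = m2[perms[:, iu], perms[:, ju]]
    r_perm = _pearson_rows(v1, v2p)
    r_perm = np.nan_to_num(r_perm, nan=0.0)
    eps = 1e-12
    if tail == "greater":
        extreme = int(np.sum(r_perm >= r_obs - eps))
    elif tail == "less":
        extreme = int(np.sum(r_perm <= r_obs + eps))
    else:
        extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))

    if method == "exact":
        p = extreme / n_used
    else:
        p = (1 + extreme) / (n_used + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_used, tail=tail, seed=seed, method=method)


def assemblage_from_observations(
    label: str, observations: Iterable[tuple[str, float]]
) -> AssemblageCounts:
    """Aggregate (species, count) observation rows into one locality assemblage."""
    counts: dict[str, float] = {}
    for sp, c in observations:
        counts[sp] = counts.get(sp, 0.0) + float(c)
    return AssemblageCounts(label, counts)
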