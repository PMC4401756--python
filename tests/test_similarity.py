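"""Proportional similarity, bootstrap significance, distances and Mantel tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import mantel as skbio_mantel

from antmosaic.similarity import (
    AssemblageCounts,
    DistanceMatrix,
    bootstrap_ps_test,
    dissimilarity_matrix,
    geographic_distance_matrix,
    mantel_test,
    proportional_similarity,
    scalar_dissimilarity,
)


def _ps_oracle(a: dict, b: dict) -> float:
    # direct evaluation of 2W/(A+B), independent of the implementation
    w = sum(min(a[s], b[s]) for s in a if s in b)
    return 2.0 * w / (sum(a.values()) + sum(b.values()))


class TestProportionalSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"s1": 4, "s2": 6}, {"s1": 4, "s2": 6}, 1.0),
            ({"s1": 4}, {"s2": 7}, 0.0),
            ({"s1": 3, "s2": 1}, {"s1": 1, "s2": 1}, 2.0 * 2.0 / 6.0),
        ],
    )
    def test_hand_examples(self, a, b, expected):
        ps = proportional_similarity(AssemblageCounts("a", a), AssemblageCounts("b", b))
        assert ps == pytest.approx(expected, abs=1e-12)

    def test_empty_assemblage_rejected(self):
        with pytest.raises(ValueError):
            proportional_similarity(AssemblageCounts("a", {}), AssemblageCounts("b", {"s": 1}))
        with pytest.raises(ValueError):
            AssemblageCounts("a", {"s": -1})

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_range_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        species = [f"s{i}" for i in range(8)]
        a = {s: int(c) for s, c in zip(species, rng.integers(0, 20, 8)) if c > 0}
        b = {s: int(c) for s, c in zip(species, rng.integers(0, 20, 8)) if c > 0}
        if not a or not b:
            return
        ca, cb = AssemblageCounts("a", a), AssemblageCounts("b", b)
        ps = proportional_similarity(ca, cb)
        assert proportional_similarity(cb, ca) == ps
        assert 0.0 <= ps <= 1.0
        assert ps == pytest.approx(_ps_oracle(a, b), abs=1e-12)

    def test_identity_iff_equal_raw_abundances(self):
        # PS = 1 exactly for identical multisets; proportional but unequal
        # totals stay below 1 (no normalization is applied)
        same = AssemblageCounts("a", {"x": 3, "y": 7})
        assert proportional_similarity(same, AssemblageCounts("b", {"x": 3, "y": 7})) == 1.0
        scaled = AssemblageCounts("b", {"x": 6, "y": 14})
        assert proportional_similarity(same, scaled) < 1.0


class TestBootstrapPS:
    def test_disjoint_ci_is_degenerate(self):
        res = bootstrap_ps_test(
            AssemblageCounts("a", {"s1": 30}),
            AssemblageCounts("b", {"s2": 40}),
            n_boot=400,
            seed=1,
        )
        assert res.ps == 0.0 and (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert not res.reject_dissimilarity

    def test_identical_assemblages_reject_null(self):
        a = AssemblageCounts("a", {"s1": 60, "s2": 40})
        res = bootstrap_ps_test(a, AssemblageCounts("b", {"s1": 60, "s2": 40}), n_boot=1000, seed=2)
        assert res.reject_dissimilarity
        assert res.ci_low <= res.ps <= res.ci_high

    def test_deterministic_under_seed(self):
        a = AssemblageCounts("a", {"s1": 10, "s2": 5, "s3": 2})
        b = AssemblageCounts("b", {"s1": 4, "s3": 9})
        assert bootstrap_ps_test(a, b, seed=7) == bootstrap_ps_test(a, b, seed=7)

    def test_invalid_arguments(self):
        a = AssemblageCounts("a", {"s1": 10})
        with pytest.raises(ValueError):
            bootstrap_ps_test(a, a, alpha=1.5)
        with pytest.raises(ValueError):
            bootstrap_ps_test(a, a, n_boot=50)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for scale, label in ((1, "small"), (20, "large")):
            ws = []
            for seed in range(8):
                a = AssemblageCounts("a", {"s1": 6 * scale, "s2": 4 * scale})
                b = AssemblageCounts("b", {"s1": 4 * scale, "s2": 6 * scale})
                r = bootstrap_ps_test(a, b, n_boot=400, seed=seed)
                ws.append(r.ci_high - r.ci_low)
            widths[label] = np.mean(ws)
        assert widths["large"] < widths["small"]


class TestDistanceMatrices:
    def test_dissimilarity_identical_and_disjoint(self):
        same = [AssemblageCounts(f"L{i}", {"x": 2, "y": 3}) for i in range(3)]
        dm = dissimilarity_matrix(same)
        assert np.allclose(dm.data, 0.0)
        disjoint = [AssemblageCounts(f"L{i}", {f"sp{i}": 5}) for i in range(3)]
        dm = dissimilarity_matrix(disjoint)
        off = dm.data[np.triu_indices(3, k=1)]
        assert np.allclose(off, 1.0)

    def test_three_locality_hand_matrix(self):
        a = AssemblageCounts("a", {"s1": 3, "s2": 1})
        b = AssemblageCounts("b", {"s1": 1, "s2": 1})
        c = AssemblageCounts("c", {"s3": 5})
        dm = dissimilarity_matrix([a, b, c])
        assert dm["a", "b"] == pytest.approx(1.0 - 2.0 * 2.0 / 6.0, abs=1e-12)
        assert dm["a", "c"] == 1.0 and dm["b", "c"] == 1.0

    def test_duplicate_labels_rejected(self):
        a = AssemblageCounts("a", {"s": 1})
        with pytest.raises(ValueError):
            dissimilarity_matrix([a, a])

    def test_scalar_dissimilarity(self):
        dm = scalar_dissimilarity({"a": 1.0, "b": 4.0, "c": 6.0})
        assert dm["a", "b"] == 3.0 and dm["a", "c"] == 5.0 and dm["b", "c"] == 2.0
        assert np.allclose(scalar_dissimilarity({"a": 2.0, "b": 2.0}).data, 0.0)
        with pytest.raises(ValueError):
            scalar_dissimilarity({"a": 1.0, "b": float("nan")})

    def test_haversine_closed_forms(self):
        dm = geographic_distance_matrix({"o": (0.0, 0.0), "e": (0.0, 1.0), "anti": (0.0, 180.0)})
        assert dm["o", "o"] == 0.0
        assert dm["o", "e"] == pytest.approx(111.19492664455873, rel=1e-9)
        assert dm["o", "anti"] == pytest.approx(20015.086796020572, rel=1e-9)
        with pytest.raises(ValueError):
            geographic_distance_matrix({"bad": (95.0, 0.0), "ok": (0.0, 0.0)})


def _random_dm(rng, n, ids=None):
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=ids or [f"L{i}" for i in range(n)])


class TestMantel:
    def test_self_correlation(self, rng):
        d = _random_dm(rng, 6)
        res = mantel_test(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p >= 1.0 / 200.0

    def test_exact_enumeration_matches_brute_force(self, rng):
        # independent oracle: enumerate all 24 relabelings with plain numpy
        d1, d2 = _random_dm(rng, 4), _random_dm(rng, 4)
        m1, m2 = d1.data, d2.data
        iu = np.triu_indices(4, k=1)
        v1 = m1[iu]

        def corr(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        r_obs = corr(v1, m2[iu])
        count = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            p = np.asarray(perm)
            r_p = corr(v1, m2[np.ix_(p, p)][iu])
            count += r_p >= r_obs - 1e-12
            total += 1
        res = mantel_test(d1, d2, tail="greater", method="exact")
        assert res.p == pytest.approx(count / total, abs=1e-12)
        assert res.n_perm == 24

    def test_agrees_with_skbio(self, rng):
        d1, d2 = _random_dm(rng, 8), _random_dm(rng, 8)
        r_ref, p_ref, _ = skbio_mantel(d1, d2, permutations=999, alternative="greater")
        res = mantel_test(d1, d2, n_perm=999, tail="greater", seed=1)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(res.p - p_ref) < 0.12  # same test, independent permutation streams

    def test_label_and_size_preconditions(self, rng):
        d1 = _random_dm(rng, 4, ids=list("abcd"))
        d2 = _random_dm(rng, 4, ids=list("abce"))
        with pytest.raises(ValueError):
            mantel_test(d1, d2)
        small = _random_dm(rng, 2)
        with pytest.raises(ValueError):
            mantel_test(small, small)

    def test_tails_are_complementary(self, rng):
        d1, d2 = _random_dm(rng, 7), _random_dm(rng, 7)
        g = mantel_test(d1, d2, n_perm=999, tail="greater", seed=3)
        l = mantel_test(d1, d2, n_perm=999, tail="less", seed=3)
        # same permutations: counts of >= and <= sum to >= n_perm
        assert g.p + l.p >= 999.0 / 1000.0
        assert g.r == l.r
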