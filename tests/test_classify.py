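"""Matched/mismatched classification, matching types, hotspot logic."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from antmosaic.classify import (
    HotspotResult,
    PopulationPhenotype,
    classify_cohort,
    classify_hotspot,
    classify_matching,
    matching_type,
)
from antmosaic.interface import fit_interface, predict_band
from antmosaic.simulate import generate_interface_pool


def _model(noise_sd=4.0, seed=1):
    pool = generate_interface_pool(noise_sd=noise_sd, seed=seed)
    return fit_interface(pool, "body_length_mm", "mean_efn_visited")


def _pop(pid="popX", efn=20.0, size=7.0, **kw):
    defaults = dict(
        var_efn=20.0,
        community_recruitment=10.0,
        ant_abundance=5.0,
        prop_occupied=0.8,
        herbivory=0.3,
        relative_leaf_production=0.1,
        prop_flowering=0.5,
        seedling_density=1.5,
    )
    defaults.update(kw)
    return PopulationPhenotype(
        population_id=pid, mean_efn=efn, community_size_mm=size, **defaults
    )


class TestClassifyMatching:
    def test_on_the_line_is_matched(self):
        model = _model()
        size = 7.0
        yhat, _, _ = predict_band(model, size, kind="prediction")
        res = classify_matching(_pop(efn=yhat, size=size), size_model=model)
        assert res.label == "matched" and res.matched_by_size is True

    def test_far_outside_is_mismatched(self):
        model = _model()
        size = 7.0
        yhat, lo, hi = predict_band(model, size, kind="prediction")
        res = classify_matching(_pop(efn=yhat + 10 * (hi - yhat), size=size), size_model=model)
        assert res.label == "mismatched" and res.matched_by_size is False

    def test_no_community_trait_unclassifiable(self):
        res = classify_matching(_pop(size=float("nan")), size_model=_model())
        assert res.label == "unclassifiable"
        assert res.matched_by_size is None

    def test_both_predictors_reported(self):
        size_model = _model(seed=1)
        pool = generate_interface_pool(noise_sd=4.0, seed=2)
        pool["recruitment"] = np.exp(4.2 - 0.28 * pool["body_length_mm"])
        rec_model = fit_interface(pool, "recruitment", "mean_efn_visited")
        res = classify_matching(_pop(), size_model=size_model, recruitment_model=rec_model)
        assert res.matched_by_size is not None and res.matched_by_recruitment is not None

    def test_unknown_primary_rejected(self):
        with pytest.raises(ValueError):
            classify_matching(_pop(), size_model=_model(), primary="nectar")


def _cohort(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "population_id",
            "community_size_mm",
            "mean_efn",
            "var_efn",
            "herbivory",
            "relative_leaf_production",
            "prop_flowering",
            "seedling_density",
        ],
    )


class TestMatchingType:
    def _matched_result(self, pid):
        model = _model()
        yhat, _, _ = predict_band(model, 7.0, kind="prediction")
        return classify_matching(_pop(pid, efn=yhat, size=7.0), size_model=model)

    def test_quadrants_by_cohort_medians(self):
        cohort = _cohort(
            [("p1", 3.0, 5.0, 1, 0.3, 0.1, 0.5, 1.0)]
            + [(f"p{i}", 9.0, 45.0, 1, 0.3, 0.1, 0.5, 1.0) for i in range(2, 9)]
        )
        m = self._matched_result("p1")
        assert matching_type(_pop("p1", efn=5.0, size=3.0), m, cohort) == "small-ant/low-EFN"
        assert matching_type(_pop("p2", efn=45.0, size=9.0), m, cohort) == "big-ant/high-EFN"
        # mixed quadrant: big ants, few EFNs
        assert matching_type(_pop("p3", efn=5.0, size=9.0), m, cohort) == "not-applicable"

    def test_exactly_at_medians_counts_as_big(self):
        cohort = _cohort([(f"p{i}", 6.0, 30.0, 1, 0.3, 0.1, 0.5, 1.0) for i in range(5)])
        m = self._matched_result("p0")
        assert matching_type(_pop("p0", efn=30.0, size=6.0), m, cohort) == "big-ant/high-EFN"

    def test_mismatched_gets_not_applicable(self):
        model = _model()
        yhat, lo, hi = predict_band(model, 7.0, kind="prediction")
        m = classify_matching(_pop("p0", efn=yhat + 20 * (hi - yhat), size=7.0), size_model=model)
        cohort = _cohort([(f"p{i}", 6.0, 30.0, 1, 0.3, 0.1, 0.5, 1.0) for i in range(5)])
        assert matching_type(_pop("p0"), m, cohort) == "not-applicable"

    def test_small_cohort_rejected(self):
        cohort = _cohort([("p1", 6.0, 30.0, 1, 0.3, 0.1, 0.5, 1.0)] * 2)
        with pytest.raises(ValueError):
            matching_type(_pop("p1"), self._matched_result("p1"), cohort)


class TestClassifyHotspot:
    def _matched_result(self, pid, matched=True):
        model = _model()
        yhat, lo, hi = predict_band(model, 7.0, kind="prediction")
        efn = yhat if matched else yhat + 20 * (hi - yhat)
        return classify_matching(_pop(pid, efn=efn, size=7.0), size_model=model)

    def _base_cohort(self):
        rows = []
        for i in range(9):
            rows.append((f"p{i}", 7.0, 30.0, 10.0 + i, 0.3 + 0.02 * i, 0.1, 0.4, 1.0))
        return _cohort(rows)

    def test_mismatched_cannot_be_hotspot(self):
        res = classify_hotspot(
            _pop("p0", relative_leaf_production=9.9, prop_flowering=1.0, seedling_density=9.9,
                 herbivory=0.0),
            self._matched_result("p0", matched=False),
            self._base_cohort(),
            {},
        )
        assert res.label == "coldspot-mismatched"

    def test_hotspot_requires_all_criteria(self):
        cohort = self._base_cohort()
        good = _pop(
            "p0",
            herbivory=0.05,
            relative_leaf_production=0.5,
            prop_flowering=0.9,
            seedling_density=5.0,
            var_efn=5.0,
        )
        res = classify_hotspot(good, self._matched_result("p0"), cohort, {})
        assert res.label == "hotspot"
        assert res.criteria["matched"] and res.criteria["herbivory_below_median"]
        # same population with herbivory above the cohort median: coldspot
        bad = dataclasses.replace(good, herbivory=0.9)
        res2 = classify_hotspot(bad, self._matched_result("p0"), cohort, {})
        assert res2.label == "coldspot-matched"
        assert not res2.criteria["herbivory_below_median"]

    def test_variance_letter_gate(self):
        cohort = self._base_cohort()  # narrowest variance population is p0
        good = _pop("p1", herbivory=0.0, relative_leaf_production=0.5, prop_flowering=0.9,
                    seedling_density=5.0)
        letters = {"p0": "a", "p1": "b"}  # p1 significantly wider than the narrowest
        res = classify_hotspot(good, self._matched_result("p1"), cohort, letters)
        assert res.label == "coldspot-matched"
        assert not res.criteria["variance_narrow_group"]
        letters_shared = {"p0": "a", "p1": "ab"}
        res2 = classify_hotspot(good, self._matched_result("p1"), cohort, letters_shared)
        assert res2.label == "hotspot"

    def test_identical_cohort_has_no_hotspots(self):
        rows = [(f"p{i}", 7.0, 30.0, 10.0, 0.3, 0.1, 0.4, 1.0) for i in range(6)]
        cohort = _cohort(rows)
        pop = _pop("p0", herbivory=0.3, relative_leaf_production=0.1, prop_flowering=0.4,
                   seedling_density=1.0)
        res = classify_hotspot(pop, self._matched_result("p0"), cohort, {})
        assert res.label == "coldspot-matched"  # strict exceedance fails on ties

    def test_hotspot_invariant_enforced(self):
        with pytest.raises(ValueError):
            HotspotResult("p0", "hotspot", {"matched": False})

    def test_performance_monotonicity(self, rng):
        # raising a matched population's performance can never demote hotspot
        for _ in range(30):
            rows = [
                (
                    f"p{i}",
                    7.0,
                    30.0,
                    float(rng.uniform(5, 30)),
                    float(rng.uniform(0.1, 0.6)),
                    float(rng.uniform(-0.3, 0.5)),
                    float(rng.uniform(0, 1)),
                    float(rng.uniform(0, 4)),
                )
                for i in range(8)
            ]
            cohort = _cohort(rows)
            row = rows[0]
            pop = _pop(
                "p0",
                herbivory=row[4],
                relative_leaf_production=row[5],
                prop_flowering=row[6],
                seedling_density=row[7],
                var_efn=row[3],
            )
            m = self._matched_result("p0")
            before = classify_hotspot(pop, m, cohort, {}).label
            boosted = dataclasses.replace(
                pop,
                relative_leaf_production=pop.relative_leaf_production + 1.0,
                prop_flowering=min(pop.prop_flowering + 0.3, 1.0),
                seedling_density=pop.seedling_density + 2.0,
            )
            rows2 = [(
                "p0", 7.0, 30.0, row[3], row[4],
                boosted.relative_leaf_production, boosted.prop_flowering, boosted.seedling_density,
            )] + rows[1:]
            after = classify_hotspot(boosted, m, _cohort(rows2), {}).label
            assert not (before == "hotspot" and after == "coldspot-matched")


class TestCohortClassification:
    def test_order_invariance(self):
        model = _model()
        pops = [
            _pop(f"p{i}", efn=float(10 + 5 * i), size=float(5 + 0.5 * i), var_efn=float(5 + i))
            for i in range(6)
        ]
        a = classify_cohort(pops, model, None, {})
        b = classify_cohort(list(reversed(pops)), model, None, {})
        pd.testing.assert_frame_equal(a, b)

    def test_ground_truth_recovery_single_survey(self, default_survey, default_results):
        cls = default_results["classification"].set_index("population_id")
        gt = default_survey.ground_truth.populations
        correct = sum(
            cls.loc[p, "label"] == ("matched" if d["matched"] else "mismatched")
            for p, d in gt.items()
        )
        assert correct >= 9
        for p in cls.index[cls["hotspot_label"] == "hotspot"]:
            assert cls.loc[p, "label"] == "matched"
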