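import dataclasses

import numpy as np
import pandas as pd
import pytest

from antmosaic import PipelineConfig, ScenarioConfig, generate_survey
from antmosaic.simulate import generate_species_pool


@pytest.fixture(scope="session")
def default_survey():
    """One default synthetic survey, shared across read-only tests."""
    return generate_survey(dataclasses.replace(ScenarioConfig(), seed=11))


@pytest.fixture(scope="session")
def default_results(default_survey):
    from antmosaic import analyze_survey

    return analyze_survey(
        default_survey.tables, PipelineConfig(seed=11, compute_similarity=False)
    )


@pytest.fixture()
def species_pool():
    return generate_species_pool(ScenarioConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_tables():
    """Hand-built minimal survey tables for trait-aggregation tests.

    Two populations, four plants, three ant species; plant phenotypes chosen
    so every mean is hand-checkable.
    """
    plants = pd.DataFrame(
        {
            "population_id": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "plant_id": ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"],
            "census": ["t0", "t1"] * 4,
            "n_leaves": [100, 100, 50, 50, 200, 100, 100, 100],
            "flowering": [0, 1, 0, 0, 0, 1, 0, 1],
            "n_seedlings_2m": [0, 2, 0, 0, 0, 4, 0, 0],
        }
    )
    ant_obs = pd.DataFrame(
        {
            "plant_id": ["p1", "p1", "p2", "p3", "p4", "p4"],
            "census": ["t0", "t1", "t0", "t0", "t0", "t1"],
            "species": ["antA", "antA", "antB", "antA", "antB", "antC"],
            "count": [5, 3, 4, 8, 2, 6],
        }
    )
    ant_species = pd.DataFrame(
        {"species": ["antA", "antB", "antC"], "body_length_mm": [4.0, 8.0, 6.0]}
    )
    plant_pheno = pd.DataFrame(
        {
            "plant_id": ["p1", "p2", "p3", "p4"],
            "plant_efn": [10.0, 20.0, 30.0, 40.0],
            "plant_herbivory": [0.1, 0.2, 0.3, 0.4],
        }
    )
    return plants, ant_obs, ant_species, plant_pheno
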